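"""Numba kernels for the hot loops: the fused state update and Hebbian
plasticity.

Synapses of the whole network (within- and between-area alike) live in one
flat structure-of-arrays, sorted by presynaptic cell (CSR-like), with a
secondary ordering by postsynaptic cell for the heterosynaptic LTD pass.
Both kernels only touch synapses adjacent to active cells, keeping the
per-step cost proportional to network activity rather than synapse count.
"""

from __future__ import annotations

import numba as nb
import numpy as np


@nb.njit(cache=True)
def step_core(indptr_pre, syn_post, syn_w, out, new_out, exc,
              potential, adaptation, i_potential, global_inh,
              pool_idx, noise_e, noise_i, ext,
              tau_e, tau_i, tau_adapt, tau_global, adapt_strength,
              theta, k_local, k_global, n_cells, n_areas):
    """One synchronous network step; all inputs read the previous outputs.

    Returns the flat index of the first non-finite potential, or -1.
    """
    n = potential.size
    for i in range(n):
        exc[i] = 0.0
    for p in range(n):
        o = out[p]
        if o > 0.0:
            for s in range(indptr_pre[p], indptr_pre[p + 1]):
                exc[syn_post[s]] += o * syn_w[s]
    bad = -1
    n_pool = pool_idx.shape[1]
    for a in range(n_areas):
        base = a * n_cells
        g_old = global_inh[a]
        tot = 0.0
        for j in range(n_cells):
            tot += out[base + j]
        for j in range(n_cells):
            idx = base + j
            vi_old = i_potential[idx]
            pool = noise_i[idx]
            for k in range(n_pool):
                pool += out[base + pool_idx[j, k]]
            if pool < 0.0:
                pool = 0.0
            i_potential[idx] = vi_old + (pool - vi_old) / tau_i
            total = (exc[idx] + ext[idx] + noise_e[idx]
                     - k_local * vi_old - k_global * g_old)
            v = potential[idx] + (total - potential[idx]) / tau_e
            potential[idx] = v
            ad = adaptation[idx]
            ad += (adapt_strength * out[idx] - ad) / tau_adapt
            adaptation[idx] = ad
            o = v - ad - theta
            if o < 0.0:
                o = 0.0
            elif o > 1.0:
                o = 1.0
            new_out[idx] = o
            if not np.isfinite(v) and bad < 0:
                bad = idx
        global_inh[a] = g_old + (tot - g_old) / tau_global
    return bad


@nb.njit(cache=True)
def hebbian(indptr_pre, syn_post, syn_w, indptr_post, syn_order, syn_pre,
            out, pre_thr, post_thr, ltp, ltd, ltd_hetero, w_max):
    """Threshold Hebbian rule on all e->e synapses, in place.

    LTP when both pre- and postsynaptic outputs exceed their thresholds;
    LTD when exactly one does (pre-only: ltd; post-only: ltd_hetero);
    no change when neither does.  Weights are clamped to [0, w_max].
    """
    n = out.size
    for p in range(n):
        if out[p] > pre_thr:
            for s in range(indptr_pre[p], indptr_pre[p + 1]):
                if out[syn_post[s]] > post_thr:
                    w = syn_w[s] + ltp
                    if w > w_max:
                        w = w_max
                else:
                    w = syn_w[s] - ltd
                    if w < 0.0:
                        w = 0.0
                syn_w[s] = w
    for q in range(n):
        if out[q] > post_thr:
            for k in range(indptr_post[q], indptr_post[q + 1]):
                s = syn_order[k]
                if not (out[syn_pre[s]] > pre_thr):
                    w = syn_w[s] - ltd_hetero
                    if w < 0.0:
                        w = 0.0
                    syn_w[s] = w
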