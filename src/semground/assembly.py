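"""Cell-assembly extraction and sharedness analysis.

An excitatory cell belongs to the cell assembly (CA) of a grounding
pattern if, on at least two recorded time steps, its firing rate exceeds
75% of the rate of the maximally responsive cell of its area (provided
that maximum is at least 0.01; otherwise the area contributes no members).

For each concept the three instance-CAs are overlaid per area and every
member neuron is assigned a *sharedness* level: the number of instance-CAs
(1, 2 or 3) containing it.  Neurons at sharedness >= 2 are the "shared"
(semantic) neurons; level-1 neurons are unique/idiosyncratic.  From the
resulting table come the headline quantities: CA sizes per area, counts by
sharedness, the percent change of shared-neuron counts from primary
(V1, M1L) to central (AT, PFL) extra-sylvian areas, and the proportion of
shared neurons in each concept's union CA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from semground.architecture import AREA_NAMES, area, areas_by
from semground.network import SimulationTrace

CA_MIN_RATE = 0.01       # floor on the per-area maximum rate
CA_FRACTION = 0.75       # membership threshold, fraction of the area maximum
CA_MIN_STEPS = 2         # steps on which the threshold must be exceeded

PRIMARY_EXTRA = ("V1", "M1L")
CENTRAL_EXTRA = ("AT", "PFL")


@dataclass(frozen=True)
class CellAssembly:
    """Per-area member sets of one grounding pattern's CA circuit."""

    concept_id: int
    instance_index: int
    members_per_area: dict[str, frozenset[int]]

    def size(self, area_name: str) -> int:
        return len(self.members_per_area.get(area_name, frozenset()))


def extract_ca(trace: SimulationTrace, *,
               min_rate: float = CA_MIN_RATE,
               fraction: float = CA_FRACTION,
               min_steps: int = CA_MIN_STEPS) -> CellAssembly:
    """Apply the CA membership criterion to one test trace, per area."""
    out = trace.output
    if out.ndim != 3 or out.shape[1] != len(AREA_NAMES):
        raise ValueError(f"malformed trace: shape {out.shape}")
    members: dict[str, frozenset[int]] = {}
    for ai, name in enumerate(AREA_NAMES):
        arr = out[:, ai, :]
        peak = float(arr.max())
        if peak < min_rate:
            members[name] = frozenset()
            continue
        above = (arr > fraction * peak).sum(axis=0)
        members[name] = frozenset(np.nonzero(above >= min_steps)[0].tolist())
    return CellAssembly(trace.concept_id, trace.instance_index, members)


def ca_size_frame(cas_by_subject: dict[tuple[int, str], list[CellAssembly]]
                  ) -> pd.DataFrame:
    """Long frame of instance-CA sizes.

    ``cas_by_subject`` maps (subject_id, semantic_type) to that model's
    CAs (one per pattern).
    """
    rows = []
    for (sid, stype), cas in cas_by_subject.items():
        for ca in cas:
            for name in AREA_NAMES:
                rows.append((sid, stype, ca.concept_id, ca.instance_index,
                             name, ca.size(name)))
    return pd.DataFrame(rows, columns=[
        "subject_id", "semantic_type", "concept_id", "instance", "area",
        "size"])


def _ci95_half_width(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        return 0.0
    sem = x.std(ddof=1) / np.sqrt(n)
    return float(scipy.stats.t.ppf(0.975, n - 1) * sem)


def instance_ca_sizes(frame: pd.DataFrame, grouping: str = "area"
                      ) -> pd.DataFrame:
    """Mean instance-CA size per semantic type and area (or centrality).

    Sizes are first averaged within subject, then the grand mean and the
    95% CI across subjects are reported.
    """
    if grouping == "area":
        frame = frame.copy()
        group_col = "area"
    elif grouping == "centrality":
        frame = frame.copy()
        frame["centrality"] = [area(a).centrality for a in frame["area"]]
        group_col = "centrality"
    else:
        raise ValueError(f"unknown grouping: {grouping!r}")
    per_subject = (frame.groupby(
        ["semantic_type", group_col, "subject_id"])["size"]
        .mean().reset_index())
    agg = (per_subject.groupby(["semantic_type", group_col])["size"]
           .agg(mean="mean", ci95=_ci95_half_width, n_subjects="count")
           .reset_index())
    return agg


def sharedness_counts(cas: list[CellAssembly]) -> pd.DataFrame:
    """Sharedness table rows for the three instance-CAs of one concept.

    Per area, every neuron in the union of the three member sets is
    assigned sharedness = number of instance-CAs containing it.
    Returns columns (concept_id, area, sharedness, count); all three
    levels are present (zero counts included).
    """
    if len(cas) != 3:
        raise ValueError(f"expected exactly 3 instance-CAs, got {len(cas)}")
    if len({ca.concept_id for ca in cas}) != 1:
        raise ValueError("instance-CAs belong to different concepts")
    cid = cas[0].concept_id
    rows = []
    for name in AREA_NAMES:
        sets = [ca.members_per_area.get(name, frozenset()) for ca in cas]
        level: dict[int, int] = {1: 0, 2: 0, 3: 0}
        for cell in sets[0] | sets[1] | sets[2]:
            level[sum(cell in s for s in sets)] += 1
        for sh in (1, 2, 3):
            rows.append((cid, name, sh, level[sh]))
    return pd.DataFrame(rows, columns=["concept_id", "area", "sharedness",
                                       "count"])


def sharedness_table(cas_by_subject: dict[tuple[int, str], list[CellAssembly]]
                     ) -> pd.DataFrame:
    """Full sharedness table across subjects, types, concepts and areas."""
    frames = []
    for (sid, stype), cas in cas_by_subject.items():
        by_concept: dict[int, list[CellAssembly]] = {}
        for ca in cas:
            by_concept.setdefault(ca.concept_id, []).append(ca)
        for cid, group in sorted(by_concept.items()):
            sub = sharedness_counts(
                sorted(group, key=lambda c: c.instance_index))
            sub.insert(0, "semantic_type", stype)
            sub.insert(0, "subject_id", sid)
            frames.append(sub)
    return pd.concat(frames, ignore_index=True)


def percent_change_shared(table: pd.DataFrame) -> pd.DataFrame:
    """Percent change of shared-neuron counts, primary -> central.

    For each subject x semantic type x concept, the number of shared
    neurons (sharedness >= 2) is summed over the primary extra-sylvian
    areas (V1, M1L) as baseline and over the central ones (AT, PFL);
    the change is 100 * (central - primary) / primary.  Concepts with a
    zero baseline are excluded with a warning.  Values are averaged over
    concepts within subject; the output has one row per subject x type.
    """
    shared = table[table["sharedness"] >= 2]
    rows = []
    for (sid, stype, cid), grp in shared.groupby(
            ["subject_id", "semantic_type", "concept_id"]):
        primary = grp.loc[grp["area"].isin(PRIMARY_EXTRA), "count"].sum()
        central = grp.loc[grp["area"].isin(CENTRAL_EXTRA), "count"].sum()
        if primary == 0:
            warnings.warn(
                f"zero primary-area shared count for subject {sid} "
                f"({stype}, concept {cid}); concept excluded")
            continue
        rows.append((sid, stype, cid,
                     100.0 * (central - primary) / primary))
    per_concept = pd.DataFrame(rows, columns=[
        "subject_id", "semantic_type", "concept_id", "percent_change"])
    return (per_concept.groupby(["subject_id", "semantic_type"])
            ["percent_change"].mean().reset_index())


def proportion_shared(table: pd.DataFrame) -> pd.DataFrame:
    """Proportion of shared neurons in each concept x area union CA.

    (# neurons at sharedness >= 2) / (# neurons in the union of the three
    instance-CAs); empty unions are excluded with a warning.  Returns one
    row per subject x semantic type x concept x area, restricted to the
    six extra-sylvian areas.
    """
    extra = areas_by(system="extra-sylvian")
    sub = table[table["area"].isin(extra)]
    rows = []
    for (sid, stype, cid, name), grp in sub.groupby(
            ["subject_id", "semantic_type", "concept_id", "area"]):
        union = grp["count"].sum()
        if union == 0:
            warnings.warn(
                f"empty union CA for subject {sid} ({stype}, concept {cid}, "
                f"area {name})")
            continue
        shared = grp.loc[grp["sharedness"] >= 2, "count"].sum()
        rows.append((sid, stype, cid, name, shared / union))
    return pd.DataFrame(rows, columns=[
        "subject_id", "semantic_type", "concept_id", "area", "proportion"])


def cas_from_result(result) -> dict[tuple[int, str], list[CellAssembly]]:
    """Extract all CAs from an ExperimentResult, keyed by (subject,
    condition)."""
    out = {}
    for (sid, cond), sc in result.data.items():
        out[(sid, cond)] = [extract_ca(t) for t in sc.traces]
    return out


def ca_archive_frame(cas_by_subject: dict[tuple[int, str],
                                          list[CellAssembly]]) -> pd.DataFrame:
    """Plain-text-ready CA archive: one row per CA x area with sorted
    member indices."""
    rows = []
    for (sid, stype), cas in cas_by_subject.items():
        for ca in cas:
            for name in AREA_NAMES:
                members = ",".join(
                    map(str, sorted(ca.members_per_area.get(name, ()))))
                rows.append((sid, stype, ca.concept_id, ca.instance_index,
                             name, members))
    return pd.DataFrame(rows, columns=[
        "subject_id", "semantic_type", "concept_id", "instance", "area",
        "members"])
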