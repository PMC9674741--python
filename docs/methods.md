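# Methods

`semground` simulates how distributed cortical cell assemblies (CAs) form
when a brain-constrained multi-area network repeatedly experiences the
sensorimotor instances of concrete and abstract concepts, and quantifies
how "semantic" (shared) neurons distribute across the network afterwards.

## Network model

**Architecture.** Twelve areas model four processing streams: auditory
(A1 → AB → PB) and articulatory (M1i → PMi → PFi) in peri-sylvian cortex,
visual (V1 → TO → AT) and dorsal-motor (M1L → PML → PFL) extra-sylvian.
Each stream runs from a primary area through a secondary area into a
multimodal connector hub; the four hubs (PB, PFi, AT, PFL) are linked
all-to-all by long-distance connections. Within each stream there are
next-neighbour links between adjacent areas and one "jumping" link from
primary to central area, giving 8 + 4 + 6 = 18 reciprocal between-area
pathways.

Each area is a 25 × 25 sheet of excitatory graded-rate cells (one
inhibitory cell under each). Excitatory links are sparse and random with
a truncated-Gaussian neighbourhood bias, restricted to a 19 × 19 window;
the grid is toroidal so every cell has a complete neighbourhood (the
alternative — absorbing edges — creates boundary artefacts the analysis
would then have to exclude).

**Cell dynamics.** Per time step (synchronous update; all terms read the
previous step's outputs):

```
V   <- V + (input - V) / tau_e            input = recurrent + external + noise
                                                   - k_local * Vi - k_global * G
A   <- A + (a * O - A) / tau_adapt        subtractive adaptation
O    = clip(V - A - theta, 0, 1)          graded output (firing rate)
Vi  <- Vi + (pool5x5(O) - Vi) / tau_i     local lateral inhibition
G   <- G + (sum_area(O) - G) / tau_global slow area-level regulation
```

The output is a deterministic piecewise-linear rate; the stochasticity of
threshold spiking is carried by the white noise added to every cell's
input at every step. Choosing a graded rate rather than binary spikes
keeps the CA membership criterion (a firing-rate criterion) natural and
the dynamics cheap.

**Plasticity.** Every excitatory→excitatory synapse follows a threshold
Hebbian rule evaluated on pre- and postsynaptic output: LTP (+`ltp`) when
both exceed their thresholds, LTD when exactly one does, no change
otherwise; weights are clamped to [0, `w_max`]. The two LTD cases carry
separate magnitudes: homosynaptic (pre active, post silent; `ltd`) and
heterosynaptic (post active, pre silent; `ltd_hetero`, stronger by
default). The heterosynaptic component is the instance-separation force:
a cell that fires inside an assembly while some of its presynaptic
partners stay silent sheds those out-of-assembly links. For an abstract
concept this hits exactly the pairwise-overlap pathways on the third
instance's trials (whose pair inputs are then silent), preventing the
i1·i2 / i1·i3 / i2·i3 chain from fusing all three instance assemblies
into one merged concept attractor — while the shared-by-all core of a
concrete concept is active on every trial of its concept and is never
eroded.

## Key parameter choices

All constants live in `SimConfig` / `data/default_config.yaml` (units:
time constants in simulation steps, weights unitless in [0, w_max]).
Three choices carry the mechanism and deserve explanation:

* **Initial weights, within vs between** (`w_init_max_within = 0.01`,
  `w_init_max_between = 0.45`, uniform on (0, max]): within-area
  recurrence must start far below the ignition gain (≈ 50 links/cell;
  stronger initial values make the naive network epileptic), while
  between-area links must deliver a feed-forward signal that individual
  driven cells can distinguish from the noise floor, otherwise Hebbian
  selection has no gradient to climb. Between-area wiring is therefore
  sparse but individually strong (`between_density = 0.08`,
  `between_sigma = 3`: ≈ 4–5 links per cell per pathway). Both bounds
  stay well below `w_max = 1`.
* **LTP ≫ LTD** (`ltp = 0.004`, `ltd = 0.0002`,
  `ltd_hetero = 0.0006`): a pattern is presented on only 1/30 of trials,
  while LTD can hit a synapse on every trial in which one of its ends
  fires alone. The large LTP:LTD ratio makes stimulus-coincident
  potentiation win for correlated pairs while uncorrelated background
  weights still decay (their LTP expectation is quadratic in the noise
  firing probability, their LTD linear). The heterosynaptic magnitude is
  set ~3× the homosynaptic one; weaker values let abstract instance
  assemblies merge (see Plasticity above), much stronger ones erode
  legitimate recruitment and shrink all assemblies.
* **Global inhibition** (`k_global = 0.07`, `tau_global = 8`): the slow
  area-level signal is the winner-take-all force that keeps ignitions to
  a few dozen cells per area and sets the equilibrium assembly size.
  Together with heterosynaptic LTD it determines whether the three
  instance assemblies of one concept stay distinct: too little
  competition and assemblies balloon, too much and none form.

The ISI criterion monitors global inhibition in A1 and PB. Because A1
receives continuous input noise during training, its inhibition
equilibrates near 16; `isi_threshold = 18` sits just above that
equilibrium, so an ISI ends as soon as stimulus-driven activity (which
pushes the monitored signal higher) has decayed back to the noise
baseline.

## Grounding patterns (synthetic data)

Each concept is a grounding set of three instance patterns, 12 active
cells per pattern in each stimulated area (V1, M1L), instantiated
independently per area, drawn uniformly from the area's free pool, with
no overlap between concepts:

* concrete: 6 cells shared by all three instances + 6 unique per
  instance (24 distinct per area; 18 shared-cell activations per cycle);
* abstract: 4 cells per instance pair, pairwise overlaps disjoint,
  triple intersection empty, + 4 unique per instance (24 distinct;
  24 shared-cell activations per cycle).

Both types are matched on cells per pattern (12) and distinct cells per
set (24). A full inventory holds 10 concepts (30 patterns, 240 cells per
area).

## Protocol

Training presents a uniformly chosen not-yet-exhausted pattern to V1 and
M1L for 16 steps (learning on, extra input noise to A1/M1i), followed by
a noise-only ISI (input noise to all four primary areas) gated by the
inhibition criterion, until every pattern has run `reps_per_pattern`
times. Per subject, one wiring is cloned and trained separately on a
concrete and an abstract inventory (within-subject design); an optional
control condition re-trains the concrete inventory at half the
repetitions. Testing resets the network, stimulates each pattern for 2
noise-free steps, and records all 12 areas for 30 steps with learning
off.

A cell joins a pattern's CA if its rate exceeds 75 % of the area's
maximally responsive cell (strict inequality) on at least 2 recorded
steps, provided that maximum is at least 0.01. The per-area maximum is
taken over the whole 30-step window, as a single scalar. Sharedness of a
neuron is the number of instance-CAs of its concept that contain it
(1–3); "shared/semantic" means ≥ 2. Percent change of shared neurons
uses the summed counts in V1+M1L as baseline and AT+PFL as central
value, averaged concept → subject. Statistics are within-subject ANOVAs
(statsmodels AnovaRM, uncorrected dfs) and Bonferroni-corrected paired
t-tests at base α = 0.01; 95 % CIs are t-based across subject means.

## Scaled presets and what they show

The full design (12 subjects × 2 types × 30 patterns × 4000
presentations) runs for hours on one CPU (preset `full`). The shipped
`desk` preset (2 subjects, 4 concepts, 400 presentations per pattern,
control at 200) finishes in minutes and is the scale at which the test
suite and the acceptance script operate. At this scale the qualitative
dissociation — shared-neuron counts increasing from primary to central
areas for concrete concepts, decreasing for abstract ones, with no CAs
in the noise-driven A1/M1i — is reproduced in subject-averaged form;
individual subjects are noisy, and the printed full-scale effect sizes
(+42.3 % / −21.1 % with sub-percent SEMs) should not be expected from a
desk run. The `smoke` preset only exercises plumbing.

The generator emulates the designed overlap structure exactly; what it
does not emulate is any within-instance variability, graded feature
salience, or spatial structure of real perceptual patterns — passing
tests therefore demonstrate the mechanism under the idealized pattern
geometry, not robustness to realistic input statistics.

## Numerical choices and degenerate inputs

Synchronous updates and one master seed with spawned substreams (wiring,
patterns, per-condition noise and pattern order) make every run bit-
reproducible. NaN/Inf in any membrane potential aborts the step with the
area and step index. Ties at exactly the 75 % criterion are excluded
(strict inequality). Concepts with a zero primary-area shared count are
excluded from percent change with a warning; empty union CAs likewise
for the proportion measure. Checkpoints store the flat synapse arrays,
state vectors, config snapshot and RNG state and restore bit-identically.

## Known limitations

* Graded-rate cells; no refractoriness, conduction delays or
  spike-timing plasticity.
* The instance/concept attractor separation depends on the inhibition
  calibration; far outside the shipped parameter band the abstract
  condition can merge instance assemblies (over-sharing) or fail to form
  assemblies at all.
* Small desk-scale designs give noisy per-subject percent changes; only
  subject means are meaningful there. Likewise, while the shared-neuron
  *counts* dissociate reliably at desk scale (and the concrete-vs-
  abstract crossover of the shared *proportion* between primary and
  central areas holds), the within-abstract U-shape of the proportion
  measure need not appear at that scale.
* No verbal-label (peri-sylvian pattern) learning: A1/M1i receive only
  uncorrelated noise, deliberately.
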