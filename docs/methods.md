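# Methods

## The model

### Neurons

All cells are two-variable Izhikevich point neurons,

    v' = 0.04 v^2 + 5 v + 140 − u + I,      u' = a (b v − u),

with a spike cutoff at v = 30 mV and reset v ← c, u ← u + d.  Excitatory
cells are regular-spiking (RS: a=0.02, b=0.2, c=−65, d=8), inhibitory cells
fast-spiking (FS: a=0.1, b=0.2, c=−65, d=2).  Integration uses two 0.5 ms
forward-Euler substeps for v and one 1 ms step for u per tick, with the
cutoff checked after each substep; input for a tick is held constant across
its substeps.  This scheme follows the widely used reference network
simulator for this neuron model, and all timing in the package is on a 1 ms
grid.

RS cells are integrators: with the recovery variable at rest the membrane
has a stable fixed point near −70 mV and an unstable one near −55 mV, so a
just-suprathreshold volley parks v barely above the saddle and the spike
escapes only after a long drift — *spike latency*.  Stronger input fires
earlier.  This property carries several of the package's mechanistic demos.

### Network

1000 cells (800 RS, 200 FS).  Every cell sends exactly 100 connections to
distinct targets (no self-connections; target sampling without
replacement); inhibitory cells project to excitatory cells only.
Excitatory connections: uniform integer delays 1–20 ms, initial weight
+3.0 mV, plastic, hard-clipped to [0, 10] mV.  Inhibitory connections:
delay 1 ms, fixed weight −2.0 mV.  Spikes deliver their weight to the
post-synaptic input exactly `delay` ms after firing; simultaneous arrivals
sum linearly.

### STDP and the synaptic derivative

Pairing uses exponential traces (τ₊ = τ₋ = 20 ms) with reset-on-spike
(nearest-event) semantics.  A post-synaptic spike at time t potentiates
each plastic afferent by A₊·exp(−Δ/τ₊), where Δ is the time since the
pre-synaptic spike *arrived* (spike time + delay) — conduction delays are
therefore part of the pairing rule.  A pre-synaptic arrival Δ ms after the
last post-synaptic spike depresses the synapse by 1.2·A₋·exp(−Δ/τ₋).
Baselines are A₊ = 0.1 and A₋ = 0.12; the extra 1.2 factor on depression is
inherited from the reference simulator's depression step and gives the net
LTD bias (effective 0.144 vs 0.1) that prunes unused synapses during
maturation.  It is a config knob (`StdpParams.ltd_scale`).  A pre arrival
and post spike in the same tick (Δ = 0) count as full potentiation and no
depression; arrivals are processed before integration each tick, so the
tie-break is deterministic.

Pending changes accumulate in a per-synapse *derivative* — the synaptic
drive signal.  Once per second each plastic weight moves by
`drift + derivative` (drift = +0.01 mV), is clipped to [0, w_max], and the
derivative is scaled by 0.9.  The retained, decaying derivative makes the
drive an exponentially weighted history of recent pairing consistency.

### Metaplasticity

Each plastic synapse is scored by the weighting function

    f(d, w) = r·e^{p·map(d)}·(w − min) − r·e^{p·(10 − map(d))}·(max − w),

with map(d) = clip(0.5·(d + 10), 0, 10) taking the derivative's normal
±10 range onto 0–10.  f is near zero over the central (drive, weight)
region and rises exponentially in the two opposing corners: it resists
potentiation of strongly driven large weights and depression of negatively
driven small weights.  Per post-synaptic cell, the modification threshold
averages f over the plastic afferents,

    θ = tanh(I · mean_i f(d_i, w_i)),     θ ∈ (−1, 1),

and scales the STDP amplitudes in direct proportion:
A_LTP = A₊·(1 − θ), A_LTD = A₋·(1 + θ).  Positive θ makes potentiation
harder and depression easier; the symmetry keeps
A_LTP/A₊ + A_LTD/A₋ = 2.  θ and the amplitudes are recomputed at every
one-second update, immediately before weights are applied, and hold for the
next second; the cadence is configurable.  θ is maintained for every cell
with at least one plastic afferent (including inhibitory cells, which
receive plastic excitatory synapses); a cell with none keeps θ = 0.

Defaults: network runs use r = 0.1, p = 0.5, I = 0.2, soft limits 0–10 mV;
the single-synapse demo uses p = 0.05 with soft limits 0–15 mV matching its
15 mV cap.  With r = 0 the weighting function vanishes identically and a
run is bit-for-bit identical to metaplasticity disabled (a tested
invariant).

## Experimental protocol

Three phases on each network, each driven by seeded, reproducible input:

1. **Maturation** — 1 Hz independent Poisson background per cell (each
   event a 20 mV pulse), STDP on, metaplasticity off.  Weights bimodalise;
   with the depression bias the census settles prune-heavy at ~3.5 Hz
   firing.
2. **Training** — the *ascending pattern* (40 forced firing events, one per
   cell at offsets 1–40 ms) repeated at 5 Hz over 1 Hz background, STDP on,
   metaplasticity per experimental arm.
3. **Probing** — the same pattern at 4 Hz (250 ms frames) with 1 Hz
   background and all plasticity frozen.

Pattern events are forced spikes, so pattern cells fire at exactly their
offsets every frame.  The paired experiment matures each network once and
runs both arms (metaplasticity on/off) from the same matured snapshot with
identical input seeds, so arm differences are attributable to the
metaplastic modulation alone.

Measurements per arm: PNG size (below), the exact three-way weight census
(pruned = 0, saturated = w_max, other), the excitatory firing rate over the
last 10 s of training, and the connection-activation partition.

## Analyses

**Response fingerprint / PNG size.**  Per neuron, a peri-stimulus histogram
over probe frames at 1 ms bins counts, per bin, the fraction of frames with
at least one spike.  Maximal runs of bins above a low floor (0.25), merged
across gaps of ≤ 1 ms, form candidate windows; a window is kept iff the
fraction of frames with a spike anywhere inside it reaches the consistency
threshold (0.75).  PNG size is the number of distinct neurons with at least
one window.  The floor and merge gap are assumptions isolated behind
config; the probing default is 400 frames at 4 Hz (100 s).  Raising the
threshold can only shrink the PNG (tested), and a planted polychronous
chain over 400 frames with 1 Hz noise is recovered exactly at 0.75.

**Connection activation.**  A connection is *active* if the raster contains
a pre-spike at t₁ and a post-spike at t₂ with
delay ≤ t₂ − t₁ ≤ delay + jitter (jitter 2 ms).  The implementation is
checked against a brute-force double loop on random rasters.  Over long
rasters chance pairs eventually satisfy the rule for nearly every
connection, so the experiment fits the partition over the first second of
probing (configurable, `RunConfig.partition_s`).

**Input space response.**  For the six-cell circuit, the firing times of
the three input cells are varied over 0–20 ms; each combination is one
independent 250 ms frame from a fresh state.  Results are reported in
difference coordinates (t1−t2, t2−t3), which removes translated
duplicates; cells with |dt12 + dt23| > 20 are not realisable inside the
timing range and are excluded.  Without background noise a frame is
deterministic, so the 100-of-400-trials consistency criterion reduces to a
single frame per grid cell; a `noise_hz` option restores genuine trial
counting.  The latency-optimisation sweep trials ten 1 mV weight steps
(1–10 mV) on the 0→3 connection and marks a cell active if any step fires
the target.

## Problem sizes and defaults

The paired experiment defaults to desk scale: 5 networks, 20 min
maturation, 180 s training per arm, 100 s probing (about 3.5 min wall on
one CPU with the compiled engine); the full protocol (20 networks, 2 h
maturation) is the same code with bigger numbers in `RunConfig`.  The demo
circuits run in seconds.  The engine is a single numba kernel advancing
1 ms ticks; a run is a pure, deterministic function of the initial state
and the event stream, snapshots capture the full dynamic state for
bit-exact resume, and a runaway guard (mean network rate > 100 Hz over a
second, off for toy circuits) aborts parameter errors with diagnostics.

## Design choices on open points

- **Single-synapse drive schedule.**  The two-cell regulation demo drives
  both cells with two bursts per second of six forced spike pairs, 15 ms
  between pulses, the pre-synaptic spike leading by 5 ms.  The burst
  spacing is a free parameter (exposed); this setting produces clean,
  sustained positive drive: without metaplasticity the weight saturates at
  the 15 mV cap within ~13 s, with metaplasticity it oscillates between
  ~7 and ~12 mV and never caps.
- **Latency sweep geometry.**  The spike-latency demo uses delays
  (10, 10, 13) ms with base weights (8, 8, 0.8) stepped together so that
  the 17 mV lower end of the combined-weight sweep is barely
  suprathreshold; the output then fires at 22 ms at 17 mV, declining
  monotonically to 12 ms at 30 mV.
- **Pattern cells** default to the 40 lowest excitatory indices.

## Known limitations

- At the network defaults (r = 0.1, p = 0.5, I = 0.2), the mean of f over
  a prune-heavy weight distribution is strongly negative (the weight terms
  scale like e^{5p}·(2·w̄ − 10)), so θ settles around −0.3 to −0.5 for most
  cells during training.  The resulting sustained LTP boost drives the
  weight distribution toward the soft-limit midpoint far more aggressively
  than the gentle shifts the threshold is meant to produce, raises firing
  rates, and degrades stimulus-locked timing, shrinking the measured PNG
  rather than enlarging it.  Damping the threshold gain restores mild
  behaviour (and a PNG increase) but weakens the census shifts.  The
  single-synapse regulation results are unaffected.  See the acceptance
  suite: the paired-experiment PNG-size direction is asserted and currently
  fails under the stated parameters.
- The Poisson background is sampled as the population-level superposition
  of the per-cell processes (distributionally identical, much faster); the
  per-cell streams are therefore not individually seeded.
- Synthetic inputs only: the generator emulates Poisson background and
  noise-free repeating stimuli.  It does not emulate correlated background,
  stimulus jitter, or conduction-delay variability, so passing tests bound
  behaviour under idealised drive, not under in-vivo-like input statistics.
- Sub-millisecond timing, conductance-based synapses and other Izhikevich
  cell classes are out of scope.
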