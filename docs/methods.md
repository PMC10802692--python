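# Methods

This note documents the scientific and numerical choices behind
`patchywave`: the network model and its operating point, the LFP proxy,
the wave/motif pipeline conventions, the feature-selective analyses, the
synthetic-data generator, and the reduced-scale study protocol. It states
what the defaults are and why; every empirical number quoted here is
produced by the test suite or `scripts/acceptance.py`.

## Network model

Conductance-based leaky integrate-and-fire neurons on a two-dimensional
sheet with periodic boundaries. The excitatory population (80% of N) and
inhibitory population (20%) sit on concentric uniform grids covering
`[0, L)^2`; all distances are torus distances (per-axis wrap). Membrane and
synaptic dynamics, spike/reset rules and the linear distance-delay rule are
as stated in the README. Delays are quantized to the integration grid
(round to nearest, minimum one step).

Wiring: each neuron emits exactly K synapses without replacement, no
autapses — 0.8 K onto excitatory targets sampled by weight, where the
weight is `0.9 * Gaussian(torus distance; sigma) + 0.1 * W_long`, and
`W_long` is uniform over the sheet (random long-range control) or the
normalized von Mises tuning kernel `exp(kappa (cos(dpref) - 1))`
independent of distance (patchy). Inhibitory presynaptic neurons are purely
local (their long-range weight is zero). The 0.2 K inhibitory targets are
placed "at the locations of the excitatory projections": each is the
inhibitory neuron nearest to one of the row's excitatory targets,
deduplicated in random order (ties and shortfalls fall back to the nearest
unused inhibitory cells). Weighted sampling without replacement uses the
Gumbel top-k construction, which is exact and vectorizes.

Tuning map: one square pinwheel of `grid_side^2` neurons is built by
sampling the counterphase angle density
`sin(theta + pi/2) (1 - 1/sqrt(2)) + 1` (the direction of the pi/2 shift is
exposed as a switch, as either reading is defensible), sorting the draws,
assigning them to neurons ordered by polar angle around the pinwheel
center, and equalizing the 100 angle-bin counts by a neighbor-swap shuffle
(surplus members move to the adjacent bin until every bin is exactly
equal — 36 neurons per bin for a 60x60 pinwheel). The base tile is mirrored
across alternating axes to cover the excitatory grid and cropped; the
inhibitory map subsamples the excitatory grid at every second row and
column, which yields exactly the inhibitory grid.

### Parameters and the operating point

Units: pF, nS, mV, ms, mm; conduction speed in m/s (numerically mm/ms).

| parameter | default | meaning |
|---|---|---|
| Cm | 200 | membrane capacitance |
| GL | 10 | leak conductance (tau_m = 20 ms) |
| EL = Vr | -51 | rest / reset potential |
| VT | -50 | spike threshold |
| Ee, Ei | 0, -80 | synaptic reversal potentials |
| tau_e, tau_i | 5, 5 | synaptic decay constants |
| t_ref | 5 | refractory period |
| tau_s | 1 | fixed synaptic delay |
| v_c | 0.2 | conduction speed |
| sigma | 0.6 (full) / 0.24 (reduced) | local wiring scale |
| kappa | 1.25 | von Mises concentration |
| K | 1000 (full) / 200 (reduced) | out-degree |
| Ge, Gi | 0.3, 3.9 at K=200 | conductance increments |

The membrane/synapse constants are a calibration, not a published table.
The requirement is a self-sustained asynchronous-irregular (AI) state with
5-40 Hz wave content and no external drive. At desk scale (~10^4 neurons,
K = 200) the low-rate AI state of large balanced networks is fragile — it
either dies or locks into fast synchrony for most parameter settings — so
the resting potential sits 1 mV below threshold (a Vogels-Abbott-style
choice) and the weights were scanned (`scripts/calibrate.py`) for points
with a late-window rate of 1-12 Hz, ISI CV near 1, and robustness to
restarting from Gaussian moments of a burn-in state. The shipped point
(Ge = 0.3, Gi = 3.9, inhibition ratio 13) runs at ~9 Hz with population
median CV ~1.1-1.3 and restarts reliably. With these weights the LFP proxy
carries roughly two thirds of its 1-300 Hz power inside the 5-40 Hz
analysis band, and spatial correlation decays with channel separation —
the substrate the wave pipeline needs.

Initialization draws V, g_e, g_i independently from Gaussian moments
(clipped at zero conductance and just below threshold). The default
moments were measured from the final state of a 5 s burn-in of the
reduced reference network; `measure_moments` re-derives them for any other
configuration.

Integration: exponential-Euler for the conductances (exact), forward Euler
for V, dt = 0.1 ms (guarded at tau/5). Within a step, deliveries are
applied before integration and the threshold test. The production kernel is
a numba ring-buffer event loop; a transparent numpy stepper with identical
semantics is kept for validation, and the test suite checks the two produce
identical spike sequences on a small network.

## LFP proxy

One channel per non-overlapping pool of `pool_side^2` excitatory cells
(10x10 default): `lambda(t) = sum_j Ie_j(t - tau) - alpha sum_j Ii_j(t)`
with tau = 6 ms and alpha = 1.65, where the pooled currents use the
driving force to the pool-mean membrane potential, sampled at 1 kHz.
Channels are independent across pools by construction (no volume
conduction, no frequency-dependent spatial integration). The 6 ms shift is
edge-padded with the first value; the discarded initial 200 ms of every
simulation covers the transient. Units are arbitrary: every downstream
statistic is phase-based.

## Wave pipeline conventions

* Band-pass: 4th-order Butterworth 5-40 Hz, forward-reverse (zero phase),
  per channel, mean-subtracted.
* Generalized Phase: analytic-signal phase, unwrapped; samples that fall
  below the running maximum (negative instantaneous frequency) are
  replaced by shape-preserving (PCHIP) interpolation through the valid
  samples, and a final running-maximum pass guarantees monotone phase.
  All-zero channels are masked.
* Cycles: the anchor is the circular-mean phase of a 3x3 channel block at
  the grid center (configurable; the biological choice would be the
  retinotopic locus of the stimulus). Boundaries are successive upward
  0-crossings whose boundary sample is within 0.2 rad of zero; the test
  time is the in-window sample closest to +-pi; windows outside one period
  of the analysis band are dropped.
* Wave gate: the phase gradient is computed by centered circular
  differences on the channel grid (masked channels excluded; divergence
  only where the full stencil exists). The source is the channel with the
  largest |divergence| — a radial wave sampled at opposite half-cycles
  flips the sign of both the divergence and the phase-distance slope, so
  the magnitude finds the source either way — and rho_phi_d is the signed
  circular-linear (Mardia) correlation of phase against distance from the
  source, sign-oriented by the divergence so that coherent radial
  structure of either polarity scores positive. Patterns with rho_phi_d
  >= 0.3 (the empirical chance level; configurable) are waves. A
  spatial-shuffle null (>= 100 permutations, full source-finding re-run)
  is evaluated for gated patterns.

## Motifs

PSI is the Fisher-Lee sine-product circular-circular correlation over
shared valid channels (at least 8), which is exactly +1/-1 for identical /
direction-reversed maps and invariant to a global phase rotation. Motif
definition binarizes the PSI matrix at S (diagonal excluded; undefined
pairs count as below threshold), computes repeat counts r_j, flags
patterns with `r_j / mean(r) > R` as high-repetition, and scans them in
ascending index order: each anchor not already inside an emitted motif
emits `{anchor} U {its repeats}`. Later motifs may overlap earlier ones
(only anchors are excluded, mirroring the wording of the defining
procedure); a deduplicating label view is provided. An optional
`min_repeats` guard (absolute repeat count) suppresses tiny spurious
clusters on small pattern pools; the model protocol leaves it off, the
array protocol uses 4.

Parameters: the model protocol uses S = 0.55, R = 3 (high-dimensional
model LFP maps make chance PSI small); array-style data with 64 channels
uses S = 0.8, R = 3 with min_repeats = 4, reflecting the higher chance
similarity of low-channel-count maps. Separation is scored by
eigendecomposing C + 1 (shifted to be nonnegative), projecting patterns on
the top-3 eigenvectors scaled by sqrt(eigenvalue), and taking mean
between-centroid distance over mean pattern-to-own-centroid distance;
degenerate (zero-spread) motifs report a cap of 1e3, fewer than two motifs
report NaN.

## Feature-selective analyses

Channel tuning is the resultant vector of mean-normalized per-direction
responses; resultant length < 0.05 marks an untuned channel. Motif tuning
normalizes per-channel spike rates inside each member pattern's window
(model: +-5 ms around the test time; array-style: the cycle window) by the
channel's grand spontaneous rate, averages over member patterns, bins by
preference (6 partition bins for array data; 9 overlapping bins of +-pi/4
for the model), and takes the resultant; significance is the 95th
percentile of >= 100 preference-shuffle nulls, z the null-standardized
length. Evoked-window patterns are assigned to motifs when their mean PSI
to a motif's members exceeds the 95th percentile of that statistic over
all trials (catch and high-contrast trials excluded); ties go to the
highest mean PSI. Evoked gain uses MI = (Ra - Ro)/(Ra + Ro) over
baseline-normalized evoked rates on motif-aligned vs motif-opposed trials
(target within pi/3 of the unit preference; motif alignment within pi/2
for gain, within pi/3 / beyond pi - pi/3 for behavior — the two
half-widths follow the respective analyses and are both parameters), with
count-matched random reassignment as control. Detection performance per
motif and target location normalizes per-direction hit rates by the grand
per-direction hit rate (pooled over locations), scores the curve by its
resultant, and z-scores against count-matched random trial draws.

## Synthetic data

The generator emulates an 8x8 array at 400 um pitch, 1 kHz, with 5-40 Hz
background noise and traveling oscillatory packets added on top
(raised-cosine envelope of 3 cycles). Motif templates are radial waves
with fixed source, speed 0.10-0.15 m/s, and frequency 10-15 Hz — slow,
steep phase maps that survive noise and per-channel jitter (sd 0.1 rad).
The majority of wave events are one-offs: radial or planar, either
polarity, speeds 0.1-0.3 m/s, with strong independent channel jitter
(sd 0.45 rad) so they pass the wave gate yet rarely resemble one another —
mimicking the situation in cortical data where most iTWs do not repeat.
Defaults: 140 epochs of 1.5 s, 90% containing an event, 20% of events
motif repeats over 3 motifs. Spiking is inhomogeneous Poisson at a
multi-unit-like 20 Hz baseline (lognormal heterogeneity); during a motif
packet, channels whose planted preference lies within pi/6 of the motif's
arc gain a factor 1 + depth (depth 0.2 default), others lose depth/2.
Trials (2000-trial analyses; 1000 default) draw exponential target onsets,
6 directions, two locations, 10% catch and 10% high-contrast trials, a
50% titrated hit rate, and a +0.15 hit boost when the evoked-window
motif's arc is within pi/3 of the target direction.

For epoch-structured data the recovery protocol keeps one pattern per
epoch (the largest rho_phi_d): a single packet spans several cycles whose
near-identical maps would otherwise count as within-event repeats. What
passing recovery shows: the pipeline finds the planted motif count (+-1),
labels with adjusted agreement 1.0 on the default fixtures, arcs within
one direction bin, and the sign of the behavioral boost. What it does not
show: performance on real recordings with volume conduction, non-Poisson
spiking, eye movements, or non-stationary noise — none of which the
generator attempts.

## Reduced-scale study protocol

The full-scale network (450k neurons, K = 1000, L = 5 mm) is supported by
the code but not by a desk-scale budget. The reference protocol uses a
90x90 excitatory grid (8100 E + 2025 I), L = 2 mm, sigma = 240 um (sigma/L
preserved at 0.12), K = 200 with conductances rescaled accordingly, 9x9
LFP channels. Per wiring mode and seed, one network is built and simulated
8 times for 1.2 s each (first 200 ms discarded) from independent Gaussian
initial states; phase patterns are pooled across runs before motif
definition, so repeats must reflect the wiring, not the persistence of a
single wave. Tuning uses a random sample of 5000 excitatory neurons.
These problem sizes (seeds 5 per mode, 8 runs per seed) were chosen as the
smallest at which the patchy-vs-random contrast is measurable.

At this scale the *orderings* reproduce — patchy wiring yields a larger
spectral distance ratio than random long-range wiring and motif tuning z
above the shuffled control (pooled mean z ~ 1.3) — but the *levels* of
the ratio (~5-6 vs the full-scale 2.88/1.43) and of the percent modulation
(~20-25% vs 7%) do not: with 9x9 channels the PSI is far less specific
than over a 60x60 model LFP grid, making motifs smaller and internally
tighter (inflating the embedding ratio), and per-bin spike counts are
orders of magnitude smaller (inflating the peak-bin deviation). Both
effects shrink with network and sample size; the acceptance script reports
the reduced-scale values as computed.

## Known limitations

* The AI operating point at desk scale sits closer to threshold than a
  full-scale balanced network would; rate distributions are narrower and
  the CV can exceed 1.3 in long runs with strong wave content.
* Cycle segmentation assumes a single dominant oscillatory event per
  anchor cycle; overlapping simultaneous waves produce mixed maps.
* The divergence-based source finder is restricted to interior channels
  (full centered stencil); sources on the array edge are pulled inward.
* Motif definition is order-dependent by construction (anchors scan in
  index order), exactly as specified by the defining procedure.
* The gain-modulation analysis requires trial counts that the default
  synthetic task only reaches with several thousand trials; with fewer,
  units are skipped by the minimum-trial rules rather than estimated
  noisily.
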