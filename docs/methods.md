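# Methods

This note documents the models, rules and numerical choices implemented in
`beemb`, the parameters that matter, what the synthetic-data generator does
and does not emulate, and the known limitations.

## Signal conventions

Glomerular activity is expressed as −ΔF/F: fluorescence is baseline-
normalised against the mean of the 1 s window before stimulus onset and
sign-flipped, so that calcium increases (Fura-2 fluorescence decreases)
read as positive responses. All times are relative to stimulus onset; the
odorant is ON during [0, 5) s. Analysis windows are half-open with
nearest-sample alignment: PRE = [−1, 0) s, ON = [1, 5) s, POST = [1, 4) s
after offset. The default recording protocol is 127 Hz sampling, 20 trials
per odorant on a 5 s ON / 25 s OFF schedule.

## Response-profile taxonomy and the generator

Nine recurrent profile classes are modelled, plus flat unresponsive
traces: (1) inhibition spanning the stimulus, (2) prolonged inhibition,
(3) inhibition with post-stimulus excitation, (4) sustained excitation,
(5) excitation with post-stimulus inhibition, (6) prolonged excitation,
(7) short phasic excitation, (8) short excitation truncated by inhibition,
(9) weak unclassifiable activity. Profiles are difference-of-exponential
transients gated by onset/offset events (fast rise τ = 30 ms, decay
τ = 300 ms), with three additions that the flat-gate caricature misses:

- **Phasic-tonic adaptation.** Excitatory responses peak early and relax
  toward a tonic plateau; inhibitory responses deepen gradually. Time
  constants and tonic levels are drawn per glomerulus (τ ∼ U(0.6, 2.5) s,
  tonic fraction ∼ U(0.3, 0.8)), so the population vector *rotates* during
  stimulation rather than merely scaling. This heterogeneity is what
  creates distinct early and late odour signatures downstream; without it
  the early/delay conditioning protocols become indistinguishable.
- **Short-excitation kinetics.** The printed termination latencies
  (346 ± 47 ms, ~35 ms after excitation onset) describe the end of the
  underlying drive. The synthesised calcium signal persists through a
  250 ms decay tail, and the truncating inhibition of class 8 builds with
  slow (300 ms) kinetics. Consequently the 1-SD termination estimator,
  which reads the measured trace, reports values several hundred ms above
  the configured drive end — an expected property of the observable, not a
  recovery failure (onset recovery is exact to one sample).
- **Group 9** is synthesised as brief (~100 ms) alternating blips that
  never exceed the detection threshold long enough to count as a proper
  component, keeping it distinct from flat unresponsive traces.

Latencies are drawn from the empirical distributions: excitatory onsets
N(313, 22²) ms, inhibitory onsets N(351, 47²) ms, short terminations
N(346, 47²) ms (clipped to ≥ 30 ms after onset). Response amplitudes are
N(0.2, 0.05²) clipped to [0.1, 0.4] −ΔF/F; class-9 amplitude is 0.06.
Default class proportions partition the printed three-way split (48 %
excitatory, 37 % inhibitory, 15 % non-responsive) across subgroups in the
ratios of the balanced-odorant composition; they are configuration, not
constants, since per-class population frequencies are only reported
graphically.

**Trial noise** is i.i.d. Gaussian sample noise (sd 0.05), a slow
Ornstein–Uhlenbeck drift (sd 0.01, τ = 1 s) emulating baseline wander, and
per-trial onset jitter with sd equal to the class latency sd. Every trial
is re-baselined on its PRE window, mirroring the ΔF/F normalisation.
What the generator does **not** emulate: correlated noise across
glomeruli, amplitude adaptation across the 20-trial session, glomerulus
identity shared across animals, and odorant-specific chemistry — synthetic
odorants differ only through which classes and parameters each glomerulus
draws. Passing tests therefore demonstrate that the analysis chain behaves
correctly on data with this statistical structure, not that real
recordings would yield the same numbers.

## Classifier and latency estimators

Classification is deterministic and rule-based, applied to trial-averaged
traces. Detection uses mean_PRE ± 2·sd_PRE, floored at an absolute
tolerance of 0.02 (−ΔF/F); a *component* must stay beyond threshold for
≥ 150 ms contiguously, a weak *event* for ≥ 60 ms. A trace with no
components is class 9 if it has events, unresponsive otherwise. The first
component sets the polarity; excitation terminating before 1.5 s is
"short" (class 8 if inhibition follows, also recognised when the brief
excitatory event precedes an inhibitory primary component); responses
beyond threshold throughout the first second after offset are "prolonged"
(classes 2/6); post-stimulus components of opposite sign decide classes
3/5. Latency uses the 1-SD threshold (floored at the same tolerance, and
flagged when the floor applies, e.g. on noiseless input), requiring the
crossing to persist 100 ms so single noise samples cannot trigger it;
short-excitation termination is the first sustained timepoint after the
peak at which the trace is no longer above the upper band. Thresholds and
durations are exposed in `ClassifierParams`.

## Mushroom-body model

- 3 PNs per recorded glomerulus, identical signal, independent wiring.
- PN activity bin-averaged onto the 20 Hz MB oscillatory grid (50 ms
  non-overlapping bins — simple and antialiasing). Negative values are
  preserved: a glomerulus is silent only at maximal inhibition.
- Binary connectivity matrix W (n_PN × 1000): each KC samples exactly
  round(0.30 · n_PN) PNs without replacement (the exact in-degree makes
  the 30 % density testable; only the percentage itself is empirical).
- Per time step, KC input is the matrix product of the PN activity vector
  with W; winner-take-all feedback inhibition fires exactly
  k = round(0.10 · n_KC) cells with the largest summed input. Ties at the
  cut are broken deterministically by lowest KC index; all-equal-input
  time steps (e.g. zero input) are flagged as degenerate. The batched
  implementation (partition + tie sweep) is bit-equivalent to the stable
  full sort and is cross-checked against it.
- Simulations run over 10 independent replicate networks (seeds derived
  from the master seed) and analyses average across replicates.

## KC analyses

Turnover between adjacent steps is |A(t+1) \ A(t)| / |A(t+1)| — 0 for a
stable assembly, 1 for full replacement; undefined (empty set) values are
flagged, never zeroed. Cumulative recruitment counts distinct KCs active
since onset. Odour trajectories use covariance PCA on mean-centred
population vectors, PN and KC spaces decomposed separately. The
decorrelation experiment assembles 100 artificial odorants of 30 profiles
subsampled with constant composition (rows ordered by class so maps are
row-aligned), takes ON-window mean response vectors (t = 1–4 s; the 0.5–5 s
variant is a config preset), and compares pairwise Pearson correlations in
PN space against replicate-averaged KC firing-probability vectors through
a common set of networks; all C(100,2) = 4950 pairs are reported along
with any excluded undefined pairs.

## MBON learning

All 1000 KC→MBON synapses start at weight 1 (a broadly tuned MBON).
During a 3 s learning window a KC firing ≥ *spt* times is switched to 0;
weights never increase. spt = 15 at 50 ms steps means ≥ 750 ms cumulative
activation (spt = 40 ⇒ 2 s). Protocols are defined by the US onset:
backward −2 s, early +1 s, delay +4 s, trace +7 s; windows are
start-inclusive/end-exclusive on the 20 Hz grid (60 steps). The backward
window requires 2 s of pre-stimulus raster coverage, so conditioning runs
use a protocol with a 2 s pre window; pre-stimulus noise-driven KC
activity then contributes to depression, which is precisely what makes
backward learning weak but non-zero.

The AP-probability readout (the formula is this package's
operationalisation) is the fraction of currently firing KCs whose synapse
is intact, averaged over replicate networks and test trials: 1 for an
untrained MBON, NaN-flagged where no KC fires. The learned-response score
is 1 − mean probability over the CS window; learned latency is the first
timepoint after CS onset at which the probability reaches 90 % of its
maximal drop, i.e. p ≤ 1 − 0.9·(1 − p_min) (the phrase "90 % of minimal
activity" is ambiguous; this reading is monotone in the drop and exact for
step and ramp traces). Training uses the mean of the first five CS
repetitions; testing uses the next five repetitions of the CS and of the
novel odorant through the same networks (fresh trials, same wiring). The
protocol battery uses one network per animal/odorant-role combination
(16 networks); replicate averaging is a parameter.

## Ablation experiment

Balanced odorants (32 profiles: 5/3/3/7/1/2/2/1/4 across classes 1–9 plus
4 unresponsive) are assembled per repeat; removal variants zero the rows
of the targeted classes (map shape and PN indexing preserved). For each
repeat, early and delay conditioning run on the same trials and the paired
early-vs-delay latency difference is tested (Wilcoxon signed-rank); the
summary is the p-value distribution over repeats and the fraction below
0.05 per variant.

## Problem sizes and determinism

Default analysis sizes: 8 animals × 3 odorants × 25 glomeruli × 20 trials;
1000 KCs, 10 replicate networks for coding analyses; 100 × 30 odorants for
decorrelation; 16 conditioning combinations. The ablation script defaults
to 100 repeats; the acceptance script recomputes it at 20 repeats, a size
chosen to keep a from-scratch desk run at a few minutes while leaving the
fraction-significant estimate stable to ±0.1. Every stochastic operation
receives a seed derived from the master seed and an operation path
(CRC-based, < 2³¹), so identical seeds give bit-identical datasets,
rasters and reports.

## Known limitations

- No spiking dynamics, membrane time constants or oscillation phase; the
  20 Hz discretisation stands in for the MB oscillatory cycle.
- No plasticity of PN→KC synapses; no dopaminergic/octopaminergic circuit
  — the learning window is the US stand-in.
- The generator's noise is independent across glomeruli, so pre-stimulus
  KC turnover is near-maximal (~0.9) rather than the partially structured
  values real recordings produce; within-window directions and orderings
  are the meaningful comparisons, not absolute turnover levels.
- Measured short-excitation termination latencies include the calcium
  decay tail (see above) and exceed the configured drive-end times.
- Trace conditioning captures only the coincidence mechanism: the model
  learns the after-smell population, and correctly predicts a
  post-offset response minimum, but any attention-like prolongation of
  the stimulus trace is out of scope.
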