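# Methods

This note documents the models, defaults and numerical choices behind
`patchdose`, and what the synthetic-data validation does and does not
establish about real recordings.

## Sulfide speciation and effective dose

NaHS dissociates completely to Na⁺ + HS⁻; HS⁻ protonates to H₂S according
to the first dissociation equilibrium.  The dissolved H₂S concentration is

    [H₂S] = S_tot / (1 + K₁/[H⁺] + K₁K₂/[H⁺]²),

with the simplified form dropping the K₂ term (pK₂ ≈ 19, so the term is
below 10⁻⁶ relative for pH < 9; the package verifies this on a grid and the
two forms diverge measurably only in strongly alkaline solutions).  pK₁ is
computed from temperature and salinity by the Millero fit (see README).
Defaults reflect a physiological bath: pH 7.21, 293.15 K, 11.5 g/L salts,
pK₂ = 19.

**Exact vs printed fraction.**  Exact evaluation at pH 7.21 with
pK₁ = 6.679 gives a speciation fraction of ≈0.2275, while the published
chain that motivated this package reports 22.3% and derives its percent
figures and EC50 rescalings from that rounded value.  The module always
computes exactly and exposes a `paper_fraction` override (CLI
`--paper-fraction 0.223`) that affects only percent-of-total reporting, so
the rounded chain is reproducible bit-for-bit without contaminating the
model.  The bundled sensor calibration table is consistent with this
picture: its H₂S column matches NaHS × 0.223 for five rows and the exact
fraction for the 226 µM row.

**Calibration.**  The sensor line (current vs [H₂S]) is unweighted OLS over
points within the linear range (default upper bound 51 µM H₂S); points
beyond it are excluded and counted, and inverse predictions outside
[0, linear_max] carry an extrapolation flag.  Reported s.e.m. values are
stored but not used as weights, since no weighting scheme is defined for
the measurements.

**Evaporation.**  Loss anchors are interpolated monotonically and
piecewise-linearly, constant after the last anchor.  The bundled preset —
(0, 0), (5 min, 0.35), (10 min, 0.42), (20 min, 0.42) — encodes a ~30–40%
loss during the first 5 min of handling (midpoint 35%), ~6–8% more during
the 5-min application, and a measured 42% total at 20 min.  A single
exponential cannot satisfy these anchors simultaneously, which is why no
kinetic law is fitted.  The corresponding retained fraction, 0.50–0.60, is
the default retention range for effective doses and EC50 rescaling.

**Rounding.**  Reported values round half-up at the printed precision of
each quantity; full precision is retained internally.

## Gating simulator

Channels are independent identical continuous-time Markov chains with a
0/1 conductance per state; the default is the two-state C⇌O model, which
suffices because only open-dwell statistics are analysed downstream
(closed-state substructure would alter closed-time distributions that the
pipeline deliberately ignores — patches contain several channels, making
closed kinetics uninterpretable).  Simulation is exact and event-driven:
exponential holding times from the state's exit rate, jumps from the
embedded chain, initial states from the stationary distribution.  All
public entry points require a seed.

Rendering samples the superposed open-channel count at 20 kHz (dt =
0.05 ms), scales by a unitary amplitude of 5 pA, adds white Gaussian noise
(default SD 0.625 pA, i.e. signal-to-noise 8) and applies a Gaussian
low-pass with −3 dB at 1 kHz (σ_ms = √(ln 2)/(2π f_c); 10–90% step rise
time ≈ 0.34/f_c).  The unitary amplitude and noise level are configuration
choices — single-channel studies rarely report them — and are stated here
rather than inferred.  No 1/f or line-frequency noise components are
modelled, and rates carry no voltage or Ca²⁺ dependence (recordings being
emulated are at fixed +30 mV, 0.5 µM free Ca²⁺).

Condition presets (`ATP0`, `ATP1`, `PKA`, `PKG`, `PKCsu`, `PKCin`, `STS`,
`OA`) pin the stationary Po and mean open dwell to magnitudes typical of
GH-cell BK recordings (per-channel Po ≈ 0.015–0.31, dwells ≈ 0.7–2 ms).
They parameterize simulations only and are never analysis targets.

**Experiment generator.**  Multi-patch designs place each patch's paired
control/H₂S measurements on the logit-Po scale: condition baseline +
patch random intercept (SD 0.55) + phase effect (default 0.65 logits,
≈1.9-fold at these baselines) + residual (SD 0.25).  The intercept SD was
chosen so that the implied between-patch spread of Po matches the s.e.m.
magnitudes seen in 12-patch data sets at these baselines; the residual SD
represents within-patch measurement repeatability.  Dwell times are
lognormal around the condition mean (log-SD 0.35), amplitudes Gaussian
(5 ± 0.3 pA).  Inverse-logit guarantees Po strictly inside (0, 1).

## Idealization

**Baseline.**  The trace is segmented (default 1 s); per segment the
baseline is the median of closed-classified samples (below baseline +
A/2, refined over three iterations) when the unitary amplitude A is known,
or a half-sample-mode estimate otherwise.  Segment values are linearly
interpolated and linearly extrapolated at the ends, which removes locally
linear drift exactly.  Updating only from closed-classified samples avoids
open-level contamination; a segment with no closed samples falls back to a
global estimate with a warning.

**Thresholding.**  Level k is entered when the corrected current crosses
(k ± ½)·A, with a hysteresis of 0.1·A beyond the threshold to suppress
chatter (configurable).  The recurrence `level ← clip(level, up_k, down_k)`
is evaluated by a compiled loop.  Events shorter than the dead time
(default two sampling intervals, 0.1 ms at 20 kHz) are absorbed into the
longer adjacent neighbor (previous on ties) until the record is stable.
Records needing more than `max_levels` (default 4) are clipped and
flagged.

**NPo/Po.**  The primary NPo is the level-weighted occupancy
Σ level·duration / total — the field convention behind the shorthand
to/(to+tc), and identical to it for a single channel.  The literal
unweighted open/(open+closed) aggregate is reported alongside.  Po =
NPo/n with n the maximum observed level; for traces long enough for every
channel to open, n equals the channel count and Po is the per-channel open
probability.

**Dwell-time mixtures.**  Open dwells are maximal sojourns above the
closed level.  Exponential mixtures are fitted by EM on dwells shifted by
the dead time (memorylessness keeps component τs invariant under left
truncation; truncated-scale weights are mapped back via w_k ∝ v_k
e^{t₀/τ_k}).  Candidates with 1..3 components (configurable) run with five
restarts on a deterministic seed schedule, a 10⁻⁴ weight floor and a
10⁻¹⁰ relative log-likelihood convergence tolerance; the component count
minimizing BIC (= −2ℓ + (2K−1) ln n) is selected.  Non-convergence returns
the best-so-far fit with a flag.

**Amplitudes.**  The unitary amplitude is the Gaussian MLE over level-1
event means (events ≥ 1 ms, trimmed 0.3 ms at each edge to exclude filter
rise), chosen over all-point histograms because event means are robust to
the heavy closed-level mass in low-Po patches.  An explicit
`NoOpenEventsError` distinguishes "nothing to fit" from fit failure.

## Statistics

Po values are logit-transformed (ln(p/(1−p))) and dwell times
log-transformed before modelling; rows at the boundary (Po exactly 0 or 1)
are flagged, never silently dropped.  Fixed condition×phase effects with a
per-patch random intercept are estimated by REML (statsmodels MixedLM).
The Powell optimizer is used because it tracks the profiled variance
optimum to ~10⁻⁷, tight enough that on balanced paired designs the H₂S
contrast reproduces the paired t statistic to 10⁻⁶ (the package's oracle
test); lbfgs is the fallback.

Contrast tests use a t reference with within-patch residual degrees of
freedom, df = n_obs − n_groups − rank(X) + 1, which equals n − 1 on a
balanced paired design.  A normal reference (df = ∞) is available but is
anti-conservative at realistic patch counts: in a 1000-replicate null
simulation (5 conditions × 6 patches, 5 contrasts) the z-based max-|t|
family-wise error was 0.085 at nominal 0.05, versus ≈0.047 with the t
reference.  The default multiplicity adjustment is the single-step
max-|t| method — adjusted p = P(max_j |T_j| ≥ |t_i|) computed as a
rectangle probability of the joint t distribution of the contrast
statistics (seeded, hence deterministic); Holm is available as a
closed-form fallback.  Star coding: '' for p ≥ 0.05, `*` for
0.01 < p < 0.05, `**` for 0.001 < p ≤ 0.01, `***` for p ≤ 0.001 — exact
boundary values fall in the category these inequalities assign them.

**Percent of control** uses the per-patch-ratio convention: each patch's
H₂S value divided by its own control, ×100, then averaged with s.e.m.
across patches.  This is deliberately not the ratio of group means: the
two differ whenever fold-change correlates with baseline across patches
(mean-of-ratios exceeds ratio-of-means under negative correlation, a
Jensen-gap property demonstrated in the test suite), and published percent
figures in this field follow the per-patch convention.  Back-transformed
group means are computed on the transform scale and mapped through the
inverse, with the s.e.m. band transformed the same way (hence asymmetric
on the response scale).

## Validation scope

Synthetic traces validate the recovery chain: on 60-s two-channel
recordings at 20 kHz, SNR 8 and 1 kHz filtering, idealization recovers
ground-truth NPo and Po within 10% relative across presets spanning
per-channel Po 0.015–0.31; on noise-free unfiltered traces it reproduces
the sampled ground-truth event list exactly for every preset.  EM recovers
a single τ within 5% and a 0.7/0.3 two-component mixture's τs within 15%
at n = 5000.  Mixed-model estimation recovers a 0.65-logit effect with
|bias| < 0.05 over 500 simulated 12-patch experiments.

These checks establish correctness of the algorithms under the generative
model, not performance on real data: real recordings contain 1/f and line
noise, baseline artifacts beyond slow drift, channel number uncertainty,
cooperative or modal gating, and filter characteristics other than
Gaussian.  The dead-time truncation corrects the dwell likelihood but no
full missed-event correction is attempted; closed-time kinetics, burst
analysis and voltage-ramp protocols are out of scope.  Problem sizes in
the automated checks (trace lengths, replicate counts) are chosen to make
Monte-Carlo error small relative to each tolerance.
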