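# patchdose

H₂S dosimetry for NaHS donor solutions and single-channel BK patch-clamp
analysis.

Sodium hydrosulfide (NaHS) is the standard fast-releasing H₂S donor in ion
channel pharmacology, but the concentration that actually reaches a membrane
patch is far below the nominal donor concentration: only the neutral H₂S
fraction of the sulfide equilibrium is membrane-permeant, that fraction
depends on pH, temperature and salinity through pK₁, and H₂S evaporates
quickly during solution handling and perfusion.  `patchdose` implements the
full correction chain, and alongside it the single-channel analysis used to
quantify H₂S effects on large-conductance Ca²⁺-activated K⁺ (BK) channels:
event detection by the half-amplitude threshold method, NPo/Po, open
dwell-time and amplitude fitting, and logit-scale mixed-model statistics for
multi-patch designs.  A Markov-gating simulator supplies synthetic
recordings with known ground truth for validation.

Intended users: electrophysiologists analysing multi-channel patch
recordings, and anyone needing defensible effective-H₂S estimates for
NaHS-based experiments.

## The model in brief

**Speciation.**  With total sulfide S_tot and first dissociation constant
K₁ = 10^(−pK₁),

    [H₂S] = S_tot / (1 + K₁/[H⁺] + K₁K₂/[H⁺]²)  ≈  S_tot / (1 + 10^(pH − pK₁))

(the K₂ term is negligible below pH 9).  pK₁ is corrected for temperature
T (Kelvin) and salinity S (g/L) by the Millero fit

    pK₁ = −98.08 + 5765.4/T + 15.04555 ln T − 0.157 √S + 0.0135 S.

The *effective* concentration multiplies [H₂S] by the fraction retained
after evaporative loss (a monotone piecewise-linear loss-vs-time model);
donor-denominated dose–response parameters (EC50s) rescale by the same
factors.

**Single-channel analysis.**  A baseline-corrected trace is idealized by
assigning level k where the current crosses (k − ½)·A for unitary amplitude
A (with hysteresis and a dead time).  NPo is the time-weighted mean number
of open channels, Po = NPo/n with n the maximum simultaneous openings
observed.  Open dwell times (maximal sojourns above the closed level) are
fitted with exponential mixtures by EM with dead-time left-truncation and
BIC model selection; unitary amplitudes by a Gaussian over level-1 event
means.  Po is logit-transformed, dwell times log-transformed, and condition
and H₂S-phase effects are estimated by a random-intercept (per patch) mixed
model with max-|t|-adjusted linear contrasts.

## Worked example

What does a 300 µM NaHS application deliver in a physiological bath
(pH 7.21, 20 °C, 11.5 g/L salts)?

```sh
patchdose dose --nahs 300 --ph 7.21 --temp-c 20 --salinity 11.5 \
    --retention 0.5:0.6 --paper-fraction 0.223
```

```json
{
  "nahs_uM": 300.0,
  "ph": 7.21,
  "temperature_K": 293.15,
  "salinity_g_per_L": 11.5,
  "pk1": 6.678923265638765,
  "dissolved_h2s_uM": 68.2306208470577,
  "fraction_dissolved": 0.22743540282352565,
  "retention_low": 0.5,
  "retention_high": 0.6,
  "effective_low_uM": 34.11531042352885,
  "effective_high_uM": 40.938372508234615,
  "effective_fraction_low": 0.1115,
  "effective_fraction_high": 0.1338
}
```

Reading: the salinity-corrected pK₁ is 6.679, so only ~68 µM (≈23%) of the
300 µM donor is dissolved H₂S, and after 40–50% evaporative loss the patch
sees 34–41 µM — 11–13% of the nominal concentration.  The
`--paper-fraction` flag reproduces a published reporting chain that rounds
the speciation fraction to 22.3% before computing percentages; omit it to
use the exact equilibrium fraction throughout.

A full synthetic analysis run — simulate a two-channel patch, idealize it,
summarize NPo/Po/dwells/amplitude, then fit a mixed model to a simulated
multi-patch experiment:

```sh
patchdose pipeline --seed 42 --outdir out/
```

writes `dose.json`, `trace.tsv`, `truth.json`, `events.csv`,
`summary.json`, `table.csv`, `stats_results.csv` and
`percent_of_control.csv`, every file stamped with the package version,
seed and config hash.  Outputs are byte-identical across reruns with the
same seed.

## Layout

```
src/patchdose/speciation.py   sulfide equilibrium, calibration, evaporation, EC50 rescaling
src/patchdose/simulate.py     CTMC gating simulator, trace rendering, experiment designs
src/patchdose/idealize.py     half-amplitude idealization, NPo/Po, dwell & amplitude fits
src/patchdose/stats.py        logit pipeline, mixed models, contrasts, percent-of-control
src/patchdose/io.py           trace/table formats, config, provenance
src/patchdose/cli.py          `patchdose` command-line interface
docs/methods.md               modelling and statistical methods in detail
```
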