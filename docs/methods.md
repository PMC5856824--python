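# Methods

## The synthetic cohort generator

The pipeline's inputs are per-ROI source current time series — three
orthogonal components per region, the form produced by distributed inverse
solutions. Clinical recordings of this kind are not freely shareable, so the
package ships a generator whose output carries exactly the statistical
structure the downstream analyses are designed to detect.

For every subject and ROI the three components share one core waveform
through a random unit direction vector `w` (a fixed dipole orientation):

    x_c(t) = w_c · core(t) + σ · pink_c(t),    c ∈ {1, 2, 3}

with independent 1/f^β pink-noise backgrounds per component (β = 1 by
default, σ = `noise_sigma`). Healthy subjects, and patients outside their
affected ROIs, carry a pure alpha core

    core(t) = A · sin(2π f_α t + φ),           f_α = 10 Hz.

In a patient's affected ROIs the alpha rhythm is slowed to theta and fast
carriers appear whose amplitude rides on the theta wave:

    core(t) = A·s_θ(t) + H·(1 + m·s_θ(t))·[sin(2π f_β t + φ_β) + sin(2π f_γ t + φ_γ)]

where `s_θ(t) = sin(2π f_θ t + φ)` is the theta carrier (already unit
range), `m ∈ [0, 1]` the modulation depth, and f_β, f_γ are drawn per
subject from [13, 30] and [30.5, 44] Hz. Coupling is injected as *linear*
amplitude modulation because the nesting statistic downstream is a Pearson
correlation between the theta waveform and the fast-band envelope: linear
modulation makes the expected statistic monotone in `m` and exactly zero at
`m = 0`.

The affected-ROI map is: tinnitus → bilateral auditory cortex; pain →
bilateral somatosensory + motor cortex; Parkinson → bilateral motor cortex;
depression → subgenual ACC; every disorder additionally involves the
dACC/sgACC common areas. An optional left-parahippocampal alpha boost for
depression exists (`depression_phc_alpha`) but is off by default.

### Parameter defaults and why

| parameter | default | role |
|---|---|---|
| `duration_s` | 300 s (tests/analyses use 60 s) | 5-minute resting recordings |
| `fs` | 128 Hz | analysis band is 2–44 Hz; Nyquist margin |
| `alpha_freq` / `theta_freq` | 10 / 6 Hz | band centers |
| `osc_amplitude` A | 0.8 | rhythm amplitude relative to noise |
| `hf_amplitude` H | 0.4 | edge-effect carrier amplitude |
| `modulation_depth` m | 0.8 | strong nesting in patients |
| `noise_sigma` σ | 0.4 | 1/f background level |
| `amp_jitter` | 0.5 | per-subject log-normal sd of A and H |
| `pink_exponent` β | 1 | background spectral slope |

A, H, and σ were calibrated once, jointly, so that (i) affected-ROI band
features separate patient from healthy groups at Cohen's d ≈ 2–3 — large
but not trivially so, in the spirit of clearly separable clinical groups;
(ii) a patient's spectrum reliably peaks in theta rather than in the 1/f
background; and (iii) the theta–gamma nesting of an affected ROI averages
r ≈ 0.65–0.75 at m = 0.8 over 60 s records. `amp_jitter` supplies the
between-subject amplitude variability real cohorts show; at 0.5 the
log-normal lower tail keeps essentially every subject's rhythm above the
noise floor (a larger jitter occasionally produces oscillation-free
"patients", which breaks the construction guarantees).

Dipole orientations are drawn uniformly but canonicalized to the hemisphere
whose dominant Cartesian component is positive. Orientation is physically
sign-ambiguous — (w, core) and (−w, −core) generate identical data — and
without a canonical hemisphere the sign of the first principal component,
and hence of the nesting correlation, would be arbitrary per subject.

Per-subject seeds derive from the cohort master seed via a seed sequence;
generation is a pure function of (counts, params, master seed).

### What the generator does *not* emulate

No volume conduction or ROI-to-ROI leakage, no artifacts (blinks, EMG,
line noise), no nonstationarity beyond the modulation itself, single fixed
oscillation frequencies per cohort rather than individual peak frequencies,
and no whole-brain spectral shifts outside the mapped ROIs. Passing tests
therefore demonstrate that the *analysis chain* recovers the structure it
targets under realistic noise — not that real patient EEG will separate
this cleanly.

## Spectral analysis

Band-pass filtering is a zero-phase frequency-domain filter: unit gain
inside the band, raised-cosine (Hann-shaped) transitions of 0.5 Hz on
either side, zero outside. Band power is the mean Welch PSD (4 s Hann
windows, 50 % overlap) over the band, averaged across the three components,
then log₁₀-transformed — the ROI-level analogue of log current density
averaged over voxels. Whole-record spectra use 1 s windows for an exact
1-Hz grid over 2–44 Hz (43 bins); power is averaged on the linear scale
across components and ROIs and log-transformed afterwards (treated as log
power; recorded in metadata). Group comparison runs a per-frequency one-way
ANOVA with an uncorrected α = 0.05 mask (simple contrasts); a Pillai's-trace
MANOVA omnibus is attempted only when subjects outnumber bins + groups,
since the 43-dimensional covariance is otherwise singular.

## Classification protocol

Features are standardized on training-split statistics only; the classifier
is an L2-regularized linear logistic regression (C = 1, lbfgs, tight
tolerance so label-flip symmetry holds numerically). Constant features
standardize to zero columns and keep zero weight — effectively dropped.
Stratified ten-fold cross-validation preserves class proportions per fold
(100 subjects at 60/40 give training splits of exactly 54/36); ten repeats
with distinct fold seeds provide the dispersion reported with each metric.
The multiclass "full model" is one-vs-rest with macro-averaged TPR/FPR/AUC
and Weka-style probability residuals (per-instance mean over classes).
Feature selection is post-hoc: |standardized weight| ≥ 0.25 × max.

The permutation null shuffles labels (class counts preserved), reruns the
full cross-validation, and averages metrics over 100 permutations. Two
real-vs-null comparisons are reported:

* a one-way ANOVA of the real model's per-repeat values against the
  per-permutation values — the study's descriptive comparison; and
* a calibrated permutation p-value, (1 + #{permutations ≥ real}) / (n + 1).

**Calibration caveat.** The ANOVA's real-side replicates differ only by
fold split, not by label assignment, so their variance omits the
assignment-level component (≈ 0.06 sd of accuracy at 40 subjects/task).
At desk scale this makes the ANOVA anticonservative on null data: a single
unlucky label assignment (e.g. one that "anti-learns" below chance) yields
p < 0.01 against its own permutation distribution. At the full study scale
(hundreds of subjects per task) the assignment-level variance is several
times smaller and the issue is immaterial next to the enormous real
effects. Decisions about whether a model is significant at desk scale —
including the non-TCD negative control — therefore use the permutation
p-value; the ANOVA is always computed and reported alongside.

## Nesting statistic and comodulogram

Per ROI: each component is band-passed in theta (4–7.5), beta1 (12.5–30),
and gamma (30.5–44 Hz); each band is reduced to the first principal
component of the 3×3 component covariance (sign convention: positive
correlation with the largest-variance component); the Hilbert envelope of
the beta1 and gamma components is correlated (Pearson) with the theta
component, excluding 1 s at each edge for filter/Hilbert transients. Note
this measures *linear* covariation between the theta waveform and the fast
envelope — it is not a phase-binned modulation index, and its sign follows
the PC orientation. Individual scores are thresholded against the 95th
percentile of |r| under circular shifts of the envelope by ≥ 2 s (spectra
preserved, alignment destroyed; 200 surrogates). Group differences per ROI
use a one-way ANOVA with Bonferroni-corrected pairwise t contrasts (factor
= number of group pairs).

The comodulogram runs a multitaper spectrogram (2 s windows, 0.25 s steps,
3 DPSS tapers at NW = 2 — artifact choices, recorded in output metadata) on
the broadband first PC and correlates mean-removed amplitude time courses
for every 1-Hz frequency pair. The estimator's ±1 Hz bandwidth correlates
immediately neighboring bins; empirical-null statements are made for pairs
separated by more than the bandwidth. Comodulograms are computed per
subject and averaged where group summaries are needed. A nested signal
shows *no* power-to-power coupling between the theta and gamma bins here,
because the theta carrier's own amplitude is constant — phase-to-amplitude
and power-to-power coupling are genuinely different observables.

## Conjunction

Each disorder-vs-healthy contrast gives a 13 × 5 z-map: two-sample
equal-variance t per (ROI, band) mapped through z = Φ⁻¹(T_df(t)),
sign-symmetric and capped at |z| = 37 to stay finite. The conjunction is
the cellwise minimum across contrasts, significant one-sided at
z > Φ⁻¹(0.95) — the "conjunction null" reading, requiring *every* contrast
to show the effect, which matches the claim of areas common to all four
disorders (the alternative global-null test is weaker and not used).
α = 0.05 is uncorrected across the 65 cells, consistent with the reporting
convention it mirrors; the choice is deliberate and visible in the output.

## Problem sizes

Analyses and tests run at desk scale: 20 subjects per group, 60 s records
(the generator's default record length is 300 s), 100 permutations, 200
surrogates, 10 CV repeats. These sizes were chosen as the smallest at which
every statistical behavior of interest is stable; the full-study scale
(264/153/78/31/15 subjects, 5-minute records) is available by configuration
(`tcd simulate --scale 1.0`).

## Known limitations

* ROI-level only: no voxel grids, no inverse solution; EDF ingestion stops
  at channels.
* The nesting statistic inherits the sign ambiguity of PCA; group means are
  interpretable here because the generator canonicalizes orientations.
* The repeats-vs-permutations ANOVA is anticonservative at small n (see
  the calibration caveat above).
* The exact attribute-selection procedure of the original classification
  toolchain is unspecified; weight thresholding is a transparent stand-in.
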