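# Methods

`timemap` implements the analysis chain of a self-projection-in-time EEG
study — questionnaire scoring, behavioral statistics, evoked-potential (EP)
microstate mapping, and distributed source localization — together with a
synthetic-data generator that plays the role of the study cohorts.  This
note documents the models, the defaults and why they were chosen, and what
the synthetic data can and cannot show.

## The latent-trait cohort model

No raw data from the original experiments are publicly available, so every
pipeline input is simulated.  A single latent schizotypy trait
`z ~ N(0, 1)` per subject drives all trait-linked observables:

* **tPAS** (temporal Perceptual Aberration Scale, 20 items rated 1-10):
  item rating = `round(baseline + a·z + u_t + e_i)` clipped to [1, 10],
  with subject-level method noise `u_t` and item noise `e_i`.  The scale
  score is the mean item rating.
* **PAS** (classical Perceptual Aberration Scale, 35 true/false items):
  item endorsement ~ `Bernoulli(logistic(c + b·z + u_p))`; the score is the
  endorsement count.
* **Reaction times**: trial RT = `(m_cond + s_b·u_s + s_rt·z) ·
  exp(σ·ε − σ²/2)` — multiplicative lognormal trial noise (cv ≈ σ) around
  a subject-and-condition mean; condition means 475.3 / 401.1 / 480.1 ms
  (Past / Now / Future).  The location is floored at 150 ms so extreme
  trait/subject draws stay physiological.  Error probabilities are
  condition base rates perturbed by a subject-level logit offset; accuracy
  is deliberately *not* trait-coupled.
* **Time-map duration**: the planted microstate duration per subject and
  condition is `m_cond + s_d·z + sd_cond·η`, rounded to whole samples;
  condition means 110.2 / 39.2 / 105.0 ms with total between-subject SDs
  12.3 / 8.4 / 15.2 ms.

All constants live in `src/timemap/calibration.yaml`.  They were fixed once
by large-n Monte-Carlo so that, in expectation, the generated cohorts
reproduce the reference summary statistics: corr(tPAS, PAS) ≈ 0.57,
corr(tPAS, mean RT) ≈ 0.69, corr(tPAS, time-map duration) ≈ 0.59, the scale
means/SDs, RT condition means, and error rates.  One joint constraint is
not satisfiable under this single-factor structure: per-condition
between-subject RT SDs of ~137-159 ms together with corr(tPAS, RT) = 0.69.
The correlation was prioritized; the generator's between-subject RT SDs
come out near 130 ms.  Error-rate base values sit slightly below the target
group means to offset the Jensen inflation introduced by the subject-level
logit noise.

What the generator does **not** emulate: real electrode geometry (the
montage is a synthetic Fibonacci-spiral cap), ocular/muscle artifacts
(except a toy fixture used to exercise epoch rejection), gradual topography
drift inside a microstate, between-subject topography variability, and any
sex differences (none were reported as significant).  Passing tests
therefore demonstrate *internal* correctness and parameter recovery, not
performance on recorded EEG.

## Evoked-potential generator

EPs are 0-800 ms epochs (half-open window; 1638 samples at the default
2048 Hz) built from six smooth, mutually orthogonal, zero-mean, unit-GFP
template topographies laid out in a fixed sequence; the fourth segment
(onset 350 ms) is the condition-modulated "time-map".  Within a segment the
active template is scaled by a positive envelope (sin² bump between 1.5 and
6 µV) so GFP varies within segments and fitting is not degenerate; spatial
Gaussian sensor noise (0.5 µV) is added and the result re-referenced to the
average.  Ground-truth segment boundaries are recorded next to every
evoked.  The generated EPs represent *already preprocessed* data
(average-referenced, in-band); the default pipeline therefore does not
band-pass them again (re-filtering would smear the planted boundaries) —
the filter stage is exercised on its own fixtures.

## Microstate analysis

Segmentation is a modified spatial k-means on the time-point topographies
of the concatenated per-condition group averages: templates are initialized
from random normalized time-point maps; samples are assigned to the
template with the highest spatial (Pearson, across channels) correlation;
templates are updated from their assigned maps; best of `n_restarts`
(default 10) by GFP²-weighted global explained variance.  Assignment is
**polarity-sensitive** by default — these are stimulus-locked EPs where
polarity is meaningful — with the polarity-invariant variant (squared
correlation, dominant-eigenvector update) behind a flag.

The number of maps q is chosen over 2..12 by the cross-validation
criterion `CV(q) = σ² · ((N−1)/(N−1−q))²`, where σ² is the mean per-sample
map power unexplained by the assigned (unit-norm) template divided by N−1.
With N = 192 electrodes the penalty is weak and the criterion tends to
select generously many maps on near-noiseless group averages; the surplus
templates capture transition blends and do not bias individual back-fitting
(verified by the parameter-recovery tests).

Back-fitting assigns every sample of an individual EP to the
best-correlating group template; per template this yields the duration
(assigned samples × sampling interval) and the mean GFP over assigned
samples (missing when a template receives no samples).  Runs shorter than
`min_duration_samples` (default 1 = off) are absorbed by the stronger
neighbor.  Ties in the assignment go to the lowest template index.

Duration and GFP are analyzed per template with a one-way within-subject
ANOVA over the Time factor (explicit SS decomposition, df = (k−1, (k−1)(n−1)),
no sphericity correction by default, Greenhouse-Geisser available).  When
the residual SS vanishes with a non-zero condition effect the result is
flagged as perfect separation instead of dividing by zero; when the
condition SS also vanishes F = 0.  The "time-map" is identified as the
template with the most significant duration ANOVA; because the temporal
neighbor of a variable-duration segment necessarily shows the complementary
effect, near-ties are broken toward the template appearing earliest in the
group segmentation.  Score correlations use each subject's measure averaged
over the three conditions (an assumption; the aggregation is not uniquely
determined by the study description) and two-tailed Pearson tests at
α = 0.05 with no multiple-testing correction (matching the original
analysis; a correction switch exists but is off by default).

## Forward model and distributed inverse

The head is three concentric spheres (brain/skull/scalp radii 87/92/100 mm,
conductivities 0.33/0.0042/0.33 S/m).  The dipole lead field is the exact
spherical-harmonic series: per degree the shell coefficients solve the
continuity/boundary system (radii normalized by the scalp radius for
conditioning; 100 terms), and the solver reduces to the classical
closed-form homogeneous-sphere series when all conductivities are equal —
that closed form, implemented independently, is the test oracle.  A
current dipole at the sphere center produces the classic cosθ surface
pattern (n = 1 term); the forward tests assert that behavior.

The solution space is a cubic lattice clipped to 95% of the brain radius
(default 12 mm spacing, ~1400 nodes; the spacing is configurable and the
default keeps the node count in the 1000-4000 range).  The inverse follows
the local-autoregressive-average idea: each node's current should resemble
a distance-weighted average of its neighbors (radius 2.1 × spacing ≈ the
26-neighborhood, weights ∝ distance⁻²).  With `A = I − α·W` (row-normalized
W; damping α = 0.5 keeps A invertible and balances the spatial prior
against sharpness) the source metric is `M = AᵀA`, augmented with depth
weighting (prior variance ∝ ‖L_i‖⁻²), and the estimate is the Tikhonov
solution `J = C Lᵀ (L C Lᵀ + λI)⁻¹ v`.  λ is fixed or chosen per map by an
L-curve corner scan on a log grid.

Linear inverses localize with a systematic position bias when peaks are
read off the raw current magnitude.  Peak detection therefore uses the
**resolution-standardized power**: at each node the 3-vector estimate is
normalized by its model resolution covariance (the sLORETA construction,
applied to the LAURA-type kernel).  Noiseless single superficial dipoles
then peak at the true node for ~87% of sources and never more than one
face-neighbor away; the raw magnitude remains available.  Reported source
coordinates are relative to the spherical model — no anatomical labels are
implied.

## Numerical conventions and edge cases

* Windows are half-open `[t0, t1)` with 0-based samples; durations are
  rounded to whole samples; planted durations are clipped to ≥ 1 sample
  (with a warning) and to leave the following segment non-empty.
* GFP is the spatial standard deviation (ddof 0); spatial correlation
  centers both maps; flat maps are errors, zero-GFP samples are assigned
  but contribute zero weight to explained variance.
* Residual variance in the CV criterion is clamped at 0 against roundoff;
  model selection is argmin over the q grid.
* Empty k-means clusters are re-seeded at the worst-explained sample.
* All randomness flows through `numpy.random.default_rng`; cohort-level
  generators spawn child streams per subject × condition, so outputs are
  bit-reproducible for a fixed seed and independent of iteration order.
* Reports contain no timestamps; a fixed config + seed produces
  byte-identical artifacts.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run the full-resolution
14-subject EEG pipeline (192 channels, 2048 Hz) for duration recovery, and
reduced configurations elsewhere — 64 channels / 512 Hz for the 200-subject
correlation cohort, 16-32 channels / 256-512 Hz for replicated simulations
(type-I calibration at 200 replicate cohorts, parameter recovery over 20
cohorts), and a 16 mm source grid for inverse tests.  These sizes are the
package's chosen defaults for its own validation harness; the generator's
scientific defaults (cohort sizes, noise levels, effect sizes) are never
reduced in the calibration checks that target the reference statistics.

## Known limitations

* The spherical three-shell model and synthetic montage make source
  coordinates qualitatively, not anatomically, interpretable.
* The CV criterion's weak penalty at high channel counts over-selects q on
  clean group averages (see above); real, noisier data would not show this.
* The PAS scoring key is configurable but defaults to all-true keying; the
  official instrument key is not distributed here.
* The questionnaire item-level calibration is unconstrained beyond
  scale-level targets (no public item statistics exist); item-level
  analyses of the synthetic cohorts are therefore not meaningful.
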