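# Methods

This note documents the models, parameter choices and numerical
decisions behind `physiophen`, in the spirit of a methods appendix: what
each component assumes, which knobs matter, and what the synthetic
validation does and does not establish.

## Synthetic cohort model

### RR-interval (tachogram) generator

Beat-to-beat intervals are generated additively:

    RR_k = base + a_LF sin(2π·0.1·t_k + φ1) + a_HF sin(2π·0.25·t_k + φ2)
           + ε_k + J_k,     ε_k ~ N(0, σ²),   J_k = pause jumps

with `base = 60000 / HR` ms, sparse strictly positive "ectopic pause"
jumps (per-beat probability p, mean magnitude M, ±30% uniform spread)
and a 250 ms floor.  This is a statistical emulator, not a
cardiovascular model: only the distributional signatures that the
downstream extractor measures are controlled.

Calibration is closed-form and cached per archetype:

- σ (plus the sinusoid contribution to successive differences) is
  solved from the pNN50 target via the Gaussian successive-difference
  relation `pNN50 = 2(1 − Φ(50/σ_d))`; when pNN50 ≈ 0 the SDNN target
  sets the variance budget instead.
- The LF/HF target splits the sinusoidal variance, accounting for the
  broadband (white-jitter) power that falls into each band.
- The jump process carries the variance the continuous components
  cannot deliver, with magnitude set by the RR-skewness target
  (`skew ≈ p·M³/σ³` for rare positive jumps).

An important interaction is documented here deliberately: the HRV
extractor applies a standard NN artifact filter (intervals outside
[300, 2000] ms or changing >30% against the last accepted interval are
excluded).  That filter removes exactly the pause intervals that
produce very large "SDNN" values in artifact-contaminated recordings.
Archetype targets that combine a large SDNN with a small pNN50 are
therefore *infeasible after NN filtering*; calibration approaches them
best-effort (a warning names the shortfall) and guarantees instead the
ordering of the archetypes (SP3 > SP2 > SP1 in filtered SDNN, SP4
highest in pNN50).  The raw RR series — summarized separately
(skewness, entropy, extremes) — retains the pause-driven signatures.

### Waveform synthesizers

- **ECG**: one PQRST Gaussian-sum template per beat at the cumulative RR
  times; the R amplitude is modulated by the respiratory phase
  (default depth 10%), which is what ECG-derived respiration recovers;
  optional <0.3 Hz baseline wander and white noise at a configurable
  SNR (cohort default 25 dB).
- **PPG**: one pulse per beat, delayed by the pulse-arrival time.  Each
  pulse is a raised-cosine systolic upstroke (exactly zero at the foot,
  peak at `rise_frac` of the cycle) followed by an exponential
  diastolic runoff (τ = 0.3 cycle) that keeps decaying into the next
  foot — so the onset is a genuine local minimum — plus a dicrotic
  Gaussian wave scaled by the notch prominence (0 removes the notch
  entirely; the decay is shifted to end at zero so window truncation
  leaves no curvature artifact).  Per-beat AC amplitudes come from a
  standardized-gamma family whose skewness matches the archetype
  target (gamma skewness 2/√k, sign-flipped for negative targets).
- **RESP**: quasi-sinusoidal cycles starting at the trough, with
  multiplicative period jitter (default 5%) and additive noise.

### Covariates and outcomes

SBP / respiratory rate are Gaussian with means chosen so the
archetype's abnormality prevalence (SBP ≤ 100, RR ≥ 22) is hit exactly
under the assumed spreads (15 mmHg, 4 /min); GCS is 15 with the
complementary probability, otherwise uniform 8–14.  Death times are
exponential with the rate matching the archetype's 28-day mortality,
censored at day 28.  Support flags (septic shock, vasopressors,
ventilation) are sampled as a *first-activation day* against the
cumulative day-2/7/28 probabilities, so a flag set at day 2 is set at
all later horizons (monotone exposure).  HRV-statistic targets, heart
rates and mortality rates follow the published per-group medians/rates
of a reference sepsis cohort; PPG morphology, respiratory rates,
support-flag and covariate prevalences are package choices consistent
with the qualitative group descriptions (e.g. the highest-mortality
archetype gets the slowest systolic upstroke and the highest shock/
vasopressor burden).

## Waveform interpreter

- **QC**: flatline = 2 s rolling-window variance collapse; clipping =
  rail-value runs ≥ 0.2 s; amplitude outliers |z| > 6 masked and
  bridged by linear interpolation; optional polyphase resampling.  A
  record whose worst channel is <50% usable is flagged low quality and
  yields a missing feature row rather than an exception.
- **Denoising**: per-channel despike median filter then zero-phase
  4th-order Butterworth band-pass (ECG 0.5–40 Hz, PPG 0.5–8 Hz, RESP
  0.1–0.5 Hz).  The despike kernels are per-channel (ECG 12 ms, PPG
  40 ms, RESP 200 ms): a kernel near 200 ms on ECG would erase the
  ~80 ms QRS complex and defeat R-peak detection.  Forward–backward
  filtering doubles the effective roll-off, giving ≥20 dB suppression
  one octave outside the band while in-band tones stay within 3 dB.
- **Delineation**: R peaks by the derivative–square–moving-integral
  energy transform with an adaptive threshold and 200 ms refractory
  period, refined to the local ECG maximum.  PPG onsets are the signal
  minima preceding maximal VPG upstrokes; systolic peaks the maxima
  between onsets; the dicrotic notch the first negative-to-positive APG
  zero crossing inside the 40–70% span of the pulse (fallback: VPG
  local minimum), guarded by a requirement that a real deceleration dip
  precede the crossing — filter ripple around zero otherwise produces
  phantom notches on notchless pulses.  Respiratory extrema are
  detected on a 0.5 s-smoothed signal and refined to sub-sample
  precision by intersecting straight-line fits to the two limbs of each
  extremum; unlike parabolic refinement this is unbiased for asymmetric
  (sawtooth-like) breaths, and it removes the sample-grid quantization
  that otherwise turns slowly varying ratios (I:E) into discrete
  levels.
- **Pulse validity**: pulses whose onset-to-onset duration falls
  outside 0.4–1.8× the median are excluded from morphology statistics,
  the same way NN filtering excludes non-normal beats; a single merged
  (missed-onset) pulse otherwise dominates tail-sensitive statistics
  such as skewness.
- **HRV**: time-domain definitions with the sample SD (n−1);
  frequency-domain from the Lomb–Scargle periodogram of the irregular
  NN tachogram, reported as fractions of the 0.003–0.5 Hz grid power so
  all band indices are dimensionless (the native units of "total
  power" in the reference tables are unstated; a normalized fraction
  keeps the printed magnitudes representable); nonlinear indices with
  fixed estimator parameters (m = 2, r = 0.2·SD, multiscale scales 1–3,
  correlation-dimension embeddings 2–5 with the log–log least-squares
  slope over the 10th–60th distance percentiles; Katz fractal dimension
  log10(n)/(log10(n)+log10(d/L))).  A 5-minute window yields roughly
  300–500 beats, which is the regime these estimator settings are
  intended for.
- **Catalog**: 192 unique physiomarker definitions = 27 scalar HRV
  indices + 5 interbeat-covariance eigenvalues + 32 time-varying
  markers × 5 retained summary statistics (mean, p25, p75, skewness,
  histogram Shannon entropy with Freedman–Diaconis binning capped at
  512 bins).  The manifest is data-driven; extraction iterates over it.

## Feature pipeline

Fixed order: outlier cells (|z| > 6, strict) → missingness filter
(>15%, strict) → chained-equation imputation with predictive mean
matching (10 sweeps, 5 donors, ridge-stabilised regressions; one
completed dataset; imputed values always drawn from a column's observed
support) → near-constant filter (dominant value >99% or raw SD < 1e-8;
"SD < 0.01 after standardization" is not a usable rule since
post-standardization SDs are 1 by construction) → iterative correlation
reduction (|r| > 0.85; the worst pair loses its member with the higher
mean absolute correlation to the remaining columns, the conventional
direction; a flag flips it) → standard scaling with stored moments.
Covariate indicators are exempt from the variance/correlation filters
by default because the composite score correlates with its components
by construction.  The pipeline is idempotent on its own output and its
report accounts for every dropped column exactly.

## Representation learning

The FT-Transformer autoencoder follows the reference configuration:
per-feature learnable affine tokenization into a 128-d token space, a
learnable CLS token plus feature-identity embeddings, three post-norm
encoder blocks (4 heads × 32, 256-unit ReLU feed-forward, dropout 0.1),
a linear 32-d latent head on the CLS output, and a two-layer
feed-forward decoder; Adam at 2e-3 with plateau halving (patience 6),
early stopping (patience 20, best weights restored) and batch size 32.
Because no deep-learning framework is assumed, the model runs on a
small in-repo reverse-mode autodiff engine over numpy (float32;
attention and layer-norm are fused primitives with hand-written
backward passes, gradient-checked against finite differences).  The
validation split is 20% of rows by seed; `max_train_rows` caps the
optimisation subset for large inputs while every row is still encoded.
The DVAE baseline is a 128–64–32 Gaussian-latent VAE with mirrored
decoder and KL weight 1 (scaled by feature count so the two ELBO terms
share units); its architecture is a package assumption, config-exposed.

## Consensus phenotyping and the choice of K

Clustering operates on the 2-D UMAP projection of the embedding
(direct clustering of high-dimensional embeddings produced unstable
consensus structure).  Each of 100 iterations subsamples 80% without
replacement, builds one Ward dendrogram, and cuts it at every K in
2–8; consensus(i,j) = co-cluster count / co-sample count (pairs never
co-sampled stay undefined and are excluded from the CDFs).

K is selected from the consensus CDFs.  Two summaries are computed per
K: the area under the CDF with its relative gain over K−1, and the
*ambiguity* — the CDF mass strictly between 0.1 and 0.9, i.e. the
fraction of pairs co-clustered inconsistently across resamples.  The
selected K is the largest K whose partition is still crisp (ambiguity
≤ 2%).  A fixed threshold on the AUC gain alone turned out to be
unusable: on ideally separated four-cluster data the AUC keeps gaining
3–7% per extra K, because over-splitting keeps moving pair mass toward
zero consensus — the gain never falls below any sensible fixed
threshold, while the ambiguity jumps from exactly 0 to several percent
right after the true K.  The 2% default was calibrated on ideal
blob/single-blob studies; with no crisp K at all (one homogeneous
cloud) the result is flagged unstable and K falls back to the smallest
candidate.  Final labels come from average-linkage clustering of
1 − consensus at K*, with per-patient confidence = mean consensus with
co-members.

## Classifier and explanations

XGBoost at library defaults, stratified 80/20 split (stratification
protects the 12.5% archetype at moderate cohort sizes), one-vs-rest
ROC/PR AUCs.  Per-class attributions come from the ensemble's native
TreeSHAP (`pred_contribs`), which is exact for tree models and
satisfies additivity to the margin by construction; the top-20 ranking
uses mean |attribution| and the direction of effect is the sign of the
correlation between feature value and attribution.  The classifier is
trained on the post-pipeline feature table on its raw scale (trees are
invariant to monotone rescaling, so this matches the standardized
matrix up to feature naming).

## Outcome statistics

Kruskal–Wallis (tie-corrected, chi-squared approximation — group sizes
in intended use are ≫5), chi-squared without continuity correction for
k×2 tables (a flag enables Yates for 2×2), one-way ANOVA reconstructed
from per-group (n, mean, SD) summaries — algebraically identical to the
raw-data F test, letting printed cohort tables be tested — and
Kaplan–Meier with Greenwood-variance confidence intervals plus the
multi-group log-rank test (via lifelines, validated against
hand-computed product-limit and observed-vs-expected oracles in the
test suite).  All rows are treated as independent patients.

## Problem sizes used in validation

The end-to-end validation runs ten independently seeded 400-patient
cohorts (5-minute records at ECG 250 Hz / PPG 125 Hz / RESP 62.5 Hz)
through the full pipeline; the transformer training inside those runs
uses the reference architecture with a reduced optimisation budget
(3 epochs on a 96-row training subset, 8% validation split) — embedding
quality at this budget is sufficient for archetype recovery, and
`scripts/acceptance.py` uses the same configuration.  The
representation-quality criterion (validation MSE < 25% of the untrained
MSE on rank-deficient data) is evaluated at 200×50 over 20 seeds with
5-epoch training.

## What the synthetic validation does and does not show

Passing tests establish that the implementation is internally correct
(formulas match independent oracles, filters meet their attenuation
specs, imputation beats naive baselines, the selection rule recovers
planted structure) and that the pipeline recovers subgroups whose
signatures match the planted archetypes.  The generator's archetypes
are far cleaner than real ICU physiology: no arrhythmia taxonomies, no
electrode artifacts or missing channels at realistic rates, no
covariate-outcome confounding beyond the archetype level, and pulse
morphology from a three-component template rather than measured
hemodynamics.  Recovery of four phenotypes here therefore validates the
machinery, not the clinical claim that four subtypes exist in any given
cohort.

## Known limitations

- LF/HF calibration is approximate when white jitter dominates the
  spectrum; only the cross-archetype ordering is relied upon.
- The NN artifact filter makes extreme SDNN targets unreachable by
  design (see the RR-model section); warnings are emitted.
- Band-pass filtering shifts the detected PPG foot by 1–2 samples; the
  pulse-arrival-time ground-truth check uses the unfiltered clean path,
  and cohort-level PAT carries a small constant offset common to all
  patients.
- UMAP determinism holds for a fixed seed and library version;
  cross-version layouts may differ, which can change selected K on
  borderline data.
- The transformer trains on CPU; wall-clock scales roughly with
  n_tokens² per block, so very wide feature tables should cap
  `max_train_rows` or prune features first.
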