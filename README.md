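# physiophen

Waveform-based physiological phenotyping of sepsis.

Most sepsis phenotyping works from intermittently charted clinical
variables. `physiophen` instead derives patient subtypes ("physio-
phenotypes") from the continuous bedside waveforms themselves — a
5-minute window of single-lead ECG, photoplethysmogram (PPG) and
transthoracic-impedance respiration per patient — and stratifies
clinical outcomes by the discovered subtypes.  It is written for
researchers in physiological signal processing and clinical informatics
who want a tested, end-to-end reference pipeline they can run without
access to protected ICU data.

## What the pipeline computes

1. **Synthetic cohort generator** — four archetypal autonomic/vascular
   signatures (SP1–SP4: suppressed HRV with irregular dynamics; pause-
   driven high-SDNN rhythms with negative PPG-amplitude skewness;
   high-variability slow-upstroke vascular profiles; parasympathetic-
   dominant high-pNN50 physiology) are planted into fully synthetic
   ECG/PPG/RESP records together with covariates (SBP, respiratory
   rate, GCS) and 28-day outcomes, giving every downstream stage a
   ground truth.
2. **Multimodal waveform interpreter** — QC (flatline/clipping/outlier
   masking), zero-phase band-pass denoising (ECG 0.5–40 Hz, PPG
   0.5–8 Hz, RESP 0.1–0.5 Hz), derived signals (EDR, VPG, APG),
   fiducial delineation (R peaks; pulse onset/systolic/dicrotic-notch/
   offset; respiratory extrema) and **192 physiomarkers**: scalar HRV
   indices (SDNN, RMSSD, pNN50, Lomb–Scargle band powers, sample/fuzzy/
   multiscale entropy, correlation dimension, Katz fractal dimension,
   …), per-pulse PPG morphology/timing (AC amplitude, normalized
   systolic/diastolic areas, pulse widths, pulse-arrival time, interbeat
   shape eigenvalues) and per-cycle respiratory dynamics, each
   time-varying series summarized by five retained statistics (mean,
   p25, p75, skewness, Shannon entropy).
3. **Feature pipeline** — covariate indicator encoding
   (SBP ≤ 100 mmHg, RR ≥ 22/min, GCS < 15, composite 0–3), |z| > 6 cell
   rejection, >15% missingness filtering, chained-equation imputation
   with predictive mean matching, near-constant and |r| > 0.85
   correlation filtering, standard scaling.
4. **Representation learning** — a feature-tokenizer transformer
   autoencoder (numeric features as tokens, CLS summary token, 3 blocks
   × 4 heads × 128-d, 32-d latent, MSE reconstruction objective) with
   PCA, deep variational autoencoder, and identity baselines.
5. **Consensus phenotyping** — UMAP to 2-D
   (`n_neighbors=30, min_dist=0.1`), 100 × 80%-resampled Ward-linkage
   consensus clustering, CDF-based selection of the cluster number, and
   per-patient assignment confidence.
6. **Distillation & outcomes** — an XGBoost phenotype classifier with
   native TreeSHAP per-phenotype explanations, Kruskal–Wallis /
   chi-squared / summary-statistics ANOVA group comparisons,
   Kaplan–Meier curves with log-rank tests, and day-2/7/28 septic
   shock / vasopressor / ventilation prevalence tables.

## Worked example

```python
import numpy as np
from sklearn.metrics import adjusted_rand_score
from physiophen.cohort import CohortConfig, generate_cohort
from physiophen.workflow import DiscoveryConfig, run_discovery

bundle = generate_cohort(CohortConfig(n_patients=400, seed=7))
res = run_discovery(bundle, DiscoveryConfig(
    seed=7, method="ft_t",
    method_kwargs={"max_epochs": 3, "max_train_rows": 96, "val_fraction": 0.08}))

truth = bundle.metadata.set_index("patient_id").loc[res.features.index, "archetype"]
print("selected K:", res.clusterer.k_selected_)
print("ARI vs planted archetypes:", round(adjusted_rand_score(truth, res.labels), 3))
print("silhouette:", round(res.metrics["silhouette"], 2))
```

prints

```
selected K: 4
ARI vs planted archetypes: 1.0
silhouette: 0.9
```

i.e. consensus clustering selects four phenotypes and they coincide
exactly with the four planted archetypes; the silhouette describes how
compact and separated the clusters are in the 2-D projection.  The same
run exposes the cleaned feature matrix (`res.matrix`), the 32-d
embedding, per-patient assignment confidence, and the per-K consensus
matrices/CDFs for stability inspection.

A command-line interface mirrors the library:

```bash
physiophen simulate --n 400 --seed 7 --out cohort/
physiophen extract --in cohort/ --out features.csv
physiophen preprocess --in features.csv --out matrix.csv --report report.json
physiophen embed --in matrix.csv --method ft_t --out emb.csv --seed 7
physiophen cluster --in emb.csv --out labels.csv --seed 7
physiophen outcomes --labels labels.csv --outcomes cohort/metadata.csv --out report/
```

## Layout

- `physiophen.cohort` — archetype table, RR-interval model, waveform synthesizers, cohort assembly and the CSV+JSON cohort container
- `physiophen.interpreter` — stages 1–6 of the waveform interpreter and the physiomarker catalog
- `physiophen.pipeline` — sklearn-style cleaning transformers and the composed `FeaturePipeline`
- `physiophen.representation` — FT-Transformer autoencoder, DVAE, PCA/identity baselines, and the small autodiff engine they run on
- `physiophen.phenotyping` — UMAP projection, `ConsensusClusterer`, K selection, cluster metrics
- `physiophen.predictor` — `PhenotypeClassifier` (XGBoost + TreeSHAP)
- `physiophen.outcomes` — group tests, summary ANOVA, Kaplan–Meier/log-rank, prevalence tables
- `physiophen.workflow` — the end-to-end discovery driver used by the CLI, tests and acceptance script

See `docs/methods.md` for the modelling assumptions, parameter
defaults, numerical choices and known limitations.
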