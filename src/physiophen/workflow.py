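"""End-to-end phenotype discovery driver.

Chains the whole study on a waveform cohort: physiomarker extraction,
covariate encoding, feature cleaning, representation learning, 2-D
projection, consensus clustering and (optionally) classifier
distillation.  Used by the command-line interface, the test suite and
the acceptance script, so every consumer runs the identical pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .cohort import CohortBundle, CohortConfig, generate_cohort
from .interpreter import WaveformFeatureExtractor
from .phenotyping import ConsensusClusterer, ProjectionConfig, cluster_metrics, project
from .pipeline import FeaturePipeline, encode_covariates
from .representation import make_embedder

__all__ = ["DiscoveryConfig", "DiscoveryResult", "run_discovery",
           "extract_cohort_features"]


@dataclass
class DiscoveryConfig:
    method: str = "ft_t"
    k_range: tuple = (2, 3, 4, 5, 6, 7, 8)
    n_iterations: int = 100
    sample_fraction: float = 0.8
    seed: int = 0
    # representation-training budget; None = estimator defaults
    method_kwargs: dict = field(default_factory=dict)
    projection: Optional[ProjectionConfig] = None


@dataclass
class DiscoveryResult:
    features: pd.DataFrame          # raw physiomarker rows (+ covariates)
    matrix: pd.DataFrame            # cleaned standardized matrix
    embedding: np.ndarray
    points: np.ndarray              # 2-D projection
    clusterer: ConsensusClusterer
    labels: np.ndarray
    metrics: dict
    pipeline: FeaturePipeline
    embedder: object


def extract_cohort_features(bundle: CohortBundle) -> pd.DataFrame:
    """Physiomarker rows plus encoded covariates for a generated cohort."""
    extractor = WaveformFeatureExtractor()
    feats = extractor.transform([p.waveforms for p in bundle.patients])
    meta = bundle.metadata.set_index("patient_id")
    cov = encode_covariates(meta.loc[feats.index, "sbp"],
                            meta.loc[feats.index, "resp_rate"],
                            meta.loc[feats.index, "gcs"])
    cov.index = feats.index
    return pd.concat([feats, cov], axis=1)


def run_discovery(bundle: CohortBundle, config: DiscoveryConfig | None = None,
                  features: pd.DataFrame | None = None) -> DiscoveryResult:
    """Run extraction -> cleaning -> embedding -> projection -> consensus."""
    config = config or DiscoveryConfig()
    if features is None:
        features = extract_cohort_features(bundle)
    pipeline = FeaturePipeline(random_state=config.seed)
    matrix = pipeline.fit_transform(features)

    embedder = make_embedder(config.method, random_state=config.seed,
                             **config.method_kwargs)
    z = embedder.fit(matrix.to_numpy()).transform(matrix.to_numpy())

    proj = config.projection or ProjectionConfig(seed=config.seed)
    pts = project(z, proj)

    cc = ConsensusClusterer(k_range=config.k_range,
                            n_iterations=config.n_iterations,
                            sample_fraction=config.sample_fraction,
                            random_state=config.seed).fit(pts)
    metrics = cluster_metrics(pts, cc.labels_) if len(set(cc.labels_)) > 1 else {}
    return DiscoveryResult(features=features, matrix=matrix, embedding=z,
                           points=pts, clusterer=cc, labels=cc.labels_,
                           metrics=metrics, pipeline=pipeline, embedder=embedder)
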