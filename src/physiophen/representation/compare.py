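"""Head-to-head evaluation of representation methods.

Runs each candidate embedding through the same projection + consensus
clustering pipeline and reports consensus-CDF sharpness, internal
cluster-quality metrics and (when planted ground truth is available)
adjusted-Rand label recovery.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from ..phenotyping import (ConsensusClusterer, ProjectionConfig, cluster_metrics,
                           project)
from .baselines import IdentityEmbedding, PCAEmbedding
from .dvae import DeepVAE
from .ft_transformer import FTTransformerAutoencoder

__all__ = ["make_embedder", "compare_representations"]

METHODS = ("ft_t", "pca", "dvae", "none")


def make_embedder(method: str, random_state: int | None = None, **overrides):
    """Factory for the four representation methods."""
    if method == "ft_t":
        return FTTransformerAutoencoder(random_state=random_state, **overrides)
    if method == "pca":
        return PCAEmbedding(random_state=random_state, **overrides)
    if method == "dvae":
        return DeepVAE(random_state=random_state, **overrides)
    if method == "none":
        return IdentityEmbedding(**overrides)
    raise ValueError(f"unknown representation method: {method}")


def compare_representations(matrix, methods=METHODS, labels_true=None,
                            random_state: int = 0,
                            projection: ProjectionConfig | None = None,
                            consensus_kwargs: dict | None = None,
                            method_kwargs: dict | None = None) -> pd.DataFrame:
    """Cluster with every method and report quality side by side.

    ``consensus_cdf_sharpness`` is the fraction of defined consensus
    values within 0.1 of either 0 or 1 at the selected K (1.0 for an
    ideal block-diagonal consensus matrix).
    """
    x = np.asarray(matrix, dtype=float)
    projection = projection or ProjectionConfig(seed=random_state)
    consensus_kwargs = dict(consensus_kwargs or {})
    consensus_kwargs.setdefault("random_state", random_state)
    method_kwargs = method_kwargs or {}
    rows = []
    for method in methods:
        emb = make_embedder(method, random_state=random_state,
                            **method_kwargs.get(method, {}))
        z = emb.fit(x).transform(x)
        pts = project(z, projection)
        cc = ConsensusClusterer(**consensus_kwargs).fit(pts)
        cons = cc.result_.consensus[cc.k_selected_]
        iu = np.triu_indices(len(cons), k=1)
        vals = cons[iu]
        vals = vals[np.isfinite(vals)]
        sharp = float(np.mean((vals < 0.1) | (vals > 0.9))) if len(vals) else np.nan
        row = {"method": method, "k_selected": cc.k_selected_,
               "consensus_cdf_sharpness": sharp}
        row.update(cluster_metrics(pts, cc.labels_))
        if labels_true is not None:
            row["ari"] = float(adjusted_rand_score(labels_true, cc.labels_))
        rows.append(row)
    return pd.DataFrame(rows).set_index("method")
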