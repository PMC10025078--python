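"""Pre-modeling screens and descriptive structure.

Collinearity screening with pairwise Pearson correlations (|r| >= 0.7 flags
a predictor pair as inadmissible), Ward hierarchical clustering of site
composition on Euclidean distances, and average-silhouette validation of
candidate partition sizes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.metrics import silhouette_samples

logger = logging.getLogger(__name__)

COLLINEARITY_THRESHOLD = 0.7


def pearson_screen(env: pd.DataFrame, threshold: float = COLLINEARITY_THRESHOLD) -> pd.DataFrame:
    """Flag numeric predictor pairs with |Pearson r| >= threshold.

    Categorical columns are excluded; constant columns are skipped with a
    warning (their correlation is undefined). An empty result means every
    pair is admissible.
    """
    num = env.select_dtypes(include=[np.number])
    if num.shape[1] < 2:
        raise ValueError("need at least two numeric columns to screen")
    keep = []
    for c in num.columns:
        if num[c].nunique() <= 1:
            warnings.warn(f"column {c!r} is constant; correlation undefined, skipped")
        else:
            keep.append(c)
    corr = num[keep].corr(method="pearson")
    rows = []
    for i, a in enumerate(keep):
        for b in keep[i + 1 :]:
            r = corr.loc[a, b]
            if abs(r) >= threshold:
                rows.append((a, b, float(r)))
    return pd.DataFrame(rows, columns=["var_a", "var_b", "r"])


@dataclass
class ClusterResult:
    """Ward dendrogram with cut labels and silhouette widths per candidate k."""

    linkage: np.ndarray  # scipy linkage matrix
    labels: dict[int, np.ndarray]  # k -> labels (1..k)
    sites: list[str]
    silhouette: dict[int, float] | None = None
    best_k: int | None = None


def ward_cluster(density: pd.DataFrame, log1p: bool = False, max_k: int = 10) -> ClusterResult:
    """Ward minimum-variance clustering of sites by species composition.

    Operates on raw site coordinates (density rows), which makes the
    increase-in-variance criterion internally consistent with Euclidean
    distances. ``log1p`` optionally compresses dominant species first.
    """
    X = density.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least two sites to cluster")
    if log1p:
        X = np.log1p(X)
    Z = linkage(X, method="ward")
    ks = range(2, min(max_k, X.shape[0] - 1) + 1)
    labels = {k: fcluster(Z, t=k, criterion="maxclust") for k in ks}
    return ClusterResult(linkage=Z, labels=labels, sites=list(density.index))


def silhouette_validate(
    density: pd.DataFrame, result: ClusterResult, log1p: bool = False
) -> ClusterResult:
    """Mean silhouette width per candidate k; best k is the argmax.

    Singleton clusters contribute a silhouette of 0 (sklearn's convention,
    adopted here as the documented choice).
    """
    X = density.to_numpy(dtype=float)
    if log1p:
        X = np.log1p(X)
    sil: dict[int, float] = {}
    for k, lab in result.labels.items():
        if len(np.unique(lab)) < 2:
            continue
        sil[k] = float(np.mean(silhouette_samples(X, lab)))
    result.silhouette = sil
    result.best_k = max(sil, key=lambda k: (sil[k], -k)) if sil else None
    return result


def cluster_tables(result: ClusterResult) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(labels per k, silhouette per k) as exportable DataFrames."""
    lab = pd.DataFrame(
        {f"k{k}": v for k, v in result.labels.items()}, index=pd.Index(result.sites, name="site")
    )
    sil = pd.DataFrame(
        sorted((result.silhouette or {}).items()), columns=["k", "mean_silhouette"]
    )
    return lab, sil
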