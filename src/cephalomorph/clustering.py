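"""Sub-phenotype discovery by k-means on the proportion feature space.

Within each sex, specimens are clustered on their eight proportions.
Because the proportions differ roughly five-fold in magnitude (P05 ~ 5,
P04 ~ 1), the default standardises each feature to zero mean and unit
variance before clustering; unscaled clustering is available to probe
sensitivity.  The elbow curve (total within-cluster sum of squares versus
k) is reported as a diagnostic; the number of clusters itself is always an
explicit input to the pipeline.

With k = 2 the clusters are given the orthodontic growth-pattern labels:
the cluster with the larger mean P01 (facial height over fronto-orbital
width, i.e. a longer, narrower face) is labelled dolichofacial, the other
brachyfacial.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.cluster import KMeans

from .landmarks import PROPORTION_CODES, ProportionVector

__all__ = [
    "ClusterModel",
    "ElbowCurve",
    "kmeans_fit",
    "elbow_curve",
    "label_phenotypes",
]

DOLICHOFACIAL = "dolichofacial"
BRACHYFACIAL = "brachyfacial"
UNLABELLED = "unlabelled"


@dataclass
class ClusterModel:
    """A fitted k-means partition of one group's proportion vectors."""

    k: int
    centroids: np.ndarray          # (k, 8) in the clustering feature space
    assignments: np.ndarray        # (n,) cluster index per specimen
    wss: float                     # total within-cluster sum of squares
    feature_scaling: str           # "none" | "zscore"
    seed: int
    feature_mean: np.ndarray       # (8,) scaling parameters (zeros/ones if none)
    feature_sd: np.ndarray
    phenotype_labels: list[str] = field(default_factory=list)

    def cluster_mean_proportions(
        self, features: Sequence[ProportionVector]
    ) -> list[ProportionVector]:
        """Per-cluster mean of the raw (unscaled) proportions."""
        X = np.stack([p.as_array() for p in features])
        means = []
        for c in range(self.k):
            members = X[self.assignments == c]
            if members.size == 0:
                means.append(ProportionVector(*([float("nan")] * 8)))
            else:
                means.append(ProportionVector(*members.mean(axis=0)))
        return means

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "centroids": self.centroids.tolist(),
            "assignments": self.assignments.tolist(),
            "wss": self.wss,
            "feature_scaling": self.feature_scaling,
            "seed": self.seed,
            "feature_mean": self.feature_mean.tolist(),
            "feature_sd": self.feature_sd.tolist(),
            "phenotype_labels": list(self.phenotype_labels),
            "feature_names": list(PROPORTION_CODES),
        }


@dataclass
class ElbowCurve:
    """Total within-cluster sum of squares over a range of k."""

    k_values: list[int]
    wss_values: list[float]
    suggested_k: int


def _feature_matrix(
    features: Sequence[ProportionVector], scaling: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    X = np.stack([p.as_array() for p in features])
    if scaling == "none":
        return X, np.zeros(X.shape[1]), np.ones(X.shape[1])
    if scaling != "zscore":
        raise ValueError(f"unknown feature scaling {scaling!r}")
    mu = X.mean(axis=0)
    sd = X.std(ddof=0, axis=0)
    sd = np.where(sd == 0, 1.0, sd)  # constant feature carries no information
    return (X - mu) / sd, mu, sd


def kmeans_fit(
    features: Sequence[ProportionVector],
    k: int,
    scaling: str = "zscore",
    seed: int = 0,
    n_init: int = 20,
) -> ClusterModel:
    """Fit k-means (k-means++ inits, Lloyd iterations, best of ``n_init``).

    Deterministic given ``seed``.  All-identical feature vectors collapse to
    a single effective centroid; this is reported with a warning rather
    than an error.
    """
    n = len(features)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of specimens n={n}")
    X, mu, sd = _feature_matrix(features, scaling)
    n_distinct = np.unique(X, axis=0).shape[0]
    if n_distinct < k:
        warnings.warn(
            f"only {n_distinct} distinct feature vectors for k={k}: "
            "clustering is degenerate (single effective centroid)",
            RuntimeWarning,
            stacklevel=2,
        )
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", category=UserWarning, module="sklearn")
        km = KMeans(
            n_clusters=k,
            init="k-means++",
            n_init=n_init,
            algorithm="lloyd",
            random_state=seed,
        ).fit(X)
    return ClusterModel(
        k=k,
        centroids=km.cluster_centers_.copy(),
        assignments=km.labels_.copy(),
        wss=float(km.inertia_),
        feature_scaling=scaling,
        seed=seed,
        feature_mean=mu,
        feature_sd=sd,
    )


def elbow_curve(
    features: Sequence[ProportionVector],
    k_max: int,
    scaling: str = "zscore",
    seed: int = 0,
    n_init: int = 20,
) -> ElbowCurve:
    """WSS for k = 1..k_max plus an automated elbow suggestion.

    The suggestion is the k maximising the discrete second difference
    wss(k-1) - 2 wss(k) + wss(k+1), a proxy for the visual elbow; it
    requires k_max >= 3, otherwise k = 1 is suggested.
    """
    n = len(features)
    if k_max >= n:
        raise ValueError(f"k_max={k_max} must be smaller than n={n}")
    ks = list(range(1, k_max + 1))
    wss = [kmeans_fit(features, k, scaling=scaling, seed=seed, n_init=n_init).wss for k in ks]
    if k_max >= 3:
        second_diff = [wss[i - 1] - 2 * wss[i] + wss[i + 1] for i in range(1, k_max - 1)]
        suggested = ks[1 + int(np.argmax(second_diff))]
    else:
        suggested = 1
    return ElbowCurve(k_values=ks, wss_values=[float(w) for w in wss], suggested_k=suggested)


def label_phenotypes(
    model: ClusterModel, cluster_mean_props: Sequence[ProportionVector]
) -> ClusterModel:
    """Attach growth-pattern labels to a two-cluster model.

    The cluster with the larger mean P01 is dolichofacial (longer face
    relative to fronto-orbital width), the other brachyfacial.  Exact ties
    on P01 are broken by mean P02; any k other than 2 leaves the clusters
    unlabelled with a warning.
    """
    if model.k != 2:
        warnings.warn(
            f"phenotype labels are defined for k=2, got k={model.k}; leaving unlabelled",
            RuntimeWarning,
            stacklevel=2,
        )
        model.phenotype_labels = [UNLABELLED] * model.k
        return model
    p01 = [m.P01 for m in cluster_mean_props]
    p02 = [m.P02 for m in cluster_mean_props]
    if p01[0] != p01[1]:
        dolicho = int(np.argmax(p01))
    else:
        dolicho = int(np.argmax(p02))
    labels = [BRACHYFACIAL, BRACHYFACIAL]
    labels[dolicho] = DOLICHOFACIAL
    model.phenotype_labels = labels
    return model
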