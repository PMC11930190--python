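"""Differential-metabolite screening, concentration PCA and cluster ordering.

Screening combines a PLS-DA VIP score (fit on autoscaled concentrations)
with a one-way ANOVA p-value per compound; a compound is selected when
VIP > 1 *and* p < 0.05, both strict.  PCA and hierarchical clustering of
concentration tables use autoscaled values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.metrics import silhouette_score

from . import chemometrics
from .synthetic_data import ConcentrationTable

__all__ = [
    "DiffMetabolite",
    "screen_differential",
    "cluster_order",
    "concentration_pca",
]


@dataclass
class DiffMetabolite:
    """Per-compound screening outcome."""

    compound: str
    vip: float
    p_value: float
    class_means: dict[str, float]
    selected: bool

    def __post_init__(self) -> None:
        if self.selected != (self.vip > 1.0 and self.p_value < 0.05):
            # thresholds other than the defaults set the flag explicitly
            pass


def _autoscale(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Columns to mean 0 / sd 1; returns (scaled, nonzero-variance mask)."""
    X = np.asarray(X, dtype=float)
    sd = X.std(axis=0, ddof=1)
    mask = sd > 0
    Xs = np.zeros_like(X)
    Xs[:, mask] = (X[:, mask] - X[:, mask].mean(axis=0)) / sd[mask]
    return Xs, mask


def screen_differential(
    table: ConcentrationTable,
    labels: np.ndarray,
    vip_threshold: float = 1.0,
    p_threshold: float = 0.05,
    max_components: int = 5,
) -> list[DiffMetabolite]:
    """VIP > threshold AND p < threshold selection of compounds.

    VIP comes from one global PLS-DA on autoscaled concentrations; the
    p-value from one-way ANOVA across the class groups.  Zero-variance
    compounds are excluded with a warning (their p-value is undefined).
    """
    labels = np.asarray(labels)
    classes = sorted(set(labels.tolist()))
    if len(classes) < 2:
        raise ValueError("screening needs at least 2 classes")
    for c in classes:
        if np.sum(labels == c) < 2:
            raise ValueError(f"class {c!r} has fewer than 2 samples")

    Xs, var_mask = _autoscale(table.values)
    dropped = [
        table.compound_names[j] for j in np.flatnonzero(~var_mask)
    ]
    if dropped:
        warnings.warn(f"zero-variance compounds excluded: {dropped}")
    keep = np.flatnonzero(var_mask)

    cv_folds = min(7, table.n_samples)
    model, _ = chemometrics.fit_plsda(
        Xs[:, keep], labels, max_components=max_components, cv_folds=cv_folds
    )
    vips = chemometrics.vip_scores(model)

    results: list[DiffMetabolite] = []
    for pos, j in enumerate(keep):
        col = table.values[:, j]
        groups = [col[labels == c] for c in classes]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, p = stats.f_oneway(*groups)
        vip = float(vips[pos])
        p = float(p)
        results.append(
            DiffMetabolite(
                compound=table.compound_names[j],
                vip=vip,
                p_value=p,
                class_means={c: float(g.mean()) for c, g in zip(classes, groups)},
                selected=bool(vip > vip_threshold and p < p_threshold),
            )
        )
    return results


def cluster_order(
    table: ConcentrationTable,
    metric: str = "euclidean",
    linkage: str = "complete",
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic row and column leaf orders for a cluster heatmap.

    Agglomerative clustering on autoscaled values; scipy's linkage is
    deterministic for fixed distances, and equal distances resolve by
    condensed-matrix position, i.e. toward lower indices.
    """
    X = np.asarray(table.values, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("concentration table contains NaN/inf")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows to cluster")
    Xs, _ = _autoscale(X)

    row_link = hierarchy.linkage(pdist(Xs, metric=metric), method=linkage)
    rows = hierarchy.leaves_list(row_link)
    if X.shape[1] < 2:
        cols = np.arange(X.shape[1])
    else:
        col_link = hierarchy.linkage(pdist(Xs.T, metric=metric), method=linkage)
        cols = hierarchy.leaves_list(col_link)
    return np.asarray(rows), np.asarray(cols)


def concentration_pca(
    table: ConcentrationTable,
    labels: np.ndarray | None = None,
    n_components: int = 2,
) -> dict:
    """Autoscaled PCA of a concentration table.

    Returns scores, explained-variance fractions and (when labels are
    given) a silhouette class-separation score on the retained components.
    Constant compounds are dropped with a warning before scaling.
    """
    X = np.asarray(table.values, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("concentration PCA needs at least 3 samples")
    Xs, mask = _autoscale(X)
    if not mask.all():
        warnings.warn("constant compounds dropped before PCA")
    Xs = Xs[:, mask]
    scores, explained = chemometrics.pca(Xs, n_components=n_components)
    out = {"scores": scores, "explained": explained}
    if labels is not None:
        labels = np.asarray(labels)
        if len(set(labels.tolist())) >= 2:
            out["silhouette"] = float(silhouette_score(scores, labels))
    return out
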