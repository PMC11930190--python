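"""PCA, PLS-DA with VIP/permutation diagnostics, and PLSR calibration.

Latent-variable models are backed by scikit-learn's NIPALS PLS
(``PLSRegression(scale=False)``); component counts are chosen by minimum
RMSECV over venetian-blind folds laid out along the Kennard-Stone order of
the calibration set.  Spectra are column-mean-centered, never
unit-variance scaled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA

from .preprocess import PretreatmentChain, apply_chain
from .sampling import SplitIndices, kennard_stone_order, split as ks_split
from .synthetic_data import ConcentrationTable, SpectrumSet

__all__ = [
    "LatentModel",
    "ClassReport",
    "RegressReport",
    "pca",
    "fit_plsda",
    "vip_scores",
    "permutation_test",
    "fit_plsr",
    "chain_search_classification",
    "chain_search_regression",
]

RPD_CAP = 1e6


@dataclass
class LatentModel:
    """Fitted PLS decomposition with the pieces VIP and prediction need."""

    x_weights: np.ndarray  # p x A
    x_loadings: np.ndarray  # p x A
    x_scores: np.ndarray  # n x A
    y_loadings: np.ndarray  # q x A
    coef: np.ndarray  # p x q
    x_mean: np.ndarray
    y_mean: np.ndarray
    n_components: int
    chain_name: str = "Raw"
    classes: tuple | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X - self.x_mean) @ self.coef + self.y_mean

    def predict_labels(self, X: np.ndarray) -> np.ndarray:
        if self.classes is None:
            raise ValueError("model was not fitted as a classifier")
        scores = self.predict(X)
        return np.asarray(self.classes)[np.argmax(scores, axis=1)]


@dataclass
class ClassReport:
    """Classification metric bundle (one PLS-DA model, one chain)."""

    chain: str
    n_components: int
    r2x: float
    r2y: float
    q2: float
    rmsecv: float
    rmsep: float | None
    train_accuracy: float
    test_accuracy: float | None
    train_assignments: np.ndarray | None = None
    test_assignments: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.train_accuracy <= 1.0):
            raise ValueError("train accuracy outside [0, 1]")
        if self.test_accuracy is not None and not (0.0 <= self.test_accuracy <= 1.0):
            raise ValueError("test accuracy outside [0, 1]")


@dataclass
class RegressReport:
    """Regression metric bundle for one compound / one chain."""

    compound: str
    chain: str
    n_components: int
    r2c: float
    r2p: float | None
    rmsep: float | None
    rpd: float | None
    rpd_capped: bool = False


def pca(
    X: np.ndarray, n_components: int, scale: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Column-mean-centered PCA scores and explained-variance fractions."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 samples")
    n_components = min(n_components, X.shape[0] - 1, X.shape[1])
    if scale:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    model = PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(X)
    return scores, model.explained_variance_ratio_


def _one_hot(labels: np.ndarray, classes: Sequence) -> np.ndarray:
    classes = list(classes)
    Y = np.zeros((len(labels), len(classes)))
    for i, lab in enumerate(labels):
        Y[i, classes.index(lab)] = 1.0
    return Y


def _fit_pls(X: np.ndarray, Y: np.ndarray, n_components: int) -> PLSRegression:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        m = PLSRegression(n_components=n_components, scale=False)
        m.fit(X, Y)
    return m


def _venetian_folds(X_cal: np.ndarray, n_folds: int) -> list[np.ndarray]:
    """Venetian-blind folds laid out along the Kennard-Stone order."""
    order = kennard_stone_order(X_cal)
    n_folds = min(n_folds, len(order))
    return [order[k::n_folds] for k in range(n_folds)]


def _cv_press(
    X: np.ndarray, Y: np.ndarray, n_components: int, folds: list[np.ndarray]
) -> float:
    press = 0.0
    for fold in folds:
        mask = np.ones(X.shape[0], dtype=bool)
        mask[fold] = False
        a = min(n_components, int(mask.sum()) - 1, X.shape[1])
        if a < 1:
            raise ValueError("fold leaves too few samples to fit")
        m = _fit_pls(X[mask], Y[mask], a)
        press += float(((Y[fold] - m.predict(X[fold])) ** 2).sum())
    return press


def _select_components(
    X: np.ndarray, Y: np.ndarray, max_components: int, cv_folds: int
) -> tuple[int, float, float]:
    """Minimum-RMSECV component count; returns (A, RMSECV, Q2)."""
    n, p = X.shape
    cap = min(max_components, n - 1, p)
    folds = _venetian_folds(X, cv_folds)
    ss_tot = float(((Y - Y.mean(axis=0)) ** 2).sum())
    best = None
    for a in range(1, cap + 1):
        press = _cv_press(X, Y, a, folds)
        if best is None or press < best[1]:
            best = (a, press)
    a, press = best
    rmsecv = float(np.sqrt(press / Y.size))
    q2 = 1.0 - press / ss_tot if ss_tot > 0 else float("nan")
    return a, rmsecv, q2


def _model_from(m: PLSRegression, chain: str, classes=None) -> LatentModel:
    return LatentModel(
        x_weights=m.x_weights_,
        x_loadings=m.x_loadings_,
        x_scores=m.x_scores_,
        y_loadings=m.y_loadings_,
        coef=m.coef_.T,
        x_mean=m._x_mean,
        y_mean=m._y_mean,
        n_components=m.n_components,
        chain_name=chain,
        classes=tuple(classes) if classes is not None else None,
    )


def _r2x(X: np.ndarray, m: PLSRegression) -> float:
    Xc = X - X.mean(axis=0)
    resid = Xc - m.x_scores_ @ m.x_loadings_.T
    tot = float((Xc**2).sum())
    return 1.0 - float((resid**2).sum()) / tot if tot > 0 else float("nan")


def fit_plsda(
    X: np.ndarray,
    labels: np.ndarray,
    max_components: int = 10,
    cv_folds: int = 7,
    X_test: np.ndarray | None = None,
    labels_test: np.ndarray | None = None,
    chain_name: str = "Raw",
    n_components: int | None = None,
) -> tuple[LatentModel, ClassReport]:
    """PLS-DA on one-hot labels with CV-selected component count.

    The class decision is the argmax of the predicted one-hot scores.  Test
    metrics (RMSEP, test accuracy) are reported when a held-out partition
    is supplied.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    classes = sorted(set(labels.tolist()))
    if len(classes) < 2:
        raise ValueError("PLS-DA needs at least 2 classes")
    Y = _one_hot(labels, classes)

    if n_components is None:
        a, rmsecv, q2 = _select_components(X, Y, max_components, cv_folds)
    else:
        a = n_components
        folds = _venetian_folds(X, cv_folds)
        press = _cv_press(X, Y, a, folds)
        rmsecv = float(np.sqrt(press / Y.size))
        ss_tot = float(((Y - Y.mean(axis=0)) ** 2).sum())
        q2 = 1.0 - press / ss_tot

    m = _fit_pls(X, Y, a)
    model = _model_from(m, chain_name, classes)

    Y_hat = model.predict(X)
    ss_tot = float(((Y - Y.mean(axis=0)) ** 2).sum())
    r2y = 1.0 - float(((Y - Y_hat) ** 2).sum()) / ss_tot
    train_pred = model.predict_labels(X)
    train_acc = float(np.mean(train_pred == labels))

    rmsep = test_acc = test_pred = None
    if X_test is not None:
        if len(X_test) == 0:
            raise ValueError("empty test partition")
        Y_test = _one_hot(np.asarray(labels_test), classes)
        Y_test_hat = model.predict(X_test)
        rmsep = float(np.sqrt(((Y_test - Y_test_hat) ** 2).mean()))
        test_pred = model.predict_labels(X_test)
        test_acc = float(np.mean(test_pred == np.asarray(labels_test)))

    report = ClassReport(
        chain=chain_name,
        n_components=a,
        r2x=_r2x(X, m),
        r2y=r2y,
        q2=q2,
        rmsecv=rmsecv,
        rmsep=rmsep,
        train_accuracy=train_acc,
        test_accuracy=test_acc,
        train_assignments=train_pred,
        test_assignments=test_pred,
    )
    return model, report


def vip_scores(model: LatentModel) -> np.ndarray:
    """Variable importance in projection.

    ``VIP_j = sqrt(p * sum_a(SSY_a * w_aj^2 / ||w_a||^2) / sum_a SSY_a)``
    where ``SSY_a = ||t_a||^2 ||q_a||^2`` is the Y-variance captured by
    component a.  The mean of squared VIPs is exactly 1.
    """
    W = model.x_weights  # p x A
    T = model.x_scores  # n x A
    Q = model.y_loadings  # q x A
    p = W.shape[0]
    ssy = (T**2).sum(axis=0) * (Q**2).sum(axis=0)  # per component
    total = float(ssy.sum())
    if total <= 0:
        raise ValueError("model explains no Y-variance; VIP undefined")
    wnorm2 = (W**2).sum(axis=0)
    contrib = (W**2 / wnorm2) @ ssy
    return np.sqrt(p * contrib / total)


@dataclass
class PermutationResult:
    """Permuted-label reference distribution for one PLS-DA pipeline."""

    true_r2y: float
    true_q2: float
    permuted_r2y: np.ndarray
    permuted_q2: np.ndarray
    correlations: np.ndarray
    r2y_intercept: float
    q2_intercept: float
    p_value_q2: float
    overfit: bool


def permutation_test(
    X: np.ndarray,
    labels: np.ndarray,
    n_perm: int = 200,
    max_components: int = 10,
    cv_folds: int = 7,
    seed: int = 0,
    alpha: float = 0.05,
) -> PermutationResult:
    """Label-permutation diagnostic for a PLS-DA pipeline.

    Each permutation refits the full pipeline including component
    selection.  The correlation axis is the cosine between the centered
    permuted and original one-hot matrices; intercepts come from a least
    squares line through the permuted points plus the unpermuted point at
    correlation 1.  The model is flagged overfit when at least ``alpha`` of
    permuted Q2 values reach the true Q2.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    classes = sorted(set(labels.tolist()))
    Y = _one_hot(labels, classes)
    Yc = Y - Y.mean(axis=0)
    y_norm = float(np.sqrt((Yc**2).sum()))

    rng = np.random.default_rng(seed)
    _, true_report = fit_plsda(
        X, labels, max_components=max_components, cv_folds=cv_folds
    )
    r2ys, q2s, corrs = [], [], []
    for _ in range(n_perm):
        perm = rng.permutation(len(labels))
        lab_p = labels[perm]
        _, rep = fit_plsda(
            X, lab_p, max_components=max_components, cv_folds=cv_folds
        )
        Yp = _one_hot(lab_p, classes)
        Ypc = Yp - Yp.mean(axis=0)
        corrs.append(float((Ypc * Yc).sum()) / (y_norm**2))
        r2ys.append(rep.r2y)
        q2s.append(rep.q2)

    r2ys = np.array(r2ys)
    q2s = np.array(q2s)
    corrs = np.array(corrs)

    def _intercept(vals: np.ndarray, true_val: float) -> float:
        x = np.concatenate([np.abs(corrs), [1.0]])
        y = np.concatenate([vals, [true_val]])
        slope, intercept = np.polyfit(x, y, 1)
        return float(intercept)

    p_q2 = float((np.sum(q2s >= true_report.q2) + 1) / (n_perm + 1))
    return PermutationResult(
        true_r2y=true_report.r2y,
        true_q2=true_report.q2,
        permuted_r2y=r2ys,
        permuted_q2=q2s,
        correlations=corrs,
        r2y_intercept=_intercept(r2ys, true_report.r2y),
        q2_intercept=_intercept(q2s, true_report.q2),
        p_value_q2=p_q2,
        overfit=p_q2 >= alpha,
    )


def fit_plsr(
    X: np.ndarray,
    y: np.ndarray,
    max_components: int = 10,
    cv_folds: int = 7,
    X_test: np.ndarray | None = None,
    y_test: np.ndarray | None = None,
    compound: str = "y",
    chain_name: str = "Raw",
) -> tuple[LatentModel, RegressReport]:
    """Univariate PLSR with CV-selected components, RMSEP and RPD.

    ``RPD = sd(y_test, ddof=1) / RMSEP``; a vanishing RMSEP is capped at
    ``RPD_CAP`` and flagged instead of dividing by zero.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).reshape(-1, 1)
    if X.shape[0] < 2:
        raise ValueError("PLSR needs at least 2 calibration samples")
    a, _, _ = _select_components(X, y, max_components, cv_folds)
    m = _fit_pls(X, y, a)
    model = _model_from(m, chain_name)

    y_hat = model.predict(X)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2c = 1.0 - float(((y - y_hat) ** 2).sum()) / ss_tot

    r2p = rmsep = rpd = None
    capped = False
    if X_test is not None:
        yt = np.asarray(y_test, dtype=float).reshape(-1, 1)
        yt_hat = model.predict(X_test)
        rmsep = float(np.sqrt(((yt - yt_hat) ** 2).mean()))
        ss_t = float(((yt - yt.mean()) ** 2).sum())
        r2p = 1.0 - float(((yt - yt_hat) ** 2).sum()) / ss_t if ss_t > 0 else float("nan")
        sd_ref = float(np.std(yt, ddof=1))
        if rmsep < 1e-12 * max(1.0, sd_ref):
            rpd, capped = RPD_CAP, True
        else:
            rpd = sd_ref / rmsep
    report = RegressReport(
        compound=compound,
        chain=chain_name,
        n_components=a,
        r2c=r2c,
        r2p=r2p,
        rmsep=rmsep,
        rpd=rpd,
        rpd_capped=capped,
    )
    return model, report


def _apply_chain_split(
    spectra: SpectrumSet, chain: PretreatmentChain, idx_cal, idx_test
):
    cal = spectra.subset(idx_cal)
    test = spectra.subset(idx_test)
    cal_t, state = apply_chain(cal, chain)
    test_t, _ = apply_chain(test, chain, fitted_state=state)
    return cal_t, test_t


def chain_search_classification(
    spectra: SpectrumSet,
    chains: Sequence[PretreatmentChain],
    split: SplitIndices | None = None,
    fractions: dict[str, float] | None = None,
    max_components: int = 10,
    cv_folds: int = 7,
) -> tuple[list[ClassReport], int]:
    """Fit PLS-DA for every chain on one fixed split; pick the best.

    Best = highest test accuracy, ties broken by lower RMSECV, then lower
    RMSEP, then first listed.  The split is computed once (Kennard-Stone on
    the raw spectra) and reused for every chain.
    """
    chains = list(chains)
    if not chains:
        raise ValueError("chain list must be non-empty")
    if split is None:
        fractions = fractions or {"calibration": 0.7, "test": 0.3}
        split = ks_split(spectra.absorbance, fractions)
    names = list(split.partitions)
    idx_cal, idx_test = split[names[0]], split[names[1]]

    reports = []
    for chain in chains:
        cal_t, test_t = _apply_chain_split(spectra, chain, idx_cal, idx_test)
        _, rep = fit_plsda(
            cal_t.absorbance,
            cal_t.labels,
            max_components=max_components,
            cv_folds=cv_folds,
            X_test=test_t.absorbance,
            labels_test=test_t.labels,
            chain_name=chain.name,
        )
        reports.append(rep)
    order = sorted(
        range(len(reports)),
        key=lambda i: (
            -reports[i].test_accuracy,
            reports[i].rmsecv,
            reports[i].rmsep,
            i,
        ),
    )
    return reports, order[0]


def chain_search_regression(
    spectra: SpectrumSet,
    table: ConcentrationTable,
    chains: Sequence[PretreatmentChain],
    compound: str,
    split: SplitIndices | None = None,
    fractions: dict[str, float] | None = None,
    max_components: int = 10,
    cv_folds: int = 7,
) -> tuple[list[RegressReport], int]:
    """Per-compound chain search; best = highest R2p, ties by higher RPD."""
    chains = list(chains)
    if not chains:
        raise ValueError("chain list must be non-empty")
    y = table.column(compound)
    if split is None:
        fractions = fractions or {"calibration": 0.7, "test": 0.3}
        split = ks_split(spectra.absorbance, fractions)
    names = list(split.partitions)
    idx_cal, idx_test = split[names[0]], split[names[1]]

    reports = []
    for chain in chains:
        cal_t, test_t = _apply_chain_split(spectra, chain, idx_cal, idx_test)
        _, rep = fit_plsr(
            cal_t.absorbance,
            y[idx_cal],
            max_components=max_components,
            cv_folds=cv_folds,
            X_test=test_t.absorbance,
            y_test=y[idx_test],
            compound=compound,
            chain_name=chain.name,
        )
        reports.append(rep)
    order = sorted(
        range(len(reports)),
        key=lambda i: (-reports[i].r2p, -reports[i].rpd, i),
    )
    return reports, order[0]
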