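"""Multivariate modelling of feature tables: PCA and PLS-DA diagnostics.

Workflow mirrors standard chemometrics practice for untargeted LC-MS data:
intensities are log10-transformed and scaled to unit variance, then modelled
with PCA (unsupervised overview) or two-class PLS-DA fitted by NIPALS with
sequential deflation. Model quality is summarised by R2X(cum) and R2Y(cum)
(cumulative fraction of X / y variance explained), predictive power by
Q2(cum) from stratified 7-fold cross-validation using the cumulative-product
convention Q2(cum) = 1 - prod_a(PRESS_a / SS_{a-1}), and model significance
by CV-ANOVA, an F-test of the cross-validated predictive residuals against
the total y variation with component-adjusted degrees of freedom.

Cross-validation here operates on the already-preprocessed matrix (scaling
estimated once on the full data), matching how these diagnostics are
conventionally produced; fold assignment is stratified by class and
seed-controlled.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .tables import FeatureTable

log = logging.getLogger(__name__)

#: minimum Q2 gain for which an extra PLS component is considered worthwhile
Q2_GAIN_THRESHOLD = 0.01
MAX_COMPONENTS = 5


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScalingParams:
    """log10 + unit-variance scaling parameters for inversion and reuse."""

    feature_ids: tuple[str, ...]
    means: np.ndarray
    sds: np.ndarray
    dropped: tuple[str, ...] = ()


def preprocess(
    table: FeatureTable | pd.DataFrame | np.ndarray,
    feature_ids: list[str] | None = None,
) -> tuple[np.ndarray, ScalingParams]:
    """log10-transform and unit-variance scale analytical intensities.

    Accepts a :class:`FeatureTable` (analytical rows are used), a DataFrame
    or a bare array. Columns with zero variance after the log transform are
    dropped with a warning; zero or negative intensities are an error (run
    the presence filter first, or offset the data).
    """
    if isinstance(table, FeatureTable):
        frame = table.analytical
        ids = list(frame.columns)
        X = frame.to_numpy(dtype=float)
    elif isinstance(table, pd.DataFrame):
        ids = list(table.columns)
        X = table.to_numpy(dtype=float)
    else:
        X = np.asarray(table, dtype=float)
        ids = feature_ids or [f"x{j}" for j in range(X.shape[1])]
    if (X <= 0).any():
        i, j = np.argwhere(X <= 0)[0]
        raise ValueError(
            f"non-positive intensity at row {i}, feature {ids[j]!r}: "
            "log10 scaling needs strictly positive values "
            "(apply the presence filter or add an offset)"
        )
    L = np.log10(X)
    means = L.mean(axis=0)
    sds = L.std(axis=0, ddof=1)
    keep = sds > 0
    dropped = tuple(fid for fid, k in zip(ids, keep) if not k)
    if dropped:
        log.warning("dropping %d zero-variance column(s): %s", len(dropped), dropped[:5])
        warnings.warn(
            f"dropping {len(dropped)} zero-variance column(s)", UserWarning, stacklevel=2
        )
    Z = (L[:, keep] - means[keep]) / sds[keep]
    params = ScalingParams(
        feature_ids=tuple(fid for fid, k in zip(ids, keep) if k),
        means=means[keep],
        sds=sds[keep],
        dropped=dropped,
    )
    return Z, params


def inverse_preprocess(Z: np.ndarray, params: ScalingParams) -> np.ndarray:
    """Undo unit-variance scaling and the log10 transform."""
    return 10.0 ** (Z * params.sds + params.means)


def encode_classes(y) -> tuple[np.ndarray, tuple]:
    """Binary class labels -> centred 0/1 dummy; returns (dummy, class order)."""
    y = np.asarray(y)
    classes = tuple(sorted(pd.unique(y), key=str))
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {classes}")
    dummy = (y == classes[1]).astype(float)
    return dummy - dummy.mean(), classes


# ---------------------------------------------------------------------------
# PLS-DA (NIPALS, single y)
# ---------------------------------------------------------------------------


@dataclass
class PlsModel:
    """Fitted PLS-DA model (scores/weights/loadings per component)."""

    n_components: int
    scores: np.ndarray        # T, n x A
    weights: np.ndarray       # W, p x A
    x_loadings: np.ndarray    # P, p x A
    y_loadings: np.ndarray    # c, A
    y_mean: float
    classes: tuple
    r2x_per_component: np.ndarray
    r2y_per_component: np.ndarray

    @property
    def r2x_cum(self) -> float:
        return float(self.r2x_per_component.sum())

    @property
    def r2y_cum(self) -> float:
        return float(self.r2y_per_component.sum())

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Scores of new (preprocessed) samples via sequential deflation."""
        Xa = np.array(X, dtype=float, copy=True)
        T = np.empty((Xa.shape[0], self.n_components))
        for a in range(self.n_components):
            t = Xa @ self.weights[:, a]
            T[:, a] = t
            Xa -= np.outer(t, self.x_loadings[:, a])
        return T

    def predict_y(self, X: np.ndarray, n_components: int | None = None) -> np.ndarray:
        """Continuous y-hat (on the centred-dummy scale plus training mean)."""
        A = self.n_components if n_components is None else n_components
        T = self.transform(X)[:, :A]
        return self.y_mean + T @ self.y_loadings[:A]


def fit_plsda(X: np.ndarray, y, n_components: int = 2) -> PlsModel:
    """Fit a two-class PLS-DA by NIPALS with X and y deflation.

    ``X`` must already be preprocessed (centred/scaled); ``y`` holds two
    class labels, internally encoded as a centred 0/1 dummy. For a single
    response the NIPALS weight vector has the closed form w = X'y / |X'y|
    per deflation step.
    """
    X = np.asarray(X, dtype=float)
    yd, classes = encode_classes(y)
    n, p = X.shape
    if n_components > min(n - 1, p):
        raise ValueError(f"n_components={n_components} exceeds rank bound {min(n - 1, p)}")
    ss_x = float((X**2).sum())
    ss_y = float((yd**2).sum())
    if ss_y == 0:
        raise ValueError("y has a single class")
    y_mean_raw = float(np.mean(np.asarray(y) == classes[1]))

    Xa = X.copy()
    ya = yd.copy()
    T = np.empty((n, n_components))
    W = np.empty((p, n_components))
    P = np.empty((p, n_components))
    c = np.empty(n_components)
    r2x = np.empty(n_components)
    r2y = np.empty(n_components)
    for a in range(n_components):
        w = Xa.T @ ya
        norm = np.linalg.norm(w)
        if norm == 0:
            raise ValueError(f"component {a + 1}: X carries no covariance with y")
        w /= norm
        t = Xa @ w
        tt = float(t @ t)
        ca = float(t @ ya) / tt
        pa = Xa.T @ t / tt
        prev_ss_x = float((Xa**2).sum())
        prev_ss_y = float((ya**2).sum())
        Xa = Xa - np.outer(t, pa)
        ya = ya - t * ca
        T[:, a], W[:, a], P[:, a], c[a] = t, w, pa, ca
        r2x[a] = (prev_ss_x - float((Xa**2).sum())) / ss_x
        r2y[a] = (prev_ss_y - float((ya**2).sum())) / ss_y
    return PlsModel(
        n_components=n_components, scores=T, weights=W, x_loadings=P,
        y_loadings=c, y_mean=y_mean_raw, classes=classes,
        r2x_per_component=r2x, r2y_per_component=r2y,
    )


# ---------------------------------------------------------------------------
# cross-validation and CV-ANOVA
# ---------------------------------------------------------------------------


@dataclass
class CvResult:
    """Cross-validated predictive diagnostics of a PLS-DA model."""

    n_components: int
    q2_cum: float
    q2_per_component: np.ndarray       # 1 - PRESS_a / SS_{a-1}
    residuals: np.ndarray              # per-sample held-out y residual (all comps)
    fold_assignment: np.ndarray
    press_per_component: np.ndarray
    ss_per_component: np.ndarray       # SS_{a-1} of the full-data model


def stratified_folds(y, folds: int, seed: int = 0) -> np.ndarray:
    """Round-robin fold labels within each class after a seeded shuffle."""
    y = np.asarray(y)
    n = len(y)
    if folds < 2:
        raise ValueError("need at least 2 folds")
    if folds > n:
        raise ValueError(f"folds={folds} exceeds n={n}")
    rng = np.random.default_rng(seed)
    assignment = np.empty(n, dtype=int)
    for cls in pd.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        assignment[idx] = np.arange(len(idx)) % folds
    return assignment


def cross_validate(
    X: np.ndarray, y, n_components: int, folds: int = 7, seed: int = 0
) -> CvResult:
    """Stratified k-fold cross-validation of a PLS-DA fit.

    For each held-out fold the model is refitted on the remaining samples
    and the fold's y residuals are accumulated per component stage; PRESS_a
    against the full-data model's residual SS after a-1 components gives the
    per-component Q2, combined multiplicatively into Q2(cum).
    """
    X = np.asarray(X, dtype=float)
    yd_all, classes = encode_classes(y)
    y01 = (np.asarray(y) == classes[1]).astype(float)
    n = len(y01)
    assignment = stratified_folds(y, folds, seed=seed)

    full = fit_plsda(X, y, n_components=n_components)
    ss = np.empty(n_components)  # SS_{a-1} of full model
    resid = yd_all.copy()
    for a in range(n_components):
        ss[a] = float((resid**2).sum())
        resid = resid - full.scores[:, a] * full.y_loadings[a]

    press = np.zeros(n_components)
    cv_pred = np.empty(n)
    for k in np.unique(assignment):
        test = assignment == k
        train = ~test
        if len(np.unique(y01[train])) < 2:
            raise ValueError(f"fold {k}: training split lost a class; use fewer folds")
        sub = fit_plsda(X[train], np.asarray(y)[train], n_components=n_components)
        # per-component residual stages for held-out samples
        y_resid = y01[test] - sub.y_mean
        Xa = np.array(X[test], dtype=float, copy=True)
        for a in range(n_components):
            t = Xa @ sub.weights[:, a]
            incr = t * sub.y_loadings[a]
            press[a] += float(((y_resid - incr) ** 2).sum())
            y_resid = y_resid - incr
            Xa -= np.outer(t, sub.x_loadings[:, a])
        cv_pred[test] = sub.predict_y(X[test], n_components=n_components)

    ratios = np.where(ss > 0, press / np.maximum(ss, 1e-300), np.inf)
    q2_per = 1.0 - ratios
    q2_cum = 1.0 - float(np.prod(ratios))
    return CvResult(
        n_components=n_components,
        q2_cum=q2_cum,
        q2_per_component=q2_per,
        residuals=y01 - cv_pred,
        fold_assignment=assignment,
        press_per_component=press,
        ss_per_component=ss,
    )


def cv_anova(cv_residuals: np.ndarray, y, n_components: int = 1) -> tuple[float, float]:
    """F-test of cross-validated residuals against total y variation.

    F = ((SS_tot - PRESS)/A) / (PRESS/(N-1-A)) with A model components,
    following the published CV-ANOVA formulation for PLS significance
    testing; p from the F(A, N-1-A) distribution. PRESS = 0 gives p = 0
    with a warning; a model explaining nothing gives F = 0, p = 1.
    """
    resid = np.asarray(cv_residuals, dtype=float)
    yd, _ = encode_classes(y)
    n = len(yd)
    ss_tot = float((yd**2).sum())
    press = float((resid**2).sum())
    df_reg = n_components
    df_res = n - 1 - n_components
    if df_res <= 0:
        raise ValueError("too few samples for the component count")
    if press == 0:
        warnings.warn("zero cross-validated residuals; CV-ANOVA p set to 0", UserWarning)
        return float("inf"), 0.0
    if ss_tot <= press:
        return 0.0, 1.0
    F = ((ss_tot - press) / df_reg) / (press / df_res)
    p = float(stats.f.sf(F, df_reg, df_res))
    return float(F), p


# ---------------------------------------------------------------------------
# model summary
# ---------------------------------------------------------------------------


@dataclass
class PlsSummary:
    """Headline diagnostics of a fitted + cross-validated PLS-DA model."""

    n_components: int
    r2x_cum: float
    r2y_cum: float
    q2_cum: float
    cv_anova_F: float
    cv_anova_p: float
    classes: tuple
    scores: pd.DataFrame = field(repr=False)
    model: PlsModel = field(repr=False)
    cv: CvResult = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "n_components": self.n_components,
            "r2x_cum": round(self.r2x_cum, 4),
            "r2y_cum": round(self.r2y_cum, 4),
            "q2_cum": round(self.q2_cum, 4),
            "cv_anova_F": round(self.cv_anova_F, 4),
            "cv_anova_p": self.cv_anova_p,
            "classes": [str(c) for c in self.classes],
        }


def select_n_components(
    X: np.ndarray, y, folds: int = 7, seed: int = 0, max_components: int = MAX_COMPONENTS
) -> int:
    """Add components while each improves Q2(cum) by more than the gain
    threshold, capped at ``max_components`` and the rank bound."""
    n, p = np.asarray(X).shape
    cap = min(max_components, n - 2, p)
    best_a, best_q2 = 1, cross_validate(X, y, 1, folds=folds, seed=seed).q2_cum
    for a in range(2, cap + 1):
        q2 = cross_validate(X, y, a, folds=folds, seed=seed).q2_cum
        if q2 > best_q2 + Q2_GAIN_THRESHOLD:
            best_a, best_q2 = a, q2
        else:
            break
    return best_a


def plsda_summary(
    table: FeatureTable,
    case_label: str,
    control_label: str,
    n_components: int | None = None,
    folds: int = 7,
    seed: int = 0,
) -> PlsSummary:
    """Preprocess, fit, cross-validate and significance-test a PLS-DA model."""
    mask = table.role_mask("analytical") & table.sample_meta["group"].isin(
        [case_label, control_label]
    )
    frame = table.intensities.loc[mask]
    y = table.sample_meta.loc[mask, "group"].to_numpy()
    Z, _ = preprocess(frame)
    if n_components is None:
        n_components = select_n_components(Z, y, folds=folds, seed=seed)
    model = fit_plsda(Z, y, n_components=n_components)
    cv = cross_validate(Z, y, n_components, folds=folds, seed=seed)
    F, p = cv_anova(cv.residuals, y, n_components=n_components)
    scores = pd.DataFrame(
        model.scores,
        index=frame.index,
        columns=[f"t{a + 1}" for a in range(n_components)],
    )
    scores.insert(0, "class", y)
    return PlsSummary(
        n_components=n_components,
        r2x_cum=model.r2x_cum,
        r2y_cum=model.r2y_cum,
        q2_cum=cv.q2_cum,
        cv_anova_F=F,
        cv_anova_p=p,
        classes=model.classes,
        scores=scores,
        model=model,
        cv=cv,
    )


def t1_class_separation_pct(scores_t1: np.ndarray, y) -> float:
    """Class difference on the first score axis, as percent of its range.

    Defined as |mean t1(case) - mean t1(control)| / (max t1 - min t1) x 100;
    one reasonable reading of "a class difference of x% of t[1]" for a
    scores plot, reported as such.
    """
    t1 = np.asarray(scores_t1, dtype=float)
    y = np.asarray(y)
    classes = pd.unique(y)
    if len(classes) != 2:
        raise ValueError("need exactly 2 classes")
    span = float(t1.max() - t1.min())
    if span == 0:
        return 0.0
    diff = abs(float(t1[y == classes[0]].mean() - t1[y == classes[1]].mean()))
    return 100.0 * diff / span


def fit_pca(X: np.ndarray, n_components: int = 2):
    """PCA overview model: returns (scores, loadings, r2x per component)."""
    X = np.asarray(X, dtype=float)
    n_components = min(n_components, min(X.shape))
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    return scores, pca.components_.T, pca.explained_variance_ratio_
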