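"""Descriptor pretreatment, PCA, K-means and PLS with leave-one-out Q2.

The regression core is a univariate NIPALS partial-least-squares
implementation with coefficients back-transformed to the original
descriptor scale.  Predictivity is measured by leave-one-out
cross-validation: each sample is removed, the model (including the
column scaling) is refit on the remainder and the held-out response is
predicted, giving Q2 = 1 - PRESS/TSS.  Q2 may legitimately be
negative and is reported as computed.

Autoscaling (zero mean, unit variance per column) is the default for
both PCA and PLS; ``scale="center_only"`` is available for matrices in
commensurate units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin, TransformerMixin
from sklearn.cluster import KMeans

__all__ = [
    "DescriptorPretreater",
    "PretreatReport",
    "ScaledPCA",
    "PCAModel",
    "ClusterResult",
    "PLSRegressorQ2",
    "PLSModel",
    "pretreat",
    "pca_fit",
    "kmeans_cluster",
    "pls_fit",
    "loo_q2",
    "select_features",
    "DEFAULT_ADME_EXCLUSIONS",
]

#: Descriptor names designed for drug ADME modelling, excluded from the
#: biodegradability analysis by default.
DEFAULT_ADME_EXCLUSIONS = ("CACO2", "MetStab", "PB", "VD", "LgBB", "SKIN")

_SCALES = ("autoscale", "center_only")


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, float)
    return pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])


def _check_scale(scale: str) -> None:
    if scale not in _SCALES:
        raise ValueError(f"scale must be one of {_SCALES}, got {scale!r}")


# ---------------------------------------------------------------------------
# pretreatment
# ---------------------------------------------------------------------------


@dataclass
class PretreatReport:
    dropped_zero_variance: list[str]
    dropped_excluded: list[str]
    kept: int


class DescriptorPretreater(BaseEstimator, TransformerMixin):
    """Drop zero-variance columns and named (e.g. ADME) exclusions."""

    def __init__(self, exclude=DEFAULT_ADME_EXCLUSIONS, var_tol: float = 1e-12):
        self.exclude = exclude
        self.var_tol = var_tol

    def fit(self, X, y=None):
        X = _as_frame(X)
        if len(X) < 2:
            raise ValueError("pretreatment needs at least two rows")
        variances = X.var(axis=0, ddof=1)
        self.dropped_zero_variance_ = [
            str(c) for c in X.columns[variances.values <= self.var_tol]
        ]
        excl = set(self.exclude or ())
        self.dropped_excluded_ = [
            str(c) for c in X.columns if str(c) in excl
        ]
        dropped = set(self.dropped_zero_variance_) | set(self.dropped_excluded_)
        self.kept_columns_ = [c for c in X.columns if str(c) not in dropped]
        if not self.kept_columns_:
            raise ValueError("pretreatment dropped every column")
        return self

    def transform(self, X) -> pd.DataFrame:
        return _as_frame(X)[self.kept_columns_]

    @property
    def report_(self) -> PretreatReport:
        return PretreatReport(
            dropped_zero_variance=list(self.dropped_zero_variance_),
            dropped_excluded=list(self.dropped_excluded_),
            kept=len(self.kept_columns_),
        )


def pretreat(
    X, exclude=DEFAULT_ADME_EXCLUSIONS, var_tol: float = 1e-12
) -> tuple[pd.DataFrame, PretreatReport]:
    """Functional form of :class:`DescriptorPretreater`."""
    pre = DescriptorPretreater(exclude=exclude, var_tol=var_tol).fit(X)
    return pre.transform(X), pre.report_


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass
class PCAModel:
    loadings: pd.DataFrame  # components x descriptors
    scores: pd.DataFrame  # samples x components
    explained_pct: np.ndarray


class ScaledPCA(BaseEstimator, TransformerMixin):
    """PCA by SVD of the scaled matrix, with a fixed sign convention.

    The largest-magnitude loading of each component is forced positive
    so that plots are reproducible across row permutations and BLAS
    builds.
    """

    def __init__(self, n_components: int = 2, scale: str = "autoscale"):
        self.n_components = n_components
        self.scale = scale

    def fit(self, X, y=None):
        _check_scale(self.scale)
        X = _as_frame(X)
        n, p = X.shape
        if not 1 <= self.n_components <= min(n - 1, p):
            raise ValueError(
                f"n_components={self.n_components} out of range for {n}x{p} matrix"
            )
        self.mean_ = X.mean(axis=0).values
        sd = X.std(axis=0, ddof=1).values
        if self.scale == "autoscale":
            if np.any(sd == 0):
                raise ValueError("autoscaling impossible: zero-variance column present")
            self.scale_ = sd
        else:
            self.scale_ = np.ones(p)
        Z = (X.values - self.mean_) / self.scale_
        u, s, vt = np.linalg.svd(Z, full_matrices=False)
        # sign convention: largest |loading| per component positive
        for k in range(vt.shape[0]):
            j = np.argmax(np.abs(vt[k]))
            if vt[k, j] < 0:
                vt[k] *= -1.0
                u[:, k] *= -1.0
        k = self.n_components
        total_var = (s**2).sum()
        self.components_ = vt[:k]
        self.singular_values_ = s[:k]
        self.explained_pct_ = 100.0 * s[:k] ** 2 / total_var
        self.columns_ = list(X.columns)
        self.scores_ = u[:, :k] * s[:k]
        self.index_ = list(X.index)
        return self

    def transform(self, X) -> np.ndarray:
        X = _as_frame(X)
        Z = (X.values - self.mean_) / self.scale_
        return Z @ self.components_.T

    def model_(self) -> PCAModel:
        comp_names = [f"PC{i + 1}" for i in range(self.n_components)]
        return PCAModel(
            loadings=pd.DataFrame(self.components_, index=comp_names, columns=self.columns_),
            scores=pd.DataFrame(self.scores_, index=self.index_, columns=comp_names),
            explained_pct=self.explained_pct_.copy(),
        )


def pca_fit(X, n_comp: int = 2, scale: str = "autoscale") -> PCAModel:
    return ScaledPCA(n_components=n_comp, scale=scale).fit(X).model_()


# ---------------------------------------------------------------------------
# K-means
# ---------------------------------------------------------------------------


@dataclass
class ClusterResult:
    k: int
    labels: np.ndarray
    seed: int
    inertia: float


def kmeans_cluster(scores, k: int, seed: int = 0, n_init: int = 20) -> ClusterResult:
    """Best-of-``n_init`` Lloyd iterations, deterministic for a fixed seed."""
    scores = np.asarray(scores, float)
    if scores.ndim == 1:
        scores = scores[:, None]
    n = len(scores)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} must be in [1, {n}]")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(scores)
    return ClusterResult(
        k=k, labels=km.labels_.copy(), seed=seed, inertia=float(km.inertia_)
    )


# ---------------------------------------------------------------------------
# PLS (univariate NIPALS) with LOO Q2
# ---------------------------------------------------------------------------


@dataclass
class PLSModel:
    n_lv: int
    coefficients: pd.Series  # original descriptor scale
    intercept: float
    R2: float
    Q2: float | None
    PRESS: float | None


class PLSRegressorQ2(BaseEstimator, RegressorMixin):
    """Univariate partial least squares (NIPALS) with optional LOO Q2.

    Fitted attributes: ``coef_`` (original scale), ``intercept_``,
    ``r2_``; ``q2_``/``press_`` after :meth:`cross_validate`.
    """

    def __init__(self, n_lv: int = 2, scale: str = "autoscale"):
        self.n_lv = n_lv
        self.scale = scale

    def fit(self, X, y):
        _check_scale(self.scale)
        X = _as_frame(X)
        y = np.asarray(y, float).ravel()
        n, p = X.shape
        if len(y) != n:
            raise ValueError("X and y have different numbers of rows")
        rank = np.linalg.matrix_rank(X.values - X.values.mean(axis=0))
        if not 1 <= self.n_lv <= rank:
            raise ValueError(f"n_lv={self.n_lv} exceeds rank {rank} of centred X")
        y_sd = y.std(ddof=1)
        if y_sd == 0:
            raise ValueError("constant response: TSS = 0")

        self.x_mean_ = X.mean(axis=0).values
        x_sd = X.std(axis=0, ddof=1).values
        self.x_scale_ = (
            np.where(x_sd == 0, 1.0, x_sd) if self.scale == "autoscale" else np.ones(p)
        )
        if self.scale == "autoscale" and np.any(x_sd == 0):
            raise ValueError("autoscaling impossible: zero-variance column present")
        self.y_mean_ = y.mean()

        Xc = (X.values - self.x_mean_) / self.x_scale_
        yc = y - self.y_mean_

        W = np.zeros((p, self.n_lv))
        P = np.zeros((p, self.n_lv))
        q = np.zeros(self.n_lv)
        Xd = Xc.copy()
        for h in range(self.n_lv):
            w = Xd.T @ yc
            norm = np.linalg.norm(w)
            if norm < 1e-14:
                # response already fully deflated; truncate
                W, P, q = W[:, :h], P[:, :h], q[:h]
                break
            w /= norm
            t = Xd @ w
            tt = t @ t
            ph = Xd.T @ t / tt
            qh = yc @ t / tt
            Xd -= np.outer(t, ph)
            yc = yc - qh * t
            W[:, h], P[:, h], q[h] = w, ph, qh

        b_scaled = W @ np.linalg.solve(P.T @ W, q) if W.shape[1] else np.zeros(p)
        self.coef_ = b_scaled / self.x_scale_
        self.intercept_ = self.y_mean_ - self.x_mean_ @ self.coef_
        self.columns_ = list(X.columns)

        resid = y - self.predict(X)
        tss = ((y - y.mean()) ** 2).sum()
        self.r2_ = 1.0 - (resid**2).sum() / tss
        self.n_components_fitted_ = W.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        X = _as_frame(X)
        return X.values @ self.coef_ + self.intercept_

    def cross_validate(self, X, y) -> "PLSRegressorQ2":
        """Leave-one-out Q2 and PRESS (refitting the scaling each fold)."""
        X = _as_frame(X)
        y = np.asarray(y, float).ravel()
        n = len(y)
        if n < 3:
            raise ValueError("leave-one-out needs at least three samples")
        press = 0.0
        for i in range(n):
            mask = np.arange(n) != i
            sub = PLSRegressorQ2(n_lv=self.n_lv, scale=self.scale)
            sub.fit(X.iloc[mask], y[mask])
            pred = sub.predict(X.iloc[[i]])[0]
            press += (y[i] - pred) ** 2
        tss = ((y - y.mean()) ** 2).sum()
        self.press_ = float(press)
        self.q2_ = float(1.0 - press / tss)
        return self

    def model_(self) -> PLSModel:
        return PLSModel(
            n_lv=self.n_lv,
            coefficients=pd.Series(self.coef_, index=self.columns_),
            intercept=float(self.intercept_),
            R2=float(self.r2_),
            Q2=getattr(self, "q2_", None),
            PRESS=getattr(self, "press_", None),
        )


def pls_fit(X, y, n_lv: int, scale: str = "autoscale") -> PLSModel:
    return PLSRegressorQ2(n_lv=n_lv, scale=scale).fit(X, y).model_()


def loo_q2(X, y, n_lv: int, scale: str = "autoscale") -> tuple[float, float]:
    """Leave-one-out Q2 = 1 - PRESS/TSS and PRESS."""
    est = PLSRegressorQ2(n_lv=n_lv, scale=scale).fit(X, y).cross_validate(X, y)
    return est.q2_, est.press_


# ---------------------------------------------------------------------------
# feature selection
# ---------------------------------------------------------------------------


def select_features(
    X,
    y=None,
    mode: str = "explicit_list",
    *,
    names=None,
    n_lv: int = 2,
    scale: str = "autoscale",
    tol: float = 1e-6,
    max_features: int | None = None,
) -> list[str]:
    """Return a descriptor subset.

    ``explicit_list`` validates and returns ``names`` (the packaged
    18-descriptor list is the default reproduction path).  ``forward_q2``
    greedily adds the column that maximises LOO Q2 until no addition
    improves it by more than ``tol``.
    """
    X = _as_frame(X)
    cols = [str(c) for c in X.columns]
    if mode == "explicit_list":
        if names is None:
            raise ValueError("explicit_list mode requires names")
        missing = [n for n in names if str(n) not in cols]
        if missing:
            raise KeyError(f"descriptors not in matrix: {missing}")
        return [str(n) for n in names]
    if mode != "forward_q2":
        raise ValueError(f"unknown mode {mode!r}")
    if y is None:
        raise ValueError("forward_q2 mode requires y")

    y = np.asarray(y, float).ravel()
    selected: list[str] = []
    best_q2 = -np.inf
    limit = max_features or len(cols)
    while len(selected) < limit:
        gains = []
        for c in cols:
            if c in selected:
                continue
            trial = selected + [c]
            lv = min(n_lv, len(trial))
            try:
                q2, _ = loo_q2(X[trial], y, n_lv=lv, scale=scale)
            except ValueError:
                continue
            gains.append((q2, c))
        if not gains:
            break
        q2, c = max(gains)
        if q2 <= best_q2 + tol:
            break
        best_q2 = q2
        selected.append(c)
    return selected
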