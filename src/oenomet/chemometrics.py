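"""PCA and two-class OPLS-DA with VIP, cross-validated Q2 and permutation
validation.

OPLS-DA (orthogonal projections to latent structures discriminant
analysis) splits the predictor variation into a single component that is
predictive of the two-class membership and ``k_ortho`` components that
are orthogonal to it.  Model quality is summarised by R2X (fraction of X
variance modelled), R2Y (fraction of class variance modelled) and Q2
(cross-validated R2Y); per-variable importance is the VIP score, whose
squares average to 1 so that VIP >= 1 marks above-average contributors.
Permutation of the class labels provides the standard overfitting guard:
a sound model's R2Y and Q2 exceed every permuted value.

The API follows the familiar model/results pattern: construct
:class:`OPLSDA` from a data matrix and labels, call :meth:`OPLSDA.fit`,
inspect the returned :class:`OPLSDAResults`.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from oenomet.io import OenometError


# ---------------------------------------------------------------------------
# scaling helpers
# ---------------------------------------------------------------------------


def autoscale(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Center each column and scale to unit variance (SIMCA-style UV scaling)."""
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd_safe, mu, sd


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class PCAResult:
    """Scores, loadings and per-component explained variance (%)."""

    scores: np.ndarray  # (n_samples, k)
    loadings: np.ndarray  # (n_variables, k)
    explained_pct: np.ndarray  # (k,)

    def reconstruct(self) -> np.ndarray:
        """Centered-matrix reconstruction from the retained components."""
        return self.scores @ self.loadings.T


def pca(X: np.ndarray, k: int, scale: bool = False) -> PCAResult:
    """SVD-based principal component analysis of a samples × variables matrix.

    ``X`` is column-centered (and unit-variance scaled when ``scale``);
    the sign of each component is fixed so its largest-magnitude loading
    is positive.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if k > min(n - 1, p):
        raise OenometError(f"k={k} exceeds min(n-1, p)={min(n - 1, p)}")
    if scale:
        Xc, _, _ = autoscale(X)
    else:
        Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    total = float(np.sum(s**2))
    scores = U[:, :k] * s[:k]
    loadings = Vt[:k].T
    for j in range(k):  # deterministic sign: largest-|loading| entry positive
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    explained = 100.0 * s[:k] ** 2 / total if total > 0 else np.zeros(k)
    return PCAResult(scores, loadings, explained)


# ---------------------------------------------------------------------------
# OPLS-DA
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class _OPLSCore:
    """Fitted O-PLS quantities on the scaled training matrix."""

    w: np.ndarray  # predictive weights (p,)
    p_pred: np.ndarray  # predictive loadings (p,)
    c: float  # y-loading of the predictive score
    W_ortho: np.ndarray  # (p, k_ortho)
    P_ortho: np.ndarray  # (p, k_ortho)
    t_pred: np.ndarray  # (n,)
    T_ortho: np.ndarray  # (n, k_ortho)


def _opls_decompose(Xs: np.ndarray, yc: np.ndarray, k_ortho: int) -> _OPLSCore:
    """Trygg–Wold O-PLS for a single centered response vector."""
    Xf = Xs.copy()
    w = Xf.T @ yc
    nw = np.linalg.norm(w)
    if nw == 0:
        raise OenometError("response carries no X covariance; cannot fit")
    w /= nw
    W_o, P_o, T_o = [], [], []
    for _ in range(k_ortho):
        t = Xf @ w
        p_load = Xf.T @ t / (t @ t)
        w_o = p_load - (w @ p_load) * w
        n_o = np.linalg.norm(w_o)
        if n_o < 1e-12:
            break  # no orthogonal variation left
        w_o /= n_o
        t_o = Xf @ w_o
        p_o = Xf.T @ t_o / (t_o @ t_o)
        Xf = Xf - np.outer(t_o, p_o)
        W_o.append(w_o)
        P_o.append(p_o)
        T_o.append(t_o)
    t = Xf @ w
    p_pred = Xf.T @ t / (t @ t)
    c = float(yc @ t / (t @ t))
    k = len(W_o)
    return _OPLSCore(
        w=w,
        p_pred=p_pred,
        c=c,
        W_ortho=np.column_stack(W_o) if k else np.zeros((Xs.shape[1], 0)),
        P_ortho=np.column_stack(P_o) if k else np.zeros((Xs.shape[1], 0)),
        t_pred=t,
        T_ortho=np.column_stack(T_o) if k else np.zeros((Xs.shape[0], 0)),
    )


def _opls_filter_predict(core: _OPLSCore, Xs: np.ndarray) -> np.ndarray:
    """Remove orthogonal variation from new (scaled) data, predict centered y."""
    Xf = Xs.copy()
    for j in range(core.W_ortho.shape[1]):
        t_o = Xf @ core.W_ortho[:, j]
        Xf = Xf - np.outer(t_o, core.P_ortho[:, j])
    return (Xf @ core.w) * core.c


def _vip(
    core: _OPLSCore, Xs: np.ndarray, yc: np.ndarray, mode: str = "total"
) -> np.ndarray:
    """VIP scores; squares average to exactly 1 over retained variables.

    ``mode="total"`` weights the predictive component by its explained Y
    sum-of-squares and each orthogonal component by its explained X
    sum-of-squares (the total-variation VIP for OPLS); ``"predictive"``
    uses the predictive component alone.
    """
    p = Xs.shape[1]
    w2 = core.w**2  # already unit norm
    ssy = float(core.c**2 * (core.t_pred @ core.t_pred))
    if mode == "predictive" or core.W_ortho.shape[1] == 0:
        return np.sqrt(p * w2)
    weights = [ssy]
    comps = [w2]
    ssx_tot = float(np.sum(Xs**2))
    ssy_tot = float(yc @ yc)
    for j in range(core.W_ortho.shape[1]):
        t_o = core.T_ortho[:, j]
        p_o = core.P_ortho[:, j]
        ssx_j = float((t_o @ t_o) * (p_o @ p_o))
        # express X- and Y-variance shares on a common (fractional) scale
        weights.append(ssx_j / ssx_tot * ssy_tot)
        comps.append(core.W_ortho[:, j] ** 2)
    weights_arr = np.asarray(weights)
    comp_arr = np.column_stack(comps)  # (p, 1+k_ortho), each column sums to 1
    vip2 = p * (comp_arr @ weights_arr) / weights_arr.sum()
    return np.sqrt(vip2)


@dataclasses.dataclass
class PermutationReport:
    """Label-permutation validation of an OPLS-DA model.

    ``passed`` is True when the original Q2 strictly exceeds every
    permuted Q2 (R2Y is reported but does not gate: with few samples and
    many variables even permuted models reach R2Y ≈ 1 by overfitting,
    which is exactly what Q2 exposes).  With ``n_permutations == 0`` it
    is None (undefined, flagged).  ``q2_intercept`` reports the
    regression-through-data intercept of permuted Q2 against the
    label-permutation correlation — a conventional diagnostic, not a
    gate.
    """

    n_permutations: int
    permuted_r2y: list[float]
    permuted_q2: list[float]
    original_r2y: float
    original_q2: float
    permuted_label_cor: list[float] = dataclasses.field(default_factory=list)

    @property
    def passed(self) -> bool | None:
        if self.n_permutations == 0:
            return None
        return self.original_q2 > max(self.permuted_q2)

    @property
    def q2_intercept(self) -> float | None:
        """Intercept at zero label correlation of the Q2-vs-|cor| line."""
        if len(self.permuted_q2) < 2 or not self.permuted_label_cor:
            return None
        x = np.abs(np.asarray(self.permuted_label_cor + [1.0]))
        yv = np.asarray(self.permuted_q2 + [self.original_q2])
        slope, intercept = np.polyfit(x, yv, 1)
        return float(intercept)


class OPLSDAResults:
    """Fitted OPLS-DA model: scores, fit statistics and VIP.

    Attributes
    ----------
    t_pred : predictive component scores per sample.
    T_ortho : orthogonal component scores (n_samples × k_ortho).
    r2x, r2y, q2 : fit statistics (Q2 from stratified k-fold CV).
    vip : per-variable VIP over the retained (non-constant) variables.
    """

    def __init__(
        self,
        model: "OPLSDA",
        core: _OPLSCore,
        r2x: float,
        r2y: float,
        q2: float,
        vip: np.ndarray,
    ) -> None:
        self.model = model
        self._core = core
        self.t_pred = core.t_pred
        self.T_ortho = core.T_ortho
        self.r2x = r2x
        self.r2y = r2y
        self.q2 = q2
        self.vip = vip

    @property
    def vip_series(self) -> pd.Series:
        return pd.Series(self.vip, index=self.model.var_names, name="VIP")

    def permutation_test(
        self, n_perm: int = 200, seed: int | None = None
    ) -> PermutationReport:
        """Refit under random label permutations (reproducible given seed)."""
        if 0 < n_perm < 20:
            warnings.warn("fewer than 20 permutations gives an unstable validation")
        rng = np.random.default_rng(seed)
        r2ys, q2s, cors = [], [], []
        y = self.model.y
        y01 = self.model.y01
        for _ in range(n_perm):
            # redraw permutations that reproduce the original class split
            # (or its mirror): with few samples the label space is small
            # and such draws would tie the original model by construction
            for _attempt in range(100):
                perm = rng.permutation(len(y))
                yp01 = y01[perm]
                if not (np.array_equal(yp01, y01) or np.array_equal(yp01, 1 - y01)):
                    break
            else:
                continue
            yp = y[perm]
            try:
                res = OPLSDA(
                    self.model.X,
                    yp,
                    k_ortho=self.model.k_ortho,
                    cv_folds=self.model.cv_folds,
                    scale=self.model.scale,
                ).fit(compute_vip=False)
            except OenometError:
                continue
            r2ys.append(res.r2y)
            q2s.append(res.q2)
            cors.append(float(np.corrcoef(y01, y01[perm])[0, 1]))
        return PermutationReport(
            n_permutations=len(r2ys),
            permuted_r2y=r2ys,
            permuted_q2=q2s,
            original_r2y=self.r2y,
            original_q2=self.q2,
            permuted_label_cor=cors,
        )

    def summary(self) -> pd.DataFrame:
        """One-row fit summary (R2X, R2Y, Q2, component counts)."""
        return pd.DataFrame(
            {
                "n_samples": [len(self.model.y)],
                "n_variables": [len(self.vip)],
                "k_ortho": [self.T_ortho.shape[1]],
                "R2X": [self.r2x],
                "R2Y": [self.r2y],
                "Q2": [self.q2],
            }
        )


class OPLSDA:
    """Two-class OPLS-DA model specification.

    Parameters
    ----------
    X : samples × variables matrix (typically autoscaled log10 peak areas;
        scaling is applied internally by default).
    y : two-class label vector (any two values).
    k_ortho : number of orthogonal components (default 1).
    cv_folds : folds for the stratified Q2 cross-validation (default 7,
        capped at the sample count).
    scale : autoscale columns before fitting (default True).
    var_names : optional variable names for reporting.
    """

    def __init__(
        self,
        X,
        y,
        k_ortho: int = 1,
        cv_folds: int = 7,
        scale: bool = True,
        var_names=None,
        vip_mode: str = "total",
    ) -> None:
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes = np.unique(y)
        if len(classes) != 2:
            raise OenometError(f"OPLS-DA needs exactly 2 classes, got {len(classes)}")
        counts = [(y == c).sum() for c in classes]
        if min(counts) < 2:
            raise OenometError("each class needs n >= 2")
        keep = X.std(axis=0, ddof=1) > 0
        if not keep.all():
            warnings.warn(f"dropping {int((~keep).sum())} constant variable column(s)")
        self.X = X[:, keep]
        self.kept_mask = keep
        self.var_names = (
            [n for n, k in zip(var_names, keep) if k]
            if var_names is not None
            else [f"V{i + 1}" for i in np.flatnonzero(keep)]
        )
        self.y01 = (y == classes[1]).astype(float)
        self.y = y
        self.classes = classes
        self.k_ortho = int(k_ortho)
        self.cv_folds = int(cv_folds)
        self.scale = scale
        self.vip_mode = vip_mode

    # -- internals ----------------------------------------------------------
    def _prepare(self, X: np.ndarray, y01: np.ndarray):
        if self.scale:
            Xs, mu, sd = autoscale(X)
        else:
            mu = X.mean(axis=0)
            sd = np.ones(X.shape[1])
            Xs = X - mu
        yc = y01 - y01.mean()
        return Xs, yc, mu, sd

    def _cv_folds_for(self, y01: np.ndarray) -> list[np.ndarray]:
        """Deterministic stratified fold assignment (round-robin per class)."""
        n = len(y01)
        k = max(2, min(self.cv_folds, n))
        folds: list[list[int]] = [[] for _ in range(k)]
        pos = 0
        for cls in (0.0, 1.0):
            for i in np.flatnonzero(y01 == cls):
                folds[pos % k].append(int(i))
                pos += 1
        return [np.asarray(f, dtype=int) for f in folds if f]

    def fit(self, compute_vip: bool = True) -> OPLSDAResults:
        """Fit the O-PLS decomposition and cross-validate Q2."""
        Xs, yc, _, _ = self._prepare(self.X, self.y01)
        core = _opls_decompose(Xs, yc, self.k_ortho)
        ssy = float(yc @ yc)
        resid = yc - core.c * core.t_pred
        r2y = 1.0 - float(resid @ resid) / ssy if ssy > 0 else 0.0
        ssx = float(np.sum(Xs**2))
        modelled = np.outer(core.t_pred, core.p_pred)
        for j in range(core.T_ortho.shape[1]):
            modelled += np.outer(core.T_ortho[:, j], core.P_ortho[:, j])
        r2x = float(np.sum(modelled**2)) / ssx if ssx > 0 else 0.0

        # stratified k-fold CV for Q2
        press = 0.0
        for test_idx in self._cv_folds_for(self.y01):
            train_idx = np.setdiff1d(np.arange(len(self.y01)), test_idx)
            ytr = self.y01[train_idx]
            if len(np.unique(ytr)) < 2 or min(
                (ytr == 0).sum(), (ytr == 1).sum()
            ) < 1:
                continue
            Xtr, ytr_c, mu, sd = self._prepare(self.X[train_idx], ytr)
            sd_safe = np.where(sd > 0, sd, 1.0)
            try:
                core_cv = _opls_decompose(Xtr, ytr_c, self.k_ortho)
            except OenometError:
                continue
            Xte = (self.X[test_idx] - mu) / sd_safe if self.scale else self.X[test_idx] - mu
            yhat = _opls_filter_predict(core_cv, Xte) + ytr.mean()
            press += float(np.sum((self.y01[test_idx] - yhat) ** 2))
        ssy_tot = float(np.sum((self.y01 - self.y01.mean()) ** 2))
        q2 = 1.0 - press / ssy_tot if ssy_tot > 0 else 0.0

        vip = _vip(core, Xs, yc, self.vip_mode) if compute_vip else np.array([])
        return OPLSDAResults(self, core, r2x, r2y, q2, vip)


def oplsda_fit(X, y, k_ortho: int = 1, cv_folds: int = 7, **kwargs) -> OPLSDAResults:
    """Functional convenience wrapper around :class:`OPLSDA`."""
    return OPLSDA(X, y, k_ortho=k_ortho, cv_folds=cv_folds, **kwargs).fit()


def permutation_validate(
    results: OPLSDAResults, n_perm: int = 200, seed: int | None = None
) -> PermutationReport:
    """Functional wrapper for :meth:`OPLSDAResults.permutation_test`."""
    return results.permutation_test(n_perm=n_perm, seed=seed)
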