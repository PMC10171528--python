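"""Principal component regression with embedded stepwise selection (SWR-PCR).

The standardised predictor matrix is orthogonalised by PCA; the component
scores are candidate predictors in a bidirectional stepwise linear regression
that adds or removes one component at a time, accepting only moves that
strictly decrease the Bayesian information criterion. The selected-component
coefficients are finally projected back to the original feature space, where
each feature's coefficient is the loading-weighted sum of the selected
component coefficients — predictions are identical in either parameterisation.

BIC uses the Gaussian profile-likelihood form ``n ln(RSS/n) + k ln(n)`` with
k counting the intercept and the slope terms; the error variance is profiled
out, consistently across all compared models, so only differences matter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .features import impute_by_mean

__all__ = [
    "PCRModel",
    "bic",
    "pca_orthogonalise",
    "stepwise_bic",
    "backproject",
    "fit_pcr",
]

_RSS_FLOOR_SENTINEL = -1e12


def bic(residual_sum_squares: float, n_obs: int, n_params: int) -> float:
    """Gaussian profile-likelihood BIC: ``n ln(RSS/n) + k ln(n)``."""
    if residual_sum_squares < 0:
        raise ValueError("RSS must be nonnegative")
    if n_obs <= n_params:
        raise ValueError("need more observations than parameters")
    if residual_sum_squares == 0:
        warnings.warn("RSS is exactly zero; returning large negative sentinel")
        return _RSS_FLOOR_SENTINEL + n_params * np.log(n_obs)
    return float(
        n_obs * np.log(residual_sum_squares / n_obs) + n_params * np.log(n_obs)
    )


def pca_orthogonalise(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centre X and return (scores, loadings) for all rank-supported
    components: ``scores = U S``, ``loadings = V``, ``Xc ~= scores @ V.T``."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 observations for PCA")
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    tol = s[0] * max(Xc.shape) * np.finfo(float).eps if s.size else 0.0
    r = int(np.sum(s > tol))
    if r == 0:
        raise ValueError("design matrix has rank zero after centring")
    return U[:, :r] * s[:r], Vt[:r].T


def stepwise_bic(
    scores: np.ndarray,
    y: np.ndarray,
    bidirectional: bool = True,
    return_trace: bool = False,
):
    """Greedy stepwise selection over orthogonal PC scores by strict BIC
    decrease.

    From the intercept-only model, every single addition (and removal, when
    bidirectional) is evaluated each step; the move with the largest strict
    BIC decrease is applied; ties go to the smaller model, then the lower
    component index. Because centred PCA scores are exactly orthogonal, the
    RSS of any subset is the centred total sum of squares minus each selected
    component's independent contribution.

    Returns (selected indices in selection order, beta over selected,
    intercept, final BIC).
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = scores.shape
    if y.shape[0] != n:
        raise ValueError("scores and y are not row-aligned")
    yc = y - y.mean()
    tss = float(yc @ yc)
    ss = np.einsum("ij,ij->j", scores, scores)  # per-component score norms
    proj = scores.T @ yc
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = np.where(ss > 0, proj**2 / ss, 0.0)  # RSS drop per component

    in_model = np.zeros(p, dtype=bool)
    selected: list[int] = []
    rss = tss
    cur = bic(rss, n, 1)
    trace = [cur]
    while True:
        best = (0.0, None, None)  # (delta_bic, kind, index)
        can_add = 2 + int(in_model.sum()) < n  # keep the model identifiable
        for j in range(p):
            if not in_model[j]:
                if not can_add:
                    continue
                cand = bic(max(rss - contrib[j], 0.0), n, 2 + int(in_model.sum()))
                delta = cand - cur
                if delta < best[0] - 1e-12:
                    best = (delta, "add", j)
            elif bidirectional:
                cand = bic(rss + contrib[j], n, int(in_model.sum()))
                delta = cand - cur
                # strict decrease required; ties favour removal (smaller model)
                if delta < best[0] - 1e-12 or (
                    abs(delta - best[0]) <= 1e-12 and best[1] == "add"
                ):
                    best = (delta, "remove", j)
        if best[1] is None or best[0] >= -1e-12:
            break
        _, kind, j = best
        if kind == "add":
            in_model[j] = True
            selected.append(j)
            rss = max(rss - contrib[j], 0.0)
        else:
            in_model[j] = False
            selected.remove(j)
            rss += contrib[j]
        cur = bic(rss, n, 1 + int(in_model.sum()))
        trace.append(cur)

    beta = np.array([proj[j] / ss[j] for j in selected])
    intercept = float(y.mean())
    if return_trace:
        return selected, beta, intercept, cur, trace
    return selected, beta, intercept, cur


@dataclass(frozen=True)
class PCRModel:
    """A fitted SWR-PCR model with both parameterisations."""

    column_means: np.ndarray
    column_scales: np.ndarray
    impute_means: np.ndarray
    kept_columns: np.ndarray
    loadings: np.ndarray
    candidate_components: int
    selected: list[int]
    beta_pc: np.ndarray
    intercept: float
    beta_original: np.ndarray
    bic: float
    n_obs: int
    feature_labels: list | None = None

    def _standardised(self, X: np.ndarray) -> np.ndarray:
        X, _ = impute_by_mean(np.asarray(X, dtype=float), self.impute_means)
        X = X[:, self.kept_columns]
        return (X - self.column_means) / self.column_scales

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predict from raw features via the back-projected coefficients."""
        return self.intercept + self._standardised(X) @ self.beta_original

    def predict_pc(self, X: np.ndarray) -> np.ndarray:
        """Predict via PC scores; identical to :meth:`predict` by identity."""
        scores = self._standardised(X) @ self.loadings
        if not self.selected:
            return np.full(X.shape[0], self.intercept)
        return self.intercept + scores[:, self.selected] @ self.beta_pc


def backproject(loadings: np.ndarray, selected: list[int], beta_pc: np.ndarray) -> np.ndarray:
    """Coefficients on the standardised original features: the selected
    loadings weighted by the PC-space coefficients."""
    beta = np.zeros(loadings.shape[0])
    if selected:
        beta = loadings[:, selected] @ beta_pc
    return beta


def fit_pcr(
    X: np.ndarray,
    y: np.ndarray,
    feature_labels: list | None = None,
    bidirectional: bool = True,
) -> PCRModel:
    """Full SWR-PCR fit: impute, drop constants, standardise, PCA,
    stepwise-BIC selection, back-projection.

    Centring of the PC scores is inherited from standardisation, so the
    intercept is the training outcome mean in both parameterisations.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    X_imp, impute_means = impute_by_mean(X)
    sd = X_imp.std(axis=0)
    kept = np.flatnonzero(sd > 1e-12)
    if kept.size == 0:
        raise ValueError("all predictor columns are constant")
    Xk = X_imp[:, kept]
    means = Xk.mean(axis=0)
    scales = Xk.std(axis=0)
    Xs = (Xk - means) / scales
    scores, loadings = pca_orthogonalise(Xs)
    selected, beta_pc, intercept, model_bic = stepwise_bic(
        scores, y, bidirectional=bidirectional
    )
    beta_original = backproject(loadings, selected, beta_pc)
    return PCRModel(
        column_means=means,
        column_scales=scales,
        impute_means=impute_means,
        kept_columns=kept,
        loadings=loadings,
        candidate_components=scores.shape[1],
        selected=selected,
        beta_pc=beta_pc,
        intercept=intercept,
        beta_original=beta_original,
        bic=model_bic,
        n_obs=X.shape[0],
        feature_labels=(
            [feature_labels[k] for k in kept] if feature_labels is not None else None
        ),
    )
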