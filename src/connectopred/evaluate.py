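"""Validation layer: BBC-CV, permutation significance, model contrasts.

Out-of-sample skill is estimated with bootstrap-bias-corrected
cross-validation (BBC-CV): K-fold CV with the entire preprocessing chain
(imputation, standardisation, PCA, stepwise selection) refitted inside each
training fold, pooled out-of-fold predictions, then B bootstrap resamples of
subjects; on each resample the coefficient of determination is computed on
the out-of-bag complement of the pooled predictions, and the corrected point
estimate is the mean of that bootstrap distribution.

Significance of a model's predictive R-squared comes from randomising the
pairing of pooled predictions to outcomes; competing models are contrasted
with Wilcoxon rank-sum tests on their bootstrap R-squared distributions and
with BIC differences read on Kass-Raftery evidence bands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .pcr import PCRModel, fit_pcr

__all__ = [
    "CVResult",
    "ComparisonResult",
    "coefficient_of_determination",
    "stratified_folds",
    "bbc_cv",
    "permutation_test",
    "wilcoxon_ranksum",
    "delta_bic_category",
    "compare_models",
]


def coefficient_of_determination(y: np.ndarray, y_hat: np.ndarray) -> float:
    """R^2 = 1 - SS_res / SS_tot; may be negative for held-out predictions."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape or y.size < 2:
        raise ValueError("y and y_hat must be equal-length vectors (n >= 2)")
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0:
        raise ValueError("R^2 undefined for constant y")
    return 1.0 - float(np.sum((y - y_hat) ** 2)) / tss


@dataclass(frozen=True)
class CVResult:
    """Pooled out-of-fold predictions and the BBC-CV performance summary."""

    pooled_predictions: np.ndarray
    y: np.ndarray
    r2_apparent: float
    r2_pooled: float
    r2_bootstrap: np.ndarray
    r2_corrected: float
    permutation_null: np.ndarray
    p_value: float
    config: dict


@dataclass(frozen=True)
class ComparisonResult:
    """BIC and bootstrap-distribution contrast between two models."""

    delta_bic: float
    category: str
    wilcoxon_z: float
    wilcoxon_p: float


def stratified_folds(y: np.ndarray, n_folds: int, rng: np.random.Generator) -> np.ndarray:
    """Fold assignment stratified by outcome quantile: subjects are sorted by
    y, consecutive blocks of K are dealt to folds in random order."""
    n = y.shape[0]
    order = np.argsort(y, kind="stable")
    fold = np.empty(n, dtype=int)
    for start in range(0, n, n_folds):
        block = order[start : start + n_folds]
        fold[block] = rng.permutation(n_folds)[: block.size]
    return fold


def bbc_cv(
    X: np.ndarray,
    y: np.ndarray,
    n_folds: int = 10,
    n_boot: int = 1000,
    n_perm: int = 1000,
    seed: int = 0,
    bidirectional: bool = True,
) -> tuple[CVResult, PCRModel]:
    """Bootstrap-bias-corrected cross-validation of the SWR-PCR learner.

    Returns the CV result together with the model refitted on all subjects
    (whose in-sample R^2 is the apparent performance and whose BIC feeds the
    model-evidence comparison).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    if n_folds < 2 or n // n_folds < 3:
        raise ValueError("each fold needs at least 3 subjects")
    if n_boot < 100:
        raise ValueError("need at least 100 bootstrap resamples")
    rng = np.random.default_rng(seed)

    fold = stratified_folds(y, n_folds, rng)
    pooled = np.empty(n)
    for k in range(n_folds):
        te = fold == k
        model = fit_pcr(X[~te], y[~te], bidirectional=bidirectional)
        pooled[te] = model.predict(X[te])

    full_model = fit_pcr(X, y, bidirectional=bidirectional)
    r2_apparent = coefficient_of_determination(y, full_model.predict(X))
    r2_pooled = coefficient_of_determination(y, pooled)

    boots = np.empty(n_boot)
    filled = 0
    while filled < n_boot:
        idx = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), idx, assume_unique=False)
        if oob.size < 2 or np.var(y[oob]) == 0:
            continue
        boots[filled] = coefficient_of_determination(y[oob], pooled[oob])
        filled += 1
    r2_corrected = float(boots.mean())

    null, p = permutation_test(pooled, y, n_perm=n_perm, seed=seed + 1)

    result = CVResult(
        pooled_predictions=pooled,
        y=y,
        r2_apparent=r2_apparent,
        r2_pooled=r2_pooled,
        r2_bootstrap=boots,
        r2_corrected=r2_corrected,
        permutation_null=null,
        p_value=p,
        config={
            "folds": n_folds,
            "B": n_boot,
            "n_perm": n_perm,
            "seed": seed,
        },
    )
    return result, full_model


def permutation_test(
    pooled_predictions: np.ndarray,
    y: np.ndarray,
    n_perm: int = 10_000,
    seed: int = 0,
    add_one: bool = True,
) -> tuple[np.ndarray, float]:
    """Randomise the pairing of predictions to outcomes and recompute R^2.

    Null statistics at least as high as the observed one count against the
    model. With ``add_one`` (default) the Phipson-Smyth correction
    ``p = (1 + exceedances) / (1 + n_perm)`` keeps p strictly positive; the
    plain proportion is available with ``add_one=False``.
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    yhat = np.asarray(pooled_predictions, dtype=float)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    observed = coefficient_of_determination(y, yhat)
    tss = float(np.sum((y - y.mean()) ** 2))
    null = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(yhat.size)
        null[b] = 1.0 - float(np.sum((y - yhat[perm]) ** 2)) / tss
    exceed = int(np.sum(null >= observed))
    if add_one:
        p = (1.0 + exceed) / (1.0 + n_perm)
    else:
        p = exceed / n_perm
    return null, float(p)


def wilcoxon_ranksum(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Rank-sum test with midranks, tie-corrected variance and continuity
    correction; Z > 0 means the first sample is stochastically larger.
    Returns (Z, two-sided p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("each sample needs at least 2 values")
    N = na + nb
    ranks = stats.rankdata(np.concatenate([a, b]))
    W = float(ranks[:na].sum())
    mu = na * (N + 1) / 2.0
    _, counts = np.unique(np.concatenate([a, b]), return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (N * (N - 1))
    var = na * nb / 12.0 * ((N + 1) - tie_term)
    if var <= 0:
        return 0.0, 1.0
    diff = W - mu
    z = 0.0 if diff == 0 else (diff - 0.5 * np.sign(diff)) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(min(p, 1.0))


def delta_bic_category(delta_bic: float) -> str:
    """Kass-Raftery reading of ``delta = BIC_M1 - BIC_M2``: positive values
    favour M2. Bands: 1-3 weak, 3-20 positive, 20-150 strong, >150 very
    strong; |delta| < 1 is no meaningful evidence."""
    mag = abs(delta_bic)
    favours = "M2" if delta_bic > 0 else "M1"
    if mag < 1:
        return "no meaningful evidence"
    if mag <= 3:
        band = "weak"
    elif mag <= 20:
        band = "positive"
    elif mag <= 150:
        band = "strong"
    else:
        band = "very strong"
    return f"{band} evidence for {favours}"


def compare_models(
    model1_bic: float, model2_bic: float, cv1: CVResult, cv2: CVResult
) -> ComparisonResult:
    """Contrast two fitted models: BIC difference on Kass-Raftery bands and a
    Wilcoxon rank-sum test on the bootstrap R^2 distributions (Z > 0 means
    the first model's distribution is larger)."""
    if cv1.pooled_predictions.size != cv2.pooled_predictions.size:
        raise ValueError("models were not evaluated on the same cohort")
    delta = float(model1_bic - model2_bic)
    z, p = wilcoxon_ranksum(cv1.r2_bootstrap, cv2.r2_bootstrap)
    return ComparisonResult(
        delta_bic=delta,
        category=delta_bic_category(delta),
        wilcoxon_z=z,
        wilcoxon_p=p,
    )
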