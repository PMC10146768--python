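"""Model diagnostics: fit statistics, Durbin-Watson, variance inflation
factors, cross-validated q^2, origin-regression slopes (k, k'),
fold-difference coverage and the adjusted-R^2 model-size curve.

Note on naming: the source material labels the multicollinearity check
"VIP" but describes the variance inflation factor (1/(1-R^2) of each
predictor regressed on the others, threshold 5); it is implemented and
named as VIF here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .datasets import DescriptorTable, ModelingDataset
from .regression import MLRModel, StepwiseConfig, _design, _ols, fit_stepwise

__all__ = [
    "RoySlopes",
    "ValidationReport",
    "fit_statistics",
    "durbin_watson",
    "vif",
    "q2_cross_validation",
    "roy_slopes",
    "fold_coverage",
    "model_size_curve",
    "validate_model",
]

_COVERAGE_RTOL = 1e-12  # boundary ("within a factor of f") is inclusive


def fit_statistics(y: np.ndarray, y_hat: np.ndarray, p: int) -> tuple[float, float, float]:
    """Return ``(r2, r2_adj, rmse)`` for observed vs fitted values.

    r2 = 1 - SS_res/SS_tot; r2_adj = 1 - (1-r2)(n-1)/(n-p-1);
    rmse = sqrt(mean((y - y_hat)^2)).
    """
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape or y.ndim != 1:
        raise ValueError("y and y_hat must be equal-length vectors")
    n = len(y)
    if n < 2:
        raise ValueError("need at least 2 observations")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("zero response variance: r2 undefined")
    ss_res = float(np.sum((y - y_hat) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    rmse = float(np.sqrt(ss_res / n))
    if n > p + 1:
        r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    else:
        r2_adj = float("nan")
    return r2, r2_adj, rmse


def durbin_watson(residuals: np.ndarray) -> float:
    """``sum(diff(e)^2) / sum(e^2)``; lies in [0, 4], 2 = no autocorrelation."""
    e = np.asarray(residuals, dtype=float)
    if e.ndim != 1 or len(e) < 2:
        raise ValueError("need a vector of at least 2 residuals")
    denom = float(e @ e)
    if denom == 0:
        raise ValueError("all residuals are zero: Durbin-Watson undefined")
    return float(np.sum(np.diff(e) ** 2) / denom)


def vif(table: DescriptorTable) -> dict[str, float]:
    """Variance inflation factor per column via auxiliary regressions.

    ``VIF_j = 1/(1 - R^2_j)`` where column j is regressed (with
    intercept) on all other columns.  Perfect collinearity yields
    ``inf`` rather than an exception.
    """
    p = table.n_descriptors
    if p < 2:
        raise ValueError("VIF needs at least 2 columns")
    out: dict[str, float] = {}
    X = table.values
    for j, name in enumerate(table.descriptor_names):
        others = np.delete(X, j, axis=1)
        target = X[:, j]
        A = _design(others)
        beta, *_ = np.linalg.lstsq(A, target, rcond=None)
        resid = target - A @ beta
        ss_tot = float(np.sum((target - target.mean()) ** 2))
        if ss_tot == 0:
            raise ValueError(f"constant column {name!r}: auxiliary R^2 undefined")
        r2_j = 1.0 - float(resid @ resid) / ss_tot
        out[name] = float("inf") if r2_j >= 1.0 - 1e-12 else 1.0 / (1.0 - r2_j)
    return out


def q2_cross_validation(
    dataset: ModelingDataset,
    terms: Sequence[str],
    scheme: str = "loo",
    k: int = 5,
    seed: int = 0,
) -> float:
    """Cross-validated ``q^2 = 1 - PRESS/SS_tot`` over the training set.

    ``scheme`` is ``"loo"`` (deterministic, the default) or ``"kfold"``
    with *k* shuffled folds seeded by *seed*.  Every training fold must
    keep more rows than ``len(terms) + 2``.
    """
    train = dataset.train_table.select(list(terms)) if terms else dataset.train_table
    y = dataset.y_train
    n = len(y)
    X = train.matrix(list(terms))
    p = len(terms)
    if n <= p + 2:
        raise ValueError("training set too small for cross-validation")

    if scheme == "loo":
        folds = [np.array([i]) for i in range(n)]
    elif scheme == "kfold":
        if not 2 <= k <= n:
            raise ValueError("k must lie in [2, n_train]")
        rng = np.random.default_rng(seed)
        folds = np.array_split(rng.permutation(n), k)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    press = 0.0
    for fold in folds:
        mask = np.ones(n, dtype=bool)
        mask[fold] = False
        if mask.sum() <= p + 2:
            raise ValueError("a training fold has fewer rows than terms + 2")
        A = _design(X[mask])
        beta, *_ = np.linalg.lstsq(A, y[mask], rcond=None)
        pred = _design(X[fold]) @ beta
        press += float(np.sum((y[fold] - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("zero training response variance")
    return 1.0 - press / ss_tot


@dataclass(frozen=True)
class RoySlopes:
    k: float
    k_prime: float
    passed: bool
    bounds: tuple[float, float]


def roy_slopes(
    y_obs: np.ndarray,
    y_pred: np.ndarray,
    bounds: tuple[float, float] = (0.85, 1.15),
) -> RoySlopes:
    """Origin-forced regression slopes between observed and predicted.

    ``k = sum(y_obs*y_pred)/sum(y_pred^2)``,
    ``k' = sum(y_obs*y_pred)/sum(y_obs^2)``; the pass flag requires both
    within *bounds*.
    """
    y_obs = np.asarray(y_obs, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_obs.shape != y_pred.shape or len(y_obs) < 2:
        raise ValueError("need equal-length vectors with n >= 2")
    sp = float(y_pred @ y_pred)
    so = float(y_obs @ y_obs)
    if sp == 0 or so == 0:
        raise ValueError("zero-norm input: slopes undefined")
    cross = float(y_obs @ y_pred)
    k = cross / sp
    k_prime = cross / so
    lo, hi = bounds
    passed = (lo <= k <= hi) and (lo <= k_prime <= hi)
    return RoySlopes(k, k_prime, passed, (lo, hi))


def fold_coverage(
    rfd_obs: np.ndarray,
    rfd_pred: np.ndarray,
    factors: Sequence[float] = (5.0, 10.0),
) -> dict[float, float]:
    """Fraction of chemicals whose predicted/observed ratio stays within
    each fold factor (boundary inclusive)."""
    obs = np.asarray(rfd_obs, dtype=float)
    pred = np.asarray(rfd_pred, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("length mismatch")
    if np.any(obs <= 0) or np.any(pred <= 0):
        raise ValueError("all values must be positive")
    ratio = np.maximum(pred / obs, obs / pred)
    out: dict[float, float] = {}
    for f in factors:
        if not f > 1:
            raise ValueError("fold factors must exceed 1")
        out[float(f)] = float(np.mean(ratio <= f * (1.0 + _COVERAGE_RTOL)))
    return out


def model_size_curve(
    dataset: ModelingDataset, cfg: StepwiseConfig = StepwiseConfig()
) -> list[tuple[int, float]]:
    """Adjusted R^2 after each stepwise entry step, in step order."""
    _, log = fit_stepwise(dataset, cfg)
    return [(s.n_terms, s.r2_adj) for s in log if s.action == "enter"]


@dataclass
class ValidationReport:
    r2_train: float
    r2_adj: float
    r2_test: float
    rmse_train: float
    rmsep: float
    dw: float
    vif: dict[str, float]
    q2: float
    k: float
    k_prime: float
    roy_passed: bool
    coverage: dict[float, float]
    f_pvalue: Optional[float] = None
    q2_scheme: str = "loo"

    def to_dict(self) -> dict:
        return {
            "r2_train": self.r2_train,
            "r2_adj": self.r2_adj,
            "r2_test": self.r2_test,
            "rmse_train": self.rmse_train,
            "rmsep": self.rmsep,
            "dw": self.dw,
            "vif": dict(self.vif),
            "q2": self.q2,
            "q2_scheme": self.q2_scheme,
            "k": self.k,
            "k_prime": self.k_prime,
            "roy_passed": self.roy_passed,
            "coverage": {str(f): v for f, v in self.coverage.items()},
            "f_pvalue": self.f_pvalue,
        }


def validate_model(
    model: MLRModel,
    dataset: ModelingDataset,
    coverage_factors: Sequence[float] = (5.0, 10.0),
    q2_scheme: str = "loo",
    q2_k: int = 5,
    q2_seed: int = 0,
    roy_bounds: tuple[float, float] = (0.85, 1.15),
) -> ValidationReport:
    """Compute the full diagnostics suite for *model* on *dataset*.

    RMSEP and the Roy slopes use the test partition; R^2/RMSE/DW/q^2 use
    the training partition; coverage is on the RfD scale over all rows.
    """
    if not model.terms:
        raise ValueError("validation needs a model with at least one term")
    y_tr = dataset.y_train
    y_te = dataset.y_test
    pred_tr = model.predict_matrix(dataset.train_table)
    pred_te = model.predict_matrix(dataset.test_table)
    p = len(model.terms)

    r2_train, r2_adj, rmse_train = fit_statistics(y_tr, pred_tr, p)
    r2_test, _, rmsep = fit_statistics(y_te, pred_te, p)
    dw = durbin_watson(y_tr - pred_tr)
    vifs = vif(dataset.train_table.select(model.terms)) if p >= 2 else {model.terms[0]: 1.0}
    q2 = q2_cross_validation(dataset, model.terms, scheme=q2_scheme, k=q2_k, seed=q2_seed)
    roy = roy_slopes(y_te, pred_te, bounds=roy_bounds)

    rfd_obs = 10.0 ** (-dataset.response)
    rfd_pred = 10.0 ** (-model.predict_matrix(dataset.table))
    cov = fold_coverage(rfd_obs, rfd_pred, coverage_factors)

    return ValidationReport(
        r2_train=r2_train, r2_adj=r2_adj, r2_test=r2_test,
        rmse_train=rmse_train, rmsep=rmsep, dw=dw, vif=vifs, q2=q2,
        k=roy.k, k_prime=roy.k_prime, roy_passed=roy.passed,
        coverage=cov, f_pvalue=model.f_pvalue, q2_scheme=q2_scheme,
    )
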