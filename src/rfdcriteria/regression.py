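"""Ordinary least squares and forward-backward stepwise regression on
the -log10(RfD) scale, plus the published 12-descriptor model preset.

Entry uses the partial-F criterion (equivalently the two-sided t-test of
the candidate coefficient): the candidate with the smallest p-value
enters while p < ``p_enter``; after each entry, included terms whose
p-value exceeds ``p_remove`` are removed, worst first.  Descriptors are
used unstandardized so fitted coefficients apply to raw values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .datasets import DescriptorTable, ModelingDataset

__all__ = [
    "StepwiseConfig",
    "MLRModel",
    "StepwiseStep",
    "PUBLISHED_RFD_MODEL",
    "fit_ols",
    "fit_stepwise",
    "predict_neg_log_rfd",
    "neg_log_to_rfd",
    "adopt_rfd",
    "round_sig",
]


@dataclass(frozen=True)
class StepwiseConfig:
    """Thresholds for stepwise term entry/removal (entry strictly stricter)."""

    p_enter: float = 0.05
    p_remove: float = 0.10
    max_terms: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_enter < 1.0:
            raise ValueError("p_enter must lie in [0, 1)")
        if not 0.0 < self.p_remove <= 1.0:
            raise ValueError("p_remove must lie in (0, 1]")
        if not self.p_enter < self.p_remove:
            raise ValueError("p_enter must be smaller than p_remove")
        if self.max_terms is not None and self.max_terms < 1:
            raise ValueError("max_terms must be a positive integer")


@dataclass
class MLRModel:
    """An affine model ``neg_log_rfd = intercept + sum(coef * descriptor)``."""

    intercept: float
    coefficients: dict[str, float]
    n_train: Optional[int] = None
    residuals: Optional[np.ndarray] = None
    stderr: Optional[dict[str, float]] = None
    tvalues: Optional[dict[str, float]] = None
    pvalues: Optional[dict[str, float]] = None
    f_pvalue: Optional[float] = None

    @property
    def terms(self) -> list[str]:
        return list(self.coefficients)

    def predict(self, descriptors: Mapping[str, float]) -> float:
        return predict_neg_log_rfd(self, descriptors)

    def predict_matrix(self, table: DescriptorTable) -> np.ndarray:
        """Vectorized prediction for every row of *table*."""
        missing = [t for t in self.terms if t not in table.descriptor_names]
        if missing:
            raise ValueError(f"table lacks model descriptor {missing[0]!r}")
        X = table.matrix(self.terms)
        beta = np.array([self.coefficients[t] for t in self.terms])
        return self.intercept + X @ beta

    def to_dict(self) -> dict:
        out = {
            "intercept": self.intercept,
            "coefficients": dict(self.coefficients),
        }
        if self.n_train is not None:
            out["n_train"] = self.n_train
        for key in ("stderr", "tvalues", "pvalues"):
            val = getattr(self, key)
            if val is not None:
                out[key] = dict(val)
        if self.f_pvalue is not None:
            out["f_pvalue"] = self.f_pvalue
        return out

    @classmethod
    def from_dict(cls, d: Mapping) -> "MLRModel":
        return cls(
            intercept=float(d["intercept"]),
            coefficients={str(k): float(v) for k, v in d["coefficients"].items()},
            n_train=d.get("n_train"),
            stderr=d.get("stderr"),
            tvalues=d.get("tvalues"),
            pvalues=d.get("pvalues"),
            f_pvalue=d.get("f_pvalue"),
        )


@dataclass(frozen=True)
class StepwiseStep:
    action: str  # "enter" | "remove"
    name: str
    p_value: float
    n_terms: int  # term count after the step
    r2_adj: float

    def to_dict(self) -> dict:
        return {
            "action": self.action,
            "name": self.name,
            "p_value": self.p_value,
            "n_terms": self.n_terms,
            "r2_adj": self.r2_adj,
        }


#: The published 12-descriptor reference-dose model, coefficients kept
#: exactly as printed.
PUBLISHED_RFD_MODEL = MLRModel(
    intercept=1.468,
    coefficients={
        "Ui": -0.483,
        "ATS1m": 0.361,
        "MAXDP": -0.195,
        "xp9": 0.265,
        "SdssC_acnt": -0.312,
        "ssi": 1.516,
        "SHHBd": -0.108,
        "MATS8e": -0.559,
        "MATS2m": -1.162,
        "MATS2e": 0.76,
        "SsssCH_acnt": 0.097,
        "piPC08": 0.108,
    },
)


# ---------------------------------------------------------------------
# OLS
# ---------------------------------------------------------------------

def _design(X: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones(X.shape[0]), X])


def _collinear_columns(X: np.ndarray, names: Sequence[str]) -> list[str]:
    """Greedy sweep naming columns that add no rank to the design."""
    kept = np.ones((X.shape[0], 1))
    bad = []
    rank = 1
    for j, name in enumerate(names):
        cand = np.column_stack([kept, X[:, j]])
        r = np.linalg.matrix_rank(cand)
        if r > rank:
            kept, rank = cand, r
        else:
            bad.append(name)
    return bad


def _ols(X: np.ndarray, y: np.ndarray) -> dict:
    """Core least squares with classical inference quantities."""
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 (got n={n}, p={p})")
    A = _design(X)
    if np.linalg.matrix_rank(A) < p + 1:
        raise ValueError("rank-deficient design")
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    fitted = A @ beta
    resid = y - fitted
    df = n - p - 1
    ss_res = float(resid @ resid)
    sigma2 = ss_res / df
    cov = sigma2 * np.linalg.inv(A.T @ A)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    scale = max(1.0, float(np.max(np.abs(beta))))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / np.where(se > 0, se, 1.0), np.inf)
    # exact fit: a coefficient that is numerically zero is "insignificant"
    t = np.where((se == 0) & (np.abs(beta) <= 1e-10 * scale), 0.0, t)
    pvals = 2.0 * stats.t.sf(np.abs(t), df)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    f_p: Optional[float]
    if p > 0 and ss_tot > 0:
        if ss_res > 0:
            f = ((ss_tot - ss_res) / p) / (ss_res / df)
            f_p = float(stats.f.sf(f, p, df))
        else:
            f_p = 0.0
    else:
        f_p = None
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / df if ss_tot > 0 else float("nan")
    return {
        "beta": beta, "resid": resid, "se": se, "t": t, "p": pvals,
        "f_pvalue": f_p, "r2": r2, "r2_adj": r2_adj, "df": df,
        "ss_res": ss_res, "ss_tot": ss_tot,
    }


def fit_ols(table: DescriptorTable, y: np.ndarray) -> MLRModel:
    """Least-squares fit of *y* on all columns of *table* (with intercept).

    Raises on rank deficiency (naming the collinear columns) and on
    ``n <= p + 1``.
    """
    y = np.asarray(y, dtype=float)
    if y.shape != (table.n_chemicals,):
        raise ValueError("response not aligned to table rows")
    X = table.values
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 rows (got n={n}, p={p})")
    if np.linalg.matrix_rank(_design(X)) < p + 1:
        bad = _collinear_columns(X, table.descriptor_names)
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    res = _ols(X, y)
    names = table.descriptor_names
    return MLRModel(
        intercept=float(res["beta"][0]),
        coefficients={nm: float(b) for nm, b in zip(names, res["beta"][1:])},
        n_train=n,
        residuals=res["resid"],
        stderr={nm: float(s) for nm, s in zip(names, res["se"][1:])},
        tvalues={nm: float(t) for nm, t in zip(names, res["t"][1:])},
        pvalues={nm: float(pv) for nm, pv in zip(names, res["p"][1:])},
        f_pvalue=res["f_pvalue"],
    )


# ---------------------------------------------------------------------
# Stepwise selection
# ---------------------------------------------------------------------

def fit_stepwise(
    dataset: ModelingDataset,
    cfg: StepwiseConfig = StepwiseConfig(),
) -> tuple[MLRModel, list[StepwiseStep]]:
    """Forward-backward stepwise selection on the training partition.

    Returns the fitted model (intercept-only if nothing qualifies) and a
    log recording every entry/exit with its p-value and the adjusted R^2
    after the step.
    """
    train = dataset.train_table
    y = dataset.y_train
    if train.n_chemicals == 0:
        raise ValueError("empty training partition")
    names = train.descriptor_names
    cols = {nm: train.column(nm) for nm in names}
    n = train.n_chemicals

    included: list[str] = []
    log: list[StepwiseStep] = []
    seen_states: set[frozenset] = {frozenset()}

    ss_tot = float(np.sum((y - y.mean()) ** 2))
    exact_tol = 1e-12 * max(ss_tot, 1e-300)  # fit counted as exact below this
    ss_cur = ss_tot

    def matrix(sel: Sequence[str]) -> np.ndarray:
        if not sel:
            return np.empty((n, 0))
        return np.column_stack([cols[nm] for nm in sel])

    def partial_f_p(ss_new: float, df_new: int) -> float:
        """p-value for one added term via the F(1, df) improvement test."""
        if ss_new <= exact_tol:
            return 0.0 if ss_cur > exact_tol else 1.0
        f = max(ss_cur - ss_new, 0.0) / (ss_new / df_new)
        return float(stats.f.sf(f, 1, df_new))

    while True:
        if cfg.max_terms is not None and len(included) >= cfg.max_terms:
            break
        if n <= len(included) + 2:  # no room for another term
            break
        if ss_cur <= exact_tol:  # already interpolating; nothing can improve
            break
        best_name, best_p, best_fit = None, None, None
        for nm in names:
            if nm in included:
                continue
            trial = included + [nm]
            X = matrix(trial)
            if np.linalg.matrix_rank(_design(X)) < len(trial) + 1:
                continue
            res = _ols(X, y)
            pv = partial_f_p(float(res["ss_res"]), int(res["df"]))
            if best_p is None or pv < best_p:
                best_name, best_p, best_fit = nm, pv, res
        if best_name is None or not best_p < cfg.p_enter:
            break
        included.append(best_name)
        ss_cur = float(best_fit["ss_res"])
        log.append(StepwiseStep("enter", best_name, best_p,
                                len(included), float(best_fit["r2_adj"])))

        # backward pass
        res = best_fit
        while included:
            pvals = res["p"][1:]
            worst = int(np.argmax(pvals))
            if not pvals[worst] > cfg.p_remove:
                break
            gone = included.pop(worst)
            res = _ols(matrix(included), y) if included else None
            ss_cur = float(res["ss_res"]) if res is not None else ss_tot
            r2_adj = float(res["r2_adj"]) if res is not None else 0.0
            log.append(StepwiseStep("remove", gone, float(pvals[worst]),
                                    len(included), r2_adj))
            if res is None:
                break
        state = frozenset(included)
        if state in seen_states:  # cycle guard
            break
        seen_states.add(state)

    final = fit_ols(train.select(included), y) if included else _intercept_only(y)
    return final, log


def _intercept_only(y: np.ndarray) -> MLRModel:
    mu = float(np.mean(y))
    return MLRModel(intercept=mu, coefficients={}, n_train=len(y),
                    residuals=np.asarray(y, dtype=float) - mu)


# ---------------------------------------------------------------------
# Prediction and RfD adoption
# ---------------------------------------------------------------------

def predict_neg_log_rfd(model: MLRModel, descriptors: Mapping[str, float]) -> float:
    """Evaluate the affine model; missing descriptors are an error, never 0."""
    total = model.intercept
    for name, coef in model.coefficients.items():
        if name not in descriptors:
            raise ValueError(f"missing descriptor {name!r}")
        total += coef * float(descriptors[name])
    return total


def neg_log_to_rfd(y: float) -> float:
    """Back-transform ``-log10(RfD)`` to an RfD in mg/kg/d."""
    return 10.0 ** (-y)


def round_sig(x: float, sig_figs: int) -> float:
    """Round to *sig_figs* significant figures (0 stays 0)."""
    if sig_figs < 1:
        raise ValueError("sig_figs must be >= 1")
    if x == 0 or not math.isfinite(x):
        return x
    ndigits = sig_figs - 1 - int(math.floor(math.log10(abs(x))))
    return round(x, ndigits)


def adopt_rfd(rfd: float, sig_figs: int = 1) -> float:
    """Adopt a predicted RfD at a fixed significant-figure count."""
    if rfd <= 0:
        raise ValueError("rfd must be positive")
    return round_sig(rfd, sig_figs)
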