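"""Descriptor pre-screening.

Three rules applied in a fixed order:

1. drop columns with (sample) variance not exceeding a small epsilon;
2. drop columns whose fraction of non-zero entries is below a minimum
   (strictly below — a column exactly at the threshold is retained);
3. greedily drop one member of every column pair whose absolute Pearson
   correlation exceeds a threshold.

Each removal is recorded with the rule that triggered it (and, for rule
3, the partner column) so the reduction is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .datasets import DescriptorTable

__all__ = [
    "RULE_ZERO_VARIANCE",
    "RULE_SPARSE",
    "RULE_CORRELATED",
    "ScreeningConfig",
    "Removal",
    "ScreeningReport",
    "filter_zero_variance",
    "filter_sparse",
    "filter_correlated",
    "screen_descriptors",
]

RULE_ZERO_VARIANCE = "zero_variance"
RULE_SPARSE = "sparse"
RULE_CORRELATED = "correlated"


@dataclass(frozen=True)
class ScreeningConfig:
    variance_epsilon: float = 0.0
    nonzero_fraction_min: float = 0.10
    corr_threshold: float = 0.90
    zero_tolerance: float = 1e-12

    def __post_init__(self) -> None:
        if self.variance_epsilon < 0:
            raise ValueError("variance_epsilon must be >= 0")
        if not 0.0 <= self.nonzero_fraction_min <= 1.0:
            raise ValueError("nonzero_fraction_min must lie in [0, 1]")
        if not 0.0 <= self.corr_threshold <= 1.0:
            raise ValueError("corr_threshold must lie in [0, 1]")
        if self.zero_tolerance < 0:
            raise ValueError("zero_tolerance must be >= 0")


@dataclass(frozen=True)
class Removal:
    name: str
    rule: str
    partner: Optional[str] = None

    def to_dict(self) -> dict:
        d = {"name": self.name, "rule": self.rule}
        if self.partner is not None:
            d["partner"] = self.partner
        return d


@dataclass
class ScreeningReport:
    removed: list[Removal]
    retained: list[str]
    stage_counts: list[tuple[int, int]]  # (before, after) per stage, order 1->3

    def to_dict(self) -> dict:
        return {
            "removed": [r.to_dict() for r in self.removed],
            "retained": list(self.retained),
            "stage_counts": [
                {"stage": rule, "before": b, "after": a}
                for rule, (b, a) in zip(
                    (RULE_ZERO_VARIANCE, RULE_SPARSE, RULE_CORRELATED),
                    self.stage_counts,
                )
            ],
        }


def filter_zero_variance(
    table: DescriptorTable, cfg: ScreeningConfig = ScreeningConfig()
) -> tuple[DescriptorTable, list[Removal]]:
    """Rule 1: retain columns with sample variance > ``variance_epsilon``."""
    if table.n_descriptors == 0:
        return table, []
    if table.n_chemicals < 2:
        variances = np.zeros(table.n_descriptors)
    else:
        # shift by the first row so a truly constant column has variance
        # exactly 0 (plain np.var leaves summation dust ~1e-31)
        shifted = table.values - table.values[0:1, :]
        variances = np.var(shifted, axis=0, ddof=1)
    removed = [
        Removal(name, RULE_ZERO_VARIANCE)
        for name, v in zip(table.descriptor_names, variances)
        if not v > cfg.variance_epsilon
    ]
    return table.drop(r.name for r in removed), removed


def filter_sparse(
    table: DescriptorTable, cfg: ScreeningConfig = ScreeningConfig()
) -> tuple[DescriptorTable, list[Removal]]:
    """Rule 2: drop columns with non-zero fraction strictly below the minimum.

    "Non-zero" means ``|x| > zero_tolerance``.
    """
    if table.n_descriptors == 0:
        return table, []
    n = table.n_chemicals
    frac = np.count_nonzero(np.abs(table.values) > cfg.zero_tolerance, axis=0) / n
    removed = [
        Removal(name, RULE_SPARSE)
        for name, f in zip(table.descriptor_names, frac)
        if f < cfg.nonzero_fraction_min
    ]
    return table.drop(r.name for r in removed), removed


def filter_correlated(
    table: DescriptorTable,
    cfg: ScreeningConfig = ScreeningConfig(),
    response: Optional[np.ndarray] = None,
) -> tuple[DescriptorTable, list[Removal]]:
    """Rule 3: no retained pair may have |Pearson r| above the threshold.

    Pairs are scanned greedily in column order; once a column is dropped
    it takes part in no further pair.  Victim choice within a pair: the
    member with the smaller |correlation to the response| if a response
    is supplied, otherwise the member with the larger mean absolute
    correlation to all other columns; ties drop the lexicographically
    later name.
    """
    p = table.n_descriptors
    if p < 2:
        return table, []
    if table.n_chemicals < 3:
        raise ValueError("correlation filter needs at least 3 rows")
    variances = np.var(table.values, axis=0, ddof=1)
    if np.any(variances <= 0):
        j = int(np.argmin(variances))
        raise ValueError(
            f"constant column {table.descriptor_names[j]!r}; "
            "apply the zero-variance filter first"
        )
    corr = np.corrcoef(table.values, rowvar=False)
    abs_corr = np.abs(corr)

    if response is not None:
        response = np.asarray(response, dtype=float)
        if response.shape != (table.n_chemicals,):
            raise ValueError("response not aligned to table rows")
        if np.var(response) > 0:
            resp_corr = np.abs(
                [np.corrcoef(table.values[:, j], response)[0, 1] for j in range(p)]
            )
        else:
            response = None  # constant response carries no preference
    mean_abs = (abs_corr.sum(axis=1) - 1.0) / (p - 1)

    names = table.descriptor_names
    dropped: set[int] = set()
    removed: list[Removal] = []

    tie_tol = 1e-12  # row sums of identical columns differ by summation dust

    def victim(i: int, j: int) -> int:
        if response is not None:
            if abs(resp_corr[i] - resp_corr[j]) > tie_tol:
                return i if resp_corr[i] < resp_corr[j] else j
        else:
            if abs(mean_abs[i] - mean_abs[j]) > tie_tol:
                return i if mean_abs[i] > mean_abs[j] else j
        return i if names[i] > names[j] else j

    for i in range(p):
        if i in dropped:
            continue
        for j in range(i + 1, p):
            if j in dropped:
                continue
            if abs_corr[i, j] > cfg.corr_threshold:
                v = victim(i, j)
                partner = j if v == i else i
                removed.append(Removal(names[v], RULE_CORRELATED, names[partner]))
                dropped.add(v)
                if v == i:
                    break
    return table.drop(r.name for r in removed), removed


def screen_descriptors(
    table: DescriptorTable,
    cfg: ScreeningConfig = ScreeningConfig(),
    response: Optional[np.ndarray] = None,
) -> tuple[DescriptorTable, ScreeningReport]:
    """Apply the three rules in order and report every removal.

    A column removable by more than one rule is attributed to the
    earliest stage that sees it.  Idempotent: screening a screened
    table removes nothing.
    """
    counts: list[tuple[int, int]] = []
    t1, rem1 = filter_zero_variance(table, cfg)
    counts.append((table.n_descriptors, t1.n_descriptors))
    t2, rem2 = filter_sparse(t1, cfg)
    counts.append((t1.n_descriptors, t2.n_descriptors))
    if t2.n_descriptors >= 2:
        t3, rem3 = filter_correlated(t2, cfg, response)
    else:
        t3, rem3 = t2, []
    counts.append((t2.n_descriptors, t3.n_descriptors))
    report = ScreeningReport(rem1 + rem2 + rem3, list(t3.descriptor_names), counts)
    return t3, report
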