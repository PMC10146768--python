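"""Hazard-quotient risk assessment against an ambient water quality
criterion.

``HQ = EEC / AWQC`` with monitoring concentrations in ng/L and the
criterion in ug/L (the ng->ug conversion is internal and deliberately
not configurable).  Categories, boundaries resolved to half-open bins
assigning boundary values to the more protective category:

    [0, 0.1)   no_risk
    [0.1, 1)   low
    [1, 10]    intermediate
    (10, inf)  high
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CATEGORY_ORDER",
    "BINNING_RULE",
    "MonitoringSample",
    "RiskResult",
    "RiskSummary",
    "hazard_quotient",
    "classify_risk",
    "assess_sites",
    "summarize_sites",
    "load_monitoring_table",
    "save_monitoring_table",
]

NO_RISK = "no_risk"
LOW = "low"
INTERMEDIATE = "intermediate"
HIGH = "high"
CATEGORY_ORDER = (NO_RISK, LOW, INTERMEDIATE, HIGH)

#: Identifier of the boundary-resolution rule, recorded in summaries.
BINNING_RULE = "half-open:[0,0.1)no|[0.1,1)low|[1,10]intermediate|(10,inf)high"


@dataclass(frozen=True)
class MonitoringSample:
    site_id: str
    eec_ng_per_L: float

    def __post_init__(self) -> None:
        if self.eec_ng_per_L < 0:
            raise ValueError(f"negative concentration at site {self.site_id!r}")


@dataclass(frozen=True)
class RiskResult:
    site_id: str
    hq: float
    category: str


@dataclass
class RiskSummary:
    n_sites: int
    fractions: dict[str, float]
    median_eec_ng_per_L: float
    median_hq: float
    median_category: str
    binning_rule: str = BINNING_RULE

    def to_dict(self) -> dict:
        return {
            "n_sites": self.n_sites,
            "fractions": dict(self.fractions),
            "median_eec_ng_per_L": self.median_eec_ng_per_L,
            "median_hq": self.median_hq,
            "median_category": self.median_category,
            "binning_rule": self.binning_rule,
        }


def hazard_quotient(eec_ng_per_L: float, awqc_ug_per_L: float) -> float:
    """Dimensionless HQ; the EEC is converted ng/L -> ug/L internally."""
    if awqc_ug_per_L <= 0:
        raise ValueError("AWQC must be positive")
    if eec_ng_per_L < 0:
        raise ValueError("EEC must be non-negative")
    return (eec_ng_per_L / 1000.0) / awqc_ug_per_L


def classify_risk(hq: float) -> str:
    if hq < 0:
        raise ValueError("HQ must be non-negative")
    if hq < 0.1:
        return NO_RISK
    if hq < 1.0:
        return LOW
    if hq <= 10.0:
        return INTERMEDIATE
    return HIGH


def assess_sites(
    samples: Sequence[MonitoringSample], awqc_ug_per_L: float
) -> list[RiskResult]:
    out = []
    for s in samples:
        hq = hazard_quotient(s.eec_ng_per_L, awqc_ug_per_L)
        out.append(RiskResult(s.site_id, hq, classify_risk(hq)))
    return out


def summarize_sites(
    samples: Sequence[MonitoringSample], awqc_ug_per_L: float
) -> RiskSummary:
    """Per-category site fractions plus the HQ of the median concentration.

    The median concentration is the headline exposure level; even-length
    inputs use the midpoint of the two central order statistics.
    """
    if not samples:
        raise ValueError("need at least one monitoring sample")
    results = assess_sites(samples, awqc_ug_per_L)
    n = len(results)
    fractions = {c: sum(r.category == c for r in results) / n for c in CATEGORY_ORDER}
    median_eec = float(np.median([s.eec_ng_per_L for s in samples]))
    median_hq = hazard_quotient(median_eec, awqc_ug_per_L)
    return RiskSummary(
        n_sites=n,
        fractions=fractions,
        median_eec_ng_per_L=median_eec,
        median_hq=median_hq,
        median_category=classify_risk(median_hq),
    )


def load_monitoring_table(path: str | Path) -> list[MonitoringSample]:
    """Read a monitoring CSV with columns (site, concentration ng/L)."""
    raw = pd.read_csv(path, float_precision="round_trip")
    if raw.shape[1] < 2:
        raise ValueError(f"monitoring table needs (site, eec) columns: {path}")
    samples = [
        MonitoringSample(str(row.iloc[0]), float(row.iloc[1]))
        for _, row in raw.iterrows()
    ]
    if not samples:
        raise ValueError(f"empty monitoring table: {path}")
    return samples


def save_monitoring_table(samples: Sequence[MonitoringSample], path: str | Path) -> None:
    pd.DataFrame(
        {
            "site_id": [s.site_id for s in samples],
            "eec_ng_per_L": [s.eec_ng_per_L for s in samples],
        }
    ).to_csv(path, index=False)
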