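"""Human-health ambient water quality criteria (AWQC).

The chain implemented here:

* freely dissolved fraction of a chemical from its octanol-water
  partition coefficient and the water's organic-carbon content,

      f_fd = 1 / (1 + POC*Kow + DOC*0.08*Kow),      Kow = 10**lgKow

* baseline bioaccumulation factor per trophic level from a laboratory
  bioconcentration factor,

      BL_BAF = FCM * (BCF/f_fd - 1) / f_l

* conversion back to a wet-weight, total-water final BAF,

      F_BAF = (BL_BAF * f_l + 1) * f_fd

* the criterion itself,

      AWQC = RfD * RSC * BW / (DI + sum_i FI_i * BAF_i),  i in {2,3,4}

with the quotient in mg/L, reported in ug/L after rounding to a fixed
count of significant figures (one by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Sequence

import yaml

from .regression import round_sig

__all__ = [
    "TROPHIC_LEVELS",
    "ChemicalPartitioning",
    "OrganicCarbonWater",
    "TrophicLevelParams",
    "ExposureParams",
    "CriteriaInput",
    "BafDerivation",
    "free_dissolved_fraction",
    "organic_carbon_term_from_ffd",
    "bcf_from_baseline_baf",
    "baseline_baf",
    "final_baf",
    "derive_bafs",
    "derive_awqc",
    "load_criteria_config",
    "builtin_criteria_path",
    "derive_awqc_from_config",
]

TROPHIC_LEVELS = (2, 3, 4)


@dataclass(frozen=True)
class ChemicalPartitioning:
    chem_id: str
    lg_kow: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.lg_kow):
            raise ValueError("lg_kow must be finite")

    @property
    def kow(self) -> float:
        return 10.0 ** self.lg_kow


@dataclass(frozen=True)
class OrganicCarbonWater:
    """Organic-carbon content of the water body, both in kg/L."""

    poc: float
    doc: float

    def __post_init__(self) -> None:
        if self.poc < 0 or self.doc < 0:
            raise ValueError("POC and DOC must be non-negative")


@dataclass(frozen=True)
class TrophicLevelParams:
    level: int
    f_l: float   # lipid fraction of tissue
    fcm: float   # food chain multiplication factor
    bcf: float   # laboratory bioconcentration factor, L/kg

    def __post_init__(self) -> None:
        if self.level not in TROPHIC_LEVELS:
            raise ValueError(f"trophic level must be one of {TROPHIC_LEVELS}")
        if not 0.0 < self.f_l < 1.0:
            raise ValueError("lipid fraction must lie in (0, 1)")
        if self.fcm < 1.0:
            raise ValueError("FCM must be >= 1")
        if self.bcf <= 0:
            raise ValueError("BCF must be positive")


@dataclass(frozen=True)
class ExposureParams:
    bw: float                 # body weight, kg
    di: float                 # drinking water intake, L/d
    fi: Mapping[int, float]   # aquatic-product intake per level, kg/d
    rsc: float                # relative source contribution

    def __post_init__(self) -> None:
        if self.bw <= 0 or self.di <= 0:
            raise ValueError("BW and DI must be positive")
        if set(self.fi) != set(TROPHIC_LEVELS):
            raise ValueError(f"FI must cover trophic levels {TROPHIC_LEVELS}")
        if any(v < 0 for v in self.fi.values()):
            raise ValueError("FI values must be non-negative")
        if not 0.0 < self.rsc <= 1.0:
            raise ValueError("RSC must lie in (0, 1]")


@dataclass(frozen=True)
class CriteriaInput:
    chem_id: str
    rfd: float                 # mg/kg/d
    exposure: ExposureParams
    bafs: Mapping[int, float]  # final BAF per level, L/kg

    def __post_init__(self) -> None:
        if self.rfd <= 0:
            raise ValueError("RfD must be positive")
        if set(self.bafs) != set(TROPHIC_LEVELS):
            raise ValueError(f"BAFs must cover trophic levels {TROPHIC_LEVELS}")
        if any(b <= 0 for b in self.bafs.values()):
            raise ValueError("BAFs must be positive")


@dataclass(frozen=True)
class BafDerivation:
    chem_id: str
    f_fd: float
    baseline: Mapping[int, float]
    final: Mapping[int, float]

    def to_dict(self) -> dict:
        return {
            "chem_id": self.chem_id,
            "f_fd": self.f_fd,
            "baseline_baf": {str(k): v for k, v in self.baseline.items()},
            "final_baf": {str(k): v for k, v in self.final.items()},
        }


# ---------------------------------------------------------------------
# Partitioning
# ---------------------------------------------------------------------

def free_dissolved_fraction(chem: ChemicalPartitioning, water: OrganicCarbonWater) -> float:
    """Fraction of the chemical freely dissolved in the water column."""
    kow = chem.kow
    return 1.0 / (1.0 + water.poc * kow + water.doc * 0.08 * kow)


def organic_carbon_term_from_ffd(lg_kow: float, f_fd: float) -> float:
    """Back-solve the combined organic-carbon term ``POC + 0.08*DOC``
    from a known freely dissolved fraction.

    Useful when only f_fd values are reported and the water's POC/DOC
    pair is not.
    """
    if not 0.0 < f_fd <= 1.0:
        raise ValueError("f_fd must lie in (0, 1]")
    return (1.0 / f_fd - 1.0) / (10.0 ** lg_kow)


# ---------------------------------------------------------------------
# Bioaccumulation factors
# ---------------------------------------------------------------------

def baseline_baf(tl: TrophicLevelParams, f_fd: float) -> float:
    """Lipid- and dissolved-normalized baseline BAF for one trophic level."""
    if not 0.0 < f_fd <= 1.0:
        raise ValueError("f_fd must lie in (0, 1]")
    ratio = tl.bcf / f_fd
    if ratio <= 1.0:
        raise ValueError("BCF/f_fd must exceed 1 for a positive baseline BAF")
    return tl.fcm * (ratio - 1.0) / tl.f_l


def bcf_from_baseline_baf(bl_baf: float, tl: TrophicLevelParams, f_fd: float) -> float:
    """Invert the baseline-BAF formula to recover the laboratory BCF."""
    if bl_baf < 0:
        raise ValueError("baseline BAF must be non-negative")
    return (bl_baf * tl.f_l / tl.fcm + 1.0) * f_fd


def final_baf(bl_baf: float, tl: TrophicLevelParams, f_fd: float) -> float:
    """Wet-weight, total-water final BAF; always >= f_fd."""
    if bl_baf < 0:
        raise ValueError("baseline BAF must be non-negative")
    return (bl_baf * tl.f_l + 1.0) * f_fd


def derive_bafs(
    chem: ChemicalPartitioning,
    water: OrganicCarbonWater,
    levels: Sequence[TrophicLevelParams],
) -> BafDerivation:
    """Full chain: f_fd, then baseline and final BAF for every level."""
    if sorted(tl.level for tl in levels) != list(TROPHIC_LEVELS):
        raise ValueError(f"need exactly the trophic levels {TROPHIC_LEVELS}")
    f_fd = free_dissolved_fraction(chem, water)
    baseline = {tl.level: baseline_baf(tl, f_fd) for tl in levels}
    final = {tl.level: final_baf(baseline[tl.level], tl, f_fd) for tl in levels}
    return BafDerivation(chem.chem_id, f_fd, baseline, final)


# ---------------------------------------------------------------------
# The criterion
# ---------------------------------------------------------------------

def derive_awqc(inp: CriteriaInput, report_sig_figs: int = 1) -> tuple[float, float]:
    """Return ``(awqc_mg_per_L, awqc_ug_per_L_adopted)``.

    Numerator mg/d, denominator L/d; the adopted value is converted to
    ug/L and rounded to *report_sig_figs* significant figures.
    """
    exp = inp.exposure
    denom = exp.di + sum(exp.fi[i] * inp.bafs[i] for i in TROPHIC_LEVELS)
    awqc_mg = inp.rfd * exp.rsc * exp.bw / denom
    adopted = round_sig(awqc_mg * 1000.0, report_sig_figs)
    return awqc_mg, adopted


# ---------------------------------------------------------------------
# YAML config plumbing
# ---------------------------------------------------------------------

def builtin_criteria_path(name: str) -> Path:
    """Path of a packaged criteria fixture (``"ppDDE"`` or ``"alphaHCH"``)."""
    p = resources.files("rfdcriteria").joinpath("data", f"{name}.yaml")
    return Path(str(p))


def load_criteria_config(path: str | Path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"criteria config must be a mapping: {path}")
    return cfg


def derive_awqc_from_config(cfg: Mapping, report_sig_figs: int = 1) -> dict:
    """Run the full criteria chain from a parsed YAML mapping.

    Schema: ``chemical`` (id, lg_kow, rfd), ``water`` (poc, doc),
    ``trophic_levels`` ({2,3,4} -> f_l, fcm, bcf), ``exposure``
    (bw, di, fi2..fi4, rsc) and an optional ``bafs`` block that, when
    present, overrides the BCF-derived final BAFs (used to encode
    published BAF tables verbatim).
    """
    chem_block = cfg["chemical"]
    chem = ChemicalPartitioning(str(chem_block["id"]), float(chem_block["lg_kow"]))
    water = OrganicCarbonWater(float(cfg["water"]["poc"]), float(cfg["water"]["doc"]))
    levels = [
        TrophicLevelParams(
            level=i,
            f_l=float(cfg["trophic_levels"][i]["f_l"]),
            fcm=float(cfg["trophic_levels"][i]["fcm"]),
            bcf=float(cfg["trophic_levels"][i]["bcf"]),
        )
        for i in TROPHIC_LEVELS
    ]
    derivation = derive_bafs(chem, water, levels)
    if "bafs" in cfg and cfg["bafs"] is not None:
        bafs = {i: float(cfg["bafs"][i]) for i in TROPHIC_LEVELS}
    else:
        bafs = dict(derivation.final)
    ex_block = cfg["exposure"]
    exposure = ExposureParams(
        bw=float(ex_block["bw"]),
        di=float(ex_block["di"]),
        fi={i: float(ex_block[f"fi{i}"]) for i in TROPHIC_LEVELS},
        rsc=float(ex_block["rsc"]),
    )
    inp = CriteriaInput(chem.chem_id, float(chem_block["rfd"]), exposure, bafs)
    awqc_mg, adopted = derive_awqc(inp, report_sig_figs)
    return {
        "chem_id": chem.chem_id,
        "rfd_mg_per_kg_d": inp.rfd,
        "baf_derivation": derivation.to_dict(),
        "bafs_used": {str(i): bafs[i] for i in TROPHIC_LEVELS},
        "awqc_mg_per_L": awqc_mg,
        "awqc_ug_per_L": awqc_mg * 1000.0,
        "awqc_ug_per_L_adopted": adopted,
        "report_sig_figs": report_sig_figs,
    }
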