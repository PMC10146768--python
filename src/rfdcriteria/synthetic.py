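"""Synthetic fixtures with the statistical structure the pipeline
assumes: descriptor matrices containing correlated Gaussian blocks,
count-like columns, constant/sparse/duplicated columns, responses from a
known sparse linear model, and lognormal monitoring tables.

Every generator is a pure function of its spec plus seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .datasets import ChemicalRecord, DescriptorTable

__all__ = [
    "SyntheticSpec",
    "generate_descriptor_matrix",
    "generate_response",
    "generate_monitoring_table",
]

# every COUNT_STRIDE-th regular column is an independent count column,
# mimicking *_acnt atom-count descriptors
COUNT_STRIDE = 9


@dataclass(frozen=True)
class SyntheticSpec:
    n_chemicals: int = 109
    n_descriptors: int = 50
    n_constant: int = 0
    n_sparse: int = 0
    n_duplicated: int = 0
    true_coefficients: Mapping[str, float] = field(default_factory=dict)
    intercept: float = 1.5
    noise_sd: float = 0.0
    block_correlation: float = 0.0
    block_size: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chemicals < 1 or self.n_descriptors < 1:
            raise ValueError("need at least one chemical and one descriptor")
        if min(self.n_constant, self.n_sparse, self.n_duplicated) < 0:
            raise ValueError("degenerate-column counts must be non-negative")
        if self.n_regular < 1:
            raise ValueError(
                "degenerate columns leave no regular descriptor columns"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0.0 <= self.block_correlation < 1.0:
            raise ValueError("block_correlation must lie in [0, 1)")
        if self.block_size < 1:
            raise ValueError("block_size must be positive")
        bad = set(self.true_coefficients) - set(self.regular_names)
        if bad:
            raise ValueError(f"true_coefficients refer to unknown columns: {sorted(bad)}")

    @property
    def n_regular(self) -> int:
        return (self.n_descriptors - self.n_constant - self.n_sparse
                - self.n_duplicated)

    @property
    def regular_names(self) -> list[str]:
        return [f"X{j + 1:03d}" for j in range(self.n_regular)]

    @property
    def true_support(self) -> tuple[str, ...]:
        return tuple(self.true_coefficients)


def generate_descriptor_matrix(spec: SyntheticSpec) -> DescriptorTable:
    """Deterministic descriptor table with the requested column mix.

    Layout: regular columns first (correlated Gaussian blocks, every
    ``COUNT_STRIDE``-th column an independent Poisson count), then
    constant, sparse (<10% non-zero) and duplicated columns.
    """
    n = spec.n_chemicals
    rng = np.random.default_rng(spec.seed)

    if spec.n_sparse > 0:
        k_nonzero = max(1, int(0.05 * n))
        if k_nonzero / n >= 0.10:
            raise ValueError(
                f"cannot build sparse columns below 10% non-zero with n={n}"
            )

    # regular columns: equicorrelated within consecutive blocks
    rho = spec.block_correlation
    cols: list[np.ndarray] = []
    common = None
    for j in range(spec.n_regular):
        if j % spec.block_size == 0:
            common = rng.normal(size=n)
        if COUNT_STRIDE > 1 and (j + 1) % COUNT_STRIDE == 0:
            cols.append(rng.poisson(3.0, size=n).astype(float))
        else:
            cols.append(math.sqrt(rho) * common + math.sqrt(1.0 - rho) * rng.normal(size=n))
    names = list(spec.regular_names)

    for j in range(spec.n_constant):
        cols.append(np.full(n, 1.0 + j))
        names.append(f"const{j + 1:02d}")

    for j in range(spec.n_sparse):
        col = np.zeros(n)
        support = rng.choice(n, size=max(1, int(0.05 * n)), replace=False)
        col[support] = rng.normal(loc=2.0, size=len(support))
        cols.append(col)
        names.append(f"sparse{j + 1:02d}")

    for j in range(spec.n_duplicated):
        src = j % spec.n_regular
        cols.append(cols[src].copy())
        names.append(f"dup{j + 1:02d}_of_{spec.regular_names[src]}")

    chem_ids = [f"chem{i + 1:04d}" for i in range(n)]
    return DescriptorTable(chem_ids, names, np.column_stack(cols))


def generate_response(table: DescriptorTable, spec: SyntheticSpec) -> list[ChemicalRecord]:
    """Responses from the spec's sparse linear model plus Gaussian noise.

    ``neg_log_rfd = intercept + sum(coef * x) + N(0, noise_sd^2)``;
    the stored RfD is ``10**(-neg_log_rfd)``.  The noise stream is
    seeded independently of the descriptor stream (seed + 1).
    """
    missing = [nm for nm in spec.true_support if nm not in table.descriptor_names]
    if missing:
        raise ValueError(f"table lacks support column {missing[0]!r}")
    y = np.full(table.n_chemicals, spec.intercept, dtype=float)
    for nm, coef in spec.true_coefficients.items():
        y += coef * table.column(nm)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed + 1)
        y += rng.normal(scale=spec.noise_sd, size=len(y))
    return [
        ChemicalRecord(chem_id, 10.0 ** (-v))
        for chem_id, v in zip(table.chem_ids, y)
    ]


def generate_monitoring_table(
    n_sites: int, log_mean: float, log_sd: float, seed: int = 0
) -> list:
    """Lognormal site concentrations (ng/L), deterministic per seed."""
    from .risk import MonitoringSample

    if n_sites < 1:
        raise ValueError("need at least one site")
    if log_sd < 0:
        raise ValueError("log_sd must be non-negative")
    rng = np.random.default_rng(seed)
    eec = rng.lognormal(mean=log_mean, sigma=log_sd, size=n_sites)
    return [
        MonitoringSample(f"site{i + 1:04d}", float(c)) for i, c in enumerate(eec)
    ]
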