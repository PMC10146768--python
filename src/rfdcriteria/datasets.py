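"""Descriptor/response table I/O and modelling-dataset assembly.

Tables are plain CSV (UTF-8, header row, first column = chemical
identifier).  Responses are oral reference doses (RfD, mg/kg/d); the
regression response is ``-log10(RfD)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ChemicalRecord",
    "DescriptorTable",
    "ModelingDataset",
    "DEFAULT_TRAIN_FRACTION",
    "load_descriptor_table",
    "save_descriptor_table",
    "load_response_table",
    "save_response_table",
    "build_dataset",
]

#: Default train fraction; on a 109-row table this yields an 80/29 split.
DEFAULT_TRAIN_FRACTION = 80.0 / 109.0


@dataclass(frozen=True)
class ChemicalRecord:
    """A chemical identifier with its oral reference dose.

    Parameters
    ----------
    chem_id:
        Opaque text identifier (CAS number or name).
    rfd:
        Oral reference dose in mg/kg/d; must be a positive finite real.
    """

    chem_id: str
    rfd: float

    def __post_init__(self) -> None:
        if not isinstance(self.chem_id, str) or not self.chem_id:
            raise ValueError("chem_id must be a non-empty string")
        if not (math.isfinite(self.rfd) and self.rfd > 0):
            raise ValueError(
                f"rfd for {self.chem_id!r} must be a positive finite real, got {self.rfd!r}"
            )

    @property
    def neg_log_rfd(self) -> float:
        """Regression response ``-log10(rfd)``."""
        return -math.log10(self.rfd)


@dataclass
class DescriptorTable:
    """A chemicals x descriptors matrix with named rows and columns.

    Invariants: unique identifiers, unique descriptor names, finite
    values, shape consistent with both name lists.
    """

    chem_ids: list[str]
    descriptor_names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.chem_ids = [str(c) for c in self.chem_ids]
        self.descriptor_names = [str(d) for d in self.descriptor_names]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        n, p = self.values.shape
        if n != len(self.chem_ids) or p != len(self.descriptor_names):
            raise ValueError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.chem_ids)} ids / {len(self.descriptor_names)} descriptors"
            )
        dup = _first_duplicate(self.chem_ids)
        if dup is not None:
            raise ValueError(f"duplicate chemical identifier: {dup!r}")
        dup = _first_duplicate(self.descriptor_names)
        if dup is not None:
            raise ValueError(f"duplicate descriptor name: {dup!r}")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite value at chemical {self.chem_ids[i]!r}, "
                f"descriptor {self.descriptor_names[j]!r}"
            )

    # -- shape ---------------------------------------------------------
    @property
    def n_chemicals(self) -> int:
        return self.values.shape[0]

    @property
    def n_descriptors(self) -> int:
        return self.values.shape[1]

    # -- access --------------------------------------------------------
    def column(self, name: str) -> np.ndarray:
        try:
            j = self.descriptor_names.index(name)
        except ValueError:
            raise KeyError(f"unknown descriptor {name!r}") from None
        return self.values[:, j]

    def select(self, names: Sequence[str]) -> "DescriptorTable":
        """Column subset, in the order of *names*."""
        idx = [self.descriptor_names.index(n) for n in names]
        return DescriptorTable(list(self.chem_ids), list(names), self.values[:, idx])

    def drop(self, names: Iterable[str]) -> "DescriptorTable":
        dropset = set(names)
        keep = [n for n in self.descriptor_names if n not in dropset]
        return self.select(keep)

    def rows(self, ids: Sequence[str]) -> "DescriptorTable":
        """Row subset, in the order of *ids*."""
        pos = {c: i for i, c in enumerate(self.chem_ids)}
        idx = [pos[c] for c in ids]
        return DescriptorTable(list(ids), list(self.descriptor_names), self.values[idx, :])

    def matrix(self, names: Sequence[str] | None = None) -> np.ndarray:
        if names is None:
            return self.values
        return self.select(list(names)).values

    # -- pandas bridge -------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.chem_ids, name="chem_id"),
            columns=self.descriptor_names,
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "DescriptorTable":
        return cls(
            [str(i) for i in frame.index],
            [str(c) for c in frame.columns],
            frame.to_numpy(dtype=float),
        )


def _first_duplicate(items: Sequence[str]) -> str | None:
    seen: set[str] = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return None


# ---------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------

def load_descriptor_table(path: str | Path) -> DescriptorTable:
    """Read a descriptor CSV: column 1 = identifier, the rest numeric.

    Raises ``ValueError`` naming the offending identifier or cell for
    duplicate ids, non-numeric/missing cells, or an empty table.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""])
    if raw.shape[0] == 0 or raw.shape[1] < 2:
        raise ValueError(f"empty or id-only descriptor table: {path}")
    ids = raw.iloc[:, 0].astype(str)
    dup = _first_duplicate(list(ids))
    if dup is not None:
        raise ValueError(f"duplicate chemical identifier {dup!r} in {path}")
    names = list(raw.columns[1:])
    numeric = np.empty((raw.shape[0], len(names)), dtype=float)
    for j, name in enumerate(names):
        for i, cell in enumerate(raw[name]):
            # python float() parses exactly (pandas' fast parser may be
            # one ulp off, breaking bit-identical round trips)
            try:
                value = float(cell)
            except (TypeError, ValueError):
                value = float("nan")
            if not math.isfinite(value):
                raise ValueError(
                    f"non-numeric or missing cell at row {ids.iloc[i]!r}, "
                    f"column {name!r}: {cell!r}"
                )
            numeric[i, j] = value
    return DescriptorTable(list(ids), names, numeric)


def save_descriptor_table(table: DescriptorTable, path: str | Path) -> None:
    # default float formatting is repr(), which round-trips exactly
    table.to_frame().to_csv(path)


def load_response_table(path: str | Path) -> list[ChemicalRecord]:
    """Read a response CSV with columns (identifier, rfd)."""
    raw = pd.read_csv(path, float_precision="round_trip")
    if raw.shape[1] < 2:
        raise ValueError(f"response table needs (id, rfd) columns: {path}")
    out = []
    for _, row in raw.iterrows():
        chem_id = str(row.iloc[0])
        try:
            rfd = float(row.iloc[1])
        except (TypeError, ValueError):
            raise ValueError(f"non-numeric rfd for chemical {chem_id!r}") from None
        out.append(ChemicalRecord(chem_id, rfd))
    if not out:
        raise ValueError(f"empty response table: {path}")
    return out


def save_response_table(records: Sequence[ChemicalRecord], path: str | Path) -> None:
    pd.DataFrame(
        {"chem_id": [r.chem_id for r in records], "rfd": [r.rfd for r in records]}
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------

@dataclass
class ModelingDataset:
    """Descriptor table joined to -log10(RfD) with a train/test split."""

    table: DescriptorTable
    response: np.ndarray  # aligned to table.chem_ids
    train_ids: list[str]
    test_ids: list[str]
    split_seed: int
    train_fraction: float = field(default=DEFAULT_TRAIN_FRACTION)

    def __post_init__(self) -> None:
        self.response = np.asarray(self.response, dtype=float)
        if self.response.shape != (self.table.n_chemicals,):
            raise ValueError("response not aligned to descriptor table")
        tr, te, al = set(self.train_ids), set(self.test_ids), set(self.table.chem_ids)
        if tr & te:
            raise ValueError("train and test sets overlap")
        if tr | te != al:
            raise ValueError("train/test sets do not partition the chemicals")

    def _index(self, ids: Sequence[str]) -> np.ndarray:
        pos = {c: i for i, c in enumerate(self.table.chem_ids)}
        return np.array([pos[c] for c in ids], dtype=int)

    @property
    def train_index(self) -> np.ndarray:
        return self._index(self.train_ids)

    @property
    def test_index(self) -> np.ndarray:
        return self._index(self.test_ids)

    @property
    def train_table(self) -> DescriptorTable:
        return self.table.rows(self.train_ids)

    @property
    def test_table(self) -> DescriptorTable:
        return self.table.rows(self.test_ids)

    @property
    def y_train(self) -> np.ndarray:
        return self.response[self.train_index]

    @property
    def y_test(self) -> np.ndarray:
        return self.response[self.test_index]

    def with_table(self, table: DescriptorTable) -> "ModelingDataset":
        """Same rows/split on a different (e.g. screened) column set."""
        if table.chem_ids != self.table.chem_ids:
            raise ValueError("replacement table must keep the same chemicals")
        return ModelingDataset(
            table, self.response, list(self.train_ids), list(self.test_ids),
            self.split_seed, self.train_fraction,
        )


def build_dataset(
    table: DescriptorTable,
    responses: Sequence[ChemicalRecord],
    train_fraction: float = DEFAULT_TRAIN_FRACTION,
    seed: int = 0,
) -> ModelingDataset:
    """Join descriptors with responses and split train/test at random.

    The split is a simple random partition, deterministic for a fixed
    *seed*; the train size is ``round(train_fraction * n)`` clamped so
    both partitions are non-empty.
    """
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must lie in (0, 1)")
    by_id: dict[str, ChemicalRecord] = {}
    for rec in responses:
        if rec.chem_id in by_id:
            raise ValueError(f"duplicate response for chemical {rec.chem_id!r}")
        by_id[rec.chem_id] = rec
    missing = [c for c in table.chem_ids if c not in by_id]
    if missing:
        raise ValueError(f"no response for chemical {missing[0]!r}")
    y = np.array([by_id[c].neg_log_rfd for c in table.chem_ids], dtype=float)

    n = table.n_chemicals
    n_train = int(round(train_fraction * n))
    n_train = min(max(n_train, 1), n - 1) if n > 1 else n
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train_pos = set(perm[:n_train].tolist())
    train_ids = [c for i, c in enumerate(table.chem_ids) if i in train_pos]
    test_ids = [c for i, c in enumerate(table.chem_ids) if i not in train_pos]
    return ModelingDataset(table, y, train_ids, test_ids, seed, train_fraction)
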