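"""Modeling-table I/O, descriptor filtering, design assembly and splitting.

A modeling table is a CSV with one row per observation:

    compound_id, T_K, pH, Seq_ppm, log10_CMC, <descriptor columns...>

``T_K`` is temperature in kelvin, ``Seq_ppm`` the NaCl-equivalent salinity
of the brine in ppm, and ``log10_CMC`` the response.  Every remaining column
is treated as a molecular descriptor of the surfactant anion (the table
stores whatever the upstream descriptor software exported; no ionisation
checks are performed here).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

PHYSICAL_VARIABLES = ("T", "pH", "S_eq")

REQUIRED_COLUMNS = ("compound_id", "T_K", "pH", "Seq_ppm", "log10_CMC")

# CSV header name -> design-matrix variable name
_PHYS_MAP = {"T": "T_K", "pH": "pH", "S_eq": "Seq_ppm"}


class FormatError(ValueError):
    """Input table violates the expected CSV layout."""


@dataclass(frozen=True)
class SampleRecord:
    compound_id: str
    T: float          # kelvin
    pH: float
    S_eq: float       # ppm NaCl-equivalent
    log_cmc: float | None = None

    def __post_init__(self):
        if not self.T > 0:
            raise ValueError(f"T must be positive, got {self.T}")
        if self.S_eq < 0:
            raise ValueError(f"S_eq must be nonnegative, got {self.S_eq}")
        if not self.pH > 0:
            raise ValueError(f"pH must be positive, got {self.pH}")


@dataclass
class DescriptorTable:
    """compound x descriptor numeric matrix with row/column names."""

    compound_ids: list[str]
    descriptor_names: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.compound_ids)) != len(self.compound_ids):
            raise ValueError("duplicate compound_id in descriptor table")
        if len(set(self.descriptor_names)) != len(self.descriptor_names):
            raise ValueError("duplicate descriptor name")
        if self.values.shape != (len(self.compound_ids), len(self.descriptor_names)):
            raise ValueError("descriptor matrix shape mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("descriptor matrix contains non-finite values")

    def column(self, name: str) -> np.ndarray:
        try:
            j = self.descriptor_names.index(name)
        except ValueError:
            raise KeyError(f"unknown descriptor {name!r}") from None
        return self.values[:, j]


@dataclass
class ModelingDataset:
    records: list[SampleRecord]
    descriptors: DescriptorTable

    def __post_init__(self):
        if len(self.records) < 1:
            raise ValueError("dataset needs at least one record")
        known = set(self.descriptors.compound_ids)
        for r in self.records:
            if r.compound_id not in known:
                raise ValueError(f"record {r.compound_id!r} has no descriptor row")

    @property
    def n(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class SplitResult:
    train_indices: tuple[int, ...]
    test_indices: tuple[int, ...]
    seed: int

    def to_csv(self) -> str:
        lines = ["index,role"]
        roles = {i: "train" for i in self.train_indices}
        roles.update({i: "test" for i in self.test_indices})
        lines += [f"{i},{roles[i]}" for i in sorted(roles)]
        return "\n".join(lines) + "\n"


def read_dataset(path) -> ModelingDataset:
    """Read a modeling table CSV into a :class:`ModelingDataset`.

    Raises :class:`FormatError` naming the first missing required column,
    and a parse error locating any non-numeric cell.
    """
    df = pd.read_csv(path, dtype={"compound_id": str})
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r}")
    desc_cols = [c for c in df.columns if c not in REQUIRED_COLUMNS]
    num = df[[c for c in df.columns if c != "compound_id"]].apply(
        pd.to_numeric, errors="coerce"
    )
    bad = num.isna() & df[num.columns].notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"non-numeric value in row {int(r)}, column {bad.columns[c]!r}"
        )
    records = [
        SampleRecord(
            compound_id=str(row.compound_id),
            T=float(num.at[i, "T_K"]),
            pH=float(num.at[i, "pH"]),
            S_eq=float(num.at[i, "Seq_ppm"]),
            log_cmc=float(num.at[i, "log10_CMC"]),
        )
        for i, row in df.iterrows()
    ]
    table = DescriptorTable(
        compound_ids=[r.compound_id for r in records],
        descriptor_names=list(desc_cols),
        values=num[desc_cols].to_numpy(dtype=float) if desc_cols
        else np.empty((len(records), 0)),
    )
    return ModelingDataset(records=records, descriptors=table)


def write_dataset(dataset: ModelingDataset, path) -> None:
    """Write a dataset back to the modeling-table CSV layout (full precision)."""
    desc = dataset.descriptors
    rows = {}
    rows["compound_id"] = [r.compound_id for r in dataset.records]
    rows["T_K"] = [r.T for r in dataset.records]
    rows["pH"] = [r.pH for r in dataset.records]
    rows["Seq_ppm"] = [r.S_eq for r in dataset.records]
    rows["log10_CMC"] = [r.log_cmc for r in dataset.records]
    df = pd.DataFrame(rows)
    order = {cid: i for i, cid in enumerate(desc.compound_ids)}
    idx = [order[r.compound_id] for r in dataset.records]
    for j, name in enumerate(desc.descriptor_names):
        df[name] = desc.values[idx, j]
    df.to_csv(path, index=False, float_format="%.17g")


def join_descriptors(dataset: ModelingDataset, path) -> ModelingDataset:
    """Join an extra descriptor-only CSV (compound_id + descriptor columns)."""
    extra = pd.read_csv(path, dtype={"compound_id": str})
    if "compound_id" not in extra.columns:
        raise FormatError("missing required column 'compound_id'")
    extra = extra.set_index("compound_id")
    desc = dataset.descriptors
    missing = [c for c in desc.compound_ids if c not in extra.index]
    if missing:
        raise FormatError(f"descriptor CSV lacks compounds: {missing[:5]}")
    new_names = [c for c in extra.columns if c not in desc.descriptor_names]
    values = np.hstack(
        [desc.values, extra.loc[desc.compound_ids, new_names].to_numpy(dtype=float)]
    )
    table = DescriptorTable(desc.compound_ids, desc.descriptor_names + new_names, values)
    return ModelingDataset(records=dataset.records, descriptors=table)


def drop_uninformative_descriptors(
    table: DescriptorTable, tol: float = 0.0
) -> tuple[DescriptorTable, list[str]]:
    """Remove descriptor columns whose sample standard deviation is <= *tol*.

    Columns that take the same value for every compound carry no
    information for regression; the default ``tol=0`` removes exactly
    those, a positive tolerance (on the standard-deviation scale, i.e. in
    the descriptor's own units) also catches numerically near-constant
    exports.  Column order is otherwise preserved.  Returns the filtered
    table and the list of removed names.
    """
    if tol < 0:
        raise ValueError("tol must be nonnegative")
    if not table.descriptor_names:
        raise ValueError("empty descriptor table")
    sd = table.values.std(axis=0, ddof=1) if table.values.shape[0] > 1 else \
        np.zeros(table.values.shape[1])
    keep = [j for j, v in enumerate(sd) if v > tol]
    removed = [table.descriptor_names[j] for j in range(len(sd)) if j not in set(keep)]
    if not keep:
        raise ValueError("all descriptor columns removed; degenerate pool")
    out = DescriptorTable(
        compound_ids=list(table.compound_ids),
        descriptor_names=[table.descriptor_names[j] for j in keep],
        values=table.values[:, keep],
    )
    return out, removed


def train_test_split(dataset: ModelingDataset, test_fraction: float, seed: int) -> SplitResult:
    """Uniform random train/test partition; |test| = floor(test_fraction * n).

    The floor rule matches a 488-observation table splitting into 440
    training and 48 test records at ``test_fraction=0.1``.
    """
    n = dataset.n
    if n < 2:
        raise ValueError("need at least 2 records to split")
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    n_test = int(np.floor(test_fraction * n))
    if n_test < 1 or n_test >= n:
        raise ValueError(
            f"test_fraction {test_fraction} gives empty train or test set for n={n}"
        )
    rng = np.random.default_rng(seed)
    test = np.sort(rng.choice(n, size=n_test, replace=False))
    mask = np.ones(n, dtype=bool)
    mask[test] = False
    return SplitResult(
        train_indices=tuple(int(i) for i in np.flatnonzero(mask)),
        test_indices=tuple(int(i) for i in test),
        seed=int(seed),
    )


def assemble_design(
    dataset: ModelingDataset,
    variable_names: list[str],
    indices=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Build (X, y) with columns in the requested order.

    Variable names are drawn from the physical variables ``T``, ``pH``,
    ``S_eq`` and the descriptor names; *indices* optionally restricts the
    rows (e.g. to a train split).  y is log10(CMC).
    """
    recs = dataset.records if indices is None else [dataset.records[i] for i in indices]
    desc = dataset.descriptors
    row_of = {cid: i for i, cid in enumerate(desc.compound_ids)}
    cols = []
    for name in variable_names:
        if name in PHYSICAL_VARIABLES:
            cols.append([getattr(r, {"T": "T", "pH": "pH", "S_eq": "S_eq"}[name]) for r in recs])
        elif name in desc.descriptor_names:
            j = desc.descriptor_names.index(name)
            cols.append([desc.values[row_of[r.compound_id], j] for r in recs])
        else:
            raise KeyError(f"unknown variable name {name!r}")
    for r in recs:
        if r.log_cmc is None:
            raise ValueError(f"record {r.compound_id!r} has no response")
    X = np.column_stack(cols) if cols else np.empty((len(recs), 0))
    y = np.array([r.log_cmc for r in recs], dtype=float)
    return X, y
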