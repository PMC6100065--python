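"""Compound records, datasets and descriptor matrices with CSV I/O.

Units are fixed: critical temperature in kelvin, critical pressure in
megapascal, the acentric factor dimensionless.  The compound-table header
carries the units (``tc_K``, ``pc_MPa``); any other unit annotation is
rejected rather than silently converted.

Missing experimental values are represented as ``None`` on records and as
NaN in descriptor matrices — never as sentinel numbers — because the
descriptor pre-filter needs true missingness.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

TRAIN = "train"
VALIDATION = "validation"
UNASSIGNED = "unassigned"

#: canonical compound-table header; the ``tc_``/``pc_`` suffixes are the units
COMPOUND_COLUMNS = [
    "id",
    "name",
    "smiles",
    "tc_K",
    "pc_MPa",
    "omega",
    "rel_err_tc",
    "rel_err_pc",
]

_PROPERTY_COLUMN = {"tc": "tc_K", "pc": "pc_MPa", "omega": "omega"}


@dataclass(frozen=True)
class CompoundRecord:
    """One molecule: identifiers, structure and experimental properties.

    ``tc`` is the critical temperature in K, ``pc`` the critical pressure in
    MPa and ``omega`` the (dimensionless) acentric factor.  ``rel_err_tc`` /
    ``rel_err_pc`` are the relative errors of the experimental values as
    fractions (0.01 means 1%).  Absent values are ``None``.
    """

    id: str
    name: str = ""
    smiles: str = ""
    tc: float | None = None
    pc: float | None = None
    omega: float | None = None
    rel_err_tc: float | None = None
    rel_err_pc: float | None = None

    def __post_init__(self) -> None:
        if self.tc is not None and not self.tc > 0:
            raise ValueError(f"record {self.id!r}: tc must be positive, got {self.tc}")
        if self.pc is not None and not self.pc > 0:
            raise ValueError(f"record {self.id!r}: pc must be positive, got {self.pc}")
        for attr in ("rel_err_tc", "rel_err_pc"):
            v = getattr(self, attr)
            if v is not None and v < 0:
                raise ValueError(f"record {self.id!r}: {attr} must be >= 0, got {v}")

    def property_value(self, target: str) -> float | None:
        """Return tc, pc or omega by the short target name."""
        if target not in _PROPERTY_COLUMN:
            raise KeyError(f"unknown target {target!r}; expected one of {sorted(_PROPERTY_COLUMN)}")
        return getattr(self, target)


@dataclass
class Dataset:
    """Ordered collection of compound records with train/validation roles.

    Record order is stable (file order on read) and is the reference order
    for every downstream tie-break.  Roles partition the records.
    """

    records: list[CompoundRecord]
    roles: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.roles:
            self.roles = [UNASSIGNED] * len(self.records)
        if len(self.roles) != len(self.records):
            raise ValueError("roles and records must have equal length")
        bad = {r for r in self.roles if r not in (TRAIN, VALIDATION, UNASSIGNED)}
        if bad:
            raise ValueError(f"invalid role labels: {sorted(bad)}")
        ids = [r.id for r in self.records]
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        if dupes:
            raise ValueError(f"duplicate compound ids: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[CompoundRecord]:
        return iter(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def subset(self, role: str) -> "Dataset":
        """Records carrying the given role, in original order."""
        recs = [r for r, lab in zip(self.records, self.roles) if lab == role]
        return Dataset(records=recs, roles=[role] * len(recs))

    def property_vector(self, target: str) -> pd.Series:
        """Series of the target property indexed by compound id (NaN when absent)."""
        vals = [r.property_value(target) for r in self.records]
        return pd.Series(
            [np.nan if v is None else float(v) for v in vals], index=self.ids, name=target
        )


def _parse_cell(raw: str, row: int, column: str):
    text = raw.strip()
    if text == "":
        return None
    try:
        return float(text)
    except ValueError:
        raise ValueError(
            f"unparsable numeric cell at row {row}, column {column!r}: {raw!r}"
        ) from None


def read_compound_table(path, **csv_options) -> Dataset:
    """Read a compound CSV into a :class:`Dataset`.

    Expected header: ``id,name,smiles,tc_K,pc_MPa,omega,rel_err_tc,rel_err_pc``
    (``name`` and property columns optional, an optional trailing ``role``
    column restores a saved split).  Empty property cells become absent
    values, never zeros.  Duplicate ids and mis-annotated units are errors.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False, **csv_options)
    cols = list(frame.columns)
    if "id" not in cols or "smiles" not in cols:
        raise ValueError(f"compound table must have 'id' and 'smiles' columns, got {cols}")
    for col in cols:
        if col.startswith("tc_") and col != "tc_K":
            raise ValueError(f"unsupported unit annotation {col!r}: temperatures must be tc_K")
        if col.startswith("pc_") and col != "pc_MPa":
            raise ValueError(f"unsupported unit annotation {col!r}: pressures must be pc_MPa")
    ids = [s.strip() for s in frame["id"]]
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        raise ValueError(f"duplicate compound ids: {dupes}")

    def cell(row_idx: int, col: str):
        if col not in cols:
            return None
        return _parse_cell(frame.iloc[row_idx][col], row_idx, col)

    records, roles = [], []
    for i in range(len(frame)):
        records.append(
            CompoundRecord(
                id=ids[i],
                name=frame.iloc[i]["name"].strip() if "name" in cols else "",
                smiles=frame.iloc[i]["smiles"].strip(),
                tc=cell(i, "tc_K"),
                pc=cell(i, "pc_MPa"),
                omega=cell(i, "omega"),
                rel_err_tc=cell(i, "rel_err_tc"),
                rel_err_pc=cell(i, "rel_err_pc"),
            )
        )
        roles.append(frame.iloc[i]["role"].strip() if "role" in cols else UNASSIGNED)
    return Dataset(records=records, roles=roles)


def write_compound_table(ds: Dataset, path) -> None:
    """Write a dataset back to CSV; roles are kept so a split round-trips."""
    rows = []
    for rec, role in zip(ds.records, ds.roles):
        rows.append(
            {
                "id": rec.id,
                "name": rec.name,
                "smiles": rec.smiles,
                "tc_K": rec.tc,
                "pc_MPa": rec.pc,
                "omega": rec.omega,
                "rel_err_tc": rec.rel_err_tc,
                "rel_err_pc": rec.rel_err_pc,
                "role": role,
            }
        )
    pd.DataFrame(rows, columns=COMPOUND_COLUMNS + ["role"]).to_csv(path, index=False)


def filter_by_uncertainty(
    ds: Dataset,
    max_rel_err_tc: float = 0.01,
    max_rel_err_pc: float = 0.03,
    keep_missing: bool = False,
) -> Dataset:
    """Keep compounds whose experimental uncertainty is below the thresholds.

    A record is retained iff ``rel_err_tc < max_rel_err_tc`` and
    ``rel_err_pc < max_rel_err_pc``.  The defaults (1% on Tc, 3% on Pc —
    Pc measurements tolerate more error so enough structures survive) match
    the usual compilation practice for critical-property databases.  Records
    lacking an error field are kept only when ``keep_missing`` is set.
    """
    for name, thr in (("max_rel_err_tc", max_rel_err_tc), ("max_rel_err_pc", max_rel_err_pc)):
        if not 0 < thr <= 1:
            raise ValueError(f"{name} must be in (0, 1], got {thr}")

    def keep(rec: CompoundRecord) -> bool:
        if rec.rel_err_tc is None or rec.rel_err_pc is None:
            return keep_missing
        return rec.rel_err_tc < max_rel_err_tc and rec.rel_err_pc < max_rel_err_pc

    pairs = [(r, lab) for r, lab in zip(ds.records, ds.roles) if keep(r)]
    return Dataset(records=[p[0] for p in pairs], roles=[p[1] for p in pairs])


def split_train_validation(
    ds: Dataset, n_train: int, seed: int, stratify_by: Sequence[str] | None = None
) -> Dataset:
    """Randomly partition the dataset into ``n_train`` training records.

    Seeded uniform sampling without replacement; the same seed always yields
    the same partition.  ``stratify_by`` optionally gives one group label per
    record, in which case the training quota is allocated proportionally to
    group sizes (largest-remainder rounding) and sampled within each group.
    """
    n = len(ds)
    if not 0 < n_train < n:
        raise ValueError(f"n_train must be in (0, {n}), got {n_train}")
    rng = np.random.default_rng(seed)
    if stratify_by is None:
        train_idx = set(rng.choice(n, size=n_train, replace=False).tolist())
    else:
        if len(stratify_by) != n:
            raise ValueError("stratify_by must give one label per record")
        groups: dict[str, list[int]] = {}
        for i, g in enumerate(stratify_by):
            groups.setdefault(g, []).append(i)
        labels = sorted(groups)
        quota = {g: n_train * len(groups[g]) / n for g in labels}
        base = {g: int(np.floor(quota[g])) for g in labels}
        remainder = n_train - sum(base.values())
        for g in sorted(labels, key=lambda g: quota[g] - base[g], reverse=True)[:remainder]:
            base[g] += 1
        train_idx = set()
        for g in labels:
            members = groups[g]
            take = min(base[g], len(members))
            train_idx.update(rng.choice(members, size=take, replace=False).tolist())
    roles = [TRAIN if i in train_idx else VALIDATION for i in range(n)]
    return Dataset(records=list(ds.records), roles=roles)


ENGINE_COMPUTED = "engine-computed"
IMPORTED = "imported"


@dataclass
class DescriptorMatrix:
    """Compounds x descriptors table with explicit missing values.

    Backed by a float DataFrame (index = compound ids, columns = descriptor
    names, NaN = missing) plus a per-descriptor provenance tag saying whether
    the column was computed by the built-in engine or imported.
    """

    frame: pd.DataFrame
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.frame.columns.duplicated().any():
            dupes = self.frame.columns[self.frame.columns.duplicated()].tolist()
            raise ValueError(f"duplicate descriptor names: {dupes}")
        if self.frame.index.duplicated().any():
            dupes = self.frame.index[self.frame.index.duplicated()].tolist()
            raise ValueError(f"duplicate compound ids: {dupes}")
        self.frame = self.frame.astype(float)
        for name in self.frame.columns:
            self.provenance.setdefault(str(name), IMPORTED)

    @property
    def compound_ids(self) -> list[str]:
        return [str(i) for i in self.frame.index]

    @property
    def descriptor_names(self) -> list[str]:
        return [str(c) for c in self.frame.columns]

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy()

    @property
    def missing_mask(self) -> np.ndarray:
        return self.frame.isna().to_numpy()

    def select(self, names: Iterable[str]) -> "DescriptorMatrix":
        names = list(names)
        return DescriptorMatrix(
            frame=self.frame[names].copy(),
            provenance={n: self.provenance[n] for n in names},
        )

    def rows(self, ids: Iterable[str]) -> "DescriptorMatrix":
        ids = list(ids)
        return DescriptorMatrix(frame=self.frame.loc[ids].copy(), provenance=dict(self.provenance))


def read_descriptor_matrix(path) -> DescriptorMatrix:
    """Read a descriptor CSV (first column ``id``; empty cells = missing)."""
    frame = pd.read_csv(path, index_col="id")
    frame.index = frame.index.astype(str)
    return DescriptorMatrix(frame=frame)


def write_descriptor_matrix(m: DescriptorMatrix, path) -> None:
    m.frame.to_csv(path, index_label="id")


def write_split(ds: Dataset, path) -> None:
    """Save the role assignment as JSON keyed by compound id."""
    with open(path, "w") as fh:
        json.dump({rec.id: role for rec, role in zip(ds.records, ds.roles)}, fh, indent=1)


def read_split(ds: Dataset, path) -> Dataset:
    """Apply a saved role assignment to a dataset with matching ids."""
    with open(path) as fh:
        mapping = json.load(fh)
    missing = [r.id for r in ds.records if r.id not in mapping]
    if missing:
        raise ValueError(f"split file lacks ids: {missing}")
    return Dataset(records=list(ds.records), roles=[mapping[r.id] for r in ds.records])
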