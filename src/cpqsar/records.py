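"""Core record types and structure/table I/O.

The pipeline moves between two representations of a dataset: a list of
:class:`MoleculeRecord` (chemical identity, structure, class label, alert
annotations) and a :class:`DescriptorMatrix` (an n x p numeric table whose
rows align with the records by id).  Class labels follow the rodent
carcinogenicity convention used throughout the package: 1 = non-carcinogen
(NP), 2 = carcinogen (P).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.error")

VALID_CLASS_LABELS = (1, 2)


class DatasetError(ValueError):
    """Malformed dataset content (bad labels, duplicate ids, ...)."""


class EmptyDatasetError(DatasetError):
    """A reader produced zero valid records."""


class StructureParseError(DatasetError):
    """A structure failed to parse in strict mode."""


@dataclass
class MoleculeRecord:
    """One chemical: identifiers, structure and (optional) annotations."""

    id: str
    name: str = ""
    casrn: str | None = None
    smiles: str | None = None
    class_label: int | None = None
    alerts: set[str] | None = None

    def __post_init__(self) -> None:
        if self.class_label is not None and self.class_label not in VALID_CLASS_LABELS:
            raise DatasetError(
                f"class_label must be 1 (non-carcinogen) or 2 (carcinogen), "
                f"got {self.class_label!r} for record {self.id!r}"
            )

    def mol(self) -> Chem.Mol:
        """Parse the stored SMILES into an RDKit molecule."""
        if self.smiles is None:
            raise DatasetError(f"record {self.id!r} has no structure")
        m = Chem.MolFromSmiles(self.smiles)
        if m is None:
            raise StructureParseError(f"record {self.id!r}: unparseable SMILES {self.smiles!r}")
        return m


@dataclass
class NormalizationParams:
    """Per-column min/max fitted on a training matrix (see :mod:`cpqsar.scaling`)."""

    mins: np.ndarray
    maxs: np.ndarray
    column_names: list[str]
    constant: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.mins = np.asarray(self.mins, dtype=float)
        self.maxs = np.asarray(self.maxs, dtype=float)
        if np.any(self.maxs < self.mins):
            raise DatasetError("normalization params: max < min for some column")
        if self.constant is None:
            self.constant = self.maxs == self.mins
        self.constant = np.asarray(self.constant, dtype=bool)

    @property
    def n_columns(self) -> int:
        return len(self.mins)


@dataclass
class DescriptorMatrix:
    """n x p numeric table with row ids and column names.

    ``values`` never contains missing entries; construction fails otherwise.
    """

    values: np.ndarray
    row_ids: list[str]
    column_names: list[str]
    norm: NormalizationParams | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DatasetError("descriptor values must be a 2-D matrix")
        n, p = self.values.shape
        if p < 1:
            raise DatasetError("descriptor matrix needs at least one column")
        if len(self.row_ids) != n or len(self.column_names) != p:
            raise DatasetError("row/column labels do not match matrix shape")
        if len(set(self.row_ids)) != n:
            raise DatasetError("duplicate row ids in descriptor matrix")
        if not np.all(np.isfinite(self.values)):
            raise DatasetError("descriptor matrix contains missing/non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.column_names)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, norm: NormalizationParams | None = None) -> "DescriptorMatrix":
        return cls(
            values=df.to_numpy(dtype=float),
            row_ids=[str(i) for i in df.index],
            column_names=[str(c) for c in df.columns],
            norm=norm,
        )


def _format_from_path(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in {".smi", ".smiles", ".txt"}:
        return "smiles"
    if suffix in {".sdf", ".sd", ".mol"}:
        return "sdf"
    raise DatasetError(f"cannot infer structure format from {path.name!r}; pass format=")


def read_structures(
    path: str | Path,
    format: str | None = None,
    strict: bool = False,
) -> list[MoleculeRecord]:
    """Read molecules from a SMILES file (one per line, optional name) or SDF.

    Invalid entries are logged with their line/record index and skipped;
    ``strict=True`` raises on the first failure instead.  Ids come from the
    name field / SDF title when present, otherwise ``mol_<index>``.
    """
    path = Path(path)
    if not path.is_file():
        raise OSError(f"structure file not found: {path}")
    fmt = format or _format_from_path(path)
    records: list[MoleculeRecord] = []
    failures: list[tuple[int, str]] = []

    if fmt == "smiles":
        for lineno, line in enumerate(path.read_text().splitlines()):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            smiles = parts[0]
            name = parts[1].strip() if len(parts) > 1 else ""
            mol = Chem.MolFromSmiles(smiles)
            if mol is None:
                failures.append((lineno + 1, smiles))
                if strict:
                    raise StructureParseError(f"line {lineno + 1}: bad SMILES {smiles!r}")
                continue
            rid = name if name else f"mol_{len(records)}"
            records.append(MoleculeRecord(id=rid, name=name, smiles=smiles))
    elif fmt == "sdf":
        supplier = Chem.SDMolSupplier(str(path), sanitize=True)
        for idx, mol in enumerate(supplier):
            if mol is None:
                failures.append((idx, "<unparseable SDF record>"))
                if strict:
                    raise StructureParseError(f"SDF record {idx} failed to parse")
                continue
            title = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
            rid = title if title else f"mol_{len(records)}"
            records.append(MoleculeRecord(id=rid, name=title, smiles=Chem.MolToSmiles(mol)))
    else:
        raise DatasetError(f"unknown structure format {fmt!r}")

    for where, what in failures:
        logger.warning("skipped unparseable entry at %s: %s", where, what)
    if not records:
        raise EmptyDatasetError(f"no valid structures in {path}")
    _check_unique_ids(records)
    return records


def _check_unique_ids(records: Sequence[MoleculeRecord]) -> None:
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise DatasetError(f"duplicate record id {rec.id!r}")
        seen.add(rec.id)


def write_structures(records: Iterable[MoleculeRecord], path: str | Path) -> None:
    """Write records as canonical SMILES, one ``smiles id`` pair per line."""
    lines = []
    for rec in records:
        canonical = Chem.MolToSmiles(rec.mol())
        lines.append(f"{canonical} {rec.id}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_descriptor_csv(path: str | Path) -> DescriptorMatrix:
    """Read a descriptor table: header row, first column = molecule id."""
    path = Path(path)
    df = pd.read_csv(path, index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise DatasetError(f"duplicate ids in {path.name}: {dups}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any():
            bad = df.index[coerced.isna()][0]
            raise DatasetError(f"non-numeric cell in {path.name}: row {bad!r}, column {col!r}")
        df[col] = coerced
    return DescriptorMatrix.from_frame(df)


def write_descriptor_csv(matrix: DescriptorMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, index_label="id")
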