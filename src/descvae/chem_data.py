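"""Molecular dataset loading, curation and descriptor computation.

The curation pipeline mirrors common QSAR practice: parse and
canonicalize SMILES, drop unparseable rows, deduplicate structures by
InChIKey (conflicting labels remove the whole group), exclude salts and
mixtures (any multi-component SMILES), and binarize blood-brain-barrier
partition values at logBB = -1.  Descriptors come from RDKit's 2D
descriptor registry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors, inchi

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "TaskType",
    "MoleculeRecord",
    "MoleculeDataset",
    "DescriptorTable",
    "load_dataset",
    "make_record",
    "deduplicate",
    "remove_salts_and_mixtures",
    "binarize_logbb",
    "compute_descriptors",
    "available_descriptors",
    "CurationReport",
]


class TaskType(str, Enum):
    REGRESSION = "regression"
    CLASSIFICATION = "classification"


@dataclass(frozen=True)
class MoleculeRecord:
    """One curated molecule.

    ``structure_key`` is the InChIKey — a hashed, canonical structure
    identifier, so two SMILES spellings of the same structure collide.
    """

    raw_smiles: str
    canonical_smiles: str
    structure_key: str
    label: float | None = None


@dataclass
class MoleculeDataset:
    records: list[MoleculeRecord]
    task_type: TaskType
    name: str = "dataset"

    def __len__(self) -> int:
        return len(self.records)

    @property
    def smiles(self) -> list[str]:
        return [r.canonical_smiles for r in self.records]

    @property
    def labels(self) -> np.ndarray:
        return np.array([np.nan if r.label is None else r.label for r in self.records])


@dataclass
class CurationReport:
    """Counts of rows removed per curation rule."""

    n_input: int = 0
    n_unparseable: int = 0
    n_duplicate: int = 0
    n_conflicting: int = 0
    n_salt_or_mixture: int = 0
    n_missing_descriptor: int = 0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2))


@dataclass
class DescriptorTable:
    """Molecules x named descriptors, with per-column provenance.

    ``source`` maps column name -> one of {"computed", "noisy-synthetic",
    "planted"}.  ``index`` holds the structure keys of the rows so the
    table stays aligned with its originating dataset after row drops.
    """

    data: pd.DataFrame
    source: dict[str, str] = field(default_factory=dict)
    dropped_rows: list[str] = field(default_factory=list)

    @property
    def names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_molecules(self) -> int:
        return len(self.data)

    def column(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy(dtype=float)

    def add_column(self, name: str, values: np.ndarray, source: str) -> None:
        if len(values) != len(self.data):
            raise ValueError(
                f"column {name!r} has length {len(values)}, table has {len(self.data)} rows")
        self.data[name] = np.asarray(values, dtype=float)
        self.source[name] = source

    def subset(self, names: list[str]) -> "DescriptorTable":
        missing = [n for n in names if n not in self.data.columns]
        if missing:
            raise KeyError(f"unknown descriptor columns: {missing}")
        return DescriptorTable(
            data=self.data[names].copy(),
            source={n: self.source.get(n, "computed") for n in names},
            dropped_rows=list(self.dropped_rows),
        )


def make_record(smiles: str, label: float | None = None) -> MoleculeRecord | None:
    """Canonicalize one SMILES; None if it does not parse."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    canonical = Chem.MolToSmiles(mol)
    key = inchi.MolToInchiKey(mol)
    if not key:
        return None
    return MoleculeRecord(raw_smiles=smiles, canonical_smiles=canonical,
                          structure_key=key, label=label)


def load_dataset(path: str | Path, smiles_column: str,
                 label_column: str | None = None,
                 task_type: TaskType | str = TaskType.REGRESSION,
                 name: str | None = None,
                 report: CurationReport | None = None) -> MoleculeDataset:
    """Read a delimited text file into a MoleculeDataset.

    Unparseable SMILES are excluded and counted in ``report``.
    Classification labels must be coercible to {0, 1}.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    task_type = TaskType(task_type)
    df = pd.read_csv(path)
    if smiles_column not in df.columns:
        raise KeyError(f"column {smiles_column!r} not in {list(df.columns)}")
    if label_column is not None and label_column not in df.columns:
        raise KeyError(f"column {label_column!r} not in {list(df.columns)}")

    records: list[MoleculeRecord] = []
    n_bad = 0
    for _, row in df.iterrows():
        label = None
        if label_column is not None:
            label = float(row[label_column])
            if task_type is TaskType.CLASSIFICATION:
                if label not in (0.0, 1.0):
                    raise ValueError(
                        f"classification label {label!r} not in {{0, 1}}")
        rec = make_record(str(row[smiles_column]), label)
        if rec is None:
            n_bad += 1
            continue
        records.append(rec)
    if report is not None:
        report.n_input += len(df)
        report.n_unparseable += n_bad
    return MoleculeDataset(records=records, task_type=task_type,
                           name=name or path.stem)


def deduplicate(dataset: MoleculeDataset, label_tolerance: float = 0.01,
                report: CurationReport | None = None) -> MoleculeDataset:
    """Keep one record per structure key; drop groups with conflicting labels.

    Regression labels within ``label_tolerance`` of each other count as
    agreeing; classification labels must match exactly.  Unlabeled
    groups always collapse to their first record.
    """
    groups: dict[str, list[MoleculeRecord]] = {}
    order: list[str] = []
    for rec in dataset.records:
        if rec.structure_key not in groups:
            order.append(rec.structure_key)
        groups.setdefault(rec.structure_key, []).append(rec)

    kept: list[MoleculeRecord] = []
    n_dup = n_conflict = 0
    for key in order:
        group = groups[key]
        labels = [r.label for r in group if r.label is not None]
        if labels and (max(labels) - min(labels)) > label_tolerance:
            n_conflict += len(group)
            continue
        kept.append(group[0])
        n_dup += len(group) - 1
    if report is not None:
        report.n_duplicate += n_dup
        report.n_conflicting += n_conflict
    return replace_records(dataset, kept)


def remove_salts_and_mixtures(dataset: MoleculeDataset,
                              report: CurationReport | None = None) -> MoleculeDataset:
    """Exclude any record whose canonical SMILES has more than one
    covalently connected component (salts, mixtures, hydrates)."""
    kept = [r for r in dataset.records if "." not in r.canonical_smiles]
    if report is not None:
        report.n_salt_or_mixture += len(dataset.records) - len(kept)
    return replace_records(dataset, kept)


def replace_records(dataset: MoleculeDataset,
                    records: list[MoleculeRecord]) -> MoleculeDataset:
    return MoleculeDataset(records=records, task_type=dataset.task_type,
                           name=dataset.name)


def binarize_logbb(values: np.ndarray, threshold: float = -1.0) -> np.ndarray:
    """Map logBB to classes: value >= threshold -> 1 (BBB+), else 0."""
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("logBB values must be finite")
    return (values >= threshold).astype(int)


def available_descriptors() -> list[str]:
    """Names in the 2D descriptor registry."""
    return [name for name, _ in Descriptors.descList]


def compute_descriptors(dataset: MoleculeDataset,
                        descriptor_names: list[str] | None = None,
                        z_flag: float = 6.0,
                        drop_outliers: bool = False,
                        report: CurationReport | None = None) -> DescriptorTable:
    """Compute named RDKit 2D descriptors for every molecule.

    Rows with any non-finite value are dropped (and recorded).  Rows
    with |z| > ``z_flag`` in some column are flagged in
    ``table.data.attrs['outlier_keys']`` and only dropped when
    ``drop_outliers`` is set.
    """
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    registry = dict(Descriptors.descList)
    if descriptor_names is None:
        descriptor_names = list(registry)
    unknown = [n for n in descriptor_names if n not in registry]
    if unknown:
        raise KeyError(f"unknown descriptors: {unknown}")

    rows = []
    for rec in dataset.records:
        mol = Chem.MolFromSmiles(rec.canonical_smiles)
        rows.append([float(registry[n](mol)) for n in descriptor_names])
    df = pd.DataFrame(rows, columns=descriptor_names,
                      index=[r.structure_key for r in dataset.records])

    finite = np.isfinite(df.to_numpy()).all(axis=1)
    dropped = list(df.index[~finite])
    df = df.loc[finite]
    if report is not None:
        report.n_missing_descriptor += len(dropped)

    # flag (not drop, by default) extreme rows per column z-score
    with np.errstate(invalid="ignore", divide="ignore"):
        sd = df.std(ddof=1).replace(0.0, np.nan)
        z = (df - df.mean()) / sd
    outlier_mask = (z.abs() > z_flag).any(axis=1).fillna(False)
    outlier_keys = list(df.index[outlier_mask])
    if drop_outliers and outlier_keys:
        dropped += outlier_keys
        df = df.loc[~outlier_mask]

    table = DescriptorTable(data=df,
                            source={n: "computed" for n in descriptor_names},
                            dropped_rows=dropped)
    table.data.attrs["outlier_keys"] = outlier_keys
    return table
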