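"""Reading, cleaning, labeling and splitting of compound-activity datasets.

Datasets are delimited tables in a ChEMBL-export-compatible dialect: one row
per compound with an identifier, a SMILES string, a pChEMBL value
(−log10 molar activity; 0 encodes "inactive") and optionally a receptor
label. Activity is discretized into seven ordinal categories::

    class 1: pChEMBL < 4        (inactive / very weak; 0 is the inactive sentinel)
    class 2: 4 ≤ pChEMBL < 5
    class 3: 5 ≤ pChEMBL < 6
    class 4: 6 ≤ pChEMBL < 7
    class 5: 7 ≤ pChEMBL < 8
    class 6: 8 ≤ pChEMBL < 9
    class 7: pChEMBL ≥ 9        (most potent)

Interval edges are left-closed/right-open so the map is total, deterministic
and monotone in pChEMBL.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

logger = logging.getLogger(__name__)

# pChEMBL bin edges; class k covers [CLASS_EDGES[k-1], CLASS_EDGES[k]).
CLASS_EDGES = (0.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, float("inf"))
N_CLASSES = 7

#: Human-readable activity-range labels, indexed by class (1-based).
RANGE_LABELS = {
    1: "below 4",
    2: "4-5",
    3: "5-6",
    4: "6-7",
    5: "7-8",
    6: "8-9",
    7: "9-above",
}

#: Column-name dialects.  "chembl" follows the headers of a ChEMBL web export.
DIALECTS: dict[str, dict[str, str]] = {
    "chembl": {
        "id": "Molecule ChEMBL ID",
        "smiles": "Smiles",
        "pchembl": "pChEMBL Value",
        "receptor": "Target Name",
    },
    "simple": {
        "id": "compound_id",
        "smiles": "smiles",
        "pchembl": "pchembl",
        "receptor": "receptor",
    },
}


@dataclass
class CompoundRecord:
    """One compound: identifier, structure, activity and receptor label."""

    compound_id: str
    smiles: str
    pchembl: float
    activity_class: int | None = None
    receptor: str = ""

    def __post_init__(self) -> None:
        if self.pchembl < 0:
            raise ValueError(
                f"pChEMBL must be non-negative, got {self.pchembl} "
                f"for {self.compound_id!r}"
            )
        if self.activity_class is not None and self.activity_class not in range(
            1, N_CLASSES + 1
        ):
            raise ValueError(
                f"activity_class must be in 1..7, got {self.activity_class}"
            )


@dataclass
class ActivityDataset:
    """An ordered collection of compound records for one receptor."""

    receptor: str
    records: list[CompoundRecord] = field(default_factory=list)
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def smiles(self) -> list[str]:
        return [r.smiles for r in self.records]

    def ids(self) -> list[str]:
        return [r.compound_id for r in self.records]

    def pchembl_values(self) -> np.ndarray:
        return np.array([r.pchembl for r in self.records], dtype=float)

    def classes(self) -> np.ndarray:
        """Activity classes of all records; labels missing classes first."""
        out = np.empty(len(self.records), dtype=np.int64)
        for i, r in enumerate(self.records):
            out[i] = (
                r.activity_class
                if r.activity_class is not None
                else assign_activity_class(r.pchembl)
            )
        return out

    def subset(self, indices: Sequence[int]) -> "ActivityDataset":
        return ActivityDataset(
            receptor=self.receptor,
            records=[self.records[i] for i in indices],
            provenance=self.provenance,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "compound_id": self.ids(),
                "smiles": self.smiles(),
                "pchembl": self.pchembl_values(),
                "activity_class": [r.activity_class for r in self.records],
                "receptor": [r.receptor for r in self.records],
            }
        )


@dataclass(frozen=True)
class DataSplit:
    """A train/validation index partition of a dataset."""

    train_indices: tuple[int, ...]
    validation_indices: tuple[int, ...]
    fraction: float
    seed: int

    def __post_init__(self) -> None:
        overlap = set(self.train_indices) & set(self.validation_indices)
        if overlap:
            raise ValueError(f"train/validation overlap: {sorted(overlap)[:5]}")


def assign_activity_class(pchembl: float) -> int:
    """Map a pChEMBL value to its ordinal activity class (1–7).

    Bins are left-closed/right-open; values ≥ 9 are class 7 and the
    inactive sentinel 0 falls in class 1.
    """
    if pchembl < 0:
        raise ValueError(f"pChEMBL must be non-negative, got {pchembl}")
    if pchembl < 4.0:
        return 1
    if pchembl >= 9.0:
        return 7
    return int(np.floor(pchembl)) - 2  # [4,5)->2 ... [8,9)->6


def assign_activity_classes(pchembl: np.ndarray) -> np.ndarray:
    """Vectorized :func:`assign_activity_class`."""
    p = np.asarray(pchembl, dtype=float)
    if (p < 0).any():
        raise ValueError("pChEMBL values must be non-negative")
    return np.searchsorted(CLASS_EDGES[1:-1], p, side="right") + 1


def label_dataset(ds: ActivityDataset) -> ActivityDataset:
    """Return a copy with activity_class filled in from pChEMBL."""
    records = [
        replace(r, activity_class=assign_activity_class(r.pchembl))
        for r in ds.records
    ]
    return ActivityDataset(ds.receptor, records, ds.provenance)


def _resolve_dialect(dialect: str | Mapping[str, str]) -> dict[str, str]:
    if isinstance(dialect, str):
        try:
            return dict(DIALECTS[dialect])
        except KeyError:
            raise ValueError(
                f"unknown dialect {dialect!r}; known: {sorted(DIALECTS)}"
            ) from None
    return dict(dialect)


def read_activity_table(
    path: str | Path,
    dialect: str | Mapping[str, str] = "simple",
    receptor: str | None = None,
    sep: str | None = None,
) -> ActivityDataset:
    """Read a delimited activity table into an :class:`ActivityDataset`.

    Rows without a parseable pChEMBL value are dropped (compounds with no
    specified activity value carry no usable label) and counted in the log.

    Parameters
    ----------
    path
        CSV/TSV file. ``.smi`` files (``SMILES[ id]`` per line) are read as
        unlabeled libraries with pChEMBL 0.
    dialect
        Dialect name (``"chembl"``, ``"simple"``) or an explicit mapping
        with keys ``id``, ``smiles``, ``pchembl`` and optionally ``receptor``.
    receptor
        Overrides / supplies the receptor label for every record.
    sep
        Field separator; inferred from the extension when omitted
        (``.tsv`` → tab, otherwise comma).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"activity table not found: {path}")
    if path.suffix.lower() == ".smi":
        return _read_smi(path, receptor or "")

    cols = _resolve_dialect(dialect)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    for key in ("id", "smiles", "pchembl"):
        if cols[key] not in df.columns:
            raise ValueError(
                f"mandatory column {cols[key]!r} (role {key!r}) missing "
                f"from {path}; found {list(df.columns)}"
            )

    has_receptor = "receptor" in cols and cols["receptor"] in df.columns
    records: list[CompoundRecord] = []
    n_dropped = 0
    for _, row in df.iterrows():
        pch = pd.to_numeric(row[cols["pchembl"]], errors="coerce")
        cid = row[cols["id"]]
        smi = row[cols["smiles"]]
        if pd.isna(pch) or pd.isna(cid) or pd.isna(smi) or pch < 0:
            n_dropped += 1
            continue
        rec_receptor = receptor
        if rec_receptor is None:
            rec_receptor = str(row[cols["receptor"]]) if has_receptor else ""
        records.append(
            CompoundRecord(
                compound_id=str(cid).strip(),
                smiles=str(smi).strip(),
                pchembl=float(pch),
                receptor=rec_receptor,
            )
        )
    if n_dropped:
        logger.info("read_activity_table(%s): dropped %d unparseable rows", path, n_dropped)
    if not records:
        logger.warning("read_activity_table(%s): no usable rows", path)
    ds_receptor = receptor or (records[0].receptor if records else "")
    return ActivityDataset(
        receptor=ds_receptor, records=records, provenance=str(path)
    )


def _read_smi(path: Path, receptor: str) -> ActivityDataset:
    records = []
    for i, line in enumerate(path.read_text().splitlines()):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        smi = parts[0]
        cid = parts[1] if len(parts) > 1 else f"{path.stem}_{i}"
        records.append(
            CompoundRecord(compound_id=cid, smiles=smi, pchembl=0.0, receptor=receptor)
        )
    return ActivityDataset(receptor=receptor, records=records, provenance=str(path))


def write_activity_table(
    ds: ActivityDataset,
    path: str | Path,
    dialect: str | Mapping[str, str] = "simple",
    sep: str | None = None,
) -> Path:
    """Write a dataset back to a delimited table (inverse of reading)."""
    path = Path(path)
    cols = _resolve_dialect(dialect)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.DataFrame(
        {
            cols["id"]: ds.ids(),
            cols["smiles"]: ds.smiles(),
            cols["pchembl"]: ds.pchembl_values(),
        }
    )
    if "receptor" in cols:
        df[cols["receptor"]] = [r.receptor for r in ds.records]
    df.to_csv(path, sep=sep, index=False)
    return path


def canonical_smiles(smiles: str) -> str | None:
    """RDKit canonical form of a SMILES string, or None if unparseable."""
    RDLogger.DisableLog("rdApp.error")
    try:
        mol = Chem.MolFromSmiles(smiles)
    finally:
        RDLogger.EnableLog("rdApp.error")
    if mol is None:
        return None
    return Chem.MolToSmiles(mol)


def clean_dataset(ds: ActivityDataset) -> ActivityDataset:
    """Canonicalize SMILES, drop unparseable structures, dedupe identifiers.

    Duplicate compound_ids keep the first occurrence (order-stable). Records
    whose SMILES RDKit cannot parse are dropped. All removals are logged with
    counts. The operation is idempotent.
    """
    seen: set[str] = set()
    kept: list[CompoundRecord] = []
    n_bad_smiles = 0
    n_dupes = 0
    for rec in ds.records:
        canon = canonical_smiles(rec.smiles)
        if canon is None:
            n_bad_smiles += 1
            logger.debug("clean_dataset: dropping unparseable SMILES %r (%s)",
                         rec.smiles, rec.compound_id)
            continue
        if rec.compound_id in seen:
            n_dupes += 1
            continue
        seen.add(rec.compound_id)
        kept.append(
            replace(rec, smiles=canon,
                    activity_class=assign_activity_class(rec.pchembl))
        )
    if n_bad_smiles or n_dupes:
        logger.info(
            "clean_dataset(%s): removed %d unparseable SMILES, %d duplicate ids",
            ds.receptor, n_bad_smiles, n_dupes,
        )
    return ActivityDataset(ds.receptor, kept, ds.provenance)


def split_dataset(
    ds: ActivityDataset,
    fraction: float = 0.8,
    seed: int = 0,
    stratify: bool = False,
) -> DataSplit:
    """Uniform random train/validation partition.

    ``round(fraction * N)`` compounds go to training (default 80%), the rest
    to validation. Reproducible for a fixed seed. With ``stratify=True`` the
    split is drawn per activity class instead of globally.
    """
    n = len(ds)
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must be in (0,1), got {fraction}")
    if n < 2:
        raise ValueError(f"need at least 2 records to split, got {n}")
    rng = np.random.default_rng(seed)
    if stratify:
        classes = ds.classes()
        train: list[int] = []
        for cls in np.unique(classes):
            idx = np.flatnonzero(classes == cls)
            perm = rng.permutation(idx)
            train.extend(perm[: int(round(fraction * len(idx)))].tolist())
        train_set = sorted(train)
        val_set = sorted(set(range(n)) - set(train_set))
    else:
        perm = rng.permutation(n)
        n_train = int(round(fraction * n))
        train_set = perm[:n_train].tolist()
        val_set = perm[n_train:].tolist()
    return DataSplit(
        train_indices=tuple(train_set),
        validation_indices=tuple(val_set),
        fraction=fraction,
        seed=seed,
    )


def class_histogram(ds: ActivityDataset) -> dict[int, int]:
    """Counts per activity class 1–7; counts sum to the dataset size."""
    counts = {k: 0 for k in range(1, N_CLASSES + 1)}
    for rec in ds.records:
        if rec.activity_class is None:
            raise ValueError(
                f"record {rec.compound_id!r} has no activity class; "
                "run clean_dataset/label_dataset first"
            )
        counts[rec.activity_class] += 1
    return counts
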