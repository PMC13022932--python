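"""BIDS regression-dataset discovery, loading and leak-free splitting.

Splits are always made at the *subject* level: when a participant has
several images (sessions), every image follows its subject to one side of
the split, so no image of a training subject can leak into test or
validation.  The 80/20 train/test split is made once per client; within each
federation round the training pool is re-partitioned ``n_bootstraps`` times
into 75% train / 25% validation, giving the overall 60/20/20 accounting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SubjectRecord", "Split", "BootstrapSplit", "BidsFormatError",
    "BidsSchemaError", "discover_subjects", "subject_split",
    "bootstrap_splits", "load_volume",
]


class BidsFormatError(ValueError):
    """The directory does not look like a BIDS regression dataset."""


class BidsSchemaError(KeyError):
    """participants.tsv lacks a required column."""


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    image_paths: tuple[Path, ...]
    target: float
    sex: str | None = None
    covariates: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.image_paths:
            raise ValueError(f"{self.subject_id}: image_paths must be non-empty")
        if not np.isfinite(self.target):
            raise ValueError(f"{self.subject_id}: target must be finite")


@dataclass(frozen=True)
class Split:
    train_subjects: frozenset[str]
    test_subjects: frozenset[str]

    def __post_init__(self):
        if self.train_subjects & self.test_subjects:
            raise ValueError("train and test subjects overlap")


@dataclass(frozen=True)
class BootstrapSplit:
    round_index: int
    bootstrap_index: int
    train_subjects: frozenset[str]
    val_subjects: frozenset[str]
    seed: int = 0

    def __post_init__(self):
        if self.train_subjects & self.val_subjects:
            raise ValueError("bootstrap train and validation subjects overlap")


def _find_images(subject_dir: Path) -> list[Path]:
    paths = sorted(subject_dir.glob("anat/*_T1w.nii*"))
    paths += sorted(subject_dir.glob("ses-*/anat/*_T1w.nii*"))
    return paths


def discover_subjects(dataset_root: str | Path, target_column: str,
                      return_report: bool = False):
    """One :class:`SubjectRecord` per participants.tsv row that has a finite
    target and at least one T1w image on disk; others are logged and skipped.

    Records come back ordered lexicographically by subject ID.  With
    ``return_report=True`` a ``(records, skipped_ids)`` tuple is returned.
    """
    root = Path(dataset_root)
    table = root / "participants.tsv"
    if not table.is_file():
        raise BidsFormatError(f"{root}: no participants.tsv found")
    df = pd.read_csv(table, sep="\t")
    if "participant_id" not in df.columns:
        raise BidsFormatError(f"{table}: missing mandatory column "
                              "'participant_id'")
    if target_column not in df.columns:
        raise BidsSchemaError(
            f"{table}: target column {target_column!r} absent "
            f"(have: {list(df.columns)})")
    aux_cols = [c for c in df.columns
                if c not in ("participant_id", "sex", target_column)]
    records, skipped = [], []
    for _, row in df.iterrows():
        sid = str(row["participant_id"])
        target = pd.to_numeric(row[target_column], errors="coerce")
        images = _find_images(root / sid)
        if pd.isna(target) or not np.isfinite(target) or not images:
            skipped.append(sid)
            continue
        sex = str(row["sex"]) if "sex" in df.columns and pd.notna(
            row.get("sex")) else None
        cov = {c: row[c] for c in aux_cols if pd.notna(row[c])}
        records.append(SubjectRecord(sid, tuple(images), float(target),
                                     sex=sex, covariates=cov))
    records.sort(key=lambda r: r.subject_id)
    if skipped:
        logger.warning("skipped %d participant(s) without target or image: %s",
                       len(skipped), ", ".join(skipped))
    if return_report:
        return records, skipped
    return records


def _rounded_count(fraction: float, n: int) -> int:
    """Round-half-to-even with a floor of 1 and a ceiling of n - 1."""
    return min(max(round(fraction * n), 1), n - 1)


def subject_split(subjects: list[SubjectRecord], test_fraction: float,
                  seed: int) -> Split:
    """Subject-level train/test split, deterministic under ``seed``."""
    if not (0 < test_fraction < 1):
        raise ValueError("test_fraction must lie strictly between 0 and 1")
    ids = sorted({r.subject_id for r in subjects})
    if len(ids) < 2:
        raise ValueError("need at least 2 subjects to split")
    n_test = _rounded_count(test_fraction, len(ids))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    test = frozenset(ids[i] for i in order[:n_test])
    train = frozenset(ids[i] for i in order[n_test:])
    return Split(train_subjects=train, test_subjects=test)


def derive_seed(*parts) -> int:
    """Stable 32-bit seed derived from a mixed tuple of ints and strings."""
    import hashlib
    h = hashlib.sha256(repr(tuple(parts)).encode()).digest()
    return int.from_bytes(h[:4], "little") % (2 ** 31)


def bootstrap_splits(train_subjects: frozenset[str] | set[str],
                     n_bootstraps: int, val_fraction: float,
                     round_index: int, base_seed: int) -> list[BootstrapSplit]:
    """``n_bootstraps`` fresh 75/25-style partitions of the training pool.

    Each bootstrap is a random partition *without replacement* (train and
    validation are disjoint and together exhaust the pool), with a seed
    derived deterministically from (base_seed, round_index, bootstrap_index).
    """
    if n_bootstraps < 1:
        raise ValueError("n_bootstraps must be >= 1")
    if not (0 < val_fraction < 1):
        raise ValueError("val_fraction must lie strictly between 0 and 1")
    ids = sorted(train_subjects)
    if len(ids) == 0:
        raise ValueError("train_subjects is empty")
    if len(ids) < 2:
        raise ValueError("cannot bootstrap a single subject into train and "
                         "validation parts")
    n_val = _rounded_count(val_fraction, len(ids))
    splits = []
    for b in range(n_bootstraps):
        seed = derive_seed(base_seed, round_index, b)
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(ids))
        val = frozenset(ids[i] for i in order[:n_val])
        train = frozenset(ids[i] for i in order[n_val:])
        splits.append(BootstrapSplit(round_index=round_index,
                                     bootstrap_index=b, train_subjects=train,
                                     val_subjects=val, seed=seed))
    return splits


class VolumeData(NamedTuple):
    data: np.ndarray
    affine: np.ndarray
    spacing: tuple[float, float, float]


def load_volume(path: str | Path) -> VolumeData:
    """Read a NIfTI volume as float data + affine + voxel spacings.

    4D files with a singleton trailing dimension are squeezed to 3D.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
        data = np.asarray(img.get_fdata(), dtype=np.float32)
    except Exception as exc:
        raise IOError(f"cannot read NIfTI volume {path}: {exc}") from exc
    if data.ndim == 4 and data.shape[-1] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise IOError(f"{path}: expected a 3D volume, got shape {data.shape}")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VolumeData(data=data, affine=np.asarray(img.affine, dtype=float),
                      spacing=zooms)
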