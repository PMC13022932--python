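"""Synthetic BIDS phantom datasets for desk-scale federation runs.

Each "brain" is a sphere of unit intensity containing a darker inner
"ventricle" sphere whose radius grows linearly with the regression target,
mimicking how ventricular enlargement tracks brain ageing.  Volumes are
written as NIfTI under a minimal BIDS layout (``participants.tsv`` +
``sub-*/anat/*_T1w.nii.gz``) so that the discovery, splitting, preprocessing
and federation machinery can be exercised without any real data.

A per-client ``target_shift`` knob adds a constant to the *tabulated* target
(the phantom geometry still encodes the unshifted value), fabricating the
kind of between-centre label shift — e.g. differing test-administration
practices — that makes real federated clients non-IID.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = ["PhantomConfig", "phantom_volume", "generate_dataset"]


@dataclass(frozen=True)
class PhantomConfig:
    n_subjects: int = 10
    volume_shape: tuple[int, int, int] = (32, 32, 32)
    voxel_spacing_mm: float = 1.0
    target_name: str = "age"
    target_range: tuple[float, float] = (20.0, 80.0)
    signal_slope: float = 0.1
    noise_sd: float = 0.1
    images_per_subject: int = 1
    seed: int = 0
    target_shift: float = 0.0

    def __post_init__(self):
        if self.n_subjects <= 0 or self.images_per_subject <= 0:
            raise ValueError("n_subjects and images_per_subject must be positive")
        if self.target_range[0] >= self.target_range[1]:
            raise ValueError("target_range lower bound must be below upper")
        if any(s < 16 for s in self.volume_shape):
            raise ValueError("volume_shape entries must be >= 16 "
                             "(both spheres must fit)")
        if self.voxel_spacing_mm <= 0:
            raise ValueError("voxel_spacing_mm must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def outer_radius(self) -> float:
        return min(self.volume_shape) / 2.0 - 2.0

    @property
    def base_inner_radius(self) -> float:
        return self.outer_radius / 2.0

    def inner_radius(self, target_value: float) -> float:
        mid = 0.5 * (self.target_range[0] + self.target_range[1])
        r = self.base_inner_radius + self.signal_slope * (target_value - mid)
        return float(np.clip(r, 1.0, self.outer_radius - 2.0))

    def to_dict(self) -> dict:
        return {
            "n_subjects": self.n_subjects,
            "volume_shape": list(self.volume_shape),
            "voxel_spacing_mm": self.voxel_spacing_mm,
            "target_name": self.target_name,
            "target_range": list(self.target_range),
            "signal_slope": self.signal_slope,
            "noise_sd": self.noise_sd,
            "images_per_subject": self.images_per_subject,
            "seed": self.seed,
            "target_shift": self.target_shift,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomConfig":
        d = dict(d)
        if "volume_shape" in d:
            d["volume_shape"] = tuple(d["volume_shape"])
        if "target_range" in d:
            d["target_range"] = tuple(d["target_range"])
        return cls(**d)


def phantom_volume(target_value: float, config: PhantomConfig,
                   subject_seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Render one phantom volume and its RAS affine.

    Background is 0, the brain sphere 1.0 and the ventricle sphere 0.2;
    Gaussian intensity noise of sd ``config.noise_sd`` is added inside the
    brain sphere only.  Identical ``(target_value, subject_seed)`` pairs give
    identical arrays.
    """
    lo, hi = config.target_range
    if not (lo <= target_value <= hi):
        raise ValueError(
            f"target {target_value} outside target_range [{lo}, {hi}]")
    shape = config.volume_shape
    center = [(s - 1) / 2.0 for s in shape]
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    dist = np.sqrt(sum((g - c) ** 2 for g, c in zip(grids, center)))
    vol = np.zeros(shape, dtype=np.float32)
    brain = dist <= config.outer_radius
    vol[brain] = 1.0
    vol[dist <= config.inner_radius(target_value)] = 0.2
    if config.noise_sd > 0:
        rng = np.random.default_rng(subject_seed)
        noise = rng.normal(0.0, config.noise_sd, shape).astype(np.float32)
        vol[brain] += noise[brain]
    affine = np.diag([config.voxel_spacing_mm] * 3 + [1.0]).astype(np.float64)
    return vol, affine


def _subject_seed(config: PhantomConfig, subject_idx: int,
                  image_idx: int) -> int:
    ss = np.random.SeedSequence([config.seed, subject_idx, image_idx])
    return int(ss.generate_state(1)[0])


def generate_dataset(config: PhantomConfig, output_root: str | Path) -> dict:
    """Write a BIDS phantom dataset; refuses a non-empty output directory.

    Targets are drawn uniformly from ``target_range``; the value recorded in
    ``participants.tsv`` is the drawn value plus ``target_shift`` while the
    geometry encodes the unshifted draw.  Returns a summary with the number
    of subjects written and the participants-table path.
    """
    root = Path(output_root)
    root.mkdir(parents=True, exist_ok=True)
    if any(root.iterdir()):
        raise FileExistsError(f"output_root {root} is not empty; refusing to "
                              "overwrite an existing dataset")
    rng = np.random.default_rng(config.seed)
    lo, hi = config.target_range
    targets = rng.uniform(lo, hi, config.n_subjects)
    rows = []
    n_images = 0
    for k in range(config.n_subjects):
        sub = f"sub-{k + 1:03d}"
        target = float(targets[k])
        rows.append({
            "participant_id": sub,
            "sex": "m" if k % 2 == 0 else "f",
            config.target_name: round(target + config.target_shift, 4),
        })
        for j in range(config.images_per_subject):
            vol, affine = phantom_volume(target, config,
                                         _subject_seed(config, k, j))
            img = nib.Nifti1Image(vol, affine)
            if config.images_per_subject > 1:
                anat = root / sub / f"ses-{j + 1}" / "anat"
                name = f"{sub}_ses-{j + 1}_T1w.nii.gz"
            else:
                anat = root / sub / "anat"
                name = f"{sub}_T1w.nii.gz"
            anat.mkdir(parents=True, exist_ok=True)
            nib.save(img, str(anat / name))
            n_images += 1
    table_path = root / "participants.tsv"
    pd.DataFrame(rows).to_csv(table_path, sep="\t", index=False,
                              lineterminator="\n")
    return {"n_subjects": config.n_subjects, "n_images": n_images,
            "participants_path": table_path}
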