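"""Cohort input/output and voxel/world geometry.

The pipeline operates on a stack of per-subject gray-matter-volume (GMV)
images sharing one grid and affine, a boolean gray-matter mask, and a
participants table. The participants table is the single source of subject
ordering: images are aligned to it (by ``subject_id`` when file names carry
ids, by position otherwise), so a cohort can never be silently misaligned.

World coordinates are NIfTI affine millimeters (MNI by convention); voxel
indices are 0-based.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import ConfigurationError, FormatError, SchemaError

#: Columns every participants table must provide.
REQUIRED_COLUMNS = [
    "subject_id",
    "group",
    "age",
    "sex",
    "education",
    "tiv",
    "ahs_score",
    "p3_score",
]

#: Columns meaningful only for patients; NaN/empty for controls.
PATIENT_ONLY_COLUMNS = ["illness_duration", "onset_age", "cpz_dose"]

#: Default range of the auditory-hallucination severity scale (PSYRATS AHS).
AHS_RANGE = (0, 44)


@dataclass(frozen=True)
class Participant:
    """One row of the participants table.

    ``ahs_score`` is the PSYRATS auditory-hallucination-subscale total and
    ``p3_score`` the PANSS hallucination item (1-7); both serve as severity
    keys. ``illness_duration`` (months), ``onset_age`` (years) and
    ``cpz_dose`` (mg/day chlorpromazine equivalents) apply to patients only.
    """

    subject_id: str
    group: str
    age: float
    sex: str
    education: float
    tiv: float
    ahs_score: int
    p3_score: int
    illness_duration: float | None = None
    onset_age: float | None = None
    cpz_dose: float | None = None

    def __post_init__(self) -> None:
        if self.group not in ("patient", "control"):
            raise SchemaError(f"group must be 'patient' or 'control', got {self.group!r}")
        if self.sex not in ("M", "F"):
            raise SchemaError(f"sex must be 'M' or 'F', got {self.sex!r}")
        if not (AHS_RANGE[0] <= self.ahs_score <= AHS_RANGE[1]):
            raise SchemaError(
                f"ahs_score {self.ahs_score} outside scale range {AHS_RANGE}"
            )
        if self.group == "patient" and not (1 <= self.p3_score <= 7):
            raise SchemaError(f"p3_score {self.p3_score} outside 1..7")
        if self.group == "control":
            for name in PATIENT_ONLY_COLUMNS:
                value = getattr(self, name)
                if value is not None and np.isfinite(value):
                    raise SchemaError(f"{name} must be absent for controls")


def validate_participants(table: pd.DataFrame) -> None:
    """Check a participants DataFrame against the cohort schema."""
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(
            f"participants table is missing required columns: {missing}; "
            f"required: {REQUIRED_COLUMNS}"
        )
    if table["subject_id"].duplicated().any():
        dups = table.loc[table["subject_id"].duplicated(), "subject_id"].tolist()
        raise SchemaError(f"duplicate subject_id values: {dups}")
    bad_group = set(table["group"]) - {"patient", "control"}
    if bad_group:
        raise SchemaError(f"unknown group labels: {sorted(bad_group)}")


@dataclass
class Cohort:
    """A stack of GMV volumes with a common grid, mask and participants table.

    ``volumes`` has shape (n_subjects, nx, ny, nz) and is aligned row-for-row
    with ``participants``. ``ground_truth`` is set by the synthetic generator
    so tests can assert against the planted cascade; it is ``None`` for real
    data.
    """

    volumes: np.ndarray
    affine: np.ndarray
    mask: np.ndarray
    participants: pd.DataFrame
    ground_truth: object | None = None

    def __post_init__(self) -> None:
        self.volumes = np.asarray(self.volumes, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.volumes.ndim != 4:
            raise FormatError("volumes must be 4-D (subject, i, j, k)")
        if self.affine.shape != (4, 4):
            raise FormatError("affine must be 4x4")
        if self.mask.shape != self.volumes.shape[1:]:
            raise FormatError(
                f"mask shape {self.mask.shape} != volume grid {self.volumes.shape[1:]}"
            )
        if len(self.participants) != self.volumes.shape[0]:
            raise FormatError(
                f"{self.volumes.shape[0]} volumes but "
                f"{len(self.participants)} participants"
            )
        validate_participants(self.participants)
        if not np.isfinite(self.volumes[:, self.mask]).all():
            raise FormatError("non-finite values inside the gray-matter mask")

    @property
    def n_subjects(self) -> int:
        return self.volumes.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.volumes.shape[1:]

    def subset(self, index: np.ndarray) -> "Cohort":
        """Row-subset the cohort (boolean or integer index over subjects)."""
        part = self.participants.iloc[np.asarray(index)].reset_index(drop=True)
        return Cohort(self.volumes[index], self.affine, self.mask, part,
                      ground_truth=self.ground_truth)

    def patients(self) -> "Cohort":
        return self.subset((self.participants["group"] == "patient").to_numpy())

    def controls(self) -> "Cohort":
        return self.subset((self.participants["group"] == "control").to_numpy())


@dataclass(frozen=True)
class SeedSpec:
    """A spherical seed: MNI-mm center and radius."""

    center_mm: tuple[float, float, float]
    radius_mm: float = 6.0

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ConfigurationError("seed radius must be > 0")


def voxel_to_mm(ijk: Sequence[float], affine: np.ndarray) -> np.ndarray:
    """Map a 0-based voxel index to world mm through the affine."""
    ijk = np.asarray(ijk, dtype=float)
    return affine[:3, :3] @ ijk + affine[:3, 3]


def mni_to_voxel(
    coord_mm: Sequence[float],
    affine: np.ndarray,
    shape: tuple[int, int, int] | None = None,
) -> tuple[int, int, int]:
    """Nearest 0-based voxel index of a world-mm coordinate.

    When ``shape`` is given, a coordinate mapping outside the grid raises
    ``ConfigurationError``.
    """
    inv = np.linalg.inv(np.asarray(affine, dtype=float))
    ijk = inv[:3, :3] @ np.asarray(coord_mm, dtype=float) + inv[:3, 3]
    idx = tuple(int(v) for v in np.round(ijk))
    if shape is not None:
        if any(i < 0 or i >= s for i, s in zip(idx, shape)):
            raise ConfigurationError(
                f"coordinate {tuple(coord_mm)} maps to voxel {idx}, "
                f"outside grid of shape {shape}"
            )
    return idx


def sphere_mask(
    seed: SeedSpec,
    shape: tuple[int, int, int],
    affine: np.ndarray,
    gm_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Boolean mask of voxels whose centers lie within ``radius_mm`` of the seed.

    Distances are Euclidean in world mm; voxels exactly at the radius are
    included. If ``gm_mask`` is supplied the sphere is intersected with it;
    an empty intersection raises ``ConfigurationError``.
    """
    center = np.asarray(seed.center_mm, dtype=float)
    # bounding box in voxel space keeps the scan cheap on large grids
    inv = np.linalg.inv(affine)
    cvox = inv[:3, :3] @ center + inv[:3, 3]
    # conservative per-axis half-width: radius / smallest singular value
    svals = np.linalg.svd(affine[:3, :3], compute_uv=False)
    halfw = seed.radius_mm / svals.min() + 1.0
    lo = np.maximum(np.floor(cvox - halfw).astype(int), 0)
    hi = np.minimum(np.ceil(cvox + halfw).astype(int) + 1, np.asarray(shape))
    if np.any(lo >= hi):
        raise ConfigurationError(f"seed center {tuple(center)} outside grid")
    ii, jj, kk = np.meshgrid(
        *(np.arange(lo[a], hi[a]) for a in range(3)), indexing="ij"
    )
    ijk = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
    mm = ijk @ affine[:3, :3].T + affine[:3, 3]
    inside = np.linalg.norm(mm - center, axis=1) <= seed.radius_mm
    out = np.zeros(shape, dtype=bool)
    out[ijk[inside, 0], ijk[inside, 1], ijk[inside, 2]] = True
    if not out.any():
        raise ConfigurationError("sphere contains no voxel centers")
    if gm_mask is not None:
        out &= gm_mask
        if not out.any():
            raise ConfigurationError(
                "seed sphere does not intersect the gray-matter mask"
            )
    return out


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def read_nifti(path: str | os.PathLike) -> tuple[np.ndarray, np.ndarray]:
    """Load a NIfTI volume, returning (data, affine)."""
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=np.float64), np.asarray(img.affine)

def write_nifti(volume: np.ndarray, affine: np.ndarray, path: str | os.PathLike) -> None:
    """Write a volume as NIfTI-1; round-trips bit-identically for float64."""
    volume = np.asarray(volume)
    if volume.dtype == bool:
        volume = volume.astype(np.uint8)
    img = nib.Nifti1Image(volume, np.asarray(affine, dtype=np.float64))
    nib.save(img, str(path))


def read_participants(path: str | os.PathLike) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    validate_participants(table)
    table["subject_id"] = table["subject_id"].astype(str)
    return table


def write_participants(table: pd.DataFrame, path: str | os.PathLike) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_cohort(
    image_paths: Iterable[str | os.PathLike],
    participants_path: str | os.PathLike,
    mask_path: str | os.PathLike,
) -> Cohort:
    """Assemble a :class:`Cohort` from per-subject NIfTI files, a TSV and a mask.

    Image order follows the participants table. If every image file name stem
    matches a ``subject_id``, images are aligned by id; otherwise the given
    path order must already match the table row order.
    """
    image_paths = [Path(p) for p in image_paths]
    for p in list(image_paths) + [Path(participants_path), Path(mask_path)]:
        if not p.exists():
            raise FileNotFoundError(p)
    table = read_participants(participants_path)
    if len(image_paths) != len(table):
        raise FormatError(
            f"{len(image_paths)} images but {len(table)} participant rows"
        )

    stems = [p.name.partition(".")[0] for p in image_paths]
    ids = table["subject_id"].tolist()
    if set(stems) == set(ids):
        by_stem = dict(zip(stems, image_paths))
        image_paths = [by_stem[s] for s in ids]

    mask, mask_affine = read_nifti(mask_path)
    mask = mask > 0

    volumes = np.empty((len(image_paths),) + mask.shape, dtype=np.float64)
    ref_affine = None
    for i, p in enumerate(image_paths):
        data, affine = read_nifti(p)
        if data.shape != mask.shape:
            raise FormatError(
                f"{p}: grid {data.shape} differs from mask grid {mask.shape}"
            )
        if ref_affine is None:
            ref_affine = affine
            if not np.allclose(affine, mask_affine, atol=1e-4):
                raise FormatError(f"{mask_path}: mask affine differs from {p}")
        elif not np.allclose(affine, ref_affine, atol=1e-4):
            raise FormatError(f"{p}: affine differs from {image_paths[0]}")
        volumes[i] = data
    return Cohort(volumes, ref_affine, mask, table)


CLUSTER_TABLE_COLUMNS = [
    "region",
    "cluster_size_voxels",
    "peak_x",
    "peak_y",
    "peak_z",
    "peak_stat",
]


def write_cluster_table(table: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a cluster table as TSV, rows in descending peak-statistic order."""
    out = table.copy()
    for col in CLUSTER_TABLE_COLUMNS:
        if col not in out.columns:
            if col == "region":
                out["region"] = "unlabeled"
            else:
                raise SchemaError(f"cluster table missing column {col!r}")
    out = out[CLUSTER_TABLE_COLUMNS].sort_values(
        "peak_stat", ascending=False, kind="mergesort"
    )
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_cluster_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
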