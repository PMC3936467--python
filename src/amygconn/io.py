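"""Volume, mask, motion-table and cohort-table I/O.

Volumes are NIfTI-1 (read and written with nibabel); motion parameters are
plain whitespace-delimited text with one row per volume and six columns
(three translations in mm, three rotations in degrees); the cohort table is
a TSV with columns ``subject_id``, ``group``, ``years_education``,
``years_smoking``. Group labels are ``relapse``, ``nonrelapse`` and
``control``.

Everything downstream assumes all of a study's volumes live on one common
grid; grid compatibility is checked here, at load time, so later stages
never have to.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import FormatError, GridError, ValidationError
from .grid import VolumeGrid

logger = logging.getLogger(__name__)

GROUP_LABELS = ("relapse", "nonrelapse", "control")
COHORT_COLUMNS = ("subject_id", "group", "years_education", "years_smoking")


@dataclass
class SubjectScan:
    """One subject's 4D BOLD series plus motion table and tissue masks.

    ``series`` is indexed (x, y, z, t). Masks are boolean 3D arrays on the
    same grid. ``motion`` has one row per timepoint and six columns.
    """

    subject_id: str
    grid: VolumeGrid
    series: np.ndarray
    tr: float
    motion: np.ndarray
    brain_mask: np.ndarray
    wm_mask: np.ndarray
    csf_mask: np.ndarray
    segmentation: np.ndarray = None  # amygdala segmentation, may be absent

    def __post_init__(self):
        if self.series.ndim != 4:
            raise ValidationError(f"series must be 4D, got ndim={self.series.ndim}")
        if self.series.shape[:3] != self.grid.dims:
            raise GridError(
                f"series shape {self.series.shape[:3]} does not match grid {self.grid.dims}"
            )
        self.motion = np.asarray(self.motion, dtype=float)
        if self.motion.ndim != 2 or self.motion.shape[1] != 6:
            raise ValidationError(f"motion table must be T x 6, got {self.motion.shape}")
        if self.motion.shape[0] != self.series.shape[3]:
            raise ValidationError(
                f"motion rows ({self.motion.shape[0]}) != series length ({self.series.shape[3]})"
            )
        for name in ("brain_mask", "wm_mask", "csf_mask", "segmentation"):
            m = getattr(self, name)
            if m is None:
                continue
            if m.shape != self.grid.dims:
                raise GridError(f"{name} shape {m.shape} does not match grid {self.grid.dims}")

    @property
    def n_volumes(self):
        return self.series.shape[3]


def write_volume(data, grid, path):
    """Write a 3D/4D array as NIfTI-1 at ``path`` (deterministic bytes)."""
    data = np.asarray(data)
    img = nib.Nifti1Image(data.astype(np.float32, copy=False), grid.affine())
    img.header.set_xyzt_units("mm", "sec")
    img.to_filename(str(path))


def write_mask(mask, grid, path):
    img = nib.Nifti1Image(np.asarray(mask).astype(np.uint8), grid.affine())
    img.to_filename(str(path))


def read_volume(path, expected_grid=None):
    """Read a NIfTI volume; returns ``(data, grid)``.

    Raises :class:`FormatError` for unreadable files and :class:`GridError`
    when ``expected_grid`` is given and does not match.
    """
    try:
        img = nib.load(str(path))
        data = np.asarray(img.get_fdata())
    except FileNotFoundError:
        raise
    except Exception as exc:  # nibabel raises several format exceptions
        raise FormatError(f"could not read {path} as NIfTI: {exc}") from exc
    if data.ndim not in (3, 4):
        raise FormatError(f"{path}: expected 3D or 4D volume, got ndim={data.ndim}")
    grid = VolumeGrid.from_affine(img.affine, data.shape[:3])
    if expected_grid is not None:
        expected_grid.check_compatible(grid, what=str(path))
    return data, grid


def read_mask(path, grid):
    """Read a 3D volume as a boolean mask on ``grid``.

    Any nonzero voxel becomes True. An all-zero mask is returned (not an
    error) but logged, since empty masks are unusable downstream; callers
    that require a nonempty mask check at the point of use.
    """
    data, file_grid = read_volume(path)
    if data.ndim != 3:
        raise FormatError(f"{path}: mask must be 3D")
    grid.check_compatible(file_grid, what=str(path))
    mask = data != 0
    if not mask.any():
        logger.warning("mask %s is empty", path)
    return mask


def write_motion(motion, path):
    np.savetxt(str(path), np.asarray(motion, dtype=float), fmt="%.6f")


def read_motion(path, n_volumes=None):
    try:
        motion = np.loadtxt(str(path), ndmin=2)
    except ValueError as exc:
        raise FormatError(f"could not parse motion table {path}: {exc}") from exc
    if motion.shape[1] != 6:
        raise FormatError(f"{path}: motion table must have 6 columns, got {motion.shape[1]}")
    if n_volumes is not None and motion.shape[0] != n_volumes:
        raise ValidationError(
            f"{path}: motion rows ({motion.shape[0]}) != scan length ({n_volumes})"
        )
    return motion


def validate_cohort(table):
    """Validate a cohort DataFrame in place; returns it.

    Checks required columns, unique subject ids, known group labels, and
    that each group present has at least 2 members.
    """
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"cohort table missing columns: {missing}")
    if table["subject_id"].duplicated().any():
        dupes = table.loc[table["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValidationError(f"duplicate subject ids: {dupes}")
    unknown = sorted(set(table["group"]) - set(GROUP_LABELS))
    if unknown:
        raise ValidationError(f"unknown group labels: {unknown} (expected {GROUP_LABELS})")
    counts = table["group"].value_counts()
    small = counts[counts < 2]
    if len(small):
        raise ValidationError(f"groups with fewer than 2 members: {dict(small)}")
    logger.info("cohort loaded: %s", dict(counts))
    return table


def load_cohort(path):
    """Load and validate the cohort TSV; returns a DataFrame."""
    try:
        table = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    except Exception as exc:
        raise FormatError(f"could not parse cohort table {path}: {exc}") from exc
    return validate_cohort(table)


def write_cohort(table, path):
    table.to_csv(path, sep="\t", index=False)
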