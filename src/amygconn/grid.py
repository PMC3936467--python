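"""Voxel grid and coordinate conventions.

All volumes in a study share one :class:`VolumeGrid`: integer dimensions,
millimetre voxel sizes, and a millimetre origin for voxel (0, 0, 0). Data
arrays are indexed ``(x, y, z)`` (plus a trailing time axis for 4D series)
with internal axes oriented Right/Anterior/Superior: +x points to the
subject's right, +y anterior, +z superior.

Peak coordinates in cluster reports follow the radiology-style convention in
which printed values are positive along the Left, Posterior and Inferior
axes, i.e. the negation of the internal RAS millimetre coordinate. That
convention is an interpretation choice, so it is isolated behind the
``convention`` argument of :func:`VolumeGrid.voxel_to_report_mm`
(``"lpi"``, the default, or ``"ras"``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GridError

#: Supported reporting conventions for peak coordinates.
COORD_CONVENTIONS = ("lpi", "ras")


@dataclass(frozen=True)
class VolumeGrid:
    """Geometry of the common analysis grid.

    Parameters
    ----------
    dims : tuple of 3 ints
        Number of voxels along x, y, z.
    voxel_size : tuple of 3 floats
        Voxel edge length in mm along x, y, z.
    origin : tuple of 3 floats, optional
        mm coordinate of voxel (0, 0, 0). Defaults to placing the grid
        centre at the coordinate origin.
    """

    dims: tuple
    voxel_size: tuple
    origin: tuple = None  # type: ignore[assignment]

    def __post_init__(self):
        dims = tuple(int(d) for d in self.dims)
        vs = tuple(float(v) for v in self.voxel_size)
        if len(dims) != 3 or len(vs) != 3:
            raise GridError("dims and voxel_size must each have 3 entries")
        if any(d < 1 for d in dims):
            raise GridError(f"dims must be >= 1, got {dims}")
        if any(v <= 0 for v in vs):
            raise GridError(f"voxel sizes must be > 0, got {vs}")
        object.__setattr__(self, "dims", dims)
        object.__setattr__(self, "voxel_size", vs)
        if self.origin is None:
            origin = tuple(-(d - 1) / 2.0 * v for d, v in zip(dims, vs))
        else:
            origin = tuple(float(o) for o in self.origin)
            if len(origin) != 3:
                raise GridError("origin must have 3 entries")
        object.__setattr__(self, "origin", origin)

    @property
    def shape(self):
        return self.dims

    @property
    def n_voxels(self):
        return int(np.prod(self.dims))

    def affine(self):
        """4x4 voxel-to-mm affine (diagonal; internal RAS axes)."""
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.voxel_size)
        aff[:3, 3] = self.origin
        return aff

    @classmethod
    def from_affine(cls, affine, dims):
        """Build a grid from a NIfTI affine; requires axis-aligned voxels."""
        affine = np.asarray(affine, dtype=float)
        rot = affine[:3, :3]
        off_diag = rot - np.diag(np.diag(rot))
        if np.abs(off_diag).max() > 1e-6:
            raise GridError("oblique affines are not supported; volumes must be pre-aligned")
        voxel_size = tuple(np.abs(np.diag(rot)))
        return cls(dims=tuple(dims[:3]), voxel_size=voxel_size, origin=tuple(affine[:3, 3]))

    def voxel_to_mm(self, ijk):
        """Internal RAS mm coordinate of voxel index ``ijk``."""
        ijk = np.asarray(ijk, dtype=float)
        return ijk * np.asarray(self.voxel_size) + np.asarray(self.origin)

    def voxel_to_report_mm(self, ijk, convention="lpi"):
        """mm coordinate of voxel ``ijk`` in the reporting convention."""
        if convention not in COORD_CONVENTIONS:
            raise GridError(f"unknown coordinate convention {convention!r}")
        mm = self.voxel_to_mm(ijk)
        if convention == "lpi":
            mm = -mm
        return mm

    def matches(self, other, atol=1e-4):
        """True when two grids have identical dims and voxel geometry."""
        return (
            self.dims == other.dims
            and np.allclose(self.voxel_size, other.voxel_size, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )

    def check_compatible(self, other, what="volume"):
        if not self.matches(other):
            raise GridError(
                f"{what} grid {other.dims}@{other.voxel_size} does not match "
                f"analysis grid {self.dims}@{self.voxel_size}"
            )
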