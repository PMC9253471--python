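"""Template grid: the reference voxel lattice shared by all volumes and tractograms.

A :class:`TemplateGrid` plays the role a standard template space (e.g. an
MNI-like template) plays in a real study: every lesion mask, visitation map
and disconnectome map lives on the same lattice, and streamline coordinates
are expressed in the grid's world (mm) frame via its affine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Round half away from zero (tie-stable, unlike banker's rounding)."""
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


@dataclass(frozen=True)
class TemplateGrid:
    """An axis-aligned voxel lattice with a voxel-to-world affine.

    Parameters
    ----------
    shape : tuple of int
        Voxels per axis, each >= 1.
    affine : (4, 4) ndarray
        Voxel-index-to-world-mm map (NIfTI convention: maps the *center*
        of voxel ``(i, j, k)`` to world coordinates). Must be invertible.
    """

    shape: tuple[int, int, int]
    affine: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        object.__setattr__(self, "shape", shape)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ValueError(f"shape must be three entries >= 1, got {shape}")
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(aff[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        object.__setattr__(self, "affine", aff)

    @classmethod
    def isotropic(cls, n: int = 32, voxel_size: float = 1.0) -> "TemplateGrid":
        """Small RAS+ isotropic grid (default 32³ at 1 mm) used by the phantoms."""
        if voxel_size <= 0:
            raise ValueError("voxel_size must be > 0")
        aff = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
        return cls(shape=(n, n, n), affine=aff)

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge lengths in mm per axis."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    @property
    def inverse_affine(self) -> np.ndarray:
        return np.linalg.inv(self.affine)

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        """Map world-mm points to continuous voxel coordinates."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        inv = self.inverse_affine
        return pts @ inv[:3, :3].T + inv[:3, 3]

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def nearest_voxel(self, points: np.ndarray) -> np.ndarray:
        """Voxel whose center is nearest to each world point.

        Ties are broken by rounding half away from zero in voxel
        coordinates, which is stable under sign flips of the affine.
        """
        return _round_half_away(self.world_to_voxel(points)).astype(np.int64)

    def inside(self, ijk: np.ndarray) -> np.ndarray:
        """Boolean mask of voxel index rows that fall inside the lattice."""
        ijk = np.atleast_2d(ijk)
        ok = np.ones(len(ijk), dtype=bool)
        for ax in range(3):
            ok &= (ijk[:, ax] >= 0) & (ijk[:, ax] < self.shape[ax])
        return ok

    def world_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """(lo, hi) world-mm corners of the lattice's bounding box.

        The box spans from half a voxel before the first voxel center to
        half a voxel past the last, i.e. the full extent of the voxels.
        """
        corners_vox = np.array(
            [[i, j, k] for i in (-0.5, self.shape[0] - 0.5)
             for j in (-0.5, self.shape[1] - 0.5)
             for k in (-0.5, self.shape[2] - 0.5)]
        )
        corners = self.voxel_to_world(corners_vox)
        return corners.min(axis=0), corners.max(axis=0)

    def voxel_centers(self) -> np.ndarray:
        """World coordinates of every voxel center, shape (n_voxels, 3)."""
        idx = np.indices(self.shape).reshape(3, -1).T
        return self.voxel_to_world(idx)
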