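"""Disconnectome maps, the white-matter mask, and the global disconnectome (GD).

Given one subject's binary lesion mask and a set of N normative control
tractograms on a common template grid, the disconnectome map gives, per
voxel, the fraction of controls with at least one streamline that both
passes through that voxel and intersects the lesion — read as the
probability that the lesion disconnects fibers through the voxel.

The per-control visitation maps are binarised before averaging, so the
map takes values on the lattice {0, 1/N, ..., 1} ("percentage overlap").
Maps are conventionally thresholded at a strictly-greater-than 50% cutoff
(at least half the controls agree) before the global statistic is taken.

GD is the mean of the (thresholded) map over a cohort white-matter mask —
the union of nonzero support across all subjects' maps — so it captures
both the proportion of white matter affected (zeros inside the mask count
in the denominator) and the severity at affected voxels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import TemplateGrid
from .tractogram import Tractogram, select_through_mask, visitation_map

__all__ = [
    "DisconnectomeMap",
    "disconnectome_map",
    "threshold_map",
    "build_wm_mask",
    "global_disconnectome",
    "lesion_volume_ml",
]


@dataclass
class DisconnectomeMap:
    """Per-voxel disconnection probability in [0, 1] on a template grid."""

    prob: np.ndarray
    grid: TemplateGrid
    thresholded: bool = False
    cutoff: float | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.prob, dtype=float)
        if p.shape != self.grid.shape:
            raise ValueError(f"map shape {p.shape} != grid shape {self.grid.shape}")
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("disconnection probabilities must lie in [0, 1]")
        self.prob = p

    @property
    def support(self) -> np.ndarray:
        return self.prob > 0


def disconnectome_map(
    lesion: np.ndarray,
    controls: list[Tractogram],
    grid: TemplateGrid,
    step: float | None = None,
) -> DisconnectomeMap:
    """Unthresholded disconnectome map for one lesion against N controls.

    For each control: select its streamlines through the lesion, rasterise
    them into a visitation map, binarise (count > 0), then average the N
    binary maps voxelwise. Values lie on {k/N : 0 <= k <= N}.
    """
    if len(controls) == 0:
        raise ValueError("need at least one control tractogram")
    lesion = np.asarray(lesion).astype(bool)
    if lesion.shape != grid.shape:
        raise ValueError(f"lesion shape {lesion.shape} != grid shape {grid.shape}")
    if not lesion.any():
        raise ValueError("lesion mask is empty")
    from .tractogram import tractogram_flat_voxels

    flat_lesion = lesion.ravel()
    acc = np.zeros(int(np.prod(grid.shape)), dtype=float)
    for control in controls:
        flat = tractogram_flat_voxels(control, grid, step)
        crossing = [v for v in flat if v.size and flat_lesion[v].any()]
        if crossing:
            acc[np.unique(np.concatenate(crossing))] += 1.0
    prob = (acc / len(controls)).reshape(grid.shape)
    return DisconnectomeMap(prob=prob, grid=grid, thresholded=False)


def threshold_map(d: DisconnectomeMap, cutoff: float = 0.5, strict: bool = True) -> DisconnectomeMap:
    """Zero out voxels at or below ``cutoff``; retained values are unchanged.

    The strict-inequality default keeps voxels only where *more* than half
    of the controls agree; ``strict=False`` keeps ties at the cutoff.
    """
    if d.thresholded:
        raise ValueError("map is already thresholded")
    if not (0.0 <= cutoff < 1.0):
        raise ValueError(f"cutoff must lie in [0, 1), got {cutoff}")
    keep = d.prob > cutoff if strict else d.prob >= cutoff
    return DisconnectomeMap(
        prob=np.where(keep, d.prob, 0.0), grid=d.grid, thresholded=True, cutoff=cutoff
    )


def build_wm_mask(maps: list[DisconnectomeMap]) -> np.ndarray:
    """Cohort white-matter mask: union of nonzero support across maps."""
    if len(maps) == 0:
        raise ValueError("need at least one disconnectome map")
    grid = maps[0].grid
    for m in maps[1:]:
        if m.grid.shape != grid.shape or not np.allclose(m.grid.affine, grid.affine):
            raise ValueError("disconnectome maps are not on a common grid")
    out = np.zeros(grid.shape, dtype=bool)
    for m in maps:
        out |= m.support
    return out


def global_disconnectome(d: DisconnectomeMap, wm_mask: np.ndarray) -> float:
    """GD: mean disconnection probability over the white-matter mask.

    Voxels inside the mask where the (thresholded) map is zero still count
    in the denominator, so GD reflects both extent and severity.
    """
    wm = np.asarray(wm_mask).astype(bool)
    if wm.shape != d.grid.shape:
        raise ValueError("white-matter mask is not on the map's grid")
    if not wm.any():
        raise ValueError("white-matter mask is empty")
    return float(d.prob[wm].mean())


def lesion_volume_ml(lesion: np.ndarray, grid: TemplateGrid) -> float:
    """Lesion volume in millilitres: voxel count x voxel volume / 1000."""
    lesion = np.asarray(lesion).astype(bool)
    return float(lesion.sum()) * grid.voxel_volume_mm3 / 1000.0
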