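"""Streamline containers, tractogram file I/O, and streamline-voxel geometry.

Streamlines are ordered sequences of world-coordinate (mm) points. The
geometric primitives here — polyline resampling, voxelisation, visitation
maps and lesion-intersection filtering — are the building blocks of the
disconnectome computation: a lesion "seeds" the selection of every
normative streamline that passes through it, and the selected set is
rasterised into a per-voxel visitation count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from nibabel.streamlines import Tractogram as _NibTractogram
from nibabel.streamlines.trk import TrkFile
from nibabel.streamlines.tck import TckFile

from .grid import TemplateGrid

logger = logging.getLogger(__name__)

__all__ = [
    "Tractogram",
    "TractogramParseError",
    "as_streamline",
    "read_tractogram",
    "write_tractogram",
    "resample_streamline",
    "streamline_voxels",
    "visitation_map",
    "select_through_mask",
]


class TractogramParseError(ValueError):
    """Raised when a tractogram file cannot be parsed."""


def as_streamline(points) -> np.ndarray:
    """Validate and return a streamline as an (n, 3) float array.

    A streamline must have >= 2 finite points with consecutive points
    distinct (zero-length segments carry no direction information).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
        raise ValueError("streamline must be an (n>=2, 3) point array")
    if not np.all(np.isfinite(pts)):
        raise ValueError("streamline contains non-finite coordinates")
    seg = np.diff(pts, axis=0)
    if np.any(np.all(seg == 0, axis=1)):
        raise ValueError("streamline has duplicated consecutive points")
    return pts


@dataclass
class Tractogram:
    """A list of streamlines sharing one reference space.

    ``space`` is a free-form identifier of the grid the world coordinates
    refer to (all streamlines of one tractogram share it). The container
    may be empty.
    """

    streamlines: list[np.ndarray] = field(default_factory=list)
    space: str = "template"
    _voxel_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.streamlines = [as_streamline(s) for s in self.streamlines]

    def __len__(self) -> int:
        return len(self.streamlines)

    def __iter__(self):
        return iter(self.streamlines)


def _dialect_from_path(path: str, dialect: str | None) -> str:
    if dialect is not None:
        d = dialect.lower()
        if d not in ("trk", "tck"):
            raise ValueError(f"dialect must be 'trk' or 'tck', got {dialect!r}")
        return d
    p = str(path).lower()
    if p.endswith(".trk"):
        return "trk"
    if p.endswith(".tck"):
        return "tck"
    raise ValueError(f"cannot infer tractogram dialect from {path!r}")


def read_tractogram(path: str, dialect: str | None = None) -> Tractogram:
    """Read a TRK- or TCK-style tractogram file; coordinates in world mm."""
    d = _dialect_from_path(path, dialect)
    cls = TrkFile if d == "trk" else TckFile
    try:
        tf = cls.load(str(path), lazy_load=False)
    except Exception as exc:  # nibabel raises several header/data errors
        raise TractogramParseError(f"cannot parse {d} file {path}: {exc}") from exc
    streamlines = [np.asarray(s, dtype=float) for s in tf.tractogram.streamlines]
    return Tractogram(streamlines=streamlines)


def write_tractogram(
    t: Tractogram,
    path: str,
    dialect: str | None = None,
    grid: TemplateGrid | None = None,
) -> None:
    """Write a tractogram; TRK headers carry the grid geometry if given."""
    d = _dialect_from_path(path, dialect)
    nt = _NibTractogram(list(t.streamlines), affine_to_rasmm=np.eye(4))
    header = {}
    if d == "trk" and grid is not None:
        header = {
            "voxel_to_rasmm": grid.affine.astype(np.float32),
            "voxel_sizes": grid.voxel_size.astype(np.float32),
            "dimensions": np.asarray(grid.shape, dtype=np.int16),
            "voxel_order": "RAS",
        }
    cls = TrkFile if d == "trk" else TckFile
    cls(nt, header=header or None).save(str(path))


def read_volume(path: str) -> tuple[np.ndarray, np.ndarray]:
    """Read a 3-D NIfTI volume; returns ``(data, affine)``."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D volume, got {data.ndim}-D in {path}")
    return data, np.asarray(img.affine, dtype=float)


def write_volume(volume: np.ndarray, affine: np.ndarray, path: str) -> None:
    """Write a 3-D volume as NIfTI, preserving dtype (bool saved as uint8)."""
    vol = np.asarray(volume)
    if vol.ndim != 3:
        raise ValueError(f"expected a 3-D volume, got {vol.ndim}-D")
    if vol.dtype == bool:
        vol = vol.astype(np.uint8)
    nib.save(nib.Nifti1Image(vol, np.asarray(affine, dtype=float)), str(path))


def resample_streamline(points: np.ndarray, step: float) -> np.ndarray:
    """Subdivide a polyline so consecutive points are at most ``step`` apart.

    Every input vertex is kept (so the output lies exactly on the input
    polyline and the arc length is unchanged); each segment of length L is
    split into ``ceil(L / step)`` equal pieces.
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    pts = as_streamline(points)
    out = [pts[0]]
    for a, b in zip(pts[:-1], pts[1:]):
        length = float(np.linalg.norm(b - a))
        n = max(1, int(np.ceil(length / step)))
        frac = np.arange(1, n + 1, dtype=float)[:, None] / n
        out.extend(a + frac * (b - a))
    return np.asarray(out)


def default_step(grid: TemplateGrid) -> float:
    """Default resampling step: a quarter of the smallest voxel edge.

    Dense enough that a streamline cannot cross a voxel diagonally
    without depositing at least one sample in it.
    """
    return 0.25 * float(np.min(grid.voxel_size))


def streamline_voxels(
    points: np.ndarray, grid: TemplateGrid, step: float | None = None
) -> set[tuple[int, int, int]]:
    """The set of 0-based voxel indices a streamline visits.

    The streamline is resampled at ``step`` (default a quarter voxel; at
    most half the smallest voxel edge, enforced) and each sample is
    assigned to the voxel whose center is nearest. Samples outside the
    grid are dropped (logged, not an error).
    """
    if step is None:
        step = default_step(grid)
    max_step = 0.5 * float(np.min(grid.voxel_size))
    if step > max_step:
        raise ValueError(
            f"step {step} exceeds half the smallest voxel size ({max_step}); "
            "coarser sampling can skip voxels on diagonal crossings"
        )
    dense = resample_streamline(points, step)
    ijk = grid.nearest_voxel(dense)
    ok = grid.inside(ijk)
    n_out = int((~ok).sum())
    if n_out:
        logger.debug("dropped %d streamline samples outside the grid", n_out)
    return {tuple(int(v) for v in row) for row in ijk[ok]}


def _flat_voxels(points: np.ndarray, grid: TemplateGrid, step: float) -> np.ndarray:
    """Unique linear voxel indices a streamline visits (internal fast path)."""
    dense = resample_streamline(points, step)
    ijk = grid.nearest_voxel(dense)
    ijk = ijk[grid.inside(ijk)]
    if len(ijk) == 0:
        return np.empty(0, dtype=np.int64)
    return np.unique(np.ravel_multi_index(ijk.T, grid.shape))


def tractogram_flat_voxels(
    t: Tractogram, grid: TemplateGrid, step: float | None = None
) -> list[np.ndarray]:
    """Per-streamline unique linear voxel indices, cached on the tractogram.

    The voxelisation depends only on (streamlines, grid, step), so it is
    computed once per tractogram and reused across every lesion the
    tractogram is intersected with.
    """
    if step is None:
        step = default_step(grid)
    key = (grid.shape, grid.affine.tobytes(), float(step))
    cached = t._voxel_cache.get(key)
    if cached is None:
        cached = [_flat_voxels(s, grid, step) for s in t]
        t._voxel_cache[key] = cached
    return cached


def visitation_map(
    t: Tractogram, grid: TemplateGrid, step: float | None = None
) -> np.ndarray:
    """Per-voxel count of streamlines visiting each voxel.

    Each streamline contributes at most 1 to any voxel, regardless of how
    many of its points fall there.
    """
    counts = np.zeros(int(np.prod(grid.shape)), dtype=np.int64)
    flat = tractogram_flat_voxels(t, grid, step)
    if flat:
        np.add.at(counts, np.concatenate(flat), 1)
    return counts.reshape(grid.shape)


def select_through_mask(
    t: Tractogram, mask: np.ndarray, grid: TemplateGrid, step: float | None = None
) -> Tractogram:
    """Streamlines whose voxel set intersects a binary mask, order preserved.

    This is the lesion-seeding emulation: instead of seeding tractography
    from the lesion, whole-brain normative streamlines are filtered down
    to those passing through lesioned voxels — the same selection
    criterion without a tractography engine.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.shape != grid.shape:
        raise ValueError(f"mask shape {mask.shape} != grid shape {grid.shape}")
    flat_mask = mask.ravel()
    flat = tractogram_flat_voxels(t, grid, step)
    kept = [s for s, v in zip(t.streamlines, flat) if flat_mask[v].any()]
    return Tractogram(streamlines=kept, space=t.space)
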