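"""Synthetic phantoms: template grids, fiber bundles, lesions, and a cohort.

Everything downstream of raw data collection is testable on phantoms from
this module:

* **Bundles and controls** — parametric fiber bundles (a centerline plus
  transverse Gaussian spread) realised as streamline sets, replicated into
  N pseudo-control tractograms with optional per-control rigid jitter
  standing in for imperfect template-to-native registration.
* **Lesions** — spherical binary masks defined by voxel-center-in-sphere
  membership (orientation-free and unambiguous).
* **Cohort** — a longitudinal multicenter table (two visits, four centers,
  three phenotype and three treatment classes) whose global-disconnectome
  response is generated from an explicit linear mixed model
  ``y = Xb + b_subject + b_center + eps`` with configurable planted
  effects, so the downstream model fits can be checked against ground
  truth. Serum NfL is drawn right-skewed (lognormal) with optional
  injected extreme values to exercise the outlier rule; T2 lesion volume
  is generated as a noisy monotone companion of the response so the
  GD-T2LV association and its quadratic fit have realistic structure.

All generators are pure functions of (configuration, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .grid import TemplateGrid
from .tractogram import Tractogram, as_streamline, resample_streamline

__all__ = [
    "BundleSpec",
    "CohortSimConfig",
    "generate_bundle",
    "generate_controls",
    "generate_lesion",
    "generate_cohort",
    "generate_cohort_table",
    "write_cohort_table",
    "read_cohort_table",
    "load_cohort_config",
]

CENTER_NAMES = ("Barcelona", "Oslo", "Berlin", "Genoa")
PHENOTYPES = ("CIS", "RRMS", "PMS")
TREATMENTS = ("none", "effective", "highly-effective")

#: TSV column order of the cohort table.
COHORT_COLUMNS = [
    "subject_id", "center", "timepoint", "age", "sex", "disease_duration",
    "phenotype", "treatment", "snfl", "edss", "gd", "t2lv",
]


@dataclass(frozen=True)
class BundleSpec:
    """A fiber bundle: centerline polyline (world mm) plus transverse spread."""

    centerline: np.ndarray
    n_streamlines: int = 50
    radial_spread: float = 1.0
    step: float = 0.5

    def __post_init__(self) -> None:
        object.__setattr__(self, "centerline", as_streamline(self.centerline))
        if self.n_streamlines < 1:
            raise ValueError("n_streamlines must be >= 1")
        if self.step <= 0:
            raise ValueError("step must be > 0")
        if self.radial_spread < 0:
            raise ValueError("radial_spread must be >= 0")


def _check_in_bounds(points: np.ndarray, grid: TemplateGrid, what: str) -> None:
    lo, hi = grid.world_bounds()
    if np.any(points < lo) or np.any(points > hi):
        raise ValueError(f"{what} exits the grid world bounds {lo}..{hi}")


def generate_bundle(
    grid: TemplateGrid, spec: BundleSpec, rng: np.random.Generator
) -> list[np.ndarray]:
    """Realise one bundle as streamlines offset from its centerline.

    Each streamline is the resampled centerline shifted by a Gaussian
    offset perpendicular to the bundle's chord direction (SD =
    ``radial_spread`` mm). Offsets are clipped so no point leaves the
    grid; the centerline itself must lie inside the grid.
    """
    _check_in_bounds(spec.centerline, grid, "bundle centerline")
    center = resample_streamline(spec.centerline, spec.step)
    chord = spec.centerline[-1] - spec.centerline[0]
    chord = chord / np.linalg.norm(chord)
    lo, hi = grid.world_bounds()
    out = []
    for _ in range(spec.n_streamlines):
        offset = rng.normal(0.0, spec.radial_spread, size=3)
        offset -= chord * (offset @ chord)  # transverse only
        out.append(np.clip(center + offset, lo, hi))
    return out


def generate_controls(
    grid: TemplateGrid,
    bundles: list[BundleSpec],
    n_controls: int = 10,
    jitter: float = 0.0,
    seed: int = 0,
) -> list[Tractogram]:
    """N pseudo-control tractograms sharing one bundle geometry.

    The bundle realisation (per-streamline offsets) is drawn once; each
    control then receives an independent rigid translation with SD
    ``jitter`` mm, emulating residual registration variability. With
    ``jitter=0`` all controls are identical.
    """
    if n_controls < 1:
        raise ValueError("n_controls must be >= 1")
    if jitter < 0:
        raise ValueError("jitter must be >= 0")
    rng = np.random.default_rng(seed)
    base = []
    for spec in bundles:
        base.extend(generate_bundle(grid, spec, rng))
    lo, hi = grid.world_bounds()
    controls = []
    for _ in range(n_controls):
        shift = rng.normal(0.0, jitter, size=3) if jitter > 0 else np.zeros(3)
        controls.append(
            Tractogram(streamlines=[np.clip(s + shift, lo, hi) for s in base])
        )
    return controls


def generate_lesion(
    grid: TemplateGrid, center, radius: float, seed: int = 0
) -> np.ndarray:
    """Spherical binary lesion mask: voxels whose center is within ``radius``.

    ``seed`` is accepted for interface uniformity; the sphere itself is
    deterministic in (grid, center, radius).
    """
    del seed
    if radius <= 0:
        raise ValueError("radius must be > 0")
    center = np.asarray(center, dtype=float)
    _check_in_bounds(center[None, :], grid, "lesion center")
    centers = grid.voxel_centers()
    dist = np.linalg.norm(centers - center, axis=1)
    mask = (dist <= radius).reshape(grid.shape)
    if not mask.any():
        raise ValueError(
            f"sphere of radius {radius} mm at {center} contains no voxel centers"
        )
    return mask


# ---------------------------------------------------------------------------
# Cohort simulation


@dataclass
class CohortSimConfig:
    """Planted-effect configuration for the longitudinal cohort generator.

    Effects are coefficients of the generating model for the global
    disconnectome response: continuous covariates enter z-scored, timepoint
    is coded 0/1 (baseline / follow-up), and center shifts are fixed
    intercept offsets per center relative to the first. Defaults are the
    magnitudes typical of multicenter MS disconnectome-biomarker cohorts
    (NfL +0.03, timepoint -0.04, interaction -0.01; center means around
    0.2-0.4, subject SD 0.16, near-zero residual).
    """

    n_subjects: int = 300
    n_centers: int = 4
    timepoints: int = 2
    beta_nfl_gd: float = 0.03
    beta_time: float = -0.04
    beta_interaction: float = -0.01
    beta_age: float = 0.18
    beta_duration: float = 0.14
    intercept: float = 0.30
    center_shifts: tuple = (0.0, -0.06, -0.10, 0.08)
    subject_sd: float = 0.16
    center_sd: float = 0.0
    noise_sd: float = 0.02
    n_nfl_outliers: int = 0
    nfl_outlier_factor: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_centers < 1 or self.n_centers > len(CENTER_NAMES):
            raise ValueError(f"n_centers must be in 1..{len(CENTER_NAMES)}")
        if self.timepoints < 1:
            raise ValueError("timepoints must be >= 1")
        if self.timepoints > 2:
            raise NotImplementedError(
                "only the two-visit (baseline/follow-up) design is supported"
            )
        for name in ("subject_sd", "center_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        shifts = tuple(float(s) for s in self.center_shifts)
        if len(shifts) < self.n_centers:
            raise ValueError("center_shifts shorter than n_centers")
        self.center_shifts = shifts


def load_cohort_config(path: str) -> CohortSimConfig:
    """Read a CohortSimConfig from YAML or JSON; ``seed`` is mandatory."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) if not str(path).endswith(".json") else json.load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    if "seed" not in raw:
        raise ValueError("cohort config must set an explicit seed")
    return CohortSimConfig(**raw)


def _zscore_pop(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std(ddof=1)


def _edss_grid(x: np.ndarray) -> np.ndarray:
    return np.clip(np.round(2 * x) / 2, 0.0, 10.0)


def generate_cohort_table(cfg: CohortSimConfig) -> pd.DataFrame:
    """Longitudinal cohort table with the configured planted effects.

    The ``gd`` column is the modelled response itself (not passed through
    an image pipeline), so fixed effects are recoverable exactly up to
    sampling noise; it is not clipped to [0, 1] because truncation would
    bias the recovery loop. EDSS trajectories include worsening, stable
    and improving cases by construction.
    """
    rng = np.random.default_rng(cfg.seed)
    n, T = cfg.n_subjects, cfg.timepoints
    centers = np.array(CENTER_NAMES[: cfg.n_centers])
    center_ix = rng.integers(0, cfg.n_centers, size=n)
    age = np.clip(rng.normal(45.0, 11.0, size=n), 18.0, 80.0)
    sex = rng.choice(["F", "M"], size=n, p=[0.7, 0.3])
    duration = np.clip(rng.lognormal(np.log(7.0), 0.7, size=n), 0.1, 45.0)
    phenotype = rng.choice(PHENOTYPES, size=n, p=[0.10, 0.72, 0.18])
    treatment = rng.choice(TREATMENTS, size=n, p=[0.30, 0.40, 0.30])

    # serum NfL: lognormal baseline, correlated follow-up, optional extremes
    snfl = np.empty((n, T))
    snfl[:, 0] = rng.lognormal(np.log(10.0), 0.5, size=n)
    for t in range(1, T):
        snfl[:, t] = snfl[:, 0] * rng.lognormal(0.0, 0.3, size=n)
    if cfg.n_nfl_outliers > 0:
        # extremes anchored at a multiple of the typical level, so they sit
        # clearly beyond mean + 3 SD even after they inflate both moments
        flat = rng.choice(n * T, size=cfg.n_nfl_outliers, replace=False)
        snfl.reshape(-1)[flat] = cfg.nfl_outlier_factor * np.median(snfl)

    b_subject = rng.normal(0.0, cfg.subject_sd, size=n) if cfg.subject_sd > 0 else np.zeros(n)
    b_center = (
        rng.normal(0.0, cfg.center_sd, size=cfg.n_centers)
        if cfg.center_sd > 0 else np.zeros(cfg.n_centers)
    )

    # EDSS: baseline on the half-point grid; follow-up mixes worsening,
    # stable and improving trajectories
    edss0 = _edss_grid(np.abs(rng.normal(2.5, 1.5, size=n)))
    traj = rng.choice(["worse", "stable", "improve"], size=n, p=[0.20, 0.65, 0.15])
    delta = np.where(
        traj == "worse", rng.choice([1.0, 1.5, 2.0], size=n),
        np.where(traj == "improve", -1.0, rng.choice([-0.5, 0.0, 0.5], size=n)),
    )
    edss1 = _edss_grid(edss0 + delta)

    rows = []
    z_nfl_all = _zscore_pop(snfl.reshape(-1)).reshape(n, T)
    z_age = _zscore_pop(age)
    z_dur = _zscore_pop(duration)
    eps = rng.normal(0.0, cfg.noise_sd, size=(n, T)) if cfg.noise_sd > 0 else np.zeros((n, T))
    # noise scale calibrated so the baseline GD-T2LV Pearson r sits near
    # the ~0.8 level typical of lesion-volume/disconnection data
    t2lv_noise = rng.lognormal(0.0, 0.45, size=(n, T))
    for i in range(n):
        for t in range(T):
            gd = (
                cfg.intercept
                + cfg.beta_nfl_gd * z_nfl_all[i, t]
                + cfg.beta_time * t
                + cfg.beta_interaction * z_nfl_all[i, t] * t
                + cfg.beta_age * z_age[i]
                + cfg.beta_duration * z_dur[i]
                + cfg.center_shifts[center_ix[i]]
                + b_center[center_ix[i]]
                + b_subject[i]
                + eps[i, t]
            )
            # T2LV as a noisy monotone companion of GD (GD saturates with
            # volume, hence roughly GD ~ sqrt(T2LV))
            t2lv = (max(gd, 0.02) / 0.103) ** 2 * t2lv_noise[i, t]
            rows.append(
                {
                    "subject_id": f"S{i:04d}",
                    "center": centers[center_ix[i]],
                    "timepoint": t,
                    "age": age[i],
                    "sex": sex[i],
                    "disease_duration": duration[i],
                    "phenotype": phenotype[i],
                    "treatment": treatment[i],
                    "snfl": snfl[i, t],
                    "edss": edss0[i] if t == 0 else edss1[i],
                    "gd": gd,
                    "t2lv": t2lv,
                }
            )
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def generate_cohort(
    cfg: CohortSimConfig,
    grid: TemplateGrid | None = None,
    controls: list[Tractogram] | None = None,
) -> tuple[pd.DataFrame, dict | None]:
    """Cohort table plus, if a grid and controls are given, lesion masks.

    Lesion masks are spherical, centered on randomly chosen points of the
    control streamlines (so each lesion intersects the normative bundles
    and yields a nonempty disconnectome), with radii increasing with the
    subject's T2 lesion volume rank. Returns ``(table, masks)`` where
    ``masks`` maps ``(subject_id, timepoint)`` to a binary volume, or
    ``None`` when no grid was supplied.
    """
    table = generate_cohort_table(cfg)
    if grid is None:
        return table, None
    if not controls:
        raise ValueError("need at least one control tractogram to place lesions")
    rng = np.random.default_rng(cfg.seed + 1)
    all_points = np.vstack([s for c in controls for s in c.streamlines])
    ranks = table["t2lv"].rank(pct=True).to_numpy()
    masks: dict = {}
    for row, pct in zip(table.itertuples(index=False), ranks):
        radius = 1.5 + 3.5 * pct
        for _ in range(50):
            center = all_points[rng.integers(0, len(all_points))]
            try:
                masks[(row.subject_id, row.timepoint)] = generate_lesion(
                    grid, center, radius
                )
                break
            except ValueError:
                continue
        else:  # pragma: no cover - streamline points are in-bounds by construction
            raise RuntimeError("could not place a lesion on the control bundles")
    return table, masks


def write_cohort_table(table: pd.DataFrame, path: str) -> None:
    table.to_csv(path, sep="\t", index=False, columns=[c for c in COHORT_COLUMNS if c in table.columns])


def read_cohort_table(path: str) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = set(COHORT_COLUMNS[:8]) - set(table.columns)
    if missing:
        raise ValueError(f"cohort table {path} lacks columns: {sorted(missing)}")
    return table
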