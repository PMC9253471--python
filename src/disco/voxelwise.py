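"""Mass-univariate GLM over disconnectome maps with permutation inference.

Per-voxel ordinary least squares relates the stack of subjects'
disconnectome maps to serum NfL (the explanatory variable of interest)
while adjusting for age, sex, disease duration, diagnosis and treatment
(diagnosis and treatment are combined into joint dummy columns; empty
combinations are dropped). Spatial signal is boosted with threshold-free
cluster enhancement (TFCE), which integrates cluster extent e(h)^E times
height h^H over all thresholds h, and family-wise error is controlled by
the permutation max-statistic method under the Freedman-Lane scheme:
residuals of the nuisance-only model are permuted, the full model is
refit, and the maximum TFCE value per permutation forms the null.

Both one-sided contrasts (positive and negative NfL association) are
tested; each is reported at the configured FWER level.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.ndimage as ndi

from .cohort import add_zscored

logger = logging.getLogger(__name__)

__all__ = [
    "DesignMatrix",
    "TfceConfig",
    "VoxelwiseResult",
    "build_design",
    "glm_tmap",
    "tfce",
    "permutation_fwer",
]


@dataclass
class DesignMatrix:
    """Subject-by-term design with a named column of interest.

    ``X`` holds intercept, z-scored continuous covariates, sex, and joint
    diagnosis-x-treatment indicator columns (reference level and empty
    combinations dropped). ``interest`` names the column the contrasts
    test (the NfL column).
    """

    X: pd.DataFrame
    interest: str = "z_snfl"

    def __post_init__(self) -> None:
        if self.interest not in self.X.columns:
            raise ValueError(f"column of interest {self.interest!r} not in design")

    @property
    def names(self) -> list[str]:
        return list(self.X.columns)

    def contrast(self, sign: int = +1) -> np.ndarray:
        c = np.zeros(self.X.shape[1])
        c[self.names.index(self.interest)] = float(sign)
        return c

    def nuisance(self) -> np.ndarray:
        """Design with the column of interest removed (Freedman-Lane Z)."""
        return self.X.drop(columns=[self.interest]).to_numpy(dtype=float)

    def array(self) -> np.ndarray:
        return self.X.to_numpy(dtype=float)


def build_design(records: pd.DataFrame, interest: str = "z_snfl") -> DesignMatrix:
    """Baseline design matrix for the voxel-wise GLM.

    One row per subject (baseline records). Continuous covariates are
    z-scored; diagnosis (phenotype) and treatment are combined into joint
    categories so every observed phenotype-treatment condition gets its
    own indicator column, with the first observed combination as
    reference and unobserved combinations dropped. Raises on a
    rank-deficient result, listing the aliased columns.
    """
    data = records[records["timepoint"] == 0] if "timepoint" in records else records
    if data["subject_id"].duplicated().any():
        raise ValueError("expected one baseline record per subject")
    data = add_zscored(data)
    X = pd.DataFrame(index=data.index)
    X["intercept"] = 1.0
    X["z_snfl"] = data["z_snfl"]
    X["z_age"] = data["z_age"]
    X["z_disease_duration"] = data["z_disease_duration"]
    X["sex_F"] = (data["sex"] == "F").astype(float)
    combo = data["phenotype"].astype(str) + "*" + data["treatment"].astype(str)
    levels = sorted(combo.unique())  # empty combinations never appear
    for level in levels[1:]:  # first observed combination is the reference
        X[f"dx_tx[{level}]"] = (combo == level).astype(float)
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        _, _, piv = scipy.linalg.qr(arr, pivoting=True, mode="economic")
        aliased = sorted(X.columns[i] for i in piv[rank:])
        raise ValueError(f"rank-deficient design; aliased columns: {aliased}")
    return DesignMatrix(X=X, interest=interest)


def glm_tmap(
    Y: np.ndarray, X: np.ndarray, contrast: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel OLS t-statistic for a contrast.

    ``Y`` is subjects x voxels, ``X`` subjects x terms. Voxels with zero
    residual variance get t = 0 and are flagged in the returned boolean
    array (a response column exactly collinear with the model has no
    finite t).
    """
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    c = np.asarray(contrast, dtype=float)
    n, k = X.shape
    pinv = np.linalg.pinv(X)
    beta = pinv @ Y
    resid = Y - X @ beta
    dof = n - np.linalg.matrix_rank(X)
    if dof <= 0:
        raise ValueError("no residual degrees of freedom")
    sigma2 = (resid**2).sum(axis=0) / dof
    var_c = float(c @ (pinv @ pinv.T) @ c)
    effect = c @ beta
    # numerically-zero residual variance (response inside the column span)
    flat = sigma2 <= 100 * np.finfo(float).eps * (Y**2).mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(flat, 0.0, effect / np.sqrt(sigma2 * var_c))
    if flat.any():
        logger.warning("%d voxels with zero residual variance; t set to 0", flat.sum())
    return t, flat


@dataclass(frozen=True)
class TfceConfig:
    """TFCE parameters: height exponent H, extent exponent E, step dh,
    and neighbourhood connectivity (6, 18 or 26 in 3-D)."""

    H: float = 2.0
    E: float = 0.5
    dh: float = 0.1
    connectivity: int = 26

    def __post_init__(self) -> None:
        if self.H < 0 or self.E < 0:
            raise ValueError("H and E must be >= 0")
        if self.dh <= 0:
            raise ValueError("dh must be > 0")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")

    def structure(self) -> np.ndarray:
        order = {6: 1, 18: 2, 26: 3}[self.connectivity]
        return ndi.generate_binary_structure(3, order)


def _tfce_one_sided(stat: np.ndarray, mask: np.ndarray, cfg: TfceConfig) -> np.ndarray:
    """Sum e(h,v)^E * h^H * dh over thresholds h = dh, 2dh, ... <= stat(v)."""
    out = np.zeros_like(stat, dtype=float)
    vmax = float(stat[mask].max(initial=0.0))
    if vmax < cfg.dh:
        return out
    structure = cfg.structure()
    n_steps = int(np.floor(vmax / cfg.dh + 1e-12))
    for i in range(1, n_steps + 1):
        h = i * cfg.dh
        sup = (stat >= h - 1e-12) & mask
        if not sup.any():
            break
        labels, n_lab = ndi.label(sup, structure=structure)
        sizes = np.bincount(labels.ravel())
        out[sup] += sizes[labels[sup]] ** cfg.E * h**cfg.H * cfg.dh
    return out


def tfce(
    stat_map: np.ndarray,
    mask: np.ndarray,
    cfg: TfceConfig | None = None,
    two_sided: bool = True,
) -> np.ndarray:
    """Threshold-free cluster enhancement of a statistic map within a mask.

    Positive values are enhanced on the map itself; with ``two_sided``,
    negative values are enhanced on the negated map and returned with
    negative sign, so the output preserves the sign of the input.
    """
    cfg = cfg or TfceConfig()
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty analysis mask")
    stat = np.asarray(stat_map, dtype=float)
    if not np.all(np.isfinite(stat[mask])):
        raise ValueError("non-finite statistic values inside the mask")
    out = _tfce_one_sided(np.where(mask, stat, 0.0), mask, cfg)
    if two_sided:
        out -= _tfce_one_sided(np.where(mask, -stat, 0.0), mask, cfg)
    return out


@dataclass
class VoxelwiseResult:
    """t-map, TFCE maps and FWER-corrected p-maps for both NfL contrasts."""

    t_map: np.ndarray
    tfce_pos: np.ndarray
    tfce_neg: np.ndarray
    fwer_p_pos: np.ndarray
    fwer_p_neg: np.ndarray
    null_max_pos: np.ndarray
    null_max_neg: np.ndarray
    mask: np.ndarray
    n_perm: int
    exhaustive: bool = False

    def significant(self, alpha: float = 0.05, contrast: str = "pos") -> np.ndarray:
        p = self.fwer_p_pos if contrast == "pos" else self.fwer_p_neg
        return (p < alpha) & self.mask


def _t_factory(X: np.ndarray, contrast: np.ndarray):
    """Precompute the OLS pieces so each permutation is two matmuls."""
    pinv = np.linalg.pinv(X)
    hat = X @ pinv
    cpinv = contrast @ pinv
    var_c = float(contrast @ (pinv @ pinv.T) @ contrast)
    dof = X.shape[0] - np.linalg.matrix_rank(X)

    def tmap(Y: np.ndarray) -> np.ndarray:
        resid = Y - hat @ Y
        sigma2 = (resid**2).sum(axis=0) / dof
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(sigma2 <= 0, 0.0, (cpinv @ Y) / np.sqrt(sigma2 * var_c))

    return tmap


def permutation_fwer(
    maps: np.ndarray,
    design: DesignMatrix,
    mask: np.ndarray,
    n_perm: int = 5000,
    cfg: TfceConfig | None = None,
    seed: int = 0,
    alpha: float = 0.05,
) -> VoxelwiseResult:
    """Freedman-Lane max-TFCE permutation test for both NfL contrasts.

    ``maps`` is a (subjects, *volume) stack aligned with the design rows.
    Nuisance-model residuals are permuted, added back to the nuisance
    fit, and the full-model t-map is TFCE-enhanced; the maximum enhanced
    value inside the mask per permutation forms the null distribution,
    separately for the positive and negative contrast. p-values use the
    (1 + exceedances) / (1 + n_perm) estimator so they are never zero.
    When every distinct relabelling can be enumerated within ``n_perm``,
    the exact exhaustive null is used instead (logged).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    cfg = cfg or TfceConfig()
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty analysis mask")
    maps = np.asarray(maps, dtype=float)
    n = maps.shape[0]
    shape = maps.shape[1:]
    if shape != mask.shape:
        raise ValueError(f"map shape {shape} != mask shape {mask.shape}")
    X = design.array()
    if X.shape[0] != n:
        raise ValueError("design rows do not match number of maps")
    Y = maps.reshape(n, -1)[:, mask.ravel()]

    tmap_fn = _t_factory(X, design.contrast(+1))

    def enhance(t_flat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        vol = np.zeros(shape)
        vol[mask] = t_flat
        pos = _tfce_one_sided(np.where(mask, vol, 0.0), mask, cfg)
        neg = _tfce_one_sided(np.where(mask, -vol, 0.0), mask, cfg)
        return pos, neg

    t_obs = tmap_fn(Y)
    tfce_pos_obs, tfce_neg_obs = enhance(t_obs)

    # Freedman-Lane: permute residuals of the nuisance-only model
    Z = design.nuisance()
    hat_z = Z @ np.linalg.pinv(Z)
    fitted_z = hat_z @ Y
    resid_z = Y - fitted_z

    exhaustive = math.factorial(n) <= n_perm
    if exhaustive:
        perms = [np.asarray(p) for p in itertools.permutations(range(n))]
        logger.info(
            "requested %d permutations >= %d distinct relabelings; "
            "enumerating exhaustively", n_perm, len(perms),
        )
    else:
        rng = np.random.default_rng(seed)
        perms = [rng.permutation(n) for _ in range(n_perm)]

    null_pos = np.empty(len(perms))
    null_neg = np.empty(len(perms))
    for j, perm in enumerate(perms):
        t_perm = tmap_fn(fitted_z + resid_z[perm])
        pos, neg = enhance(t_perm)
        null_pos[j] = pos[mask].max(initial=0.0)
        null_neg[j] = neg[mask].max(initial=0.0)

    def pmap(obs: np.ndarray, null: np.ndarray) -> np.ndarray:
        exceed = (null[None, :] >= obs[mask][:, None]).sum(axis=1)
        if exhaustive:
            p_in = exceed / len(null)
        else:
            p_in = (1 + exceed) / (1 + len(null))
        out = np.ones(shape)
        out[mask] = p_in
        return out

    t_vol = np.zeros(shape)
    t_vol[mask] = t_obs
    return VoxelwiseResult(
        t_map=t_vol,
        tfce_pos=tfce_pos_obs,
        tfce_neg=tfce_neg_obs,
        fwer_p_pos=pmap(tfce_pos_obs, null_pos),
        fwer_p_neg=pmap(tfce_neg_obs, null_neg),
        null_max_pos=null_pos,
        null_max_neg=null_neg,
        mask=mask,
        n_perm=len(perms),
        exhaustive=exhaustive,
    )
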