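"""End-to-end orchestration: simulate -> map -> gd -> cohort -> lmm -> voxelwise.

Each stage reads and writes files under the run's output directory, so
stages are independently inspectable and restartable, and a manifest
(config echo, input hashes, stage timings, package version) makes a run
reproducible: identical config and seed give numerically identical
outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.ndimage
import yaml

from . import __version__
from .grid import TemplateGrid
from .tractogram import (
    Tractogram, read_tractogram, write_tractogram, read_volume, write_volume,
)
from .synthetic import (
    BundleSpec, CohortSimConfig, generate_controls, generate_cohort,
    write_cohort_table, read_cohort_table,
)
from .disconnectome import (
    DisconnectomeMap, disconnectome_map, threshold_map, build_wm_mask,
    global_disconnectome, lesion_volume_ml,
)
from .cohort import (
    fit_cross_sectional, classify_edss_change, remove_nfl_outliers,
    gd_t2lv_association,
)
from .lmm import LmmSpec, fit_lmm, fit_lmm_interaction, fit_robust_lmm
from .voxelwise import TfceConfig, build_design, permutation_fwer

logger = logging.getLogger(__name__)

STAGES = ("simulate", "map", "gd", "cohort", "lmm", "voxelwise")


@dataclass
class RunConfig:
    """Configuration of a full synthetic pipeline run.

    All randomness derives from ``seed``; the config round-trips through
    YAML losslessly.
    """

    output_dir: str
    seed: int
    grid_n: int = 32
    voxel_size: float = 1.0
    n_controls: int = 10
    control_jitter: float = 0.5
    n_subjects: int = 30
    cutoff: float = 0.5
    n_perm: int = 500
    tfce_h: float = 2.0
    tfce_e: float = 0.5
    tfce_dh: float = 0.1
    tfce_connectivity: int = 26
    lmm_center: str = "fixed"
    cohort: dict = field(default_factory=dict)  # CohortSimConfig overrides

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("config must set an explicit seed")
        self.seed = int(self.seed)

    @classmethod
    def from_file(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ValueError(f"config {path} must be a mapping")
        if "seed" not in raw:
            raise ValueError("config must set an explicit seed")
        return cls(**raw)

    def to_file(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def grid(self) -> TemplateGrid:
        return TemplateGrid.isotropic(self.grid_n, self.voxel_size)

    def tfce(self) -> TfceConfig:
        return TfceConfig(
            H=self.tfce_h, E=self.tfce_e, dh=self.tfce_dh,
            connectivity=self.tfce_connectivity,
        )

    def cohort_config(self) -> CohortSimConfig:
        kw = {"n_subjects": self.n_subjects, "seed": self.seed, **self.cohort}
        return CohortSimConfig(**kw)


def default_bundles(grid: TemplateGrid) -> list[BundleSpec]:
    """Two crossing fiber bundles spanning the phantom grid."""
    lo, hi = grid.world_bounds()
    mid = 0.5 * (lo + hi)
    span0, span1 = lo + 0.15 * (hi - lo), hi - 0.15 * (hi - lo)
    b1 = BundleSpec(
        centerline=np.array([[span0[0], mid[1], mid[2]], [span1[0], mid[1], mid[2]]]),
        n_streamlines=50, radial_spread=2.0,
    )
    b2 = BundleSpec(
        centerline=np.array([[mid[0], span0[1], span0[2]], [mid[0], span1[1], span1[2]]]),
        n_streamlines=50, radial_spread=2.0,
    )
    return [b1, b2]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages in order and return the run manifest."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logfile = out / "run.log"
    handler = logging.FileHandler(logfile)
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("disco")
    root.addHandler(handler)
    manifest: dict = {
        "version": __version__, "config": asdict(cfg), "stages": {}, "outputs": {},
    }
    state: dict = {}
    try:
        for stage in STAGES:
            t0 = time.perf_counter()
            logger.info("stage %s: start", stage)
            try:
                globals()[f"_stage_{stage}"](cfg, out, state)
            except Exception as exc:
                raise PipelineError(stage, exc) from exc
            manifest["stages"][stage] = {
                "status": "complete",
                "seconds": round(time.perf_counter() - t0, 3),
            }
            logger.info("stage %s: complete", stage)
    finally:
        root.removeHandler(handler)
        handler.close()
    for f in sorted(out.rglob("*")):
        if f.is_file() and f.name not in ("manifest.json", "run.log"):
            manifest["outputs"][str(f.relative_to(out))] = _sha256(f)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _stage_simulate(cfg: RunConfig, out: Path, state: dict) -> None:
    grid = cfg.grid()
    controls = generate_controls(
        grid, default_bundles(grid), cfg.n_controls, cfg.control_jitter, cfg.seed
    )
    cdir = out / "controls"
    cdir.mkdir(exist_ok=True)
    for i, t in enumerate(controls):
        write_tractogram(t, str(cdir / f"control_{i:02d}.trk"), grid=grid)
    table, masks = generate_cohort(cfg.cohort_config(), grid, controls)
    write_cohort_table(table, str(out / "cohort.tsv"))
    ldir = out / "lesions"
    ldir.mkdir(exist_ok=True)
    for (sid, tp), mask in masks.items():
        write_volume(mask, grid.affine, str(ldir / f"{sid}_t{tp}.nii"))
    state.update(grid=grid, controls=controls, table=table, masks=masks)


def _stage_map(cfg: RunConfig, out: Path, state: dict) -> None:
    grid, controls, masks = state["grid"], state["controls"], state["masks"]
    mdir = out / "maps"
    mdir.mkdir(exist_ok=True)
    dmaps: dict = {}
    for (sid, tp), lesion in masks.items():
        d = disconnectome_map(lesion, controls, grid)
        write_volume(d.prob.astype(np.float32), grid.affine, str(mdir / f"{sid}_t{tp}.nii"))
        dmaps[(sid, tp)] = d
    state["dmaps"] = dmaps


def _stage_gd(cfg: RunConfig, out: Path, state: dict) -> None:
    grid, masks, dmaps = state["grid"], state["masks"], state["dmaps"]
    thresholded = {k: threshold_map(d, cfg.cutoff) for k, d in dmaps.items()}
    wm = build_wm_mask(list(thresholded.values()))
    write_volume(wm, grid.affine, str(out / "wm_mask.nii"))
    rows = [
        {
            "subject_id": sid,
            "timepoint": tp,
            "gd": global_disconnectome(thresholded[(sid, tp)], wm),
            "t2lv": lesion_volume_ml(masks[(sid, tp)], grid),
        }
        for (sid, tp) in sorted(thresholded)
    ]
    pd.DataFrame(rows).to_csv(out / "gd.tsv", sep="\t", index=False, float_format="%.10g")
    state["wm"] = wm
    state["thresholded"] = thresholded


def _load_analysis_table(out: Path) -> pd.DataFrame:
    table = read_cohort_table(str(out / "cohort.tsv"))
    if "gd" not in table.columns or "t2lv" not in table.columns:
        gd = pd.read_csv(out / "gd.tsv", sep="\t")
        table = table.merge(gd, on=["subject_id", "timepoint"], how="left")
    return table


def _stage_cohort(cfg: RunConfig, out: Path, state: dict) -> None:
    table = _load_analysis_table(out)
    for response in ("gd", "t2lv"):
        fit_cross_sectional(table, response).to_csv(
            out / f"cross_sectional_{response}.tsv", sep="\t", float_format="%.6g"
        )
    base = table[table["timepoint"] == 0].set_index("subject_id")
    follow = table[table["timepoint"] == 1].set_index("subject_id")
    common = base.index.intersection(follow.index)
    changes = pd.Series(
        [classify_edss_change(base.loc[s, "edss"], follow.loc[s, "edss"]) for s in common],
        index=common, name="edss_change",
    )
    changes.to_csv(out / "edss_change.tsv", sep="\t")
    _, removed = remove_nfl_outliers(table["snfl"].to_numpy())
    assoc = gd_t2lv_association(table[table["timepoint"] == 0])
    with open(out / "cohort_summary.json", "w") as fh:
        json.dump(
            {
                "n_records": len(table),
                "edss_change_counts": changes.value_counts().to_dict(),
                "n_nfl_outliers_flagged": int(removed.size),
                "gd_t2lv_r": assoc.r,
                "gd_t2lv_quadratic_coef": list(map(float, assoc.coef)),
            },
            fh, indent=2, sort_keys=True,
        )
    state["table"] = table


def _stage_lmm(cfg: RunConfig, out: Path, state: dict) -> None:
    table = state["table"]
    spec = LmmSpec(response="gd", center=cfg.lmm_center)
    for name, fit in (
        ("lmm_gd", fit_lmm(table, spec)),
        ("lmm_gd_interaction", fit_lmm_interaction(table, spec)),
        ("rlmm_gd_interaction", fit_robust_lmm(
            table, LmmSpec(response="gd", interaction=True, center=cfg.lmm_center))),
    ):
        fit.params.to_csv(out / f"{name}.tsv", sep="\t", float_format="%.6g")
        logger.info(
            "%s: converged=%s method=%s vc=%s", name, fit.converged, fit.method,
            fit.variance_components,
        )


def _stage_voxelwise(cfg: RunConfig, out: Path, state: dict) -> None:
    table, wm, dmaps = state["table"], state["wm"], state["dmaps"]
    base = table[table["timepoint"] == 0].reset_index(drop=True)
    # NfL outlier removal precedes the GLM
    _, removed = remove_nfl_outliers(base["snfl"].to_numpy())
    base = base.drop(index=removed).reset_index(drop=True)
    design = build_design(base)
    maps = np.stack([dmaps[(sid, 0)].prob for sid in base["subject_id"]])
    result = permutation_fwer(
        maps, design, wm, n_perm=cfg.n_perm, cfg=cfg.tfce(), seed=cfg.seed
    )
    grid = state["grid"]
    vdir = out / "voxelwise"
    vdir.mkdir(exist_ok=True)
    write_volume(result.t_map.astype(np.float32), grid.affine, str(vdir / "tstat.nii"))
    for name, vol in (
        ("tfce_pos", result.tfce_pos), ("tfce_neg", result.tfce_neg),
        ("one_minus_p_pos", 1.0 - result.fwer_p_pos),
        ("one_minus_p_neg", 1.0 - result.fwer_p_neg),
    ):
        write_volume(vol.astype(np.float32), grid.affine, str(vdir / f"{name}.nii"))
    rows = []
    for contrast in ("pos", "neg"):
        sig = result.significant(contrast=contrast)
        labels, n_lab = scipy.ndimage.label(sig, structure=cfg.tfce().structure())
        for lab in range(1, n_lab + 1):
            inside = labels == lab
            peak = np.unravel_index(
                np.argmax(np.abs(result.t_map) * inside), inside.shape
            )
            rows.append(
                {
                    "contrast": contrast,
                    "cluster": lab,
                    "n_voxels": int(inside.sum()),
                    "peak_t": float(result.t_map[peak]),
                    "peak_i": peak[0], "peak_j": peak[1], "peak_k": peak[2],
                }
            )
    pd.DataFrame(
        rows,
        columns=["contrast", "cluster", "n_voxels", "peak_t",
                 "peak_i", "peak_j", "peak_k"],
    ).to_csv(vdir / "clusters.tsv", sep="\t", index=False, float_format="%.6g")
    summary = {
        "n_subjects": int(len(base)),
        "n_removed_nfl_outliers": int(removed.size),
        "n_perm": int(result.n_perm),
        "n_sig_pos": int(result.significant(contrast="pos").sum()),
        "n_sig_neg": int(result.significant(contrast="neg").sum()),
    }
    with open(vdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
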