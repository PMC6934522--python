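"""Report orchestration: every figure/table product from one plan bundle.

``run_report`` is a pure function of (bundle, config): identical inputs give
byte-identical CSV/JSON artefacts.  Nothing is computed here that the
underlying modules cannot reproduce call-for-call; this module only
sequences them and writes files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .plan_metrics import (
    compute_dvh,
    distal_extension,
    line_profile,
    profile_to_csv,
    roi_stats,
    stats_to_json,
)
from .rbe_models import (
    MODEL_LET_FLAVOUR,
    ModelName,
    ModelParams,
    Quantity,
    TissueParams,
    apply_model,
    ratio_map,
)
from .voxel_model import PlanBundle, write_grid

logger = logging.getLogger(__name__)

ALL_MODELS = tuple(ModelName)


class ReportConfigError(ValueError):
    pass


@dataclass(frozen=True)
class ReportConfig:
    """What to compute and where to put it.

    ``extension_level_Gy`` of ``None`` means 80% of the prescription.
    ``profile_start_mm`` / ``profile_end_mm`` are physical (z, y, x)
    coordinates; ``None`` disables profiles and extensions.
    """

    models: tuple[ModelName, ...] = ALL_MODELS
    rois: tuple[str, ...] = ("ptv", "brainstem", "spinal_cord")
    tissue: TissueParams = field(default_factory=TissueParams)
    params: ModelParams = field(default_factory=ModelParams)
    dvh_bin_width_Gy: float = 0.01
    profile_start_mm: tuple[float, float, float] | None = None
    profile_end_mm: tuple[float, float, float] | None = None
    profile_step_mm: float = 2.0
    extension_level_Gy: float | None = None
    include_ratio_map: bool = True
    grid_encoding: str = "csv"
    outdir: str | Path = "report"

    def __post_init__(self):
        object.__setattr__(self, "models", tuple(ModelName(m) for m in self.models))
        if self.dvh_bin_width_Gy <= 0:
            raise ReportConfigError("DVH bin width must be positive")


def validate_config(bundle: PlanBundle, cfg: ReportConfig) -> None:
    """Fail fast, before any model evaluation."""
    missing = [r for r in cfg.rois if r not in bundle.masks]
    if missing:
        raise ReportConfigError(f"requested ROIs not in bundle: {missing}")
    if ModelName.MCNAMARA in cfg.models:
        no_ab = [r for r in cfg.rois if r not in cfg.tissue.alpha_beta_Gy]
        if no_ab:
            raise ReportConfigError(
                f"mcnamara requested but no alpha/beta configured for ROIs: {no_ab}")
    for roi in cfg.rois:
        if bundle.masks[roi].nvoxels_true == 0:
            raise ReportConfigError(f"ROI {roi!r} is empty")


def _let_for(bundle: PlanBundle, model: ModelName):
    flavour = MODEL_LET_FLAVOUR[model]
    if flavour is None:
        return None
    return bundle.let_t if flavour is Quantity.LET_T else bundle.let_d


def run_report(bundle: PlanBundle, cfg: ReportConfig) -> dict:
    """Write all requested artefacts; returns the manifest (also on disk).

    Per model: weighted-dose grid, RBE-map grid, one DVH CSV per ROI and ROI
    statistics for both weighted dose and RBE.  If a profile is configured:
    per-model line-profile CSVs and a distal-extension table against the
    constant-RBE reference.  Plus the residual:misrepair ratio grid.
    """
    validate_config(bundle, cfg)
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    level = (cfg.extension_level_Gy if cfg.extension_level_Gy is not None
             else 0.8 * bundle.prescription_Gy)
    artefacts: list[dict] = []

    def record(kind: str, path: Path, **extra):
        artefacts.append({"kind": kind, "file": path.name, **extra})

    weighted_grids: dict[ModelName, object] = {}
    for model in cfg.models:
        logger.info("applying model %s", model.value)
        weighted, rbe = apply_model(
            bundle.dose, _let_for(bundle, model), model, cfg.params,
            masks=bundle.masks, tissue=cfg.tissue,
        )
        weighted_grids[model] = weighted
        record("weighted_dose_grid",
               write_grid(weighted, outdir / f"weighted_{model.value}",
                          encoding=cfg.grid_encoding), model=model.value)
        record("rbe_grid",
               write_grid(rbe, outdir / f"rbe_{model.value}",
                          encoding=cfg.grid_encoding), model=model.value)

        stats = []
        for roi in cfg.rois:
            mask = bundle.masks[roi]
            dvh = compute_dvh(weighted, mask, cfg.dvh_bin_width_Gy)
            dvh_path = outdir / f"dvh_{model.value}_{roi}.csv"
            dvh.to_csv(dvh_path)
            record("dvh", dvh_path, model=model.value, roi=roi)
            s = roi_stats(weighted, mask)
            s["quantity"] = "weighted_dose_Gy"
            s_rbe = roi_stats(rbe, mask)
            s_rbe["quantity"] = "rbe"
            stats.extend([s, s_rbe])
            logger.debug("stats %s/%s: %s", model.value, roi, s)
        stats_path = outdir / f"stats_{model.value}.json"
        stats_to_json(stats, stats_path)
        record("roi_stats", stats_path, model=model.value)

    if cfg.profile_start_mm is not None and cfg.profile_end_mm is not None:
        profiles = {}
        for model, weighted in weighted_grids.items():
            prof = line_profile(weighted, cfg.profile_start_mm, cfg.profile_end_mm,
                                cfg.profile_step_mm)
            profiles[model] = prof
            prof_path = outdir / f"profile_{model.value}.csv"
            profile_to_csv(prof, prof_path)
            record("profile", prof_path, model=model.value)
        if ModelName.CONSTANT in profiles:
            import pandas as pd

            rows = []
            for model, prof in profiles.items():
                if model is ModelName.CONSTANT:
                    continue
                ext = distal_extension(profiles[ModelName.CONSTANT], prof, level)
                rows.append({"model": model.value, "level_Gy": level,
                             "extension_mm": ext})
            ext_path = outdir / "distal_extensions.csv"
            pd.DataFrame(rows).to_csv(ext_path, index=False)
            record("distal_extension_table", ext_path)

    if cfg.include_ratio_map:
        ratio = ratio_map(bundle.dose, bundle.let_t, cfg.params)
        record("ratio_grid",
               write_grid(ratio, outdir / "ratio_residual_misrepair",
                          encoding=cfg.grid_encoding))

    manifest = {
        "artefacts": artefacts,
        "parameters": {
            "models": [m.value for m in cfg.models],
            "rois": list(cfg.rois),
            "kappa_um_per_keV": cfg.params.let_weighted.kappa,
            "alpha_beta_Gy": dict(cfg.tissue.alpha_beta_Gy),
            "default_alpha_beta_Gy": cfg.tissue.default_alpha_beta_Gy,
            "dvh_bin_width_Gy": cfg.dvh_bin_width_Gy,
            "extension_level_Gy": level,
            "prescription_Gy": bundle.prescription_Gy,
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
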