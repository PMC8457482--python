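"""End-to-end pipeline: simulate/ingest -> thin -> background -> screen ->
select -> fit -> validate -> map, with a reproducible run manifest.

One structured config governs every stage. Each stage logs what it did; a
failure aborts with the stage name while earlier outputs stay on disk. The
manifest records the config snapshot, all derived seeds, and a SHA-256
checksum for every artefact, so a rerun from the same manifest reproduces the
coefficient table and the risk raster bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as bio
from .mapping import classify_hotspots, crop_to_focus, project_model
from .raster import extract_values
from .rspf import build_design, fit_rspf
from .sampling import BackgroundSpec, generate_background, spatial_thin
from .selection import enumerate_subsets, rank_and_select, screen_covariates
from .simulate import (CovariateDef, LandscapeSpec, TrueModel,
                       full_synthetic_study)
from .validation import (evaluate_split, focal_membership, kfold_cv,
                         robustness_check, subset_rows)

logger = logging.getLogger(__name__)

__all__ = ["RunManifest", "default_config", "run_pipeline"]


class StageError(RuntimeError):
    """A pipeline stage failed; earlier outputs are preserved."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunManifest:
    """Everything needed to audit or reproduce a run."""

    config: dict
    seeds: dict[str, int] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    checksums: dict[str, str] = field(default_factory=dict)
    stages: list[str] = field(default_factory=list)

    def record(self, name: str, path: Path) -> None:
        self.outputs[name] = str(path)
        self.checksums[name] = hashlib.sha256(Path(path).read_bytes()).hexdigest()

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(
            {"config": self.config, "seeds": self.seeds,
             "outputs": self.outputs, "checksums": self.checksums,
             "stages": self.stages}, indent=2))
        return path


def default_config(seed: int = 0) -> dict:
    """A small synthetic end-to-end configuration (40x40 grid, 120 conflicts)."""
    return {
        "seed": seed,
        "landscape": {
            "n_rows": 40, "n_cols": 40, "cell_size": 50.0,
            "covariates": [
                {"name": "elevation", "smoothing_range": 8, "mean": 500.0, "sd": 150.0},
                {"name": "log_pop_density", "smoothing_range": 4, "mean": 1.0, "sd": 1.0},
                {"name": "dist_urban", "smoothing_range": 6, "mean": 3000.0, "sd": 1500.0},
            ],
            "n_cover_classes": 4,
        },
        "truth": {
            # conflict concentrates at the urban-wildland interface: strong
            # selection, so the true w spans most of (0, 1) over the landscape
            "beta0": -3.0,
            "betas": {"elevation": 0.006, "log_pop_density": 1.2,
                      "dist_urban": -0.0004},
            "cover_effects": {"1": -1.0, "2": 0.8},
        },
        "n_used": 120,
        "thin": {"min_distance": 100.0, "n_repetitions": 20},
        "background": {"buffer_radius": 100.0, "ratio": 5},
        "screen": {"vif_threshold": 10.0, "r2_threshold": 0.7, "priority": None},
        "select": {"delta_threshold": 2.0},
        "fit": {"B": 50, "m": 0},
        "validate": {"k": 5, "min_auc": 0.7, "max_overall_omission": 0.3,
                     "focal_fraction": 0.25},
        "map": {"breaks": [0.25, 0.5, 0.75], "block_rows": 16},
    }


def _sub_seed(base: int, stage: str) -> int:
    # stable per-stage substream, kept below 2**31
    h = hashlib.sha256(f"{base}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def _build_study(config: dict):
    lc = config["landscape"]
    spec = LandscapeSpec(
        n_rows=lc["n_rows"], n_cols=lc["n_cols"], cell_size=lc["cell_size"],
        seed=config["seed"],
        covariate_defs=tuple(CovariateDef(**c) for c in lc["covariates"]),
        n_cover_classes=lc.get("n_cover_classes", 8),
    )
    t = config["truth"]
    truth = TrueModel(beta0=t["beta0"], betas=dict(t["betas"]),
                      cover_effects={int(k): v for k, v in
                                     t.get("cover_effects", {}).items()})
    return full_synthetic_study(
        spec, truth, focal_fraction=config["validate"]["focal_fraction"])


def run_pipeline(config: dict, out_dir: str | Path) -> RunManifest:
    """Execute every stage of the analysis on a synthetic study.

    Returns the :class:`RunManifest`; all artefacts are written under
    ``out_dir``. Any stage failure raises :class:`StageError` naming the
    stage, with earlier outputs preserved on disk.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    manifest = RunManifest(config=json.loads(json.dumps(config)))
    manifest.seeds = {s: _sub_seed(seed, s) for s in
                      ("conflicts", "thin", "background", "fit", "kfold")}

    stage = "simulate"
    try:
        study = _build_study(config)
        from .simulate import simulate_conflicts
        used = simulate_conflicts(study, int(config["n_used"]),
                                  seed=manifest.seeds["conflicts"])
        bio.write_stack(study.stack, out / "stack")
        bio.write_ascii_grid(study.region_mask, out / "region_mask.asc")
        bio.write_ascii_grid(study.focal_mask, out / "focal_mask.asc")
        manifest.record("used_points", bio.write_points_csv(used, out / "used_points.csv"))
        manifest.stages.append(stage)

        stage = "thin"
        tc = config["thin"]
        thin = spatial_thin(used, tc["min_distance"], tc["n_repetitions"],
                            seed=manifest.seeds["thin"])
        logger.info("thin: retained %d of %d", thin.n_retained, len(used))
        manifest.record("thinned_points",
                        bio.write_points_csv(thin.retained, out / "thinned_points.csv"))
        manifest.stages.append(stage)

        stage = "background"
        bc = config["background"]
        bg = generate_background(
            study.region_mask, thin.retained,
            BackgroundSpec(bc["buffer_radius"], bc["ratio"],
                           seed=manifest.seeds["background"]))
        bg = extract_values(study.stack, bg)
        import pandas as pd
        points = pd.concat([thin.retained, bg], ignore_index=True)
        points["id"] = np.arange(len(points))
        manifest.record("points", bio.write_points_csv(points, out / "points.csv"))
        manifest.stages.append(stage)

        stage = "screen"
        continuous = [c["name"] for c in config["landscape"]["covariates"]]
        sc = config["screen"]
        priority = sc.get("priority") or continuous
        report = screen_covariates(points[continuous], priority,
                                   vif_threshold=sc["vif_threshold"],
                                   r2_threshold=sc["r2_threshold"])
        screen_path = out / "screening.json"
        screen_path.write_text(json.dumps(
            {"vif": report.vif, "removed": report.removed,
             "retained": report.retained}, indent=2))
        manifest.record("screening", screen_path)
        manifest.stages.append(stage)

        stage = "select"
        design = build_design(points, report.retained, cover="cover")
        subsets = enumerate_subsets(report.retained + ["cover"])
        ranking = rank_and_select(design, subsets,
                                  delta_threshold=config["select"]["delta_threshold"])
        rank_path = out / "model_ranking.csv"
        ranking.table().to_csv(rank_path, index=False)
        manifest.record("ranking", rank_path)
        logger.info("select: chose %s", ranking.selected_terms)
        manifest.stages.append(stage)

        stage = "fit"
        fit = fit_rspf(design.subset(list(ranking.selected_terms)),
                       B=int(config["fit"]["B"]), m=int(config["fit"]["m"]),
                       seed=manifest.seeds["fit"])
        for name, p in bio.save_fit(fit, out, "fit").items():
            manifest.record(f"fit_{name}", p)
        manifest.stages.append(stage)

        stage = "validate"
        vc = config["validate"]
        sel_design = design.subset(list(ranking.selected_terms))
        inside = focal_membership(points, study.focal_mask)
        if not inside.any() or inside.all():
            raise ValueError("spatial holdout produced an empty side")
        holdout = robustness_check(
            evaluate_split(subset_rows(sel_design, ~inside),
                           subset_rows(sel_design, inside)),
            vc["min_auc"], vc["max_overall_omission"])
        kfold = robustness_check(
            kfold_cv(sel_design, k=int(vc["k"]), seed=manifest.seeds["kfold"]),
            vc["min_auc"], vc["max_overall_omission"])
        val_path = out / "validation.json"
        val_path.write_text(json.dumps(
            {"spatial_holdout": holdout.to_dict(), "kfold": kfold.to_dict()},
            indent=2))
        manifest.record("validation", val_path)
        if kfold.per_fold is not None:
            pf_path = out / "kfold.csv"
            kfold.per_fold.to_csv(pf_path, index=False)
            manifest.record("kfold_table", pf_path)
        manifest.stages.append(stage)

        stage = "map"
        mc = config["map"]
        risk = project_model(fit, study.stack, block_rows=int(mc["block_rows"]))
        focal_risk = crop_to_focus(risk, study.focal_mask)
        classes = classify_hotspots(risk, mc["breaks"])
        manifest.record("risk", bio.write_ascii_grid(risk.raster, out / "risk.asc"))
        manifest.record("risk_focal",
                        bio.write_ascii_grid(focal_risk.raster, out / "risk_focal.asc"))
        manifest.record("risk_classes",
                        bio.write_ascii_grid(classes, out / "risk_classes.asc"))
        _quicklook(risk, out / "risk.png")
        manifest.stages.append(stage)
    except StageError:
        raise
    except Exception as err:
        raise StageError(stage, err) from err

    manifest.save(out / "manifest.json")
    return manifest


def _quicklook(risk, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(5, 5))
    im = ax.imshow(risk.raster.values, cmap="inferno", vmin=0, vmax=1)
    fig.colorbar(im, ax=ax, label="probability of conflict")
    ax.set_title("conflict risk")
    ax.set_axis_off()
    fig.savefig(path, dpi=100, bbox_inches="tight")
    plt.close(fig)
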