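"""End-to-end pipeline: simulate -> crowns -> compete -> fit -> evaluate.

Each stage reads its inputs from and writes its outputs to the run
directory, so stages are individually resumable; a manifest records the
config hash and per-file checksums, and identical configs reproduce
identical checksums for the deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .competition import (CROWN_METRIC_NAMES, CompetitionSpec, NeighborhoodSpec,
                          compute_ci, neighbors_area, neighbors_boundary,
                          radius_for_mean_count, standardize)
from .config import PipelineConfig
from .crowns import (CrownRule, close_pits, crown_metrics_table,
                     delineate_crowns, match_trees, segment_growing_spaces)
from .evaluate import FitRecord, build_study_plan, rank_and_report
from .io import (read_pedigree, read_trees, write_crown_geojson,
                 write_pedigree, write_trees, write_truth)
from .models import ModelSpec, SpatialGeneticModel
from .pedigree import additive_matrix, simulate_pedigree
from .raster import CHMRaster, write_labels
from .simulate import simulate_buffer, simulate_chm, simulate_phenotypes
from .trial import apply_mortality, assign_families, generate_layout

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "RunManifest", "parse_spec_label"]

STAGES = ("simulate", "crowns", "compete", "fit", "evaluate")

_METRIC_BY_TOKEN = {m.replace("_", ""): m for m in CROWN_METRIC_NAMES}


def parse_spec_label(label: str, radius: float) -> CompetitionSpec:
    """Parse a label like 'CVF_CIA_NB' into a CompetitionSpec."""
    token, formulation, nb = label.rsplit("_", 2)
    if token not in _METRIC_BY_TOKEN:
        raise ValueError(f"unknown crown metric token {token!r} in {label!r}")
    if nb not in ("NA", "NB"):
        raise ValueError(f"unknown neighborhood token {nb!r} in {label!r}")
    hood = (NeighborhoodSpec("area", radius) if nb == "NA"
            else NeighborhoodSpec("boundary"))
    return CompetitionSpec(_METRIC_BY_TOKEN[token], formulation, hood)


@dataclasses.dataclass
class RunManifest:
    config_hash: str
    version: str
    stages: dict  # stage -> {file: sha256}
    timestamps: dict

    def write(self, path: str) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(config: PipelineConfig) -> str:
    def enc(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        return str(o)
    blob = json.dumps(dataclasses.asdict(config), default=enc, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()


def _stage_simulate(cfg: PipelineConfig, out: Path) -> None:
    trial = cfg.trial
    layout = generate_layout(trial)
    trees = assign_families(layout, trial, cfg.seed)
    groups = [trees.loc[trees["family"] == f, "tree_id"].tolist()
              for f in range(1, trial.n_families + 1)]
    ped = simulate_pedigree(trial.n_families, "half_sib", cfg.seed,
                            offspring_ids=groups)
    trees = apply_mortality(trees, cfg.mortality_rate, cfg.seed + 1)
    buffer = simulate_buffer(trial, layout.extent(), cfg.seed + 2)
    phen = simulate_phenotypes(trees, ped, cfg.seed + 3, spacing=trial.spacing,
                               buffer=buffer, trait_params=cfg.trait_params())
    live = phen.loc[phen["alive"], ["x", "y", "H"]]
    scene = pd.concat([live, buffer], ignore_index=True)
    chm = simulate_chm(scene, cfg.chm, cfg.seed + 4)

    write_trees(phen, out / "trees.csv")
    write_pedigree(ped, out / "pedigree.csv")
    buffer.to_csv(out / "buffer.csv", index=False)
    chm.write(str(out / "chm.tif"))
    truth = {"seed": cfg.seed,
             "trial": dataclasses.asdict(trial),
             "mortality_rate": cfg.mortality_rate,
             "traits": {t: dataclasses.asdict(p)
                        for t, p in cfg.trait_params().items()}}
    write_truth(truth, out / "truth.json")


def _stage_crowns(cfg: PipelineConfig, out: Path) -> None:
    chm = CHMRaster.read(str(out / "chm.tif"))
    trees = read_trees(out / "trees.csv")
    buffer = pd.read_csv(out / "buffer.csv")
    chm = close_pits(chm, cfg.crowns.kernel)

    markers = None
    if cfg.crowns.markers == "stems":
        live = trees.loc[trees["alive"], ["x", "y"]]
        markers = pd.concat([live, buffer[["x", "y"]]], ignore_index=True).to_numpy()
    seg = segment_growing_spaces(chm, cfg.crowns.sigma, markers=markers,
                                 min_distance=cfg.crowns.min_distance,
                                 min_height=cfg.crowns.min_height)
    rule = CrownRule(cfg.crowns.crown_min_height, cfg.crowns.crown_apex_fraction)
    crowns = delineate_crowns(seg, chm, rule)
    metrics = crown_metrics_table(chm, seg, crowns)

    live = trees.loc[trees["alive"]]
    m = match_trees(metrics[["x", "y"]].to_numpy(),
                    live[["x", "y"]].to_numpy(), cfg.crowns.match_max_dist)
    tree_ids = np.full(len(metrics), -1)
    tree_ids[m["detected"].to_numpy()] = live["tree_id"].to_numpy()[m["planted"]]
    metrics["tree_id"] = tree_ids
    n_unmatched = int((tree_ids < 0).sum())
    logger.info("crowns: %d segments, %d unmatched (buffer or segmentation error)",
                len(metrics), n_unmatched)
    metrics.to_csv(out / "metrics.csv", index=False)
    write_labels(str(out / "segments.tif"), seg.labels, seg.cell_size, seg.origin)
    write_crown_geojson(crowns, seg.cell_size, seg.origin,
                        str(out / "crowns.geojson"))


def _stage_compete(cfg: PipelineConfig, out: Path) -> None:
    from .raster import read_labels

    metrics = pd.read_csv(out / "metrics.csv")
    labels, _, _ = read_labels(str(out / "segments.tif"))
    radius = cfg.competition.radius or radius_for_mean_count(cfg.trial.spacing, 20)

    pos = metrics[["x", "y"]].to_numpy()
    subject = metrics["tree_id"].to_numpy() > 0
    adj_area = neighbors_area(pos, radius)
    nb_by_label = neighbors_boundary(labels, cfg.competition.connectivity)
    lbl_to_idx = {int(l): i for i, l in enumerate(metrics["label"])}
    adj_boundary = [np.array([lbl_to_idx[l] for l in
                              nb_by_label.get(int(lbl), []) if l in lbl_to_idx],
                             dtype=int)
                    for lbl in metrics["label"]]

    rows = []
    wide = metrics.loc[subject, ["tree_id"]].reset_index(drop=True)
    for label in cfg.competition.specs:
        spec = parse_spec_label(label, radius)
        adj = adj_area if spec.neighborhood.method == "area" else adj_boundary
        vals = metrics[spec.crown_metric].to_numpy(dtype=float)
        tab = compute_ci(vals, pos, adj, spec.formulation, subject=subject)
        raw = tab.loc[subject, "ci"].to_numpy()
        std = standardize(raw)
        wide[f"ci_{label}"] = std
        rows.append(pd.DataFrame({
            "tree_id": metrics.loc[subject, "tree_id"].to_numpy(),
            "spec": label, "ci_raw": raw, "ci_std": std,
            "n_neighbors": tab.loc[subject, "n_neighbors"].to_numpy()}))
    pd.concat(rows, ignore_index=True).to_csv(out / "ci.csv", index=False)
    wide.to_csv(out / "ci_wide.csv", index=False)


def _stage_fit(cfg: PipelineConfig, out: Path) -> None:
    trees = read_trees(out / "trees.csv")
    ped = read_pedigree(out / "pedigree.csv")
    wide = pd.read_csv(out / "ci_wide.csv")
    data = trees.merge(wide, on="tree_id", how="left")
    amat = additive_matrix(ped)

    plan = build_study_plan(cfg.models.traits, cfg.competition.specs)
    plan.runs.to_csv(out / "study_plan.csv", index=False)
    runs = plan.runs[plan.runs["family"].isin(cfg.models.families)]
    random_comp = cfg.models.competition == "random"
    records = []
    for run in runs.itertuples(index=False):
        spec = ModelSpec(run.family, run.trait, run.competition,
                         competition_random=random_comp and run.competition is not None)
        try:
            model = SpatialGeneticModel.from_dataframe(data, spec, amat)
            fit = model.fit(n_starts=cfg.models.n_starts, seed=cfg.seed,
                            maxiter=cfg.models.maxiter)
            records.append(fit.to_dict())
        except (ValueError, np.linalg.LinAlgError) as e:
            logger.warning("fit failed for %s: %s", spec, e)
    Path(out / "fits.json").write_text(json.dumps(records, indent=1))


def _stage_evaluate(cfg: PipelineConfig, out: Path) -> None:
    records = json.loads(Path(out / "fits.json").read_text())
    fits = [FitRecord(d) for d in records]
    trees = read_trees(out / "trees.csv")
    wide = pd.read_csv(out / "ci_wide.csv")
    tables = rank_and_report(fits, bic_convention=cfg.evaluation.bic_convention,
                             ci_table=wide, phenotypes=trees)
    tables["model_table"].to_csv(out / "table3_analogue.csv", index=False)
    tables["best_table"].to_csv(out / "table4_analogue.csv", index=False)


_STAGE_FUNCS = {"simulate": _stage_simulate, "crowns": _stage_crowns,
                "compete": _stage_compete, "fit": _stage_fit,
                "evaluate": _stage_evaluate}


def run_pipeline(config: PipelineConfig,
                 stages: tuple[str, ...] = STAGES) -> RunManifest:
    """Execute the configured stages, writing outputs and a manifest.

    A stage failure aborts with the stage name; the manifest written so
    far is preserved in the run directory.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=_config_hash(config),
                           version=__version__, stages={}, timestamps={})
    for stage in stages:
        if stage not in _STAGE_FUNCS:
            raise ValueError(f"unknown stage {stage!r}")
        logger.info("stage %s ...", stage)
        t0 = time.time()
        try:
            _STAGE_FUNCS[stage](config, out)
        except Exception:
            manifest.write(str(out / "manifest.json"))
            logger.error("stage %s failed", stage)
            raise
        manifest.stages[stage] = {
            f: _sha256(out / f) for f in _stage_outputs(stage) if (out / f).exists()}
        manifest.timestamps[stage] = round(time.time() - t0, 3)
    manifest.write(str(out / "manifest.json"))
    return manifest


def _stage_outputs(stage: str) -> list[str]:
    return {
        "simulate": ["trees.csv", "pedigree.csv", "buffer.csv", "chm.tif",
                     "truth.json"],
        "crowns": ["metrics.csv", "segments.tif", "crowns.geojson"],
        "compete": ["ci.csv", "ci_wide.csv"],
        "fit": ["fits.json", "study_plan.csv"],
        "evaluate": ["table3_analogue.csv", "table4_analogue.csv"],
    }[stage]
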