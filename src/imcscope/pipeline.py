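"""End-to-end pipeline: simulate -> segment -> cluster -> quantify ->
neighborhood -> model, with config validation, master seeding, per-stage
manifests and deterministic reruns.

A run directory has a fixed layout::

    run_dir/
      images/      ROI stacks (TIFF) and truth masks
      masks/       segmented 1x label masks
      tables/      cell table, assignment, features, results (CSV)
      manifests/   one JSON manifest per stage (params, seed, output hashes)
      report.json  stage list with timings

One master seed deterministically derives every stage seed, so rerunning an
identical config reproduces identical numerical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io, model, neighborhood, phenotype, quantify, segment, simulate
from .panel import MarkerPanel, default_panel, read_panel

logger = logging.getLogger(__name__)

STAGES = ("simulate", "segment", "cluster", "quantify", "neighborhood", "model")

_DEFAULTS: dict[str, dict] = {
    "simulate": {
        "n_nr_roi": 2,
        "n_cr_roi": 2,
        "roi_shape_px": [300, 300],
        "nr_overrides": {},
        "cr_overrides": {},
    },
    "segment": {
        "hotpixel_factor": 5.0,
        "nuclear_prob_threshold": 0.5,
        "min_nucleus_area_px": 4,
        "watershed_min_seed_distance_px": 3,
        "max_expansion_px": 5.0,
        "training_pixels_per_class": 1500,
        "n_estimators": 60,
    },
    "cluster": {"k": 75, "z_threshold": 1.0, "tsne": False,
                "perplexity": 30.0, "theta": 0.5},
    "neighborhood": {"radius_px": 4.0, "n_perm": 5000, "alpha": 0.01,
                     "mode": "immune"},
    "model": {"scale": True, "features": "clusters",
              "correlation_method": "spearman", "correlation_threshold": 0.8},
}


class ConfigError(ValueError):
    """Invalid or unknown run-configuration content."""


class PipelineError(RuntimeError):
    """A stage failed; partial outputs are retained."""


@dataclass
class RunConfig:
    out_dir: str = "imcscope_run"
    seed: int = 0
    panel_path: str | None = None
    stages: dict[str, bool] = field(
        default_factory=lambda: {s: True for s in STAGES}
    )
    params: dict[str, dict] = field(
        default_factory=lambda: {s: dict(_DEFAULTS[s]) for s in _DEFAULTS}
    )

    def to_dict(self) -> dict:
        out = {
            "out_dir": self.out_dir,
            "seed": self.seed,
            "panel_path": self.panel_path,
            "stages": dict(self.stages),
        }
        out.update({k: dict(v) for k, v in self.params.items()})
        return out

    def panel(self) -> MarkerPanel:
        return read_panel(self.panel_path) if self.panel_path else default_panel()

    def stage_seed(self, stage: str) -> int:
        idx = STAGES.index(stage)
        return int(np.random.SeedSequence(self.seed).generate_state(len(STAGES))[idx] % (2**31))


def validate_config(path: str | Path) -> RunConfig:
    """Parse + validate a YAML run config; unknown keys are an error and
    defaults are filled in. Cross-field checks mirror each stage's
    contracts (radius > 0, alpha in (0, 1), k >= 1, ...)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return validate_config_dict(raw)


def validate_config_dict(raw: dict) -> RunConfig:
    known_top = {"out_dir", "seed", "panel_path", "stages"} | set(_DEFAULTS)
    unknown = set(raw) - known_top
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(
        out_dir=raw.get("out_dir", "imcscope_run"),
        seed=int(raw.get("seed", 0)),
        panel_path=raw.get("panel_path"),
    )
    stages = raw.get("stages", {})
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ConfigError(f"unknown stage toggles: {sorted(unknown)}")
    cfg.stages.update({k: bool(v) for k, v in stages.items()})
    for stage, defaults in _DEFAULTS.items():
        block = raw.get(stage, {})
        unknown = set(block) - set(defaults)
        if unknown:
            raise ConfigError(f"unknown keys in {stage!r} block: {sorted(unknown)}")
        cfg.params[stage].update(block)
    nb = cfg.params["neighborhood"]
    if not 0 < nb["alpha"] < 1:
        raise ConfigError(f"alpha must be in (0, 1), got {nb['alpha']}")
    if nb["radius_px"] <= 0:
        raise ConfigError("radius_px must be positive")
    if nb["mode"] not in ("immune", "all"):
        raise ConfigError("neighborhood mode must be 'immune' or 'all'")
    if cfg.params["cluster"]["k"] < 1:
        raise ConfigError("cluster k must be >= 1")
    if cfg.params["model"]["features"] not in ("clusters", "markers"):
        raise ConfigError("model features must be 'clusters' or 'markers'")
    if cfg.panel_path and not Path(cfg.panel_path).exists():
        raise ConfigError(f"panel file not found: {cfg.panel_path}")
    return cfg


def write_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))


@dataclass
class RunReport:
    stages: list[dict]

    @property
    def completed(self) -> list[str]:
        return [s["stage"] for s in self.stages]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _manifest(run_dir: Path, stage: str, params: dict, seed: int,
              outputs: list[Path]) -> None:
    man = {
        "stage": stage,
        "params": params,
        "seed": seed,
        "outputs": {str(p.relative_to(run_dir)): _sha256(p) for p in outputs},
    }
    mdir = run_dir / "manifests"
    mdir.mkdir(parents=True, exist_ok=True)
    (mdir / f"{stage}.json").write_text(json.dumps(man, indent=2, sort_keys=True))


def run_pipeline(cfg: RunConfig) -> RunReport:
    """Execute all enabled stages in order; a failing stage halts the run
    (named in the raised error) with earlier outputs retained."""
    run_dir = Path(cfg.out_dir)
    for sub in ("images", "masks", "tables", "manifests"):
        (run_dir / sub).mkdir(parents=True, exist_ok=True)
    panel = cfg.panel()
    report = RunReport(stages=[])
    state: dict = {"panel": panel}
    for stage in STAGES:
        if not cfg.stages.get(stage, True):
            continue
        t0 = time.perf_counter()
        try:
            outputs = _STAGE_FN[stage](cfg, run_dir, state)
        except Exception as exc:
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
        dt = time.perf_counter() - t0
        _manifest(run_dir, stage, cfg.params.get(stage, {}),
                  cfg.stage_seed(stage), outputs)
        report.stages.append({"stage": stage, "seconds": round(dt, 3)})
        logger.info("stage %s done in %.1fs", stage, dt)
    (run_dir / "report.json").write_text(
        json.dumps({"stages": report.stages}, indent=2)
    )
    return report


def _stage_simulate(cfg: RunConfig, run_dir: Path, state: dict) -> list[Path]:
    p = cfg.params["simulate"]
    shape = tuple(p["roi_shape_px"])
    nr = simulate.nr_default_config(roi_shape_px=shape, **p["nr_overrides"])
    cr = simulate.cr_default_config(roi_shape_px=shape, **p["cr_overrides"])
    cohort = simulate.generate_cohort(
        p["n_nr_roi"], p["n_cr_roi"], nr, cr,
        seed=cfg.stage_seed("simulate"), panel=state["panel"],
    )
    outputs = []
    truth_rows = []
    state["rois"], state["truths"] = [], []
    for roi, truth in cohort:
        img = run_dir / "images" / f"{roi.roi_id}.tiff"
        io.write_roi(roi, img)
        mask = run_dir / "images" / f"{roi.roi_id}_truth_mask.tiff"
        io.write_mask(truth.true_mask, mask)
        outputs += [img, mask]
        truth_rows.append(
            truth.cells.assign(cohort=truth.cohort)[
                ["roi_id", "cell_id", "phenotype", "cohort"]
            ]
        )
        state["rois"].append(roi)
        state["truths"].append(truth)
    ptable = run_dir / "images" / "true_phenotypes.csv"
    pd.concat(truth_rows).to_csv(ptable, index=False)
    outputs.append(ptable)
    return outputs


def _stage_segment(cfg: RunConfig, run_dir: Path, state: dict) -> list[Path]:
    p = cfg.params["segment"]
    seed = cfg.stage_seed("segment")
    params = segment.SegmentationParams(
        hotpixel_factor=p["hotpixel_factor"],
        nuclear_prob_threshold=p["nuclear_prob_threshold"],
        min_nucleus_area_px=p["min_nucleus_area_px"],
        watershed_min_seed_distance_px=p["watershed_min_seed_distance_px"],
        max_expansion_px=p["max_expansion_px"],
    )
    rois = state.get("rois")
    if rois is None:
        raise PipelineError("segment stage requires the simulate stage's ROIs")
    truth0 = state["truths"][0]
    roi0 = rois[0]
    stack2x = segment.upscale2x(
        segment.remove_hot_pixels(roi0.stack, params.hotpixel_factor)
    )
    labels2x = simulate.training_labels_from_truth(
        truth0, n_per_class=p["training_pixels_per_class"], seed=seed
    )
    clf = segment.train_pixel_classifier(
        [stack2x], [labels2x], seed=seed, n_estimators=p["n_estimators"]
    )
    outputs = []
    tables = []
    state["masks"] = {}
    for roi in rois:
        mask, cells = segment.segment_roi(roi, clf, params)
        out = run_dir / "masks" / f"{roi.roi_id}_mask.tiff"
        io.write_mask(mask, out)
        outputs.append(out)
        tables.append(cells)
        state["masks"][roi.roi_id] = mask
        logger.info("ROI %s: %d cells", roi.roi_id, len(cells))
    cells = pd.concat(tables, ignore_index=True)
    ct = run_dir / "tables" / "cells.csv"
    io.write_cell_table(cells, ct)
    outputs.append(ct)
    state["cells"] = cells
    state["cohort_of_roi"] = pd.Series(
        {r.roi_id: r.cohort for r in rois}, name="cohort"
    )
    return outputs


def _stage_cluster(cfg: RunConfig, run_dir: Path, state: dict) -> list[Path]:
    p = cfg.params["cluster"]
    panel = state["panel"]
    cells = state["cells"]
    assignment = phenotype.phenograph_cluster(
        cells, list(panel.markers), k=p["k"], seed=cfg.stage_seed("cluster")
    )
    profile = phenotype.profile_clusters(cells, assignment, list(panel.markers))
    assignment = phenotype.annotate_immune(
        assignment, profile, panel, z_threshold=p["z_threshold"]
    )
    out_assign = run_dir / "tables" / "assignment.csv"
    cells[["roi_id", "cell_id"]].assign(
        meta_cluster=assignment.cell_cluster,
        phenotype_label=assignment.cell_labels(),
    ).to_csv(out_assign, index=False)
    out_clusters = run_dir / "tables" / "clusters.csv"
    assignment.clusters.to_csv(out_clusters, index=False)
    out_prof = run_dir / "tables" / "cluster_profile_z.csv"
    profile.z.to_csv(out_prof)
    outputs = [out_assign, out_clusters, out_prof]
    if p["tsne"]:
        emb = phenotype.tsne_embed(
            cells, list(panel.markers), perplexity=p["perplexity"],
            theta=p["theta"], seed=cfg.stage_seed("cluster"),
        )
        out_tsne = run_dir / "tables" / "tsne.csv"
        pd.DataFrame(emb, columns=["tsne1", "tsne2"]).to_csv(out_tsne, index=False)
        outputs.append(out_tsne)
    state["assignment"] = assignment
    return outputs


def _stage_quantify(cfg: RunConfig, run_dir: Path, state: dict) -> list[Path]:
    panel = state["panel"]
    cells = state["cells"]
    assignment = state["assignment"]
    labels = assignment.cell_labels()
    medians = quantify.median_marker_per_roi(cells, list(panel.markers))
    counts = quantify.immune_counts(cells, labels)
    props = quantify.immune_proportions(cells, labels)
    z = quantify.standardize_counts(counts) if len(counts) >= 2 else counts * np.nan
    comp = quantify.compare_cohorts(props, state["cohort_of_roi"])
    outputs = []
    for name, df in [
        ("roi_median_markers", medians),
        ("roi_immune_counts", counts),
        ("roi_immune_proportions", props),
        ("roi_immune_counts_z", z),
        ("cohort_comparison", comp),
    ]:
        out = run_dir / "tables" / f"{name}.csv"
        df.to_csv(out, index=name != "cohort_comparison")
        outputs.append(out)
    state["counts"] = counts
    state["medians"] = medians
    return outputs


def _stage_neighborhood(cfg: RunConfig, run_dir: Path, state: dict) -> list[Path]:
    p = cfg.params["neighborhood"]
    cells = state["cells"]
    assignment = state["assignment"]
    labels_all = pd.Series(assignment.cell_labels(), index=cells.index)
    immune_mask = pd.Series(assignment.immune_cell_mask(), index=cells.index)
    seed = cfg.stage_seed("neighborhood")
    results = []
    for i, (roi_id, grp) in enumerate(cells.groupby("roi_id")):
        mask = state["masks"][roi_id]
        graph = segment.build_neighbor_graph(mask, radius_px=p["radius_px"])
        lab = pd.Series(labels_all[grp.index].to_numpy(), index=grp["cell_id"])
        if p["mode"] == "immune":
            permutable = pd.Series(
                immune_mask[grp.index].to_numpy(), index=grp["cell_id"]
            )
            phenos = sorted(set(lab[permutable]) - {phenotype.NON_IMMUNE_LABEL})
        else:
            permutable = None
            phenos = sorted(set(lab))
        if not phenos:
            continue
        results.append(
            neighborhood.permutation_test(
                graph, lab, n_perm=p["n_perm"], alpha=p["alpha"],
                seed=seed + i, phenotypes=phenos, permutable=permutable,
                roi_id=roi_id,
            )
        )
    results = (
        pd.concat(results, ignore_index=True) if results else pd.DataFrame()
    )
    summary = neighborhood.summarize_cohort(results)
    out_r = run_dir / "tables" / "neighborhood_results.csv"
    results.to_csv(out_r, index=False)
    out_s = run_dir / "tables" / "neighborhood_summary.csv"
    summary.to_csv(out_s, index=False)
    return [out_r, out_s]


def _stage_model(cfg: RunConfig, run_dir: Path, state: dict) -> list[Path]:
    p = cfg.params["model"]
    feats = state["counts"] if p["features"] == "clusters" else state["medians"]
    cohorts = state["cohort_of_roi"]
    pca = model.pca_fit(feats, scale=p["scale"])
    stat, pval = model.pc1_test(pca, cohorts)
    lr = model.logistic_pc1(pca, cohorts)
    edges, constant = model.correlation_network(
        state["medians"], method=p["correlation_method"],
        threshold=p["correlation_threshold"],
    )
    summary = {
        "pc1_explained_pct": float(pca.explained_pct[0]),
        "pc1_wilcoxon_p": pval,
        "logistic": {
            "intercept": lr.intercept,
            "slope": lr.slope,
            "ridge": lr.ridge,
            "separation_flag": lr.separation_flag,
            "n_high_confidence": lr.n_high_confidence,
            "n_outliers": lr.n_outliers,
        },
        "constant_columns": constant,
    }
    out_scores = run_dir / "tables" / "pca_scores.csv"
    pca.scores.to_csv(out_scores)
    out_contrib = run_dir / "tables" / "pca_contributions.csv"
    pca.contributions_pct.to_csv(out_contrib)
    out_edges = run_dir / "tables" / "correlation_edges.csv"
    edges.to_csv(out_edges, index=False)
    out_sum = run_dir / "tables" / "model_summary.json"
    io.write_json(summary, out_sum)
    return [out_scores, out_contrib, out_edges, out_sum]


_STAGE_FN = {
    "simulate": _stage_simulate,
    "segment": _stage_segment,
    "cluster": _stage_cluster,
    "quantify": _stage_quantify,
    "neighborhood": _stage_neighborhood,
    "model": _stage_model,
}
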