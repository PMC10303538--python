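"""End-to-end pipeline: simulate/load → partition → alpha → beta → niche →
distance decay → assembly, with one JSON run report.

Sub-communities are classified within each treatment group (the default
partitioning convention); analyses that span both groups within one
abundance class use the union of the per-group class memberships. All
randomness derives from a single master seed via fixed per-stage child
seeds, so a full run is bit-reproducible and stages can be re-run
independently.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import alpha as alpha_mod
from . import beta as beta_mod
from . import io as io_mod
from .assembly import assembly_analysis, patristic_matrix, process_fractions
from .containers import CommunityTable, ValidationError
from .niche import community_breadth
from .partition import CLASSES, classify_taxa, split_table
from .simulate import SimulationConfig, preset_config, simulate_dataset
from .spatial import distance_decay, env_mantel_panel, haversine_matrix

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]

STAGES = ("data", "partition", "alpha", "beta", "niche", "decay", "assembly")


@dataclass
class RunConfig:
    """Thresholds, permutation counts and inputs for one full run.

    Defaults are the analysis' canonical values: abundance thresholds
    0.1% / 0.01%, niche-breadth thresholds 3 / 1.5, |βNTI| threshold 2,
    |RC| threshold 0.95, 9999 PERMANOVA permutations and 999 for all other
    permutation/null procedures.
    """

    table_path: str | None = None
    tree_path: str | None = None
    metadata_path: str | None = None
    simulation: dict | None = None  # SimulationConfig fields or {"preset": name}
    partition_upper: float = 0.001
    partition_lower: float = 0.0001
    generalist_min: float = 3.0
    specialist_max: float = 1.5
    n_perm_permanova: int = 9999
    n_perm: int = 999
    n_null: int = 999
    seed: int = 0
    out_dir: str = "results"
    stages: tuple = STAGES

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        if "stages" in d:
            cfg.stages = tuple(d["stages"])
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(io_mod.read_yaml(path))


def _load_data(config: RunConfig, report: dict):
    if config.simulation is not None:
        sim = dict(config.simulation)
        preset = sim.pop("preset", None)
        sim.setdefault("seed", config.seed)
        sim_cfg = (preset_config(preset, **sim) if preset
                   else SimulationConfig(**sim))
        table, tree, meta, truth = simulate_dataset(sim_cfg)
        report["simulation_truth"] = truth["config"]
    else:
        if not config.table_path or not config.metadata_path:
            raise ValidationError("need table_path and metadata_path (or simulation)")
        table = io_mod.read_community_table(config.table_path)
        meta = io_mod.read_metadata(config.metadata_path)
        tree = io_mod.read_tree(config.tree_path) if config.tree_path else None
        if tree is None and "assembly" in config.stages:
            raise ValidationError("assembly stage requires tree_path")
    table, tree, meta, align_report = io_mod.align_inputs(table, tree, meta)
    report["dropped_taxa"] = align_report.dropped_taxa
    report["dropped_samples"] = align_report.dropped_samples
    return table, tree, meta


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and write all outputs under ``out_dir``.

    Returns the run report (also written as ``run_report.json``). Any stage
    failure aborts with the stage name; outputs written so far are retained
    alongside a FAILED marker.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages_run": [], "warnings": [],
                    "thresholds": {
                        "partition_upper": config.partition_upper,
                        "partition_lower": config.partition_lower,
                        "generalist_min": config.generalist_min,
                        "specialist_max": config.specialist_max,
                        "beta_nti": 2.0, "rc_bray": 0.95,
                    },
                    "permutations": {
                        "permanova": config.n_perm_permanova,
                        "other": config.n_perm, "n_null": config.n_null,
                    }}
    stage = "data"
    try:
        table, tree, meta, labels_by_group, cells, class_union = (
            None, None, None, {}, {}, {})

        table, tree, meta = _load_data(config, report)
        io_mod.write_community_table(table, out / "otu_table.tsv")
        io_mod.write_metadata(meta, out / "metadata.tsv")
        if tree is not None:
            io_mod.write_tree(tree, out / "tree.nwk")
        report["n_taxa"], report["n_samples"] = table.n_taxa, table.n_samples
        report["stages_run"].append(stage)

        groups = sorted(meta["group"].unique())
        group_samples = {g: sorted(meta.loc[meta["group"] == g, "sample_id"])
                         for g in groups}

        stage = "partition"
        if stage in config.stages:
            label_frames = []
            for g in groups:
                sub = table.select_samples(group_samples[g])
                present = [t for t, s in zip(sub.taxon_ids,
                                             sub.counts.sum(axis=1)) if s > 0]
                sub = sub.select_taxa(present)
                labels = classify_taxa(sub, config.partition_upper,
                                       config.partition_lower)
                labels_by_group[g] = labels
                lf = labels.to_frame()
                lf["group"] = g
                label_frames.append(lf)
                for cls, t in split_table(sub, labels).items():
                    cells[(g, cls)] = t
            pd.concat(label_frames).to_csv(out / "partition_labels.tsv",
                                           sep="\t", index=False)
            report["class_percent"] = {
                g: {cls: round(100.0 * len(labels_by_group[g].taxa_in(cls))
                               / len(labels_by_group[g].labels), 3)
                    for cls in CLASSES}
                for g in groups}
            for cls in CLASSES:
                taxa = sorted(set().union(*(labels_by_group[g].taxa_in(cls)
                                            for g in groups)))
                class_union[cls] = (table.select_taxa(taxa, drop_empty_samples=True)
                                    if taxa else None)
            report["stages_run"].append(stage)

        stage = "alpha"
        if stage in config.stages and cells:
            frames = []
            for g in groups:
                at = alpha_mod.alpha_table({c: cells.get((g, c)) for c in CLASSES})
                frames.append(at)
            alpha_df = pd.concat(frames, ignore_index=True)
            alpha_df.to_csv(out / "alpha_per_sample.tsv", sep="\t", index=False)
            comp = alpha_mod.compare_groups(alpha_df, meta)
            comp.to_csv(out / "alpha_group_tests.tsv", sep="\t", index=False)
            report["alpha_tests"] = comp.to_dict("records")
            report["stages_run"].append(stage)

        stage = "beta"
        if stage in config.stages and class_union:
            rows, disp_frames = [], []
            for cls, sub in class_union.items():
                if sub is None or sub.n_samples < 4:
                    continue
                grp = meta.loc[sub.sample_ids, "group"]
                d = beta_mod.bray_curtis(sub, relative=True)
                d.to_frame().to_csv(out / f"bray_curtis_{cls}.tsv", sep="\t")
                ord_res = beta_mod.pcoa(d)
                pd.DataFrame(ord_res.axes[:, :2], index=d.ids,
                             columns=["PCo1", "PCo2"]).to_csv(
                    out / f"pcoa_{cls}.tsv", sep="\t")
                perma = beta_mod.permanova(d, grp, config.n_perm_permanova,
                                           seed=config.seed)
                ano = beta_mod.anosim(d, grp, config.n_perm, seed=config.seed)
                disp_df, disp = beta_mod.dispersion_homogeneity(
                    d, grp, config.n_perm, seed=config.seed)
                disp_df["class"] = cls
                disp_frames.append(disp_df)
                for res in (perma, ano, disp):
                    rows.append({"class": cls, "statistic_name": res.statistic_name,
                                 "statistic": res.statistic, "p_value": res.p_value,
                                 "n_permutations": res.n_permutations})
            tests = pd.DataFrame(rows)
            tests.to_csv(out / "beta_tests.tsv", sep="\t", index=False)
            if disp_frames:
                disp_all = pd.concat(disp_frames, ignore_index=True)
                disp_all.to_csv(out / "dispersion.tsv", sep="\t", index=False)
                report["dispersion_means"] = {
                    f"{cls}/{g}": float(sub["distance_to_centroid"].mean())
                    for (cls, g), sub in disp_all.groupby(["class", "group"])}
            report["beta_tests"] = tests.to_dict("records")
            report["stages_run"].append(stage)

        stage = "niche"
        if stage in config.stages and cells:
            per_taxon, summary, comps = community_breadth(
                cells, config.generalist_min, config.specialist_max)
            per_taxon.to_csv(out / "niche_per_taxon.tsv", sep="\t", index=False)
            summary.to_csv(out / "niche_summary.tsv", sep="\t", index=False)
            comps.to_csv(out / "niche_group_tests.tsv", sep="\t", index=False)
            report["niche_summary"] = summary.to_dict("records")
            report["stages_run"].append(stage)

        stage = "decay"
        if stage in config.stages and cells:
            rows = []
            for (g, cls), sub in sorted(cells.items()):
                if sub is None or sub.n_samples < 4:
                    continue
                d = beta_mod.bray_curtis(sub, relative=True)
                sim = d.values.copy()
                sim = 1.0 - sim
                np.fill_diagonal(sim, 0.0)
                sim_m = type(d)(d.ids, sim)
                geo = haversine_matrix(meta.loc[sub.sample_ids])
                try:
                    fit = distance_decay(sim_m, geo, n_perm=config.n_perm,
                                         seed=config.seed)
                except ValidationError as exc:
                    logger.warning("decay: skipping cell (%s, %s): %s", g, cls, exc)
                    report["warnings"].append(f"decay skipped ({g}, {cls}): {exc}")
                    continue
                rows.append({"group": g, "class": cls, "slope": fit.slope,
                             "intercept": fit.intercept, "r_squared": fit.r_squared,
                             "p_value": fit.p_value, "n_pairs": fit.n_pairs,
                             "n_excluded": fit.n_excluded})
                panel, spearman = env_mantel_panel(d, meta.loc[sub.sample_ids],
                                                   n_perm=config.n_perm,
                                                   seed=config.seed)
                panel.insert(0, "class", cls)
                panel.insert(0, "group", g)
                panel.to_csv(out / f"env_mantel_{g}_{cls}.tsv", sep="\t",
                             index=False)
                spearman.to_csv(out / f"env_spearman_{g}_{cls}.tsv", sep="\t")
            decay_df = pd.DataFrame(rows)
            decay_df.to_csv(out / "distance_decay.tsv", sep="\t", index=False)
            report["decay_slopes"] = decay_df.to_dict("records")
            report["stages_run"].append(stage)

        stage = "assembly"
        if stage in config.stages and cells and tree is not None:
            pdm_full = patristic_matrix(tree)
            frames = []
            for (g, cls), sub in sorted(cells.items()):
                if sub is None or sub.n_samples < 3 or sub.n_taxa < 3:
                    continue
                res = assembly_analysis(sub, pdm_full.submatrix(sub.taxon_ids),
                                        n_null=config.n_null, seed=config.seed)
                res.insert(0, "class", cls)
                res.insert(0, "group", g)
                frames.append(res)
            if frames:
                pairs = pd.concat(frames, ignore_index=True)
                pairs.to_csv(out / "assembly_pairs.tsv", sep="\t", index=False)
                fractions = process_fractions(pairs, by=["group", "class"])
                fractions.to_csv(out / "assembly_fractions.tsv", sep="\t",
                                 index=False)
                report["process_fractions"] = fractions.to_dict("records")
            report["stages_run"].append(stage)

    except Exception as exc:
        (out / "FAILED").write_text(f"stage {stage}: {exc}\n")
        raise ValidationError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    with open(out / "run_report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, default=_json_default)
    return report


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
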