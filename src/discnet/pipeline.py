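"""End-to-end orchestration: simulate -> reduce -> stats -> networks.

``reduce_dataset`` turns raw records into tidy per-animal endpoint tables;
``run_pipeline`` executes the whole study analysis and writes trait tables,
ANOVA reports, per-sex networks (GraphML + TSV edge list), a male/female
comparison report, and a manifest with config hash and file checksums.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import biomech, io as dio, phenotypes
from .config import PipelineConfig, config_hash, config_to_dict
from .group_stats import StatsError, two_way_anova
from .network import (
    assemble_trait_table,
    compare_networks,
    default_trait_classes,
    network_from_table,
)
from .simulate import StudyDataset, generate_study

log = logging.getLogger("discnet")

EDGES_OF_INTEREST = (
    ("injury", "vf_w6"),
    ("injury", "grade_total"),
    ("injury", "height_pct_punctured"),
)

#: endpoint traits reported with a 2-way (injury x sex) ANOVA
ANOVA_TRAITS = (
    "vf_w6", "height_pct_punctured", "grade_total",
    "tensile_stiffness", "compressive_stiffness", "axial_rom",
    "axial_hysteresis", "torsional_stiffness", "torque_range",
    "total_displacement", "slow_time_constant",
)


def reduce_biomech(ds: StudyDataset, cycle_index: int = 20,
                   fit_window_fraction: float = 0.2) -> pd.DataFrame:
    """Per-animal axial, torsional and creep properties from the raw traces."""
    cfg = ds.config
    rows = []
    traces = dict(tuple(ds.cyclic_traces.groupby(["animal_id", "kind"])))
    creeps = dict(tuple(ds.creep_curves.groupby("animal_id")))
    for aid in ds.animals["animal_id"]:
        row = {"animal_id": aid}
        ax = traces[(aid, "axial")]
        t, d, f = biomech.extract_cycle(
            ax["time_s"].values, ax["primary"].values, ax["conjugate"].values,
            cycle_index, cfg.cycle_frequency_hz, cfg.n_cycles)
        ap = biomech.axial_properties(t, d, f, fit_window_fraction)
        row.update(tensile_stiffness=ap.tensile_stiffness,
                   compressive_stiffness=ap.compressive_stiffness,
                   axial_rom=ap.axial_rom, axial_hysteresis=ap.axial_hysteresis)
        to = traces[(aid, "torsional")]
        t, th, tq = biomech.extract_cycle(
            to["time_s"].values, to["primary"].values, to["conjugate"].values,
            cycle_index, cfg.cycle_frequency_hz, cfg.n_cycles)
        tp = biomech.torsional_properties(t, th, tq, fit_window_fraction)
        row.update(torsional_stiffness=tp.torsional_stiffness,
                   torque_range=tp.torque_range,
                   torsional_hysteresis=tp.torsional_hysteresis)
        cc = creeps[aid]
        fit = biomech.fit_creep_model(cc["time_s"].values,
                                      cc["displacement_mm"].values,
                                      cc["load_n"].iloc[0])
        if fit.converged:
            row.update(elastic_stiffness=fit.elastic_stiffness,
                       fast_stiffness=fit.fast_stiffness,
                       slow_stiffness=fit.slow_stiffness,
                       fast_time_constant=fit.fast_time_constant,
                       slow_time_constant=fit.slow_time_constant,
                       total_displacement=fit.total_displacement)
        else:  # failed fit propagates as missing traits
            row.update({k: np.nan for k in (
                "elastic_stiffness", "fast_stiffness", "slow_stiffness",
                "fast_time_constant", "slow_time_constant", "total_displacement")})
        rows.append(row)
    return pd.DataFrame(rows)


def reduce_dataset(ds: StudyDataset, cycle_index: int = 20,
                   fit_window_fraction: float = 0.2,
                   rout_q_percent: float = 1.0) -> dict:
    """All endpoint reductions as tidy frames keyed by reduction name."""
    return {
        "von_frey": phenotypes.von_frey_table(ds.filament_responses),
        "heights": phenotypes.height_percent_change(
            ds.ivd_heights, ds.config.punctured_levels),
        "grades": phenotypes.total_degeneration_grade(ds.histology),
        "expression": phenotypes.expression_table(
            ds.ct_records, ds.animals, rout_q_percent),
        "biomech": reduce_biomech(ds, cycle_index, fit_window_fraction),
    }


def trait_tables(ds: StudyDataset, reduced: dict,
                 trait_classes: dict | None = None) -> dict:
    return {sex: assemble_trait_table(ds.animals, reduced, sex, trait_classes)
            for sex in ("female", "male")}


def edge_list(graph: nx.Graph) -> pd.DataFrame:
    rows = [dict(trait_a=u, trait_b=v, rho=d["rho"], q=d["q"], sign=d["sign"])
            for u, v, d in graph.edges(data=True)]
    return pd.DataFrame(rows, columns=["trait_a", "trait_b", "rho", "q", "sign"])


def run_stats(tables: dict, ds: StudyDataset, traits=ANOVA_TRAITS):
    """2-way (injury x sex) ANOVA with Tukey for the main endpoint traits."""
    merged = pd.concat(
        [tables[sex].assign(sex=sex) for sex in tables], axis=0).reset_index()
    recs, logs = [], []
    for trait in traits:
        if trait not in merged.columns:
            continue
        sub = merged[["animal_id", "sex", "injury", trait]].copy()
        sub["injury_group"] = np.where(sub["injury"] > 0, "injury", "sham")
        try:
            res = two_way_anova(sub, trait, "injury_group", "sex")
        except StatsError as exc:
            logs.append(f"{trait}: ANOVA skipped ({exc})")
            continue
        for _, r in res.table.iterrows():
            if r["term"] == "residual":
                continue
            recs.append(dict(trait=trait, term=r["term"], F=r["F"], p=r["p"],
                             df=r["df"]))
        lines = [f"== {trait} =="]
        lines += [f"  {r['term']}: F={r['F']:.3f} p={r['p']:.4g}"
                  for _, r in res.table.iterrows() if r["term"] != "residual"]
        lines += [f"  Tukey {r.group_a} vs {r.group_b}: diff={r.mean_diff:.3g} "
                  f"p_adj={r.p_adj:.4g}" for _, r in res.tukey.iterrows()]
        logs.append("\n".join(lines))
    return pd.DataFrame(recs), "\n\n".join(logs)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: PipelineConfig, out_dir=None,
                 dataset: StudyDataset | None = None) -> dict:
    """Execute every stage and write all artifacts; returns the manifest.

    A pre-built (e.g. imported) dataset can be supplied in place of
    simulation; given identical values, downstream artifacts are identical.
    """
    cfg.validate()
    out = Path(out_dir if out_dir is not None else cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings = {}

    t0 = time.perf_counter()
    ds = dataset if dataset is not None else generate_study(cfg.study)
    dio.write_dataset(ds, out / "dataset")
    timings["simulate_s"] = round(time.perf_counter() - t0, 3)
    log.info("simulated %d animals (%d excluded)", len(ds.animals),
             len(ds.excluded_ids))

    t0 = time.perf_counter()
    reduced = reduce_dataset(ds, cfg.cycle_index, cfg.fit_window_fraction,
                             cfg.rout_q_percent)
    tables = trait_tables(ds, reduced)
    for sex, tbl in tables.items():
        tbl.to_csv(out / f"traits_{sex}.csv")
    timings["reduce_s"] = round(time.perf_counter() - t0, 3)

    t0 = time.perf_counter()
    stats_df, stats_log = run_stats(tables, ds)
    stats_df.to_csv(out / "anova.csv", index=False)
    (out / "anova.txt").write_text(stats_log + "\n")
    timings["stats_s"] = round(time.perf_counter() - t0, 3)

    t0 = time.perf_counter()
    classes = default_trait_classes()
    nets = {}
    for sex, tbl in tables.items():
        g, rho, p, q = network_from_table(tbl, cfg.alpha, cfg.min_pairwise_n,
                                          classes)
        nets[sex] = g
        nx.write_graphml(g, out / f"network_{sex}.graphml")
        edge_list(g).to_csv(out / f"edges_{sex}.tsv", sep="\t", index=False)
    report = compare_networks(nets["male"], nets["female"], EDGES_OF_INTEREST)
    (out / "network_comparison.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, default=str))
    timings["network_s"] = round(time.perf_counter() - t0, 3)

    manifest = {
        "config_hash": config_hash(cfg),
        "seed": cfg.study.seed,
        "config": config_to_dict(cfg),
        "n_animals": int(len(ds.animals)),
        "excluded_ids": ds.excluded_ids,
        "timings": timings,
        "checksums": {p.name: _checksum(p)
                      for p in sorted(out.rglob("*")) if p.is_file()
                      and p.name != "manifest.json"},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
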