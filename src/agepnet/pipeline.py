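"""End-to-end orchestration: filter -> stats -> network -> communities -> tables.

A :class:`RunConfig` either points at input files (ICSR table + ATC map) or
carries a simulation block; :func:`run_pipeline` executes every stage,
writes all outputs under one directory and records a manifest with the
seed, versions and flow counters.  Identical config + seed produce
byte-identical CSV outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import shutil
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import __version__
from .community import cluster_summary, leading_eigenvector, louvain, stratified_analysis
from .cooccurrence import (
    combination_table,
    format_table,
    marginal_prevalence,
    top_table,
)
from .descriptive import demographics_table
from .icsr import TableDialect, load_report_set
from .network import build_graph, export_graph, filter_graph
from .simulate import SimConfig, generate_reports, simulate_report_set
from .types import ReportSet

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are removed."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Everything one analysis run needs.

    Exactly one of (``icsr_table`` + ``atc_map``) or ``simulate`` must be
    provided.
    """

    output_dir: str = "agepnet_out"
    icsr_table: Optional[str] = None
    atc_map: Optional[str] = None
    simulate: Optional[SimConfig] = None
    top_n: int = 20
    min_edge_weight: int = 1
    stratify: tuple[str, ...] = ("sex", "age65")
    attach_oe: bool = True
    seed: int = 0
    dialect: TableDialect = field(default_factory=TableDialect)

    def __post_init__(self) -> None:
        file_mode = self.icsr_table is not None and self.atc_map is not None
        if not file_mode and self.simulate is None:
            raise ValueError(
                "config needs either input paths (icsr_table + atc_map) "
                "or a simulate block"
            )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulate", None)
        if sim is not None:
            from .simulate import NoiseConfig, TherapyProfile

            profiles = [TherapyProfile(**p) for p in sim.pop("profiles", [])]
            noise = NoiseConfig(**sim.pop("noise", {}))
            universe = [tuple(x) for x in sim.pop("drug_universe", [])]
            sim = SimConfig(profiles=profiles, noise=noise,
                            drug_universe=universe, **sim)
        dialect = TableDialect(**raw.pop("dialect", {}))
        if "stratify" in raw:
            raw["stratify"] = tuple(raw["stratify"])
        return cls(simulate=sim, dialect=dialect, **raw)


def _load_cohort(config: RunConfig) -> ReportSet:
    if config.simulate is not None:
        sim = dataclasses.replace(config.simulate, seed=config.seed)
        report_set, _ = simulate_report_set(sim)
        return report_set
    return load_report_set(config.icsr_table, config.atc_map, config.dialect)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the manifest dictionary.

    Stage order: cohort (filtering), marginal/pair/triad statistics,
    network build + export, Louvain and leading-eigenvector clustering with
    summaries, demographic table, stratified reruns.  Any stage failure
    raises :class:`StageError` and removes the partially written output
    directory.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "agepnet",
        "version": __version__,
        "seed": config.seed,
        "outputs": [],
        "timings_s": {},
    }

    def emit(name: str, writer) -> None:
        path = out / name
        writer(path)
        manifest["outputs"].append(name)

    stage = "cohort"
    try:
        t0 = time.perf_counter()
        cohort = _load_cohort(config)
        if cohort.flow is not None:
            manifest["flow"] = {
                "extracted": cohort.flow.extracted,
                "after_duplicate_removal": cohort.flow.after_duplicate_removal,
                "after_drug_exclusions": cohort.flow.after_drug_exclusions,
                "retained": cohort.flow.retained,
            }
            emit("flow.csv",
                 lambda p: cohort.flow.to_frame().to_csv(p, index=False))
        manifest["timings_s"][stage] = round(time.perf_counter() - t0, 3)

        stage = "stats"
        t0 = time.perf_counter()
        if cohort.n_reports == 0:
            raise ValueError("no reports retained after exclusions")
        marginals = marginal_prevalence(cohort)
        emit("marginals.csv", lambda p: format_table(
            top_table(marginals, "n", config.top_n)).to_csv(p, index=False))
        emit("marginals_full.csv",
             lambda p: marginals.to_csv(p, index=False))
        for k, name in ((2, "pairs"), (3, "triads")):
            table = combination_table(cohort, k)
            emit(f"{name}.csv", lambda p, t=table: format_table(
                top_table(t, "n_obs", config.top_n)).to_csv(p, index=False)
                if len(t) else t.to_csv(p, index=False))
        manifest["timings_s"][stage] = round(time.perf_counter() - t0, 3)

        stage = "network"
        t0 = time.perf_counter()
        graph = build_graph(cohort, attach_oe=config.attach_oe)
        view = filter_graph(graph, min_edge_weight=config.min_edge_weight)
        emit("network.graphml", lambda p: export_graph(view, p, "graphml"))
        emit("network.gexf", lambda p: export_graph(view, p, "gexf"))
        emit("edges.csv", lambda p: export_graph(view, p, "csv"))
        manifest["timings_s"][stage] = round(time.perf_counter() - t0, 3)

        stage = "communities"
        t0 = time.perf_counter()
        part_louvain = louvain(graph, seed=config.seed)
        part_eigen = leading_eigenvector(graph)
        manifest["modularity"] = {
            "louvain": part_louvain.modularity,
            "leading_eigenvector": part_eigen.modularity,
        }
        emit("communities_louvain.csv",
             lambda p: part_louvain.to_frame().to_csv(p, index=False))
        emit("communities_eigenvector.csv",
             lambda p: part_eigen.to_frame().to_csv(p, index=False))
        summary = cluster_summary(graph, part_louvain, cohort, config.top_n)
        emit("cluster_overview.csv",
             lambda p: summary.overview.to_csv(p, index=False))
        emit("cluster_top_drugs.csv",
             lambda p: summary.top_drugs.to_csv(p, index=False))
        manifest["timings_s"][stage] = round(time.perf_counter() - t0, 3)

        stage = "descriptive"
        t0 = time.perf_counter()
        emit("table1.csv", lambda p: demographics_table(
            cohort, "sex").to_csv(p, index=False))
        manifest["timings_s"][stage] = round(time.perf_counter() - t0, 3)

        stage = "stratified"
        t0 = time.perf_counter()
        for strata in config.stratify:
            results = stratified_analysis(cohort, strata, seed=config.seed,
                                          top_n=config.top_n)
            for key, res in results.items():
                safe = key.replace("<", "lt").replace("+", "plus")
                subdir = out / f"stratum_{strata}_{safe}"
                subdir.mkdir(exist_ok=True)
                export_graph(res.graph, subdir / "network.graphml", "graphml")
                res.louvain.to_frame().to_csv(
                    subdir / "communities_louvain.csv", index=False)
                res.leading_eigenvector.to_frame().to_csv(
                    subdir / "communities_eigenvector.csv", index=False)
                res.summary.overview.to_csv(
                    subdir / "cluster_overview.csv", index=False)
                manifest["outputs"].append(f"stratum_{strata}_{safe}/")
        manifest["timings_s"][stage] = round(time.perf_counter() - t0, 3)

        manifest["n_reports"] = cohort.n_reports
        manifest["n_drugs"] = len(cohort.drug_names())
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        manifest["outputs"].append("manifest.json")
    except Exception as exc:  # noqa: BLE001 - stage-named rethrow
        shutil.rmtree(out, ignore_errors=True)
        raise StageError(stage, exc) from exc
    return manifest


def simulate_to_files(sim: SimConfig, out_dir) -> tuple[Path, Path]:
    """Write a simulated raw table + ATC map; returns their paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries, meta, truth = generate_reports(sim)
    merged = entries.merge(meta, on="report_id", how="left")
    table_path = out / "icsr_table.tsv"
    merged.to_csv(table_path, sep="\t", index=False)
    map_path = out / "atc_map.tsv"
    with open(map_path, "w") as fh:
        fh.write("drug_name\tatc_code\n")
        for name, code in sim.drug_universe:
            fh.write(f"{name}\t{code}\n")
    labels_path = out / "ground_truth_labels.tsv"
    with open(labels_path, "w") as fh:
        fh.write("drug\tprofile\n")
        for drug, label in sorted(truth.drug_labels.items()):
            fh.write(f"{drug}\t{label}\n")
    return table_path, map_path
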