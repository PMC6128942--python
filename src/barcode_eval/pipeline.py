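"""End-to-end library evaluation.

Runs the full chain — dataset summary, pairwise distances,
intra/interspecific decomposition, family- and subfamily-level threshold
optimization, best-close-match identification at the optimal threshold,
and haplotype networks for flagged problem groups — and emits one
machine-readable JSON report plus TSV tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np

from . import distance as dist_mod
from . import threshold_opt as th_mod
from .best_close_match import best_close_match, efficiency_summary
from .haplotype_network import (collapse_haplotypes, minimum_spanning_network,
                                shared_haplotypes)
from .io_metadata import (BarcodeDataset, dataset_summary, read_dataset,
                          split_by_taxon)

logger = logging.getLogger("barcode_eval")

REPORT_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    fasta: str | None = None
    metadata: str | None = None
    label: str = "dataset"
    model: str = "K2P"
    grid_min: float = 0.001
    grid_max: float = 0.10
    grid_step: float = 0.001
    rank: str = "subfamily"
    bcm_threshold: float | None = None      # None = use family OT
    singleton_policy: str = "correct"
    problem_cutoff: float | None = None     # None = use family OT
    outdir: str | None = None
    log_level: str = "INFO"


def _percent(x: float) -> float:
    return 100.0 * x


def flag_problem_groups(bcm_report, decomposition: dist_mod.DistanceDecomposition,
                        cutoff: float) -> list[set[str]]:
    """Connected groups of species linked by any interspecific distance
    <= cutoff (transitive closure); these are the candidates for shared or
    near-identical haplotypes that defeat threshold identification."""
    g = nx.Graph()
    close = decomposition.inter[decomposition.inter["distance"] <= cutoff]
    for sp_a, sp_b in zip(close["species_a"], close["species_b"]):
        g.add_edge(sp_a, sp_b)
    return [set(c) for c in nx.connected_components(g)]


def run_pipeline(config: RunConfig,
                 dataset: BarcodeDataset | None = None) -> dict:
    """Evaluate a barcode library end to end; returns the report dict.

    Pass ``dataset`` directly or set fasta/metadata paths in the config.
    When ``config.outdir`` is set, TSV tables, GraphML networks and the
    JSON report are written there.
    """
    logging.basicConfig(level=config.log_level)
    if dataset is None:
        if not (config.fasta and config.metadata):
            raise ValueError("need a dataset or fasta+metadata paths")
        dataset = read_dataset(config.fasta, config.metadata,
                               label=config.label)
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    logger.info("stage summary: %d sequences", len(dataset))
    summary = dataset_summary(dataset)

    logger.info("stage distances (%s)", config.model)
    matrix = dist_mod.distance_matrix(dataset, model=config.model)
    decomp = dist_mod.decompose(matrix, dataset)
    dsum = decomp.summary()

    def _set_percent(d):
        if d["n"]:
            return {"n": d["n"], "mean_percent": _percent(d["mean"]),
                    "min_percent": _percent(d["min"]),
                    "max_percent": _percent(d["max"])}
        return {"n": 0, "mean_percent": None, "min_percent": None,
                "max_percent": None}

    logger.info("stage thresholds")
    grid = th_mod.default_grid(config.grid_min, config.grid_max,
                               config.grid_step)
    family_scan = th_mod.threshold_scan(matrix, dataset.species_labels, grid,
                                        label=dataset.label)
    partition_scans = th_mod.partitioned_scan(dataset, rank=config.rank,
                                              grid=grid, model=config.model)
    comparison = th_mod.compare_family_vs_partitions(family_scan,
                                                     partition_scans)

    logger.info("stage best close match")
    t_bcm = (config.bcm_threshold if config.bcm_threshold is not None
             else family_scan.optimal)
    bcm_report = best_close_match(
        matrix, dataset.species_labels, t_bcm,
        singleton_policy=config.singleton_policy)
    bcm_summary = efficiency_summary(bcm_report)

    logger.info("stage problem groups & networks")
    cutoff = (config.problem_cutoff if config.problem_cutoff is not None
              else family_scan.optimal)
    groups = flag_problem_groups(bcm_report, decomp, cutoff)
    networks = []
    for gi, group in enumerate(sorted(groups, key=sorted)):
        sub = BarcodeDataset(
            [r for r in dataset.records if r.species in group],
            label=f"group{gi + 1}", alignment_length=dataset.alignment_length)
        haps = collapse_haplotypes(sub)
        net = minimum_spanning_network(haps)
        networks.append((sorted(group), net))

    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "parameters": {
            "model": config.model, "rank": config.rank,
            "grid": [config.grid_min, config.grid_max, config.grid_step],
            "bcm_threshold": t_bcm, "problem_cutoff": cutoff,
            "singleton_policy": config.singleton_policy,
        },
        "summary": summary,
        "distances": {
            "intra": _set_percent(dsum["intra"]),
            "inter": _set_percent(dsum["inter"]),
            "n_undefined_pairs": dsum["n_undefined"],
        },
        "family_threshold": {
            "optimal_threshold_percent": _percent(family_scan.optimal),
            "ce": family_scan.ce_at_optimal,
            "fp": family_scan.fp_at_optimal,
            "fn": family_scan.fn_at_optimal,
            "ce_percent": th_mod.cumulative_error_percent(
                family_scan.fp_at_optimal, family_scan.fn_at_optimal,
                len(dataset)),
            "n_doubly_flagged": family_scan.n_doubly_flagged_at_optimal,
        },
        "partition_thresholds": [
            {"taxon": taxon, "n_sequences": len(scan.ids),
             "optimal_threshold_percent": _percent(scan.optimal),
             "ce": scan.ce_at_optimal, "fp": scan.fp_at_optimal,
             "fn": scan.fn_at_optimal}
            for taxon, scan in partition_scans],
        "family_vs_partitions": {
            "family_ce": comparison.family_ce,
            "family_ce_percent": comparison.family_ce_percent,
            "partition_ce_sum": comparison.partition_ce_sum,
            "partition_ce_percent": comparison.partition_ce_percent,
            "n_sequences": comparison.n_sequences,
            "t_statistic": comparison.t_statistic,
            "p_value": comparison.p_value,
            "note": comparison.note,
        },
        "bcm": bcm_summary | {"threshold_percent": _percent(t_bcm)},
        "problem_groups": [
            {"species": sp, "n_haplotypes": len(net.nodes),
             "n_shared_haplotypes": len(shared_haplotypes(net.nodes))}
            for sp, net in networks],
    }

    if outdir:
        matrix.to_tsv(outdir / "distance_matrix.tsv")
        dist_mod.pairs_long_format(matrix, dataset).to_csv(
            outdir / "pairs.tsv", sep="\t", index=False)
        family_scan.to_frame().to_csv(outdir / "threshold_scan_family.tsv",
                                      sep="\t", index=False)
        for taxon, scan in partition_scans:
            scan.to_frame().to_csv(
                outdir / f"threshold_scan_{taxon}.tsv", sep="\t", index=False)
        bcm_report.to_tsv(outdir / "bcm.tsv")
        for gi, (sp, net) in enumerate(networks):
            net.node_table().to_csv(outdir / f"network_group{gi + 1}_nodes.tsv",
                                    sep="\t", index=False)
            net.edge_table().to_csv(outdir / f"network_group{gi + 1}_edges.tsv",
                                    sep="\t", index=False)
            net.to_graphml(outdir / f"network_group{gi + 1}.graphml")
        (outdir / "report.json").write_text(
            json.dumps(report, indent=2, default=_json_default) + "\n")
    return report


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
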