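"""End-to-end orchestration: simulate/load -> assign -> enrich -> randomize
-> network -> direction, with one config, fixed seeds and a JSON report.

The report collects the headline numbers of every stage (significant terms
per cohort and direction, connectivity folds and empirical p-values,
component sizes, direction-split sizes, regulator enrichments) together with
the config echo and seed, so a run is reproducible and auditable from its
output directory alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from . import __version__
from .dosage import regulator_enrichment, reclassify_partial, split_by_direction
from .enrichment import (
    ScanConfig,
    hierarchical_phenotype_scan,
    replication_flag,
    results_to_frame,
)
from .genome_cnv import (
    assign_genes_to_cnvs,
    filter_control_genes,
    read_chrom_sizes,
    read_cnv_calls,
    read_gene_models,
)
from .network import (
    connectivity_permutation_test,
    expand_network,
    largest_component,
    singleton_hub_test,
)
from .ontology import (
    load_ontology,
    map_orthologs,
    propagate_annotations,
    read_annotation_pairs,
    read_orthology,
)
from .randomization import null_pvalue_distribution
from .simulate import (
    NEG_ROOT,
    POS_ROOT,
    SimConfig,
    World,
    generate_cohort,
    generate_world,
)

__all__ = ["run_all", "load_config"]

logger = logging.getLogger(__name__)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def _stage(name: str):
    logger.info("stage %s", name)
    return time.perf_counter()


def _sim_config(block: Mapping[str, Any], seed: int) -> SimConfig:
    fields = {f.name for f in dataclasses.fields(SimConfig)}
    kwargs = {k: v for k, v in block.items() if k in fields}
    unknown = set(block) - fields - {"enabled"}
    if unknown:
        raise ValueError(f"unknown simulate option(s): {sorted(unknown)}")
    kwargs.setdefault("rng_seed", seed)
    # YAML lists -> tuples for range-valued fields
    for k, v in list(kwargs.items()):
        if isinstance(v, list):
            kwargs[k] = tuple(v)
    return SimConfig(**kwargs)


def _load_inputs(block: Mapping[str, Any]):
    required = [
        "genes",
        "chrom_sizes",
        "ontology",
        "annotations",
        "orthology",
        "go_ontology",
        "go_annotations",
        "ppi",
        "case_cnvs",
    ]
    missing = [k for k in required if k not in block]
    if missing:
        raise ValueError(f"missing input path(s): {missing}")
    for k in required + (["control_cnvs"] if "control_cnvs" in block else []):
        if not Path(block[k]).exists():
            raise FileNotFoundError(f"input {k!r}: {block[k]}")
    catalog = read_gene_models(block["genes"])
    chrom_sizes = read_chrom_sizes(block["chrom_sizes"])
    onto = load_ontology(block["ontology"])
    table = map_orthologs(
        propagate_annotations(read_annotation_pairs(block["annotations"]), onto),
        read_orthology(block["orthology"]),
    )
    go_onto = load_ontology(block["go_ontology"])
    go_table = propagate_annotations(
        read_annotation_pairs(block["go_annotations"]), go_onto
    )
    from .network import load_ppi_edges

    ppi = load_ppi_edges(block["ppi"])
    case = read_cnv_calls(block["case_cnvs"])
    control = (
        read_cnv_calls(block["control_cnvs"]) if "control_cnvs" in block else []
    )
    return catalog, chrom_sizes, onto, table, go_onto, go_table, ppi, case, control


def run_all(
    config: str | Path | Mapping[str, Any],
    outdir: str | Path,
    seed: int | None = None,
) -> dict:
    """Execute the full pipeline from a config mapping or YAML path.

    Returns the run report (also written to ``<outdir>/report.json``).
    """
    if not isinstance(config, Mapping):
        config = load_config(config)
    config = dict(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0) if seed is None else seed)
    rng = np.random.default_rng(seed)
    report: dict[str, Any] = {
        "config": _jsonable(config),
        "seed": seed,
        "version": __version__,
        "stages": {},
        "outputs": {},
    }

    # ----- inputs -------------------------------------------------------
    t0 = _stage("inputs")
    truth: dict = {}
    if "simulate" in config:
        sim_cfg = _sim_config(config.get("simulate") or {}, seed)
        world = generate_world(sim_cfg, outdir / "inputs")
        cohort = generate_cohort(world, sim_cfg, rng, set_label="SIM")
        cohort.write(outdir / "inputs")
        catalog, chrom_sizes = world.catalog, world.chrom_sizes
        onto, table = world.pheno_onto, world.pheno_table
        go_onto, go_table, ppi = world.go_onto, world.go_table, world.ppi
        case, control = cohort.case, cohort.control
        truth = {**world.truth, **cohort.truth}
        report["outputs"]["inputs"] = str(outdir / "inputs")
    elif "inputs" in config:
        (
            catalog,
            chrom_sizes,
            onto,
            table,
            go_onto,
            go_table,
            ppi,
            case,
            control,
        ) = _load_inputs(config["inputs"])
    else:
        raise ValueError("config must contain a 'simulate' or 'inputs' block")
    report["stages"]["inputs"] = {"seconds": time.perf_counter() - t0}

    # ----- assignment ---------------------------------------------------
    t0 = _stage("assign")
    assignment = assign_genes_to_cnvs(case, catalog)
    if control:
        control_assignment = assign_genes_to_cnvs(control, catalog)
        assignment = filter_control_genes(assignment, control_assignment)
    assignment.to_tsv(outdir / "assignment.tsv")
    report["outputs"]["assignment"] = str(outdir / "assignment.tsv")
    report["stages"]["assign"] = {
        "seconds": time.perf_counter() - t0,
        "records": len(assignment),
        "genes_all": len(assignment.gene_set("all")),
        "genes_gain": len(assignment.gene_set("gain")),
        "genes_loss": len(assignment.gene_set("loss")),
    }

    # ----- enrichment scan ----------------------------------------------
    t0 = _stage("enrich")
    scan_block = dict(config.get("scan") or {})
    scan_cfg = ScanConfig(
        alpha=float(scan_block.get("alpha", 0.05)),
        gate_extra_categories=tuple(scan_block.get("gate_extra_categories", ())),
        replication_min_sets=int(scan_block.get("replication_min_sets", 3)),
        stage2_family=scan_block.get("stage2_family", "joint"),
    )
    results = hierarchical_phenotype_scan(assignment, table, onto, scan_cfg)
    frame = results_to_frame(results)
    frame.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    report["outputs"]["enrichment"] = str(outdir / "enrichment.tsv")
    sig = frame[frame["significant"] == True]  # noqa: E712
    report["stages"]["enrich"] = {
        "seconds": time.perf_counter() - t0,
        "tests": len(frame),
        "significant_terms": {
            f"{s}/{d}": int(((sig["set_label"] == s) & (sig["direction"] == d)).sum())
            for s in sorted(set(frame["set_label"]))
            for d in sorted(set(frame["direction"]))
        },
        "replicated_terms": sorted(
            replication_flag(results, scan_cfg.replication_min_sets)
        ),
    }

    # ----- randomization (optional) -------------------------------------
    rand_block = dict(config.get("randomization") or {})
    if rand_block.get("enabled", False):
        t0 = _stage("randomize")
        rand_report = null_pvalue_distribution(
            case,
            catalog,
            table,
            onto,
            chrom_sizes,
            n_reps=int(rand_block.get("n_reps", 500)),
            rng=rng,
        )
        rand_report.pvalues.to_csv(
            outdir / "null_pvalues.tsv", sep="\t", index=False
        )
        with open(outdir / "randomization.json", "w") as fh:
            json.dump(rand_report.to_json_dict(), fh, indent=2)
        report["outputs"]["randomization"] = str(outdir / "randomization.json")
        report["stages"]["randomize"] = {
            "seconds": time.perf_counter() - t0,
            "n_reps": rand_report.n_reps,
            "ks": rand_report.to_json_dict()["ks"],
        }
    else:
        report["stages"]["randomize"] = {"skipped": True}

    # ----- network -------------------------------------------------------
    t0 = _stage("network")
    net_block = dict(config.get("network") or {})
    n_perms = int(net_block.get("n_perms", 500))
    seed_term = net_block.get("seed_term")
    if seed_term is None and truth:
        seed_term = truth.get("planted_term") or truth.get("planted_term", None)
    if seed_term is None:
        stage2 = frame[(frame["stage"] == 2) & (frame["significant"] == True)]  # noqa: E712
        seed_term = (
            stage2.sort_values("p_raw").iloc[0]["term_id"] if len(stage2) else None
        )
    network_report: dict[str, Any] = {"seconds": None}
    if seed_term is None:
        network_report["skipped"] = "no seed term available"
    else:
        cnv_genes = assignment.gene_set("all")
        seed_genes = sorted(cnv_genes & table.genes_with_term(seed_term))
        if not seed_genes:
            network_report["skipped"] = f"no CNV genes carry seed term {seed_term}"
        else:
            pool = sorted(ppi.nodes)
            conn = connectivity_permutation_test(
                seed_genes, ppi, pool, n_perms=n_perms, rng=rng
            )
            candidates = expand_network(
                seed_genes,
                sorted(cnv_genes),
                ppi,
                gene_directions=assignment.gene_directions(),
                gene_patients=assignment.gene_patients(),
            )
            candidates.to_tsv(outdir / "candidates.tsv")
            comp = largest_component(candidates.edges, candidates.genes)
            counts = candidates.patient_counts()
            hub: dict[str, Any] | None = None
            if (counts == 1).any() and (counts > 1).any():
                h = singleton_hub_test(candidates)
                hub = {
                    "median_single": h.median_single,
                    "median_multi": h.median_multi,
                    "p_value": h.p_value,
                }
            network_report.update(
                {
                    "seed_term": seed_term,
                    "seed_genes": len(seed_genes),
                    "candidate_genes": len(candidates.genes),
                    "observed_edges": conn.observed_edges,
                    "fold": conn.fold,
                    "p_emp": conn.p_emp,
                    "component_sizes": comp[:5],
                    "largest_component_fraction": (
                        comp[0] / len(candidates.genes) if candidates.genes else None
                    ),
                    "patients_with_candidates": int(len(counts)),
                    "median_candidates_per_patient": (
                        float(counts.median()) if len(counts) else None
                    ),
                    "singleton_hub_test": hub,
                }
            )
            report["outputs"]["candidates"] = str(outdir / "candidates.tsv")
    network_report["seconds"] = time.perf_counter() - t0
    report["stages"]["network"] = network_report

    # ----- dosage direction ----------------------------------------------
    t0 = _stage("direction")
    dir_block = dict(config.get("direction") or {})
    pos_term = dir_block.get("pos_term", POS_ROOT)
    neg_term = dir_block.get("neg_term", NEG_ROOT)
    directions = assignment.gene_directions()
    direction_report: dict[str, Any] = {}
    if directions:
        split = split_by_direction(directions)
        if dir_block.get("reclassify_partial", True):
            split = reclassify_partial(
                split, assignment.genes_with_all_partial_gains()
            )
        direction_report["split"] = split.sizes()
        if pos_term in go_table.term_genes or neg_term in go_table.term_genes:
            reg = regulator_enrichment(
                {
                    "duplications": split.dup_only,
                    "deletions": split.del_only,
                },
                go_table,
                pos_term,
                neg_term,
                alpha=float(dir_block.get("alpha", 0.05)),
            )
            direction_report["regulators"] = [
                {
                    "set": r.set_label,
                    "class": r.direction,
                    "k": r.k,
                    "n": r.n,
                    "fold": r.fold,
                    "p_bh": r.p_bh,
                    "significant": r.significant,
                }
                for r in reg
            ]
    else:
        direction_report["skipped"] = "no direction records"
    direction_report["seconds"] = time.perf_counter() - t0
    report["stages"]["direction"] = direction_report

    with open(outdir / "report.json", "w") as fh:
        json.dump(_jsonable(report), fh, indent=2)
    report["outputs"]["report"] = str(outdir / "report.json")
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, Path):
        return str(obj)
    return obj
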