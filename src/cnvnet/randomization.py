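"""Matched random genomic regions and the null-calibration control.

If the gene-assignment rule or the genome's gene geography biased the
enrichment test (long genes under long CNVs, clustered paralogues, ...),
random regions matched in number and size to the observed CNV regions would
show it: their stage-1 category p-values would depart from Uniform(0, 1).
This module draws such matched region sets — chromosome chosen with
probability proportional to its length among chromosomes long enough to hold
the region, start uniform over valid positions — and summarises the null
p-value distribution per category with a Kolmogorov-Smirnov test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import kstest

from .enrichment import fisher_enrichment
from .genome_cnv import (
    CNVCall,
    GeneCatalog,
    GenomicInterval,
    assign_genes_to_cnvs,
)
from .ontology import AnnotationTable, Ontology

__all__ = [
    "RandomizationReport",
    "sample_matched_regions",
    "null_pvalue_distribution",
]


def _as_rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def sample_matched_regions(
    template: Sequence[GenomicInterval],
    genome: Mapping[str, int],
    rng: np.random.Generator | int | None = None,
    mask: Sequence[GenomicInterval] = (),
    max_tries: int = 1000,
) -> list[GenomicInterval]:
    """One random region per template region, with identical length.

    ``genome`` maps chromosome -> length.  Regions may overlap each other.
    ``mask`` optionally excludes intervals (e.g. assembly gaps): placements
    overlapping a masked interval are rejected and redrawn.
    """
    rng = _as_rng(rng)
    chroms = sorted(genome)
    lengths = np.array([genome[c] for c in chroms], dtype=np.int64)
    out = []
    for region in template:
        L = region.length
        eligible = lengths >= L
        if not eligible.any():
            raise ValueError(
                f"template region of length {L} exceeds every chromosome"
            )
        probs = np.where(eligible, lengths, 0).astype(float)
        probs /= probs.sum()
        for _ in range(max_tries):
            ci = int(rng.choice(len(chroms), p=probs))
            start = int(rng.integers(1, lengths[ci] - L + 2))
            cand = GenomicInterval(chroms[ci], start, start + L - 1)
            if not any(cand.overlaps(m) for m in mask):
                break
        else:
            raise RuntimeError("could not place region outside mask")
        out.append(cand)
    return out


@dataclass
class RandomizationReport:
    """Null stage-1 p-values over randomized region sets.

    ``pvalues``: one row per replicate, one column per category root.
    ``ks``: per-category (statistic, p) against Uniform(0, 1); None when
    fewer than 2 replicates were run.
    """

    n_reps: int
    pvalues: pd.DataFrame
    ks: dict[str, tuple[float, float]] | None

    def to_json_dict(self) -> dict:
        return {
            "n_reps": self.n_reps,
            "ks": {c: {"stat": s, "p": p} for c, (s, p) in (self.ks or {}).items()},
        }


def null_pvalue_distribution(
    template_cnvs: Sequence[CNVCall],
    catalog: GeneCatalog,
    table: AnnotationTable,
    onto: Ontology,
    genome: Mapping[str, int],
    n_reps: int = 500,
    rng: np.random.Generator | int | None = None,
) -> RandomizationReport:
    """Rebuild assignments on matched random regions ``n_reps`` times and
    record, per replicate, the raw stage-1 category enrichment p-values.

    Replicates whose random regions hit no annotated gene contribute p = 1
    for every category (an empty query can never look enriched).
    """
    rng = _as_rng(rng)
    template = [c.interval for c in template_cnvs]
    roots = sorted(onto.roots)
    universe = table.genes
    rows = []
    for _ in range(n_reps):
        regions = sample_matched_regions(template, genome, rng)
        calls = [
            CNVCall(patient_id="rand", interval=r, direction="gain", set_label="rand")
            for r in regions
        ]
        assignment = assign_genes_to_cnvs(calls, catalog)
        query = assignment.gene_set("all") & universe
        if not query:
            rows.append({root: 1.0 for root in roots})
            continue
        rows.append(
            {
                root: fisher_enrichment(query, table, root).p_raw
                for root in roots
            }
        )
    pvalues = pd.DataFrame(rows, columns=roots)
    ks = None
    if n_reps >= 2:
        ks = {
            root: tuple(map(float, kstest(pvalues[root].to_numpy(), "uniform")[:2]))
            for root in roots
        }
    return RandomizationReport(n_reps=n_reps, pvalues=pvalues, ks=ks)
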