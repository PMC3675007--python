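"""Direction-of-copy-change analysis of candidate genes.

Deleted and duplicated genes can perturb the same pathway in the same
direction: deleting a positive regulator of a process and duplicating a
negative regulator of it both push the process down.  This module splits
candidate genes by the direction of their copy change, optionally
reclassifies partially duplicated (hence likely disrupted, deletion-like)
genes as deleted, and tests each direction set for enrichment of positive
(GO:0048518-style) and negative (GO:0048519-style) regulators against the
genome-wide GO-annotated background.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .enrichment import EnrichmentResult, bh_adjust, fisher_enrichment
from .ontology import AnnotationTable

__all__ = [
    "DirectionSplit",
    "split_by_direction",
    "reclassify_partial",
    "regulator_flags",
    "regulator_enrichment",
]


@dataclass(frozen=True)
class DirectionSplit:
    """Partition of candidate genes by copy-change direction.

    ``both`` holds genes duplicated in one patient and deleted in another;
    they are excluded from the direction-specific tests to avoid double
    counting.
    """

    dup_only: frozenset[str]
    del_only: frozenset[str]
    both: frozenset[str]

    def __post_init__(self) -> None:
        if (
            self.dup_only & self.del_only
            or self.dup_only & self.both
            or self.del_only & self.both
        ):
            raise ValueError("direction sets must be pairwise disjoint")

    @property
    def all_genes(self) -> frozenset[str]:
        return self.dup_only | self.del_only | self.both

    def sizes(self) -> dict[str, int]:
        return {
            "dup_only": len(self.dup_only),
            "del_only": len(self.del_only),
            "both": len(self.both),
        }


def split_by_direction(gene_directions: Mapping[str, Iterable[str]]) -> DirectionSplit:
    """Partition genes into duplication-only, deletion-only and both.

    ``gene_directions`` maps gene -> its copy-change direction records
    ({'gain'}, {'loss'} or {'gain', 'loss'}); a gene with no record is an
    error.
    """
    dup, dele, both = set(), set(), set()
    for gene, dirs in gene_directions.items():
        dirs = set(dirs)
        if not dirs:
            raise ValueError(f"candidate {gene!r} has no direction record")
        unknown = dirs - {"gain", "loss"}
        if unknown:
            raise ValueError(f"candidate {gene!r} has unknown direction(s) {unknown}")
        if dirs == {"gain"}:
            dup.add(gene)
        elif dirs == {"loss"}:
            dele.add(gene)
        else:
            both.add(gene)
    return DirectionSplit(frozenset(dup), frozenset(dele), frozenset(both))


def reclassify_partial(
    split: DirectionSplit, partial_flags: Mapping[str, bool] | Iterable[str]
) -> DirectionSplit:
    """Move duplication-only genes whose every duplication is partial into
    the deletion-only set (a truncated copy functionally resembles a
    deletion).  Genes with at least one full-length duplication stay put;
    the total candidate count is conserved.
    """
    if isinstance(partial_flags, Mapping):
        all_partial = {g for g, v in partial_flags.items() if v}
    else:
        all_partial = set(partial_flags)
    moving = split.dup_only & all_partial
    return DirectionSplit(
        dup_only=split.dup_only - moving,
        del_only=split.del_only | moving,
        both=split.both,
    )


def regulator_flags(
    go_table: AnnotationTable, pos_term: str, neg_term: str
) -> pd.DataFrame:
    """Per-gene positive/negative regulator booleans from the propagated GO
    table (annotation to either regulator root; a gene may carry both)."""
    pos = go_table.genes_with_term(pos_term)
    neg = go_table.genes_with_term(neg_term)
    genes = sorted(go_table.genes)
    return pd.DataFrame(
        {
            "gene_id": genes,
            "positive_regulator": [g in pos for g in genes],
            "negative_regulator": [g in neg for g in genes],
        }
    )


def regulator_enrichment(
    queries: Mapping[str, Iterable[str]],
    go_table: AnnotationTable,
    pos_term: str,
    neg_term: str,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """One-sided Fisher enrichment of positive and negative regulators in
    each query set versus the GO-annotated genome background; BH-corrected
    over all tests in the batch.

    ``queries`` maps a label (e.g. ``deletions`` / ``duplications``) to its
    gene set.  Typical batch: 2 direction sets x 2 regulator classes.
    """
    if not go_table.genes:
        raise ValueError("empty GO background")
    results = []
    for label in queries:
        genes = set(queries[label]) & go_table.genes
        for term, cls in ((pos_term, "positive"), (neg_term, "negative")):
            if genes:
                r = fisher_enrichment(
                    genes, go_table, term, set_label=label, direction=cls
                )
            else:
                r = EnrichmentResult(
                    term_id=term,
                    k=0,
                    n=0,
                    K=len(go_table.genes_with_term(term)),
                    N=len(go_table.genes),
                    p_raw=1.0,
                    set_label=label,
                    direction=cls,
                )
            results.append(r)
    bh_adjust(results, alpha)
    return results
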