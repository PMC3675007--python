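"""One-sided Fisher enrichment, BH correction and the category-gated scan.

With only a few dozen de novo CNVs per cohort and no de novo control set, a
case/control comparison is not possible; instead each term is tested against
the genome-wide background of annotated genes: does the query gene set carry
the term more often than a random draw of the same size would?  That is a
one-sided Fisher's exact test (hypergeometric upper tail).

The scan is hierarchical to limit the multiple-testing burden: stage 1 tests
only the top-level category roots per cohort and copy-change direction;
stage 2 descends into the populated finer terms of the categories that pass
(plus any categories force-included on a-priori grounds, e.g. a nervous-
system category for a behavioural disorder).  Benjamini-Hochberg correction
is applied within each declared test family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .genome_cnv import GeneAssignment
from .ontology import AnnotationTable, Ontology, filter_populated_terms

__all__ = [
    "EnrichmentResult",
    "ScanConfig",
    "fisher_enrichment",
    "bh_adjust",
    "hierarchical_phenotype_scan",
    "replication_flag",
    "results_to_frame",
]


@dataclass
class EnrichmentResult:
    """A 2x2 enrichment test of one term in one query gene set.

    k of n query genes carry the term; K of N background genes do.  ``fold``
    is the ratio of observed to expected carriers, k / (n*K/N); it is None
    (reported missing) when K == 0 or n == 0.
    """

    term_id: str
    k: int
    n: int
    K: int
    N: int
    p_raw: float
    set_label: str = ""
    direction: str = "all"
    category_id: str = ""
    stage: int = 0
    p_bh: float | None = None
    significant: bool | None = None

    @property
    def fold(self) -> float | None:
        if self.K == 0 or self.n == 0:
            return None
        return self.k * self.N / (self.n * self.K)


@dataclass(frozen=True)
class ScanConfig:
    """Knobs of the hierarchical scan.

    alpha: BH false-discovery level (default 0.05, the customary 5%).
    gate_extra_categories: category roots whose fine terms are tested even if
        the root itself misses stage-1 significance.
    replication_min_sets: cohorts a term must be significant in to count as
        replicated (3 = "triplicated").
    stage2_family: "joint" corrects all stage-2 terms of a (set, direction)
        together; "per_category" corrects within each category separately.
    populated_threshold: minimum fraction of a category's genes a term must
        annotate to be testable.
    """

    alpha: float = 0.05
    gate_extra_categories: tuple[str, ...] = ()
    replication_min_sets: int = 3
    stage2_family: str = "joint"
    populated_threshold: float = 0.01
    directions: tuple[str, ...] = ("all", "gain", "loss")

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.stage2_family not in ("joint", "per_category"):
            raise ValueError(f"unknown stage2_family {self.stage2_family!r}")


def fisher_enrichment(
    query_genes: Iterable[str],
    background_table: AnnotationTable,
    term: str,
    *,
    set_label: str = "",
    direction: str = "all",
) -> EnrichmentResult:
    """One-sided (greater) Fisher's exact test of ``term`` in the query.

    The background universe is the set of genes with >= 1 annotation in the
    table; query genes outside that universe are ignored (no information).
    A term absent from the background yields K = 0 and p = 1.
    """
    universe = background_table.genes
    query = set(query_genes) & universe
    if not query:
        raise ValueError("query contains no annotated genes")
    term_set = background_table.genes_with_term(term)
    N = len(universe)
    n = len(query)
    K = len(term_set)
    k = len(query & term_set)
    if K == 0:
        p = 1.0
    else:
        # upper tail P(X >= k) of Hypergeom(N, K, n)
        p = float(hypergeom.sf(k - 1, N, K, n))
    return EnrichmentResult(
        term_id=term,
        k=k,
        n=n,
        K=K,
        N=N,
        p_raw=min(p, 1.0),
        set_label=set_label,
        direction=direction,
    )


def bh_adjust(
    results: Sequence[EnrichmentResult], alpha: float = 0.05
) -> list[EnrichmentResult]:
    """Benjamini-Hochberg step-up over one test family; flags significance
    at ``p_bh <= alpha``.  Returns the same result objects, annotated."""
    if not results:
        return []
    pvals = [r.p_raw for r in results]
    reject, p_bh, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    for r, adj, rej in zip(results, p_bh, reject):
        r.p_bh = float(adj)
        r.significant = bool(r.p_bh <= alpha)
    return list(results)


def _scan_one(
    query: set[str],
    table: AnnotationTable,
    onto: Ontology,
    cfg: ScanConfig,
    populated: set[str],
    set_label: str,
    direction: str,
) -> list[EnrichmentResult]:
    roots = sorted(onto.roots)
    stage1 = []
    for root in roots:
        r = fisher_enrichment(
            query, table, root, set_label=set_label, direction=direction
        )
        r.stage = 1
        r.category_id = root
        stage1.append(r)
    bh_adjust(stage1, cfg.alpha)

    gated = [r.term_id for r in stage1 if r.significant]
    for extra in cfg.gate_extra_categories:
        if extra in onto.roots and extra not in gated:
            gated.append(extra)

    # collect testable descendants per gated category
    per_cat: dict[str, list[str]] = {}
    for cat in gated:
        members = sorted((onto.descendants(cat) & populated) - onto.roots)
        per_cat[cat] = members

    stage2: list[EnrichmentResult] = []
    if cfg.stage2_family == "per_category":
        for cat, terms in per_cat.items():
            fam = []
            for t in terms:
                r = fisher_enrichment(
                    query, table, t, set_label=set_label, direction=direction
                )
                r.stage = 2
                r.category_id = cat
                fam.append(r)
            bh_adjust(fam, cfg.alpha)
            stage2.extend(fam)
    else:  # joint family across categories; each term tested once
        term_cats: dict[str, list[str]] = {}
        for cat, terms in per_cat.items():
            for t in terms:
                term_cats.setdefault(t, []).append(cat)
        fam = []
        for t in sorted(term_cats):
            r = fisher_enrichment(
                query, table, t, set_label=set_label, direction=direction
            )
            r.stage = 2
            r.category_id = ",".join(sorted(term_cats[t]))
            fam.append(r)
        bh_adjust(fam, cfg.alpha)
        stage2 = fam
    return stage1 + stage2


def hierarchical_phenotype_scan(
    assignment: GeneAssignment,
    table: AnnotationTable,
    onto: Ontology,
    cfg: ScanConfig | None = None,
) -> list[EnrichmentResult]:
    """Two-stage category-gated enrichment scan over every cohort and
    direction (all / gain / loss) in the assignment."""
    cfg = cfg or ScanConfig()
    populated = filter_populated_terms(table, onto, cfg.populated_threshold)
    universe = table.genes
    out: list[EnrichmentResult] = []
    for set_label in assignment.set_labels():
        for direction in cfg.directions:
            query = assignment.gene_set(direction, set_label) & universe
            if not query:
                warnings.warn(
                    f"no annotated query genes for set={set_label!r} "
                    f"direction={direction!r}; skipping"
                )
                continue
            out.extend(
                _scan_one(query, table, onto, cfg, populated, set_label, direction)
            )
    return out


def replication_flag(
    results: Iterable[EnrichmentResult], min_sets: int = 3
) -> set[str]:
    """Terms BH-significant in at least ``min_sets`` distinct cohorts."""
    per_term: dict[str, set[str]] = {}
    for r in results:
        if r.significant:
            per_term.setdefault(r.term_id, set()).add(r.set_label)
    return {t for t, sets in per_term.items() if len(sets) >= min_sets}


def results_to_frame(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    rows = [
        {
            "set_label": r.set_label,
            "direction": r.direction,
            "stage": r.stage,
            "category_id": r.category_id,
            "term_id": r.term_id,
            "k": r.k,
            "n": r.n,
            "K": r.K,
            "N": r.N,
            "fold": r.fold,
            "p_raw": r.p_raw,
            "p_bh": r.p_bh,
            "significant": r.significant,
        }
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "set_label",
            "direction",
            "stage",
            "category_id",
            "term_id",
            "k",
            "n",
            "K",
            "N",
            "fold",
            "p_raw",
            "p_bh",
            "significant",
        ],
    )
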