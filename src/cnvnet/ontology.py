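"""Ontology loading, annotation propagation and the populated-term filter.

The phenotype resource is modelled as a multi-rooted directed acyclic graph
(DAG) of terms connected by ``is_a`` edges, as in the Mammalian Phenotype
Ontology, whose top-level terms are over-arching categories such as
behaviour/neurological or hearing/vestibular/ear.  Gene annotations are
"propagated" (interpolated) upward: a gene annotated to a term is implicitly
annotated to every ancestor of that term, up to the category roots.

Only terms annotating at least 1% of the genes of one of their categories are
considered testable; rarer terms carry too few genes to be informative and
would dilute multiple-testing power.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import obonet

__all__ = [
    "Ontology",
    "AnnotationTable",
    "OrthologyMap",
    "load_ontology",
    "read_annotation_pairs",
    "read_orthology",
    "propagate_annotations",
    "map_orthologs",
    "term_categories",
    "filter_populated_terms",
]


class Ontology:
    """A DAG of terms; edges run child -> parent along ``is_a`` links."""

    def __init__(
        self,
        edges: Iterable[tuple[str, str]],
        names: Mapping[str, str] | None = None,
        extra_terms: Iterable[str] = (),
    ):
        g = nx.DiGraph()
        g.add_edges_from(edges)
        g.add_nodes_from(extra_terms)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValueError(f"ontology contains a cycle: {cycle}")
        self.graph = g
        self.names = dict(names or {})
        self.roots = frozenset(n for n in g.nodes if g.out_degree(n) == 0)
        self._anc_cache: dict[str, frozenset[str]] = {}

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def terms(self) -> list[str]:
        return list(self.graph.nodes)

    def parents(self, term: str) -> set[str]:
        return set(self.graph.successors(term))

    def ancestors(self, term: str) -> frozenset[str]:
        """All terms reachable from ``term`` via is_a, excluding itself."""
        cached = self._anc_cache.get(term)
        if cached is None:
            cached = frozenset(nx.descendants(self.graph, term))
            self._anc_cache[term] = cached
        return cached

    def descendants(self, term: str) -> frozenset[str]:
        """All terms from which ``term`` is reachable, excluding itself."""
        return frozenset(nx.ancestors(self.graph, term))

    def depth(self, term: str) -> int:
        """Length of the longest path from ``term`` up to a root."""
        if term in self.roots:
            return 0
        return 1 + max(self.depth(p) for p in self.parents(term))


def load_ontology(path: str | Path, super_root: str | None = None) -> Ontology:
    """Load an OBO 1.2 file into an :class:`Ontology`.

    Only ``is_a`` relationships are traversed; ``part_of`` and other edge
    types are ignored.  Roots are terms without is_a parents, or — when a
    single designated ``super_root`` exists — its direct children.
    Terms with no edges at all raise a warning (orphans).
    """
    multi = obonet.read_obo(str(path))
    edges = [
        (child, parent)
        for child, parent, key in multi.edges(keys=True)
        if key == "is_a"
    ]
    names = {n: data.get("name", n) for n, data in multi.nodes(data=True)}
    connected = {u for e in edges for u in e}
    orphans = [n for n in multi.nodes if n not in connected]
    if orphans and len(multi.nodes) > 1:
        warnings.warn(f"{len(orphans)} orphan term(s) in {path}: {orphans[:5]}")
    onto = Ontology(edges, names=names, extra_terms=orphans)
    if super_root is not None:
        if super_root not in onto.graph:
            raise ValueError(f"designated super-root {super_root} not in ontology")
        g = onto.graph.copy()
        children = set(g.predecessors(super_root))
        g.remove_node(super_root)
        onto2 = Ontology(g.edges, names=onto.names)
        onto2.roots = frozenset(children)
        return onto2
    return onto


@dataclass
class AnnotationTable:
    """Gene -> term annotations, closed under ancestors after propagation."""

    gene_terms: dict[str, frozenset[str]]
    direct: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        self._term_genes: dict[str, set[str]] | None = None

    @property
    def genes(self) -> set[str]:
        return set(self.gene_terms)

    def __len__(self) -> int:
        return len(self.gene_terms)

    def terms_of(self, gene: str) -> frozenset[str]:
        return self.gene_terms.get(gene, frozenset())

    @property
    def term_genes(self) -> dict[str, set[str]]:
        if self._term_genes is None:
            tg: dict[str, set[str]] = {}
            for gene, terms in self.gene_terms.items():
                for t in terms:
                    tg.setdefault(t, set()).add(gene)
            self._term_genes = tg
        return self._term_genes

    def genes_with_term(self, term: str) -> set[str]:
        return self.term_genes.get(term, set())


@dataclass(frozen=True)
class OrthologyMap:
    """Simple 1:1 orthology pairs; each id occurs in at most one pair."""

    human_to_mouse: Mapping[str, str]

    def __post_init__(self) -> None:
        mouse = list(self.human_to_mouse.values())
        if len(set(mouse)) != len(mouse):
            raise ValueError("orthology map is not 1:1 (duplicated mouse id)")

    @property
    def mouse_to_human(self) -> dict[str, str]:
        return {m: h for h, m in self.human_to_mouse.items()}

    def __len__(self) -> int:
        return len(self.human_to_mouse)


def _rows(path: str | Path):
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield lineno, line.split("\t")


def read_annotation_pairs(path: str | Path) -> list[tuple[str, str]]:
    """Read a ``gene_id<TAB>term_id`` annotation table."""
    pairs = []
    for lineno, fields in _rows(path):
        if fields[0] in ("gene_id", "mouse_gene_id"):
            continue
        if len(fields) < 2:
            raise ValueError(f"{path}:{lineno}: expected 2 columns")
        pairs.append((fields[0], fields[1]))
    return pairs


def read_orthology(path: str | Path) -> OrthologyMap:
    """Read a ``human_id<TAB>mouse_id`` 1:1 orthology table."""
    h2m: dict[str, str] = {}
    for lineno, fields in _rows(path):
        if fields[0] == "human_id":
            continue
        if len(fields) < 2:
            raise ValueError(f"{path}:{lineno}: expected 2 columns")
        human, mouse = fields[0], fields[1]
        if human in h2m:
            raise ValueError(f"{path}:{lineno}: duplicated human id {human}")
        h2m[human] = mouse
    return OrthologyMap(h2m)


def propagate_annotations(
    direct: Iterable[tuple[str, str]], onto: Ontology
) -> AnnotationTable:
    """Annotate each gene with its direct terms plus all their ancestors."""
    direct_map: dict[str, set[str]] = {}
    for row, (gene, term) in enumerate(direct, start=1):
        if term not in onto:
            raise ValueError(f"row {row}: unknown term {term!r} for gene {gene!r}")
        direct_map.setdefault(gene, set()).add(term)
    gene_terms = {}
    for gene, terms in direct_map.items():
        closed = set(terms)
        for t in terms:
            closed |= onto.ancestors(t)
        gene_terms[gene] = frozenset(closed)
    return AnnotationTable(
        gene_terms=gene_terms,
        direct={g: frozenset(t) for g, t in direct_map.items()},
    )


def map_orthologs(mouse_table: AnnotationTable, orth: OrthologyMap) -> AnnotationTable:
    """Re-key a mouse-gene annotation table to human genes via 1:1 orthology.

    Mouse genes without a mapping are dropped: for them no phenotype data can
    be transferred (they are absent, not annotated-with-nothing).
    """
    m2h = orth.mouse_to_human
    gene_terms = {}
    direct = {}
    for mouse, terms in mouse_table.gene_terms.items():
        human = m2h.get(mouse)
        if human is None:
            continue
        gene_terms[human] = terms
        direct[human] = mouse_table.direct.get(mouse, frozenset())
    return AnnotationTable(gene_terms=gene_terms, direct=direct)


def term_categories(onto: Ontology) -> dict[str, frozenset[str]]:
    """Map every term to the set of top-level category roots above it.

    A term under several roots belongs to all of them; roots map to
    themselves.
    """
    roots = onto.roots
    out = {}
    for term in onto.terms:
        if term in roots:
            out[term] = frozenset([term])
        else:
            out[term] = frozenset(onto.ancestors(term) & roots)
    return out


def filter_populated_terms(
    table: AnnotationTable, onto: Ontology, threshold: float = 0.01
) -> set[str]:
    """Terms annotating >= ``threshold`` of the genes of >= 1 of their
    categories (category size = genes propagated to the category root).

    The comparison is inclusive (``>=``) with plain real arithmetic: 2 genes
    in a 200-gene category passes at the default 1%.
    """
    cats = term_categories(onto)
    root_counts = {r: len(table.genes_with_term(r)) for r in onto.roots}
    keep = set()
    for term, genes in table.term_genes.items():
        if term not in onto:
            continue
        for root in cats.get(term, ()):  # pragma: no branch
            if len(genes) >= threshold * root_counts.get(root, 0):
                keep.add(term)
                break
    return keep
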