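"""Protein-protein interaction connectivity with permutation nulls.

The central question: do the protein products of a gene set interact with
each other more often than size-matched random gene sets would?  The
statistic is the number of direct PPI edges with both endpoints inside the
set; the null is built from random draws out of a caller-chosen pool —
either all network genes or an annotation-matched pool (e.g. genes with
behavioural/neurological mouse phenotypes, to discount the tendency of
functionally similar genes to interact).  The empirical p uses the add-one
estimator (1 + #{null >= observed}) / (n_perms + 1), so an observation never
exceeded in 500 permutations reports p = 1/501, the "p < 0.002" convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

__all__ = [
    "ConnectivityResult",
    "CandidateTable",
    "HubTestResult",
    "load_ppi_edges",
    "direct_connectivity",
    "connectivity_permutation_test",
    "expand_network",
    "largest_component",
    "singleton_hub_test",
    "cross_network_connectivity",
]

logger = logging.getLogger(__name__)

SYNAPTIC = "synaptic-phenotype"
IMPLICATED = "implicated"
INTERACTOR = "interactor"


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def load_ppi_edges(path: str | Path) -> nx.Graph:
    """Read an undirected 2-column edge list; deduplicates (a-b == b-a) and
    drops self-loops (the number dropped is logged)."""
    net = nx.Graph()
    self_loops = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] in ("gene_a", "protein_a"):
                continue
            if len(fields) < 2 or not fields[0] or not fields[1]:
                raise ValueError(f"{path}:{lineno}: expected 2 gene ids")
            a, b = fields[0], fields[1]
            if a == b:
                self_loops += 1
                continue
            net.add_edge(a, b)
    if self_loops:
        logger.info("dropped %d self-loop(s) from %s", self_loops, path)
    net.graph["self_loops_dropped"] = self_loops
    return net


def direct_connectivity(genes: Iterable[str], net: nx.Graph) -> int:
    """Number of network edges with both endpoints in ``genes``."""
    members = set(genes) & set(net.nodes)
    return net.subgraph(members).number_of_edges()


@dataclass
class ConnectivityResult:
    """Observed direct connectivity versus a size-matched permutation null."""

    observed_edges: int
    null_mean: float
    fold: float
    p_emp: float
    n_perms: int
    pool_label: str = "all"
    null_counts: np.ndarray | None = field(default=None, repr=False)


def _permutation_null(
    statistic, size: int, pool: list[str], n_perms: int, rng: np.random.Generator
) -> np.ndarray:
    counts = np.empty(n_perms, dtype=np.int64)
    pool_arr = np.array(pool, dtype=object)
    for i in range(n_perms):
        draw = rng.choice(pool_arr, size=size, replace=False)
        counts[i] = statistic(draw)
    return counts


def connectivity_permutation_test(
    genes: Iterable[str],
    net: nx.Graph,
    pool: Sequence[str],
    n_perms: int = 500,
    rng=None,
    pool_label: str = "all",
) -> ConnectivityResult:
    """Permutation test of within-set connectivity.

    Null sets are drawn uniformly without replacement from ``pool`` at the
    query's size.  fold = observed / mean(null); p = (1 + r) / (n_perms + 1)
    where r counts null statistics >= observed.
    """
    rng = _as_rng(rng)
    query = list(dict.fromkeys(genes))
    pool = list(dict.fromkeys(pool))
    if len(pool) < len(query):
        raise ValueError(
            f"pool ({len(pool)}) smaller than query ({len(query)})"
        )
    observed = direct_connectivity(query, net)
    null = _permutation_null(
        lambda draw: direct_connectivity(draw, net), len(query), pool, n_perms, rng
    )
    null_mean = float(null.mean())
    fold = observed / null_mean if null_mean > 0 else float("nan")
    p_emp = (1 + int((null >= observed).sum())) / (n_perms + 1)
    return ConnectivityResult(
        observed_edges=observed,
        null_mean=null_mean,
        fold=fold,
        p_emp=p_emp,
        n_perms=n_perms,
        pool_label=pool_label,
        null_counts=null,
    )


@dataclass
class CandidateTable:
    """The candidate gene network: one row per gene with its evidence class
    (synaptic-phenotype / implicated / interactor), copy-change directions,
    degree within the induced candidate subgraph, and carrying patients."""

    df: pd.DataFrame
    edges: list[tuple[str, str]]

    @property
    def genes(self) -> set[str]:
        return set(self.df["gene_id"])

    def patient_counts(self) -> pd.Series:
        """Candidate genes per patient (patients with >= 1 candidate)."""
        counts: dict[str, int] = {}
        for patients in self.df["patients"]:
            for p in patients:
                counts[p] = counts.get(p, 0) + 1
        return pd.Series(counts, dtype=int).sort_index()

    def degrees(self) -> dict[str, int]:
        return dict(zip(self.df["gene_id"], self.df["degree"]))

    def to_tsv(self, path: str | Path) -> None:
        out = self.df.copy()
        out["directions"] = [",".join(sorted(d)) for d in out["directions"]]
        out["patients"] = [",".join(sorted(p)) for p in out["patients"]]
        out.to_csv(path, sep="\t", index=False)


def expand_network(
    seed_genes: Iterable[str],
    cnv_genes: Iterable[str],
    net: nx.Graph,
    seed_classes: Mapping[str, str] | None = None,
    gene_directions: Mapping[str, set[str]] | None = None,
    gene_patients: Mapping[str, set[str]] | None = None,
) -> CandidateTable:
    """Expand a seed set by the CNV genes whose products directly interact
    with a seed gene's product; return the candidate table plus the induced
    edge list.

    Seed genes are always retained (degree 0 if absent from the network);
    interactor-class membership requires >= 1 edge to a seed by construction.
    """
    seed = list(dict.fromkeys(seed_genes))
    seed_set = set(seed)
    seed_classes = dict(seed_classes or {})
    gene_directions = gene_directions or {}
    gene_patients = gene_patients or {}

    interactors = []
    for g in dict.fromkeys(cnv_genes):
        if g in seed_set or g not in net:
            continue
        if any(nb in seed_set for nb in net.neighbors(g)):
            interactors.append(g)

    expanded = seed + interactors
    induced = net.subgraph([g for g in expanded if g in net])
    edges = sorted(tuple(sorted(e)) for e in induced.edges)
    degree = dict(induced.degree)
    rows = []
    for g in expanded:
        rows.append(
            {
                "gene_id": g,
                "evidence": seed_classes.get(g, SYNAPTIC)
                if g in seed_set
                else INTERACTOR,
                "directions": frozenset(gene_directions.get(g, ())),
                "degree": int(degree.get(g, 0)),
                "patients": frozenset(gene_patients.get(g, ())),
            }
        )
    df = pd.DataFrame(
        rows, columns=["gene_id", "evidence", "directions", "degree", "patients"]
    )
    return CandidateTable(df=df, edges=edges)


def largest_component(
    edges: Iterable[tuple[str, str]], nodes: Iterable[str]
) -> list[int]:
    """Connected-component sizes (descending); isolated nodes count as
    size-1 components."""
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    return sorted((len(c) for c in nx.connected_components(g)), reverse=True)


@dataclass(frozen=True)
class HubTestResult:
    median_single: float
    median_multi: float
    u_stat: float
    p_value: float
    n_single: int
    n_multi: int


def singleton_hub_test(
    candidates: CandidateTable, alternative: str = "two-sided"
) -> HubTestResult:
    """Compare candidate-gene degrees between patients carrying exactly one
    candidate and patients carrying several (Mann-Whitney U).

    One observation per (patient, candidate gene) record: the degree of that
    gene within the induced candidate network.
    """
    counts = candidates.patient_counts()
    single_patients = set(counts[counts == 1].index)
    multi_patients = set(counts[counts > 1].index)
    deg = candidates.degrees()
    single, multi = [], []
    for _, row in candidates.df.iterrows():
        for p in row["patients"]:
            d = deg[row["gene_id"]]
            if p in single_patients:
                single.append(d)
            elif p in multi_patients:
                multi.append(d)
    if not single or not multi:
        raise ValueError("both patient groups must be non-empty")
    u, p = mannwhitneyu(single, multi, alternative=alternative)
    return HubTestResult(
        median_single=float(np.median(single)),
        median_multi=float(np.median(multi)),
        u_stat=float(u),
        p_value=float(p),
        n_single=len(single),
        n_multi=len(multi),
    )


def cross_network_connectivity(
    set_a: Iterable[str],
    set_b: Iterable[str],
    net: nx.Graph,
    pool: Sequence[str],
    n_perms: int = 500,
    rng=None,
    pool_label: str = "all",
) -> ConnectivityResult:
    """Edges between two disjoint gene sets versus size-matched random
    replacements of the second set.

    Genes shared by both sets are excluded before testing; emptying either
    set that way is an error.
    """
    rng = _as_rng(rng)
    a = set(set_a)
    b = set(set_b)
    shared = a & b
    a -= shared
    b -= shared
    if not a or not b:
        raise ValueError("overlap removal emptied one of the sets")

    def between(draw: Iterable[str]) -> int:
        dset = set(draw)
        total = 0
        for g in a:
            if g in net:
                total += sum(1 for nb in net.neighbors(g) if nb in dset)
        return total

    observed = between(b)
    pool_eff = [g for g in dict.fromkeys(pool) if g not in a]
    if len(pool_eff) < len(b):
        raise ValueError("pool smaller than the replacement set")
    null = _permutation_null(between, len(b), pool_eff, n_perms, rng)
    null_mean = float(null.mean())
    fold = observed / null_mean if null_mean > 0 else float("nan")
    p_emp = (1 + int((null >= observed).sum())) / (n_perms + 1)
    return ConnectivityResult(
        observed_edges=observed,
        null_mean=null_mean,
        fold=fold,
        p_emp=p_emp,
        n_perms=n_perms,
        pool_label=pool_label,
        null_counts=null,
    )
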