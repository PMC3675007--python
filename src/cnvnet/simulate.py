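"""Synthetic genomes, ontologies, interactomes and CNV cohorts.

Every input the pipeline consumes can be generated here with declared,
recoverable ground truth: a multi-chromosome gene catalogue with
multi-transcript coding-exon structure, a multi-root phenotype DAG with
sparse gene annotations reached through a 1:1 orthology map, a small GO-like
regulator ontology, a scale-free-ish protein-interaction graph with a
planted dense module, and per-patient case/control CNV cohorts with a
planted term enrichment and a planted regulator-direction skew.

The generator emulates the *structure* of the real resources, not their
content: coordinates are arbitrary, annotation is independent of genomic
position (except where a signal is planted), and the interactome is a
preferential-attachment graph rather than a curated interactome.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np

from .genome_cnv import (
    CNVCall,
    GeneCatalog,
    GeneModel,
    GenomicInterval,
    read_chrom_sizes,
    read_cnv_calls,
    read_gene_models,
    write_cnv_calls,
)
from .network import load_ppi_edges
from .ontology import (
    AnnotationTable,
    Ontology,
    OrthologyMap,
    load_ontology,
    map_orthologs,
    propagate_annotations,
    read_annotation_pairs,
    read_orthology,
)

__all__ = ["SimConfig", "World", "Cohort", "generate_world", "generate_cohort", "load_world"]

POS_ROOT = "SGO:0000001"  # positive-regulation analogue
NEG_ROOT = "SGO:0000002"  # negative-regulation analogue
OTHER_ROOT = "SGO:0000003"


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic world and cohorts.

    Counts and rates are chosen to echo the real study at desk scale: a few
    dozen patients per cohort with 1-3 multi-gene de novo CNVs each, a
    phenotype ontology of ~400 terms under 6 top-level categories, phenotype
    data for roughly 60% of genes (through 1:1 orthologues), and an
    interactome with mean degree ~4.
    """

    rng_seed: int = 0
    # genome / gene models
    n_genes: int = 3000
    n_chroms: int = 6
    transcripts_per_gene: tuple[int, int] = (1, 3)
    exons_per_transcript: tuple[int, int] = (2, 8)
    exon_length: tuple[int, int] = (80, 400)
    intron_length: tuple[int, int] = (500, 5000)
    intergenic_length: tuple[int, int] = (20_000, 350_000)
    # ontology
    ontology_roots: int = 6
    ontology_branching: tuple[int, ...] = (3, 3, 2, 2)
    extra_dag_edges: int = 40
    cross_category_leaves: int = 10
    # annotations
    annotation_rate: float = 0.6
    terms_per_gene: tuple[int, int] = (1, 4)
    orthology_rate: float = 0.95
    n_unmapped_mouse_genes: int = 20
    # PPI
    ppi_mean_degree: float = 4.0
    planted_module_size: int = 20
    planted_module_p: float = 0.5
    # planted phenotype signal
    planted_term_size: int = 50
    # cohort
    n_patients: int = 60
    cnvs_per_patient: tuple[int, int] = (1, 3)
    cnv_length: tuple[int, int] = (10_000, 5_000_000)
    gain_fraction: float = 0.55
    signal_fraction: float = 0.0
    n_control_patients: int = 60
    control_cnvs_per_patient: tuple[int, int] = (1, 3)
    # regulator-direction skew
    regulator_skew: bool = False
    regulator_base_rate: float = 0.18
    regulator_signal_rate: float = 0.40

    def __post_init__(self) -> None:
        for name in (
            "annotation_rate",
            "orthology_rate",
            "planted_module_p",
            "gain_fraction",
            "signal_fraction",
            "regulator_base_rate",
            "regulator_signal_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.planted_module_size > self.n_genes:
            raise ValueError("planted module larger than gene catalogue")
        if self.planted_term_size > self.n_genes:
            raise ValueError("planted term larger than gene catalogue")


@dataclass
class World:
    """Generated reference data plus the pipeline-level objects built from it."""

    cfg: SimConfig
    catalog: GeneCatalog
    chrom_sizes: dict[str, int]
    pheno_onto: Ontology
    mouse_pairs: list[tuple[str, str]]
    orthology: OrthologyMap
    pheno_table: AnnotationTable  # human-keyed, propagated
    go_onto: Ontology
    go_pairs: list[tuple[str, str]]
    go_table: AnnotationTable  # human-keyed, propagated
    ppi: nx.Graph
    truth: dict

    def category_pool(self, root: str) -> list[str]:
        """Genes annotated (after propagation) to a category root — the
        annotation-matched permutation pool analogue."""
        return sorted(self.pheno_table.genes_with_term(root))

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        seed = self.cfg.rng_seed
        paths = {
            "genes": outdir / "genes.tsv",
            "chrom_sizes": outdir / "chrom_sizes.tsv",
            "phenotype_obo": outdir / "phenotype.obo",
            "mp_annotations": outdir / "mp_annotations.tsv",
            "orthology": outdir / "orthology.tsv",
            "go_obo": outdir / "go.obo",
            "go_annotations": outdir / "go_annotations.tsv",
            "ppi_edges": outdir / "ppi_edges.tsv",
            "truth": outdir / "truth.json",
        }
        with open(paths["genes"], "w") as fh:
            fh.write(f"# seed={seed}\n")
            fh.write("gene_id\tsymbol\ttranscript_id\tchrom\texon_start\texon_end\n")
            for gene in self.catalog:
                for tx_id, exons in gene.transcripts.items():
                    for e in exons:
                        fh.write(
                            f"{gene.gene_id}\t{gene.symbol}\t{tx_id}\t"
                            f"{e.chrom}\t{e.start}\t{e.end}\n"
                        )
        with open(paths["chrom_sizes"], "w") as fh:
            fh.write(f"# seed={seed}\nchrom\tlength\n")
            for chrom, length in self.chrom_sizes.items():
                fh.write(f"{chrom}\t{length}\n")
        _write_obo(paths["phenotype_obo"], self.pheno_onto, seed)
        _write_obo(paths["go_obo"], self.go_onto, seed)
        with open(paths["mp_annotations"], "w") as fh:
            fh.write(f"# seed={seed}\nmouse_gene_id\tterm_id\n")
            for gene, term in self.mouse_pairs:
                fh.write(f"{gene}\t{term}\n")
        with open(paths["orthology"], "w") as fh:
            fh.write(f"# seed={seed}\nhuman_id\tmouse_id\n")
            for human, mouse in self.orthology.human_to_mouse.items():
                fh.write(f"{human}\t{mouse}\n")
        with open(paths["go_annotations"], "w") as fh:
            fh.write(f"# seed={seed}\ngene_id\tterm_id\n")
            for gene, term in self.go_pairs:
                fh.write(f"{gene}\t{term}\n")
        with open(paths["ppi_edges"], "w") as fh:
            fh.write(f"# seed={seed}\ngene_a\tgene_b\n")
            for a, b in sorted(tuple(sorted(e)) for e in self.ppi.edges):
                fh.write(f"{a}\t{b}\n")
        with open(paths["truth"], "w") as fh:
            json.dump(self.truth, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return paths


def _write_obo(path: Path, onto: Ontology, seed: int) -> None:
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\n")
        fh.write(f"remark: synthetic ontology, seed={seed}\n\n")
        for term in onto.terms:
            fh.write("[Term]\n")
            fh.write(f"id: {term}\n")
            fh.write(f"name: {onto.names.get(term, term)}\n")
            for parent in sorted(onto.parents(term)):
                fh.write(f"is_a: {parent}\n")
            fh.write("\n")


def _randint(rng: np.random.Generator, bounds: tuple[int, int]) -> int:
    return int(rng.integers(bounds[0], bounds[1] + 1))


def _log_uniform(rng: np.random.Generator, bounds: tuple[int, int]) -> int:
    lo, hi = bounds
    return int(round(np.exp(rng.uniform(np.log(lo), np.log(hi)))))


def _build_genes(cfg: SimConfig, rng: np.random.Generator):
    genes: list[GeneModel] = []
    chrom_sizes: dict[str, int] = {}
    per_chrom = int(np.ceil(cfg.n_genes / cfg.n_chroms))
    gid = 0
    for ci in range(cfg.n_chroms):
        chrom = f"chr{ci + 1}"
        pos = _randint(rng, cfg.intergenic_length)
        for _ in range(per_chrom):
            if gid >= cfg.n_genes:
                break
            gid += 1
            gene_id = f"G{gid:05d}"
            n_exons = _randint(rng, cfg.exons_per_transcript)
            exons = []
            cursor = pos
            for _ in range(n_exons):
                length = _randint(rng, cfg.exon_length)
                exons.append(GenomicInterval(chrom, cursor, cursor + length - 1))
                cursor += length + _randint(rng, cfg.intron_length)
            n_tx = _randint(rng, cfg.transcripts_per_gene)
            transcripts = {f"T{gid:05d}.1": tuple(exons)}
            for ti in range(2, n_tx + 1):
                # alternative isoforms keep a random non-empty exon subset
                keep = rng.random(n_exons) < 0.7
                if not keep.any():
                    keep[int(rng.integers(n_exons))] = True
                transcripts[f"T{gid:05d}.{ti}"] = tuple(
                    e for e, k in zip(exons, keep) if k
                )
            genes.append(GeneModel(gene_id, f"SYN{gid}", transcripts))
            pos = exons[-1].end + _randint(rng, cfg.intergenic_length)
        chrom_sizes[chrom] = pos + _randint(rng, cfg.intergenic_length)
    return GeneCatalog(genes), chrom_sizes


def _build_pheno_ontology(cfg: SimConfig, rng: np.random.Generator) -> Ontology:
    edges: list[tuple[str, str]] = []
    names: dict[str, str] = {}
    counter = 0
    order: list[str] = []

    def new_term(name: str) -> str:
        nonlocal counter
        counter += 1
        tid = f"MP:{counter:07d}"
        names[tid] = name
        order.append(tid)
        return tid

    roots = [new_term(f"category {i + 1} (synthetic)") for i in range(cfg.ontology_roots)]
    subtree: dict[str, list[str]] = {}
    for ri, root in enumerate(roots):
        # category sizes are deliberately heterogeneous (real top-level
        # categories range from a couple of terms to hundreds); the first
        # category is the small one and hosts the planted term
        widths = (
            tuple(max(1, w - 1) for w in cfg.ontology_branching)
            if ri == 0
            else cfg.ontology_branching
        )
        level = [root]
        members: list[str] = []
        for depth, width in enumerate(widths, start=1):
            nxt = []
            for parent in level:
                for j in range(width):
                    child = new_term(f"cat{ri + 1} d{depth} term")
                    edges.append((child, parent))
                    nxt.append(child)
            members.extend(nxt)
            level = nxt
        subtree[root] = members
    # extra is_a edges within one category's subtree make the tree a genuine
    # DAG (multi-parent) without letting a category inherit another's terms;
    # edges point from later-created to earlier-created terms, so no cycles
    existing = set(edges)
    added = 0
    while added < cfg.extra_dag_edges:
        root = roots[int(rng.integers(len(roots)))]
        members = subtree[root]
        ci = int(rng.integers(1, len(members)))
        pi = int(rng.integers(0, ci))
        edge = (members[ci], members[pi])
        if edge in existing:
            continue
        existing.add(edge)
        edges.append(edge)
        added += 1
    # a few leaf terms belong to two categories at once (multi-root terms)
    for i in range(cfg.cross_category_leaves):
        leaf = new_term(f"cross-category leaf {i + 1}")
        ra, rb = rng.choice(len(roots), size=2, replace=False)
        for r in (roots[int(ra)], roots[int(rb)]):
            members = subtree[r]
            edges.append((leaf, members[int(rng.integers(len(members)))]))
    return Ontology(edges, names=names)


def _build_go_ontology() -> Ontology:
    edges = []
    names = {
        POS_ROOT: "positive regulation of biological process (synthetic)",
        NEG_ROOT: "negative regulation of biological process (synthetic)",
        OTHER_ROOT: "other biological process (synthetic)",
    }
    counter = 10
    for root in (POS_ROOT, NEG_ROOT, OTHER_ROOT):
        for _ in range(3):
            counter += 1
            child = f"SGO:{counter:07d}"
            names[child] = f"child of {names[root]}"
            edges.append((child, root))
    return Ontology(edges, names=names)


def generate_world(cfg: SimConfig | None = None, outdir: str | Path | None = None) -> World:
    """Generate a mutually consistent synthetic world.

    With ``outdir`` the files are also written in the dialects the reader
    modules consume; the truth JSON records the planted module members, the
    planted term and its genes, and the regulator base rates.
    """
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.rng_seed)

    catalog, chrom_sizes = _build_genes(cfg, rng)
    gene_ids = catalog.gene_ids

    pheno_onto = _build_pheno_ontology(cfg, rng)
    roots = sorted(pheno_onto.roots)
    # planted term: a leaf of the first category, so its gene count is not
    # inflated by inherited descendant annotations
    root0_terms = sorted(pheno_onto.descendants(roots[0]))
    planted_term = next(
        t
        for t in root0_terms
        if not pheno_onto.descendants(t) and pheno_onto.depth(t) >= 2
    )

    # orthology: most genes have a unique mouse counterpart
    orth_mask = rng.random(len(gene_ids)) < cfg.orthology_rate
    h2m = {
        g: f"Mm{g[1:]}" for g, keep in zip(gene_ids, orth_mask) if keep
    }
    orthology = OrthologyMap(h2m)

    # direct mouse annotations, sparse and position-independent
    non_root_terms = [t for t in pheno_onto.terms if t not in pheno_onto.roots]
    mouse_pairs: list[tuple[str, str]] = []
    annotated_humans: list[str] = []
    for g in gene_ids:
        mouse = h2m.get(g)
        if mouse is None:
            continue
        if rng.random() >= cfg.annotation_rate:
            continue
        annotated_humans.append(g)
        n_terms = _randint(rng, cfg.terms_per_gene)
        for t in sorted(rng.choice(non_root_terms, size=n_terms, replace=False)):
            mouse_pairs.append((mouse, t))
    if len(annotated_humans) < cfg.planted_term_size:
        raise ValueError(
            "infeasible config: fewer annotated genes than planted_term_size"
        )
    planted_genes = sorted(
        rng.choice(annotated_humans, size=cfg.planted_term_size, replace=False)
    )
    for g in planted_genes:
        mouse_pairs.append((h2m[g], planted_term))
    # a few annotated mouse genes without any orthologue (dropped on mapping)
    for i in range(cfg.n_unmapped_mouse_genes):
        mouse = f"MmX{i + 1:04d}"
        term = non_root_terms[int(rng.integers(len(non_root_terms)))]
        mouse_pairs.append((mouse, term))
    mouse_pairs.sort()

    mouse_table = propagate_annotations(mouse_pairs, pheno_onto)
    pheno_table = map_orthologs(mouse_table, orthology)

    # GO-like regulator annotations, human-keyed
    go_onto = _build_go_ontology()
    child_of = {
        root: sorted(go_onto.descendants(root)) for root in (POS_ROOT, NEG_ROOT, OTHER_ROOT)
    }
    go_pairs: list[tuple[str, str]] = []
    for g in gene_ids:
        if rng.random() < 0.9:
            go_pairs.append((g, child_of[OTHER_ROOT][int(rng.integers(3))]))
        if rng.random() < cfg.regulator_base_rate:
            go_pairs.append((g, child_of[POS_ROOT][int(rng.integers(3))]))
        if rng.random() < cfg.regulator_base_rate:
            go_pairs.append((g, child_of[NEG_ROOT][int(rng.integers(3))]))
    go_pairs.sort()
    go_table = propagate_annotations(go_pairs, go_onto)

    # PPI: preferential attachment + a planted dense module
    m = max(1, int(round(cfg.ppi_mean_degree / 2)))
    ba = nx.barabasi_albert_graph(
        len(gene_ids), m, seed=int(rng.integers(2**31 - 1))
    )
    perm = rng.permutation(len(gene_ids))
    relabel = {i: gene_ids[perm[i]] for i in ba.nodes}
    ppi = nx.relabel_nodes(ba, relabel)
    # the dense module lives among the planted-term genes: genes sharing the
    # planted phenotype are the ones whose products work (and interact) in a
    # common process, so cohorts hitting the term also hit the module
    module_pool = (
        planted_genes
        if cfg.planted_module_size <= len(planted_genes)
        else gene_ids
    )
    module = sorted(rng.choice(module_pool, size=cfg.planted_module_size, replace=False))
    for i, a in enumerate(module):
        for b in module[i + 1 :]:
            if rng.random() < cfg.planted_module_p:
                ppi.add_edge(a, b)

    truth = {
        "seed": cfg.rng_seed,
        "planted_term": planted_term,
        "planted_term_category": roots[0],
        "planted_term_genes": planted_genes,
        "planted_module": module,
        "regulator_base_rate": cfg.regulator_base_rate,
        "category_roots": roots,
        "go_pos_root": POS_ROOT,
        "go_neg_root": NEG_ROOT,
    }

    world = World(
        cfg=cfg,
        catalog=catalog,
        chrom_sizes=chrom_sizes,
        pheno_onto=pheno_onto,
        mouse_pairs=mouse_pairs,
        orthology=orthology,
        pheno_table=pheno_table,
        go_onto=go_onto,
        go_pairs=go_pairs,
        go_table=go_table,
        ppi=ppi,
        truth=truth,
    )
    if outdir is not None:
        world.write(outdir)
    return world


def load_world(indir: str | Path, cfg: SimConfig | None = None) -> World:
    """Rebuild a :class:`World` from generated files via the reader modules."""
    indir = Path(indir)
    catalog = read_gene_models(indir / "genes.tsv")
    chrom_sizes = read_chrom_sizes(indir / "chrom_sizes.tsv")
    pheno_onto = load_ontology(indir / "phenotype.obo")
    mouse_pairs = read_annotation_pairs(indir / "mp_annotations.tsv")
    orthology = read_orthology(indir / "orthology.tsv")
    pheno_table = map_orthologs(
        propagate_annotations(mouse_pairs, pheno_onto), orthology
    )
    go_onto = load_ontology(indir / "go.obo")
    go_pairs = read_annotation_pairs(indir / "go_annotations.tsv")
    go_table = propagate_annotations(go_pairs, go_onto)
    ppi = load_ppi_edges(indir / "ppi_edges.tsv")
    with open(indir / "truth.json") as fh:
        truth = json.load(fh)
    return World(
        cfg=cfg or SimConfig(rng_seed=truth.get("seed", 0)),
        catalog=catalog,
        chrom_sizes=chrom_sizes,
        pheno_onto=pheno_onto,
        mouse_pairs=mouse_pairs,
        orthology=orthology,
        pheno_table=pheno_table,
        go_onto=go_onto,
        go_pairs=go_pairs,
        go_table=go_table,
        ppi=ppi,
        truth=truth,
    )


@dataclass
class Cohort:
    """A generated case/control CNV cohort with its ground truth."""

    case: list[CNVCall]
    control: list[CNVCall]
    truth: dict

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "case": outdir / "case_cnvs.tsv",
            "control": outdir / "control_cnvs.tsv",
            "truth": outdir / "cohort_truth.json",
        }
        seed = self.truth.get("seed", "?")
        write_cnv_calls(self.case, paths["case"], header=f"seed={seed}")
        write_cnv_calls(self.control, paths["control"], header=f"seed={seed}")
        with open(paths["truth"], "w") as fh:
            json.dump(self.truth, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return paths


def _place_uniform(
    world: World, length: int, rng: np.random.Generator
) -> GenomicInterval:
    chroms = sorted(world.chrom_sizes)
    lengths = np.array([world.chrom_sizes[c] for c in chroms], dtype=np.int64)
    eligible = lengths >= length
    if not eligible.any():
        raise ValueError(f"CNV length {length} exceeds every chromosome")
    probs = np.where(eligible, lengths, 0).astype(float)
    probs /= probs.sum()
    ci = int(rng.choice(len(chroms), p=probs))
    start = int(rng.integers(1, lengths[ci] - length + 2))
    return GenomicInterval(chroms[ci], start, start + length - 1)


def _place_covering(
    world: World, gene_id: str, length: int, rng: np.random.Generator
) -> GenomicInterval:
    """An interval of the given length fully covering the gene's exon span
    (so the gene is assigned whole, never partially)."""
    span = world.catalog[gene_id].span
    length = max(length, span.length)
    chrom_len = world.chrom_sizes[span.chrom]
    length = min(length, chrom_len)
    lo = max(1, span.end - length + 1)
    hi = min(span.start, chrom_len - length + 1)
    if hi < lo:  # gene too close to an edge for this length; snap to span
        start = span.start
        length = span.length
    else:
        start = int(rng.integers(lo, hi + 1))
    return GenomicInterval(span.chrom, start, start + length - 1)


def generate_cohort(
    world: World,
    cfg: SimConfig | None = None,
    rng: np.random.Generator | int | None = None,
    set_label: str = "SIM",
) -> Cohort:
    """Generate case and control CNV cohorts over a world.

    A configured fraction of case CNVs is placed to fully cover a gene
    carrying the planted phenotype term; the rest (and all controls) are
    placed uniformly with log-uniform lengths.  With ``regulator_skew`` each
    patient instead receives one single-gene deletion and one single-gene
    duplication whose target genes are sampled so that deletions carry the
    positive-regulator flag, and duplications the negative-regulator flag,
    at the configured signal rate against the base rate elsewhere.
    """
    cfg = cfg or world.cfg
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed)
    elif not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    case: list[CNVCall] = []
    truth: dict = {"seed": cfg.rng_seed, "set_label": set_label}

    if cfg.regulator_skew:
        pos = world.go_table.genes_with_term(POS_ROOT)
        neg = world.go_table.genes_with_term(NEG_ROOT)
        universe = sorted(world.go_table.genes)
        available = set(universe)
        del_genes, dup_genes = [], []
        for pi in range(cfg.n_patients):
            patient = f"P{pi + 1:04d}"
            for direction, flagged, chosen in (
                ("loss", pos, del_genes),
                ("gain", neg, dup_genes),
            ):
                pool = sorted(
                    (available & flagged)
                    if rng.random() < cfg.regulator_signal_rate
                    else (available - flagged)
                )
                gene = pool[int(rng.integers(len(pool)))]
                available.discard(gene)
                chosen.append(gene)
                span = world.catalog[gene].span
                case.append(
                    CNVCall(patient, span, direction, True, set_label)
                )
        truth["del_genes"] = del_genes
        truth["dup_genes"] = dup_genes
    else:
        planted = world.truth["planted_term_genes"]
        signal_hits = []
        for pi in range(cfg.n_patients):
            patient = f"P{pi + 1:04d}"
            for _ in range(_randint(rng, cfg.cnvs_per_patient)):
                direction = "gain" if rng.random() < cfg.gain_fraction else "loss"
                length = _log_uniform(rng, cfg.cnv_length)
                if planted and rng.random() < cfg.signal_fraction:
                    gene = planted[int(rng.integers(len(planted)))]
                    interval = _place_covering(world, gene, length, rng)
                    signal_hits.append({"patient": patient, "gene": gene})
                else:
                    interval = _place_uniform(world, length, rng)
                case.append(CNVCall(patient, interval, direction, True, set_label))
        truth["signal_hits"] = signal_hits
        truth["planted_term"] = world.truth["planted_term"]

    control: list[CNVCall] = []
    for pi in range(cfg.n_control_patients):
        patient = f"C{pi + 1:04d}"
        for _ in range(_randint(rng, cfg.control_cnvs_per_patient)):
            direction = "gain" if rng.random() < cfg.gain_fraction else "loss"
            length = _log_uniform(rng, cfg.cnv_length)
            interval = _place_uniform(world, length, rng)
            control.append(CNVCall(patient, interval, direction, True, "CTRL"))
    return Cohort(case=case, control=control, truth=truth)
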