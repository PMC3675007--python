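"""CNV-to-gene assignment on exon-resolved gene models.

A gene is counted as affected by a copy-number variant (CNV) only under a
conservative rule: the CNV interval must overlap at least one coding exon of
*every* known transcript of the gene.  This avoids calling a gene "hit" when
the variant touches only an intron or only a minor isoform.  Coordinates are
1-based and fully closed (Ensembl convention); overlap means a shared length
of at least 1 bp.  Strand is ignored — the rule is purely positional.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "GeneCatalog",
    "CNVCall",
    "GeneAssignment",
    "read_gene_models",
    "read_cnv_calls",
    "read_chrom_sizes",
    "assign_genes_to_cnvs",
    "flag_partial_duplication",
    "filter_control_genes",
]

GAIN = "gain"
LOSS = "loss"
DIRECTIONS = (GAIN, LOSS)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 1-based, fully-closed genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"end ({self.end}) < start ({self.start})")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share >= 1 bp on the same chromosome."""
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and self.end >= other.start
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and self.end >= other.end
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene with one or more transcripts, each a tuple of coding exons.

    All exons of all transcripts must lie on a single chromosome.
    """

    gene_id: str
    symbol: str
    transcripts: Mapping[str, tuple[GenomicInterval, ...]]

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValueError(f"gene {self.gene_id} has no transcripts")
        chroms = set()
        for tx_id, exons in self.transcripts.items():
            if not exons:
                raise ValueError(
                    f"transcript {tx_id} of gene {self.gene_id} has no coding exons"
                )
            chroms.update(e.chrom for e in exons)
        if len(chroms) != 1:
            raise ValueError(
                f"gene {self.gene_id} has exons on multiple chromosomes: "
                f"{sorted(chroms)}"
            )

    @property
    def chrom(self) -> str:
        first = next(iter(self.transcripts.values()))
        return first[0].chrom

    @property
    def span(self) -> GenomicInterval:
        """Smallest interval covering every coding exon of every transcript."""
        starts = [e.start for exons in self.transcripts.values() for e in exons]
        ends = [e.end for exons in self.transcripts.values() for e in exons]
        return GenomicInterval(self.chrom, min(starts), max(ends))

    def all_exons(self) -> list[GenomicInterval]:
        return [e for exons in self.transcripts.values() for e in exons]

    def overlapped_by(self, region: GenomicInterval) -> bool:
        """Conservative overlap rule: >=1 coding exon of EVERY transcript."""
        if region.chrom != self.chrom:
            return False
        return all(
            any(e.start <= region.end and e.end >= region.start for e in exons)
            for exons in self.transcripts.values()
        )


class GeneCatalog:
    """Collection of :class:`GeneModel` keyed by gene id, with a per-chromosome
    span index for fast candidate lookup."""

    def __init__(self, genes: Iterable[GeneModel]):
        self._genes: dict[str, GeneModel] = {}
        for g in genes:
            if g.gene_id in self._genes:
                raise ValueError(f"duplicate gene_id {g.gene_id}")
            self._genes[g.gene_id] = g
        self._index: dict[str, tuple[np.ndarray, np.ndarray, list[str]]] | None = None

    def __len__(self) -> int:
        return len(self._genes)

    def __iter__(self):
        return iter(self._genes.values())

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._genes

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self._genes[gene_id]

    @property
    def gene_ids(self) -> list[str]:
        return list(self._genes)

    @property
    def chromosomes(self) -> set[str]:
        return {g.chrom for g in self}

    def _build_index(self) -> dict[str, tuple[np.ndarray, np.ndarray, list[str]]]:
        by_chrom: dict[str, list[tuple[int, int, str]]] = {}
        for g in self:
            sp = g.span
            by_chrom.setdefault(g.chrom, []).append((sp.start, sp.end, g.gene_id))
        index = {}
        for chrom, rows in by_chrom.items():
            rows.sort()
            starts = np.array([r[0] for r in rows], dtype=np.int64)
            ends = np.array([r[1] for r in rows], dtype=np.int64)
            ids = [r[2] for r in rows]
            index[chrom] = (starts, ends, ids)
        return index

    def candidates(self, region: GenomicInterval) -> list[GeneModel]:
        """Genes whose exon span overlaps ``region`` (coarse pre-filter)."""
        if self._index is None:
            self._index = self._build_index()
        entry = self._index.get(region.chrom)
        if entry is None:
            return []
        starts, ends, ids = entry
        # span starts sorted ascending; anything starting after region.end is out
        hi = int(np.searchsorted(starts, region.end, side="right"))
        sel = np.nonzero(ends[:hi] >= region.start)[0]
        return [self._genes[ids[i]] for i in sel]


@dataclass(frozen=True)
class CNVCall:
    """One patient's de novo copy-number event."""

    patient_id: str
    interval: GenomicInterval
    direction: str
    validated: bool = True
    set_label: str = ""

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValueError(
                f"direction must be one of {DIRECTIONS}, got {self.direction!r}"
            )


@dataclass
class GeneAssignment:
    """Per-(gene, CNV) assignment records produced by the overlap rule.

    ``records`` columns: gene_id, patient_id, cnv_index, set_label, direction,
    partial, validated.  ``partial`` is True when at least one coding exon of
    the gene lies outside the CNV interval (meaningful for duplications, where
    a partial copy likely disrupts rather than doses the gene).
    """

    records: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=[
                "gene_id",
                "patient_id",
                "cnv_index",
                "set_label",
                "direction",
                "partial",
                "validated",
            ]
        )
    )

    COLUMNS = (
        "gene_id",
        "patient_id",
        "cnv_index",
        "set_label",
        "direction",
        "partial",
        "validated",
    )

    def __len__(self) -> int:
        return len(self.records)

    def gene_set(self, direction: str = "all", set_label: str | None = None) -> set[str]:
        """Genes carrying at least one record of the given direction.

        ``direction='all'`` is the union of the gain and loss gene sets.
        """
        df = self.records
        if set_label is not None:
            df = df[df["set_label"] == set_label]
        if direction != "all":
            if direction not in DIRECTIONS:
                raise ValueError(f"unknown direction {direction!r}")
            df = df[df["direction"] == direction]
        return set(df["gene_id"])

    def set_labels(self) -> list[str]:
        return sorted(set(self.records["set_label"]))

    def cnv_genes(self, cnv_index: int) -> set[str]:
        df = self.records
        return set(df.loc[df["cnv_index"] == cnv_index, "gene_id"])

    def gene_directions(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for gene, direction in zip(self.records["gene_id"], self.records["direction"]):
            out.setdefault(gene, set()).add(direction)
        return out

    def gene_patients(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for gene, pat in zip(self.records["gene_id"], self.records["patient_id"]):
            out.setdefault(gene, set()).add(pat)
        return out

    def genes_with_all_partial_gains(self) -> set[str]:
        """Genes whose every duplication record is a partial duplication."""
        gains = self.records[self.records["direction"] == GAIN]
        if gains.empty:
            return set()
        grouped = gains.groupby("gene_id")["partial"].all()
        return set(grouped[grouped].index)

    def to_tsv(self, path: str | Path) -> None:
        self.records.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# readers


def _open_rows(path: str | Path):
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield lineno, line.split("\t")


def read_gene_models(path: str | Path) -> GeneCatalog:
    """Read gene models from a flat TSV or a GFF3/GTF file.

    The flat dialect has columns
    ``gene_id  symbol  transcript_id  chrom  exon_start  exon_end``
    (one row per coding exon, header optional).  Files ending in
    ``.gff``/``.gff3``/``.gtf`` are parsed via :mod:`gffutils`, taking CDS
    features grouped by transcript.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in {".gff", ".gff3", ".gtf"}:
        return _read_gene_models_gff(path)

    per_gene: dict[str, dict[str, list[GenomicInterval]]] = {}
    symbols: dict[str, str] = {}
    for lineno, fields in _open_rows(path):
        if fields[0] == "gene_id":  # header
            continue
        if len(fields) < 6:
            raise ValueError(f"{path}:{lineno}: expected 6 columns, got {len(fields)}")
        gene_id, symbol, tx_id, chrom = fields[:4]
        try:
            start, end = int(fields[4]), int(fields[5])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
        try:
            exon = GenomicInterval(chrom, start, end)
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from exc
        per_gene.setdefault(gene_id, {}).setdefault(tx_id, []).append(exon)
        symbols[gene_id] = symbol

    genes = []
    for gene_id, txs in per_gene.items():
        genes.append(
            GeneModel(
                gene_id=gene_id,
                symbol=symbols[gene_id],
                transcripts={t: tuple(exons) for t, exons in txs.items()},
            )
        )
    return GeneCatalog(genes)


def _read_gene_models_gff(path: Path) -> GeneCatalog:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    per_gene: dict[str, dict[str, list[GenomicInterval]]] = {}
    symbols: dict[str, str] = {}
    for cds in db.features_of_type("CDS"):
        parents = cds.attributes.get("Parent", [])
        tx_ids = parents if parents else [cds.attributes.get("transcript_id", ["?"])[0]]
        for tx_id in tx_ids:
            try:
                tx = db[tx_id]
                gene_id = tx.attributes.get("Parent", [tx_id])[0]
            except gffutils.FeatureNotFoundError:
                gene_id = cds.attributes.get("gene_id", [tx_id])[0]
            per_gene.setdefault(gene_id, {}).setdefault(tx_id, []).append(
                GenomicInterval(cds.seqid, cds.start, cds.end)
            )
            symbols.setdefault(gene_id, gene_id)
    genes = [
        GeneModel(g, symbols[g], {t: tuple(v) for t, v in txs.items()})
        for g, txs in per_gene.items()
    ]
    return GeneCatalog(genes)


def read_cnv_calls(path: str | Path) -> list[CNVCall]:
    """Read a CNV table.

    Columns: ``set_label  patient_id  chrom  start  end  direction  validated``
    with direction in {gain, loss} and validated in {0, 1}.
    """
    calls = []
    for lineno, fields in _open_rows(path):
        if fields[0] == "set_label":
            continue
        if len(fields) < 7:
            raise ValueError(f"{path}:{lineno}: expected 7 columns, got {len(fields)}")
        set_label, patient_id, chrom = fields[:3]
        try:
            start, end = int(fields[3]), int(fields[4])
            interval = GenomicInterval(chrom, start, end)
            call = CNVCall(
                patient_id=patient_id,
                interval=interval,
                direction=fields[5],
                validated=bool(int(fields[6])),
                set_label=set_label,
            )
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from exc
        calls.append(call)
    return calls


def write_cnv_calls(calls: Sequence[CNVCall], path: str | Path, header: str = "") -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        fh.write("set_label\tpatient_id\tchrom\tstart\tend\tdirection\tvalidated\n")
        for c in calls:
            fh.write(
                f"{c.set_label}\t{c.patient_id}\t{c.interval.chrom}\t"
                f"{c.interval.start}\t{c.interval.end}\t{c.direction}\t"
                f"{int(c.validated)}\n"
            )


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    for lineno, fields in _open_rows(path):
        if fields[0] == "chrom":
            continue
        if len(fields) < 2:
            raise ValueError(f"{path}:{lineno}: expected 2 columns")
        sizes[fields[0]] = int(fields[1])
    return sizes


# ---------------------------------------------------------------------------
# operations


def assign_genes_to_cnvs(
    cnvs: Sequence[CNVCall], catalog: GeneCatalog
) -> GeneAssignment:
    """Assign genes to CNVs under the every-transcript coding-exon rule.

    A gene is assigned to a CNV iff, for every transcript of the gene, at
    least one coding exon overlaps the CNV interval by >= 1 bp.  CNVs on
    chromosomes absent from the catalogue yield a warning and no assignments.
    """
    if len(catalog) == 0:
        raise ValueError("empty gene catalogue")
    known_chroms = catalog.chromosomes
    warned: set[str] = set()
    rows: list[tuple] = []
    for idx, cnv in enumerate(cnvs):
        region = cnv.interval
        if region.chrom not in known_chroms:
            if region.chrom not in warned:
                warnings.warn(
                    f"CNV chromosome {region.chrom!r} not in gene catalogue; "
                    "no genes assigned",
                    stacklevel=2,
                )
                warned.add(region.chrom)
            continue
        for gene in catalog.candidates(region):
            if gene.overlapped_by(region):
                partial = any(
                    not region.contains(e) for e in gene.all_exons()
                )
                rows.append(
                    (
                        gene.gene_id,
                        cnv.patient_id,
                        idx,
                        cnv.set_label,
                        cnv.direction,
                        partial,
                        cnv.validated,
                    )
                )
    df = pd.DataFrame(rows, columns=list(GeneAssignment.COLUMNS))
    return GeneAssignment(df)


def flag_partial_duplication(cnv: CNVCall, gene: GeneModel) -> bool:
    """True iff the duplication leaves >= 1 coding exon (of any transcript)
    outside the CNV interval; such a partial copy likely disrupts the gene."""
    if cnv.direction != GAIN:
        raise ValueError("partial-duplication flag is defined for gain CNVs only")
    return any(not cnv.interval.contains(e) for e in gene.all_exons())


def filter_control_genes(
    assignment: GeneAssignment, control_assignment: GeneAssignment
) -> GeneAssignment:
    """Drop (gene, direction) records seen copy-number variable in the same
    direction in the control cohort; the opposite direction is retained."""
    control_pairs = set(
        zip(
            control_assignment.records["gene_id"],
            control_assignment.records["direction"],
        )
    )
    if not control_pairs:
        return GeneAssignment(assignment.records.copy())
    df = assignment.records
    mask = [
        (g, d) not in control_pairs
        for g, d in zip(df["gene_id"], df["direction"])
    ]
    return GeneAssignment(df[mask].reset_index(drop=True))
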