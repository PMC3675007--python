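"""Gene models, CNV tables and the every-transcript overlap rule."""

import numpy as np
import pytest

from cnvnet import (
    CNVCall,
    GeneAssignment,
    GeneCatalog,
    GeneModel,
    GenomicInterval,
    assign_genes_to_cnvs,
    filter_control_genes,
    flag_partial_duplication,
    read_cnv_calls,
    read_gene_models,
)

from conftest import make_gene, random_catalog


def cnv(chrom, start, end, direction="gain", patient="p1", set_label="S"):
    return CNVCall(patient, GenomicInterval(chrom, start, end), direction, True, set_label)


class TestGenomicInterval:
    @pytest.mark.parametrize(
        "chrom,start,end",
        [("chr1", 0, 5), ("chr1", 5, 4), ("", 1, 2), ("chr1", -3, -1)],
    )
    def test_invalid_coordinates_rejected(self, chrom, start, end):
        with pytest.raises(ValueError):
            GenomicInterval(chrom, start, end)

    def test_overlap_is_symmetric_and_needs_one_bp(self):
        a = GenomicInterval("chr1", 10, 20)
        assert a.overlaps(GenomicInterval("chr1", 20, 30))
        assert GenomicInterval("chr1", 20, 30).overlaps(a)
        assert not a.overlaps(GenomicInterval("chr1", 21, 30))
        assert not a.overlaps(GenomicInterval("chr2", 10, 20))


class TestGeneModel:
    def test_requires_transcripts_and_exons(self):
        with pytest.raises(ValueError):
            GeneModel("g", "g", {})
        with pytest.raises(ValueError):
            GeneModel("g", "g", {"t": ()})

    def test_exons_on_two_chromosomes_rejected(self):
        with pytest.raises(ValueError, match="multiple chromosomes"):
            GeneModel(
                "g",
                "g",
                {
                    "t1": (GenomicInterval("chr1", 1, 10),),
                    "t2": (GenomicInterval("chr2", 1, 10),),
                    "t3": (GenomicInterval("chr1", 5, 15),),
                },
            )


class TestReadGeneModels:
    def test_round_trip_single_gene(self, tmp_path):
        path = tmp_path / "genes.tsv"
        path.write_text(
            "gene_id\tsymbol\ttranscript_id\tchrom\texon_start\texon_end\n"
            "g1\tSYM\tt1\tchr1\t100\t200\n"
            "g1\tSYM\tt1\tchr1\t300\t400\n"
        )
        catalog = read_gene_models(path)
        assert len(catalog) == 1
        gene = catalog["g1"]
        assert gene.symbol == "SYM"
        assert len(gene.transcripts["t1"]) == 2
        assert gene.span == GenomicInterval("chr1", 100, 400)

    def test_end_before_start_rejected_with_line_number(self, tmp_path):
        path = tmp_path / "genes.tsv"
        path.write_text("g1\tSYM\tt1\tchr1\t200\t100\n")
        with pytest.raises(ValueError, match=":1"):
            read_gene_models(path)

    def test_multi_chromosome_gene_rejected(self, tmp_path):
        path = tmp_path / "genes.tsv"
        path.write_text(
            "g1\tSYM\tt1\tchr1\t100\t200\n"
            "g1\tSYM\tt2\tchr2\t100\t200\n"
            "g1\tSYM\tt3\tchr1\t300\t400\n"
        )
        with pytest.raises(ValueError, match="multiple chromosomes"):
            read_gene_models(path)

    def test_gff3_input(self, tmp_path):
        path = tmp_path / "genes.gff3"
        path.write_text(
            "##gff-version 3\n"
            "chr1\tsrc\tgene\t100\t500\t.\t+\t.\tID=g1\n"
            "chr1\tsrc\tmRNA\t100\t500\t.\t+\t.\tID=t1;Parent=g1\n"
            "chr1\tsrc\tCDS\t100\t200\t.\t+\t0\tID=c1;Parent=t1\n"
            "chr1\tsrc\tCDS\t400\t500\t.\t+\t0\tID=c2;Parent=t1\n"
        )
        catalog = read_gene_models(path)
        assert len(catalog) == 1
        assert len(catalog["g1"].transcripts["t1"]) == 2


class TestReadCNVCalls:
    def test_round_trip_and_validation(self, tmp_path):
        path = tmp_path / "cnvs.tsv"
        path.write_text(
            "set_label\tpatient_id\tchrom\tstart\tend\tdirection\tvalidated\n"
            "S\tp1\tchr1\t100\t5000\tgain\t1\n"
            "S\tp2\tchr2\t100\t5000\tloss\t0\n"
        )
        calls = read_cnv_calls(path)
        assert len(calls) == 2
        assert calls[0].direction == "gain" and calls[0].validated
        assert calls[1].direction == "loss" and not calls[1].validated

    def test_bad_direction_rejected(self, tmp_path):
        path = tmp_path / "cnvs.tsv"
        path.write_text("S\tp1\tchr1\t100\t5000\tamplification\t1\n")
        with pytest.raises(ValueError, match=":1"):
            read_cnv_calls(path)


class TestAssignment:
    def test_cnv_spanning_whole_gene_assigns(self, two_transcript_gene):
        catalog = GeneCatalog([two_transcript_gene])
        assignment = assign_genes_to_cnvs([cnv("chr1", 1, 1000)], catalog)
        assert assignment.gene_set() == {"g1"}

    def test_exon_of_one_transcript_only_is_not_enough(self, two_transcript_gene):
        # 240-260 overlaps t2's exon (150-250) but falls between t1's exons
        catalog = GeneCatalog([two_transcript_gene])
        assignment = assign_genes_to_cnvs([cnv("chr1", 240, 260)], catalog)
        assert assignment.gene_set() == set()

    def test_single_bp_overlap_in_every_transcript_assigns(self, two_transcript_gene):
        # position 200 is the last bp of a t1 exon and inside t2's exon
        catalog = GeneCatalog([two_transcript_gene])
        assignment = assign_genes_to_cnvs([cnv("chr1", 200, 200)], catalog)
        assert assignment.gene_set() == {"g1"}

    def test_empty_catalog_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            assign_genes_to_cnvs([cnv("chr1", 1, 10)], GeneCatalog([]))

    def test_unknown_chromosome_warns_and_assigns_nothing(self, two_transcript_gene):
        catalog = GeneCatalog([two_transcript_gene])
        with pytest.warns(UserWarning, match="chrM"):
            assignment = assign_genes_to_cnvs([cnv("chrM", 1, 10)], catalog)
        assert len(assignment) == 0

    def test_matches_brute_force_oracle_and_is_monotone(self):
        # oracle: a gene is hit iff every transcript has >= 1 exon whose
        # interval intersects the CNV; computed by direct pair scanning
        import warnings

        rng = np.random.default_rng(2024)
        for _ in range(1000):
            catalog = random_catalog(rng, n_genes=int(rng.integers(1, 12)))
            chrom = f"c{rng.integers(1, 3)}"
            s = int(rng.integers(1, 2000))
            e = s + int(rng.integers(0, 400))
            call = cnv(chrom, s, e)
            with warnings.catch_warnings():
                # small catalogues may lack the sampled chromosome entirely
                warnings.simplefilter("ignore", UserWarning)
                got = assign_genes_to_cnvs([call], catalog).gene_set()
            expected = set()
            for gene in catalog:
                ok = all(
                    any(
                        ex.chrom == chrom and max(ex.start, s) <= min(ex.end, e)
                        for ex in exons
                    )
                    for exons in gene.transcripts.values()
                )
                if ok:
                    expected.add(gene.gene_id)
            assert got == expected
            # monotonicity: enlarging the CNV never un-assigns a gene
            bigger = cnv(chrom, max(1, s - 100), e + 100)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                bigger_set = assign_genes_to_cnvs([bigger], catalog).gene_set()
            assert got <= bigger_set


class TestPartialDuplication:
    def test_full_containment_is_not_partial(self, two_transcript_gene):
        assert not flag_partial_duplication(cnv("chr1", 1, 1000), two_transcript_gene)

    def test_truncated_exon_is_partial(self, two_transcript_gene):
        # covers everything except t1's second exon (400-500)
        assert flag_partial_duplication(cnv("chr1", 1, 399), two_transcript_gene)

    def test_half_covered_single_exon_gene_is_partial(self):
        gene = make_gene("g", "chr1", {"t": [(100, 200)]})
        assert flag_partial_duplication(cnv("chr1", 50, 150), gene)
        assert not flag_partial_duplication(cnv("chr1", 100, 200), gene)

    def test_loss_cnv_is_an_error(self, two_transcript_gene):
        with pytest.raises(ValueError, match="gain"):
            flag_partial_duplication(cnv("chr1", 1, 1000, "loss"), two_transcript_gene)


class TestControlFilter:
    def _assignment(self, pairs):
        import pandas as pd

        rows = [
            (g, "p", i, "S", d, False, True) for i, (g, d) in enumerate(pairs)
        ]
        return GeneAssignment(
            pd.DataFrame(rows, columns=list(GeneAssignment.COLUMNS))
        )

    def test_same_direction_removed_opposite_kept(self):
        cases = self._assignment([("g1", "gain"), ("g1", "loss"), ("g2", "gain")])
        controls = self._assignment([("g1", "gain"), ("g2", "loss")])
        filtered = filter_control_genes(cases, controls)
        assert filtered.gene_set("gain") == {"g2"}
        assert filtered.gene_set("loss") == {"g1"}

    def test_empty_control_is_identity(self):
        cases = self._assignment([("g1", "gain")])
        filtered = filter_control_genes(cases, self._assignment([]))
        assert filtered.records.equals(cases.records)

    def test_idempotent(self):
        cases = self._assignment([("g1", "gain"), ("g2", "loss"), ("g3", "gain")])
        controls = self._assignment([("g1", "gain"), ("g3", "loss")])
        once = filter_control_genes(cases, controls)
        twice = filter_control_genes(once, controls)
        assert once.records.equals(twice.records)
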