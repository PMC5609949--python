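"""Read alignment, the unique/zero-mismatch filter, site collapsing and
orientation annotation."""

from __future__ import annotations

import pytest

from trapscreen import (
    AlignedRead,
    GeneModel,
    InsertionSite,
    align_reads,
    annotate_orientation,
    collapse_to_sites,
    filter_alignments,
    read_alignments,
)
from trapscreen.mapping import (
    junction_position,
    read_genes_bed,
    read_genes_gtf,
    reverse_complement,
)

GENOME = "ATGCGTACGTTAGCCGATCGAATTCCGGAATGCATGCAGTC" + "ACGTACCGGT" * 6


class TestAlignReads:
    def test_unique_exact_match(self):
        read = GENOME[5:25]
        (aln,) = align_reads([("r1", read)], GENOME)
        assert aln.pos == 5
        assert aln.strand == "+"
        assert aln.n_mismatches == 0
        assert aln.n_placements == 1
        assert aln.span == 20

    def test_repeat_counts_all_placements(self):
        genome = "AAATTTCCCGGG" + "ACGTACGTACGTACGTACGT" + "TTTAAA" + "ACGTACGTACGTACGTACGT"
        read = "ACGTACGTACGTACGTACGT"
        (aln,) = align_reads([("r1", read)], genome)
        # the read also matches at internal offsets of each repeat copy
        assert aln.n_placements >= 2
        assert aln.n_mismatches == 0

    def test_reverse_complement_match(self):
        sub = GENOME[10:32]
        (aln,) = align_reads([("r1", reverse_complement(sub))], GENOME)
        assert aln.strand == "-"
        assert aln.pos == 10
        assert aln.n_mismatches == 0

    def test_substituted_read_reports_mismatches(self):
        read = list(GENOME[5:25])
        read[3] = "A" if read[3] != "A" else "C"
        (aln,) = align_reads([("r1", "".join(read))], GENOME)
        assert aln.n_mismatches == 1
        assert aln.pos == 5

    def test_brute_force_agreement_on_random_reads(self):
        # every exact placement found by hand-scanning both strands
        import numpy as np

        rng = np.random.default_rng(17)
        genome = "".join(rng.choice(list("ACGT"), 300))
        for start in (0, 50, 137, 270):
            read = genome[start : start + 30]
            hand = [
                i
                for i in range(len(genome) - 29)
                if genome[i : i + 30] == read
            ]
            rc = reverse_complement(genome)
            hand_rc = [
                len(genome) - 30 - i
                for i in range(len(genome) - 29)
                if rc[i : i + 30] == read
            ]
            (aln,) = align_reads([("r", read)], genome)
            assert aln.n_placements == len(hand) + len(hand_rc)
            assert aln.pos == min(hand) if hand else min(hand_rc)

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError, match="empty genome"):
            align_reads([("r", "ACGT")], "")
        with pytest.raises(ValueError, match="empty read"):
            align_reads([("r", "")], GENOME)


class TestReadAlignments:
    HEADER = "@HD\tVN:1.6\tSO:unsorted\n@SQ\tSN:chr1\tLN:1000\n"

    def _write(self, tmp_path, body: str):
        path = tmp_path / "test.sam"
        path.write_text(self.HEADER + body)
        return path

    def test_single_mapped_record(self, tmp_path):
        sam = self._write(
            tmp_path,
            "r1\t0\tchr1\t101\t60\t20M\t*\t0\t0\t" + "A" * 20 + "\t" + "I" * 20 + "\tNM:i:0\n",
        )
        alns, n_unmapped = read_alignments(sam)
        assert n_unmapped == 0
        (aln,) = alns
        assert aln.pos == 100  # SAM is 1-based
        assert aln.strand == "+"
        assert aln.n_mismatches == 0
        assert aln.n_placements == 1
        assert aln.span == 20

    def test_reverse_flag_sets_minus_strand(self, tmp_path):
        sam = self._write(
            tmp_path,
            "r1\t16\tchr1\t51\t60\t20M\t*\t0\t0\t" + "A" * 20 + "\t" + "I" * 20 + "\tNM:i:0\n",
        )
        (aln,), _ = read_alignments(sam)
        assert aln.strand == "-"

    def test_secondary_record_marks_multi_placement(self, tmp_path):
        body = (
            "r1\t0\tchr1\t101\t1\t20M\t*\t0\t0\t" + "A" * 20 + "\t" + "I" * 20 + "\tNM:i:0\n"
            "r1\t256\tchr1\t301\t0\t20M\t*\t0\t0\t*\t*\tNM:i:0\n"
        )
        alns, _ = read_alignments(self._write(tmp_path, body))
        (aln,) = alns  # only the primary is reported
        assert aln.n_placements >= 2

    def test_zero_mapq_marks_multi_placement(self, tmp_path):
        sam = self._write(
            tmp_path,
            "r1\t0\tchr1\t101\t0\t20M\t*\t0\t0\t" + "A" * 20 + "\t" + "I" * 20 + "\tNM:i:0\n",
        )
        (aln,), _ = read_alignments(sam)
        assert aln.n_placements >= 2

    def test_unmapped_record_dropped_and_counted(self, tmp_path):
        sam = self._write(
            tmp_path, "r1\t4\t*\t0\t0\t*\t*\t0\t0\t" + "A" * 20 + "\t" + "I" * 20 + "\n"
        )
        alns, n_unmapped = read_alignments(sam)
        assert alns == []
        assert n_unmapped == 1

    def test_missing_nm_tag_becomes_unknown(self, tmp_path):
        sam = self._write(
            tmp_path,
            "r1\t0\tchr1\t101\t60\t20M\t*\t0\t0\t" + "A" * 20 + "\t" + "I" * 20 + "\n",
        )
        (aln,), _ = read_alignments(sam)
        assert aln.n_mismatches is None
        kept, stats = filter_alignments([aln])
        assert kept == []
        assert stats.n_unknown_mismatches == 1


class TestFilterAlignments:
    def _aln(self, nm, placements):
        return AlignedRead("r", "chr1", 0, "+", nm, placements, 20)

    def test_strict_zero_mismatch_unique_rule(self):
        alns = [
            self._aln(0, 1),   # kept
            self._aln(1, 1),   # mismatched
            self._aln(0, 2),   # multi-placement
            self._aln(None, 1),  # unknown mismatch count
        ]
        kept, stats = filter_alignments(alns)
        assert len(kept) == 1
        assert stats.n_kept == 1
        assert stats.n_mismatched == 1
        assert stats.n_multi_placement == 1
        assert stats.n_unknown_mismatches == 1
        assert stats.n_input == 4

    def test_empty_input(self):
        kept, stats = filter_alignments([])
        assert kept == []
        assert stats.n_input == 0


class TestCollapseToSites:
    def test_grouping_by_junction(self):
        alns = [AlignedRead(f"r{i}", "chr1", 100, "+", 0, 1, 20) for i in range(3)]
        (site,) = collapse_to_sites(alns)
        assert site.position == 100
        assert site.read_count == 3

    def test_minus_strand_junction_is_rightmost_base(self):
        aln = AlignedRead("r", "chr1", 100, "-", 0, 1, 20)
        assert junction_position(aln) == 119
        (site,) = collapse_to_sites([aln])
        assert site.position == 119
        assert site.strand == "-"

    def test_read_count_conservation(self):
        alns = [
            AlignedRead(f"r{i}", "chr1", pos, "+", 0, 1, 20)
            for i, pos in enumerate([5, 5, 9, 9, 9, 40])
        ]
        sites = collapse_to_sites(alns)
        assert sum(s.read_count for s in sites) == len(alns)

    def test_six_site_gene_with_heavy_tailed_counts(self):
        # six distinct junctions whose read counts include the three large
        # PCR-skewed values a resistance gene can show; totals are their sum
        counts = {100: 9384, 150: 56450, 200: 404817, 250: 12, 300: 7, 350: 3}
        alns = [
            AlignedRead(f"r{pos}_{k}", "chr1", pos, "+", 0, 1, 20)
            for pos, n in counts.items()
            for k in range(n)
        ]
        sites = collapse_to_sites(alns)
        assert len(sites) == 6
        assert sum(s.read_count for s in sites) == 470673
        assert sorted(s.read_count for s in sites) == [3, 7, 12, 9384, 56450, 404817]

    def test_empty_input(self):
        assert collapse_to_sites([]) == []


class TestAnnotateOrientation:
    def _site(self, pos, strand, chrom="chr1"):
        return InsertionSite(chrom, pos, strand, 1)

    def test_sense_antisense_intergenic(self, toy_genes):
        sites = [self._site(200, "+"), self._site(200, "-"), self._site(600, "+")]
        out, n_unknown = annotate_orientation(sites, toy_genes)
        assert [s.orientation for s in out] == ["sense", "antisense", "intergenic"]
        assert out[0].gene_id == "geneA"
        assert out[2].gene_id == ""
        assert n_unknown == 0

    def test_minus_strand_gene(self, toy_genes):
        out, _ = annotate_orientation([self._site(800, "-")], toy_genes)
        assert out[0].orientation == "sense"
        assert out[0].gene_id == "geneB"

    def test_interval_is_half_open(self, toy_genes):
        out, _ = annotate_orientation(
            [self._site(100, "+"), self._site(500, "+")], toy_genes
        )
        assert out[0].orientation == "sense"      # start inclusive
        assert out[1].orientation == "intergenic"  # end exclusive

    def test_unknown_chromosome_counted(self, toy_genes):
        out, n_unknown = annotate_orientation([self._site(200, "+", "chrX")], toy_genes)
        assert out[0].orientation == "intergenic"
        assert n_unknown == 1

    def test_gene_order_invariance(self, toy_genes):
        sites = [self._site(p, s) for p in (150, 450, 750) for s in "+-"]
        fwd, _ = annotate_orientation(sites, toy_genes)
        rev, _ = annotate_orientation(sites, list(reversed(toy_genes)))
        assert fwd == rev

    def test_overlapping_genes_yield_one_record_each(self):
        genes = [
            GeneModel("g1", "chr1", 100, 500, "+"),
            GeneModel("g2", "chr1", 400, 800, "-"),
        ]
        out, _ = annotate_orientation([self._site(450, "+")], genes)
        assert {(s.gene_id, s.orientation) for s in out} == {
            ("g1", "sense"),
            ("g2", "antisense"),
        }


class TestGeneModelIO:
    def test_bed_round_trip(self, tmp_path, toy_genes):
        from trapscreen.simulate import write_genes_bed

        path = tmp_path / "genes.bed"
        write_genes_bed(toy_genes, path)
        assert read_genes_bed(path) == toy_genes

    def test_gtf_round_trip_converts_coordinates(self, tmp_path, toy_genes):
        from trapscreen.simulate import write_genes_gtf

        path = tmp_path / "genes.gtf"
        write_genes_gtf(toy_genes, path)
        parsed = read_genes_gtf(path)
        assert parsed == toy_genes  # 1-based inclusive on disk, 0-based half-open in memory

    def test_gtf_transcript_fallback(self, tmp_path):
        path = tmp_path / "tx.gtf"
        path.write_text(
            'chr1\tsrc\ttranscript\t101\t300\t.\t+\t.\tgene_id "g"; transcript_id "t1";\n'
            'chr1\tsrc\ttranscript\t201\t500\t.\t+\t.\tgene_id "g"; transcript_id "t2";\n'
        )
        (gene,) = read_genes_gtf(path)
        assert (gene.start, gene.end) == (100, 500)

    def test_gene_model_validation(self):
        with pytest.raises(ValueError, match="start"):
            GeneModel("g", "chr1", 10, 10, "+")
        with pytest.raises(ValueError, match="strand"):
            GeneModel("g", "chr1", 0, 10, "*")


class TestRoundTrip:
    def test_simulated_sites_recovered_exactly(self, small_screen):
        truth = small_screen
        alns = align_reads(truth.reads, truth.genome)
        kept, stats = filter_alignments(alns)
        assert stats.n_kept == stats.n_input  # noiseless reads all pass
        sites = collapse_to_sites(kept)
        glen, L = len(truth.genome), 40
        expected = {
            (int(r.position), r.strand)
            for r in truth.survivors.itertuples(index=False)
            if (r.strand == "+" and int(r.position) + L <= glen)
            or (r.strand == "-" and int(r.position) - L + 1 >= 0)
        }
        assert {(s.position, s.strand) for s in sites} == expected

    def test_filtered_read_conservation(self, small_screen):
        truth = small_screen
        kept, _ = filter_alignments(align_reads(truth.reads, truth.genome))
        sites = collapse_to_sites(kept)
        assert sum(s.read_count for s in sites) == len(kept)
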