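"""Parsing, QC filters, windows, topology and start-codon censuses."""

import re

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rtscan.genome_io import (
    GeneModel,
    GenomeSequence,
    OperonRecord,
    downstream_start_census,
    gene_sense_seq,
    operon_positions,
    pair_topology,
    parse_genome,
    qc_filter_genes,
    revcomp,
    sense_window,
    start_probability_dp,
)


def _write_genome(tmp_path, contig_seq, gff_rows, contig_id="c1"):
    fasta = tmp_path / "g.fasta"
    fasta.write_text(f">{contig_id}\n{contig_seq}\n")
    gff = tmp_path / "g.gff3"
    lines = ["##gff-version 3"]
    for start, end, strand, gid in gff_rows:
        lines.append(
            f"{contig_id}\trtest\tCDS\t{start}\t{end}\t.\t{strand}\t0\tID=cds_{gid};gene_id={gid}"
        )
    gff.write_text("\n".join(lines) + "\n")
    return fasta, gff


class TestParseGenome:
    def test_one_based_inclusive_becomes_zero_based_half_open(self, tmp_path):
        fasta, gff = _write_genome(tmp_path, "A" * 20, [(4, 9, "+", "g1")])
        _, genes = parse_genome(fasta, gff)
        assert (genes[0].cds_start, genes[0].cds_end) == (3, 9)

    def test_minus_strand_sense_is_reverse_complement(self, tmp_path):
        seq = "AACCGGTTACGTACGTAACC"
        fasta, gff = _write_genome(tmp_path, seq, [(3, 8, "-", "g1")])
        contigs, genes = parse_genome(fasta, gff)
        assert gene_sense_seq(genes[0], contigs) == revcomp(seq[2:8])

    def test_multi_part_cds_merges_span_and_flags(self, tmp_path):
        fasta, gff = _write_genome(
            tmp_path, "A" * 60, [(1, 12, "+", "g1"), (31, 42, "+", "g1")]
        )
        _, genes = parse_genome(fasta, gff)
        assert len(genes) == 1
        assert genes[0].multi_part
        assert (genes[0].cds_start, genes[0].cds_end) == (0, 42)

    def test_missing_contig_is_hard_error_naming_it(self, tmp_path):
        fasta = tmp_path / "g.fasta"
        fasta.write_text(">c1\nACGT\n")
        gff = tmp_path / "g.gff3"
        gff.write_text("##gff-version 3\nc2\tx\tCDS\t1\t3\t.\t+\t0\tID=g1\n")
        with pytest.raises(ValueError, match="c2"):
            parse_genome(fasta, gff)

    def test_cds_outside_contig_is_hard_error(self, tmp_path):
        fasta, gff = _write_genome(tmp_path, "ACGTACGT", [(3, 99, "+", "g1")])
        with pytest.raises(ValueError, match="outside contig"):
            parse_genome(fasta, gff)

    def test_synthetic_genome_roundtrip_without_exclusions(self, tmp_path, small_genome):
        paths = small_genome.write(tmp_path)
        contigs, genes = parse_genome(paths["fasta"], paths["gff"])
        assert [g.gene_id for g in genes] == [g.gene_id for g in small_genome.genes]
        assert all(
            (a.cds_start, a.cds_end, a.strand) == (b.cds_start, b.cds_end, b.strand)
            for a, b in zip(genes, small_genome.genes)
        )
        kept, report = qc_filter_genes(genes, contigs)
        assert report == []
        assert len(kept) == len(genes)


class TestQcFilters:
    def _contig(self, seq):
        return {"c1": GenomeSequence("c1", seq)}

    def _gene(self, end, strand="+"):
        return GeneModel("g1", "c1", strand, 0, end)

    def test_short_gene_excluded(self):
        seq = "ATG" + "AAA" * 10 + "TAA"  # 36 nt < 40
        kept, report = qc_filter_genes([self._gene(36)], self._contig(seq))
        assert kept == [] and report == [("g1", "short")]

    def test_length_not_multiple_of_three_excluded(self):
        seq = "ATG" + "A" * 38  # 41 nt
        kept, report = qc_filter_genes([self._gene(41)], self._contig(seq))
        assert report == [("g1", "not_multiple_of_3")]

    def test_internal_stop_excluded(self):
        seq = "ATG" + "AAA" * 5 + "TGA" + "AAA" * 7 + "TAA"  # 45 nt, TGA in frame
        kept, report = qc_filter_genes([self._gene(45)], self._contig(seq))
        assert report == [("g1", "internal_stop")]

    def test_missing_terminal_stop_excluded(self):
        seq = "ATG" + "AAA" * 12 + "CCC"
        kept, report = qc_filter_genes([self._gene(42)], self._contig(seq))
        assert report == [("g1", "no_terminal_stop")]

    def test_clean_gene_retained(self):
        seq = "ATG" + "GCT" * 13 + "TAA"  # 45 nt
        kept, report = qc_filter_genes([self._gene(45)], self._contig(seq))
        assert len(kept) == 1 and report == []


class TestSenseWindow:
    def test_axis_zero_is_first_nt_after_stop(self):
        seq = "ATG" + "GCA" * 12 + "TAA" + "GCAXYZ".replace("XYZ", "TTT")
        contigs = {"c1": GenomeSequence("c1", seq)}
        gene = GeneModel("g1", "c1", "+", 0, 42)
        assert sense_window(gene, contigs, 0, 3) == "GCA"
        assert sense_window(gene, contigs, -3, 3) == "TAA"

    def test_window_past_contig_end_is_none_not_padded(self):
        contigs = {"c1": GenomeSequence("c1", "ATGAAATAAGC")}
        gene = GeneModel("g1", "c1", "+", 0, 9)
        assert sense_window(gene, contigs, 0, 2) == "GC"
        assert sense_window(gene, contigs, 0, 3) is None

    def test_strand_invariance_of_windows(self, small_genome):
        contigs = small_genome.contigs
        flipped = {
            cid: GenomeSequence(cid, revcomp(c.residues)) for cid, c in contigs.items()
        }
        n = len(next(iter(contigs.values())).residues)
        for gene in small_genome.genes[:10]:
            mirror = GeneModel(
                gene.gene_id,
                gene.contig_id,
                "-" if gene.strand == "+" else "+",
                n - gene.cds_end,
                n - gene.cds_start,
            )
            for p in (-20, -3, 0, 7):
                assert sense_window(gene, contigs, p, 15) == sense_window(
                    mirror, flipped, p, 15
                )


class TestPairTopology:
    def _genes(self, rows):
        return [
            GeneModel(gid, "c1", strand, start, end)
            for gid, start, end, strand in rows
        ]

    def test_distance_and_strand_flags(self):
        topo = pair_topology(
            self._genes([("A", 10, 100, "+"), ("B", 125, 200, "+")])
        )
        a = topo[0]
        assert (a.next_gene_id, a.intergenic_distance, a.same_strand) == ("B", 25, True)
        assert not topo[1].downstream_exists

    def test_overlapping_downstream_gene_gives_negative_distance(self):
        topo = pair_topology(self._genes([("A", 10, 100, "+"), ("B", 95, 200, "+")]))
        assert topo[0].intergenic_distance == -5

    def test_opposite_strand_neighbour_flagged(self):
        topo = pair_topology(self._genes([("A", 10, 100, "+"), ("B", 125, 200, "-")]))
        assert topo[0].same_strand is False

    def test_minus_strand_gene_looks_leftward(self):
        topo = pair_topology(self._genes([("A", 10, 100, "+"), ("B", 130, 220, "-")]))
        b = next(t for t in topo if t.gene_id == "B")
        assert b.next_gene_id == "A"
        assert b.intergenic_distance == 30

    def test_nested_gene_skipped_as_next(self):
        topo = pair_topology(
            self._genes(
                [("A", 0, 90, "+"), ("N", 100, 130, "+"), ("C", 95, 300, "+")]
            )
        )
        a = topo[0]
        assert a.next_gene_id == "C"

    def test_translation_invariance(self):
        rows = [("A", 10, 100, "+"), ("B", 125, 200, "-"), ("C", 260, 380, "+")]
        base = pair_topology(self._genes(rows))
        shifted = pair_topology(
            self._genes([(g, s + 1000, e + 1000, st) for g, s, e, st in rows])
        )
        for t1, t2 in zip(base, shifted):
            assert (t1.next_gene_id, t1.intergenic_distance, t1.same_strand) == (
                t2.next_gene_id,
                t2.intergenic_distance,
                t2.same_strand,
            )

    def test_strand_invariance_of_topology(self, small_genome):
        genes = small_genome.genes
        n = len(next(iter(small_genome.contigs.values())).residues)
        mirrored = [
            GeneModel(
                g.gene_id,
                g.contig_id,
                "-" if g.strand == "+" else "+",
                n - g.cds_end,
                n - g.cds_start,
            )
            for g in genes
        ]
        base = {t.gene_id: t for t in pair_topology(genes)}
        flip = {t.gene_id: t for t in pair_topology(mirrored)}
        for gid in base:
            assert (
                base[gid].next_gene_id,
                base[gid].intergenic_distance,
                base[gid].same_strand,
            ) == (
                flip[gid].next_gene_id,
                flip[gid].intergenic_distance,
                flip[gid].same_strand,
            )


class TestOperonPositions:
    def test_labels(self):
        genes = [GeneModel(g, "c1", "+", i * 100, i * 100 + 60) for i, g in enumerate("abcd")]
        ops = [OperonRecord("o1", ["a", "b", "c"]), OperonRecord("o2", ["d"])]
        labels = operon_positions(ops, genes)
        assert labels == {"a": "first", "b": "internal", "c": "last", "d": "monocistronic"}

    def test_unlisted_gene_unassigned(self):
        genes = [GeneModel("x", "c1", "+", 0, 60)]
        assert operon_positions([], genes) == {"x": "unassigned"}


class TestStartCensus:
    def test_counts_all_frames(self):
        downstream = "ATGGTG" + "C" * 44
        seq = "ATG" + "AAA" * 12 + "TAA" + downstream
        contigs = {"c1": GenomeSequence("c1", seq)}
        gene = GeneModel("g1", "c1", "+", 0, 42)
        count, truncated = downstream_start_census(gene, contigs, L=50)
        assert (count, truncated) == (2, False)

    def test_poly_c_has_no_starts(self):
        seq = "ATG" + "AAA" * 12 + "TAA" + "C" * 50
        contigs = {"c1": GenomeSequence("c1", seq)}
        gene = GeneModel("g1", "c1", "+", 0, 42)
        assert downstream_start_census(gene, contigs, L=50) == (0, False)

    def test_truncation_flagged_at_contig_edge(self):
        seq = "ATG" + "AAA" * 12 + "TAA" + "ATGAA"
        contigs = {"c1": GenomeSequence("c1", seq)}
        gene = GeneModel("g1", "c1", "+", 0, 42)
        count, truncated = downstream_start_census(gene, contigs, L=50)
        assert (count, truncated) == (1, True)

    def test_matches_regex_oracle_on_synthetic_genome(self, small_genome):
        pattern = re.compile(r"(?=(ATG|GTG|TTG))")
        contigs = small_genome.contigs
        for gene in small_genome.genes:
            count, truncated = downstream_start_census(gene, contigs, L=50)
            seq = sense_window(gene, contigs, 0, 50)
            if seq is None:  # truncated gene: oracle over available length
                continue
            assert count == len(pattern.findall(seq))


class TestStartProbabilityDp:
    UNIFORM = {b: 0.25 for b in "ACGT"}

    def test_too_short_for_a_codon(self):
        assert start_probability_dp(2, self.UNIFORM) == 0.0

    def test_single_triplet_uniform(self):
        assert start_probability_dp(3, self.UNIFORM) == pytest.approx(3 / 64)

    def test_negative_length_rejected(self):
        with pytest.raises(ValueError):
            start_probability_dp(-1, self.UNIFORM)

    def test_monotone_in_length(self):
        probs = [start_probability_dp(L, self.UNIFORM) for L in range(0, 80, 4)]
        assert all(b >= a for a, b in zip(probs, probs[1:]))

    def test_matches_monte_carlo_at_l50(self):
        rng = np.random.default_rng(2024)
        n = 200_000
        draws = rng.integers(0, 4, size=(n, 50))
        seqs = np.array(list("ACGT"))[draws]
        hit = np.zeros(n, dtype=bool)
        for i in range(48):
            hit |= (
                np.isin(seqs[:, i], list("AGT"))
                & (seqs[:, i + 1] == "T")
                & (seqs[:, i + 2] == "G")
            )
        mc = hit.mean()
        se = np.sqrt(mc * (1 - mc) / n)
        exact = start_probability_dp(50, self.UNIFORM)
        assert abs(exact - mc) < 3 * se
        assert exact > 0.9  # an efficient start codon is near-certain in 50 nt

    @given(st.integers(3, 60))
    @settings(max_examples=20, deadline=None)
    def test_composition_without_g_never_hits(self, L):
        comp = {"A": 0.5, "C": 0.3, "G": 0.0, "T": 0.2}
        assert start_probability_dp(L, comp) == 0.0
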