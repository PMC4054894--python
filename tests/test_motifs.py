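from collections import Counter

import pytest

from photosplice.annotation import GeneModel
from photosplice.events import ASEvent
from photosplice.motifs import (
    MotifModel,
    SpliceFlankRegion,
    extract_flank_regions,
    fisher_enrichment,
    hit_region_count,
    positional_profile,
    scan_motif,
    select_control_regions,
    shuffle_reference,
)

from oracles import fisher_greater_enumeration


def _ir(gene_id, int_no=1):
    return ASEvent("IR", gene_id, (int_no,), ("D",), (5,), (50,))


def _region(seq, site="donor", anchor=200, gene="g", int_no=1):
    return SpliceFlankRegion(
        gene_id=gene, int_no=int_no, site=site, sequence=seq,
        chrom="chr1", genomic_start=0, genomic_end=len(seq), strand="+",
        anchor=anchor,
    )


class TestExtractFlankRegions:
    @staticmethod
    def _setup(intron_len=400, strand="+"):
        # exon1 [0,1000), intron [1000,1000+L), exon2 [1000+L, 2000+L)
        exons = ((0, 1000), (1000 + intron_len, 2000 + intron_len))
        gene = GeneModel("g", "chr1", strand, exons)
        seq = "".join("ACGT"[(i // 7) % 4] for i in range(2000 + intron_len))
        return gene, {"chr1": seq}

    def test_long_intron_yields_donor_and_acceptor_regions(self):
        gene, genome = self._setup()
        regions = extract_flank_regions([_ir("g")], [gene], genome)
        by_site = {r.site: r for r in regions}
        assert set(by_site) == {"donor", "acceptor"}
        d, a = by_site["donor"], by_site["acceptor"]
        assert (d.genomic_start, d.genomic_end) == (800, 1200)
        assert (a.genomic_start, a.genomic_end) == (1200, 1600)
        assert d.anchor == 200 and a.anchor == 200
        assert d.sequence == genome["chr1"][800:1200]

    def test_short_intron_yields_single_merged_region(self):
        gene, genome = self._setup(intron_len=150)
        (region,) = extract_flank_regions([_ir("g")], [gene], genome)
        assert region.site == "merged"
        assert (region.genomic_start, region.genomic_end) == (800, 1350)
        intron_seq = genome["chr1"][1000:1150]
        assert intron_seq in region.sequence

    def test_minus_strand_donor_centers_on_right_boundary(self):
        gene, genome = self._setup(strand="-")
        regions = extract_flank_regions([_ir("g")], [gene], genome)
        d = next(r for r in regions if r.site == "donor")
        assert (d.genomic_start, d.genomic_end) == (1200, 1600)
        # transcript orientation: reverse complement of the genomic slice
        rc = genome["chr1"][1200:1600].translate(
            str.maketrans("ACGT", "TGCA"))[::-1]
        assert d.sequence == rc

    def test_exonic_flank_truncated_at_short_exon(self):
        exons = ((900, 1000), (1400, 2400))
        gene = GeneModel("g", "chr1", "+", exons)
        genome = {"chr1": "A" * 2400}
        regions = extract_flank_regions([_ir("g")], [gene], genome)
        d = next(r for r in regions if r.site == "donor")
        assert (d.genomic_start, d.genomic_end) == (900, 1200)
        assert d.anchor == 100


class TestShuffleReference:
    def test_homopolymer_is_fixed_point(self):
        assert shuffle_reference(["AAAA"], seed=1) == ["AAAA"]

    def test_composition_preserved(self):
        seqs = ["ACGTACGTGG", "TTTTACGCGA"]
        for original, shuffled in zip(seqs, shuffle_reference(seqs, seed=3)):
            assert Counter(original) == Counter(shuffled)

    def test_deterministic_under_seed(self):
        seqs = ["ACGTACGTGGACGT" * 3]
        assert shuffle_reference(seqs, seed=7) == shuffle_reference(seqs, seed=7)


class TestSelectControlRegions:
    @staticmethod
    def _pool(n):
        genes, events = [], []
        for i in range(n):
            off = i * 3000
            genes.append(
                GeneModel(f"g{i}", "chr1", "+",
                          ((off, off + 500), (off + 900, off + 1400)))
            )
            events.append(_ir(f"g{i}"))
        genome = {"chr1": "A" * (n * 3000)}
        return events, genes, genome

    def test_pool_equal_to_n_selects_all(self):
        events, genes, genome = self._pool(6)
        regions = select_control_regions(events, genes, genome, n=6, seed=0)
        assert {r.gene_id for r in regions} == {f"g{i}" for i in range(6)}

    def test_reproducible_under_seed(self):
        events, genes, genome = self._pool(10)
        a = select_control_regions(events, genes, genome, n=4, seed=5)
        b = select_control_regions(events, genes, genome, n=4, seed=5)
        assert [r.region_id for r in a] == [r.region_id for r in b]

    def test_insufficient_pool_raises_with_pool_size(self):
        events, genes, genome = self._pool(3)
        with pytest.raises(ValueError, match="3"):
            select_control_regions(events, genes, genome, n=500, seed=0)


class TestScanMotif:
    MOTIF = MotifModel(name="gaa", consensus="GAAGAAG")

    def test_single_hit_at_reported_offset(self):
        seq = "C" * 12 + "GAAGAAG" + "C" * 10
        hits = scan_motif([seq], self.MOTIF)
        assert [(h.region_index, h.offset) for h in hits] == [(0, 12)]

    def test_no_hits_without_g(self):
        assert scan_motif(["ACTACTACTACT"], self.MOTIF) == []

    def test_overlapping_hits_reported(self):
        hits = scan_motif(["GAAGAAGAAG"], self.MOTIF)
        assert [h.offset for h in hits] == [0, 3]

    def test_iupac_degenerate_positions(self):
        motif = MotifModel(name="red", consensus="SAAGAAG")
        assert scan_motif(["CAAGAAG"], motif)
        assert scan_motif(["GAAGAAG"], motif)
        assert scan_motif(["TAAGAAG"], motif) == []

    def test_pwm_scan_finds_planted_consensus(self):
        cols = []
        for sym in "GAAGAAG":
            col = [0.03, 0.03, 0.03, 0.03]
            col["ACGT".index(sym)] = 0.91
            cols.append(tuple(col))
        motif = MotifModel(name="pwm", pwm=tuple(cols), p_threshold=1e-3)
        seq = "C" * 30 + "GAAGAAG" + "C" * 30
        hits = scan_motif([seq], motif)
        assert any(h.offset == 30 for h in hits)
        assert scan_motif(["CTCTCTCTCTCTCTCTCT"], motif) == []

    def test_motif_width_bounds_enforced(self):
        with pytest.raises(ValueError):
            MotifModel(name="short", consensus="GAAG")


class TestFisherEnrichment:
    def test_small_table_matches_exact_enumeration(self):
        result = fisher_enrichment(2, 0, 2, 2)
        assert result.fisher_p == pytest.approx(1 / 6)

    def test_equal_hit_fractions_not_enriched(self):
        result = fisher_enrichment(10, 10, 20, 20)
        assert result.fisher_p >= 0.5

    def test_p_decreases_as_control_set_grows(self):
        ps = [
            fisher_enrichment(5, 0, 5, n_control).fisher_p
            for n_control in (5, 10, 20, 40)
        ]
        assert ps == sorted(ps, reverse=True)
        for n_control, p in zip((5, 10, 20, 40), ps):
            assert p == pytest.approx(
                fisher_greater_enumeration(5, 0, 0, n_control), rel=1e-9
            )

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            fisher_enrichment(0, 0, 0, 1)


class TestPositionalProfile:
    def test_exonic_hit_falls_in_negative_window(self):
        region = _region("A" * 400)
        hits = scan_motif(["A" * 400], MotifModel(name="x", consensus="AAAAAAA"))
        # direct construction instead: one hit at offset 185 => rel -15
        from photosplice.motifs import MotifHit

        profile = positional_profile([MotifHit(0, 185, 1.0)], [region])
        assert profile["donor"][-20] == 1

    def test_hit_at_splice_site_falls_in_first_intronic_window(self):
        from photosplice.motifs import MotifHit

        region = _region("A" * 400)
        profile = positional_profile([MotifHit(0, 200, 1.0)], [region])
        assert profile["donor"][0] == 1

    def test_merged_regions_excluded(self):
        from photosplice.motifs import MotifHit

        region = _region("A" * 400, site="merged", anchor=None)
        profile = positional_profile([MotifHit(0, 100, 1.0)], [region])
        assert sum(profile["donor"].values()) == 0
        assert sum(profile["acceptor"].values()) == 0

    def test_window_counts_sum_to_non_excluded_hits(self):
        from photosplice.motifs import MotifHit

        regions = [
            _region("A" * 400, site="donor"),
            _region("A" * 400, site="acceptor", gene="h"),
            _region("A" * 400, site="merged", anchor=None, gene="m"),
        ]
        hits = [
            MotifHit(0, 10, 1.0),
            MotifHit(0, 390, 1.0),
            MotifHit(1, 200, 1.0),
            MotifHit(2, 100, 1.0),  # merged, excluded
        ]
        profile = positional_profile(hits, regions)
        total = sum(profile["donor"].values()) + sum(profile["acceptor"].values())
        assert total == 3
        assert hit_region_count(hits) == 3
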