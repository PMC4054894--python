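import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from photosplice.annotation import GeneModel, derive_introns
from photosplice.ptc import (
    IRIsoform,
    build_ir_isoform,
    detect_ptc,
    ptc_proportion,
)

from oracles import ptc_call_by_translation

NONSTOP = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


def _revcomp(seq):
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def _plus_gene(exon_seqs, intron_seqs, cds_tx_start, cds_tx_end):
    """Build a plus-strand gene and its genome from exon/intron sequences.

    ``cds_tx_*`` are spliced-transcript coordinates (stop codon included).
    """
    chrom_seq = exon_seqs[0]
    exons = [(0, len(exon_seqs[0]))]
    for i_seq, e_seq in zip(intron_seqs, exon_seqs[1:]):
        start = len(chrom_seq) + len(i_seq)
        chrom_seq += i_seq + e_seq
        exons.append((start, start + len(e_seq)))
    # map spliced coordinates to genomic for the CDS span
    def tx2g(pos):
        consumed = 0
        for s, e in exons:
            if pos - consumed < e - s:
                return s + (pos - consumed)
            consumed += e - s
        raise AssertionError
    gene = GeneModel(
        "g", "chr1", "+", tuple(exons),
        cds_start=tx2g(cds_tx_start), cds_end=tx2g(cds_tx_end - 1) + 1,
    )
    return gene, {"chr1": chrom_seq}


class TestBuildIRIsoform:
    def test_intron_upstream_of_cds_shifts_start_and_flags_uorf(self):
        # exon1 = 12 nt UTR, exon2 starts with ATG...TAA
        gene, genome = _plus_gene(
            ["ACGTACGTACGT", "ATGAAACCCTAAGGG"], ["GTCCAG"], 12, 24
        )
        (intron,) = derive_introns(gene)
        iso = build_ir_isoform(gene, intron, genome)
        assert iso.cds_offset == 12 + 6
        assert iso.uorf_candidate

    def test_intron_inside_cds_shifts_authentic_stop(self):
        gene, genome = _plus_gene(["ATGAAA", "CCCGGGTAA"], ["GTTTAG"], 0, 15)
        (intron,) = derive_introns(gene)
        iso = build_ir_isoform(gene, intron, genome)
        assert iso.cds_offset == 0
        assert iso.authentic_stop_offset == 12 + 6
        assert iso.intron_interval == (6, 12)

    def test_minus_strand_sequence_is_reverse_complement(self):
        tx_exons = ["ATGAAA", "CCCGGGTAA"]
        tx_intron = "GTTTAG"
        genomic = _revcomp(tx_exons[0] + tx_intron + tx_exons[1])
        gene = GeneModel(
            "g", "chr1", "-", ((0, 9), (15, 21)),
            cds_start=0, cds_end=21,
        )
        genome = {"chr1": genomic}
        (intron,) = derive_introns(gene)
        iso = build_ir_isoform(gene, intron, genome)
        assert iso.sequence == tx_exons[0] + tx_intron + tx_exons[1]
        assert iso.cds_offset == 0

    def test_gene_without_cds_rejected(self):
        gene = GeneModel("g", "chr1", "+", ((0, 6), (12, 18)))
        (intron,) = derive_introns(gene)
        with pytest.raises(ValueError):
            build_ir_isoform(gene, intron, {"chr1": "A" * 18})


class TestDetectPTC:
    def test_in_frame_stop_in_intron(self):
        gene, genome = _plus_gene(["ATGAAA", "CCCGGGTAA"], ["TAAGTA"], 0, 15)
        (intron,) = derive_introns(gene)
        call = detect_ptc(build_ir_isoform(gene, intron, genome))
        assert call.has_ptc
        assert call.region == "retained_intron"
        assert call.ptc_offset == 6

    def test_frame_preserving_stop_free_intron_has_no_ptc(self):
        gene, genome = _plus_gene(["ATGAAA", "CCCGGGTAA"], ["GGGCCC"], 0, 15)
        (intron,) = derive_introns(gene)
        call = detect_ptc(build_ir_isoform(gene, intron, genome))
        assert not call.has_ptc

    def test_frameshifting_intron_with_downstream_stop(self):
        # 7-nt intron shifts the frame; downstream exon then reads
        # A AT GAA TGA ... -> in-frame TGA before the (out-of-frame)
        # authentic stop
        gene, genome = _plus_gene(["ATGAAA", "AATGAATGACCCTAA"], ["GGGCCCA"], 0, 21)
        (intron,) = derive_introns(gene)
        iso = build_ir_isoform(gene, intron, genome)
        call = detect_ptc(iso)
        assert call.has_ptc
        assert call.region == "downstream"
        # manual translation: ATG AAA GGG CCC A|AA TGA -> stop at offset 15
        assert call.ptc_offset == 15

    def test_sequence_shorter_than_one_codon_rejected(self):
        iso = IRIsoform("g", 1, "ATGAA", 3, 4, (0, 1))
        with pytest.raises(ValueError):
            detect_ptc(iso)


class TestRandomIntronsAgainstTranslationOracle:
    @pytest.mark.parametrize("phase", [0, 1, 2])
    def test_calls_match_brute_force_translation(self, phase):
        rng = np.random.default_rng(100 + phase)
        mismatches = 0
        for _ in range(60):
            n_codons = int(rng.integers(10, 40))
            cds = "ATG" + "".join(
                NONSTOP[i] for i in rng.integers(0, len(NONSTOP), n_codons)
            ) + "TAA"
            split = 3 * int(rng.integers(1, n_codons))
            intron_len = 3 * int(rng.integers(30, 100)) + phase
            intron = "".join("ACGT"[i] for i in rng.integers(0, 4, intron_len))
            gene, genome = _plus_gene(
                [cds[:split], cds[split:]], [intron], 0, len(cds)
            )
            (intron_model,) = derive_introns(gene)
            iso = build_ir_isoform(gene, intron_model, genome)
            call = detect_ptc(iso)
            has, off, region = ptc_call_by_translation(
                iso.sequence, iso.cds_offset, iso.authentic_stop_offset,
                iso.intron_interval,
            )
            if (call.has_ptc, call.ptc_offset, call.region) != (has, off, region):
                mismatches += 1
        assert mismatches == 0


@given(
    n_codons=st.integers(5, 30),
    split_codon=st.integers(1, 4),
    intron_codons=st.integers(2, 40),
    data=st.data(),
)
@settings(max_examples=40)
def test_frame_preserving_stop_free_introns_never_yield_intron_ptc(
    n_codons, split_codon, intron_codons, data
):
    """A 3k intron whose in-frame codons are all non-stop cannot produce an
    intron-region PTC call."""
    cds = "ATG" + "".join(
        data.draw(st.sampled_from(NONSTOP)) for _ in range(n_codons)
    ) + "TAA"
    split = 3 * min(split_codon, n_codons)
    intron = "".join(
        data.draw(st.sampled_from(NONSTOP)) for _ in range(intron_codons)
    )
    gene, genome = _plus_gene([cds[:split], cds[split:]], [intron], 0, len(cds))
    (intron_model,) = derive_introns(gene)
    call = detect_ptc(build_ir_isoform(gene, intron_model, genome))
    assert not (call.has_ptc and call.region == "retained_intron")


class TestProportion:
    def _call(self, has):
        from photosplice.ptc import PTCCall

        return PTCCall("g", 1, has)

    @pytest.mark.parametrize(
        "flags,expected",
        [((True, True, True, False), 0.75), ((False, False), 0.0), ((True,), 1.0)],
    )
    def test_values(self, flags, expected):
        assert ptc_proportion([self._call(f) for f in flags]) == pytest.approx(expected)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            ptc_proportion([])
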