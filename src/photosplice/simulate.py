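"""Synthetic genome, annotation and spliced alignments with known truth.

The generator emulates the study design the pipeline targets: dark-grown
protonema sampled before and after short light exposure (conditions D,
L1, L4), multi-exon genes whose introns have per-condition retention
fractions (low background retention in the dark, elevated after light for
a designated responsive subset), condition-specific expression levels,
paired-end 100-nt reads producing exon-body, intron-body, exact-junction
and shifted-junction alignments, and purine-rich GAA motifs planted in
the exonic flanks of responsive introns.

Fragments are sampled uniformly along the chosen isoform with no
positional or GC bias, and alignments are written directly with the
correct gapped block structure -- no aligner is involved, so sequencing
errors are off by default.  At most one intron is retained per fragment.
Everything is deterministic under the design seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pysam

from .annotation import GeneModel, IntronModel, derive_introns, write_gff3

log = logging.getLogger(__name__)

__all__ = [
    "SimulationDesign",
    "SimulationTruth",
    "ReadTruth",
    "generate_genome_and_annotation",
    "simulate_alignments",
    "write_genome_fasta",
    "make_motif_benchmark_sets",
]

_BASES = np.array(list("ACGT"))
# sense-strand codons excluding the three stops
_NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


@dataclass(frozen=True)
class SimulationDesign:
    """Study-design parameters for one simulated experiment.

    Defaults reproduce the conditions the pipeline is validated under:
    300 genes, 30 responsive introns with dark retention 0.02 rising to
    0.30 after light, ~55x per-gene coverage from 100-nt paired-end
    fragments, and the GAA-repeat consensus planted in the exonic donor
    flank of 80% of responsive introns vs 5% of a matched control set.
    """

    n_genes: int = 300
    exons_per_gene: tuple[int, int] = (4, 6)
    exon_length: tuple[int, int] = (150, 300)
    intron_length: tuple[int, int] = (380, 560)
    intergenic: int = 500
    utr_length: int = 60
    conditions: tuple[str, ...] = ("D", "L1", "L4")
    expression_mean: float = 400.0  # expected fragments per gene per sample
    expression_sigma: float = 0.4  # lognormal spread across genes
    condition_expression: tuple[float, ...] | None = None  # per-condition multiplier
    n_responsive: int = 30
    rho_dark: float = 0.02
    rho_light: float = 0.30
    background_retention: float = 0.02
    read_length: int = 100
    fragment_length: int = 230
    motif: str = "GAAGAAG"
    motif_rate_responsive: float = 0.8
    motif_rate_control: float = 0.05
    # optional alternative-donor usage at designated introns
    n_alt_donor: int = 0
    alt_donor_shift: int = 6
    alt_donor_usage: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.rho_dark <= 1 and 0 <= self.rho_light <= 1):
            raise ValueError("retention fractions must lie in [0, 1]")
        if self.rho_dark == self.rho_light and self.n_responsive > 0:
            raise ValueError("responsive introns need rho_dark != rho_light")
        for lo, hi in (self.exons_per_gene, self.exon_length, self.intron_length):
            if lo <= 0 or hi < lo:
                raise ValueError("length ranges must be positive and ordered")
        if self.fragment_length < self.read_length:
            raise ValueError("fragment length must be >= read length")
        if self.condition_expression is not None and len(
            self.condition_expression
        ) != len(self.conditions):
            raise ValueError("condition_expression must match conditions")

    def rho(self, gene_intron: tuple[str, int], truth: "SimulationTruth", cond: str) -> float:
        return truth.retention[gene_intron][cond]


@dataclass
class SimulationTruth:
    """Planted ground truth for one simulated experiment."""

    retention: dict  # (gene_id, int_no) -> {condition: rho}
    responsive: set  # {(gene_id, int_no)}
    motif_insertions: dict  # (gene_id, int_no) -> genomic offset of planted motif
    motif_control_introns: set
    alt_donor_introns: set  # {(gene_id, int_no)} with shifted-donor usage
    expression: dict  # gene_id -> expected fragments per sample

    def to_json(self, path: str | Path) -> None:
        payload = {
            "retention": {
                f"{g}:{i}": rho for (g, i), rho in sorted(self.retention.items())
            },
            "responsive": sorted(f"{g}:{i}" for g, i in self.responsive),
            "motif_insertions": {
                f"{g}:{i}": off
                for (g, i), off in sorted(self.motif_insertions.items())
            },
            "motif_control_introns": sorted(
                f"{g}:{i}" for g, i in self.motif_control_introns
            ),
            "alt_donor_introns": sorted(
                f"{g}:{i}" for g, i in self.alt_donor_introns
            ),
            "expression": dict(sorted(self.expression.items())),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")


@dataclass(frozen=True)
class ReadTruth:
    """Per-read origin record: every emitted alignment traces to one."""

    read_id: str
    gene_id: str
    blocks: tuple[tuple[int, int], ...]
    retained_intron: int | None  # int_no, or None for a fully spliced fragment
    donor_shift: int = 0


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _stop_free_cds(rng: np.random.Generator, n_codons: int) -> str:
    idx = rng.integers(0, len(_NONSTOP_CODONS), size=n_codons)
    return "".join(_NONSTOP_CODONS[i] for i in idx) + "TAA"


def generate_genome_and_annotation(
    design: SimulationDesign,
) -> tuple[dict[str, str], list[GeneModel], SimulationTruth]:
    """Build a toy chromosome, its gene models and the planted truth.

    Genes alternate strand; the CDS spans the internal portion of the
    spliced transcript (stop-free except for the authentic terminal stop)
    with short UTRs in the first and last exons.  Introns open with GT and
    close with AG.  Responsive introns are drawn uniformly; the consensus
    motif is overwritten into the exonic donor flank at the design rates.
    """
    rng = np.random.default_rng(design.seed)
    chrom = "chr1"
    pieces: list[str] = []
    pos = 0
    genes: list[GeneModel] = []
    all_introns: list[tuple[str, int]] = []
    plant_targets: dict[tuple[str, int], tuple[int, int]] = {}

    for g_idx in range(design.n_genes):
        gene_id = f"G{g_idx + 1:04d}"
        strand = "+" if g_idx % 2 == 0 else "-"
        n_exons = int(rng.integers(design.exons_per_gene[0], design.exons_per_gene[1] + 1))
        exon_lens = [
            int(rng.integers(design.exon_length[0], design.exon_length[1] + 1))
            for _ in range(n_exons)
        ]
        intron_lens = [
            int(rng.integers(design.intron_length[0], design.intron_length[1] + 1))
            for _ in range(n_exons - 1)
        ]
        total_exonic = sum(exon_lens)
        n_codons = (total_exonic - 2 * design.utr_length - 3) // 3
        tx = (
            _random_seq(rng, design.utr_length)
            + _stop_free_cds(rng, n_codons)
        )
        tx += _random_seq(rng, total_exonic - len(tx))
        cds_tx_start = design.utr_length
        cds_tx_end = design.utr_length + 3 * n_codons + 3

        # split the spliced transcript into exons, insert introns
        exon_seqs = []
        off = 0
        for length in exon_lens:
            exon_seqs.append(tx[off : off + length])
            off += length
        intron_seqs = [
            "GT" + _random_seq(rng, length - 4) + "AG" for length in intron_lens
        ]
        pre_mrna = exon_seqs[0]
        for i_seq, e_seq in zip(intron_seqs, exon_seqs[1:]):
            pre_mrna += i_seq + e_seq

        gene_seq = pre_mrna if strand == "+" else _revcomp(pre_mrna)
        gene_start = pos + design.intergenic
        # transcript-order exon intervals within the gene, then genomic
        tx_intervals = []
        cursor = 0
        for e_len, i_len in zip(exon_lens, intron_lens + [0]):
            tx_intervals.append((cursor, cursor + e_len))
            cursor += e_len + i_len
        gene_len = cursor
        if strand == "+":
            exons = tuple(
                (gene_start + s, gene_start + e) for s, e in tx_intervals
            )
            cds_map = _tx_to_genomic_span(
                tx_intervals, gene_start, gene_len, strand, cds_tx_start, cds_tx_end
            )
        else:
            exons = tuple(
                sorted(
                    (gene_start + gene_len - e, gene_start + gene_len - s)
                    for s, e in tx_intervals
                )
            )
            cds_map = _tx_to_genomic_span(
                tx_intervals, gene_start, gene_len, strand, cds_tx_start, cds_tx_end
            )
        gene = GeneModel(
            gene_id=gene_id,
            chrom=chrom,
            strand=strand,
            exons=exons,
            cds_start=cds_map[0],
            cds_end=cds_map[1],
        )
        genes.append(gene)
        pieces.append(_random_seq(rng, design.intergenic))
        pieces.append(gene_seq)
        pos = gene_start + gene_len
        for intron in derive_introns(gene):
            all_introns.append((gene_id, intron.int_no))
            # exonic donor-flank target for motif planting: up to 200 nt of
            # the transcript-upstream exon adjacent to the donor site
            if strand == "+":
                up_exon = gene.exons[intron.int_no - 1]
                flank = (max(up_exon[0], intron.start - 200), intron.start)
            else:
                up_exon = gene.exons[intron.int_no]
                flank = (intron.end, min(up_exon[1], intron.end + 200))
            plant_targets[(gene_id, intron.int_no)] = flank
    pieces.append(_random_seq(rng, design.intergenic))
    genome = {chrom: "".join(pieces)}

    # responsive introns and retention fractions
    order = rng.permutation(len(all_introns))
    responsive = {all_introns[i] for i in order[: design.n_responsive]}
    retention = {}
    for key in all_introns:
        if key in responsive:
            rho = {
                c: (design.rho_dark if c == design.conditions[0] else design.rho_light)
                for c in design.conditions
            }
        else:
            rho = {c: design.background_retention for c in design.conditions}
        retention[key] = rho

    # alternative-donor introns among the non-responsive set
    nonresponsive = [k for i, k in enumerate(all_introns) if all_introns[i] not in responsive]
    alt_donor = set()
    if design.n_alt_donor > 0:
        alt_idx = rng.choice(len(nonresponsive), size=design.n_alt_donor, replace=False)
        alt_donor = {nonresponsive[i] for i in sorted(alt_idx)}

    # motif planting: overwrite the consensus inside the exonic donor flank
    chrom_list = list(genome[chrom])
    insertions: dict[tuple[str, int], int] = {}
    control_pool = [k for k in all_introns if k not in responsive]
    control_idx = rng.choice(
        len(control_pool), size=min(len(control_pool), len(control_pool)), replace=False
    )
    motif_controls = set(control_pool)
    genes_by_id = {g.gene_id: g for g in genes}
    for key in all_introns:
        rate = (
            design.motif_rate_responsive
            if key in responsive
            else design.motif_rate_control
        )
        if rng.random() >= rate:
            continue
        fs, fe = plant_targets[key]
        w = len(design.motif)
        if fe - fs < w:
            continue
        offset = int(rng.integers(fs, fe - w + 1))
        planted = (
            design.motif
            if genes_by_id[key[0]].strand == "+"
            else _revcomp(design.motif)
        )
        chrom_list[offset : offset + w] = list(planted)
        insertions[key] = offset
    genome = {chrom: "".join(chrom_list)}

    expr = {
        g.gene_id: float(
            design.expression_mean
            * rng.lognormal(-design.expression_sigma**2 / 2, design.expression_sigma)
        )
        for g in genes
    }
    truth = SimulationTruth(
        retention=retention,
        responsive=responsive,
        motif_insertions=insertions,
        motif_control_introns=motif_controls,
        alt_donor_introns=alt_donor,
        expression=expr,
    )
    return genome, genes, truth


def _tx_to_genomic_span(
    tx_intervals: Sequence[tuple[int, int]],
    gene_start: int,
    gene_len: int,
    strand: str,
    cds_tx_start: int,
    cds_tx_end: int,
) -> tuple[int, int]:
    """Genomic span of a spliced-transcript interval (CDS)."""

    def tx_to_pre(pos: int, last: bool) -> int:
        consumed = 0
        for (s, e) in tx_intervals:
            length = e - s
            if pos - consumed < length or (last and pos - consumed == length):
                return s + (pos - consumed)
            consumed += length
        raise ValueError("transcript position out of range")

    pre_start = tx_to_pre(cds_tx_start, last=False)
    pre_end = tx_to_pre(cds_tx_end - 1, last=False) + 1
    if strand == "+":
        return gene_start + pre_start, gene_start + pre_end
    return gene_start + gene_len - pre_end, gene_start + gene_len - pre_start


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def write_genome_fasta(genome: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in sorted(genome):
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


class _IsoformMap:
    """Transcript-to-genome block mapping for one isoform of a gene."""

    def __init__(self, segments: Sequence[tuple[int, int]], strand: str):
        # segments in ascending genomic order
        self.strand = strand
        self.segments = list(segments)
        self.length = sum(e - s for s, e in segments)

    def blocks(self, tx_start: int, tx_end: int) -> tuple[tuple[int, int], ...]:
        """Genomic blocks of a transcript interval, ascending."""
        if self.strand == "-":
            tx_start, tx_end = self.length - tx_end, self.length - tx_start
        out = []
        consumed = 0
        for s, e in self.segments:
            seg_len = e - s
            lo = max(tx_start - consumed, 0)
            hi = min(tx_end - consumed, seg_len)
            if hi > lo:
                out.append((s + lo, s + hi))
            consumed += seg_len
        return tuple(out)


def _isoform_segments(
    gene: GeneModel, introns: Sequence[IntronModel], retained: int | None,
    donor_shift_intron: int | None = None, donor_shift: int = 0,
) -> list[tuple[int, int]]:
    """Exon segments of an isoform, optionally retaining one intron or
    shifting one donor site into its intron (transcript orientation)."""
    segments = [list(e) for e in gene.exons]
    if retained is not None:
        i = retained - 1
        segments[i][1] = segments[i + 1][1]
        del segments[i + 1]
    elif donor_shift_intron is not None and donor_shift != 0:
        intron = introns[donor_shift_intron - 1]
        i = donor_shift_intron - 1
        if gene.strand == "+":
            segments[i][1] = intron.start + donor_shift
        else:
            segments[i + 1][0] = intron.end - donor_shift
    return [tuple(s) for s in segments]


def simulate_alignments(
    design: SimulationDesign,
    genome: Mapping[str, str],
    genes: Sequence[GeneModel],
    truth: SimulationTruth,
    out_dir: str | Path,
    keep_read_truth: bool = False,
) -> tuple[dict[str, Path], dict[str, list[ReadTruth]]]:
    """Emit one SAM file per condition; optionally keep per-read truth.

    Per gene and condition the fragment count is Poisson around the
    planted expression level; each fragment retains at most one intron
    (chosen by its per-condition retention fraction) or, for designated
    alternative-donor introns, splices at a shifted donor site.
    """
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 7]))
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chrom = genes[0].chrom
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": len(genome[name])} for name in sorted(genome)],
    }
    cond_mult = design.condition_expression or tuple(1.0 for _ in design.conditions)
    sam_paths: dict[str, Path] = {}
    read_truth: dict[str, list[ReadTruth]] = {}
    introns_by_gene = {g.gene_id: derive_introns(g) for g in genes}
    R, F = design.read_length, design.fragment_length

    for cond, mult in zip(design.conditions, cond_mult):
        path = out_dir / f"{cond}.sam"
        sam_paths[cond] = path
        records: list[ReadTruth] = []
        with pysam.AlignmentFile(str(path), "w", header=header) as sam:
            for gene in genes:
                introns = introns_by_gene[gene.gene_id]
                rhos = [
                    truth.retention[(gene.gene_id, it.int_no)][cond] for it in introns
                ]
                n_frags = rng.poisson(truth.expression[gene.gene_id] * mult)
                for f_idx in range(n_frags):
                    flags = rng.random(len(introns)) < rhos
                    hit = np.flatnonzero(flags)
                    if hit.size == 0:
                        retained = None
                    elif hit.size == 1:
                        retained = int(hit[0]) + 1
                    else:
                        retained = int(rng.choice(hit)) + 1
                    shift_intron = None
                    shift = 0
                    if retained is None:
                        for it in introns:
                            key = (gene.gene_id, it.int_no)
                            if key in truth.alt_donor_introns and (
                                rng.random() < design.alt_donor_usage
                            ):
                                shift_intron = it.int_no
                                shift = design.alt_donor_shift
                                break
                    segments = _isoform_segments(
                        gene, introns, retained, shift_intron, shift
                    )
                    iso = _IsoformMap(segments, gene.strand)
                    if iso.length < F:
                        continue
                    s = int(rng.integers(0, iso.length - F + 1))
                    read_id = f"{cond}:{gene.gene_id}:{f_idx}"
                    for mate_no, (m_start, m_end) in enumerate(
                        ((s, s + R), (s + F - R, s + F)), start=1
                    ):
                        blocks = iso.blocks(m_start, m_end)
                        _write_sam_record(
                            sam,
                            genome,
                            chrom,
                            read_id,
                            mate_no,
                            blocks,
                            gene.strand,
                        )
                        if keep_read_truth:
                            records.append(
                                ReadTruth(
                                    read_id=f"{read_id}/{mate_no}",
                                    gene_id=gene.gene_id,
                                    blocks=blocks,
                                    retained_intron=retained,
                                    donor_shift=shift if shift_intron else 0,
                                )
                            )
        read_truth[cond] = records
    return sam_paths, read_truth


def _write_sam_record(
    sam: pysam.AlignmentFile,
    genome: Mapping[str, str],
    chrom: str,
    read_id: str,
    mate_no: int,
    blocks: Sequence[tuple[int, int]],
    gene_strand: str,
) -> None:
    rec = pysam.AlignedSegment(sam.header)
    rec.query_name = read_id
    rec.reference_name = chrom
    rec.reference_start = blocks[0][0]
    rec.mapping_quality = 60
    cigar = []
    prev_end = None
    for s, e in blocks:
        if prev_end is not None:
            cigar.append((3, s - prev_end))  # N
        cigar.append((0, e - s))  # M
        prev_end = e
    rec.cigartuples = cigar
    seq = "".join(genome[chrom][s:e] for s, e in blocks)
    rec.query_sequence = seq
    rec.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
    flag = 0x1 | 0x2  # paired, proper pair
    flag |= 0x40 if mate_no == 1 else 0x80
    # mate orientation: read1 forward, read2 reverse (FR libraries)
    flag |= 0x20 if mate_no == 1 else 0x10
    rec.flag = flag
    sam.write(rec)


def make_motif_benchmark_sets(
    n: int = 500,
    rate_sample: float = 0.8,
    rate_control: float = 0.05,
    motif: str = "GAAGAAG",
    flank: int = 200,
    seed: int = 0,
) -> tuple[list, list]:
    """Synthetic donor-flank region sets for motif-enrichment validation.

    Builds ``n`` sample and ``n`` control donor regions (``flank`` nt
    exonic + ``flank`` nt intronic, anchor at the splice site) of random
    composition, planting ``motif`` in the exonic half of a
    ``rate_sample`` / ``rate_control`` fraction of each set.
    """
    from .motifs import SpliceFlankRegion

    rng = np.random.default_rng(seed)

    def build(region_idx: int, planted: bool, label: str) -> SpliceFlankRegion:
        seq = list(_random_seq(rng, 2 * flank))
        if planted:
            off = int(rng.integers(0, flank - len(motif) + 1))
            seq[off : off + len(motif)] = list(motif)
        return SpliceFlankRegion(
            gene_id=f"{label}{region_idx:04d}",
            int_no=1,
            site="donor",
            sequence="".join(seq),
            chrom="synthetic",
            genomic_start=0,
            genomic_end=2 * flank,
            strand="+",
            anchor=flank,
        )

    sample = [build(i, rng.random() < rate_sample, "S") for i in range(n)]
    control = [build(i, rng.random() < rate_control, "C") for i in range(n)]
    return sample, control
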