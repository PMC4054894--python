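"""The four per-sample read-count tables, plus RPKM/IPKM.

Spliced alignments are reduced to per-gene tallies:

1. per-exon read counts (any block overlapping the exon by >= 1 nt);
2. per-intron read counts (same overlap rule);
3. per exon-pair spliced-read counts for gaps exactly matching annotated
   junctions (adjacent pairs = constitutive junctions, non-adjacent pairs
   = exon-skipping junctions);
4. per exon-pair shifted-junction counts, recording the signed nt offsets
   of gaps that land near an annotated junction but differ at one or both
   ends (candidate AltD/AltA/AltDA reads).

Paired-end mates are counted as two independent reads and ``total_mapped``
counts mates separately.  Only primary alignments are counted.  A read
overlapping both exon and intron counts toward both tables, and a read
overlapping two genes counts toward both.
"""

from __future__ import annotations

import bisect
import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pysam

from .annotation import GeneModel, IntronModel, derive_introns

log = logging.getLogger(__name__)

__all__ = [
    "AlignedSegmentRecord",
    "CountTables",
    "build_count_tables",
    "iter_sam",
    "rpkm",
    "ipkm",
    "write_count_tables",
    "read_count_tables",
]

#: matching window (nt) for assigning a gap to a nearby annotated junction
DEFAULT_SHIFT_TOLERANCE = 100


@dataclass(frozen=True)
class AlignedSegmentRecord:
    """A mapped read as its ordered aligned blocks on one chromosome."""

    read_id: str
    chrom: str
    blocks: tuple[tuple[int, int], ...]
    mate_flag: str = "unpaired"  # {first, second, unpaired}

    def gaps(self) -> list[tuple[int, int]]:
        return [
            (self.blocks[i][1], self.blocks[i + 1][0])
            for i in range(len(self.blocks) - 1)
        ]


@dataclass
class CountTables:
    """The four count tables for one sample.

    Keys use 1-based exon/intron ordinals in ascending genomic order.
    ``gene_read_counts`` additionally stores, per gene, the number of
    distinct reads overlapping the exon model (the RPKM numerator and the
    'reads mapped to exon regions' quantity of the stepwise filters).
    """

    sample_id: str
    exon_counts: Counter = field(default_factory=Counter)
    intron_counts: Counter = field(default_factory=Counter)
    junction_counts: Counter = field(default_factory=Counter)
    shifted_junction_counts: Counter = field(default_factory=Counter)
    gene_read_counts: Counter = field(default_factory=Counter)
    total_mapped: int = 0

    def gene_exon_reads(self, gene_id: str) -> int:
        return self.gene_read_counts.get(gene_id, 0)


def _blocks_from_cigar(reference_start: int, cigartuples) -> tuple[tuple[int, int], ...]:
    """Aligned genomic blocks; only N operations open a new block.

    Deletions extend the current block (a deletion is not a splice
    junction), insertions and clips consume no reference.
    """
    blocks: list[tuple[int, int]] = []
    pos = reference_start
    cur_start = reference_start
    for op, length in cigartuples:
        if op in (0, 7, 8, 2):  # M, =, X, D consume reference
            pos += length
        elif op == 3:  # N: splice gap
            if pos > cur_start:
                blocks.append((cur_start, pos))
            pos += length
            cur_start = pos
        # I (1), S (4), H (5), P (6) consume no reference
    if pos > cur_start:
        blocks.append((cur_start, pos))
    return tuple(blocks)


def iter_sam(path: str | Path) -> Iterator[AlignedSegmentRecord]:
    """Yield primary mapped alignments from a SAM/BAM file."""
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.cigartuples is None:
                continue
            mate = "unpaired"
            if rec.is_paired:
                mate = "first" if rec.is_read1 else "second"
            yield AlignedSegmentRecord(
                read_id=rec.query_name,
                chrom=rec.reference_name,
                blocks=_blocks_from_cigar(rec.reference_start, rec.cigartuples),
                mate_flag=mate,
            )


class _GeneIndex:
    """Per-chromosome interval lookup over gene spans."""

    def __init__(self, genes: Sequence[GeneModel]):
        self._by_chrom: dict[str, tuple[list[int], list[GeneModel]]] = {}
        self._max_len: dict[str, int] = {}
        for chrom in sorted({g.chrom for g in genes}):
            chrom_genes = sorted(
                (g for g in genes if g.chrom == chrom), key=lambda g: g.start
            )
            self._by_chrom[chrom] = ([g.start for g in chrom_genes], chrom_genes)
            self._max_len[chrom] = max(g.end - g.start for g in chrom_genes)

    def overlapping(self, chrom: str, start: int, end: int) -> list[GeneModel]:
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return []
        starts, chrom_genes = entry
        hi = bisect.bisect_left(starts, end)
        lo_bound = start - self._max_len[chrom]
        out = []
        i = hi - 1
        while i >= 0 and starts[i] > lo_bound:
            if chrom_genes[i].end > start:
                out.append(chrom_genes[i])
            i -= 1
        out.reverse()
        return out


@dataclass(frozen=True)
class _GeneLayout:
    gene: GeneModel
    introns: tuple[IntronModel, ...]
    exact_junctions: dict  # (gap_start, gap_end) -> (exon_i, exon_j) 1-based


def _gene_layout(gene: GeneModel) -> _GeneLayout:
    introns = tuple(derive_introns(gene))
    exact = {}
    for i in range(gene.n_exons):
        for j in range(i + 1, gene.n_exons):
            exact[(gene.exons[i][1], gene.exons[j][0])] = (i + 1, j + 1)
    return _GeneLayout(gene=gene, introns=introns, exact_junctions=exact)


def _signed_shifts(
    gene: GeneModel, intron: IntronModel, gap: tuple[int, int]
) -> tuple[int, int]:
    """Signed donor/acceptor offsets of a gap against an annotated intron.

    Offsets are expressed in transcript orientation: a positive donor
    shift moves the junction into the intron from the donor side.
    """
    if gene.strand == "+":
        return gap[0] - intron.start, gap[1] - intron.end
    return intron.end - gap[1], intron.start - gap[0]


def build_count_tables(
    alignments: str | Path | Iterable[AlignedSegmentRecord],
    genes: Sequence[GeneModel],
    sample_id: str = "sample",
    shift_tolerance: int = DEFAULT_SHIFT_TOLERANCE,
) -> CountTables:
    """Reduce a stream of spliced alignments to the four count tables.

    ``alignments`` may be a SAM/BAM path or an iterable of
    :class:`AlignedSegmentRecord`.  Alignments on chromosomes absent from
    the annotation are logged and skipped (they still count toward
    ``total_mapped``).
    """
    if isinstance(alignments, (str, Path)):
        alignments = iter_sam(alignments)
    index = _GeneIndex(genes)
    layouts = {g.gene_id: _gene_layout(g) for g in genes}
    tables = CountTables(sample_id=sample_id)
    unknown_chroms: set[str] = set()

    for rec in alignments:
        tables.total_mapped += 1
        if rec.chrom not in index._by_chrom:
            if rec.chrom not in unknown_chroms:
                unknown_chroms.add(rec.chrom)
                log.warning("alignments on unknown chromosome %s skipped", rec.chrom)
            continue
        rstart, rend = rec.blocks[0][0], rec.blocks[-1][1]
        for gene in index.overlapping(rec.chrom, rstart, rend):
            layout = layouts[gene.gene_id]
            hit_exons: set[int] = set()
            hit_introns: set[int] = set()
            for bs, be in rec.blocks:
                for i, (es, ee) in enumerate(gene.exons):
                    if bs < ee and be > es:
                        hit_exons.add(i + 1)
                for intron in layout.introns:
                    if bs < intron.end and be > intron.start:
                        hit_introns.add(intron.int_no)
            for e in hit_exons:
                tables.exon_counts[(gene.gene_id, e)] += 1
            for i in hit_introns:
                tables.intron_counts[(gene.gene_id, i)] += 1
            if hit_exons:
                tables.gene_read_counts[gene.gene_id] += 1
            for gap in rec.gaps():
                pair = layout.exact_junctions.get(gap)
                if pair is not None:
                    tables.junction_counts[(gene.gene_id, pair)] += 1
                    if pair[1] == pair[0] + 1:
                        tables.shifted_junction_counts[
                            (gene.gene_id, pair, 0, 0)
                        ] += 1
                    continue
                # match the gap to the nearest annotated junction within
                # the tolerance window at both ends
                best = None
                for intron in layout.introns:
                    d, a = _signed_shifts(gene, intron, gap)
                    if abs(d) <= shift_tolerance and abs(a) <= shift_tolerance:
                        key = (abs(d) + abs(a), intron.int_no)
                        if best is None or key < best[0]:
                            best = (key, intron, d, a)
                if best is not None:
                    _, intron, d, a = best
                    pair = (intron.int_no, intron.int_no + 1)
                    tables.shifted_junction_counts[
                        (gene.gene_id, pair, d, a)
                    ] += 1
    return tables


def rpkm(c_exon: int, n: int, l_exon: int) -> float:
    """Reads per kilobase of exon model per million mapped reads."""
    if n <= 0 or l_exon <= 0:
        raise ValueError(f"rpkm requires N > 0 and L > 0 (got N={n}, L={l_exon})")
    return 1e9 * c_exon / (n * l_exon)


def ipkm(c_intron: int, n: int, l_intron: int) -> float:
    """Intron reads per kilobase of retained intron per million mapped reads."""
    if n <= 0 or l_intron <= 0:
        raise ValueError(f"ipkm requires N > 0 and L > 0 (got N={n}, L={l_intron})")
    return 1e9 * c_intron / (n * l_intron)


# ---------------------------------------------------------------------------
# TSV / JSON serialization


def write_count_tables(tables: CountTables, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sid = tables.sample_id
    with open(out_dir / f"{sid}.exon_counts.tsv", "w") as fh:
        fh.write("gene_id\texon_no\tcount\n")
        for (g, e), c in sorted(tables.exon_counts.items()):
            fh.write(f"{g}\t{e}\t{c}\n")
    with open(out_dir / f"{sid}.intron_counts.tsv", "w") as fh:
        fh.write("gene_id\tint_no\tcount\n")
        for (g, i), c in sorted(tables.intron_counts.items()):
            fh.write(f"{g}\t{i}\t{c}\n")
    with open(out_dir / f"{sid}.junction_counts.tsv", "w") as fh:
        fh.write("gene_id\texon_i\texon_j\tcount\n")
        for (g, (i, j)), c in sorted(tables.junction_counts.items()):
            fh.write(f"{g}\t{i}\t{j}\t{c}\n")
    with open(out_dir / f"{sid}.shifted_junction_counts.tsv", "w") as fh:
        fh.write("gene_id\texon_i\texon_j\tdonor_shift\tacceptor_shift\tcount\n")
        for (g, (i, j), d, a), c in sorted(tables.shifted_junction_counts.items()):
            fh.write(f"{g}\t{i}\t{j}\t{d}\t{a}\t{c}\n")
    with open(out_dir / f"{sid}.gene_reads.tsv", "w") as fh:
        fh.write("gene_id\treads\n")
        for g, c in sorted(tables.gene_read_counts.items()):
            fh.write(f"{g}\t{c}\n")
    summary = {
        "sample_id": sid,
        "total_mapped": tables.total_mapped,
        "exon_assigned": sum(tables.exon_counts.values()),
        "intron_assigned": sum(tables.intron_counts.values()),
        "junction_assigned": sum(tables.junction_counts.values()),
        "shifted_junction_assigned": sum(tables.shifted_junction_counts.values()),
    }
    with open(out_dir / f"{sid}.summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_count_tables(out_dir: str | Path, sample_id: str) -> CountTables:
    out_dir = Path(out_dir)
    tables = CountTables(sample_id=sample_id)
    with open(out_dir / f"{sample_id}.exon_counts.tsv") as fh:
        next(fh)
        for line in fh:
            g, e, c = line.rstrip("\n").split("\t")
            tables.exon_counts[(g, int(e))] = int(c)
    with open(out_dir / f"{sample_id}.intron_counts.tsv") as fh:
        next(fh)
        for line in fh:
            g, i, c = line.rstrip("\n").split("\t")
            tables.intron_counts[(g, int(i))] = int(c)
    with open(out_dir / f"{sample_id}.junction_counts.tsv") as fh:
        next(fh)
        for line in fh:
            g, i, j, c = line.rstrip("\n").split("\t")
            tables.junction_counts[(g, (int(i), int(j)))] = int(c)
    with open(out_dir / f"{sample_id}.shifted_junction_counts.tsv") as fh:
        next(fh)
        for line in fh:
            g, i, j, d, a, c = line.rstrip("\n").split("\t")
            tables.shifted_junction_counts[(g, (int(i), int(j)), int(d), int(a))] = int(c)
    with open(out_dir / f"{sample_id}.gene_reads.tsv") as fh:
        next(fh)
        for line in fh:
            g, c = line.rstrip("\n").split("\t")
            tables.gene_read_counts[g] = int(c)
    with open(out_dir / f"{sample_id}.summary.json") as fh:
        tables.total_mapped = json.load(fh)["total_mapped"]
    return tables
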