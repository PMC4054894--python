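"""Premature-termination-codon annotation of intron-retention isoforms.

For each IR event the single-intron-retention isoform is rebuilt from the
genome (transcript orientation, minus-strand genes reverse-complemented)
and translated in frame from the annotated start codon.  A PTC is any
in-frame stop strictly upstream of the authentic stop codon; it is
attributed to the retained intron when the stop codon starts inside the
inserted intron, otherwise to the downstream region (frameshifted exonic
sequence included).  No 50-nt exon-junction rule is applied.

Retained introns lying entirely upstream of the coding region do not
affect the reading frame; such isoforms are reported ``has_ptc = False``
and flagged as uORF candidates (upstream open reading frames are not
evaluated further).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq

from .annotation import GeneModel, IntronModel

log = logging.getLogger(__name__)

__all__ = [
    "IRIsoform",
    "PTCCall",
    "build_ir_isoform",
    "detect_ptc",
    "ptc_proportion",
    "write_ptc_tsv",
]

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


@dataclass(frozen=True)
class IRIsoform:
    """A transcript with exactly one retained intron, transcript-oriented.

    Offsets are 0-based positions in ``sequence``: ``cds_offset`` is the
    first base of the start codon, ``authentic_stop_offset`` the first
    base of the annotated stop codon, and ``intron_interval`` the
    half-open span of the inserted intron.
    """

    gene_id: str
    int_no: int
    sequence: str
    cds_offset: int
    authentic_stop_offset: int
    intron_interval: tuple[int, int]
    uorf_candidate: bool = False

    def __post_init__(self) -> None:
        if not self.cds_offset < self.authentic_stop_offset:
            raise ValueError(
                f"{self.gene_id}: start codon must precede the authentic stop"
            )


@dataclass(frozen=True)
class PTCCall:
    gene_id: str
    int_no: int
    has_ptc: bool
    ptc_offset: int | None = None
    region: str | None = None  # {"retained_intron", "downstream"}
    uorf_candidate: bool = False


def _transcript_segments(
    gene: GeneModel, intron: IntronModel
) -> list[tuple[int, int]]:
    """Genomic segments of the IR isoform in ascending genomic order."""
    segs: list[tuple[int, int]] = []
    for start, end in gene.exons:
        if segs and segs[-1][1] == start:
            segs[-1] = (segs[-1][0], end)
        else:
            segs.append((start, end))
        if segs[-1][1] == intron.start:
            segs[-1] = (segs[-1][0], intron.end)
    # merge the exon following the retained intron into its segment
    merged: list[tuple[int, int]] = []
    for seg in segs:
        if merged and merged[-1][1] >= seg[0]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], seg[1]))
        else:
            merged.append(seg)
    return merged


def _genomic_to_tx(segments: Sequence[tuple[int, int]], strand: str, pos: int) -> int:
    """Transcript offset of a genomic base covered by ``segments``."""
    offset = 0
    if strand == "+":
        for start, end in segments:
            if start <= pos < end:
                return offset + (pos - start)
            offset += end - start
    else:
        for start, end in reversed(segments):
            if start <= pos < end:
                return offset + (end - 1 - pos)
            offset += end - start
    raise ValueError(f"genomic position {pos} is not exonic in the isoform")


def build_ir_isoform(
    gene: GeneModel,
    intron: IntronModel,
    genome: Mapping[str, str],
) -> IRIsoform:
    """Build the single-intron-retention isoform of ``gene``.

    Raises ``ValueError`` if the gene has no annotated CDS or if the start
    or stop codon cannot be located on the isoform.
    """
    if not gene.has_cds:
        raise ValueError(f"{gene.gene_id}: no annotated CDS")
    if intron.gene_id != gene.gene_id:
        raise ValueError("intron does not belong to the gene")
    chrom_seq = genome[gene.chrom]
    segments = _transcript_segments(gene, intron)
    seq = "".join(chrom_seq[s:e] for s, e in segments)
    if gene.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    if gene.strand == "+":
        start_base = gene.cds_start
        last_base = gene.cds_end - 1
    else:
        start_base = gene.cds_end - 1
        last_base = gene.cds_start
    cds_offset = _genomic_to_tx(segments, gene.strand, start_base)
    authentic_stop_offset = _genomic_to_tx(segments, gene.strand, last_base) - 2
    intron_tx_start = min(
        _genomic_to_tx(segments, gene.strand, intron.start),
        _genomic_to_tx(segments, gene.strand, intron.end - 1),
    )
    intron_interval = (intron_tx_start, intron_tx_start + intron.length)
    return IRIsoform(
        gene_id=gene.gene_id,
        int_no=intron.int_no,
        sequence=seq,
        cds_offset=cds_offset,
        authentic_stop_offset=authentic_stop_offset,
        intron_interval=intron_interval,
        uorf_candidate=intron_interval[1] <= cds_offset,
    )


def detect_ptc(isoform: IRIsoform) -> PTCCall:
    """Scan in-frame codons from the start codon for a premature stop."""
    seq = isoform.sequence
    if len(seq) < isoform.cds_offset + 3:
        raise ValueError(f"{isoform.gene_id}: sequence shorter than one codon of CDS")
    for off in range(isoform.cds_offset, len(seq) - 2, 3):
        if off >= isoform.authentic_stop_offset:
            break
        if seq[off : off + 3] in STOP_CODONS:
            region = (
                "retained_intron"
                if isoform.intron_interval[0] <= off < isoform.intron_interval[1]
                else "downstream"
            )
            return PTCCall(
                gene_id=isoform.gene_id,
                int_no=isoform.int_no,
                has_ptc=True,
                ptc_offset=off,
                region=region,
                uorf_candidate=isoform.uorf_candidate,
            )
    return PTCCall(
        gene_id=isoform.gene_id,
        int_no=isoform.int_no,
        has_ptc=False,
        uorf_candidate=isoform.uorf_candidate,
    )


def ptc_proportion(calls: Sequence[PTCCall]) -> float:
    """Fraction of isoforms carrying a PTC."""
    if not calls:
        raise ValueError("no PTC calls given")
    return sum(c.has_ptc for c in calls) / len(calls)


def write_ptc_tsv(
    calls: Sequence[PTCCall], tsv_path: str | Path, summary_path: str | Path | None = None
) -> None:
    with open(tsv_path, "w") as fh:
        fh.write("gene_id\tint_no\thas_ptc\tptc_offset\tregion\tuorf_candidate\n")
        for c in calls:
            fh.write(
                "\t".join(
                    [
                        c.gene_id,
                        str(c.int_no),
                        str(int(c.has_ptc)),
                        "" if c.ptc_offset is None else str(c.ptc_offset),
                        c.region or "",
                        str(int(c.uorf_candidate)),
                    ]
                )
                + "\n"
            )
    if summary_path is not None:
        summary = {
            "n_isoforms": len(calls),
            "n_with_ptc": int(sum(c.has_ptc for c in calls)),
            "ptc_proportion": ptc_proportion(calls) if calls else None,
            "ptc_definition": "first in-frame stop upstream of the authentic stop;"
            " no exon-junction rule",
        }
        with open(summary_path, "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
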