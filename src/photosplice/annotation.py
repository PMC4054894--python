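"""Gene models from GFF3 + FASTA, and intron derivation.

Coordinates are stored 0-based half-open internally; GFF3 I/O converts
from/to the 1-based closed convention.  One transcript model per gene (the
annotation's primary transcript) is used throughout: the event space of the
pipeline is defined against the reference exon/intron structure, not
against annotated isoform mixtures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import gffutils
from Bio import SeqIO

log = logging.getLogger(__name__)

__all__ = [
    "GeneModel",
    "IntronModel",
    "GFF3ParseError",
    "AnnotationValidationError",
    "parse_annotation",
    "derive_introns",
    "load_genome",
    "write_gff3",
    "write_gene_summary",
]


class GFF3ParseError(ValueError):
    """A GFF3 line could not be parsed."""


class AnnotationValidationError(ValueError):
    """An annotation record is structurally invalid."""


@dataclass(frozen=True)
class GeneModel:
    """A gene as an ordered set of exon intervals on one chromosome.

    Exons are 0-based half-open genomic intervals sorted in ascending
    genomic coordinate; ``cds_start``/``cds_end`` span the annotated coding
    region (stop codon included) and are ``None`` for non-coding genes.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationValidationError(
                f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if not self.exons:
            raise AnnotationValidationError(f"{self.gene_id}: gene has no exons")
        prev_end = None
        for start, end in self.exons:
            if end - start < 1:
                raise AnnotationValidationError(
                    f"{self.gene_id}: empty exon [{start},{end})"
                )
            if prev_end is not None and start <= prev_end:
                raise AnnotationValidationError(
                    f"{self.gene_id}: exons overlap, touch or are unsorted "
                    f"at [{start},{end})"
                )
            prev_end = end
        if (self.cds_start is None) != (self.cds_end is None):
            raise AnnotationValidationError(
                f"{self.gene_id}: cds_start/cds_end must both be set or both absent"
            )

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def exon_model_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def has_cds(self) -> bool:
        return self.cds_start is not None


@dataclass(frozen=True)
class IntronModel:
    """One intron of a gene; ``int_no`` counts from the 5' end of the genome.

    ``donor_site`` and ``acceptor_site`` are boundary coordinates: on the
    plus strand the donor is the intron's left boundary, on the minus
    strand its right boundary.
    """

    gene_id: str
    chrom: str
    strand: str
    int_no: int
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def donor_site(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def acceptor_site(self) -> int:
        return self.end if self.strand == "+" else self.start


def derive_introns(gene: GeneModel) -> list[IntronModel]:
    """Introns are the maximal gaps between consecutive exons.

    Numbering is ascending by genomic coordinate regardless of strand.
    """
    introns = []
    for i in range(gene.n_exons - 1):
        introns.append(
            IntronModel(
                gene_id=gene.gene_id,
                chrom=gene.chrom,
                strand=gene.strand,
                int_no=i + 1,
                start=gene.exons[i][1],
                end=gene.exons[i + 1][0],
            )
        )
    return introns


def load_genome(fasta: str | Path) -> dict[str, str]:
    """Load a genome FASTA as an upper-case sequence dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta), "fasta")}


def _prevalidate_gff3(path: str | Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GFF3ParseError(
                    f"line {lineno}: expected 9 tab-separated fields, got {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError:
                raise GFF3ParseError(f"line {lineno}: non-integer coordinates") from None
            if start < 1 or end < start:
                raise GFF3ParseError(f"line {lineno}: invalid interval {start}..{end}")


def parse_annotation(
    gff3: str | Path,
    fasta: str | Path | Mapping[str, str],
) -> list[GeneModel]:
    """Parse a GFF3 annotation against a genome into :class:`GeneModel` s.

    Exon intervals are converted to 0-based half-open.  When a gene carries
    several transcripts, the primary one (first mRNA by identifier) defines
    the exon model.  Genes with unparseable structure are skipped and
    logged; an exon outside its chromosome raises
    :class:`AnnotationValidationError`.
    """
    _prevalidate_gff3(gff3)
    if isinstance(fasta, (str, Path)):
        chrom_lengths = {
            rec.id: len(rec.seq) for rec in SeqIO.parse(str(fasta), "fasta")
        }
    else:
        chrom_lengths = {name: len(seq) for name, seq in fasta.items()}

    db = gffutils.create_db(
        str(gff3),
        dbfn=":memory:",
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        transcripts = sorted(
            db.children(gene, featuretype=("mRNA", "transcript"), level=1),
            key=lambda f: f.id,
        )
        if transcripts:
            primary = transcripts[0]
            exon_feats = list(db.children(primary, featuretype="exon"))
            cds_feats = list(db.children(primary, featuretype="CDS"))
        else:
            primary = gene
            exon_feats = list(db.children(gene, featuretype="exon"))
            cds_feats = list(db.children(gene, featuretype="CDS"))
        if not exon_feats:
            log.warning("gene %s has no exon records; skipped", gene.id)
            continue
        if gene.seqid not in chrom_lengths:
            log.warning(
                "gene %s on unknown sequence %s; skipped", gene.id, gene.seqid
            )
            continue
        exons = tuple(sorted((f.start - 1, f.end) for f in exon_feats))
        for start, end in exons:
            if start < 0 or end > chrom_lengths[gene.seqid]:
                raise AnnotationValidationError(
                    f"gene {gene.id}: exon [{start},{end}) outside "
                    f"{gene.seqid} (length {chrom_lengths[gene.seqid]})"
                )
        cds_start = cds_end = None
        if cds_feats:
            cds_start = min(f.start - 1 for f in cds_feats)
            cds_end = max(f.end for f in cds_feats)
        try:
            genes.append(
                GeneModel(
                    gene_id=gene.id,
                    chrom=gene.seqid,
                    strand=gene.strand if gene.strand in "+-" else "+",
                    exons=exons,
                    cds_start=cds_start,
                    cds_end=cds_end,
                )
            )
        except AnnotationValidationError as exc:
            log.warning("gene %s skipped: %s", gene.id, exc)
    return genes


def write_gff3(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Serialize gene models back to GFF3 (1-based closed coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in genes:
            attrs = f"ID={gene.gene_id}"
            fh.write(
                "\t".join(
                    [
                        gene.chrom,
                        "photosplice",
                        "gene",
                        str(gene.start + 1),
                        str(gene.end),
                        ".",
                        gene.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )
            mrna_id = f"{gene.gene_id}.1"
            fh.write(
                "\t".join(
                    [
                        gene.chrom,
                        "photosplice",
                        "mRNA",
                        str(gene.start + 1),
                        str(gene.end),
                        ".",
                        gene.strand,
                        ".",
                        f"ID={mrna_id};Parent={gene.gene_id}",
                    ]
                )
                + "\n"
            )
            for start, end in gene.exons:
                fh.write(
                    "\t".join(
                        [
                            gene.chrom,
                            "photosplice",
                            "exon",
                            str(start + 1),
                            str(end),
                            ".",
                            gene.strand,
                            ".",
                            f"Parent={mrna_id}",
                        ]
                    )
                    + "\n"
                )
            if gene.has_cds:
                # CDS features are emitted per exon segment overlapping the
                # CDS span; phase is recomputed in transcript order.
                segs = []
                for start, end in gene.exons:
                    s = max(start, gene.cds_start)
                    e = min(end, gene.cds_end)
                    if e > s:
                        segs.append((s, e))
                tx_order = segs if gene.strand == "+" else segs[::-1]
                phase = 0
                phases = {}
                for s, e in tx_order:
                    phases[(s, e)] = phase
                    phase = (3 - ((e - s - phase) % 3)) % 3
                for s, e in segs:
                    fh.write(
                        "\t".join(
                            [
                                gene.chrom,
                                "photosplice",
                                "CDS",
                                str(s + 1),
                                str(e),
                                ".",
                                gene.strand,
                                str(phases[(s, e)]),
                                f"Parent={mrna_id}",
                            ]
                        )
                        + "\n"
                    )


def write_gene_summary(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write the gene-model summary TSV."""
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstrand\tn_exons\texon_model_length\n")
        for g in genes:
            fh.write(
                f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.n_exons}\t{g.exon_model_length}\n"
            )
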