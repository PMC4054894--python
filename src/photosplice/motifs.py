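"""Splice-site flank extraction, motif scanning and enrichment testing.

The analysis mirrors a MAST-style workflow: extract 200 nt of exonic and
intronic sequence around the donor and acceptor sites of top-ranked
retained introns (whole intron plus adjacent exons when the intron is
shorter than the flank), scan a motif model over a sample set and a
control set drawn from non-significant IR events, test hit/not-hit counts
with a one-sided Fisher's exact test, and profile hit positions in 20-nt
windows around the splice sites.  A per-sequence mononucleotide shuffle of
the sample set is emitted as a discovery background; it is not part of
the Fisher contrast.

Motif models are inputs: either an IUPAC consensus (exact matching) or a
position weight matrix with an exact per-window match p-value threshold.
The purine-rich GAA-repeat consensus motifs reported for red and blue
light ship as packaged defaults (``RED_LIGHT_MOTIF``, ``BLUE_LIGHT_MOTIF``).
Scanning is single-strand in transcript orientation: the motifs are
exonic elements on pre-mRNA.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .annotation import GeneModel, IntronModel, derive_introns
from .events import ASEvent

log = logging.getLogger(__name__)

__all__ = [
    "SpliceFlankRegion",
    "MotifModel",
    "MotifHit",
    "EnrichmentResult",
    "RED_LIGHT_MOTIF",
    "BLUE_LIGHT_MOTIF",
    "extract_flank_regions",
    "shuffle_reference",
    "select_control_regions",
    "scan_motif",
    "fisher_enrichment",
    "positional_profile",
    "write_regions_fasta",
]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class SpliceFlankRegion:
    """A splice-site flanking sequence in transcript orientation.

    ``anchor`` is the offset of splice-site position 0 within ``sequence``:
    for a donor region, the first intronic base (exonic positions are
    negative); for an acceptor region, the first exonic base (intronic
    positions are negative).  Merged short-intron regions have no single
    anchor and are excluded from positional profiles.
    """

    gene_id: str
    int_no: int
    site: str  # {"donor", "acceptor", "merged"}
    sequence: str
    chrom: str
    genomic_start: int
    genomic_end: int
    strand: str
    anchor: int | None

    @property
    def region_id(self) -> str:
        return f"{self.gene_id}:intron{self.int_no}:{self.site}"


@dataclass(frozen=True)
class MotifModel:
    """An IUPAC consensus or PWM motif, 7-12 nt wide.

    For PWM motifs a window is a hit when its exact match p-value under
    the background model is at or below ``p_threshold`` (MAST-like); for
    consensus motifs a hit is an exact IUPAC match.
    """

    name: str
    consensus: str | None = None
    pwm: tuple[tuple[float, float, float, float], ...] | None = None
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    p_threshold: float = 1e-4

    def __post_init__(self) -> None:
        if (self.consensus is None) == (self.pwm is None):
            raise ValueError("provide exactly one of consensus or pwm")
        if self.consensus is not None:
            bad = set(self.consensus.upper()) - set(IUPAC)
            if bad:
                raise ValueError(f"invalid IUPAC symbols {sorted(bad)}")
        else:
            for col in self.pwm:
                if abs(sum(col) - 1.0) > 1e-6:
                    raise ValueError("PWM columns must be normalized")
        if not 7 <= self.width <= 12:
            raise ValueError(f"motif width must be 7-12 nt, got {self.width}")

    @property
    def width(self) -> int:
        return len(self.consensus) if self.consensus is not None else len(self.pwm)


#: [GC]AAGAAG -- the red-light GAA-repeat exonic element
RED_LIGHT_MOTIF = MotifModel(name="GAA-repeat-red", consensus="SAAGAAG")
#: [GC]AAG[AGC]AG[GA] -- the blue-light GAA-repeat variant
BLUE_LIGHT_MOTIF = MotifModel(name="GAA-repeat-blue", consensus="SAAGVAGR")


@dataclass(frozen=True)
class MotifHit:
    region_index: int
    offset: int
    score: float


@dataclass(frozen=True)
class EnrichmentResult:
    """2 x 2 hit/not-hit contingency across sample vs control sequences."""

    n_sample_hit: int
    n_sample_miss: int
    n_control_hit: int
    n_control_miss: int
    fisher_p: float

    def as_dict(self) -> dict:
        return {
            "n_sample_hit": self.n_sample_hit,
            "n_sample_miss": self.n_sample_miss,
            "n_control_hit": self.n_control_hit,
            "n_control_miss": self.n_control_miss,
            "fisher_p": self.fisher_p,
        }


# ---------------------------------------------------------------------------
# region extraction


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTNacgtn", "TGCANtgcan"))[::-1]


def _extract(
    genome: Mapping[str, str], chrom: str, start: int, end: int, strand: str
) -> str:
    seq = genome[chrom][max(start, 0) : end]
    return _revcomp(seq) if strand == "-" else seq


def extract_flank_regions(
    top_events: Sequence[ASEvent],
    genes: Sequence[GeneModel],
    genome: Mapping[str, str],
    flank: int = 200,
) -> list[SpliceFlankRegion]:
    """Extract splice-site flank regions for IR events.

    Introns longer than ``flank`` yield a donor-centered and an
    acceptor-centered region of up to ``flank`` exonic + ``flank``
    intronic nt each; shorter introns yield one merged region covering the
    whole intron plus up to ``flank`` nt of each adjacent exon.  Exonic
    flanks are truncated at the adjacent exon's boundary (logged).
    """
    genes_by_id = {g.gene_id: g for g in genes}
    introns_by_gene = {g.gene_id: derive_introns(g) for g in genes}
    regions: list[SpliceFlankRegion] = []
    for event in top_events:
        if event.kind != "IR":
            continue
        gene = genes_by_id.get(event.gene_id)
        if gene is None:
            continue
        intron = introns_by_gene[event.gene_id][event.locus[0] - 1]
        up_exon = gene.exons[intron.int_no - 1]
        down_exon = gene.exons[intron.int_no]
        up_flank = min(flank, up_exon[1] - up_exon[0])
        down_flank = min(flank, down_exon[1] - down_exon[0])
        if up_flank < flank or down_flank < flank:
            log.info(
                "flank of %s intron %d truncated at exon bounds",
                gene.gene_id,
                intron.int_no,
            )
        if intron.length > flank:
            # two regions, each flank nt exonic + flank nt intronic
            if gene.strand == "+":
                d_start, d_end = intron.start - up_flank, intron.start + flank
                a_start, a_end = intron.end - flank, intron.end + down_flank
                d_anchor, a_anchor = up_flank, flank
            else:
                d_start, d_end = intron.end - flank, intron.end + down_flank
                a_start, a_end = intron.start - up_flank, intron.start + flank
                d_anchor, a_anchor = down_flank, flank
            for site, (s, e), anchor in (
                ("donor", (d_start, d_end), d_anchor),
                ("acceptor", (a_start, a_end), a_anchor),
            ):
                regions.append(
                    SpliceFlankRegion(
                        gene_id=gene.gene_id,
                        int_no=intron.int_no,
                        site=site,
                        sequence=_extract(genome, gene.chrom, s, e, gene.strand),
                        chrom=gene.chrom,
                        genomic_start=s,
                        genomic_end=e,
                        strand=gene.strand,
                        anchor=anchor,
                    )
                )
        else:
            s = intron.start - up_flank
            e = intron.end + down_flank
            regions.append(
                SpliceFlankRegion(
                    gene_id=gene.gene_id,
                    int_no=intron.int_no,
                    site="merged",
                    sequence=_extract(genome, gene.chrom, s, e, gene.strand),
                    chrom=gene.chrom,
                    genomic_start=s,
                    genomic_end=e,
                    strand=gene.strand,
                    anchor=None,
                )
            )
    return regions


def shuffle_reference(
    sequences: Iterable[str | SpliceFlankRegion], seed: int
) -> list[str]:
    """Per-sequence mononucleotide shuffle; each output is an anagram of
    its input and the result is deterministic under ``seed``."""
    rng = np.random.default_rng(seed)
    out = []
    for item in sequences:
        seq = item.sequence if isinstance(item, SpliceFlankRegion) else item
        chars = np.array(list(seq))
        out.append("".join(rng.permutation(chars)))
    return out


def select_control_regions(
    nonsignificant_ir_events: Sequence[ASEvent],
    genes: Sequence[GeneModel],
    genome: Mapping[str, str],
    n: int = 500,
    seed: int = 0,
    flank: int = 200,
) -> list[SpliceFlankRegion]:
    """Uniform sample (without replacement) of non-significant IR events,
    with regions extracted by the same rules as the sample set."""
    pool = [e for e in nonsignificant_ir_events if e.kind == "IR"]
    if len(pool) < n:
        raise ValueError(
            f"control pool has only {len(pool)} IR events, need {n}"
        )
    rng = np.random.default_rng(seed)
    chosen_idx = sorted(rng.choice(len(pool), size=n, replace=False))
    chosen = [pool[i] for i in chosen_idx]
    return extract_flank_regions(chosen, genes, genome, flank=flank)


# ---------------------------------------------------------------------------
# scanning


def _consensus_regex(consensus: str) -> re.Pattern:
    pattern = "".join(
        f"[{IUPAC[sym]}]" if len(IUPAC[sym]) > 1 else IUPAC[sym]
        for sym in consensus.upper()
    )
    return re.compile(f"(?=({pattern}))")


def _pwm_score_threshold(motif: MotifModel) -> float:
    """Smallest log-odds score whose exact p-value under the background is
    <= p_threshold, via dynamic programming over discretized scores."""
    scale = 1000.0
    logodds = []
    for col in motif.pwm:
        row = []
        for b in range(4):
            p = max(col[b], 1e-9)
            row.append(round(math.log2(p / motif.background[b]) * scale))
        logodds.append(row)
    dist = {0: 1.0}
    for col_idx, row in enumerate(logodds):
        nxt: dict[int, float] = {}
        for score, prob in dist.items():
            for b in range(4):
                key = score + row[b]
                nxt[key] = nxt.get(key, 0.0) + prob * motif.background[b]
        dist = nxt
    tail = 0.0
    for score in sorted(dist, reverse=True):
        tail += dist[score]
        if tail > motif.p_threshold:
            return (score + 1) / scale
    return min(dist) / scale


def scan_motif(
    regions: Sequence[str | SpliceFlankRegion], motif: MotifModel
) -> list[MotifHit]:
    """Report every window matching the motif (overlaps allowed)."""
    hits: list[MotifHit] = []
    if motif.consensus is not None:
        regex = _consensus_regex(motif.consensus)
        for idx, item in enumerate(regions):
            seq = (item.sequence if isinstance(item, SpliceFlankRegion) else item).upper()
            for m in regex.finditer(seq):
                hits.append(MotifHit(region_index=idx, offset=m.start(), score=1.0))
        return hits
    threshold = _pwm_score_threshold(motif)
    w = motif.width
    logodds = np.array(
        [
            [math.log2(max(col[b], 1e-9) / motif.background[b]) for b in range(4)]
            for col in motif.pwm
        ]
    )
    for idx, item in enumerate(regions):
        seq = (item.sequence if isinstance(item, SpliceFlankRegion) else item).upper()
        codes = np.array([_BASE_INDEX.get(c, -1) for c in seq])
        for off in range(len(seq) - w + 1):
            window = codes[off : off + w]
            if (window < 0).any():
                continue
            score = float(logodds[np.arange(w), window].sum())
            if score >= threshold:
                hits.append(MotifHit(region_index=idx, offset=off, score=score))
    return hits


def fisher_enrichment(
    sample_hits: int, control_hits: int, n_sample: int, n_control: int
) -> EnrichmentResult:
    """One-sided Fisher's exact test for motif enrichment in the sample set.

    The 2 x 2 table counts input sequences with at least one motif
    occurrence vs none, in the sample vs control sets; the p-value is the
    upper hypergeometric tail (enrichment direction).
    """
    if n_sample < 1 or n_control < 1:
        raise ValueError("both datasets must contain at least one sequence")
    table = [
        [sample_hits, n_sample - sample_hits],
        [control_hits, n_control - control_hits],
    ]
    if min(table[0]) < 0 or min(table[1]) < 0:
        raise ValueError("hit counts exceed dataset sizes")
    _, p = stats.fisher_exact(table, alternative="greater")
    return EnrichmentResult(
        n_sample_hit=sample_hits,
        n_sample_miss=n_sample - sample_hits,
        n_control_hit=control_hits,
        n_control_miss=n_control - control_hits,
        fisher_p=float(p),
    )


def hit_region_count(hits: Iterable[MotifHit]) -> int:
    """Number of distinct regions with at least one hit."""
    return len({h.region_index for h in hits})


def positional_profile(
    hits: Sequence[MotifHit],
    regions: Sequence[SpliceFlankRegion],
    window: int = 20,
    span: int = 200,
) -> dict[str, dict[int, int]]:
    """Bin motif-hit offsets into ``window``-nt windows around the splice
    sites, separately for donor and acceptor regions.

    Offsets are re-expressed relative to the splice site (position 0 is
    the first base on the far side of the junction; windows are
    ``[-span, -span+window), ...``).  Merged short-intron regions carry no
    anchor and are excluded.
    """
    starts = list(range(-span, span, window))
    profile = {
        "donor": {s: 0 for s in starts},
        "acceptor": {s: 0 for s in starts},
    }
    for hit in hits:
        region = regions[hit.region_index]
        if region.site not in ("donor", "acceptor") or region.anchor is None:
            continue
        rel = hit.offset - region.anchor
        bin_start = (rel // window) * window
        if -span <= bin_start < span:
            profile[region.site][bin_start] += 1
    return profile


def write_regions_fasta(regions: Sequence[SpliceFlankRegion], path) -> None:
    """Regions as FASTA with site and anchor offsets in the headers."""
    with open(path, "w") as fh:
        for r in regions:
            anchor = "NA" if r.anchor is None else str(r.anchor)
            fh.write(
                f">{r.region_id} {r.chrom}:{r.genomic_start}-{r.genomic_end}"
                f"({r.strand}) anchor={anchor}\n{r.sequence}\n"
            )


def write_profile_tsv(profile: Mapping[str, Mapping[int, int]], path) -> None:
    with open(path, "w") as fh:
        fh.write("window_start\tdonor_count\tacceptor_count\n")
        for start in sorted(profile["donor"]):
            fh.write(
                f"{start}\t{profile['donor'][start]}\t{profile['acceptor'][start]}\n"
            )
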