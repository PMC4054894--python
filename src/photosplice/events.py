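"""AS event calling from count tables and the three stepwise filters.

Five event kinds are called against the reference exon/intron structure:

* IR    -- intron retention: intronic reads vs reads on the gene's exons;
* ES    -- exon skipping: exon-bridging junction reads vs reads on the
           skipped exon;
* AltD / AltA / AltDA -- shifted-junction reads vs zero-shift junction
           reads at the same junction, classified by which end moved.

Candidate events are then pruned by three stepwise filters, with counts
summed over the samples of one condition group (e.g. dark + 1 h + 4 h
light): (1) the gene has >= 2 reads on exon regions; (2) >= 2 spliced
reads align to the junction(s) of the AS site; (3) >= 2 reads support the
event.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .annotation import GeneModel, derive_introns
from .counting import CountTables

log = logging.getLogger(__name__)

__all__ = [
    "ASEvent",
    "detect_events",
    "apply_stepwise_filters",
    "event_set_overlap",
    "write_events_tsv",
    "read_events_tsv",
    "write_events_bed",
]

EVENT_KINDS = ("IR", "ES", "AltD", "AltA", "AltDA")


@dataclass(frozen=True)
class ASEvent:
    """One candidate AS event with per-sample count contrasts.

    ``locus`` identifies the event within its gene: ``(int_no,)`` for IR,
    ``(exon_i, skipped_exon, exon_j)`` for ES (the bridge is part of the
    identity), and ``(exon_i, exon_j, donor_shift, acceptor_shift)`` for
    the Alt* kinds.  ``supporting``/``nonsupporting`` are aligned with
    ``samples``.
    """

    kind: str
    gene_id: str
    locus: tuple[int, ...]
    samples: tuple[str, ...]
    supporting: tuple[int, ...]
    nonsupporting: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if not (len(self.samples) == len(self.supporting) == len(self.nonsupporting)):
            raise ValueError("supporting/nonsupporting must match the sample set")

    @property
    def key(self) -> tuple:
        return (self.kind, self.gene_id, self.locus)

    @property
    def total_supporting(self) -> int:
        return sum(self.supporting)


def _classify_shift(donor_shift: int, acceptor_shift: int) -> str:
    if donor_shift != 0 and acceptor_shift == 0:
        return "AltD"
    if donor_shift == 0 and acceptor_shift != 0:
        return "AltA"
    return "AltDA"


def detect_events(
    tables_by_sample: Mapping[str, CountTables],
    genes: Sequence[GeneModel],
) -> list[ASEvent]:
    """Call candidate IR/ES/AltD/AltA/AltDA events from per-sample tables.

    The ordered keys of ``tables_by_sample`` define the sample set of every
    event (baseline first by convention).  Empty tables yield an empty
    event list.
    """
    samples = tuple(tables_by_sample)
    tables = [tables_by_sample[s] for s in samples]
    genes_by_id = {g.gene_id: g for g in genes}
    events: list[ASEvent] = []

    # IR: one event per intron with intronic reads in any sample
    ir_keys = sorted({k for t in tables for k in t.intron_counts})
    for gene_id, int_no in ir_keys:
        if gene_id not in genes_by_id:
            continue
        supporting = tuple(t.intron_counts.get((gene_id, int_no), 0) for t in tables)
        if not any(supporting):
            continue
        nonsupporting = tuple(t.gene_exon_reads(gene_id) for t in tables)
        events.append(
            ASEvent("IR", gene_id, (int_no,), samples, supporting, nonsupporting)
        )

    # ES: one event per exon bridged by a non-adjacent exact junction
    es_keys = sorted(
        {k for t in tables for k in t.junction_counts if k[1][1] > k[1][0] + 1}
    )
    for gene_id, (i, j) in es_keys:
        if gene_id not in genes_by_id:
            continue
        supporting = tuple(t.junction_counts.get((gene_id, (i, j)), 0) for t in tables)
        if not any(supporting):
            continue
        for skipped in range(i + 1, j):
            nonsupporting = tuple(
                t.exon_counts.get((gene_id, skipped), 0) for t in tables
            )
            events.append(
                ASEvent(
                    "ES", gene_id, (i, skipped, j), samples, supporting, nonsupporting
                )
            )

    # Alt*: one event per nonzero-shift junction entry
    alt_keys = sorted(
        {k for t in tables for k in t.shifted_junction_counts if k[2] or k[3]}
    )
    for gene_id, (i, j), d, a in alt_keys:
        if gene_id not in genes_by_id:
            continue
        supporting = tuple(
            t.shifted_junction_counts.get((gene_id, (i, j), d, a), 0) for t in tables
        )
        if not any(supporting):
            continue
        nonsupporting = tuple(
            t.junction_counts.get((gene_id, (i, j)), 0) for t in tables
        )
        events.append(
            ASEvent(
                _classify_shift(d, a),
                gene_id,
                (i, j, d, a),
                samples,
                supporting,
                nonsupporting,
            )
        )
    return events


def _as_site_junction_reads(
    event: ASEvent, tables: Sequence[CountTables]
) -> int:
    """Spliced reads at the junction(s) of the event's AS site, summed.

    IR uses the zero-shift junction across the retained intron, ES the
    skipping junction, Alt* the shifted junction itself.
    """
    if event.kind == "IR":
        int_no = event.locus[0]
        pair = (int_no, int_no + 1)
        return sum(t.junction_counts.get((event.gene_id, pair), 0) for t in tables)
    if event.kind == "ES":
        i, _, j = event.locus
        return sum(t.junction_counts.get((event.gene_id, (i, j)), 0) for t in tables)
    return event.total_supporting


def apply_stepwise_filters(
    events: Iterable[ASEvent],
    tables_by_sample: Mapping[str, CountTables],
    min_reads: int = 2,
) -> list[ASEvent]:
    """Apply the three stepwise filters and return the retained events."""
    tables = list(tables_by_sample.values())
    retained = []
    for event in events:
        gene_reads = sum(t.gene_exon_reads(event.gene_id) for t in tables)
        if gene_reads < min_reads:
            continue
        if _as_site_junction_reads(event, tables) < min_reads:
            continue
        if event.total_supporting < min_reads:
            continue
        retained.append(event)
    return retained


def event_set_overlap(
    events_a: Iterable[ASEvent], events_b: Iterable[ASEvent]
) -> tuple[int, int, int]:
    """Partition two event sets by identity (kind, gene, locus).

    Returns ``(only_a, shared, only_b)``.
    """
    keys_a = {e.key for e in events_a}
    keys_b = {e.key for e in events_b}
    shared = keys_a & keys_b
    return (len(keys_a - shared), len(shared), len(keys_b - shared))


# ---------------------------------------------------------------------------
# serialization


def write_events_tsv(events: Sequence[ASEvent], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("kind\tgene_id\tlocus\tsamples\tsupporting\tnonsupporting\n")
        for e in events:
            fh.write(
                "\t".join(
                    [
                        e.kind,
                        e.gene_id,
                        ",".join(map(str, e.locus)),
                        ",".join(e.samples),
                        ",".join(map(str, e.supporting)),
                        ",".join(map(str, e.nonsupporting)),
                    ]
                )
                + "\n"
            )


def read_events_tsv(path: str | Path) -> list[ASEvent]:
    events = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            kind, gene_id, locus, samples, sup, non = line.rstrip("\n").split("\t")
            events.append(
                ASEvent(
                    kind,
                    gene_id,
                    tuple(int(x) for x in locus.split(",")),
                    tuple(samples.split(",")),
                    tuple(int(x) for x in sup.split(",")),
                    tuple(int(x) for x in non.split(",")),
                )
            )
    return events


def _event_interval(event: ASEvent, gene: GeneModel) -> tuple[int, int]:
    introns = derive_introns(gene)
    if event.kind == "IR":
        intron = introns[event.locus[0] - 1]
        return intron.start, intron.end
    if event.kind == "ES":
        es, ee = gene.exons[event.locus[1] - 1]
        return es, ee
    i, j, _, _ = event.locus
    return gene.exons[i - 1][1], gene.exons[j - 1][0]


def write_events_bed(
    events: Sequence[ASEvent], genes: Sequence[GeneModel], path: str | Path
) -> None:
    """BED6 intervals of event loci for genome-browser inspection."""
    genes_by_id = {g.gene_id: g for g in genes}
    with open(path, "w") as fh:
        for e in events:
            gene = genes_by_id.get(e.gene_id)
            if gene is None:
                continue
            start, end = _event_interval(e, gene)
            name = f"{e.kind}:{e.gene_id}:{','.join(map(str, e.locus))}"
            fh.write(
                f"{gene.chrom}\t{start}\t{end}\t{name}\t{e.total_supporting}\t{gene.strand}\n"
            )
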