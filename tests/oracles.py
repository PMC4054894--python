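"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's own code paths: counting is redone
with plain per-read loops over the read's origin gene, Fisher p-values by
hypergeometric enumeration with exact rational arithmetic, and PTC calls
by direct codon scanning of the isoform sequence.
"""

from collections import Counter
from math import comb


def count_tables_from_truth(genes, read_truth_records):
    """Re-tally the four count tables from simulator per-read truth."""
    genes_by_id = {g.gene_id: g for g in genes}
    exon_counts = Counter()
    intron_counts = Counter()
    junction_counts = Counter()
    shifted_counts = Counter()
    gene_reads = Counter()
    total = 0
    for rec in read_truth_records:
        total += 1
        gene = genes_by_id[rec.gene_id]
        exons = gene.exons
        introns = [(exons[i][1], exons[i + 1][0]) for i in range(len(exons) - 1)]
        hit_exon = set()
        hit_intron = set()
        for bs, be in rec.blocks:
            for i, (es, ee) in enumerate(exons):
                if bs < ee and be > es:
                    hit_exon.add(i + 1)
            for i, (isv, iev) in enumerate(introns):
                if bs < iev and be > isv:
                    hit_intron.add(i + 1)
        for e in hit_exon:
            exon_counts[(gene.gene_id, e)] += 1
        for i in hit_intron:
            intron_counts[(gene.gene_id, i)] += 1
        if hit_exon:
            gene_reads[gene.gene_id] += 1
        for k in range(len(rec.blocks) - 1):
            gs, ge = rec.blocks[k][1], rec.blocks[k + 1][0]
            matched = False
            for i in range(len(exons)):
                for j in range(i + 1, len(exons)):
                    if (gs, ge) == (exons[i][1], exons[j][0]):
                        junction_counts[(gene.gene_id, (i + 1, j + 1))] += 1
                        if j == i + 1:
                            shifted_counts[(gene.gene_id, (i + 1, j + 1), 0, 0)] += 1
                        matched = True
            if matched:
                continue
            best = None
            for i, (isv, iev) in enumerate(introns):
                if gene.strand == "+":
                    d, a = gs - isv, ge - iev
                else:
                    d, a = iev - ge, isv - gs
                if abs(d) <= 100 and abs(a) <= 100:
                    key = (abs(d) + abs(a), i + 1)
                    if best is None or key < best[0]:
                        best = (key, i + 1, d, a)
            if best is not None:
                _, int_no, d, a = best
                shifted_counts[(gene.gene_id, (int_no, int_no + 1), d, a)] += 1
    return {
        "exon_counts": exon_counts,
        "intron_counts": intron_counts,
        "junction_counts": junction_counts,
        "shifted_junction_counts": shifted_counts,
        "gene_read_counts": gene_reads,
        "total_mapped": total,
    }


def fisher_greater_enumeration(sample_hit, sample_miss, control_hit, control_miss):
    """One-sided Fisher p by full hypergeometric enumeration."""
    n_sample = sample_hit + sample_miss
    total = n_sample + control_hit + control_miss
    hits = sample_hit + control_hit
    denom = comb(total, n_sample)
    p = 0
    for k in range(sample_hit, min(n_sample, hits) + 1):
        p += comb(hits, k) * comb(total - hits, n_sample - k)
    return p / denom


STOPS = {"TAA", "TAG", "TGA"}


def ptc_call_by_translation(sequence, cds_offset, authentic_stop_offset, intron_interval):
    """Scan codons one by one for the first premature in-frame stop."""
    off = cds_offset
    while off + 3 <= len(sequence) and off < authentic_stop_offset:
        if sequence[off : off + 3] in STOPS:
            in_intron = intron_interval[0] <= off < intron_interval[1]
            return True, off, ("retained_intron" if in_intron else "downstream")
        off += 3
    return False, None, None
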