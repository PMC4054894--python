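"""End-to-end orchestration: count -> detect -> filter -> test -> rank ->
quantify -> PTC -> motif, with a reproducible run manifest.

Stage outputs land under a run directory with fixed names; rerunning with
the same configuration reproduces byte-identical files (no timestamps are
written and every random choice derives from the configured seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .annotation import derive_introns, load_genome, parse_annotation, write_gene_summary
from .counting import build_count_tables, write_count_tables
from .events import (
    apply_stepwise_filters,
    detect_events,
    write_events_bed,
    write_events_tsv,
)
from .motifs import (
    MotifModel,
    extract_flank_regions,
    fisher_enrichment,
    hit_region_count,
    positional_profile,
    scan_motif,
    select_control_regions,
    shuffle_reference,
    write_profile_tsv,
    write_regions_fasta,
)
from .ptc import build_ir_isoform, detect_ptc, write_ptc_tsv
from .response import (
    attach_ir_quantification,
    rank_top_events,
    test_all_events,
    write_normalized_matrix,
    write_results_tsv,
)

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending input."""


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    ``samples`` maps condition labels to SAM/BAM paths in condition order
    (baseline first).  Thresholds default to the published analysis:
    significance at raw P < 0.001, stepwise-filter minimum of 2 reads,
    top 1,000 ranked events, top 500 events for motif analysis, 200-nt
    splice-site flanks and 20-nt profile windows.
    """

    genome: str
    annotation: str
    samples: dict[str, str]
    out_dir: str
    baseline: str = "D"
    alpha: float = 1e-3
    min_reads: int = 2
    top_k: int = 1000
    top_motif: int = 500
    flank: int = 200
    window: int = 20
    shift_tolerance: int = 100
    motif_consensus: str = "SAAGAAG"
    test_method: str = "homogeneity"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("alpha", "min_reads", "top_k", "top_motif", "flank", "window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")
        if self.baseline not in self.samples:
            raise ValueError(
                f"baseline condition {self.baseline!r} missing from samples"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and return the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "photosplice",
        "version": __version__,
        "config": config.to_dict(),
        "stages": {},
        "notes": {
            "transcript_model": "primary transcript per gene",
            "ranking_key": "p ascending, chi2 descending, (gene_id, locus)",
            "test_method": config.test_method,
            "significance": f"raw P < {config.alpha} (BH q-values informational)",
        },
    }

    def stage(name: str, fn):
        try:
            result = fn()
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return result

    # --- annotation ---
    def _load():
        genome = load_genome(config.genome)
        genes = parse_annotation(config.annotation, genome)
        if not genes:
            raise ValueError(f"no genes parsed from {config.annotation}")
        return genome, genes

    for path in [config.genome, config.annotation, *config.samples.values()]:
        if not Path(path).exists():
            raise PipelineError(f"stage 'inputs' failed: missing path {path}")
    genome, genes = stage("annotation", _load)
    write_gene_summary(genes, out / "gene_models.tsv")
    manifest["stages"]["annotation"] = {"genes": len(genes)}

    # --- counting ---
    # baseline condition is placed first so downstream contrasts and the
    # relative-IR baseline are well defined
    conditions = [config.baseline] + [
        c for c in config.samples if c != config.baseline
    ]
    tables_by_sample = {}
    counts_dir = out / "counts"
    for cond in conditions:
        tables_by_sample[cond] = stage(
            f"count[{cond}]",
            lambda c=cond: build_count_tables(
                config.samples[c],
                genes,
                sample_id=c,
                shift_tolerance=config.shift_tolerance,
            ),
        )
        write_count_tables(tables_by_sample[cond], counts_dir)
    manifest["stages"]["count"] = {
        c: {"total_mapped": t.total_mapped} for c, t in tables_by_sample.items()
    }

    # --- detection + filters ---
    events = stage("detect", lambda: detect_events(tables_by_sample, genes))
    filtered = stage(
        "filter",
        lambda: apply_stepwise_filters(events, tables_by_sample, config.min_reads),
    )
    write_events_tsv(filtered, out / "events.tsv")
    write_events_bed(filtered, genes, out / "events.bed")
    manifest["stages"]["detect"] = {"candidates": len(events)}
    manifest["stages"]["filter"] = {"retained": len(filtered)}

    # --- testing + ranking + quantification ---
    results = stage(
        "test",
        lambda: test_all_events(filtered, alpha=config.alpha, method=config.test_method),
    )
    ranked = rank_top_events(results, config.top_k)
    attach_ir_quantification(results, tables_by_sample, genes, baseline_index=0)
    write_results_tsv(
        sorted(results, key=lambda r: (r.rank is None, r.rank or 0)),
        out / "light_response.tsv",
    )
    top_ir = [r for r in ranked if r.event.kind == "IR"]
    n_rows = write_normalized_matrix(top_ir, conditions, out / "ir_matrix.tsv")
    n_sig = sum(r.significant for r in results if r.testable)
    manifest["stages"]["test"] = {
        "tested": sum(r.testable for r in results),
        "untestable": sum(not r.testable for r in results),
        "significant": n_sig,
    }
    manifest["stages"]["rank"] = {"ranked": len(ranked)}
    manifest["stages"]["quantify"] = {
        "ir_quantified": sum(r.ipkm_series is not None for r in results),
        "matrix_rows": n_rows,
    }

    # --- PTC annotation of significant IR events ---
    def _ptc():
        genes_by_id = {g.gene_id: g for g in genes}
        introns_by_gene = {g.gene_id: derive_introns(g) for g in genes}
        calls = []
        skipped = 0
        for r in results:
            if not (r.testable and r.significant and r.event.kind == "IR"):
                continue
            gene = genes_by_id[r.event.gene_id]
            if not gene.has_cds:
                skipped += 1
                log.info("gene %s has no CDS; IR isoform skipped", gene.gene_id)
                continue
            intron = introns_by_gene[gene.gene_id][r.event.locus[0] - 1]
            calls.append(detect_ptc(build_ir_isoform(gene, intron, genome)))
        return calls, skipped

    calls, skipped = stage("ptc", _ptc)
    write_ptc_tsv(calls, out / "ptc.tsv", out / "ptc_summary.json")
    manifest["stages"]["ptc"] = {"isoforms": len(calls), "no_cds_skipped": skipped}

    # --- motif analysis ---
    def _motif():
        sig_ir = [r for r in ranked if r.event.kind == "IR" and r.significant]
        nonsig_ir = [
            r.event
            for r in results
            if r.testable and not r.significant and r.event.kind == "IR"
        ]
        n_top = min(config.top_motif, len(sig_ir))
        n_control = min(config.top_motif, len(nonsig_ir))
        if n_top == 0 or n_control == 0:
            log.warning("motif stage skipped: no significant or no control IR events")
            return None
        sample_regions = extract_flank_regions(
            [r.event for r in sig_ir[:n_top]], genes, genome, flank=config.flank
        )
        control_regions = select_control_regions(
            nonsig_ir, genes, genome, n=n_control, seed=config.seed, flank=config.flank
        )
        motif = MotifModel(name="configured", consensus=config.motif_consensus)
        sample_hits = scan_motif(sample_regions, motif)
        control_hits = scan_motif(control_regions, motif)
        enrichment = fisher_enrichment(
            hit_region_count(sample_hits),
            hit_region_count(control_hits),
            len(sample_regions),
            len(control_regions),
        )
        profile = positional_profile(
            sample_hits, sample_regions, window=config.window, span=config.flank
        )
        shuffled = shuffle_reference(sample_regions, seed=config.seed)
        write_regions_fasta(sample_regions, out / "motif_sample_regions.fasta")
        write_regions_fasta(control_regions, out / "motif_control_regions.fasta")
        with open(out / "motif_shuffled_reference.fasta", "w") as fh:
            for i, seq in enumerate(shuffled):
                fh.write(f">shuffled_{i:04d}\n{seq}\n")
        with open(out / "motif_hits.tsv", "w") as fh:
            fh.write("dataset\tregion_id\toffset\tscore\n")
            for label, hits, regions in (
                ("sample", sample_hits, sample_regions),
                ("control", control_hits, control_regions),
            ):
                for h in hits:
                    fh.write(
                        f"{label}\t{regions[h.region_index].region_id}\t"
                        f"{h.offset}\t{h.score:.6g}\n"
                    )
        payload = enrichment.as_dict()
        payload["motif"] = config.motif_consensus
        payload["n_sample_events"] = n_top
        payload["n_control_events"] = n_control
        with open(out / "motif_enrichment.json", "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")
        write_profile_tsv(profile, out / "profile.tsv")
        return enrichment

    enrichment = stage("motif", _motif)
    manifest["stages"]["motif"] = (
        {"skipped": True} if enrichment is None else enrichment.as_dict()
    )

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
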