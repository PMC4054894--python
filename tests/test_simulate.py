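import numpy as np
import pytest

from photosplice.annotation import derive_introns, load_genome, parse_annotation, write_gff3
from photosplice.counting import build_count_tables
from photosplice.simulate import (
    SimulationDesign,
    generate_genome_and_annotation,
    make_motif_benchmark_sets,
    simulate_alignments,
    write_genome_fasta,
)


class TestDesignValidation:
    def test_retention_fractions_bounded(self):
        with pytest.raises(ValueError):
            SimulationDesign(rho_light=1.5)

    def test_responsive_introns_need_differential_retention(self):
        with pytest.raises(ValueError):
            SimulationDesign(rho_dark=0.3, rho_light=0.3)

    def test_bad_length_range_rejected(self):
        with pytest.raises(ValueError):
            SimulationDesign(exon_length=(300, 150))


class TestGenerateGenomeAndAnnotation:
    def test_structure_counts(self, tmp_path):
        design = SimulationDesign(n_genes=10, exons_per_gene=(3, 3), n_responsive=5, seed=1)
        genome, genes, truth = generate_genome_and_annotation(design)
        assert len(genes) == 10
        assert sum(len(derive_introns(g)) for g in genes) == 20
        assert len(truth.retention) == 20
        assert len(truth.responsive) == 5
        # annotation round-trips through GFF3
        write_gff3(genes, tmp_path / "a.gff3")
        write_genome_fasta(genome, tmp_path / "g.fasta")
        parsed = parse_annotation(tmp_path / "a.gff3", load_genome(tmp_path / "g.fasta"))
        assert len(parsed) == 10

    def test_same_seed_byte_identical_outputs(self, tmp_path):
        design = SimulationDesign(n_genes=6, n_responsive=2, seed=9)
        for run in ("a", "b"):
            genome, genes, _ = generate_genome_and_annotation(design)
            write_genome_fasta(genome, tmp_path / f"{run}.fasta")
            write_gff3(genes, tmp_path / f"{run}.gff3")
        assert (tmp_path / "a.fasta").read_bytes() == (tmp_path / "b.fasta").read_bytes()
        assert (tmp_path / "a.gff3").read_bytes() == (tmp_path / "b.gff3").read_bytes()

    def test_full_motif_planting_rate_marks_every_responsive_flank(self):
        design = SimulationDesign(
            n_genes=5, n_responsive=5, motif_rate_responsive=1.0,
            motif_rate_control=0.0, seed=2,
        )
        genome, genes, truth = generate_genome_and_annotation(design)
        assert set(truth.motif_insertions) >= truth.responsive
        genes_by_id = {g.gene_id: g for g in genes}
        for (gene_id, int_no), offset in truth.motif_insertions.items():
            gene = genes_by_id[gene_id]
            planted = genome[gene.chrom][offset : offset + len(design.motif)]
            if gene.strand == "+":
                assert planted == design.motif
            else:
                rc = design.motif.translate(str.maketrans("ACGT", "TGCA"))[::-1]
                assert planted == rc


class TestSimulateAlignments:
    def test_zero_retention_gives_no_intronic_reads(self, tmp_path):
        design = SimulationDesign(
            n_genes=4, exons_per_gene=(2, 2), n_responsive=0,
            background_retention=0.0, expression_mean=80, seed=3,
        )
        genome, genes, truth = generate_genome_and_annotation(design)
        sams, _ = simulate_alignments(design, genome, genes, truth, tmp_path)
        for sam in sams.values():
            tables = build_count_tables(str(sam), genes)
            assert sum(tables.intron_counts.values()) == 0
            assert all(
                (d, a) == (0, 0)
                for (_, _, d, a) in tables.shifted_junction_counts
            )

    def test_full_retention_silences_the_junction(self, tmp_path):
        design = SimulationDesign(
            n_genes=3, exons_per_gene=(2, 2), n_responsive=0,
            background_retention=1.0, expression_mean=80, seed=4,
        )
        genome, genes, truth = generate_genome_and_annotation(design)
        sams, _ = simulate_alignments(design, genome, genes, truth, tmp_path)
        for sam in sams.values():
            tables = build_count_tables(str(sam), genes)
            assert sum(tables.junction_counts.values()) == 0
            assert sum(tables.intron_counts.values()) > 0

    def test_retained_fraction_matches_binomial_expectation(self, tmp_path):
        rho = 0.3
        design = SimulationDesign(
            n_genes=4, exons_per_gene=(2, 2), n_responsive=0,
            background_retention=rho, expression_mean=500, seed=6,
        )
        genome, genes, truth = generate_genome_and_annotation(design)
        _, read_truth = simulate_alignments(
            design, genome, genes, truth, tmp_path, keep_read_truth=True
        )
        for cond, records in read_truth.items():
            frags = {r.read_id.rsplit("/", 1)[0]: r.retained_intron for r in records}
            frac = np.mean([v is not None for v in frags.values()])
            se = np.sqrt(rho * (1 - rho) / len(frags))
            assert abs(frac - rho) <= 3 * se

    def test_alt_donor_reads_produce_shifted_junctions(self, tmp_path):
        design = SimulationDesign(
            n_genes=4, exons_per_gene=(2, 2), n_responsive=0,
            background_retention=0.0, n_alt_donor=2, alt_donor_usage=0.5,
            expression_mean=100, seed=8,
        )
        genome, genes, truth = generate_genome_and_annotation(design)
        sams, _ = simulate_alignments(design, genome, genes, truth, tmp_path)
        tables = build_count_tables(str(sams["D"]), genes)
        shifted = {
            (g, pair, d, a): c
            for (g, pair, d, a), c in tables.shifted_junction_counts.items()
            if (d, a) != (0, 0)
        }
        assert shifted
        assert all(d == design.alt_donor_shift and a == 0 for (_, _, d, a) in shifted)
        assert {g for (g, _, _, _) in shifted} == {
            g for g, _ in truth.alt_donor_introns
        }


class TestMotifBenchmarkSets:
    def test_planting_rates_and_determinism(self):
        sample, control = make_motif_benchmark_sets(n=200, seed=1)
        sample2, _ = make_motif_benchmark_sets(n=200, seed=1)
        assert [r.sequence for r in sample] == [r.sequence for r in sample2]
        planted = sum("GAAGAAG" in r.sequence[:200] for r in sample)
        assert 0.7 * 200 <= planted <= 0.9 * 200
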