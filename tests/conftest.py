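import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from photosplice.annotation import GeneModel
from photosplice.simulate import (
    SimulationDesign,
    generate_genome_and_annotation,
    simulate_alignments,
)


@pytest.fixture
def two_exon_gene():
    return GeneModel("g1", "chr1", "+", ((0, 100), (200, 300)))


@pytest.fixture(scope="session")
def small_simulation(tmp_path_factory):
    """A 20-gene simulated experiment with per-read truth records."""
    out = tmp_path_factory.mktemp("smallsim")
    design = SimulationDesign(
        n_genes=20, n_responsive=4, expression_mean=120.0, seed=5
    )
    genome, genes, truth = generate_genome_and_annotation(design)
    sam_paths, read_truth = simulate_alignments(
        design, genome, genes, truth, out, keep_read_truth=True
    )
    return {
        "design": design,
        "genome": genome,
        "genes": genes,
        "truth": truth,
        "sam_paths": sam_paths,
        "read_truth": read_truth,
        "dir": out,
    }
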