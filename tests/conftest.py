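import numpy as np
import pytest

from txscape.model import Feature, FeatureTable, FragmentPlacement, Genome
from txscape.pipeline import PipelineConfig, run_pipeline
from txscape.simulate import SimConfig, generate


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Desk-scale synthetic experiment used across the unit tests."""
    return SimConfig(
        seed=11,
        genome_len=400_000,
        n_genes=300,
        n_islands=6,
        nb_mean=60.0,
        n_ribosomal=45,
    )


@pytest.fixture(scope="session")
def sim(small_config):
    return generate(small_config)


@pytest.fixture(scope="session")
def sim_dir(sim, tmp_path_factory):
    out = tmp_path_factory.mktemp("simdata")
    sim.write(out)
    return out


@pytest.fixture(scope="session")
def pipeline_out(sim_dir, tmp_path_factory):
    out = tmp_path_factory.mktemp("pipeline")
    cfg = PipelineConfig(
        genome=str(sim_dir / "genome.fasta"),
        annotation=str(sim_dir / "annotation.gff3"),
        fragments={
            "light": str(sim_dir / "fragments_light.tsv"),
            "dark": str(sim_dir / "fragments_dark.tsv"),
        },
        out_dir=str(out),
        gene_window=25,  # matched to the 15-gene planted blocks of the fixture
    )
    report = run_pipeline(cfg)
    return cfg, report, out


@pytest.fixture
def toy_genome() -> Genome:
    rng = np.random.default_rng(7)
    seq = "".join(rng.choice(list("ACGT"), size=5000))
    return Genome(id="toy", sequence=seq)


@pytest.fixture
def toy_features() -> FeatureTable:
    return FeatureTable(
        [
            Feature("rrnA", "rRNA", 100, 600, "+", "16S ribosomal RNA"),
            Feature("geneA", "CDS", 1000, 2000, "+", "protein A"),
            Feature("geneB", "CDS", 2120, 2800, "+", "hypothetical protein", True),
            Feature("geneC", "CDS", 3000, 3600, "-", "protein C"),
        ],
        genome_id="toy",
    )


def frag(i, start, end, strand="+"):
    return FragmentPlacement(f"f{i}", start, end, strand)
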