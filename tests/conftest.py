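import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from heptadnet.core_intervals import GenomeLayout, GenomicInterval, GeneModel, IntervalSet

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def toy_layout():
    return GenomeLayout(("chr1", "chr2"), {"chr1": 1_000_000, "chr2": 500_000})


@pytest.fixture
def toy_genes():
    return [
        GeneModel.from_body("G1", "GENE1", GenomicInterval("chr1", 100_000, 120_000, "+"), "+"),
        GeneModel.from_body("G2", "GENE2", GenomicInterval("chr1", 400_000, 500_000, "-"), "-"),
        GeneModel.from_body("G3", "GENE3", GenomicInterval("chr2", 200_000, 210_000, "+"), "+"),
    ]


def random_interval_set(rng, n, chroms=("c1", "c2"), max_pos=10_000, max_len=400, name=""):
    chrom = rng.choice(chroms, size=n)
    starts = rng.integers(0, max_pos, size=n)
    lengths = rng.integers(1, max_len, size=n)
    return IntervalSet(chrom, starts, starts + lengths, name=name)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def small_config(seed=0, **overrides):
    """A scaled-down study configuration for fast test bundles."""
    from heptadnet.synthetic_data import SimulationConfig

    base = dict(
        n_chrom=2,
        chrom_length_bp=2_000_000,
        n_genes=10,
        n_core_regions=20,
        cell_specific={
            "HSC-MPP": (("FLI1", "ERG", "RUNX1"), 25),
            "GMP": (("FLI1", "RUNX1", "LYL1", "LMO2"), 25),
            "MEP": (("GATA2", "TAL1", "LYL1", "LMO2"), 25),
        },
        n_background_peaks=40,
        n_atac_background=60,
        n_decoy_loops=30,
        seed=seed,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    from heptadnet.synthetic_data import simulate_study

    return simulate_study(small_config(seed=5), tmp_path_factory.mktemp("shared_bundle"))
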