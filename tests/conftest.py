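"""Shared fixtures: a written-to-disk default synthetic study, a small
fast study for repeated runs, and tiny hand-built references."""

import pytest

from clonemut.synthetic_data import SimulationConfig, simulate_all
from clonemut.variant_io import ReferenceGenome


def small_config(seed: int = 1, **overrides) -> SimulationConfig:
    """Reduced problem size for studies that repeat the simulation."""
    defaults = dict(
        seed=seed,
        n_chrom=2,
        chrom_length=100_000,
        n_genes=20,
        n_germline_het=1_000,
        n_somatic_shared=60,
        n_somatic_private_per_clone=(40, 30),
        n_somatic_lowdepth=10,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def default_study(tmp_path_factory):
    """The default synthetic fixture, written to disk once per session."""
    out = tmp_path_factory.mktemp("default_study")
    return simulate_all(SimulationConfig(seed=1), out)


@pytest.fixture(scope="session")
def small_study():
    """In-memory small study shared by read-only tests."""
    return simulate_all(small_config(seed=2))


@pytest.fixture()
def toy_reference():
    """Two tiny chromosomes with every base class represented."""
    return ReferenceGenome({"chr1": "ACGTACGTACGT", "chr2": "TTTTCCCCGGGG"})
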