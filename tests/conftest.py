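import pytest

from lakemeta.records import PathwayDefinition
from lakemeta.synthetic import CommunityConfig, simulate_community


@pytest.fixture(scope="session")
def small_community():
    """A small deterministic community: 4 compartments x 8 genomes,
    2 samples per compartment."""
    cfg = CommunityConfig(
        samples_per_compartment=2, genomes_per_compartment=8, seed=42
    )
    genomes, samples, coverage, truth = simulate_community(cfg)
    return cfg, genomes, samples, coverage, truth


@pytest.fixture
def toy_defs():
    return [
        PathwayDefinition("pw_single", {"m1": 50.0}, 1),
        PathwayDefinition("pw_strict", {"m2": 60.0, "m3": 70.0, "m4": 80.0}, 3),
    ]
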