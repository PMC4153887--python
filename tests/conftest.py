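import numpy as np
import pytest

from archaeoscan.synthetic import PlantSpec, SynthConfig, generate_genome


@pytest.fixture(scope="session")
def planted_genome():
    """One mid-sized genome with every planted element, shared across tests."""
    cfg = SynthConfig(
        seed=11,
        genome_length=80_000,
        planted=[
            PlantSpec("pyl_locus", {"split_position": 120, "reference_length": 280}),
            PlantSpec("pyl_cassette"),
            PlantSpec("orb_pair"),
            PlantSpec("crispr_array"),
            PlantSpec("rrna_set", {"arrangement": "scattered"}),
        ],
    )
    genome, features, truth = generate_genome(cfg)
    return genome, features, truth


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def truth_by_kind(truth: dict) -> dict:
    out = {}
    for entry in truth["planted"]:
        out.setdefault(entry["kind"], []).append(entry)
    return out
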