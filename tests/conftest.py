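import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def random_protospacer(rng: np.random.Generator, length: int = 20) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


@pytest.fixture
def planted_fixture(rng):
    """A small clean genome with 2 exact, 3 seed-only and 1 near-match copy."""
    from crisprdesign import PlantSpec, make_synthetic_genome

    proto = random_protospacer(rng)
    mut_base = "T" if proto[5] != "T" else "A"
    spec = PlantSpec(
        protospacer=proto,
        pam="AGG",
        copies_full=2,
        copies_seed_only=3,
        mutations=((5, mut_base),),
    )
    genome, manifest = make_synthetic_genome(6000, [spec], seed=11)
    return proto, spec, genome, manifest
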