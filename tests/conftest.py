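"""Shared fixtures: seeded references and simulator configurations."""

from __future__ import annotations

import numpy as np
import pytest

from junctionkit.sequences import Reference
from junctionkit.synthetic_data import JoinConfig, generate_switch_region


def random_unit_pool(n_units: int, unit_len: int = 10, seed: int = 99) -> tuple[str, ...]:
    """A pool of random motifs; a large pool yields references whose
    >=12-mers are mostly locus-unique (needed for origin benchmarks)."""
    rng = np.random.default_rng(seed)
    return tuple("".join(rng.choice(list("ACGT"), unit_len)) for _ in range(n_units))


@pytest.fixture(scope="session")
def repeat_regions():
    """Motif-rich donor/acceptor pair (distinct motif sets per side)."""
    donor = generate_switch_region(3000, ("GAGCT", "GGGGT"), seed=10, noise=0.02, region_id="Drep")
    acceptor = generate_switch_region(
        3000, ("CCAGGACAG", "TGGAAGTGT", "GGGGACC"), seed=11, noise=0.02, region_id="Arep"
    )
    return donor, acceptor


@pytest.fixture(scope="session")
def diverse_regions():
    """High-entropy donor/acceptor pair for origin-recovery benchmarks."""
    donor = generate_switch_region(
        3000, random_unit_pool(64, seed=7), seed=21, noise=0.05, region_id="Ddiv"
    )
    acceptor = generate_switch_region(
        3000, random_unit_pool(64, seed=8), seed=22, noise=0.05, region_id="Adiv"
    )
    return donor, acceptor


@pytest.fixture
def clean_join_cfg():
    """Mutation-free joining config used by recovery tests."""
    return JoinConfig(flank_mutation_rate=0.0, seed=42, max_template_distance=2000)


@pytest.fixture
def toy_refs():
    donor = Reference(
        id="toy_donor",
        sequence="GGGACCCAGGCTTTGAAGGCAATCCTGGGA",
        role="donor",
    )
    acceptor = Reference(
        id="toy_acceptor",
        sequence="GTACTTATAGAGGAACAGGGGCAGCGTAGA",
        role="acceptor",
    )
    return donor, acceptor
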