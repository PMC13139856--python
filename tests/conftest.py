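"""Shared fixtures: synthetic chains and complexes with planted ground truth."""

import numpy as np
import pytest

from optosite import (
    ComplexSpec,
    SegmentBlueprint,
    build_chain,
    build_complex,
)
from optosite.synthetic import CANONICAL_CHAINS


@pytest.fixture(scope="session")
def helix_model():
    return build_chain(CANONICAL_CHAINS["helix"], seed=11)


@pytest.fixture(scope="session")
def strand_model():
    return build_chain(CANONICAL_CHAINS["strand"], seed=11)


@pytest.fixture(scope="session")
def mixed_idr_model():
    """Helix-coil-helix with a low-confidence coil: plants IDR at 11-16."""
    return build_chain(CANONICAL_CHAINS["mixed_idr"], seed=12)


@pytest.fixture(scope="session")
def mixed_ior_model():
    """All-helix with a low-confidence middle: plants IOR at 11-16."""
    return build_chain(CANONICAL_CHAINS["mixed_ior"], seed=12)


@pytest.fixture(scope="session")
def far_complex():
    """Two chains 50 A apart: no contacts, empty refined list."""
    return build_complex(
        ComplexSpec(
            chain_a=[SegmentBlueprint("H", 8, 95.0)],
            chain_b=[SegmentBlueprint("H", 10, 95.0)],
            min_separation=50.0,
            seed=21,
        )
    )


@pytest.fixture(scope="session")
def touching_complex():
    """Minimum inter-chain distance 6 A: at least one contact."""
    return build_complex(
        ComplexSpec(
            chain_a=[SegmentBlueprint("H", 8, 95.0), SegmentBlueprint("C", 5, 70.0),
                     SegmentBlueprint("H", 8, 95.0)],
            chain_b=[SegmentBlueprint("H", 10, 95.0)],
            min_separation=6.0,
            seed=22,
        )
    )


@pytest.fixture(scope="session")
def planted_loop_complex():
    """Chain A carries an IDR (9-13) plus a confident coil (14-16); chain B far away.

    Every chain-A residue is >= 15 A from chain B, so the insertion-site
    policy should nominate exactly the coil residues within two positions
    of the IDR span.
    """
    return build_complex(
        ComplexSpec(
            chain_a=[SegmentBlueprint("H", 8, 95.0), SegmentBlueprint("C", 5, 70.0),
                     SegmentBlueprint("C", 3, 95.0), SegmentBlueprint("H", 8, 95.0)],
            chain_b=[SegmentBlueprint("H", 10, 95.0)],
            min_separation=15.0,
            seed=23,
        )
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20260930)
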