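import numpy as np
import pytest

from helixweak.synthetic_structures import (
    BundleSpec,
    HelixSpec,
    PlantedWeakSpot,
    build_bundle,
    build_gate_phantom,
    build_helix,
)

# the per-helix generic positions used for planted-ensemble tests; helix 3
# (TM3) is deliberately left unweakened
PLANTED_POSITIONS = {1: 46, 2: 58, 4: 53, 5: 43, 6: 47, 7: 46}


@pytest.fixture(scope="session")
def ideal_helix20():
    return build_helix(HelixSpec("A" * 20))


@pytest.fixture(scope="session")
def gate_phantom_closed():
    return build_gate_phantom(rotamer="closed")


@pytest.fixture(scope="session")
def gate_phantom_open():
    return build_gate_phantom(rotamer="open")


def make_bundle(seed: int, mechanisms=("proline", "sidechain_clamp")):
    """Bundle with one planted weak spot per helix (except TM3); the
    mechanism alternates with seed and helix so an ensemble realizes every
    position through at least two distinct mechanisms."""
    planted = tuple(
        PlantedWeakSpot(h, p, mechanisms[(seed + h) % len(mechanisms)])
        for h, p in PLANTED_POSITIONS.items()
    )
    return build_bundle(BundleSpec(planted=planted), seed=seed)


class SingleResidueNumbering:
    """Minimal numbering stub mapping one generic position to one residue."""

    def __init__(self, residue, generic="2x46"):
        self.residue = residue
        self.generic = generic

    def lookup(self, generic):
        return self.residue if str(generic) == self.generic else None


@pytest.fixture
def single_numbering():
    return SingleResidueNumbering
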