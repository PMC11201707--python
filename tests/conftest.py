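import numpy as np
import pytest

from autopoiesim.params import Color, Species
from autopoiesim.state import SimulationState
from autopoiesim import physics


@pytest.fixture
def make_state():
    """Factory for small hand-built states.

    ``particles`` is a list of (species, position, color) or (species,
    position); ``bonds`` a list of index pairs.  Neighbor lists are built.
    """

    def _make(particles, bonds=(), side=40.0, seed=0):
        state = SimulationState(container_side=side, rng=np.random.default_rng(seed))
        for spec in particles:
            sp, pos = spec[0], np.asarray(spec[1], dtype=float)
            color = spec[2] if len(spec) > 2 else (
                Color.NONE if sp == Species.ALPHA else Color.RED
            )
            state.add_particle(sp, pos, color=color)
        for i, j in bonds:
            state.add_bond(i, j)
        physics.update_neighbor_lists(state)
        return state

    return _make
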