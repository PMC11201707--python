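import numpy as np
import pytest

from autopoiesim import chemistry, physics
from autopoiesim.chemistry import arbitrate_chemistry
from autopoiesim.params import Color, SchemaParams, Species
from autopoiesim.runner import ExperimentConfig, initialize


def silent_schema(**overrides):
    """All reaction probabilities zero unless overridden."""
    zero5 = {n: 0.0 for n in range(5)}
    base = dict(
        pA1=dict(zero5),
        pA2=dict(zero5),
        pB=dict(zero5),
        pC=0.0,
        pD1=0.0,
        pE={0: 0.0, 1: 0.0, 2: 0.0},
        pF=dict(zero5),
    )
    base.update(overrides)
    return SchemaParams(**base)


ONE = {n: 1.0 for n in range(5)}


class TestArbitration:
    def test_all_probabilities_zero_is_inert(self, make_state):
        state = make_state(
            [
                (Species.GAMMA, [5, 5, 5], Color.RED),
                (Species.ALPHA, [6, 5, 5]),
                (Species.ALPHA, [5, 6, 5]),
                (Species.BETA, [7, 7, 5], Color.BLUE),
            ]
        )
        before = state.pos.copy()
        events = arbitrate_chemistry(state, silent_schema())
        assert events == []
        assert state.n_particles == 4 and np.array_equal(before, state.pos)

    def test_certain_beta_synthesis_fires_once(self, make_state):
        state = make_state(
            [
                (Species.GAMMA, [5, 5, 5], Color.RED),
                (Species.ALPHA, [6, 5, 5]),
                (Species.ALPHA, [5, 6, 5]),
            ]
        )
        events = arbitrate_chemistry(state, silent_schema(pA1=dict(ONE)))
        assert [e.mechanism for e in events] == ["A"]

    def test_shared_reagents_only_one_gamma_succeeds(self, make_state):
        # two gammas able to see the same two alphas: whichever is visited
        # first consumes them; the other must not react
        parts = [
            (Species.GAMMA, [5, 5, 5], Color.RED),
            (Species.GAMMA, [9, 5, 5], Color.BLUE),
            (Species.ALPHA, [7, 5, 5]),
            (Species.ALPHA, [7, 5.5, 5]),
        ]
        schema = silent_schema(pA1=dict(ONE))
        seen = set()
        for seed in range(20):
            state = make_state(parts, seed=seed)
            events = arbitrate_chemistry(state, schema)
            assert len(events) == 1
            seen.add(events[0].initiator)
        assert seen == {0, 1}  # both visit orders occur across seeds


class TestMechanismA:
    def make_gamma_with_alphas(self, make_state, schema_kw):
        state = make_state(
            [
                (Species.GAMMA, [5, 5, 5], Color.RED),
                (Species.ALPHA, [6, 5, 5]),
                (Species.ALPHA, [5, 7, 5]),
            ]
        )
        return state, silent_schema(pA1=dict(ONE), **schema_kw)

    def test_incorporation_bonds_and_colors_beta(self, make_state):
        state, schema = self.make_gamma_with_alphas(make_state, dict(pA2=dict(ONE)))
        (ev,) = arbitrate_chemistry(state, schema)
        assert ev.mechanism == "A" and ev.bonds_formed
        assert state.n_particles == 2
        # nearest alpha (slot 1) became a red beta bonded at rest length
        assert state.species[1] == Species.BETA and state.color[1] == Color.RED
        assert state.bonded_to(1) == [0]
        assert np.linalg.norm(state.pos[1] - state.pos[0]) == pytest.approx(1.5)
        assert state.total_alpha_equivalent_mass() == 6.0  # 2 alpha -> 1 beta

    def test_ejection_leaves_beta_unbonded(self, make_state):
        state, schema = self.make_gamma_with_alphas(make_state, {})
        arbitrate_chemistry(state, schema)  # pA2 = 0: always ejected
        assert state.species[1] == Species.BETA and state.n_bonds[1] == 0
        assert np.allclose(state.pos[1], [6, 5, 5])

    def test_saturated_gamma_forces_ejection(self, make_state):
        state = make_state(
            [
                (Species.GAMMA, [5, 5, 5], Color.RED),
                (Species.BETA, [6.5, 5, 5], Color.RED),
                (Species.BETA, [3.5, 5, 5], Color.RED),
                (Species.BETA, [5, 6.5, 5], Color.RED),
                (Species.BETA, [5, 3.5, 5], Color.RED),
                (Species.ALPHA, [5, 5, 6]),
                (Species.ALPHA, [5, 5, 4]),
            ],
            bonds=[(0, 1), (0, 2), (0, 3), (0, 4)],
        )
        schema = silent_schema(pA1=dict(ONE), pA2=dict(ONE))
        (ev,) = arbitrate_chemistry(state, schema)
        assert ev.mechanism == "A" and not ev.bonds_formed
        assert state.n_bonds[0] == 4


class TestMechanismB:
    def gamma_with_bound_betas(self, make_state, extra=(), extra_bonds=()):
        parts = [
            (Species.GAMMA, [5, 5, 5], Color.BLUE),
            (Species.BETA, [6.5, 5, 5], Color.BLUE),
            (Species.BETA, [3.5, 5, 5], Color.BLUE),
        ] + list(extra)
        return make_state(parts, bonds=[(0, 1), (0, 2)] + list(extra_bonds))

    def test_split_conserves_mass_and_inherits_color(self, make_state):
        state = self.gamma_with_bound_betas(make_state)
        (ev,) = arbitrate_chemistry(state, silent_schema(pB=dict(ONE)))
        assert ev.mechanism == "B"
        assert state.total_alpha_equivalent_mass() == 8.0  # 4 + 2*2 -> 2*4
        daughters = state.alive_indices()
        assert len(daughters) == 2
        assert all(state.species[d] == Species.GAMMA for d in daughters)
        assert all(state.color[d] == Color.BLUE for d in daughters)
        d1, d2 = daughters
        assert state.bonded_to(int(d1)) == [int(d2)]

    def test_never_fires_below_two_bound_betas(self, make_state):
        state = make_state(
            [(Species.GAMMA, [5, 5, 5], Color.RED), (Species.BETA, [6.5, 5, 5], Color.RED)],
            bonds=[(0, 1)],
        )
        assert arbitrate_chemistry(state, silent_schema(pB=dict(ONE))) == []

    def test_surviving_neighbors_reattach_to_daughters(self, make_state):
        state = self.gamma_with_bound_betas(
            make_state,
            extra=[(Species.GAMMA, [5, 7, 5], Color.BLUE)],
            extra_bonds=[(0, 3)],
        )
        (ev,) = arbitrate_chemistry(state, silent_schema(pB=dict(ONE)))
        assert ev.initiator == 0
        # the surviving gamma neighbor is bonded to exactly one daughter
        survivors = state.bonded_to(3)
        assert len(survivors) == 1
        assert state.species[survivors[0]] == Species.GAMMA


class TestMechanismC:
    def test_partially_bonded_beta_bonds_candidate(self, make_state):
        state = make_state(
            [
                (Species.BETA, [5, 5, 5], Color.RED),
                (Species.BETA, [6, 5, 5], Color.RED),
                (Species.GAMMA, [5, 7, 5], Color.BLUE),
            ],
            bonds=[(0, 1)],
        )
        events = arbitrate_chemistry(state, silent_schema(pC=1.0))
        # both one-bonded betas are eligible; each bonds the free-site gamma
        assert {e.mechanism for e in events} == {"C"}
        assert sorted(state.bonded_to(0)) == [1, 2]
        assert 0 in state.bonded_to(2)

    def test_fully_bonded_beta_ineligible(self, make_state):
        state = make_state(
            [
                (Species.BETA, [5, 5, 5], Color.RED),
                (Species.BETA, [6, 5, 5], Color.RED),
                (Species.BETA, [4, 5, 5], Color.RED),
                (Species.GAMMA, [5, 7, 5], Color.BLUE),
            ],
            bonds=[(0, 1), (0, 2)],
        )
        events = arbitrate_chemistry(state, silent_schema(pC=1.0))
        assert all(e.initiator != 0 for e in events)


class TestMechanismD:
    def test_saturated_gamma_target_forces_insertion(self, make_state):
        # free beta next to a gamma with 4 bonds: pD2(4) = 0 -> insertion
        state = make_state(
            [
                (Species.GAMMA, [5, 5, 5], Color.RED),
                (Species.BETA, [6.5, 5, 5], Color.RED),
                (Species.BETA, [3.5, 5, 5], Color.RED),
                (Species.BETA, [5, 6.5, 5], Color.RED),
                (Species.BETA, [5, 3.5, 5], Color.RED),
                (Species.BETA, [6.5, 6, 5], Color.BLUE),  # free initiator
            ],
            bonds=[(0, 1), (0, 2), (0, 3), (0, 4)],
        )
        bonds_before = len(state.bond_pairs())
        (ev,) = arbitrate_chemistry(state, silent_schema(pD1=1.0))
        assert ev.mechanism == "D" and ev.bonds_severed
        # insertion: net +1 bond, initiator fully bonded between RA and X
        assert len(state.bond_pairs()) == bonds_before + 1
        assert state.n_bonds[5] == 2 and 0 in state.bonded_to(5)
        state.check_invariants()

    def test_lone_pair_addition(self, make_state):
        # target beta with no bonds: pD2(0) = 1 -> always addition
        state = make_state(
            [
                (Species.BETA, [5, 5, 5], Color.RED),
                (Species.BETA, [6, 5, 5], Color.BLUE),
            ]
        )
        (ev,) = arbitrate_chemistry(state, silent_schema(pD1=1.0))
        assert ev.mechanism == "D" and not ev.bonds_severed
        assert state.bonded_to(0) == [1]


class TestDecay:
    def test_beta_decay_products_and_freed_sites(self, make_state):
        state = make_state(
            [(Species.GAMMA, [5, 5, 5], Color.RED), (Species.BETA, [6.5, 5, 5], Color.RED)],
            bonds=[(0, 1)],
        )
        (ev,) = arbitrate_chemistry(state, silent_schema(pE={0: 0.0, 1: 1.0, 2: 0.0}))
        assert ev.mechanism == "E" and ev.consumed == [1]
        assert state.n_bonds[0] == 0  # partner freed
        idx = state.alive_indices()
        assert sum(state.species[idx] == Species.ALPHA) == 2
        assert state.total_alpha_equivalent_mass() == 6.0

    def test_gamma_decay_yields_four_alphas(self, make_state):
        state = make_state([(Species.GAMMA, [5, 5, 5], Color.RED)])
        (ev,) = arbitrate_chemistry(state, silent_schema(pF=dict(ONE)))
        assert ev.mechanism == "F"
        idx = state.alive_indices()
        assert len(idx) == 4 and all(state.species[idx] == Species.ALPHA)
        assert state.total_alpha_equivalent_mass() == 4.0


class TestWholeSystemInvariants:
    @pytest.mark.parametrize("preset", ["I", "II", "III"])
    def test_mass_capacity_symmetry_over_many_steps(self, preset):
        cfg = ExperimentConfig(schema=preset, n_alpha=150, container_side=15.0, seed=4)
        rng = np.random.default_rng(4)
        state = initialize(cfg, rng)
        schema = cfg.resolved_schema()
        mass0 = state.total_alpha_equivalent_mass()
        for _ in range(500):
            arbitrate_chemistry(state, schema)
            physics.update_neighbor_lists(state)
            physics.update_random_walk(state, schema)
            physics.integrate_step(state, physics.internal_forces(state, schema))
        assert state.total_alpha_equivalent_mass() == mass0
        state.check_invariants()  # bond symmetry, capacity, color, containment

    def test_event_stream_reproducible_for_fixed_seed(self):
        def stream(seed):
            cfg = ExperimentConfig(schema="I", n_alpha=100, container_side=12.0)
            state = initialize(cfg, np.random.default_rng(seed))
            schema = cfg.resolved_schema()
            out = []
            for _ in range(200):
                out.extend(
                    (e.mechanism, e.initiator, tuple(e.consumed))
                    for e in arbitrate_chemistry(state, schema)
                )
                physics.update_neighbor_lists(state)
                physics.update_random_walk(state, schema)
                physics.integrate_step(state, physics.internal_forces(state, schema))
            return out, state.pos[state.alive].copy()

        ev1, pos1 = stream(9)
        ev2, pos2 = stream(9)
        assert ev1 == ev2 and np.array_equal(pos1, pos2)
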