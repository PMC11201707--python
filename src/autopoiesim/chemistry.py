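"""Stochastic reaction mechanisms, applied once per timestep before physics.

Six mechanisms transform particles and bonds:

  A  beta synthesis: a gamma catalyzes 2 alpha -> 1 beta; the beta is either
     incorporated (bonded to the gamma, probability pA2) or ejected.
  B  gamma synthesis: a gamma consumes 2 of its bound betas and splits into
     two bonded daughter gammas.
  C  addition: a beta with one free site bonds to a nearby particle with a
     free site (repair / fusion pathway).
  D  free-beta bonding: an unbonded beta is captured by a neighbor, either by
     addition (probability pD2, by the target's bond count and species) or by
     inserting itself into one of the target's existing bonds.
  E  beta decay -> 2 alpha.
  F  gamma decay -> 4 alpha.

Arbitration: particles are visited in a fresh uniform random order; each
particle initiates at most one mechanism per timestep (growth and bonding
mechanisms are rolled before decay; the first successful roll wins).
Particles consumed earlier in the same timestep are tombstoned and silently
ineligible as initiators or reagents, so no particle takes part in two
consuming reactions in one step.  All mechanisms conserve alpha-equivalent
mass (alpha 1, beta 2, gamma 4).

Color provenance: a beta inherits the color of the catalyzing gamma; daughter
gammas inherit the color of the gamma they split from; alphas are uncolored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import RC, Color, SchemaParams, Species
from .state import SimulationState


@dataclass
class ReactionEvent:
    mechanism: str  # one of A-F
    initiator: int
    timestep: int
    consumed: list[int] = field(default_factory=list)
    created: list[int] = field(default_factory=list)
    bonds_formed: list[tuple[int, int]] = field(default_factory=list)
    bonds_severed: list[tuple[int, int]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "t": self.timestep,
            "mech": self.mechanism,
            "initiator": self.initiator,
            "consumed": self.consumed,
            "created": self.created,
            "bonds_formed": [list(b) for b in self.bonds_formed],
            "bonds_severed": [list(b) for b in self.bonds_severed],
        }


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    n = np.linalg.norm(v)
    return v / n if n > 1e-12 else np.array([1.0, 0.0, 0.0])


def _nearest_sorted(state: SimulationState, origin: int, candidates: list[int]) -> list[int]:
    """Candidates sorted by distance to ``origin``; ties broken by lower id."""
    d = np.linalg.norm(state.pos[candidates] - state.pos[origin], axis=1)
    order = np.lexsort((candidates, d))
    return [candidates[k] for k in order]


def _eligible_unbound(
    state: SimulationState, i: int, tomb: set[int], species_ok: tuple[Species, ...]
) -> list[int]:
    bonded = set(state.bonded_to(i))
    out = []
    for j in state.unbound_neighbors(i):
        j = int(j)
        if j in tomb or not state.alive[j] or j in bonded:
            continue  # bonded check: an earlier event this step may have
            # already joined i and j; the list predates this step
        if Species(state.species[j]) in species_ok:
            out.append(j)
    return out


def mech_A_beta_synthesis(
    g: int, state: SimulationState, schema: SchemaParams, rng: np.random.Generator, tomb: set[int]
) -> ReactionEvent | None:
    alphas = _eligible_unbound(state, g, tomb, (Species.ALPHA,))
    if len(alphas) < 2:
        return None
    if rng.random() >= schema.pA1[int(state.n_bonds[g])]:
        return None
    a_keep, a_destroy = _nearest_sorted(state, g, alphas)[:2]
    ev = ReactionEvent("A", g, state.step_index, consumed=[a_keep, a_destroy], created=[a_keep])
    tomb.update((a_keep, a_destroy))
    state.kill_particle(a_destroy)
    # the nearer alpha is transformed in place into a beta colored like the
    # catalyst; it keeps its kinematic state
    color = Color(int(state.color[g]))
    state.species[a_keep] = int(Species.BETA)
    state.color[a_keep] = int(color)
    incorporate = rng.random() < schema.pA2[int(state.n_bonds[g])] and state.free_sites(g) > 0
    if incorporate:
        s = state.pos[a_keep] - state.pos[g]
        n = np.linalg.norm(s)
        u = s / n if n > 1e-9 else _random_unit(rng)
        rest = RC[int(Species.GAMMA)] + RC[int(Species.BETA)]
        state.pos[a_keep] = np.clip(state.pos[g] + rest * u, 0.0, state.container_side)
        state.add_bond(g, a_keep)
        ev.bonds_formed.append((g, a_keep))
    return ev


def mech_B_gamma_synthesis(
    g: int, state: SimulationState, schema: SchemaParams, rng: np.random.Generator, tomb: set[int]
) -> ReactionEvent | None:
    bound_betas = [
        j for j in state.bonded_to(g)
        if state.species[j] == Species.BETA and j not in tomb
    ]
    if len(bound_betas) < 2:
        return None
    if rng.random() >= schema.pB[int(state.n_bonds[g])]:
        return None
    b1, b2 = _nearest_sorted(state, g, bound_betas)[:2]
    ev = ReactionEvent("B", g, state.step_index, consumed=[g, b1, b2])
    tomb.update((g, b1, b2))
    for b in (b1, b2):
        ev.bonds_severed.append((g, b))
        state.kill_particle(b)
    survivors = state.bonded_to(g)
    ev.bonds_severed.extend((g, j) for j in survivors)
    parent_pos = state.pos[g].copy()
    parent_vel = state.vel[g].copy()
    color = Color(int(state.color[g]))
    state.kill_particle(g)
    axis = _random_unit(rng)
    offset = 0.5 * RC[int(Species.GAMMA)] * axis
    d1 = state.add_particle(Species.GAMMA, parent_pos + offset, color=color, velocity=parent_vel)
    d2 = state.add_particle(Species.GAMMA, parent_pos - offset, color=color, velocity=parent_vel)
    ev.created = [d1, d2]
    state.add_bond(d1, d2)
    ev.bonds_formed.append((d1, d2))
    # surviving neighbors of the parent re-attach to the nearer daughter
    for j in _nearest_sorted(state, d1, survivors) if survivors else []:
        prefer = d1 if (
            np.linalg.norm(state.pos[j] - state.pos[d1])
            <= np.linalg.norm(state.pos[j] - state.pos[d2])
        ) else d2
        other = d2 if prefer == d1 else d1
        for target in (prefer, other):
            if state.free_sites(target) > 0 and state.free_sites(j) > 0:
                state.add_bond(target, j)
                ev.bonds_formed.append((target, j))
                break
    return ev


def mech_C_addition(
    b: int, state: SimulationState, schema: SchemaParams, rng: np.random.Generator, tomb: set[int]
) -> ReactionEvent | None:
    if schema.pC <= 0.0 or state.n_bonds[b] != 1:
        return None
    cands = [
        j for j in _eligible_unbound(state, b, tomb, (Species.BETA, Species.GAMMA))
        if state.free_sites(j) > 0
    ]
    if not cands:
        return None
    if rng.random() >= schema.pC:
        return None
    j = cands[rng.integers(len(cands))]
    state.add_bond(b, j)
    return ReactionEvent("C", b, state.step_index, bonds_formed=[(b, j)])


def mech_D_free_bonding(
    b: int, state: SimulationState, schema: SchemaParams, rng: np.random.Generator, tomb: set[int]
) -> ReactionEvent | None:
    if schema.pD1 <= 0.0 or state.n_bonds[b] != 0:
        return None
    cands = _eligible_unbound(state, b, tomb, (Species.BETA, Species.GAMMA))
    if not cands:
        return None
    if rng.random() >= schema.pD1:
        return None
    ra = cands[rng.integers(len(cands))]
    table = schema.pD2_beta if state.species[ra] == Species.BETA else schema.pD2_gamma
    addition = rng.random() < table[int(state.n_bonds[ra])]
    ev = ReactionEvent("D", b, state.step_index)
    if not addition:
        xs = [j for j in state.bonded_to(ra) if j not in tomb]
        if xs:  # insert the beta into the bond R_A - X nearest to it
            x = _nearest_sorted(state, b, xs)[0]
            state.remove_bond(ra, x)
            state.add_bond(ra, b)
            state.add_bond(b, x)
            ev.bonds_severed.append((ra, x))
            ev.bonds_formed.extend([(ra, b), (b, x)])
            return ev
        addition = True  # no bond to insert into: fall back to addition
    if addition:
        if state.free_sites(ra) <= 0:
            return None
        state.add_bond(ra, b)
        ev.bonds_formed.append((ra, b))
        return ev
    return None


def _decay(
    p: int,
    state: SimulationState,
    rng: np.random.Generator,
    tomb: set[int],
    n_alpha: int,
    mech: str,
) -> ReactionEvent:
    ev = ReactionEvent(mech, p, state.step_index, consumed=[p])
    ev.bonds_severed.extend((p, j) for j in state.bonded_to(p))
    pos = state.pos[p].copy()
    vel = state.vel[p].copy()
    tomb.add(p)
    state.kill_particle(p)
    for _ in range(n_alpha):
        # small jitter so decay products do not overlap exactly
        child = state.add_particle(
            Species.ALPHA, pos + 0.1 * _random_unit(rng), velocity=vel
        )
        ev.created.append(child)
    return ev


def mech_E_beta_decay(
    b: int, state: SimulationState, schema: SchemaParams, rng: np.random.Generator, tomb: set[int]
) -> ReactionEvent | None:
    if rng.random() >= schema.pE[int(state.n_bonds[b])]:
        return None
    return _decay(b, state, rng, tomb, 2, "E")


def mech_F_gamma_decay(
    g: int, state: SimulationState, schema: SchemaParams, rng: np.random.Generator, tomb: set[int]
) -> ReactionEvent | None:
    if rng.random() >= schema.pF[int(state.n_bonds[g])]:
        return None
    return _decay(g, state, rng, tomb, 4, "F")


_GAMMA_MECHS = (mech_A_beta_synthesis, mech_B_gamma_synthesis, mech_F_gamma_decay)
_BETA_MECHS = (mech_C_addition, mech_D_free_bonding, mech_E_beta_decay)


def arbitrate_chemistry(
    state: SimulationState, schema: SchemaParams, rng: np.random.Generator | None = None
) -> list[ReactionEvent]:
    """Run one timestep of chemistry; returns the events applied.

    Requires current neighbor lists.  Alphas never initiate, so only betas
    and gammas are visited (in a fresh uniform random order).
    """
    if rng is None:
        rng = state.rng
    idx = state.alive_indices()
    initiators = idx[state.species[idx] != Species.ALPHA]
    order = rng.permutation(initiators)
    tomb: set[int] = set()
    events: list[ReactionEvent] = []
    for p in order:
        p = int(p)
        if p in tomb or not state.alive[p]:
            continue
        mechs = _GAMMA_MECHS if state.species[p] == Species.GAMMA else _BETA_MECHS
        for mech in mechs:
            ev = mech(p, state, schema, rng, tomb)
            if ev is not None:
                events.append(ev)
                break
    state.flush_free_slots()
    return events
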