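"""Per-timestep force computation and integration.

Forces on a particle (net force, with v the particle velocity):

    F_net = F_random + F_spring + F_torsion + F_collision - m * D * v

* random walk: an AR(1) Gaussian process approximating Brownian kicks from
  the implicit solvent, F_R(t) = c * F_R(t-1) + (1 - c) * w(t) with
  w ~ N(0, w * I3);
* linear springs on bonds, rest length = sum of collision radii;
* a three-body torsion spring on every bond pair at a center particle with
  >= 2 bonds, driving the inter-bond angle toward the coordination-dependent
  target (180 / 120 / 109.47 degrees).  The torque is K_T times the angle
  error in degrees (the angle tables and spring constant are given on the
  degree scale), applied as a force of magnitude torque / lever-arm length
  perpendicular to each bond in the plane of the triple;
* soft-sphere repulsion when collision spheres overlap.

Spring, torsion and collision forces are internal (they sum to zero over the
system); the random walk and drag exchange momentum with the ether.
Integration is semi-implicit Euler at dt = 0.02 s with reflective container
walls (sealed box).
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy.spatial import cKDTree

from .params import DRAG, MASS, MAX_INTERACTION_RANGE, RC, RI, SchemaParams, target_angle
from .state import SimulationState

_DEG = np.pi / 180.0


class IntegrationError(RuntimeError):
    """Raised when the state becomes non-finite after an update."""


def update_neighbor_lists(state: SimulationState) -> None:
    """Rebuild contact pairs (center distance <= rI(i) + rI(j)) and sever any
    bond whose endpoints have left each other's interaction volumes."""
    idx = state.alive_indices()
    if idx.size >= 2:
        tree = cKDTree(state.pos[idx])
        raw = tree.query_pairs(MAX_INTERACTION_RANGE, output_type="ndarray")
        pairs = idx[raw]
        d = np.linalg.norm(state.pos[pairs[:, 0]] - state.pos[pairs[:, 1]], axis=1)
        cutoff = RI[state.species[pairs[:, 0]]] + RI[state.species[pairs[:, 1]]]
        pairs = pairs[d <= cutoff]
    else:
        pairs = np.empty((0, 2), dtype=np.int64)

    for i, j in state.bond_pairs():
        d = np.linalg.norm(state.pos[j] - state.pos[i])
        if d > RI[state.species[i]] + RI[state.species[j]]:
            state.remove_bond(int(i), int(j))
    state.set_contact_pairs(pairs)


def brute_force_contact_pairs(state: SimulationState) -> np.ndarray:
    """O(N^2) all-pairs interaction-range check (test oracle)."""
    idx = state.alive_indices()
    out = []
    for a in range(idx.size):
        for b in range(a + 1, idx.size):
            i, j = int(idx[a]), int(idx[b])
            d = np.linalg.norm(state.pos[j] - state.pos[i])
            if d <= RI[state.species[i]] + RI[state.species[j]]:
                out.append((i, j))
    return np.array(out, dtype=np.int64).reshape(-1, 2)


def random_walk_force(prev: np.ndarray, rng: np.random.Generator, c: float, w: float) -> np.ndarray:
    """One AR(1) update of the Brownian kick: c * prev + (1 - c) * g, with g a
    zero-mean Gaussian of per-axis standard deviation w.

    w acts as the rate constant setting the average particle speed (a free
    alpha particle reaches a mean speed of ~w/6 length units/s at c = 0.5);
    the stationary per-axis variance of the process is w^2 (1-c)/(1+c).
    """
    kick = rng.normal(0.0, w, size=np.shape(prev))
    return c * np.asarray(prev) + (1.0 - c) * kick


def update_random_walk(state: SimulationState, schema: SchemaParams) -> None:
    idx = state.alive_indices()
    state.rw_force[idx] = random_walk_force(state.rw_force[idx], state.rng, schema.c, schema.w)


def linear_spring_forces(state: SimulationState, schema: SchemaParams) -> np.ndarray:
    forces = np.zeros_like(state.pos)
    pairs = state.bond_pairs()
    if pairs.size == 0:
        return forces
    a, b = pairs[:, 0], pairs[:, 1]
    s = state.pos[b] - state.pos[a]
    d = np.linalg.norm(s, axis=1)
    rest = RC[state.species[a]] + RC[state.species[b]]
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(d[:, None] > 0, s / np.maximum(d, 1e-300)[:, None], 0.0)
    f = schema.K_L * (d - rest)[:, None] * unit  # force on a, toward b if stretched
    np.add.at(forces, a, f)
    np.add.at(forces, b, -f)
    return forces


def _torsion_triples(state: SimulationState) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All (A, B, C) with A, C distinct bound neighbors of center B (>= 2 bonds)."""
    idx = state.alive_indices()
    A, B, C = [], [], []
    for nb in (2, 3, 4):
        centers = idx[state.n_bonds[idx] == nb]
        if centers.size == 0:
            continue
        for i, j in combinations(range(nb), 2):
            A.append(state.bonds[centers, i])
            B.append(centers)
            C.append(state.bonds[centers, j])
    if not B:
        z = np.empty(0, dtype=np.int64)
        return z, z, z
    return np.concatenate(A), np.concatenate(B), np.concatenate(C)


def torsion_forces(state: SimulationState, schema: SchemaParams) -> np.ndarray:
    forces = np.zeros_like(state.pos)
    A, B, C = _torsion_triples(state)
    if B.size == 0:
        return forces
    sBA = state.pos[A] - state.pos[B]
    sBC = state.pos[C] - state.pos[B]
    dA = np.linalg.norm(sBA, axis=1)
    dC = np.linalg.norm(sBC, axis=1)
    ok = (dA > 1e-12) & (dC > 1e-12)
    u = np.where(ok[:, None], sBA / np.maximum(dA, 1e-300)[:, None], 0.0)
    v = np.where(ok[:, None], sBC / np.maximum(dC, 1e-300)[:, None], 0.0)
    cos = np.clip(np.sum(u * v, axis=1), -1.0, 1.0)
    # angle error in degrees (the target-angle tables are in degrees)
    theta = np.arccos(cos) / _DEG
    targets = np.array([schema.target_angles[int(n)] for n in state.n_bonds[B]])
    tau = schema.K_T * (theta - targets)
    # in-plane unit directions perpendicular to each bond, pointing toward the
    # other bond (moving A along pA closes the angle)
    pA = v - cos[:, None] * u
    pC = u - cos[:, None] * v
    nA = np.linalg.norm(pA, axis=1)
    nC = np.linalg.norm(pC, axis=1)
    ok &= (nA > 1e-9) & (nC > 1e-9)  # collinear triple: undefined plane, no force
    pA = np.where(ok[:, None], pA / np.maximum(nA, 1e-300)[:, None], 0.0)
    pC = np.where(ok[:, None], pC / np.maximum(nC, 1e-300)[:, None], 0.0)
    tau = np.where(ok, tau, 0.0)
    fA = (tau / np.maximum(dA, 1e-300))[:, None] * pA  # lever-arm normalization
    fC = (tau / np.maximum(dC, 1e-300))[:, None] * pC
    np.add.at(forces, A, fA)
    np.add.at(forces, C, fC)
    np.add.at(forces, B, -(fA + fC))  # recoil closes the triple
    return forces


def collision_forces(state: SimulationState, schema: SchemaParams) -> np.ndarray:
    """Linear soft-sphere repulsion for overlapping collision spheres."""
    forces = np.zeros_like(state.pos)
    pairs = state.contact_pairs
    if pairs.size == 0:
        return forces
    a, b = pairs[:, 0], pairs[:, 1]
    s = state.pos[b] - state.pos[a]
    d = np.linalg.norm(s, axis=1)
    rsum = RC[state.species[a]] + RC[state.species[b]]
    m = d < rsum
    if not m.any():
        return forces
    a, b, s, d, rsum = a[m], b[m], s[m], d[m], rsum[m]
    unit = np.where(d[:, None] > 1e-12, s / np.maximum(d, 1e-300)[:, None], 0.0)
    f = schema.K_coll * (rsum - d)[:, None] * unit  # push a away from b
    np.add.at(forces, a, -f)
    np.add.at(forces, b, f)
    return forces


def internal_forces(state: SimulationState, schema: SchemaParams) -> np.ndarray:
    return (
        linear_spring_forces(state, schema)
        + torsion_forces(state, schema)
        + collision_forces(state, schema)
    )


def integrate_step(state: SimulationState, forces: np.ndarray) -> None:
    """Semi-implicit Euler update with drag and reflective walls.

    ``forces`` excludes drag and the random-walk force; both are applied here
    (drag from current velocity, random walk from the stored AR(1) state).
    """
    idx = state.alive_indices()
    if idx.size == 0:
        state.step_index += 1
        return
    m = MASS[state.species[idx]][:, None]
    drag = DRAG[state.species[idx]][:, None]
    accel = (forces[idx] + state.rw_force[idx]) / m - drag * state.vel[idx]
    v = state.vel[idx] + accel * state.dt
    x = state.pos[idx] + v * state.dt
    # reflect at the container walls (sealed box)
    side = state.container_side
    for _ in range(4):
        low = x < 0.0
        high = x > side
        if not (low.any() or high.any()):
            break
        x = np.where(low, -x, x)
        x = np.where(high, 2.0 * side - x, x)
        v = np.where(low | high, -v, v)
    x = np.clip(x, 0.0, side)
    if not (np.isfinite(x).all() and np.isfinite(v).all()):
        raise IntegrationError(f"non-finite state at step {state.step_index}")
    state.pos[idx] = x
    state.vel[idx] = v
    state.step_index += 1
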