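"""Individual-instance identification on the bond graph.

An instance is a maximal set of particles mutually connected by bonds and
unbound from everything else (connected component of the bond graph).  Only
components containing at least one gamma are *viable* instances: without a
catalytic gamma a fragment cannot keep producing its own components.
Alphas never bond, so they are environment and are excluded up front.

Each viable instance is classified by majority color of its gammas (red,
blue, or excluded on a tie); betas do not contribute to the majority.
Instance identity is per-frame only: components are not tracked over time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .params import MASS, Color, Species
from .state import SimulationState


@dataclass(frozen=True)
class InstanceRecord:
    members: frozenset[int]
    size: int  # particle count
    mass: float  # mass units
    n_gamma_red: int
    n_gamma_blue: int
    viable: bool
    majority: str  # "red" | "blue" | "excluded"


def find_components(n_nodes: int, edges: np.ndarray) -> list[set[int]]:
    """Connected components of an undirected graph over nodes 0..n_nodes-1.

    ``edges`` is an (m, 2) array; every edge must be symmetric in intent
    (each undirected bond listed once).  Unconnected nodes come back as
    singletons.
    """
    if n_nodes == 0:
        return []
    edges = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
    if edges.size:
        data = np.ones(len(edges), dtype=np.int8)
        adj = coo_matrix((data, (edges[:, 0], edges[:, 1])), shape=(n_nodes, n_nodes))
    else:
        adj = coo_matrix((n_nodes, n_nodes), dtype=np.int8)
    n_comp, labels = connected_components(adj, directed=False)
    comps: list[set[int]] = [set() for _ in range(n_comp)]
    for node, lab in enumerate(labels):
        comps[lab].add(int(node))
    return comps


def state_components(state: SimulationState) -> list[set[int]]:
    """Bond-graph components of the live beta/gamma particles (slot ids).

    Raises on asymmetric bond tables (consistency error).
    """
    idx = state.alive_indices()
    idx = idx[state.species[idx] != Species.ALPHA]
    if idx.size == 0:
        return []
    for i in idx:
        for j in state.bonded_to(int(i)):
            if int(i) not in state.bonded_to(j):
                raise RuntimeError(f"asymmetric bond {i}-{j}")
    remap = {int(s): k for k, s in enumerate(idx)}
    pairs = state.bond_pairs()
    edges = np.array(
        [(remap[int(a)], remap[int(b)]) for a, b in pairs], dtype=np.int64
    ).reshape(-1, 2)
    comps = find_components(idx.size, edges)
    return [{int(idx[k]) for k in comp} for comp in comps]


def viable_instances(
    components: list[set[int]], state: SimulationState
) -> list[InstanceRecord]:
    """Filter components by the gamma-viability condition and classify them."""
    out = []
    for comp in components:
        members = sorted(comp)
        sp = state.species[members]
        col = state.color[members]
        n_red = int(((sp == Species.GAMMA) & (col == Color.RED)).sum())
        n_blue = int(((sp == Species.GAMMA) & (col == Color.BLUE)).sum())
        if n_red + n_blue == 0:
            continue  # no gamma: not a viable instance
        majority = "red" if n_red > n_blue else "blue" if n_blue > n_red else "excluded"
        out.append(
            InstanceRecord(
                members=frozenset(comp),
                size=len(members),
                mass=float(MASS[sp].sum()),
                n_gamma_red=n_red,
                n_gamma_blue=n_blue,
                viable=True,
                majority=majority,
            )
        )
    return out


def instances_of(state: SimulationState) -> list[InstanceRecord]:
    return viable_instances(state_components(state), state)
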