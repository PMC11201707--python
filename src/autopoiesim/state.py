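"""Mutable simulation state: particle arrays, bond bookkeeping, neighbor lists.

Particles live in flat numpy arrays indexed by slot.  Slots of destroyed
particles are recycled through a free list, but never within the timestep in
which they were freed, so a slot index is a stable identity for the lifetime
of a particle plus the step in which it dies.  Bonds are stored as a dense
(capacity, 4) adjacency table (-1 = empty) because no species forms more
than four bonds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import DT, MASS, MAX_BONDS, Color, Species


@dataclass
class SimulationState:
    container_side: float
    rng: np.random.Generator
    dt: float = DT
    step_index: int = 0
    capacity: int = field(default=64)

    def __post_init__(self) -> None:
        n = self.capacity
        self.pos = np.zeros((n, 3))
        self.vel = np.zeros((n, 3))
        self.rw_force = np.zeros((n, 3))
        self.species = np.zeros(n, dtype=np.int8)
        self.color = np.zeros(n, dtype=np.int8)
        self.alive = np.zeros(n, dtype=bool)
        self.bonds = np.full((n, 4), -1, dtype=np.int32)
        self.n_bonds = np.zeros(n, dtype=np.int8)
        self._free: list[int] = list(range(n - 1, -1, -1))
        self._pending_free: list[int] = []
        # neighbor-list state, populated by physics.update_neighbor_lists
        self.contact_pairs = np.empty((0, 2), dtype=np.int64)
        self._nbr_indptr: np.ndarray | None = None
        self._nbr_indices: np.ndarray | None = None

    # ------------------------------------------------------------------ slots
    def _grow(self) -> None:
        old = self.capacity
        new = max(2 * old, 64)
        for name in ("pos", "vel", "rw_force"):
            arr = getattr(self, name)
            grown = np.zeros((new, 3))
            grown[:old] = arr
            setattr(self, name, grown)
        for name, fill in (("species", 0), ("color", 0), ("n_bonds", 0)):
            arr = getattr(self, name)
            grown = np.full(new, fill, dtype=arr.dtype)
            grown[:old] = arr
            setattr(self, name, grown)
        grown_alive = np.zeros(new, dtype=bool)
        grown_alive[:old] = self.alive
        self.alive = grown_alive
        grown_bonds = np.full((new, 4), -1, dtype=np.int32)
        grown_bonds[:old] = self.bonds
        self.bonds = grown_bonds
        self._free.extend(range(new - 1, old - 1, -1))
        self.capacity = new

    def add_particle(
        self,
        species: Species,
        position: np.ndarray,
        *,
        color: Color = Color.NONE,
        velocity: np.ndarray | None = None,
        rw_force: np.ndarray | None = None,
    ) -> int:
        if species != Species.ALPHA and color == Color.NONE:
            raise ValueError("beta/gamma particles must carry a color")
        if not self._free:
            self._grow()
        i = self._free.pop()
        self.pos[i] = np.clip(position, 0.0, self.container_side)
        self.vel[i] = 0.0 if velocity is None else velocity
        self.rw_force[i] = 0.0 if rw_force is None else rw_force
        self.species[i] = int(species)
        self.color[i] = int(color)
        self.alive[i] = True
        self.bonds[i] = -1
        self.n_bonds[i] = 0
        return i

    def kill_particle(self, i: int) -> None:
        """Remove particle ``i``, severing all its bonds.

        The slot is quarantined until :meth:`flush_free_slots` so that ids
        consumed in the current timestep are never reused within it.
        """
        for j in [int(b) for b in self.bonds[i] if b >= 0]:
            self.remove_bond(i, j)
        self.alive[i] = False
        self._pending_free.append(i)

    def flush_free_slots(self) -> None:
        self._free.extend(self._pending_free)
        self._pending_free.clear()

    # ------------------------------------------------------------------ bonds
    def add_bond(self, i: int, j: int) -> None:
        if i == j:
            raise ValueError("self-bond")
        if not (self.alive[i] and self.alive[j]):
            raise ValueError("bond endpoint not alive")
        for k in (i, j):
            if self.n_bonds[k] >= MAX_BONDS[self.species[k]]:
                raise ValueError(f"particle {k} has no free bond site")
        if j in self.bonds[i, : self.n_bonds[i]]:
            raise ValueError("bond already exists")
        for a, b in ((i, j), (j, i)):
            self.bonds[a, self.n_bonds[a]] = b
            self.n_bonds[a] += 1

    def remove_bond(self, i: int, j: int) -> None:
        for a, b in ((i, j), (j, i)):
            row = self.bonds[a, : self.n_bonds[a]]
            hits = np.nonzero(row == b)[0]
            if hits.size != 1:
                raise ValueError(f"bond {a}-{b} not present exactly once")
            k = hits[0]
            row[k] = row[self.n_bonds[a] - 1]
            self.bonds[a, self.n_bonds[a] - 1] = -1
            self.n_bonds[a] -= 1

    def bonded_to(self, i: int) -> list[int]:
        return [int(b) for b in self.bonds[i, : self.n_bonds[i]]]

    def free_sites(self, i: int) -> int:
        return int(MAX_BONDS[self.species[i]] - self.n_bonds[i])

    def bond_pairs(self) -> np.ndarray:
        """(n_bonds, 2) array of bonded slot pairs, each bond once (i < j)."""
        idx = np.nonzero(self.alive)[0]
        rows = []
        for c in range(4):
            col = self.bonds[idx, c]
            m = col >= 0
            rows.append(np.column_stack([idx[m], col[m]]))
        pairs = np.concatenate(rows) if rows else np.empty((0, 2), dtype=np.int64)
        pairs = pairs[pairs[:, 0] < pairs[:, 1]]
        return pairs.astype(np.int64)

    # ------------------------------------------------------- unbound neighbors
    def set_contact_pairs(self, pairs: np.ndarray) -> None:
        """Install the in-interaction-range pair list and build per-particle
        unbound-neighbor adjacency (CSR over slots)."""
        self.contact_pairs = pairs
        if pairs.size == 0:
            self._nbr_indptr = np.zeros(self.capacity + 1, dtype=np.int64)
            self._nbr_indices = np.empty(0, dtype=np.int64)
            return
        bonded = {(int(a), int(b)) for a, b in self.bond_pairs()}
        if bonded:
            keep = np.array(
                [(min(a, b), max(a, b)) not in bonded for a, b in pairs], dtype=bool
            )
            unbound = pairs[keep]
        else:
            unbound = pairs
        src = np.concatenate([unbound[:, 0], unbound[:, 1]])
        dst = np.concatenate([unbound[:, 1], unbound[:, 0]])
        order = np.argsort(src, kind="stable")
        src, dst = src[order], dst[order]
        indptr = np.zeros(self.capacity + 1, dtype=np.int64)
        np.add.at(indptr, src + 1, 1)
        np.cumsum(indptr, out=indptr)
        self._nbr_indptr = indptr
        self._nbr_indices = dst

    def unbound_neighbors(self, i: int) -> np.ndarray:
        if self._nbr_indptr is None:
            raise RuntimeError("neighbor lists not built; call update_neighbor_lists")
        return self._nbr_indices[self._nbr_indptr[i] : self._nbr_indptr[i + 1]]

    # ------------------------------------------------------------------ misc
    def alive_indices(self) -> np.ndarray:
        return np.nonzero(self.alive)[0]

    @property
    def n_particles(self) -> int:
        return int(self.alive.sum())

    def total_alpha_equivalent_mass(self) -> float:
        """Total mass in alpha units (alpha 1, beta 2, gamma 4); a conserved
        quantity of the closed container."""
        return float(MASS[self.species[self.alive]].sum())

    def check_invariants(self) -> None:
        """Raise if bond symmetry, capacity, color or containment is violated."""
        idx = self.alive_indices()
        for i in idx:
            nb = self.bonded_to(int(i))
            if len(nb) != len(set(nb)):
                raise AssertionError(f"duplicate bond on {i}")
            if self.n_bonds[i] > MAX_BONDS[self.species[i]]:
                raise AssertionError(f"capacity exceeded on {i}")
            for j in nb:
                if not self.alive[j] or int(i) not in self.bonded_to(j):
                    raise AssertionError(f"asymmetric bond {i}-{j}")
            if self.species[i] == Species.ALPHA and (nb or self.color[i] != 0):
                raise AssertionError(f"alpha {i} bonded or colored")
            if self.species[i] != Species.ALPHA and self.color[i] == 0:
                raise AssertionError(f"uncolored beta/gamma {i}")
        p = self.pos[idx]
        if p.size and (p.min() < -1e-9 or p.max() > self.container_side + 1e-9):
            raise AssertionError("particle outside container")
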