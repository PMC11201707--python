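"""Domain constants and parameter tables for the particle chemistry model.

The model has three particle species: alpha ("food" particles native to the
environment), beta (chain-forming particles with up to 2 bonds) and gamma
(catalytic hub particles with up to 4 bonds).  All physical constants and
per-timestep reaction probabilities live here; every other module consumes
them through :class:`SpeciesParams` / :class:`SchemaParams` or the pure
lookup helpers :func:`target_angle` and :func:`reaction_probability`.

Probabilities are defined *per timestep* (dt = 1/50 s) and are never
rescaled.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

DT = 0.02  # s, 50 timesteps per second
STEPS_PER_SECOND = 50


class Species(enum.IntEnum):
    ALPHA = 0
    BETA = 1
    GAMMA = 2


class Color(enum.IntEnum):
    """Provenance marker; +1 = red, -1 = blue, 0 = uncolored (alpha only).

    Purely for record keeping: color never influences the dynamics.
    """

    NONE = 0
    RED = 1
    BLUE = -1


@dataclass(frozen=True)
class SpeciesParams:
    species: Species
    collision_radius: float  # rC, length units
    interaction_radius: float  # rI, length units
    mass: float  # mass units
    drag_coeff: float  # D, 1/s
    max_bonds: int

    def __post_init__(self) -> None:
        if not (0 < self.collision_radius < self.interaction_radius):
            raise ValueError("require 0 < rC < rI")
        if self.mass <= 0 or self.drag_coeff <= 0 or self.max_bonds < 0:
            raise ValueError("physical constants must be positive")


#: Physical properties per species (alpha, beta, gamma).
SPECIES_TABLE: dict[Species, SpeciesParams] = {
    Species.ALPHA: SpeciesParams(Species.ALPHA, 0.25, 1.0, 1.0, 1.0, 0),
    Species.BETA: SpeciesParams(Species.BETA, 0.5, 2.0, 2.0, 2.0, 2),
    Species.GAMMA: SpeciesParams(Species.GAMMA, 1.0, 3.0, 4.0, 4.0, 4),
}

# Flat per-species arrays indexed by Species value; hot loops use these.
RC = np.array([SPECIES_TABLE[s].collision_radius for s in Species])
RI = np.array([SPECIES_TABLE[s].interaction_radius for s in Species])
MASS = np.array([SPECIES_TABLE[s].mass for s in Species])
DRAG = np.array([SPECIES_TABLE[s].drag_coeff for s in Species])
MAX_BONDS = np.array([SPECIES_TABLE[s].max_bonds for s in Species])

#: Maximum interaction range of any pair (gamma-gamma); neighbor search cutoff.
MAX_INTERACTION_RANGE = 2 * SPECIES_TABLE[Species.GAMMA].interaction_radius

#: Equilibrium inter-bond angle (degrees) for a center particle with NB bound
#: neighbors: linear, trigonal-planar, tetrahedral.
TARGET_ANGLES: dict[int, float] = {2: 180.0, 3: 120.0, 4: 109.4712}


def target_angle(n_bound: int) -> float:
    """Torsion-spring target angle (degrees) for ``n_bound`` bound neighbors."""
    try:
        return TARGET_ANGLES[n_bound]
    except KeyError:
        raise ValueError(f"target angle defined only for 2-4 bound neighbors, got {n_bound}")


def _prob_map(values: Mapping[int, float]) -> dict[int, float]:
    for k, v in values.items():
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"probability out of [0,1]: {k}={v}")
    return dict(values)


@dataclass(frozen=True)
class SchemaParams:
    """Reaction probabilities and spring constants defining one metabolic schema.

    Mechanisms:
      A  beta synthesis (2 alpha -> beta, gamma-catalyzed; pA1 initiation by
         gamma bond count, pA2 incorporation vs ejection)
      B  gamma synthesis (gamma + 2 bound beta -> 2 bonded gamma)
      C  partially-bonded beta bonding (addition / repair / fusion)
      D  free beta bonding (capture by addition, pD2, or insertion)
      E  beta decay (-> 2 alpha)
      F  gamma decay (-> 4 alpha)

    The three experiment presets differ only in (pC, pD1):
    I = (0.04, 0.08), II = (0, 0.08), III = (0, 0).
    """

    pA1: Mapping[int, float] = field(
        default_factory=lambda: {0: 1.0, 1: 0.5, 2: 0.25, 3: 0.125, 4: 0.0625}
    )
    # Stated as a function of the gamma's bond count but only the constant
    # 0.25 is used; kept as a map so a per-count override stays possible.
    pA2: Mapping[int, float] = field(default_factory=lambda: {n: 0.25 for n in range(5)})
    pB: Mapping[int, float] = field(
        default_factory=lambda: {0: 0.0, 1: 0.0, 2: 1e-3, 3: 4e-3, 4: 16e-3}
    )
    pC: float = 4e-2
    pD1: float = 8e-2
    pD2_beta: Mapping[int, float] = field(default_factory=lambda: {0: 1.0, 1: 0.5, 2: 0.0})
    pD2_gamma: Mapping[int, float] = field(
        default_factory=lambda: {0: 1.0, 1: 0.875, 2: 0.75, 3: 0.5, 4: 0.0}
    )
    pE: Mapping[int, float] = field(default_factory=lambda: {0: 16e-3, 1: 4e-3, 2: 1e-3})
    pF: Mapping[int, float] = field(
        default_factory=lambda: {0: 16e-4, 1: 8e-4, 2: 4e-4, 3: 2e-4, 4: 1e-4}
    )
    K_L: float = 100.0  # linear spring constant
    K_T: float = 3.0  # torsion spring constant
    K_coll: float = 200.0  # soft-sphere collision stiffness (model choice)
    c: float = 0.5  # random-walk temporal correlation
    # per-axis standard deviation of the random-walk Gaussian kick; the rate
    # constant that sets the average particle speed (~4 length/s for a free
    # alpha at c=0.5)
    w: float = 25.0
    target_angles: Mapping[int, float] = field(default_factory=lambda: dict(TARGET_ANGLES))

    def __post_init__(self) -> None:
        for name in ("pA1", "pA2", "pB", "pD2_beta", "pD2_gamma", "pE", "pF"):
            object.__setattr__(self, name, _prob_map(getattr(self, name)))
        for p in (self.pC, self.pD1):
            if not 0.0 <= p <= 1.0:
                raise ValueError("pC and pD1 must be probabilities")
        if not 0.0 <= self.c < 1.0 or self.w <= 0:
            raise ValueError("require 0 <= c < 1 and w > 0")

    # -- flat config (de)serialization: keys mirror the table names ---------
    def to_flat_dict(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for name in ("pA1", "pA2", "pB", "pD2_beta", "pD2_gamma", "pE", "pF"):
            for k, v in getattr(self, name).items():
                out[f"{name}.{k}"] = float(v)
        for k, v in self.target_angles.items():
            out[f"target_angles.{k}"] = float(v)
        for name in ("pC", "pD1", "K_L", "K_T", "K_coll", "c", "w"):
            out[name] = float(getattr(self, name))
        return out

    @classmethod
    def from_flat_dict(cls, flat: Mapping[str, float]) -> "SchemaParams":
        base = cls()
        maps: dict[str, dict[int, float]] = {
            name: dict(getattr(base, name))
            for name in ("pA1", "pA2", "pB", "pD2_beta", "pD2_gamma", "pE", "pF", "target_angles")
        }
        scalars: dict[str, float] = {}
        for key, value in flat.items():
            if "." in key:
                name, idx = key.split(".", 1)
                if name not in maps:
                    raise KeyError(f"unknown parameter table: {name}")
                maps[name][int(idx)] = float(value)
            else:
                if key not in ("pC", "pD1", "K_L", "K_T", "K_coll", "c", "w"):
                    raise KeyError(f"unknown parameter: {key}")
                scalars[key] = float(value)
        return cls(**maps, **scalars)


#: Experiment presets: successive suppression of the repair/fusion pathway
#: (mechanism C) and the capture pathway (mechanism D).
EXPERIMENT_PRESETS: dict[str, SchemaParams] = {
    "I": SchemaParams(pC=4e-2, pD1=8e-2),
    "II": SchemaParams(pC=0.0, pD1=8e-2),
    "III": SchemaParams(pC=0.0, pD1=0.0),
}


def schema_preset(name: str) -> SchemaParams:
    """Return the schema for experiment ``name`` ("I", "II" or "III")."""
    try:
        return EXPERIMENT_PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown experiment preset {name!r}; expected I, II or III")


_MECHANISMS = ("A1", "A2", "B", "C", "D1", "D2", "E", "F")


def reaction_probability(
    schema: SchemaParams,
    mechanism: str,
    *,
    n_bound: int | None = None,
    target_species: Species | None = None,
) -> float:
    """Per-timestep probability of ``mechanism`` in the given neighbor context.

    ``n_bound`` is the relevant bound-neighbor count (of the initiating
    particle, or of the target particle for D2).  For D2 the table is
    selected by ``target_species`` (beta or gamma).
    """
    if mechanism not in _MECHANISMS:
        raise ValueError(f"unknown mechanism {mechanism!r}")
    try:
        if mechanism in ("A1", "A2", "B", "F"):
            table = {"A1": schema.pA1, "A2": schema.pA2, "B": schema.pB, "F": schema.pF}[mechanism]
            return table[int(n_bound)]  # type: ignore[arg-type]
        if mechanism == "E":
            return schema.pE[int(n_bound)]  # type: ignore[arg-type]
        if mechanism == "C":
            return schema.pC
        if mechanism == "D1":
            return schema.pD1
        # D2: table by target particle's species
        if target_species == Species.BETA:
            return schema.pD2_beta[int(n_bound)]  # type: ignore[arg-type]
        if target_species == Species.GAMMA:
            return schema.pD2_gamma[int(n_bound)]  # type: ignore[arg-type]
        raise ValueError("D2 requires target_species beta or gamma")
    except (KeyError, TypeError):
        raise ValueError(
            f"invalid context for mechanism {mechanism}: n_bound={n_bound}, "
            f"target_species={target_species}"
        )
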