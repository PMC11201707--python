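"""Experiment orchestration: initial conditions, main loop, sampling, output.

The standard experimental conditions: 1000 alpha food particles plus one red and one blue
seed gamma, placed uniformly at random in a sealed cube of side 40 length
units, simulated for 300 s at 50 timesteps/s.  Each timestep runs chemistry
on the neighbor lists left by the previous physics update, refreshes the
lists, then computes forces and integrates.  Metrics are sampled at 1 Hz.

The reported experiments condition on runs in which both color lineages
survive; ``retry_until_coexistence`` reruns with an incremented seed until
both a red and a blue gamma are alive at the end, recording the attempts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
import numpy as np

from . import chemistry, physics
from .instances import instances_of
from .metrics import FrameMetrics, frame_metrics
from .params import DT, Color, SchemaParams, Species, schema_preset
from .state import SimulationState


@dataclass
class ExperimentConfig:
    schema: SchemaParams | str = "I"  # preset name or explicit parameters
    n_alpha: int = 1000
    seed_gammas: tuple[Color, ...] = (Color.RED, Color.BLUE)
    container_side: float = 40.0
    duration_s: float = 300.0
    sample_interval_s: float = 1.0
    seed: int = 0
    retry_until_coexistence: bool = False
    max_retries: int = 20
    record_events: bool = False

    def resolved_schema(self) -> SchemaParams:
        return schema_preset(self.schema) if isinstance(self.schema, str) else self.schema


@dataclass
class RunResult:
    config: ExperimentConfig
    state: SimulationState
    metrics: list[FrameMetrics]
    events: list[chemistry.ReactionEvent] = field(default_factory=list)
    frames: list[dict] = field(default_factory=list)
    attempts: int = 1
    seed_used: int = 0


def initialize(config: ExperimentConfig, rng: np.random.Generator) -> SimulationState:
    """Place the food particles and seed gammas uniformly in the cube, at
    rest, with no bonds."""
    n = config.n_alpha + len(config.seed_gammas)
    state = SimulationState(
        container_side=config.container_side, rng=rng, dt=DT, capacity=max(2 * n, 64)
    )
    for _ in range(config.n_alpha):
        state.add_particle(Species.ALPHA, rng.uniform(0.0, config.container_side, size=3))
    for color in config.seed_gammas:
        state.add_particle(
            Species.GAMMA, rng.uniform(0.0, config.container_side, size=3), color=color
        )
    physics.update_neighbor_lists(state)
    return state


def step(
    state: SimulationState,
    schema: SchemaParams,
    *,
    collect_events: bool = False,
) -> list[chemistry.ReactionEvent]:
    """One full timestep: chemistry (on current lists) -> list refresh ->
    forces -> integration."""
    events = chemistry.arbitrate_chemistry(state, schema)
    physics.update_neighbor_lists(state)
    physics.update_random_walk(state, schema)
    forces = physics.internal_forces(state, schema)
    physics.integrate_step(state, forces)
    return events if collect_events else []


def _snapshot_frame(state: SimulationState, t: float) -> dict:
    parts = []
    for i in state.alive_indices():
        i = int(i)
        parts.append(
            {
                "id": i,
                "sp": int(state.species[i]),
                "col": int(state.color[i]),
                "x": [round(float(v), 5) for v in state.pos[i]],
                "bonds": sorted(state.bonded_to(i)),
            }
        )
    return {"t": t, "particles": parts}


def run_once(
    config: ExperimentConfig,
    seed: int,
    *,
    keep_frames: bool = False,
    pooled_color: bool = False,
    abort_on_extinction: bool = False,
) -> RunResult:
    schema = config.resolved_schema()
    rng = np.random.default_rng(seed)
    state = initialize(config, rng)
    steps_per_sample = max(1, round(config.sample_interval_s / state.dt))
    n_steps = round(config.duration_s / state.dt)
    metrics: list[FrameMetrics] = []
    events: list[chemistry.ReactionEvent] = []
    frames: list[dict] = []

    def sample() -> None:
        t = state.step_index * state.dt
        metrics.append(frame_metrics(instances_of(state), state, t, pooled_color=pooled_color))
        if keep_frames:
            frames.append(_snapshot_frame(state, t))

    sample()
    for k in range(n_steps):
        evs = step(state, schema, collect_events=config.record_events)
        events.extend(evs)
        if (k + 1) % steps_per_sample == 0:
            sample()
            # a gamma color, once extinct, can never reappear (gamma color is
            # only inherited from a parent gamma), so a run conditioned on
            # coexistence can stop as soon as one lineage dies out
            if abort_on_extinction and not colors_coexist(state):
                break
    return RunResult(
        config=config, state=state, metrics=metrics, events=events, frames=frames,
        seed_used=seed,
    )


def colors_coexist(state: SimulationState) -> bool:
    idx = state.alive_indices()
    gam = idx[state.species[idx] == Species.GAMMA]
    cols = state.color[gam]
    return bool((cols == Color.RED).any() and (cols == Color.BLUE).any())


def run(config: ExperimentConfig, **kwargs) -> RunResult:
    """Run the experiment; optionally retry with incremented seeds until both
    color lineages survive to the end."""
    seed = config.seed
    for attempt in range(1, config.max_retries + 1):
        result = run_once(
            config, seed, abort_on_extinction=config.retry_until_coexistence, **kwargs
        )
        if not config.retry_until_coexistence or colors_coexist(result.state):
            result.attempts = attempt
            return result
        seed += 1
    result.attempts = config.max_retries
    return result  # last attempt, even without coexistence


# ------------------------------------------------------------------ file IO
def write_trajectory(frames: list[dict], path) -> None:
    with open(path, "w") as fh:
        for frame in frames:
            fh.write(json.dumps(frame) + "\n")


def read_trajectory(path) -> list[dict]:
    with open(path) as fh:
        return [json.loads(line) for line in fh if line.strip()]


def write_events(events: list[chemistry.ReactionEvent], path) -> None:
    with open(path, "w") as fh:
        for ev in events:
            fh.write(json.dumps(ev.to_dict()) + "\n")


_XYZ_SYMBOL = {int(Species.ALPHA): "He", int(Species.BETA): "C", int(Species.GAMMA): "N"}


def write_xyz(frames: list[dict], path) -> None:
    """Extended-XYZ export for molecular viewers (element symbols are a
    visualization convention only)."""
    with open(path, "w") as fh:
        for frame in frames:
            parts = frame["particles"]
            fh.write(f"{len(parts)}\n")
            fh.write(f'Properties=species:S:1:pos:R:3 Time={frame["t"]}\n')
            for p in parts:
                x, y, z = p["x"]
                fh.write(f"{_XYZ_SYMBOL[p['sp']]} {x} {y} {z}\n")


def state_from_frame(frame: dict, container_side: float = 40.0) -> SimulationState:
    """Rebuild a minimal state from a trajectory frame (for re-analysis)."""
    parts = frame["particles"]
    n = max((p["id"] for p in parts), default=0) + 1
    state = SimulationState(
        container_side=container_side, rng=np.random.default_rng(0), capacity=max(n, 4)
    )
    state._free = []  # slots assigned explicitly below
    for p in parts:
        i = p["id"]
        state.alive[i] = True
        state.species[i] = p["sp"]
        state.color[i] = p["col"]
        state.pos[i] = p["x"]
    for p in parts:
        for j in p["bonds"]:
            if p["id"] < j:
                state.add_bond(p["id"], j)
    return state
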