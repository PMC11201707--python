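"""Per-frame observables: instance counts, sizes, species masses, mean colors.

The mean color C(x, y) of species y within majority-x instances is computed
per instance first (mean of the +1/-1 color values of the instance's
species-y members), then averaged unweighted across the instances of that
majority.  A pooled-particle variant (all species-y particles of majority-x
instances pooled before averaging) is available behind a flag.  Undefined
means (no such instances, or instances without species-y members) are
reported as NaN and written as empty CSV fields.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .params import Species
from .state import SimulationState
from .instances import InstanceRecord

CSV_COLUMNS = [
    "time_s",
    "n_all",
    "n_red",
    "n_blue",
    "size_min",
    "size_mean",
    "size_max",
    "mass_beta",
    "mass_gamma",
    "mass_instances",
    "c_red_gamma",
    "c_red_beta",
    "c_blue_gamma",
    "c_blue_beta",
]


@dataclass(frozen=True)
class FrameMetrics:
    time_s: float
    n_all: int
    n_red: int
    n_blue: int
    size_min: float
    size_mean: float
    size_max: float
    mass_beta: float
    mass_gamma: float
    mass_instances: float
    c_red_gamma: float
    c_red_beta: float
    c_blue_gamma: float
    c_blue_beta: float
    # largest-instance diagnostics (not part of the CSV contract)
    largest_size: float = math.nan
    largest_mass: float = math.nan
    largest_mass_gamma: float = math.nan

    def as_row(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _mean_color(
    records: list[InstanceRecord],
    state: SimulationState,
    majority: str,
    species: Species,
    pooled: bool,
) -> float:
    per_instance = []
    pool: list[float] = []
    for rec in records:
        if rec.majority != majority:
            continue
        members = np.fromiter(rec.members, dtype=np.int64)
        sel = members[state.species[members] == species]
        if sel.size == 0:
            continue
        vals = state.color[sel].astype(float)
        per_instance.append(float(vals.mean()))
        pool.extend(vals)
    if pooled:
        return float(np.mean(pool)) if pool else math.nan
    return float(np.mean(per_instance)) if per_instance else math.nan


def frame_metrics(
    records: list[InstanceRecord],
    state: SimulationState,
    time_s: float,
    *,
    pooled_color: bool = False,
) -> FrameMetrics:
    sizes = np.array([r.size for r in records], dtype=float)
    masses = np.array([r.mass for r in records], dtype=float)
    mass_beta = mass_gamma = 0.0
    for r in records:
        members = np.fromiter(r.members, dtype=np.int64)
        sp = state.species[members]
        mass_beta += 2.0 * int((sp == Species.BETA).sum())
        mass_gamma += 4.0 * int((sp == Species.GAMMA).sum())
    largest = int(np.argmax(masses)) if records else -1
    largest_mass_gamma = math.nan
    if largest >= 0:
        members = np.fromiter(records[largest].members, dtype=np.int64)
        largest_mass_gamma = 4.0 * int((state.species[members] == Species.GAMMA).sum())
    return FrameMetrics(
        time_s=time_s,
        n_all=len(records),
        n_red=sum(r.majority == "red" for r in records),
        n_blue=sum(r.majority == "blue" for r in records),
        size_min=float(sizes.min()) if records else math.nan,
        size_mean=float(sizes.mean()) if records else math.nan,
        size_max=float(sizes.max()) if records else math.nan,
        mass_beta=mass_beta,
        mass_gamma=mass_gamma,
        mass_instances=float(masses.sum()),
        c_red_gamma=_mean_color(records, state, "red", Species.GAMMA, pooled_color),
        c_red_beta=_mean_color(records, state, "red", Species.BETA, pooled_color),
        c_blue_gamma=_mean_color(records, state, "blue", Species.GAMMA, pooled_color),
        c_blue_beta=_mean_color(records, state, "blue", Species.BETA, pooled_color),
        largest_size=float(records[largest].size) if records else math.nan,
        largest_mass=float(records[largest].mass) if records else math.nan,
        largest_mass_gamma=largest_mass_gamma,
    )


def metrics_dataframe(series: list[FrameMetrics]) -> pd.DataFrame:
    return pd.DataFrame([m.as_row() for m in series])


def write_metrics_csv(series: list[FrameMetrics], path) -> None:
    df = metrics_dataframe(series)[CSV_COLUMNS]
    df.to_csv(path, index=False, na_rep="")


def read_metrics_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def steady_state_summary(series: list[FrameMetrics] | pd.DataFrame, window_s: float) -> pd.DataFrame:
    """Mean and population standard deviation of each metric over the final
    ``window_s`` seconds of a 1 Hz-sampled series."""
    df = series if isinstance(series, pd.DataFrame) else metrics_dataframe(series)
    t_end = df["time_s"].max()
    if window_s > t_end - df["time_s"].min() + 1:
        raise ValueError("summary window longer than the sampled series")
    window = df[df["time_s"] > t_end - window_s]
    numeric = window.drop(columns=["time_s"])
    return pd.DataFrame({"mean": numeric.mean(), "sd": numeric.std(ddof=0)})
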