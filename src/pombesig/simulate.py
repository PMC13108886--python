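"""Time-course integration and the state → observable mapping.

Model time and experimental time are distinct axes: the system is started
from the all-zero state at model time 0, the interval [0, 100] acts as a
vegetative burn-in, and experimental hour ``h`` (hours after transfer to
starvation medium) maps to model time ``hour_offset + h`` with
``hour_offset = 100`` by default. The nitrogen-depletion step is centred at
model time ``100 + k24``.

The three measured observables are state variables directly: ``ppSpk1`` and
``tSpk1`` are Western-blot signals (the normalisation constants ``k12`` and
``k19`` live inside the ODEs) and ``aCdc42`` is the CRIB-GFP signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import odeint

from .model import (
    STATE_NAMES,
    CompiledSystem,
    GenotypeSpec,
    ModelVariant,
    _rhs_free,
    compile_system,
)
from .parameters import ParameterSet

__all__ = [
    "OBSERVABLES",
    "SolverConfig",
    "Trajectory",
    "ObservableSeries",
    "SimulationError",
    "simulate",
    "simulate_compiled",
    "observables",
    "trajectory_frame",
]

OBSERVABLES: tuple[str, ...] = ("ppSpk1", "tSpk1", "aCdc42")

#: Default experimental sampling grid (hours after starvation transfer).
DEFAULT_HOURS: tuple[int, ...] = tuple(range(25))

DEFAULT_HOUR_OFFSET = 100.0


class SimulationError(RuntimeError):
    """Raised when the integrator fails for a given genotype/parameter set."""


@dataclass(frozen=True)
class SolverConfig:
    """Stiff-capable LSODA settings. Defaults favour accuracy over speed."""

    rtol: float = 1e-8
    atol: float = 1e-10
    mxstep: int = 100_000

    def __post_init__(self):
        if self.rtol <= 0 or self.atol <= 0:
            raise ValueError("solver tolerances must be positive")


#: Looser tolerances used inside iterative fitting loops.
FIT_SOLVER = SolverConfig(rtol=1e-7, atol=1e-9)


@dataclass(frozen=True)
class Trajectory:
    """States sampled at experimental hours for one genotype/variant."""

    hours: np.ndarray            # strictly increasing experimental hours
    states: np.ndarray           # (n_hours, 7) full states, clamps filled in
    genotype: GenotypeSpec
    variant: ModelVariant
    params: ParameterSet
    hour_offset: float = DEFAULT_HOUR_OFFSET

    def state(self, name: str) -> np.ndarray:
        return self.states[:, STATE_NAMES.index(name)]


@dataclass(frozen=True)
class ObservableSeries:
    """A predicted measurement series in experimental units."""

    observable: str
    hours: np.ndarray
    values: np.ndarray
    genotype: str = ""

    def __len__(self) -> int:
        return len(self.hours)


def simulate_compiled(
    system: CompiledSystem,
    hours: Sequence[float] = DEFAULT_HOURS,
    solver: SolverConfig = SolverConfig(),
    initial_state=None,
    hour_offset: float = DEFAULT_HOUR_OFFSET,
) -> Trajectory:
    """Integrate an already-compiled system; see :func:`simulate`."""
    hours = np.asarray(sorted(set(float(h) for h in hours)))
    if hours.size == 0:
        raise ValueError("need at least one output hour")
    if hours[0] < 0:
        raise ValueError("hours must be non-negative")
    t_out = hour_offset + hours
    # LSODA needs the start time in the grid; strip it from the output later.
    ts = np.concatenate([[0.0], t_out])

    y0 = system.initial_free(initial_state)
    if system.n_free == 0:
        full = system.expand(np.zeros((ts.size - 1, 0)))
        return Trajectory(hours, full, system.genotype, system.variant,
                          system.params, hour_offset)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yfree, info = odeint(
            _rhs_free,
            y0,
            ts,
            args=(system.kvec, system.flags, system.template, system.free_idx),
            rtol=solver.rtol,
            atol=solver.atol,
            mxstep=solver.mxstep,
            full_output=True,
            printmessg=False,
        )
    if info["message"] != "Integration successful." or not np.all(np.isfinite(yfree)):
        raise SimulationError(
            f"integration failed for genotype {system.genotype.name!r} "
            f"(model {system.variant.value}): {info['message']}; "
            f"params k1..k29 = {np.round(system.params.to_vector(), 6).tolist()}"
        )
    full = system.expand(yfree[1:])
    return Trajectory(hours, full, system.genotype, system.variant,
                      system.params, hour_offset)


def simulate(
    params: ParameterSet,
    variant,
    genotype,
    hours: Sequence[float] = DEFAULT_HOURS,
    solver: SolverConfig = SolverConfig(),
    initial_state=None,
    hour_offset: float = DEFAULT_HOUR_OFFSET,
) -> Trajectory:
    """Integrate the model from the all-zero state and sample at ``hours``.

    Parameters
    ----------
    params, variant, genotype
        Passed to :func:`pombesig.model.compile_system`; genotype may be a
        registry name or a :class:`GenotypeSpec`.
    hours
        Experimental hours (deduplicated and sorted); mapped to model time
        ``hour_offset + h``.
    initial_state
        Optional full 7-state initial condition replacing the all-zero
        default (clamped entries are ignored and pinned to their clamp).

    Deterministic for fixed inputs.
    """
    system = compile_system(params, variant, genotype)
    return simulate_compiled(system, hours, solver, initial_state, hour_offset)


def observables(traj: Trajectory, which: Iterable[str] = OBSERVABLES) -> list[ObservableSeries]:
    """Extract predicted measurement series from a trajectory.

    No further scaling is applied: the normalisation constants are part of
    the ODEs, so the state values are already in blot/CRIB units.
    """
    out = []
    for name in which:
        if name not in OBSERVABLES:
            raise KeyError(f"unknown observable {name!r}; expected one of {OBSERVABLES}")
        out.append(
            ObservableSeries(name, traj.hours.copy(), traj.state(name).copy(),
                             genotype=traj.genotype.name)
        )
    return out


def trajectory_frame(traj: Trajectory, which: Iterable[str] = OBSERVABLES) -> pd.DataFrame:
    """Tidy export: columns genotype, model, observable, hour, value."""
    rows = []
    for s in observables(traj, which):
        for h, v in zip(s.hours, s.values):
            rows.append((traj.genotype.name, traj.variant.value, s.observable, h, v))
    return pd.DataFrame(rows, columns=["genotype", "model", "observable", "hour", "value"])
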