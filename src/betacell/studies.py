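"""Simulation of the emulated experimental protocols.

Three simulations cover all observation types:

* ``low``  — constant 2.8 mM glucose (reference for the step experiment
  and the 60-min comparison),
* ``step`` — 120-min 2.8 mM pre-incubation, then 16.7 mM (numerator of
  the 3/6/10/15-min fold changes),
* ``high`` — 16.7 mM from the initial state (numerator of the 60-min
  comparison, the vs-t0 fold changes, and the flux inputs of the
  insulin regression).

Fold changes are compartment-pooled per metabolite name (3:1
cytosol:mitochondria amounts) to mirror what mass spectrometry can
resolve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import STUDY_COMPARISON, STUDY_TIMEPOINTS
from .network import NetworkModel
from .parameters import ParameterSet
from .simulate import (
    StimulationProtocol,
    Trajectory,
    pooled_fold_change,
    simulate,
    time_averaged_fluxes,
)

PLSR_TIMEPOINTS = (3.0, 6.0, 10.0, 15.0, 60.0)


@dataclass
class ProtocolSet:
    """Glucose levels and timing of the emulated experiments."""

    low_glucose: float = 2.8
    high_glucose: float = 16.7
    pre_minutes: float = 120.0
    step_times: tuple[float, ...] = (3.0, 6.0, 10.0, 15.0)
    const_times: tuple[float, ...] = (60.0,)
    vs_t0_times: tuple[float, ...] = (6.0, 15.0)
    other_boundary: dict[str, float] = field(default_factory=dict)

    def boundary(self, glucose: float) -> dict[str, float]:
        return {"GLC_e": glucose, **self.other_boundary}


def _grid(times: np.ndarray, step: float | None) -> np.ndarray:
    """Observation times, optionally densified to a uniform step."""
    if step is None:
        return np.unique(np.concatenate([[0.0], times]))
    hi = float(np.max(times))
    return np.unique(np.concatenate([np.arange(0.0, hi + step / 2, step), times]))


def run_condition_simulations(model: NetworkModel, params: ParameterSet, init: np.ndarray,
                              protocols: ProtocolSet | None = None,
                              grid_step: float | None = None,
                              rtol: float = 1e-8, atol: float = 1e-10) -> dict[str, Trajectory]:
    """Run the low / step / high simulations once and return them keyed."""
    ps = protocols or ProtocolSet()
    horizon = max(max(ps.const_times), max(ps.step_times), max(ps.vs_t0_times), 60.0)
    step_abs = ps.pre_minutes + np.asarray(ps.step_times)
    low = simulate(model, params, init, StimulationProtocol(
        phases=[(ps.pre_minutes + horizon, ps.boundary(ps.low_glucose))],
        output_grid=_grid(np.concatenate([step_abs, list(ps.const_times)]), grid_step),
    ), rtol=rtol, atol=atol)
    step = simulate(model, params, init, StimulationProtocol(
        phases=[(ps.pre_minutes, ps.boundary(ps.low_glucose)),
                (horizon, ps.boundary(ps.high_glucose))],
        output_grid=_grid(step_abs, grid_step),
    ), rtol=rtol, atol=atol)
    high_times = np.unique(np.concatenate([list(ps.const_times), list(ps.vs_t0_times), [horizon]]))
    high = simulate(model, params, init, StimulationProtocol(
        phases=[(horizon, ps.boundary(ps.high_glucose))],
        output_grid=_grid(high_times, grid_step),
    ), rtol=rtol, atol=atol)
    return {"low": low, "step": step, "high": high}


def predicted_fold_changes(model: NetworkModel, params: ParameterSet, init: np.ndarray,
                           protocols: ProtocolSet | None = None,
                           rtol: float = 1e-8, atol: float = 1e-10,
                           trajectories: dict[str, Trajectory] | None = None,
                           ) -> dict[tuple[str, float, str], dict[str, float]]:
    """Pooled fold-change predictions for every emulated observation slot.

    Returns ``{(source, time_min, comparison): {metabolite_name: fc}}``
    for the spegel2013 step experiment, the malmgren 60-min comparison
    and the spegel2015 vs-t0 course.
    """
    ps = protocols or ProtocolSet()
    trajs = trajectories or run_condition_simulations(model, params, init, ps, rtol=rtol, atol=atol)
    low, step, high = trajs["low"], trajs["step"], trajs["high"]
    out: dict[tuple[str, float, str], dict[str, float]] = {}
    for t in ps.step_times:
        t_abs = ps.pre_minutes + t
        fc = pooled_fold_change(model, step.state_at(t_abs), low.state_at(t_abs),
                                comparison="high_vs_low", time=t)
        out[("spegel2013", t, "high_vs_low")] = fc.values
    for t in ps.const_times:
        fc = pooled_fold_change(model, high.state_at(t), low.state_at(t),
                                comparison="high_vs_low", time=t)
        out[("malmgren", t, "high_vs_low")] = fc.values
    for t in ps.vs_t0_times:
        fc = pooled_fold_change(model, high.state_at(t), high.concentrations[0],
                                comparison="vs_t0", time=t)
        out[("spegel2015", t, "vs_t0")] = fc.values
    return out


def insulin_flux_table(model: NetworkModel, params: ParameterSet, init: np.ndarray,
                       times: tuple[float, ...] = PLSR_TIMEPOINTS,
                       protocols: ProtocolSet | None = None,
                       rtol: float = 1e-8, atol: float = 1e-10) -> pd.DataFrame:
    """Time-averaged flux table feeding the insulin regression.

    One row per stimulation duration (min), one column per reaction:
    the trapezoidal mean flux over ``[0, t]`` of the high-glucose
    simulation on a 1-minute grid.
    """
    ps = protocols or ProtocolSet()
    horizon = max(times)
    traj = simulate(model, params, init, StimulationProtocol(
        phases=[(horizon, ps.boundary(ps.high_glucose))],
        output_grid=np.arange(0.0, horizon + 0.5, 1.0),
    ), rtol=rtol, atol=atol)
    rows = [time_averaged_fluxes(traj, (0.0, t)) for t in times]
    return pd.DataFrame(rows, index=list(times), columns=traj.reaction_ids)


def per_minute_fluxes(model: NetworkModel, params: ParameterSet, init: np.ndarray,
                      duration: float, protocols: ProtocolSet | None = None,
                      rtol: float = 1e-8, atol: float = 1e-10) -> pd.DataFrame:
    """Per-minute average fluxes over a single short time course.

    Row ``m`` (1-based minute) holds the mean flux over ``[m-1, m]`` of
    the high-glucose simulation — the input matrix of the time-resolved
    insulin regression.
    """
    ps = protocols or ProtocolSet()
    traj = simulate(model, params, init, StimulationProtocol(
        phases=[(duration, ps.boundary(ps.high_glucose))],
        output_grid=np.arange(0.0, duration + 0.25, 0.5),
    ), rtol=rtol, atol=atol)
    minutes = np.arange(1, int(duration) + 1)
    rows = [time_averaged_fluxes(traj, (m - 1.0, float(m))) for m in minutes]
    return pd.DataFrame(rows, index=minutes, columns=traj.reaction_ids)
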