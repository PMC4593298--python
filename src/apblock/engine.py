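"""Steady-state pacing of a cell model with a stiff adaptive ODE solver.

One pace is the pace period 1000/frequency ms with a square depolarizing
stimulus pulse.  The pace is integrated with scipy's variable-order BDF
method (absolute tolerance 1e-6, relative tolerance 1e-8 by default) split
at the stimulus on/off discontinuities, and the voltage is reported on a
uniform 0.1 ms output grid via dense-output interpolation — solver-internal
steps are never exposed.

Pacing is repeated until the Euclidean (L2) norm of the change in the full
ODE state vector between the ends of consecutive paces falls below 1e-6
(a pseudo-steady state: subsequent paces repeat the same trajectory), or a
pace limit is reached.  The final two traces are retained so that alternans
can be checked downstream.

A fixed-step 4th-order Runge-Kutta reference integrator is provided as an
independent accuracy oracle for the adaptive path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .cellmodels import CellModelDefinition

__all__ = [
    "PacingProtocol",
    "Trace",
    "SteadyStateResult",
    "SolverFailure",
    "simulate_pace",
    "pace_to_steady",
    "reference_pace",
]

DEFAULT_ABS_TOL = 1e-6
DEFAULT_REL_TOL = 1e-8
DEFAULT_OUTPUT_STEP = 0.1  # ms
DEFAULT_STEADY_NORM_TOL = 1e-6
# Pace limit: at most 1800 paces and at most 5 simulated minutes.
MAX_PACES_CAP = 1800
MAX_SIMULATED_MS = 5 * 60 * 1000.0


class SolverFailure(RuntimeError):
    """The ODE solver failed; carries the failure time, state and pace number."""

    def __init__(self, message: str, t: float, state: np.ndarray,
                 pace: int | None = None):
        self.t = t
        self.state = state
        self.pace = pace
        where = f" during pace {pace}" if pace is not None else ""
        super().__init__(f"{message} at t={t:.6g} ms{where}; state={state!r}")


def default_max_paces(frequency: float) -> int:
    """The smaller of 1800 paces or 5 simulated minutes at this frequency."""
    period = 1000.0 / frequency
    return min(MAX_PACES_CAP, max(1, int(MAX_SIMULATED_MS / period)))


@dataclass(frozen=True)
class PacingProtocol:
    """Pacing frequency, stimulus pulse, solver tolerances and pace limits.

    ``stim_amplitude`` is depolarizing current per capacitance (µA/µF); the
    pulse is active on ``[stim_offset, stim_offset + stim_duration)`` within
    each pace.  ``max_paces=None`` resolves to min(1800 paces, 5 simulated
    minutes).
    """

    frequency: float = 1.0  # Hz
    stim_amplitude: float = 30.0
    stim_duration: float = 2.0  # ms
    stim_offset: float = 10.0  # ms
    abs_tol: float = DEFAULT_ABS_TOL
    rel_tol: float = DEFAULT_REL_TOL
    output_step: float = DEFAULT_OUTPUT_STEP  # ms
    max_paces: int | None = None
    steady_norm_tol: float = DEFAULT_STEADY_NORM_TOL

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise ValueError(f"frequency must be > 0 Hz, got {self.frequency}")
        if self.stim_duration <= 0:
            raise ValueError("stim_duration must be > 0 ms")
        if self.stim_offset < 0:
            raise ValueError("stim_offset must be >= 0 ms")
        if self.stim_offset + self.stim_duration >= self.period:
            raise ValueError(
                f"stimulus (offset {self.stim_offset} + duration "
                f"{self.stim_duration} ms) must fit inside the pace period "
                f"({self.period:.6g} ms)"
            )
        if self.output_step <= 0:
            raise ValueError("output_step must be > 0 ms")
        n = self.period / self.output_step
        if abs(n - round(n)) > 1e-6 * max(1.0, n):
            raise ValueError(
                f"output_step {self.output_step} ms does not divide the pace "
                f"period {self.period:.6g} ms"
            )
        if self.max_paces is not None and self.max_paces < 1:
            raise ValueError("max_paces must be a positive integer")

    @property
    def period(self) -> float:
        """Pace period in ms."""
        return 1000.0 / self.frequency

    @property
    def resolved_max_paces(self) -> int:
        if self.max_paces is not None:
            return self.max_paces
        return default_max_paces(self.frequency)

    def output_times(self) -> np.ndarray:
        """The uniform output grid over one pace, both endpoints included."""
        n = int(round(self.period / self.output_step))
        return np.arange(n + 1) * self.output_step

    @classmethod
    def for_model(cls, model: CellModelDefinition, frequency: float = 1.0,
                  **overrides) -> "PacingProtocol":
        """Protocol using the model's registered default stimulus pulse."""
        stim = model.stimulus_defaults
        kw = dict(
            frequency=frequency,
            stim_amplitude=stim.amplitude,
            stim_duration=stim.duration,
            stim_offset=stim.offset,
        )
        kw.update(overrides)
        return cls(**kw)


@dataclass(frozen=True)
class Trace:
    """A uniformly sampled membrane-voltage time series for one pace."""

    times: np.ndarray  # ms, uniform, starting at 0
    voltages: np.ndarray  # mV

    def __post_init__(self) -> None:
        t = np.asarray(self.times, float)
        v = np.asarray(self.voltages, float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "voltages", v)
        if t.ndim != 1 or t.shape != v.shape:
            raise ValueError("times and voltages must be 1-D arrays of equal length")
        if len(t) >= 2:
            dt = np.diff(t)
            if np.any(dt <= 0):
                raise ValueError("times must be strictly increasing")
            if not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-9):
                raise ValueError("times must be uniformly spaced")
        if not np.all(np.isfinite(v)):
            raise ValueError("voltages must all be finite")

    @property
    def step(self) -> float:
        return float(self.times[1] - self.times[0])

    def downsample(self, step: float) -> "Trace":
        """Every k-th sample so the new step is ``step`` (for plotting/export)."""
        k = int(round(step / self.step))
        if k < 1 or abs(k * self.step - step) > 1e-9:
            raise ValueError(f"{step} ms is not a multiple of the trace step")
        return Trace(self.times[::k], self.voltages[::k])


@dataclass(frozen=True)
class SteadyStateResult:
    """Outcome of pacing to a pseudo-steady state."""

    final_trace: Trace
    previous_trace: Trace | None
    end_state: np.ndarray
    paces_run: int
    converged: bool
    final_norm: float


def _stim_segments(protocol: PacingProtocol) -> list[tuple[float, float, float]]:
    """(t0, t1, stimulus_value) sub-intervals covering one pace."""
    on = protocol.stim_offset
    off = protocol.stim_offset + protocol.stim_duration
    amp = protocol.stim_amplitude
    if amp == 0.0:
        return [(0.0, protocol.period, 0.0)]
    segs = []
    if on > 0:
        segs.append((0.0, on, 0.0))
    segs.append((on, off, amp))
    segs.append((off, protocol.period, 0.0))
    return segs


def simulate_pace(
    model: CellModelDefinition,
    params: Mapping[str, float],
    state: Sequence[float],
    protocol: PacingProtocol,
    pace_number: int | None = None,
) -> tuple[Trace, np.ndarray]:
    """Integrate one pace; return the sampled trace and the end-of-pace state.

    The integration is split at the stimulus on/off instants so the solver
    never steps across a discontinuity, and the trace is evaluated on the
    uniform output grid from the solver's dense output.
    """
    y = np.asarray(state, float)
    if not np.all(np.isfinite(y)):
        raise SolverFailure("non-finite initial state", 0.0, y, pace_number)

    grid = protocol.output_times()
    voltages = np.empty_like(grid)
    voltages[0] = y[0]

    if model.rhs_core is not None:
        pvec = model.param_vector(params)
        core = model.rhs_core

        def make_fun(stim_value):
            return lambda t, yy: core(t, yy, pvec, stim_value)
    else:
        def make_fun(stim_value):
            return lambda t, yy: model.rhs(t, yy, params, stim_value)

    for t0, t1, stim_value in _stim_segments(protocol):
        sol = solve_ivp(
            make_fun(stim_value),
            (t0, t1),
            y,
            method="BDF",
            rtol=protocol.rel_tol,
            atol=protocol.abs_tol,
            dense_output=True,
        )
        if not sol.success:
            raise SolverFailure(
                f"BDF solver failed ({sol.message})", float(sol.t[-1]),
                sol.y[:, -1], pace_number,
            )
        # sample grid points interior to (t0, t1]
        mask = (grid > t0 + 1e-12) & (grid <= t1 + 1e-12)
        if np.any(mask):
            voltages[mask] = sol.sol(np.minimum(grid[mask], t1))[0]
        y = sol.y[:, -1]

    if not np.all(np.isfinite(voltages)):
        raise SolverFailure("non-finite voltage in sampled trace",
                            protocol.period, y, pace_number)
    return Trace(grid, voltages), y


def pace_to_steady(
    model: CellModelDefinition,
    params: Mapping[str, float],
    protocol: PacingProtocol,
    initial_state: Sequence[float] | None = None,
) -> SteadyStateResult:
    """Pace until the pace-to-pace state change is below the steady tolerance.

    After each pace the Euclidean norm of the difference between the states
    at the ends of consecutive paces is computed on the raw (mixed-unit)
    state vector; convergence is declared when it drops below
    ``protocol.steady_norm_tol``.  Stops unconverged after the pace limit.
    """
    if initial_state is None:
        initial_state = model.default_initial_state
    state = np.asarray(initial_state, float)
    max_paces = protocol.resolved_max_paces

    prev_trace: Trace | None = None
    prev_end: np.ndarray | None = None
    trace: Trace | None = None
    final_norm = math.inf
    converged = False
    paces = 0
    for pace in range(1, max_paces + 1):
        prev_trace = trace
        trace, end = simulate_pace(model, params, state, protocol,
                                   pace_number=pace)
        paces = pace
        if prev_end is not None:
            final_norm = float(np.linalg.norm(end - prev_end))
            if final_norm < protocol.steady_norm_tol:
                converged = True
        prev_end = end
        state = end
        if converged:
            break

    assert trace is not None
    return SteadyStateResult(
        final_trace=trace,
        previous_trace=prev_trace,
        end_state=state,
        paces_run=paces,
        converged=converged,
        final_norm=final_norm if math.isfinite(final_norm) else math.nan,
    )


def reference_pace(
    model: CellModelDefinition,
    params: Mapping[str, float],
    state: Sequence[float],
    protocol: PacingProtocol,
    dt: float = 0.001,
) -> tuple[Trace, np.ndarray]:
    """Fixed-step classic RK4 integration of one pace (accuracy oracle).

    Independent of the adaptive BDF path: no error control, no dense output.
    ``dt`` must divide both the output step and the stimulus on/off times.
    """
    y0 = np.asarray(state, float)
    sample_every = int(round(protocol.output_step / dt))
    if abs(sample_every * dt - protocol.output_step) > 1e-12:
        raise ValueError("dt must divide the output step")
    grid = protocol.output_times()

    if model.rk4_core is not None:
        pvec = model.param_vector(params)
        volts, end = model.rk4_core(
            y0, pvec, protocol.period, dt, protocol.stim_amplitude,
            protocol.stim_offset, protocol.stim_duration, sample_every,
        )
        return Trace(grid, volts), end

    # generic (slow) fallback
    n_steps = int(round(protocol.period / dt))
    on, offt = protocol.stim_offset, protocol.stim_offset + protocol.stim_duration

    def stim(t: float) -> float:
        return protocol.stim_amplitude if on <= t < offt else 0.0

    y = y0.copy()
    volts = np.empty(n_steps // sample_every + 1)
    volts[0] = y[0]
    j = 1
    for i in range(n_steps):
        t = i * dt
        k1 = model.rhs(t, y, params, stim(t))
        k2 = model.rhs(t + dt / 2, y + dt / 2 * k1, params, stim(t + dt / 2))
        k3 = model.rhs(t + dt / 2, y + dt / 2 * k2, params, stim(t + dt / 2))
        k4 = model.rhs(t + dt, y + dt * k3, params, stim(t + dt))
        y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        if (i + 1) % sample_every == 0:
            volts[j] = y[0]
            j += 1
    return Trace(grid, volts), y
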