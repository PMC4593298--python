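"""Paced cardiac cell models and conductance-block application.

Each model is an ODE system ``dy/dt = rhs(t, y, params, I_stim)`` whose first
state is the transmembrane voltage V (mV), evolving as

    dV/dt = -(sum_j I_j)/C_m + I_stim/C_m

with the convention that a positive (depolarizing) stimulus raises V.  Drug
action is pure conductance block: each channel's maximal conductance is
multiplied by its fraction-remaining factor, kinetics untouched.

The registry ships a self-contained six-current demonstration model
("sixcurrent_demo") with Hodgkin-Huxley style INa, ICaL, IKr, IKs, IK1 and
Ito, fixed Nernst potentials and no intracellular ion dynamics.  Its gating
parameters are tuned so that 1 Hz pacing gives a ventricular-like action
potential (resting potential near -85 mV, peak near +30 mV, APD90 in the
250-300 ms range) and so that the qualitative pharmacology is right: IKr
block prolongs the action potential, ICaL block shortens it, INa block slows
the upstroke.  A second entry ("sixcurrent_demo_totalito") is the same model
flagged as carrying a single total Ito conductance, exercising the aliasing
rule used for models that do not separate Ito,fast from Ito,slow.
"""

from __future__ import annotations

import copy
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .doseresponse import BlockFactors, ChannelId

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore[misc]
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


__all__ = [
    "StimulusDefaults",
    "ModelParameters",
    "CellModelDefinition",
    "BlockWarning",
    "get_model",
    "available_models",
    "apply_block",
    "evaluate_rhs",
]


class BlockWarning(UserWarning):
    """A block factor could not be applied because the model lacks the channel."""


@dataclass(frozen=True)
class StimulusDefaults:
    """Default stimulus pulse for a model: amplitude is current per capacitance."""

    amplitude: float  # µA/µF, depolarizing positive
    duration: float  # ms
    offset: float  # ms from pace start


class ModelParameters(dict):
    """Named real parameters of a model, including all maximal conductances.

    A plain mapping ``name -> value``; conductances must be non-negative.
    """

    def __init__(self, *args, **kwargs):
        super().__init__(*args, **kwargs)
        for k, v in self.items():
            if k.startswith("g_") and v < 0:
                raise ValueError(f"maximal conductance {k} must be >= 0, got {v!r}")

    def copy(self) -> "ModelParameters":
        return ModelParameters(self)


@dataclass
class CellModelDefinition:
    """A named paced cell model.

    ``rhs(t, state, params, stim)`` returns the state derivatives; it is
    deterministic and side-effect free.  ``conductance_keys`` maps each
    blockable channel to the parameter holding its maximal conductance;
    channels a model lacks are simply absent from the mapping.
    """

    name: str
    state_names: tuple[str, ...]  # first entry is "V (mV)"
    default_initial_state: np.ndarray
    cm: float  # µF/cm² (1 in this normalized model)
    conductance_keys: dict[ChannelId, str]
    ito_is_total: bool
    rhs: Callable[[float, np.ndarray, Mapping[str, float], float], np.ndarray]
    default_parameters: ModelParameters
    stimulus_defaults: StimulusDefaults
    # fast path used by the pacing engine: rhs_core(t, y, param_vector, stim)
    param_order: tuple[str, ...] = ()
    rhs_core: Callable | None = None
    rk4_core: Callable | None = None

    def __post_init__(self) -> None:
        self.default_initial_state = np.asarray(self.default_initial_state, float)
        if len(self.default_initial_state) != len(self.state_names):
            raise ValueError(
                f"model {self.name}: initial state has "
                f"{len(self.default_initial_state)} entries for "
                f"{len(self.state_names)} state names"
            )

    def param_vector(self, params: Mapping[str, float]) -> np.ndarray:
        return np.array([params[k] for k in self.param_order], float)


# ---------------------------------------------------------------------------
# Six-current demonstration model
# ---------------------------------------------------------------------------

# State ordering: V, m, h, d, f, xr, xs, r, s
SIXCURRENT_STATE_NAMES = (
    "V (mV)",
    "m (INa activation)",
    "h (INa inactivation)",
    "d (ICaL activation)",
    "f (ICaL inactivation)",
    "xr (IKr activation)",
    "xs (IKs activation)",
    "r (Ito activation)",
    "s (Ito inactivation)",
)

# Maximal conductances in mS/µF, reversal potentials in mV, Cm in µF/cm².
# Tuned (and frozen by regression tests) to meet the morphology targets
# stated in the module docstring.
SIXCURRENT_PARAMS = {
    "g_Na": 8.0,
    "g_CaL": 0.12,
    "g_Kr": 0.04,
    "g_Ks": 0.03,
    "g_K1": 0.30,
    "g_to": 0.08,
    "E_Na": 65.0,
    "E_Ca": 60.0,
    "E_K": -88.0,
    "C_m": 1.0,
}

SIXCURRENT_PARAM_ORDER = (
    "g_Na",
    "g_CaL",
    "g_Kr",
    "g_Ks",
    "g_K1",
    "g_to",
    "E_Na",
    "E_Ca",
    "E_K",
    "C_m",
)

_SIXCURRENT_CONDUCTANCE_KEYS = {
    ChannelId.INa: "g_Na",
    ChannelId.ICaL: "g_CaL",
    ChannelId.IKr: "g_Kr",
    ChannelId.IKs: "g_Ks",
    ChannelId.IK1: "g_K1",
    ChannelId.Ito: "g_to",
}

# Quiescent state; the paced steady state is found by the engine.
SIXCURRENT_INITIAL_STATE = np.array(
    [-86.0, 0.0, 0.95, 0.0, 1.0, 0.0, 0.0, 0.0, 1.0]
)

SIXCURRENT_STIMULUS = StimulusDefaults(amplitude=30.0, duration=2.0, offset=10.0)


@njit(cache=True)
def _sixcurrent_rhs_core(t, y, p, stim):
    V = y[0]
    m = y[1]
    h = y[2]
    d = y[3]
    f = y[4]
    xr = y[5]
    xs = y[6]
    r = y[7]
    s = y[8]

    g_Na = p[0]
    g_CaL = p[1]
    g_Kr = p[2]
    g_Ks = p[3]
    g_K1 = p[4]
    g_to = p[5]
    E_Na = p[6]
    E_Ca = p[7]
    E_K = p[8]
    C_m = p[9]

    # INa gating: fast sigmoidal activation, voltage-dependent inactivation tau
    m_inf = 1.0 / (1.0 + math.exp(-(V + 40.0) / 6.0))
    tau_m = 0.12
    h_inf = 1.0 / (1.0 + math.exp((V + 70.0) / 6.0))
    tau_h = 0.25 + 8.0 / (1.0 + math.exp((V + 55.0) / 7.0))

    # ICaL gating: slow inactivation sustains the plateau
    d_inf = 1.0 / (1.0 + math.exp(-(V + 10.0) / 6.0))
    tau_d = 2.0
    f_inf = 1.0 / (1.0 + math.exp((V + 25.0) / 6.0))
    tau_f = 220.0

    # IKr activation: slow, drives late repolarisation
    xr_inf = 1.0 / (1.0 + math.exp(-(V + 25.0) / 8.0))
    tau_xr = 140.0

    # IKs activation: slower and weaker
    xs_inf = 1.0 / (1.0 + math.exp(-V / 14.0))
    tau_xs = 250.0

    # Ito: fast transient outward
    r_inf = 1.0 / (1.0 + math.exp(-(V - 5.0) / 9.0))
    tau_r = 3.0
    s_inf = 1.0 / (1.0 + math.exp((V + 30.0) / 5.0))
    tau_s = 25.0

    # Instantaneous inward-rectifier gate
    k1_inf = 1.0 / (1.0 + math.exp((V + 70.0) / 8.0))

    I_Na = g_Na * m * m * m * h * (V - E_Na)
    I_CaL = g_CaL * d * f * (V - E_Ca)
    I_Kr = g_Kr * xr * (V - E_K)
    I_Ks = g_Ks * xs * xs * (V - E_K)
    I_K1 = g_K1 * k1_inf * (V - E_K)
    I_to = g_to * r * s * (V - E_K)

    dy = np.empty(9)
    dy[0] = -(I_Na + I_CaL + I_Kr + I_Ks + I_K1 + I_to) / C_m + stim / C_m
    dy[1] = (m_inf - m) / tau_m
    dy[2] = (h_inf - h) / tau_h
    dy[3] = (d_inf - d) / tau_d
    dy[4] = (f_inf - f) / tau_f
    dy[5] = (xr_inf - xr) / tau_xr
    dy[6] = (xs_inf - xs) / tau_xs
    dy[7] = (r_inf - r) / tau_r
    dy[8] = (s_inf - s) / tau_s
    return dy


@njit(cache=True)
def _sixcurrent_rk4_pace(y0, p, period, dt, amp, stim_offset, stim_duration,
                         sample_every):
    """Classic fixed-step RK4 over one pace; samples every ``sample_every`` steps.

    Reference integrator used as an accuracy oracle for the adaptive solver.
    """
    n_steps = int(round(period / dt))
    n_out = n_steps // sample_every + 1
    out = np.empty(n_out)
    y = y0.copy()
    out[0] = y[0]
    j = 1
    for i in range(n_steps):
        t = i * dt
        th = t + 0.5 * dt
        t1 = t + dt
        s0 = amp if (stim_offset <= t < stim_offset + stim_duration) else 0.0
        sh = amp if (stim_offset <= th < stim_offset + stim_duration) else 0.0
        s1 = amp if (stim_offset <= t1 < stim_offset + stim_duration) else 0.0
        k1 = _sixcurrent_rhs_core(t, y, p, s0)
        k2 = _sixcurrent_rhs_core(th, y + 0.5 * dt * k1, p, sh)
        k3 = _sixcurrent_rhs_core(th, y + 0.5 * dt * k2, p, sh)
        k4 = _sixcurrent_rhs_core(t1, y + dt * k3, p, s1)
        y = y + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        if (i + 1) % sample_every == 0:
            out[j] = y[0]
            j += 1
    return out, y


def _sixcurrent_rhs(t, state, params, stim=0.0):
    p = np.array([params[k] for k in SIXCURRENT_PARAM_ORDER], float)
    return _sixcurrent_rhs_core(t, np.asarray(state, float), p, stim)


def _make_sixcurrent(name: str, ito_is_total: bool) -> CellModelDefinition:
    return CellModelDefinition(
        name=name,
        state_names=SIXCURRENT_STATE_NAMES,
        default_initial_state=SIXCURRENT_INITIAL_STATE.copy(),
        cm=SIXCURRENT_PARAMS["C_m"],
        conductance_keys=dict(_SIXCURRENT_CONDUCTANCE_KEYS),
        ito_is_total=ito_is_total,
        rhs=_sixcurrent_rhs,
        default_parameters=ModelParameters(SIXCURRENT_PARAMS),
        stimulus_defaults=SIXCURRENT_STIMULUS,
        param_order=SIXCURRENT_PARAM_ORDER,
        rhs_core=_sixcurrent_rhs_core,
        rk4_core=_sixcurrent_rk4_pace,
    )


_REGISTRY: dict[str, Callable[[], CellModelDefinition]] = {
    "sixcurrent_demo": lambda: _make_sixcurrent("sixcurrent_demo", False),
    "sixcurrent_demo_totalito": lambda: _make_sixcurrent(
        "sixcurrent_demo_totalito", True
    ),
}


def available_models() -> tuple[str, ...]:
    return tuple(sorted(_REGISTRY))


def get_model(name: str) -> CellModelDefinition:
    """Return a pristine definition of the named model.

    Each call returns a fresh copy with default parameters; no state leaks
    between studies.
    """
    try:
        factory = _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown cell model {name!r}; available models: "
            f"{', '.join(available_models())}"
        ) from None
    return factory()


def apply_block(
    model: CellModelDefinition,
    params: Mapping[str, float],
    factors: BlockFactors,
) -> ModelParameters:
    """Scale each mapped channel's maximal conductance by its block factor.

    Returns a copy; the input parameters are not modified.  Channels the
    model does not map get a :class:`BlockWarning` if their factor differs
    from 1 (the block is requested but cannot be applied), never a silent
    drop.  For models flagged ``ito_is_total`` the Ito factor scales the
    single total Ito conductance.
    """
    out = ModelParameters(params)
    for channel, factor in factors.items():
        key = model.conductance_keys.get(channel)
        if key is None:
            if factor != 1.0:
                warnings.warn(
                    f"model {model.name!r} has no conductance for {channel}; "
                    f"requested factor {factor:.4g} not applied",
                    BlockWarning,
                    stacklevel=2,
                )
            continue
        out[key] = params[key] * factor
    return out


def evaluate_rhs(
    model: CellModelDefinition,
    t: float,
    state: Sequence[float],
    params: Mapping[str, float],
    stim: float = 0.0,
) -> np.ndarray:
    """Evaluate the model's state derivatives, validating the state first."""
    y = np.asarray(state, float)
    if y.shape != (len(model.state_names),):
        raise ValueError(
            f"state has shape {y.shape}, expected ({len(model.state_names)},)"
        )
    bad = np.flatnonzero(~np.isfinite(y))
    if bad.size:
        raise ValueError(
            f"non-finite state entries at indices {bad.tolist()} "
            f"({[model.state_names[i] for i in bad.tolist()]})"
        )
    return model.rhs(t, y, params, stim)
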