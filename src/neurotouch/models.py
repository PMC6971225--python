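"""Floating-point reference implementations of the four discrete spiking models.

Four Euler-discretized neuron models generate the spike trains of artificial
tactile afferents:

* ``izh``  -- Izhikevich model: membrane potential ``v`` with a quadratic
  nonlinearity plus a slow recovery variable ``u``.
* ``lizh`` -- linearized Izhikevich: the quadratic term is replaced by the
  piecewise-linear term ``k1*|v + 62.5| - k2`` to remove one multiplier.
* ``qif``  -- quadratic integrate-and-fire: a single state variable with
  ``v**2`` dynamics, peak threshold and reset.
* ``lqif`` -- linearized QIF: ``M2*|v|`` dynamics, the cheapest circuit.

Each model exists in two afferent flavours.  A slowly adapting (SA-I) afferent
is driven by the force signal itself: the weighted input ``C*I[n]`` enters the
``h``-multiplied bracket of the update.  A fast adapting (FA-I) afferent is
driven by the change of the signal: the term ``C*(I[n+1] - I[n])`` is added
*outside* the bracket, so a constant force produces no drive at all.

All times are in milliseconds, membrane potentials in mV.  The force-derived
input current ``I`` is treated as the dimensionless digitized sensor signal;
the per-model coupling constants ``C_in_sa`` / ``C_in_fa`` absorb all scaling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "MODEL_NAMES",
    "TWO_VAR_MODELS",
    "NeuronParams",
    "NeuronState",
    "SimConfig",
    "initial_state",
    "step_izh",
    "step_lizh",
    "step_qif",
    "step_lqif",
    "step_model",
    "simulate_trace",
    "normalize_afferent_type",
]

MODEL_NAMES = ("izh", "lizh", "qif", "lqif")
#: Models that carry the recovery variable ``u`` in addition to ``v``.
TWO_VAR_MODELS = ("izh", "lizh")

#: Default discretization step, exactly 2**-7 ms (exact in binary and in the
#: Q13.18 register format of the digital circuits).
DEFAULT_H = 0.0078125

# Per-model (SA, FA) input coupling weights of the simulation parameter set.
_INPUT_WEIGHTS = {
    "izh": (20.0, 960.0),
    "lizh": (24.0, 960.0),
    "qif": (0.015625, 0.5),
    "lqif": (1.0, 40.0),
}


def normalize_afferent_type(afferent_type: str) -> str:
    """Return the canonical afferent-type token, ``"SA"`` or ``"FA"``.

    Accepts common spellings such as ``"SA-I"``, ``"sa"``, ``"FA-I"``.
    """
    token = str(afferent_type).strip().upper().replace("-I", "").replace("_I", "")
    if token not in ("SA", "FA"):
        raise ValueError(f"unknown afferent type {afferent_type!r}; expected SA or FA")
    return token


def _normalize_model(model: str) -> str:
    token = str(model).strip().lower().replace("-", "")
    if token not in MODEL_NAMES:
        raise ValueError(f"unknown model {model!r}; expected one of {MODEL_NAMES}")
    return token


@dataclass(frozen=True)
class NeuronParams:
    """All constants of the four spiking models (simulation parameter set).

    Defaults reproduce the parameter table used for the MATLAB/VIVADO
    characterization of the digital afferents.  ``C_in_sa`` / ``C_in_fa`` are
    the per-model input weights (``Cx1`` / ``Cx2`` of the afferent front end)
    and therefore have no single default: use :meth:`for_model`.

    Units: ``a`` in 1/ms (recovery rate), ``b`` dimensionless coupling,
    ``c`` reset voltage (mV), ``d`` recovery increment (mV), ``k1``/``k2``
    linearized slope/offset, ``M1`` quadratic gain (1/mV), ``M2`` linear gain,
    ``v_peak``/``v_reset`` in mV.  ``C_m`` and ``tau`` are the nominal
    capacitance/time constant, both 1 in the discrete equations.
    """

    C_in_sa: float
    C_in_fa: float
    a: float = 0.02
    b: float = 0.2
    c: float = -65.0
    d: float = 8.0
    k1: float = 0.75
    k2: float = 20.0
    M1: float = 1.0
    M2: float = 0.0625
    v_peak: float = 30.0
    v_reset: float = 0.0
    C_m: float = 1.0
    tau: float = 1.0

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            value = getattr(self, name)
            if not math.isfinite(float(value)):
                raise ValueError(f"NeuronParams.{name} must be finite, got {value!r}")
        if not self.v_peak > self.v_reset:
            raise ValueError("v_peak must exceed v_reset")

    @classmethod
    def for_model(cls, model: str, **overrides) -> "NeuronParams":
        """Default parameters for one of the four models."""
        sa, fa = _INPUT_WEIGHTS[_normalize_model(model)]
        params = cls(C_in_sa=sa, C_in_fa=fa)
        return replace(params, **overrides) if overrides else params

    @classmethod
    def improved_lqif(cls) -> "NeuronParams":
        """Shift-friendly L-QIF parameter set of the digital population.

        Every coefficient that multiplies a signal is a power of two
        (``M2 = 0.25``, ``C41 = 0.5``, ``C42 = 16``), so each multiplier of
        the circuit reduces to a logical shifter.  This is the parameter set
        the hardware population runs with; it is deliberately retuned from
        the simulation defaults (``M2 = 0.0625``, ``C41 = 1``, ``C42 = 40``).
        """
        return cls(C_in_sa=0.5, C_in_fa=16.0, M2=0.25)


@dataclass(frozen=True)
class NeuronState:
    """Membrane state after a step.

    ``u`` is present only for the two-variable models (``izh``, ``lizh``);
    ``spiked`` flags a reset event in the step just taken.
    """

    v: float
    u: Optional[float] = None
    spiked: bool = False

    def __post_init__(self) -> None:
        if not math.isfinite(self.v):
            raise ValueError(f"non-finite membrane potential {self.v!r}")
        if self.u is not None and not math.isfinite(self.u):
            raise ValueError(f"non-finite recovery variable {self.u!r}")


@dataclass(frozen=True)
class SimConfig:
    """Configuration of a single-neuron simulation.

    ``duration`` must be an integer multiple of the step ``h`` (both ms).
    """

    duration: float
    h: float = DEFAULT_H
    afferent_type: str = "SA"
    model: str = "izh"

    def __post_init__(self) -> None:
        if not (math.isfinite(self.h) and self.h > 0):
            raise ValueError(f"time step h must be positive, got {self.h!r}")
        if not (math.isfinite(self.duration) and self.duration > 0):
            raise ValueError(f"duration must be positive, got {self.duration!r}")
        steps = self.duration / self.h
        if abs(steps - round(steps)) > 1e-9:
            raise ValueError("duration must be an integer multiple of h")
        object.__setattr__(self, "afferent_type", normalize_afferent_type(self.afferent_type))
        object.__setattr__(self, "model", _normalize_model(self.model))

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.h))


def initial_state(model: str, params: NeuronParams) -> NeuronState:
    """Distinguished initial condition of each model family.

    Two-variable models start at the reset point ``v = c`` with the recovery
    variable at its nullcline value ``u = b*v``; one-variable models start at
    ``v = v_reset``.
    """
    model = _normalize_model(model)
    if model in TWO_VAR_MODELS:
        return NeuronState(v=params.c, u=params.b * params.c)
    return NeuronState(v=params.v_reset)


def _check_step_inputs(state: NeuronState, i_now: float, i_next: float, h: float,
                       needs_u: bool) -> None:
    if not (math.isfinite(i_now) and math.isfinite(i_next)):
        raise ValueError(f"non-finite input current ({i_now!r}, {i_next!r})")
    if not (math.isfinite(h) and h > 0):
        raise ValueError(f"time step h must be positive, got {h!r}")
    if needs_u and state.u is None:
        raise ValueError("this model requires a recovery variable u in the state")


def step_izh(state: NeuronState, i_now: float, i_next: float, params: NeuronParams,
             h: float = DEFAULT_H, afferent_type: str = "SA") -> NeuronState:
    """One Euler step of the Izhikevich model.

    SA-I: ``v[n+1] = v + h*(0.04 v^2 + 5 v + 140 - u + C*I[n])``;
    FA-I: the input instead enters as ``C*(I[n+1] - I[n])`` outside the
    bracket.  Reset: ``v >= 30  ->  v <- c, u <- u + d``.
    """
    _check_step_inputs(state, i_now, i_next, h, needs_u=True)
    fa = normalize_afferent_type(afferent_type) == "FA"
    v, u = state.v, state.u
    if fa:
        vn = v + h * (0.04 * v * v + 5.0 * v + 140.0 - u) + params.C_in_fa * (i_next - i_now)
    else:
        vn = v + h * (0.04 * v * v + 5.0 * v + 140.0 - u + params.C_in_sa * i_now)
    un = u + h * params.a * (params.b * v - u)
    if vn >= params.v_peak:
        return NeuronState(v=params.c, u=un + params.d, spiked=True)
    return NeuronState(v=vn, u=un)


def step_lizh(state: NeuronState, i_now: float, i_next: float, params: NeuronParams,
              h: float = DEFAULT_H, afferent_type: str = "SA") -> NeuronState:
    """One Euler step of the linearized Izhikevich model.

    The quadratic term is replaced by ``k1*|v + 62.5| - k2``; reset rule and
    recovery dynamics are identical to :func:`step_izh`.
    """
    _check_step_inputs(state, i_now, i_next, h, needs_u=True)
    fa = normalize_afferent_type(afferent_type) == "FA"
    v, u = state.v, state.u
    if fa:
        vn = v + h * (params.k1 * abs(v + 62.5) - params.k2 - u) \
            + params.C_in_fa * (i_next - i_now)
    else:
        vn = v + h * (params.k1 * abs(v + 62.5) - params.k2 - u + params.C_in_sa * i_now)
    un = u + h * params.a * (params.b * v - u)
    if vn >= params.v_peak:
        return NeuronState(v=params.c, u=un + params.d, spiked=True)
    return NeuronState(v=vn, u=un)


def step_qif(state: NeuronState, i_now: float, i_next: float, params: NeuronParams,
             h: float = DEFAULT_H, afferent_type: str = "SA") -> NeuronState:
    """One Euler step of the quadratic integrate-and-fire model."""
    _check_step_inputs(state, i_now, i_next, h, needs_u=False)
    fa = normalize_afferent_type(afferent_type) == "FA"
    v = state.v
    if fa:
        vn = v + h * (params.M1 * v * v) + params.C_in_fa * (i_next - i_now)
    else:
        vn = v + h * (params.M1 * v * v + params.C_in_sa * i_now)
    if vn >= params.v_peak:
        return NeuronState(v=params.v_reset, spiked=True)
    return NeuronState(v=vn)


def step_lqif(state: NeuronState, i_now: float, i_next: float, params: NeuronParams,
              h: float = DEFAULT_H, afferent_type: str = "SA") -> NeuronState:
    """One Euler step of the linearized QIF model (``M2*|v|`` dynamics)."""
    _check_step_inputs(state, i_now, i_next, h, needs_u=False)
    fa = normalize_afferent_type(afferent_type) == "FA"
    v = state.v
    if fa:
        vn = v + h * (params.M2 * abs(v)) + params.C_in_fa * (i_next - i_now)
    else:
        vn = v + h * (params.M2 * abs(v) + params.C_in_sa * i_now)
    if vn >= params.v_peak:
        return NeuronState(v=params.v_reset, spiked=True)
    return NeuronState(v=vn)


_STEP_FUNCS = {"izh": step_izh, "lizh": step_lizh, "qif": step_qif, "lqif": step_lqif}


def step_model(model: str, state: NeuronState, i_now: float, i_next: float,
               params: NeuronParams, h: float = DEFAULT_H,
               afferent_type: str = "SA") -> NeuronState:
    """Dispatch a single step to the requested model."""
    return _STEP_FUNCS[_normalize_model(model)](state, i_now, i_next, params, h,
                                                afferent_type)


def simulate_trace(config: SimConfig, params: Optional[NeuronParams],
                   current: Sequence[float],
                   state0: Optional[NeuronState] = None,
                   ) -> Tuple[np.ndarray, np.ndarray]:
    """Simulate one afferent neuron over a full current series.

    Parameters
    ----------
    config
        Model, afferent type, step and duration.  ``len(current)`` must equal
        ``config.n_steps``.
    params
        Model constants; ``None`` selects the per-model defaults.
    current
        Input series ``I[n]``.  FA afferents consume a one-sample lookahead
        ``I[n+1]``; at the final sample the last value is reused so the
        terminal difference is zero.
    state0
        Optional initial state (defaults to :func:`initial_state`).

    Returns
    -------
    trace, spike_times
        ``trace[k]`` is the membrane potential after update ``k+1``; at spike
        steps the trace stores ``v_peak`` (the pre-reset event marker used for
        plotting) while the internal state is reset.  ``spike_times`` are
        ``(k+1)*h`` in ms.  The simulation is fully deterministic.
    """
    if params is None:
        params = NeuronParams.for_model(config.model)
    current = np.asarray(current, dtype=np.float64)
    if current.ndim != 1 or current.shape[0] != config.n_steps:
        raise ValueError(
            f"current length {current.shape} does not match duration/h = {config.n_steps}")
    if not np.all(np.isfinite(current)):
        raise ValueError("current series contains non-finite values")

    n = config.n_steps
    h = config.h
    fa = config.afferent_type == "FA"
    model = config.model
    state = state0 if state0 is not None else initial_state(model, params)

    trace = np.empty(n, dtype=np.float64)
    spike_steps = []

    # Inline loops (one per model) mirror the step functions exactly; the
    # expressions are kept identical so the batched numba kernels can be
    # checked against this reference bit for bit.
    v = state.v
    u = state.u if state.u is not None else 0.0
    a, b, c, d = params.a, params.b, params.c, params.d
    k1, k2 = params.k1, params.k2
    M1, M2 = params.M1, params.M2
    v_peak, v_reset = params.v_peak, params.v_reset
    Csa, Cfa = params.C_in_sa, params.C_in_fa

    for k in range(n):
        i0 = current[k]
        i1 = current[k + 1] if k + 1 < n else current[k]
        if model == "izh":
            if fa:
                vn = v + h * (0.04 * v * v + 5.0 * v + 140.0 - u) + Cfa * (i1 - i0)
            else:
                vn = v + h * (0.04 * v * v + 5.0 * v + 140.0 - u + Csa * i0)
            un = u + h * a * (b * v - u)
        elif model == "lizh":
            if fa:
                vn = v + h * (k1 * abs(v + 62.5) - k2 - u) + Cfa * (i1 - i0)
            else:
                vn = v + h * (k1 * abs(v + 62.5) - k2 - u + Csa * i0)
            un = u + h * a * (b * v - u)
        elif model == "qif":
            if fa:
                vn = v + h * (M1 * v * v) + Cfa * (i1 - i0)
            else:
                vn = v + h * (M1 * v * v + Csa * i0)
            un = u
        else:  # lqif
            if fa:
                vn = v + h * (M2 * abs(v)) + Cfa * (i1 - i0)
            else:
                vn = v + h * (M2 * abs(v) + Csa * i0)
            un = u
        if vn >= v_peak:
            trace[k] = v_peak
            spike_steps.append(k)
            if model in TWO_VAR_MODELS:
                v, u = c, un + d
            else:
                v, u = v_reset, un
        else:
            trace[k] = vn
            v, u = vn, un

    spike_times = (np.asarray(spike_steps, dtype=np.float64) + 1.0) * h
    return trace, spike_times
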