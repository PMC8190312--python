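"""Leaky integrate-and-fire with latency (LIFL) point-neuron model.

The neuron carries a dimensionless inner state ``S`` (0 = resting potential).
Below the threshold ``S_th = 1 + c`` the neuron is *passive* and ``S`` decays
between incoming pulses (leakage term ``T_l``).  At or above threshold it is
*active*: the spike is not emitted immediately but after a state-dependent
latency, the *time to fire*

    t_f = a / (S - 1) - b,

so further input received during the latency window anticipates, postpones or
cancels the emission.  ``S_max = 1 + a/b`` (infinite when ``b = 0``) is the
zero-latency ceiling; input driving ``S`` past it fires the neuron at once.

Everything here is a pure function of ``(NeuronParams, NeuronState)``; the
event engine owns time ordering and pulse routing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional

__all__ = [
    "DecayKind",
    "Mode",
    "NeuronParams",
    "NeuronState",
    "LiflDomainError",
    "time_to_fire",
    "state_from_time_to_fire",
    "leakage_term",
    "rise_term",
    "apply_pulse",
    "fire",
    "PulseOutcome",
    "FireResult",
]


class LiflDomainError(ValueError):
    """Raised when an operation is evaluated outside its mathematical domain."""


class DecayKind(str, Enum):
    """Underthreshold decay law selected by the ``U_t`` switch."""

    LINEAR = "linear"
    EXPONENTIAL = "exponential"


class Mode(str, Enum):
    PASSIVE = "passive"
    ACTIVE = "active"
    REFRACTORY = "refractory"


@dataclass(frozen=True)
class NeuronParams:
    """Constants of a LIFL neuron.

    Parameters
    ----------
    a : float
        Latency-curve distance constant (> 0); scales the hyperbola
        ``t_f = a/(S-1) - b``.
    b : float
        Latency-curve x-axis intersection (ms, >= 0).  ``b > 0`` gives a
        finite maximum state ``S_max = 1 + a/b``.
    c : float
        Threshold constant (> 0); ``S_th = 1 + c`` and the maximum latency is
        ``t_f_max = a/c - b``.  Requires ``c < a/b`` when ``b > 0``.
    D_exc, D_inh : float
        Underthreshold decay parameter applied when the arriving pulse comes
        through an excitatory / inhibitory synapse.  For the exponential law
        this is a time constant in ms; for the linear law ``1/D`` is a slope
        in 1/ms.
    A : float
        Pre-synaptic amplitude of *this* neuron's outgoing pulses; positive
        for excitatory neurons, negative for inhibitory ones.
    t_arp : float
        Absolute refractory period (ms, >= 0).
    N_b : int
        Burst cardinality; 1 = tonic spiking, > 1 emits a train of ``N_b``
        spikes spaced by ``IBI``.
    IBI : float
        Inter-burst interval (ms); only used when ``N_b > 1``.
    U_t : DecayKind
        Underthreshold decay law.
    latency : bool
        When False the spike-latency feature is disabled and the neuron fires
        the instant its state reaches ``S_th`` (plain LIF behaviour, the
        ``N_m`` model switch).
    """

    a: float = 1.0
    b: float = 0.0
    c: float = 0.01
    D_exc: float = 20.0
    D_inh: Optional[float] = None
    A: float = 1.0
    t_arp: float = 0.0
    N_b: int = 1
    IBI: float = 1.0
    U_t: DecayKind = DecayKind.EXPONENTIAL
    latency: bool = True

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError(f"a must be positive, got {self.a}")
        if self.b < 0:
            raise ValueError(f"b must be non-negative, got {self.b}")
        if self.c <= 0:
            raise ValueError(f"c must be positive, got {self.c}")
        if self.b > 0 and self.c >= self.a / self.b:
            raise ValueError(
                f"threshold constant must satisfy c < a/b (got c={self.c}, a/b={self.a / self.b})"
            )
        if self.D_exc <= 0:
            raise ValueError("D_exc must be positive")
        if self.D_inh is not None and self.D_inh <= 0:
            raise ValueError("D_inh must be positive")
        if self.A == 0:
            raise ValueError("pre-synaptic amplitude A must be nonzero")
        if self.t_arp < 0:
            raise ValueError("t_arp must be non-negative")
        if self.N_b < 1:
            raise ValueError("burst cardinality N_b must be >= 1")
        if self.N_b > 1 and self.IBI <= 0:
            raise ValueError("IBI must be positive when bursting")
        if not isinstance(self.U_t, DecayKind):
            object.__setattr__(self, "U_t", DecayKind(self.U_t))

    @property
    def S_th(self) -> float:
        """State threshold, ``1 + c``."""
        return 1.0 + self.c

    @property
    def S_max(self) -> float:
        """Zero-latency ceiling, ``1 + a/b`` (``inf`` when b = 0)."""
        return 1.0 + self.a / self.b if self.b > 0 else math.inf

    @property
    def t_f_max(self) -> float:
        """Upper bound of the spike latency, ``a/c - b``."""
        return self.a / self.c - self.b

    @property
    def is_excitatory(self) -> bool:
        return self.A > 0

    def decay_constant(self, pulse_amplitude: float) -> float:
        """Decay parameter selected by the type of the arriving synapse."""
        if pulse_amplitude < 0 and self.D_inh is not None:
            return self.D_inh
        return self.D_exc


@dataclass
class NeuronState:
    """Dynamic state of one neuron (event-driven: updated at event times only)."""

    S: float = 0.0
    t_last: float = 0.0
    mode: Mode = Mode.PASSIVE
    t_fire_scheduled: Optional[float] = None
    refractory_until: Optional[float] = None
    burst_remaining: int = 0

    def copy(self) -> "NeuronState":
        return replace(self)


# ---------------------------------------------------------------------------
# elementary terms


def time_to_fire(S: float, params: NeuronParams) -> float:
    """Spike latency implied by an overthreshold state (the firing equation).

    ``t_f = a/(S-1) - b``; strictly decreasing in S, bounded by
    ``t_f_max = a/c - b`` at ``S = S_th``.
    """
    if S < params.S_th:
        raise LiflDomainError(f"time_to_fire requires S >= S_th={params.S_th}, got {S}")
    if S >= params.S_max:
        raise LiflDomainError(f"time_to_fire requires S < S_max={params.S_max}, got {S}")
    if not params.latency:
        return 0.0
    return params.a / (S - 1.0) - params.b


def state_from_time_to_fire(t_f: float, params: NeuronParams) -> float:
    """Inverse of the firing equation: the state whose latency equals ``t_f``."""
    if not 0.0 <= t_f <= params.t_f_max:
        raise LiflDomainError(f"t_f must lie in [0, {params.t_f_max}], got {t_f}")
    return 1.0 + params.a / (t_f + params.b)


def leakage_term(S_p: float, dt: float, D: float, U_t: DecayKind) -> float:
    """Underthreshold loss of state over ``dt`` ms in passive mode.

    Exponential law: ``T_l = S_p (1 - exp(-dt/D))`` with D a time constant in
    ms.  Linear law: ``T_l = min(S_p, dt/D)`` with 1/D a slope in 1/ms.  Both
    are 0 at dt = 0, nondecreasing in dt, and never exceed ``S_p``.
    """
    if dt < 0:
        raise LiflDomainError(f"dt must be non-negative, got {dt}")
    if S_p <= 0.0 or dt == 0.0:
        return 0.0
    if DecayKind(U_t) is DecayKind.EXPONENTIAL:
        return S_p * -math.expm1(-dt / D)
    return min(S_p, dt / D)


def rise_term(S_p: float, dt: float, params: NeuronParams) -> float:
    """Overthreshold spontaneous growth of state over ``dt`` ms in active mode.

    ``T_r = (S_p - 1)^2 dt / (a - (S_p - 1) dt)``, the algebraic companion of
    the firing equation: advancing the state by ``T_r`` shortens the residual
    latency by exactly ``dt``.
    """
    if dt < 0:
        raise LiflDomainError(f"dt must be non-negative, got {dt}")
    if not params.latency:
        return 0.0
    x = S_p - 1.0
    den = params.a - x * dt
    if den <= 0:
        raise LiflDomainError(
            f"rise_term evaluated past the scheduled emission (S_p={S_p}, dt={dt})"
        )
    return x * x * dt / den


# ---------------------------------------------------------------------------
# state transitions


@dataclass(frozen=True)
class PulseOutcome:
    """Result of delivering one synaptic pulse.

    ``fire_now`` is set when the pulse drove the state to/past ``S_max`` (or
    past threshold with latency disabled) and the neuron must emit
    immediately.  ``schedule`` carries the new absolute emission time when the
    neuron is (still) active; ``cancel`` marks a previously pending emission
    that no longer holds (post-trigger inhibition).
    """

    fire_now: bool = False
    schedule: Optional[float] = None
    cancel: bool = False
    absorbed: bool = False  # pulse discarded by refractoriness


def _enter_mode(state: NeuronState, t_now: float, params: NeuronParams,
                was_active: bool) -> PulseOutcome:
    """Classify the freshly updated state and set mode / pending-fire fields."""
    if state.S < 0.0:
        state.S = 0.0
    if state.S >= params.S_max or (not params.latency and state.S >= params.S_th):
        # immediate generation; engine will call fire()
        state.mode = Mode.ACTIVE
        state.t_fire_scheduled = t_now
        return PulseOutcome(fire_now=True)
    if state.S >= params.S_th:
        t_f = time_to_fire(state.S, params)
        state.mode = Mode.ACTIVE
        state.t_fire_scheduled = t_now + t_f
        return PulseOutcome(schedule=state.t_fire_scheduled)
    state.mode = Mode.PASSIVE
    state.t_fire_scheduled = None
    return PulseOutcome(cancel=was_active)


def apply_pulse(state: NeuronState, t_now: float, pulse_amplitude: float,
                params: NeuronParams) -> PulseOutcome:
    """Deliver a synaptic pulse of amplitude ``A_i * W_ij`` at time ``t_now``.

    Mutates ``state`` in place and reports what the event engine must do with
    the neuron's pending firing event.  Pulses arriving strictly inside the
    refractory window are discarded; a pulse arriving exactly at its end is
    accepted (the neuron resumes passive mode at rest first).
    """
    if t_now < state.t_last - 1e-12:
        raise LiflDomainError(
            f"pulse at t={t_now} precedes last state update t={state.t_last}"
        )
    if state.mode is Mode.REFRACTORY:
        if state.refractory_until is not None and t_now < state.refractory_until:
            return PulseOutcome(absorbed=True)
        state.mode = Mode.PASSIVE
        state.S = 0.0
        state.t_last = state.refractory_until if state.refractory_until is not None else t_now
        state.refractory_until = None

    dt = t_now - state.t_last
    if dt < 0.0:
        dt = 0.0
    if state.mode is Mode.PASSIVE:
        D = params.decay_constant(pulse_amplitude)
        state.S = state.S - leakage_term(state.S, dt, D, params.U_t) + pulse_amplitude
        was_active = False
    else:  # ACTIVE
        state.S = state.S + rise_term(state.S, dt, params) + pulse_amplitude
        was_active = True
    state.t_last = t_now
    return _enter_mode(state, t_now, params, was_active)


@dataclass(frozen=True)
class FireResult:
    emission_times: tuple
    refractory_until: float


def fire(state: NeuronState, t_now: float, params: NeuronParams) -> FireResult:
    """Emit the scheduled spike (or burst train) at ``t_now`` and reset.

    Returns all emission times: ``t_now + k*IBI`` for ``k < N_b``.  Burst
    emissions are committed unconditionally; the neuron is insensitive to
    input from the first emission until ``t_arp`` after the last one, then
    resumes passive mode at rest.
    """
    if state.mode is not Mode.ACTIVE:
        raise LiflDomainError("fire() called on a neuron that is not active")
    emissions = tuple(t_now + k * params.IBI for k in range(params.N_b))
    state.S = 0.0
    state.t_last = t_now
    state.mode = Mode.REFRACTORY
    state.refractory_until = emissions[-1] + params.t_arp
    state.t_fire_scheduled = None
    state.burst_remaining = params.N_b - 1
    return FireResult(emission_times=emissions, refractory_until=state.refractory_until)
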