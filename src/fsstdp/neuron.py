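"""Postsynaptic neuron models.

Two neurons are provided:

* a conductance-based leaky integrate-and-fire (LIF) neuron with
  alpha-function synaptic conductances, used in all network simulations, and
* a linear Poisson neuron whose instantaneous rate is the weighted,
  delayed sum of presynaptic spikes, used to validate the mean-field theory.

Units follow the parameter table: membrane potential in mV, capacitance in
pF, resistance in MOhm, conductances in nS, conductance time constants in
ms.  Time arguments (``dt``) are in seconds everywhere in the public API.

The alpha conductance kernel follows the standard simulator convention:
a spike through synapse ``j`` contributes
``g(s) = g_hat * w_j * (s/tau) * exp(-s/tau)``, which rises from zero and
peaks at ``s = tau`` with value ``g_hat * w_j / e``.  It is realized
exactly by a pair of linear state variables ``(h, g)`` with
``h' = -h/tau`` and ``g' = (h - g)/tau``, advanced with the exact matrix
exponential of that 2x2 system; a spike adds an impulse ``g_hat * w_j``
to ``h``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "NeuronParams",
    "NeuronState",
    "LinearPoissonNeuron",
    "step_membrane",
    "inject_spikes",
    "linear_poisson_rate",
]


@dataclass(frozen=True)
class NeuronParams:
    """Conductance-based LIF constants (table defaults)."""

    c_m: float = 200.0        # membrane capacitance, pF
    r_m: float = 100.0        # membrane resistance, MOhm
    v_th: float = -54.0       # threshold potential, mV
    v_rest: float = -70.0     # resting potential, mV
    e_exc: float = 0.0        # excitatory reversal potential, mV
    e_inh: float = -70.0      # inhibitory reversal potential, mV
    g_hat_exc: float = 0.15   # excitatory conductance amplitude, nS
    g_hat_inh: float = 0.25   # inhibitory conductance amplitude, nS
    tau_exc: float = 5.0      # excitatory conductance time constant, ms
    tau_inh: float = 5.0      # inhibitory conductance time constant, ms

    def __post_init__(self) -> None:
        if not self.v_rest < self.v_th:
            raise ValueError("v_rest must lie below v_th")
        if not (self.e_inh <= self.v_rest < self.e_exc):
            raise ValueError("require e_inh <= v_rest < e_exc")
        for name in ("c_m", "r_m", "tau_exc", "tau_inh"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def g_leak(self) -> float:
        """Leak conductance in nS (1000 / R_m[MOhm])."""
        return 1000.0 / self.r_m


@dataclass
class NeuronState:
    """Mutable LIF state: membrane potential plus conductance pairs."""

    v: float
    g_exc: float = 0.0
    h_exc: float = 0.0  # auxiliary state feeding g_exc (alpha kernel)
    g_inh: float = 0.0
    h_inh: float = 0.0
    last_spike: Optional[float] = None

    @classmethod
    def at_rest(cls, params: NeuronParams) -> "NeuronState":
        return cls(v=params.v_rest)


def _propagate_alpha(g: float, h: float, dt_ms: float, tau_ms: float) -> Tuple[float, float]:
    """Exact one-step propagator of the (h, g) alpha-kernel pair."""
    d = math.exp(-dt_ms / tau_ms)
    return d * (g + (dt_ms / tau_ms) * h), d * h


def step_membrane(
    state: NeuronState, params: NeuronParams, dt: float, t: Optional[float] = None
) -> Tuple[NeuronState, bool]:
    """Advance the LIF neuron one time step of ``dt`` seconds.

    Conductances are propagated exactly, then the membrane potential takes
    one forward-Euler step.  If the updated potential reaches threshold a
    spike is emitted and the potential is reset to rest for the next step.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    dt_ms = dt * 1e3
    g_exc, h_exc = _propagate_alpha(state.g_exc, state.h_exc, dt_ms, params.tau_exc)
    g_inh, h_inh = _propagate_alpha(state.g_inh, state.h_inh, dt_ms, params.tau_inh)
    i_total = (
        params.g_leak * (params.v_rest - state.v)
        + g_exc * (params.e_exc - state.v)
        + g_inh * (params.e_inh - state.v)
    )  # pA
    v = state.v + dt_ms * i_total / params.c_m
    spiked = v >= params.v_th
    if spiked:
        v = params.v_rest
    new = NeuronState(
        v=v, g_exc=g_exc, h_exc=h_exc, g_inh=g_inh, h_inh=h_inh,
        last_spike=t if spiked else state.last_spike,
    )
    return new, spiked


def inject_spikes(
    state: NeuronState,
    params: NeuronParams,
    exc_weights: np.ndarray,
    exc_spikers: Sequence[int] = (),
    inh_spikers: Sequence[int] = (),
) -> NeuronState:
    """Add alpha-kernel conductance transients for this bin's spikes.

    Each spiking excitatory synapse ``j`` contributes a transient peaking
    at ``g_hat_exc * w_j / e``; inhibitory synapses have fixed weight 1.
    Transients superpose linearly, so simultaneous spikes simply add their
    impulses.
    """
    exc_weights = np.asarray(exc_weights, dtype=float)
    exc_spikers = np.asarray(exc_spikers, dtype=int)
    if exc_spikers.size and (
        exc_spikers.min() < 0 or exc_spikers.max() >= exc_weights.size
    ):
        raise IndexError("excitatory spiker index out of range")
    h_exc = state.h_exc
    if exc_spikers.size:
        h_exc += params.g_hat_exc * exc_weights[exc_spikers].sum()
    h_inh = state.h_inh + params.g_hat_inh * len(inh_spikers)
    return replace(state, h_exc=h_exc, h_inh=h_inh)


@dataclass(frozen=True)
class LinearPoissonNeuron:
    """Linear Poisson readout: rate is the weighted mean of delayed inputs."""

    n_pre: int
    epsilon: float = 5e-4  # constant delay, seconds

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError("epsilon must be non-negative")

    def rate(self, weights: np.ndarray, raster_slice: np.ndarray, dt: float) -> float:
        return linear_poisson_rate(weights, raster_slice, self.n_pre, dt)


def linear_poisson_rate(
    weights: np.ndarray, raster_slice: np.ndarray, n_pre: int, dt: float
) -> float:
    """Instantaneous output rate (Hz) given the spikes one delay ago.

    ``raster_slice`` is the binary spike occupancy at time ``t - epsilon``;
    the returned rate times ``dt`` is the Bernoulli probability of a
    postsynaptic spike in the current bin (always <= 1 for weights in [0,1]).
    """
    weights = np.asarray(weights, dtype=float)
    raster_slice = np.asarray(raster_slice, dtype=float)
    if weights.shape != raster_slice.shape:
        raise ValueError("weights and raster slice must have matching length")
    return float(weights @ raster_slice) / (n_pre * dt)
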