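"""STDP rules: FS-STDP and the comparison family.

All rules share the trace-based pair form

    dw_i = +lambda * f_plus(w_i)  * z_i    on a postsynaptic spike
    dw_i = -lambda * alpha * f_minus(w_i) * z_post  on a presynaptic spike

where ``z_i`` and ``z_post`` are exponentially filtered spike trains
(time constant ``tau_stdp``) that are incremented by 1 on each spike
(all-to-all interaction).  The rules differ only in the weight-dependence
factors:

==========  =================  ==========================
rule        f_plus(w)          alpha * f_minus(w)
==========  =================  ==========================
add         1                  alpha
mlt         1                  alpha * w
mlt/mlt     1 - w              alpha * w
nlta        (1-w)^mu           alpha * w^mu
nlta*       (w0+ - w)^mu       alpha * |w - w0-|^mu
fs          (w0+ - w)^mu_i     alpha * |w - w0-|^mu_i
==========  =================  ==========================

FS-STDP additionally gives every synapse its own exponent ``mu_i``
("spineness") that low-pass filters the synaptic efficacy,

    tau_mu * dmu_i/dt = -(mu_i - (w_i + a) / q),

so silent synapses (filopodia) relax to ``a/q ~ mu_filo`` and behave
near-additively, while strong synapses (spines) acquire soft bounds.
``a`` and ``q`` are derived from the interpretable targets
``(w_filo -> mu_filo, w_spine -> mu_spine)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence, Tuple

import numpy as np

__all__ = [
    "RULES",
    "PlasticityParams",
    "SynapsePopulation",
    "solve_aq",
    "f_plus",
    "f_minus",
    "decay_traces",
    "on_pre_spike",
    "on_post_spike",
    "update_mu",
    "clip_weights",
]

RULES = ("fs", "add", "mlt", "mltmlt", "nlta", "nlta_star")
RULE_CODES = {name: i for i, name in enumerate(RULES)}


def solve_aq(
    mu_filo: float, mu_spine: float, w_filo: float, w_spine: float
) -> Tuple[float, float]:
    """Solve the mu-map constants from the two target fixed points.

    Returns the unique ``(a, q)`` with ``(w_filo + a)/q = mu_filo`` and
    ``(w_spine + a)/q = mu_spine``.
    """
    if mu_filo == mu_spine:
        raise ValueError("mu_filo == mu_spine leaves the 2x2 system singular")
    a = (mu_spine * w_filo - mu_filo * w_spine) / (mu_filo - mu_spine)
    q = (w_filo + a) / mu_filo
    return a, q


@dataclass(frozen=True)
class PlasticityParams:
    """Learning-rule parameters (table defaults)."""

    rule: str = "fs"
    lam: float = 0.006          # learning rate
    alpha: float = 1.35         # potentiation/depression imbalance
    w0_plus: float = 1.0        # upper soft bound
    w0_minus: float = 0.5       # lower soft bound
    mu_fixed: float = 0.1       # exponent for nlta / nlta*
    mu_filo: float = 0.01       # target mu of filopodia
    mu_spine: float = 0.1       # target mu of spines
    w_filo: float = 0.1         # typical filopodium efficacy
    w_spine: float = 0.75       # typical spine efficacy
    tau_stdp: float = 0.020     # trace time constant, s
    tau_mu: float = 20.0        # spineness time constant, s
    w_min: float = 0.0
    w_max: float = 1.0

    def __post_init__(self) -> None:
        if self.rule not in RULES:
            raise ValueError(f"unknown rule {self.rule!r}; expected one of {RULES}")
        if not (self.w_min <= self.w0_minus < self.w0_plus <= self.w_max):
            raise ValueError("require w_min <= w0_minus < w0_plus <= w_max")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.tau_stdp <= 0 or self.tau_mu <= 0:
            raise ValueError("time constants must be positive")

    @property
    def aq(self) -> Tuple[float, float]:
        return solve_aq(self.mu_filo, self.mu_spine, self.w_filo, self.w_spine)

    def mu_equilibrium(self, w) -> np.ndarray:
        """Fixed point of the spineness filter at constant efficacy w."""
        a, q = self.aq
        return np.maximum((np.asarray(w, dtype=float) + a) / q, 0.0)


@dataclass
class SynapsePopulation:
    """Plastic-synapse state: weights, spineness, and STDP traces."""

    w: np.ndarray
    mu: np.ndarray
    z_pre: np.ndarray
    z_post: float = 0.0

    @classmethod
    def initial(cls, n: int, w_init: float = 0.3, mu_init: float = 0.0) -> "SynapsePopulation":
        return cls(
            w=np.full(n, float(w_init)),
            mu=np.full(n, float(mu_init)),
            z_pre=np.zeros(n),
        )

    @property
    def n(self) -> int:
        return self.w.size

    def copy(self) -> "SynapsePopulation":
        return SynapsePopulation(
            w=self.w.copy(), mu=self.mu.copy(), z_pre=self.z_pre.copy(),
            z_post=self.z_post,
        )


def _mu_vector(pop: SynapsePopulation, params: PlasticityParams, idx=None) -> np.ndarray:
    """Effective exponent per synapse for the rule in force."""
    if params.rule == "fs":
        mu = pop.mu if idx is None else pop.mu[idx]
    else:
        n = pop.n if idx is None else np.size(idx)
        mu = np.full(n, params.mu_fixed)
    return mu


def f_plus(w, mu, params: PlasticityParams) -> np.ndarray:
    """Potentiation weight-dependence factor (cooperation factor)."""
    w = np.asarray(w, dtype=float)
    rule = params.rule
    if rule in ("add", "mlt"):
        return np.ones_like(w)
    if rule == "mltmlt":
        return 1.0 - w
    if rule == "nlta":
        return np.power(np.maximum(1.0 - w, 0.0), mu)
    # nlta* and fs share the soft-bounded form
    return np.power(np.maximum(params.w0_plus - w, 0.0), mu)


def f_minus(w, mu, params: PlasticityParams) -> np.ndarray:
    """Depression weight-dependence factor, excluding the alpha prefactor."""
    w = np.asarray(w, dtype=float)
    rule = params.rule
    if rule == "add":
        return np.ones_like(w)
    if rule in ("mlt", "mltmlt"):
        return w.copy()
    if rule == "nlta":
        return np.power(np.maximum(w, 0.0), mu)
    return np.power(np.abs(w - params.w0_minus), mu)


def decay_traces(pop: SynapsePopulation, dt: float, tau_stdp: float) -> SynapsePopulation:
    """Exact exponential decay of all traces over ``dt`` seconds."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    d = math.exp(-dt / tau_stdp)
    pop.z_pre *= d
    pop.z_post *= d
    return pop


def on_pre_spike(
    pop: SynapsePopulation, params: PlasticityParams, spiker_indices
) -> SynapsePopulation:
    """Apply depression to spiking synapses, then bump their traces."""
    idx = np.asarray(spiker_indices, dtype=int)
    if idx.size == 0:
        return pop
    if idx.min() < 0 or idx.max() >= pop.n:
        raise IndexError("presynaptic spiker index out of range")
    mu = _mu_vector(pop, params, idx)
    dw = params.lam * params.alpha * f_minus(pop.w[idx], mu, params) * pop.z_post
    pop.w[idx] = np.clip(pop.w[idx] - dw, params.w_min, params.w_max)
    pop.z_pre[idx] += 1.0
    return pop


def on_post_spike(pop: SynapsePopulation, params: PlasticityParams) -> SynapsePopulation:
    """Apply potentiation to every synapse, then bump the postsynaptic trace."""
    mu = _mu_vector(pop, params)
    dw = params.lam * f_plus(pop.w, mu, params) * pop.z_pre
    pop.w = np.clip(pop.w + dw, params.w_min, params.w_max)
    pop.z_post += 1.0
    return pop


def update_mu(pop: SynapsePopulation, params: PlasticityParams, dt: float) -> SynapsePopulation:
    """Relax spineness toward (w + a)/q, exactly over ``dt``, clipped at 0.

    The relaxation treats the current weight as constant over the step,
    which is exact between plasticity events.  The clip at zero is required
    because ``a/q`` is negative for the default parameters and a negative
    exponent would invert the soft-bound geometry.
    """
    if params.rule != "fs":
        raise ValueError("spineness dynamics are specific to the fs rule")
    if dt <= 0:
        raise ValueError("dt must be positive")
    a, q = params.aq
    target = (pop.w + a) / q
    d = math.exp(-dt / params.tau_mu)
    pop.mu = np.maximum(target + (pop.mu - target) * d, 0.0)
    return pop


def clip_weights(pop: SynapsePopulation, params: PlasticityParams) -> SynapsePopulation:
    """Hard clip of efficacies to [w_min, w_max]."""
    np.clip(pop.w, params.w_min, params.w_max, out=pop.w)
    return pop
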