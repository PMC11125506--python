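"""Mean-field theory of synaptic competition and its stochastic oracle.

For a linear Poisson readout neuron driven by the rank-1 correlated input
family, the ensemble-average weight velocity is

    dw_i/dt = (lam * tau * r^2 / N) *
              [ -Delta_f(w_i) * sum_j w_j  +  f_plus(w_i) * sum_j w_j C+_ij ]

with the *competition factor* ``Delta_f = f_minus - f_plus`` (with the
depression imbalance ``alpha`` folded into ``f_minus``) scaling the
correlation-independent, depressing interaction, the *cooperation factor*
``f_plus`` scaling the correlation-dependent potentiating interaction, and
the integrated normalized cross-correlation ``C+_ij = c_i c_j / (tau * r)``
for distinct trains.  The self-term kept in the j-sum is
``C+_ii = 1 / (tau * r)``: a Poisson train carries a delta at zero lag in
its own normalized autocorrelation irrespective of ``c_i``, so a synapse
always cooperates fully with itself; for small presynaptic pools this
term is not negligible.

Sign convention: ``Delta_f = f_minus - f_plus`` throughout, so that with
``alpha > 1`` competition corresponds to ``Delta_f > 0`` entering the
velocity with a minus sign.

This module provides the factors per rule, the analytic and empirical
``C+``, the mean-field right-hand side and its integrator, and a stochastic
linear-Poisson simulation that serves as an independent check of the theory
at small learning rates.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Tuple

import numpy as np

from .inputgen import CorrelationStructure, SpikeRaster, sample_spike_bins
from .plasticity import PlasticityParams, f_minus as _fm, f_plus as _fp

__all__ = [
    "MeanFieldSystem",
    "factors",
    "cij_plus",
    "empirical_cij_plus",
    "meanfield_rhs",
    "integrate_meanfield",
    "decompose_interactions",
    "simulate_linear_poisson",
]


def factors(
    rule: str,
    w,
    mu,
    alpha: float,
    w0_minus: float = 0.5,
    w0_plus: float = 1.0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Cooperation factor f_plus(w) and competition factor Delta_f(w).

    ``Delta_f = alpha * f_minus_form(w) - f_plus(w)``, vectorized over ``w``
    (and ``mu`` for the exponent rules).
    """
    params = PlasticityParams(
        rule=rule, alpha=alpha, w0_minus=w0_minus, w0_plus=w0_plus,
        mu_fixed=np.nan,
    )
    w = np.asarray(w, dtype=float)
    mu = np.asarray(mu, dtype=float)
    fp = _fp(w, mu, params)
    delta_f = alpha * _fm(w, mu, params) - fp
    return fp, delta_f


def cij_plus(c_i: float, c_j: float, tau_stdp: float, r: float) -> float:
    """Analytic integrated normalized cross-correlation c_i*c_j/(tau*r)."""
    if r <= 0 or tau_stdp <= 0:
        raise ValueError("rate and tau_stdp must be positive")
    return c_i * c_j / (tau_stdp * r)


def empirical_cij_plus(
    raster: SpikeRaster,
    i: int,
    j: int,
    tau: float,
    epsilon: float = 0.0,
    max_lag: Optional[float] = None,
) -> float:
    """Estimate C+_ij from a raster by integrating the lagged coincidence
    rate against the exponential learning kernel.

    The normalized cross-correlation at lag ``k*dt`` is estimated from
    binned cross-products; the kernel integral is taken as a Riemann sum
    over non-negative lags, shifted by the delay ``epsilon``.
    """
    dt = raster.dt
    xi = raster.bins[:, i].astype(float)
    xj = raster.bins[:, j].astype(float)
    r_i = xi.mean() / dt
    r_j = xj.mean() / dt
    if r_i == 0 or r_j == 0:
        raise ValueError("cannot normalize the cross-correlation of a silent train")
    if max_lag is None:
        max_lag = 10.0 * tau
    n_lags = int(round(max_lag / dt))
    shift = int(round(epsilon / dt))
    total = 0.0
    n_bins = raster.n_bins
    for k in range(n_lags):
        lag = k - shift  # Gamma0 evaluated at k*dt - epsilon
        if lag < 0 or lag >= n_bins:
            continue
        if lag == 0:
            coinc = float(xi @ xj)
            n_pairs = n_bins
        else:
            coinc = float(xi[:-lag] @ xj[lag:])
            n_pairs = n_bins - lag
        # density-like estimate of Gamma0 at this lag (the zero-lag bin
        # carries the delta mass divided by dt)
        gamma0 = coinc / (n_pairs * dt * dt * r_i * r_j) - 1.0
        total += (dt / tau) * np.exp(-k * dt / tau) * gamma0
    return total


@dataclass
class MeanFieldSystem:
    """State and constants for the mean-field weight dynamics."""

    w: np.ndarray
    structure: CorrelationStructure
    params: PlasticityParams
    r_pre: float = 30.0
    epsilon: float = 5e-4
    mu: Optional[np.ndarray] = None  # spineness (fs rule); defaults below

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if self.w.shape != self.structure.c.shape:
            raise ValueError("weight vector and structure must have equal length")
        if np.any(self.w < 0) or np.any(self.w > 1):
            raise ValueError("weights must lie in [0, 1]")
        if self.mu is None:
            if self.params.rule == "fs":
                self.mu = self.params.mu_equilibrium(self.w)
            else:
                self.mu = np.full(self.w.size, self.params.mu_fixed)
        else:
            self.mu = np.asarray(self.mu, dtype=float)

    @property
    def n_pre(self) -> int:
        return self.w.size

    @property
    def prefactor(self) -> float:
        """Effective learning rate lam * tau_stdp * r^2 / N_pre."""
        p = self.params
        return p.lam * p.tau_stdp * self.r_pre**2 / self.n_pre


def decompose_interactions(system: MeanFieldSystem) -> Tuple[np.ndarray, np.ndarray]:
    """Correlation-independent and correlation-dependent interactions.

    Returns the two bracketed terms of the mean-field velocity,
    ``-Delta_f(w_i) * sum_j w_j`` and ``f_plus(w_i) * sum_j w_j C+_ij``,
    per synapse, without the effective-learning-rate prefactor.
    """
    p = system.params
    fp, delta_f = factors(
        p.rule, system.w, system.mu, p.alpha, p.w0_minus, p.w0_plus
    )
    c = system.structure.c
    w_total = system.w.sum()
    # off-diagonal C+_ij = c_i c_j/(tau r); self-term C+_ii = 1/(tau r)
    coop_sum = (
        c * (system.w @ c) - c**2 * system.w + system.w
    ) / (p.tau_stdp * system.r_pre)
    return -delta_f * w_total, fp * coop_sum


def meanfield_rhs(system: MeanFieldSystem) -> np.ndarray:
    """Mean-field weight velocity (per second) for the current state."""
    indep, dep = decompose_interactions(system)
    return system.prefactor * (indep + dep)


def integrate_meanfield(
    system: MeanFieldSystem, duration: float, step: float
) -> Tuple[np.ndarray, np.ndarray]:
    """Forward-Euler trajectory of the mean-field ODE with clipping.

    For the fs rule the spineness variables are co-integrated with their
    low-pass dynamics.  Returns ``(times, trajectory)`` with one weight row
    per recorded instant (including t = 0).
    """
    if step <= 0:
        raise ValueError("step must be positive")
    n_steps = int(round(duration / step))
    p = system.params
    sys = replace_system(system, system.w.copy(), None if p.rule == "fs" else system.mu)
    if p.rule == "fs":
        sys.mu = system.mu.copy()
    traj = np.empty((n_steps + 1, sys.n_pre))
    traj[0] = sys.w
    a, q = p.aq
    for k in range(n_steps):
        sys.w = np.clip(sys.w + step * meanfield_rhs(sys), 0.0, 1.0)
        if p.rule == "fs":
            target = (sys.w + a) / q
            sys.mu = np.maximum(
                target + (sys.mu - target) * np.exp(-step / p.tau_mu), 0.0
            )
        traj[k + 1] = sys.w
    times = np.arange(n_steps + 1) * step
    return times, traj


def replace_system(system: MeanFieldSystem, w, mu) -> MeanFieldSystem:
    return MeanFieldSystem(
        w=w, structure=system.structure, params=system.params,
        r_pre=system.r_pre, epsilon=system.epsilon, mu=mu,
    )


def simulate_linear_poisson(
    system: MeanFieldSystem,
    duration: float,
    dt: float,
    n_runs: int,
    seed,
    warmup: float = 0.2,
) -> Tuple[np.ndarray, np.ndarray]:
    """Stochastic linear-Poisson ensemble: mean weight velocity and its SE.

    Simulates ``n_runs`` independent realizations of the spiking system
    from the same initial weights, applying the trace-based STDP rule
    event-by-event, and returns the ensemble mean of ``Delta_w / duration``
    per synapse together with its standard error.  During the initial
    ``warmup`` seconds the traces and postsynaptic process run but weights
    are held fixed, so the measurement starts from stationary traces.  At
    small learning rates this estimates :func:`meanfield_rhs` up to O(dt)
    discretization and O(lam * duration) trajectory curvature.
    """
    p = system.params
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = system.n_pre
    c = system.structure.c
    m = system.r_pre * dt
    if m >= 1:
        raise ValueError("rate*dt must be < 1")
    warm_steps = int(round(warmup / dt))
    steps = warm_steps + int(round(duration / dt))
    decay = np.exp(-dt / p.tau_stdp)
    mu_decay = np.exp(-dt / p.tau_mu)
    a, q = (p.aq if p.rule == "fs" else (0.0, 1.0))

    w = np.tile(system.w, (n_runs, 1))
    w0 = w.copy()
    mu = np.tile(system.mu, (n_runs, 1))
    z_pre = np.zeros((n_runs, n))
    z_post = np.zeros(n_runs)
    x_prev = np.zeros((n_runs, n))

    for step in range(steps):
        plastic = step >= warm_steps
        ref = rng.random(n_runs) < m
        prob = np.where(ref[:, None], m + c * (1.0 - m), m * (1.0 - c))
        x = (rng.random((n_runs, n)) < prob).astype(float)
        z_post *= decay
        z_pre *= decay
        # depression on presynaptic spikes (z_post from before this bin's post)
        if plastic:
            dw = p.lam * p.alpha * _fm(w, mu, p) * z_post[:, None] * x
            np.clip(w - dw, p.w_min, p.w_max, out=w)
        z_pre += x
        # postsynaptic draw from the delayed weighted input
        p_post = (w * x_prev).sum(axis=1) / n
        post = rng.random(n_runs) < p_post
        if post.any():
            rows = post
            if plastic:
                w[rows] = np.clip(
                    w[rows] + p.lam * _fp(w[rows], mu[rows], p) * z_pre[rows],
                    p.w_min, p.w_max,
                )
            z_post[rows] += 1.0
        if plastic and p.rule == "fs":
            target = (w + a) / q
            mu = np.maximum(target + (mu - target) * mu_decay, 0.0)
        x_prev = x

    velocities = (w - w0) / duration
    mean = velocities.mean(axis=0)
    se = velocities.std(axis=0, ddof=1) / np.sqrt(n_runs)
    return mean, se
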