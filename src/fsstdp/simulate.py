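"""Clock-driven simulation of the plastic feed-forward network.

One conductance-based LIF neuron receives ``n`` plastic excitatory Poisson
inputs (correlated through a :class:`~fsstdp.inputgen.CorrelationStructure`)
and a fixed pool of independent inhibitory Poisson inputs at unit weight.

The integration loop advances in bins of ``dt`` with the following order
of events inside each bin:

1. decay the STDP traces;
2. process presynaptic spikes: depression (using the postsynaptic trace
   from before any same-bin postsynaptic spike), then bump the presynaptic
   trace, then inject the conductance transient at the updated weight;
3. propagate conductances and take one forward-Euler membrane step; a
   threshold crossing emits a spike and resets to rest;
4. on a postsynaptic spike, apply potentiation using the just-bumped
   presynaptic traces (a same-bin pre->post pairing counts as causal
   potentiation), then bump the postsynaptic trace;
5. relax the spineness variable (FS rule only).

The hot loop is compiled with numba; input rasters are drawn in one-second
blocks so memory stays bounded.  The same semantics are available without
compilation in :func:`run_network_reference`, built directly from the
`neuron` and `plasticity` module operations, for cross-checking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from numba import njit

from .inputgen import CorrelationStructure, sample_spike_bins
from .neuron import NeuronParams, NeuronState, inject_spikes, step_membrane
from .plasticity import (
    RULE_CODES,
    PlasticityParams,
    SynapsePopulation,
    clip_weights,
    decay_traces,
    on_post_spike,
    on_pre_spike,
    update_mu,
)
from .recording import SimulationRecord

__all__ = ["Phase", "SimParams", "run_network", "run_network_reference"]


@dataclass(frozen=True)
class Phase:
    """One protocol phase: a fixed correlation structure at a fixed rate."""

    structure: CorrelationStructure
    rate: float = 30.0       # presynaptic excitatory rate, Hz
    duration: float = 200.0  # seconds
    plastic: bool = True

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("phase duration must be positive")


@dataclass(frozen=True)
class SimParams:
    """Integration and recording constants (table defaults)."""

    dt: float = 5e-4          # integration timestep, s
    record_every: float = 1.0  # weight/spineness recording period, s
    w_init: float = 0.3       # initial synaptic efficacy
    mu_init: float = 0.0      # initial spineness
    n_inh: int = 200          # inhibitory pool size
    r_inh: float = 10.0       # inhibitory rate, Hz

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.record_every <= 0:
            raise ValueError("dt and record_every must be positive")


@njit(cache=True)
def _fplus(w, mu, rule, w0p):
    if rule == 1 or rule == 2:  # add, mlt
        return 1.0
    if rule == 3:  # mlt/mlt
        return 1.0 - w
    if rule == 4:  # nlta
        return max(1.0 - w, 0.0) ** mu
    return max(w0p - w, 0.0) ** mu  # nlta*, fs


@njit(cache=True)
def _fminus(w, mu, rule, w0m):
    if rule == 1:  # add
        return 1.0
    if rule == 2 or rule == 3:  # mlt, mlt/mlt
        return w
    if rule == 4:  # nlta
        return max(w, 0.0) ** mu
    return abs(w - w0m) ** mu  # nlta*, fs


@njit(cache=True)
def _simulate_chunk(
    exc_spikes,      # (steps, n) bool
    inh_counts,      # (steps,) float64
    w, mu, z_pre,    # (n,) float64, mutated in place
    scal,            # [v, g_e, h_e, g_i, h_i, z_post] float64, mutated
    post_bins,       # (steps,) int64 scratch for postsynaptic spike bins
    rule, plastic,
    lam, alpha, w0m, w0p, mu_fixed, a_over_q_num, q_inv,
    decay_stdp, mu_decay,
    dt_ms, c_m, g_leak, v_rest, v_th, e_exc, e_inh,
    amp_e, amp_i, d_e, r_e, d_i, r_i,
):
    steps, n = exc_spikes.shape
    v = scal[0]
    g_e = scal[1]
    h_e = scal[2]
    g_i = scal[3]
    h_i = scal[4]
    z_post = scal[5]
    n_post = 0
    do_mu = plastic and rule == 0
    for t in range(steps):
        z_post *= decay_stdp
        s_w = 0.0
        for i in range(n):
            z_pre[i] *= decay_stdp
            if exc_spikes[t, i]:
                if plastic:
                    m = mu[i] if rule == 0 else mu_fixed
                    wi = w[i] - lam * alpha * _fminus(w[i], m, rule, w0m) * z_post
                    if wi < 0.0:
                        wi = 0.0
                    elif wi > 1.0:
                        wi = 1.0
                    w[i] = wi
                z_pre[i] += 1.0
                s_w += w[i]
        # conductance propagation (exact for the alpha-kernel pair)
        g_e = d_e * (g_e + r_e * h_e)
        h_e = d_e * h_e
        g_i = d_i * (g_i + r_i * h_i)
        h_i = d_i * h_i
        # inject this bin's spikes (affect the membrane from the next bin)
        h_e += amp_e * s_w
        h_i += amp_i * inh_counts[t]
        # forward-Euler membrane step
        i_tot = g_leak * (v_rest - v) + g_e * (e_exc - v) + g_i * (e_inh - v)
        v = v + dt_ms * i_tot / c_m
        if v >= v_th:
            v = v_rest
            post_bins[n_post] = t
            n_post += 1
            if plastic:
                for i in range(n):
                    m = mu[i] if rule == 0 else mu_fixed
                    wi = w[i] + lam * _fplus(w[i], m, rule, w0p) * z_pre[i]
                    if wi < 0.0:
                        wi = 0.0
                    elif wi > 1.0:
                        wi = 1.0
                    w[i] = wi
            z_post += 1.0
        if do_mu:
            for i in range(n):
                tgt = (w[i] + a_over_q_num) * q_inv
                m = tgt + (mu[i] - tgt) * mu_decay
                mu[i] = m if m > 0.0 else 0.0
    scal[0] = v
    scal[1] = g_e
    scal[2] = h_e
    scal[3] = g_i
    scal[4] = h_i
    scal[5] = z_post
    return n_post


def run_network(
    phases: Sequence[Phase],
    pparams: PlasticityParams,
    nparams: Optional[NeuronParams] = None,
    sim: Optional[SimParams] = None,
    seed: int = 0,
    pop: Optional[SynapsePopulation] = None,
) -> SimulationRecord:
    """Simulate the full feed-forward network over a list of phases.

    Parameters
    ----------
    phases : sequence of Phase
        Executed in order; the correlation structure switches instantaneously
        at phase boundaries.
    pop : SynapsePopulation, optional
        Starting synaptic state; defaults to the homogeneous initial
        condition ``w = w_init``, ``mu = mu_init``.
    seed : int or numpy.random.Generator
        Drives all input sampling (excitatory raster and inhibitory pool).

    Returns
    -------
    SimulationRecord
        Weight and spineness snapshots every ``record_every`` seconds
        (including t = 0) plus postsynaptic spike times.
    """
    if not phases:
        raise ValueError("need at least one phase")
    nparams = nparams or NeuronParams()
    sim = sim or SimParams()
    n = phases[0].structure.n
    for ph in phases:
        if ph.structure.n != n:
            raise ValueError("all phases must share the presynaptic count")
    if pop is None:
        pop = SynapsePopulation.initial(n, sim.w_init, sim.mu_init)
    else:
        pop = pop.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    dt = sim.dt
    steps_per_chunk = int(round(sim.record_every / dt))
    a, q = pparams.aq
    rule = RULE_CODES[pparams.rule]
    decay_stdp = math.exp(-dt / pparams.tau_stdp)
    mu_decay = math.exp(-dt / pparams.tau_mu)
    dt_ms = dt * 1e3
    d_syn = math.exp(-dt_ms / nparams.tau_exc)
    d_inh = math.exp(-dt_ms / nparams.tau_inh)

    scal = np.array([nparams.v_rest, 0.0, 0.0, 0.0, 0.0, 0.0])
    post_bins = np.empty(steps_per_chunk, dtype=np.int64)
    p_inh = sim.r_inh * dt

    times = [0.0]
    w_snap = [pop.w.copy()]
    mu_snap = [pop.mu.copy()]
    post_times: List[np.ndarray] = []
    t_offset = 0.0
    global_bin = 0

    for ph in phases:
        n_chunks = int(round(ph.duration / sim.record_every))
        if abs(n_chunks * sim.record_every - ph.duration) > 1e-9 or n_chunks < 1:
            raise ValueError("phase duration must be a positive multiple of record_every")
        m = ph.rate * dt
        if m >= 1.0:
            raise ValueError("rate*dt must be < 1")
        c = np.ascontiguousarray(ph.structure.c)
        for _ in range(n_chunks):
            exc = sample_spike_bins(c, m, steps_per_chunk, rng)
            inh = rng.binomial(sim.n_inh, p_inh, size=steps_per_chunk).astype(np.float64)
            n_post = _simulate_chunk(
                exc, inh, pop.w, pop.mu, pop.z_pre, scal, post_bins,
                rule, ph.plastic,
                pparams.lam, pparams.alpha, pparams.w0_minus, pparams.w0_plus,
                pparams.mu_fixed, a, 1.0 / q,
                decay_stdp, mu_decay,
                dt_ms, nparams.c_m, nparams.g_leak, nparams.v_rest, nparams.v_th,
                nparams.e_exc, nparams.e_inh,
                nparams.g_hat_exc, nparams.g_hat_inh,
                d_syn, dt_ms / nparams.tau_exc, d_inh, dt_ms / nparams.tau_inh,
            )
            if n_post:
                post_times.append((global_bin + post_bins[:n_post]) * dt)
            global_bin += steps_per_chunk
            t_offset += sim.record_every
            times.append(t_offset)
            w_snap.append(pop.w.copy())
            mu_snap.append(pop.mu.copy())
        pop.z_post = scal[5]

    return SimulationRecord(
        times=np.asarray(times),
        w=np.asarray(w_snap),
        mu=np.asarray(mu_snap),
        post_spike_times=(
            np.concatenate(post_times) if post_times else np.empty(0)
        ),
        final_pop=pop,
    )


def run_network_reference(
    phases: Sequence[Phase],
    pparams: PlasticityParams,
    nparams: Optional[NeuronParams] = None,
    sim: Optional[SimParams] = None,
    seed: int = 0,
    pop: Optional[SynapsePopulation] = None,
) -> SimulationRecord:
    """Uncompiled simulator built from the neuron/plasticity primitives.

    Semantically identical to :func:`run_network` (same event ordering and
    the same random stream), but orders of magnitude slower; intended for
    short cross-validation runs only.
    """
    nparams = nparams or NeuronParams()
    sim = sim or SimParams()
    n = phases[0].structure.n
    if pop is None:
        pop = SynapsePopulation.initial(n, sim.w_init, sim.mu_init)
    else:
        pop = pop.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    state = NeuronState.at_rest(nparams)
    dt = sim.dt
    steps_per_chunk = int(round(sim.record_every / dt))
    p_inh = sim.r_inh * dt

    times = [0.0]
    w_snap = [pop.w.copy()]
    mu_snap = [pop.mu.copy()]
    post_times = []
    t = 0.0

    for ph in phases:
        n_chunks = int(round(ph.duration / sim.record_every))
        m = ph.rate * dt
        for _ in range(n_chunks):
            exc = sample_spike_bins(ph.structure.c, m, steps_per_chunk, rng)
            inh = rng.binomial(sim.n_inh, p_inh, size=steps_per_chunk)
            for k in range(steps_per_chunk):
                decay_traces(pop, dt, pparams.tau_stdp)
                spikers = np.nonzero(exc[k])[0]
                if ph.plastic:
                    on_pre_spike(pop, pparams, spikers)
                else:
                    pop.z_pre[spikers] += 1.0
                state, spiked = step_membrane(state, nparams, dt, t)
                # inject after propagation: this bin's spikes reach the
                # membrane from the next bin, as in the compiled kernel
                state = inject_spikes(
                    state, nparams, pop.w, spikers, range(int(inh[k]))
                )
                if spiked:
                    post_times.append(t)
                    if ph.plastic:
                        on_post_spike(pop, pparams)
                    else:
                        pop.z_post += 1.0
                if ph.plastic and pparams.rule == "fs":
                    update_mu(pop, pparams, dt)
                t += dt
            t = round(t / dt) * dt  # keep the clock on the grid
            times.append(round(t, 9))
            w_snap.append(pop.w.copy())
            mu_snap.append(pop.mu.copy())

    return SimulationRecord(
        times=np.asarray(times),
        w=np.asarray(w_snap),
        mu=np.asarray(mu_snap),
        post_spike_times=np.asarray(post_times),
        final_pop=pop,
    )
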