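"""STDP rules, traces, the spineness map, and rule reductions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fsstdp.plasticity import (
    PlasticityParams,
    SynapsePopulation,
    clip_weights,
    decay_traces,
    on_post_spike,
    on_pre_spike,
    solve_aq,
    update_mu,
)

# oracle: independent 2x2 linear solve of (w_filo + a)/q = mu_filo,
# (w_spine + a)/q = mu_spine for the table targets
AQ_ORACLE = (-0.02777777777777779, 7.222222222222221)


class TestSolveAQ:
    def test_matches_linear_solve_oracle(self):
        a, q = solve_aq(0.01, 0.1, 0.1, 0.75)
        assert a == pytest.approx(AQ_ORACLE[0], rel=1e-12)
        assert q == pytest.approx(AQ_ORACLE[1], rel=1e-12)

    @given(
        mu_f=st.floats(0.001, 0.2),
        mu_s=st.floats(0.25, 0.9),
        w_f=st.floats(0.01, 0.3),
        w_s=st.floats(0.5, 1.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_round_trip_identity(self, mu_f, mu_s, w_f, w_s):
        a, q = solve_aq(mu_f, mu_s, w_f, w_s)
        assert (w_f + a) / q == pytest.approx(mu_f, rel=1e-9)
        assert (w_s + a) / q == pytest.approx(mu_s, rel=1e-9)

    def test_equal_targets_singular(self):
        with pytest.raises(ValueError):
            solve_aq(0.1, 0.1, 0.1, 0.75)


class TestTraces:
    def test_exact_exponential_decay(self, pparams):
        pop = SynapsePopulation.initial(3)
        pop.z_pre[:] = 1.0
        pop.z_post = 1.0
        decay_traces(pop, pparams.tau_stdp, pparams.tau_stdp)
        assert pop.z_post == pytest.approx(math.exp(-1))
        np.testing.assert_allclose(pop.z_pre, math.exp(-1))

    def test_zero_stays_zero(self, pparams):
        pop = SynapsePopulation.initial(2)
        decay_traces(pop, 0.01, pparams.tau_stdp)
        assert pop.z_post == 0.0
        assert np.all(pop.z_pre == 0.0)

    def test_semigroup_property(self, pparams):
        a = SynapsePopulation.initial(1)
        b = SynapsePopulation.initial(1)
        a.z_pre[:] = b.z_pre[:] = 0.7
        decay_traces(a, 0.02, pparams.tau_stdp)
        decay_traces(b, 0.01, pparams.tau_stdp)
        decay_traces(b, 0.01, pparams.tau_stdp)
        assert a.z_pre[0] == pytest.approx(b.z_pre[0], rel=1e-15)


class TestSpikeUpdates:
    def test_fs_depression_vanishes_at_lower_bound(self, pparams):
        pop = SynapsePopulation.initial(2, w_init=pparams.w0_minus)
        pop.mu[:] = 0.1
        pop.z_post = 2.0
        on_pre_spike(pop, pparams, [0, 1])
        np.testing.assert_array_equal(pop.w, pparams.w0_minus)
        np.testing.assert_array_equal(pop.z_pre, 1.0)

    def test_no_depression_without_postsynaptic_trace(self):
        for rule in ("fs", "add", "mlt", "mltmlt", "nlta", "nlta_star"):
            p = PlasticityParams(rule=rule)
            pop = SynapsePopulation.initial(1, w_init=0.7)
            pop.z_post = 0.0
            on_pre_spike(pop, p, [0])
            assert pop.w[0] == 0.7

    def test_mlt_depression_scales_linearly_with_weight(self):
        p = PlasticityParams(rule="mlt")
        pop = SynapsePopulation.initial(2)
        pop.w[:] = [0.2, 0.6]
        pop.z_post = 1.0
        w_before = pop.w.copy()
        on_pre_spike(pop, p, [0, 1])
        dw = w_before - pop.w
        assert dw[1] / dw[0] == pytest.approx(3.0)

    def test_fs_potentiation_vanishes_at_upper_bound(self, pparams):
        pop = SynapsePopulation.initial(1, w_init=1.0)
        pop.mu[:] = 0.1
        pop.z_pre[:] = 2.0
        on_post_spike(pop, pparams)
        assert pop.w[0] == 1.0
        assert pop.z_post == 1.0

    def test_no_potentiation_without_presynaptic_trace(self, pparams):
        pop = SynapsePopulation.initial(3)
        on_post_spike(pop, pparams)
        np.testing.assert_array_equal(pop.w, 0.3)

    def test_out_of_range_spiker_rejected(self, pparams):
        pop = SynapsePopulation.initial(3)
        with pytest.raises(IndexError):
            on_pre_spike(pop, pparams, [3])


class TestSpinenessDynamics:
    def test_fixed_points_of_the_mu_map(self, pparams):
        a, q = pparams.aq
        pop = SynapsePopulation.initial(2)
        pop.w[:] = [pparams.w_spine, 0.0]
        for _ in range(10000):
            update_mu(pop, pparams, 0.1)
        assert pop.mu[0] == pytest.approx(pparams.mu_spine, rel=1e-9)
        # at w=0 the target a/q is negative, so mu clips at 0
        assert a / q < 0
        assert pop.mu[1] == 0.0

    def test_relaxation_reaches_one_minus_inv_e_after_tau(self, pparams):
        pop = SynapsePopulation.initial(1, w_init=pparams.w_spine)
        update_mu(pop, pparams, pparams.tau_mu)
        assert pop.mu[0] == pytest.approx(
            (1 - math.exp(-1)) * pparams.mu_spine, rel=1e-12
        )

    def test_pinned_weight_matches_fine_euler_oracle(self, pparams):
        # scalar ODE tau_mu mu' = -(mu - (w+a)/q) at constant w=0.6
        a, q = pparams.aq
        w, t_end = 0.6, 7.0
        target = (w + a) / q
        # independent fine-step Euler integration
        mu_euler, h = 0.0, 1e-4
        for _ in range(int(t_end / h)):
            mu_euler += -h / pparams.tau_mu * (mu_euler - target)
        pop = SynapsePopulation.initial(1, w_init=w)
        update_mu(pop, pparams, t_end)
        assert pop.mu[0] == pytest.approx(mu_euler, rel=1e-3)
        exact = target * (1 - math.exp(-t_end / pparams.tau_mu))
        assert pop.mu[0] == pytest.approx(exact, rel=1e-12)

    def test_requires_fs_rule(self):
        pop = SynapsePopulation.initial(1)
        with pytest.raises(ValueError):
            update_mu(pop, PlasticityParams(rule="add"), 0.1)


class TestClipping:
    @pytest.mark.parametrize("w_in,w_out", [(1.2, 1.0), (-0.1, 0.0), (0.5, 0.5)])
    def test_clip(self, pparams, w_in, w_out):
        pop = SynapsePopulation.initial(1)
        pop.w[0] = w_in
        clip_weights(pop, pparams)
        assert pop.w[0] == w_out


def _apply_history(params, n, events, w_init=0.3, mu=None):
    """Replay a fixed pre/post event history through the trace machinery."""
    pop = SynapsePopulation.initial(n, w_init=w_init)
    if mu is not None:
        pop.mu[:] = mu
    for kind, payload in events:
        decay_traces(pop, 5e-4, params.tau_stdp)
        if kind == "pre":
            on_pre_spike(pop, params, payload)
        else:
            on_post_spike(pop, params)
    return pop.w


def _random_history(rng, n, n_events=400):
    events = []
    for _ in range(n_events):
        if rng.random() < 0.25:
            events.append(("post", None))
        else:
            k = rng.integers(1, max(2, n // 3))
            events.append(("pre", rng.choice(n, size=k, replace=False)))
    return events


class TestRuleReductions:
    """Exact trajectory equalities between rule family members."""

    def test_fs_with_frozen_zero_mu_equals_add(self, rng):
        events = _random_history(rng, 10)
        # fs with mu pinned at 0 and bounds [0, 1] (mu never updated here)
        fs = PlasticityParams(rule="fs", w0_minus=0.0, w0_plus=1.0)
        add = PlasticityParams(rule="add")
        w_fs = _apply_history(fs, 10, events, mu=0.0)
        w_add = _apply_history(add, 10, events)
        np.testing.assert_array_equal(w_fs, w_add)

    def test_fs_with_frozen_mu_equals_nlta_star(self, rng):
        events = _random_history(rng, 10)
        fs = PlasticityParams(rule="fs")
        star = PlasticityParams(rule="nlta_star", mu_fixed=0.07)
        w_fs = _apply_history(fs, 10, events, mu=0.07)
        w_star = _apply_history(star, 10, events)
        np.testing.assert_array_equal(w_fs, w_star)

    def test_nlta_mu_one_equals_mltmlt(self, rng):
        events = _random_history(rng, 10)
        nlta = PlasticityParams(rule="nlta", mu_fixed=1.0)
        mm = PlasticityParams(rule="mltmlt")
        np.testing.assert_allclose(
            _apply_history(nlta, 10, events),
            _apply_history(mm, 10, events),
            rtol=0, atol=1e-15,
        )

    def test_nlta_mu_zero_equals_add(self, rng):
        events = _random_history(rng, 10)
        nlta = PlasticityParams(rule="nlta", mu_fixed=0.0)
        add = PlasticityParams(rule="add")
        np.testing.assert_array_equal(
            _apply_history(nlta, 10, events), _apply_history(add, 10, events)
        )


class TestBoundedness:
    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_weights_stay_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        rule = str(rng.choice(["fs", "add", "mlt", "mltmlt", "nlta", "nlta_star"]))
        params = PlasticityParams(rule=rule, lam=0.3)  # aggressive updates
        pop = SynapsePopulation.initial(5, w_init=float(rng.uniform(0, 1)))
        pop.mu[:] = rng.uniform(0, 1, size=5)
        for kind, payload in _random_history(rng, 5, n_events=150):
            decay_traces(pop, 5e-4, params.tau_stdp)
            if kind == "pre":
                on_pre_spike(pop, params, payload)
            else:
                on_post_spike(pop, params)
            assert np.all(pop.w >= 0.0) and np.all(pop.w <= 1.0)
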