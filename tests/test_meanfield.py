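"""Competition/cooperation factors, C+ estimates, and the mean-field ODE."""

import numpy as np
import pytest

from fsstdp.inputgen import CorrelationStructure, make_squared_pulse, sample_spikes
from fsstdp.meanfield import (
    MeanFieldSystem,
    cij_plus,
    decompose_interactions,
    empirical_cij_plus,
    factors,
    integrate_meanfield,
    meanfield_rhs,
)
from fsstdp.plasticity import PlasticityParams


class TestFactors:
    def test_add_factors_are_constant(self):
        fp, df = factors("add", np.array([0.0, 0.5, 1.0]), 0.0, alpha=1.35)
        np.testing.assert_allclose(fp, 1.0)
        np.testing.assert_allclose(df, 0.35)

    def test_mltmlt_competition_root(self):
        alpha = 1.35
        w_root = 1.0 / (1.0 + alpha)
        _, df = factors("mltmlt", w_root, 0.0, alpha=alpha)
        assert df == pytest.approx(0.0, abs=1e-15)
        # numerical cross-check: sign change around the root
        _, lo = factors("mltmlt", w_root - 0.01, 0.0, alpha=alpha)
        _, hi = factors("mltmlt", w_root + 0.01, 0.0, alpha=alpha)
        assert lo < 0 < hi

    def test_fs_boundary_zeros(self):
        # depression factor vanishes at w0-, cooperation factor at w0+
        fp, df = factors("fs", 0.5, 0.2, alpha=1.35, w0_minus=0.5, w0_plus=1.0)
        assert df == pytest.approx(-fp)  # f_minus = 0 there
        fp_hi, _ = factors("fs", 1.0, 0.2, alpha=1.35)
        assert fp_hi == 0.0

    def test_fs_at_filopodial_mu_approximates_add(self):
        w = np.linspace(0.0, 0.9, 50)
        fp_fs, df_fs = factors("fs", w, 0.01, alpha=1.35)
        fp_add, df_add = factors("add", w, 0.0, alpha=1.35)
        assert np.max(np.abs(fp_fs - fp_add)) < 0.06
        assert np.max(np.abs(df_fs - df_add)) < 0.12

    def test_fs_at_fixed_mu_equals_nlta_star(self):
        w = np.linspace(0.0, 1.0, 21)
        np.testing.assert_array_equal(
            np.c_[factors("fs", w, 0.1, alpha=1.35)],
            np.c_[factors("nlta_star", w, 0.1, alpha=1.35)],
        )

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError):
            factors("hebb", 0.5, 0.1, alpha=1.35)


class TestCijPlus:
    def test_arithmetic_and_symmetry(self):
        assert cij_plus(0.0, 0.5, 0.02, 30.0) == 0.0
        assert cij_plus(0.3, 0.3, 0.02, 30.0) == pytest.approx(0.15)
        assert cij_plus(0.2, 0.7, 0.02, 30.0) == cij_plus(0.7, 0.2, 0.02, 30.0)
        with pytest.raises(ValueError):
            cij_plus(0.3, 0.3, 0.02, 0.0)

    def test_empirical_estimate_matches_analytic(self):
        c = np.array([0.3, 0.3, 0.0])
        s = CorrelationStructure(c=c, kind="gaussian", c_tot=0.6)
        raster = sample_spikes(s, rate=30.0, dt=5e-4, duration=50.0, seed=8)
        est = empirical_cij_plus(raster, 0, 1, tau=0.02)
        assert est == pytest.approx(0.15, abs=0.05)
        est0 = empirical_cij_plus(raster, 0, 2, tau=0.02)
        assert abs(est0) < 0.05

    def test_silent_train_rejected(self):
        s = CorrelationStructure(c=np.zeros(2), kind="gaussian", c_tot=0.0)
        raster = sample_spikes(s, rate=10.0, dt=5e-4, duration=1.0, seed=0)
        raster.bins[:, 0] = False
        with pytest.raises(ValueError):
            empirical_cij_plus(raster, 0, 1, tau=0.02)


def _system(rule="add", **kwargs):
    c = np.array([0.0, 0.2, 0.4, 0.6])
    structure = CorrelationStructure(c=c, kind="gaussian", c_tot=float(c.sum()))
    w = kwargs.pop("w", np.array([0.3, 0.4, 0.5, 0.6]))
    params = PlasticityParams(rule=rule, **kwargs)
    return MeanFieldSystem(w=w, structure=structure, params=params, r_pre=30.0)


class TestRHS:
    def test_zero_weights_zero_velocity(self):
        sys = _system(w=np.zeros(4))
        np.testing.assert_array_equal(meanfield_rhs(sys), 0.0)

    def test_pure_competition_is_depressing(self):
        # with no input correlation only the self-cooperation term opposes
        # the competition term, and it is O(1/N): at moderate pool sizes
        # every weight is driven down
        n = 50
        structure = CorrelationStructure(c=np.zeros(n), kind="gaussian", c_tot=0.0)
        params = PlasticityParams(rule="add", alpha=1.35)  # Delta_f = 0.35 > 0
        sys = MeanFieldSystem(
            w=np.full(n, 0.5), structure=structure, params=params, r_pre=30.0
        )
        rhs = meanfield_rhs(sys)
        assert np.all(rhs < 0)

    def test_decomposition_identity(self):
        sys = _system()
        indep, dep = decompose_interactions(sys)
        np.testing.assert_allclose(
            sys.prefactor * (indep + dep), meanfield_rhs(sys), rtol=1e-12
        )

    def test_correlation_term_quadratic_in_c(self):
        # with w_i = 0 the self-term drops and the correlation-dependent
        # interaction on synapse i scales as c_i * c_j -> quadruples when
        # every c doubles
        c1 = np.array([0.0, 0.2, 0.3, 0.25])
        w = np.array([0.0, 0.5, 0.5, 0.5])
        p = PlasticityParams(rule="add")
        s1 = MeanFieldSystem(
            w=w, structure=CorrelationStructure(c=c1, kind="gaussian"), params=p,
            r_pre=30.0,
        )
        s2 = MeanFieldSystem(
            w=w, structure=CorrelationStructure(c=2 * c1, kind="gaussian"), params=p,
            r_pre=30.0,
        )
        dep1 = decompose_interactions(s1)[1]
        dep2 = decompose_interactions(s2)[1]
        assert dep1[0] == 0.0 and dep2[0] == 0.0  # c_0 = 0, w_0 = 0
        # pick synapse 1 with a temporary zero weight to isolate the law
        w_iso = w.copy()
        w_iso[1] = 0.0
        d1 = decompose_interactions(
            MeanFieldSystem(w=w_iso, structure=s1.structure, params=p, r_pre=30.0)
        )[1][1]
        d2 = decompose_interactions(
            MeanFieldSystem(w=w_iso, structure=s2.structure, params=p, r_pre=30.0)
        )[1][1]
        assert d2 == pytest.approx(4.0 * d1, rel=1e-12)


class TestIntegration:
    def test_zero_state_is_stationary(self):
        sys = _system(w=np.zeros(4))
        _, traj = integrate_meanfield(sys, duration=10.0, step=0.5)
        np.testing.assert_array_equal(traj, 0.0)

    def test_add_rule_bimodal_split(self):
        # a sufficiently correlated subgroup wins; the rest decays to zero
        structure = make_squared_pulse(100, 20, 16.0)  # c_i = 0.8
        params = PlasticityParams(rule="add", alpha=1.1)
        sys = MeanFieldSystem(
            w=np.full(100, 0.3), structure=structure, params=params, r_pre=30.0
        )
        _, traj = integrate_meanfield(sys, duration=3000.0, step=0.25)
        w_end = traj[-1]
        assert np.all(w_end[structure.c > 0] > 0.95)
        assert np.all(w_end[structure.c == 0] < 0.05)
        assert np.all(traj >= 0.0) and np.all(traj <= 1.0)

    def test_fs_co_integrates_spineness(self):
        sys = _system(rule="fs", w=np.array([0.1, 0.4, 0.6, 0.8]))
        _, traj = integrate_meanfield(sys, duration=5.0, step=0.1)
        assert traj.shape == (51, 4)
        assert np.all(traj >= 0.0) and np.all(traj <= 1.0)
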