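"""Mixed-effects likelihood, conditional modes, OFV, fitting, LRT, CWRES."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import expm

import metcycle as mc
from metcycle.estimate import (Subject, _predict, conditional_mode, joint_nll,
                               lrt, lrt_threshold, ofv)
from metcycle.model_core import PopulationModel
from metcycle.synthetic_data import StudyDesign


def make_subject(sid=1, zdf=0, doses=((0.0, 0.8),), times=(0.5, 2.0),
                 cmts=(2, 5), y=(1.0, 0.005)):
    t = np.asarray(times, dtype=float)
    grid, gmap = np.unique(t, return_inverse=True)
    state = np.array([1 if c == 2 else 4 for c in cmts])
    return Subject(sid=sid, zdf=zdf, doses=tuple(doses), obs_times=t,
                   state_idx=state, y=np.asarray(y, dtype=float),
                   grid=grid, grid_map=gmap)


def ofv_quadrature(subs, pop, n_nodes=21):
    """Independent oracle: adaptive tensor Gauss-Hermite quadrature of the
    marginal likelihood, centred and scaled at the conditional mode."""
    from numpy.polynomial.hermite import hermgauss
    from scipy.special import logsumexp

    z, w = hermgauss(n_nodes)
    total = 0.0
    for sub in subs:
        cm = conditional_mode(sub, pop)
        d = cm.hessian.shape[0]
        if d == 0:
            total += cm.nll
            continue
        cov = np.linalg.inv(cm.hessian / 2.0)
        L = np.linalg.cholesky(cov)
        if d == 1:
            zz = z[:, None]
            logw = np.log(w)
        else:
            zz = np.array([[zi, zj] for zi in z for zj in z])
            logw = np.add.outer(np.log(w), np.log(w)).ravel()
        dims = [i for i, om in enumerate((pop.omega_khm, pop.omega_khp))
                if om > 0]
        terms = np.empty(zz.shape[0])
        for k, zk in enumerate(zz):
            eta = cm.eta.copy()
            eta[dims] += math.sqrt(2.0) * (L @ zk)
            terms[k] = -0.5 * joint_nll(sub, pop, eta) + float(zk @ zk)
        log_integral = logsumexp(logw + terms) + \
            0.5 * d * math.log(2.0) + math.log(np.linalg.det(L))
        total += -2.0 * log_integral
    return total


@pytest.fixture(scope="module")
def rich_pop(pop):
    """Lower residual noise for sharp conditional-mode checks."""
    return PopulationModel(theta=pop.theta, zdf_effects=dict(pop.zdf_effects),
                           omega_khm=pop.omega_khm, omega_khp=pop.omega_khp,
                           sigma_add=1e-4, sigma_prop=0.001)


class TestJointNLL:
    def test_no_observations_reduces_to_prior(self, pop):
        sub = make_subject(times=(), cmts=(), y=())
        expected = sum(math.log(2 * math.pi * om ** 2)
                       for om in (pop.omega_khm, pop.omega_khp))
        assert joint_nll(sub, pop, (0.0, 0.0)) == pytest.approx(expected)
        # prior is minimized at eta = 0
        assert joint_nll(sub, pop, (0.5, 0.0)) > expected

    def test_exact_residual_leaves_variance_constant(self, pop):
        # set y to the model prediction: the data term is just log(2 pi v)
        sub0 = make_subject(times=(1.0,), cmts=(2,), y=(0.0,))
        f = _predict(sub0, pop, (0.0, 0.0))
        sub = make_subject(times=(1.0,), cmts=(2,), y=(float(f[0]),))
        v = pop.sigma_add ** 2 + (pop.sigma_prop * f[0]) ** 2
        prior = sum(math.log(2 * math.pi * om ** 2)
                    for om in (pop.omega_khm, pop.omega_khp))
        assert joint_nll(sub, pop, (0.0, 0.0)) == pytest.approx(
            prior + math.log(2 * math.pi * v))

    def test_matches_hand_computed_gaussian_sum(self, pop):
        # independent oracle: predictions via dense expm, density via formula
        sub = make_subject(times=(0.5, 2.0), cmts=(2, 5), y=(1.2, 0.004))
        eta = (0.3, -0.2)
        p = mc.individual_pars(pop, mc.IndividualEffects(*eta, 0))
        M = mc.build_rate_matrix(p)
        A0 = np.zeros(7); A0[1] = 0.8
        f = np.array([(expm(M * 0.5) @ A0)[1], (expm(M * 2.0) @ A0)[4]]) / p.Vc
        v = pop.sigma_add ** 2 + (pop.sigma_prop * f) ** 2
        expected = float(np.sum(np.log(2 * np.pi * v) + (sub.y - f) ** 2 / v))
        expected += sum(math.log(2 * math.pi * om ** 2) + (e / om) ** 2
                        for e, om in zip(eta, (pop.omega_khm, pop.omega_khp)))
        assert joint_nll(sub, pop, eta) == pytest.approx(expected, rel=1e-9)

    def test_predose_sample_prediction_is_zero(self, pop):
        sub = make_subject(times=(0.0, 0.5), cmts=(2, 2), y=(0.0, 1.0))
        f = _predict(sub, pop, (0.0, 0.0))
        assert f[0] == 0.0 and f[1] > 0


class TestConditionalMode:
    def test_vanishing_variability_pins_eta_at_zero(self, pop):
        tight = PopulationModel(theta=pop.theta,
                                zdf_effects=dict(pop.zdf_effects),
                                omega_khm=1e-5, omega_khp=1e-5,
                                sigma_add=pop.sigma_add,
                                sigma_prop=pop.sigma_prop)
        sub = make_subject(times=(0.5, 2.0), cmts=(2, 5), y=(1.0, 0.01))
        cm = conditional_mode(sub, tight)
        assert np.abs(cm.eta).max() < 1e-3

    def test_recovers_known_effects_from_rich_data(self, rich_pop):
        times = np.linspace(0.1, 7.0, 25)
        fx = mc.IndividualEffects(0.4, -0.3, 1)
        pr = mc.simulate_subject(rich_pop, fx, mc.regimen_single_iv(0.8), times)
        sub = make_subject(zdf=1, times=np.r_[times, times],
                           cmts=[2] * 25 + [5] * 25,
                           y=np.r_[pr.c_met, pr.c_hcy])
        cm = conditional_mode(sub, rich_pop)
        assert cm.eta[0] == pytest.approx(0.4, rel=0.05)
        assert cm.eta[1] == pytest.approx(-0.3, rel=0.05)
        assert cm.converged

    def test_curvature_positive_definite_at_mode(self, pop, small_study):
        sub = mc.subjects_from_frame(small_study)[0]
        cm = conditional_mode(sub, pop)
        assert np.all(np.linalg.eigvalsh(cm.hessian) > 0)


class TestOFV:
    @pytest.mark.parametrize("sl", [slice(0, 5), slice(3, 13)])
    def test_laplace_matches_quadrature(self, pop, small_study, sl):
        # the combined proportional error and wide IIV skew the integrand,
        # so Laplace carries a small but genuine approximation error
        subs = mc.subjects_from_frame(small_study)[sl]
        lap = ofv(subs, pop)
        quad = ofv_quadrature(subs, pop)
        assert lap == pytest.approx(quad, abs=0.5)

    def test_duplicating_subjects_doubles_ofv(self, pop, small_study):
        subs = mc.subjects_from_frame(small_study)[:4]
        doubled = subs + [Subject(sid=s.sid + 100, zdf=s.zdf, doses=s.doses,
                                  obs_times=s.obs_times, state_idx=s.state_idx,
                                  y=s.y, grid=s.grid, grid_map=s.grid_map)
                          for s in subs]
        assert ofv(doubled, pop) == pytest.approx(2 * ofv(subs, pop), abs=1e-6)

    def test_invariant_to_subject_order(self, pop, small_study):
        subs = mc.subjects_from_frame(small_study)
        assert ofv(list(reversed(subs)), pop) == pytest.approx(
            ofv(subs, pop), abs=1e-8)


class TestFit:
    def test_all_fixed_returns_initial_model(self, pop, small_study):
        res = mc.fit(small_study, pop, [])
        assert res.pop == pop
        assert res.ofv == pytest.approx(ofv(small_study, pop))
        assert res.estimates == {}

    def test_rejects_unknown_parameter(self, pop, small_study):
        with pytest.raises(ValueError):
            mc.fit(small_study, pop, ["K_XX"])

    def test_single_parameter_recovery_smoke(self, pop):
        # small-n smoke test of the optimizer plumbing (the full-scale
        # recovery experiment lives in the acceptance suite)
        df = mc.generate_study(StudyDesign(n_per_group=12), pop, seed=2,
                               groups=(0,))
        res = mc.fit(df, pop, ["K_SH"], n_starts=1, compute_rse=False)
        assert 0.5 * 11.6 < res.estimates["K_SH"] < 1.5 * 11.6
        assert res.ofv <= ofv(df, pop) + 1e-6  # no worse than the truth

    def test_trace_monotone_over_accepted_iterates(self, pop):
        df = mc.generate_study(StudyDesign(n_per_group=6), pop, seed=9,
                               groups=(1,))
        res = mc.fit(df, pop, ["ZDF_K_SH"], n_starts=1, compute_rse=False)
        trace = res.ofv_trace
        assert all(b <= a + 1e-6 for a, b in zip(trace, trace[1:]))

    def test_nonfinite_initial_ofv_raises(self, pop, small_study):
        broken = small_study.copy()
        broken.loc[broken["EVID"] == 0, "DV"] = np.nan
        broken.loc[broken["EVID"] == 0, "MDV"] = 0
        with pytest.raises(ValueError):
            mc.fit(broken, pop, ["K_SH"])


class TestLRT:
    def test_published_significance_threshold(self):
        assert lrt_threshold(df=1, alpha=0.001) == pytest.approx(10.83, abs=0.005)

    def test_threshold_case(self):
        p, sig = lrt(100.0, 110.83, df=1)
        assert p == pytest.approx(0.001, rel=0.01)
        assert sig

    def test_null_and_marginal_cases(self):
        p, sig = lrt(50.0, 50.0)
        assert p == 1.0 and not sig
        p, sig = lrt(50.0, 53.84)
        assert p == pytest.approx(0.05, rel=0.01)
        assert not sig  # 3.84 is the 5% cut, far short of the 0.1% rule


class TestCWRES:
    def test_near_zero_for_noiseless_data(self, pop):
        quiet = PopulationModel(theta=pop.theta,
                                zdf_effects=dict(pop.zdf_effects),
                                omega_khm=pop.omega_khm,
                                omega_khp=pop.omega_khp,
                                sigma_add=1e-7, sigma_prop=1e-7)
        times = np.linspace(0.1, 7, 8)
        pr = mc.simulate_subject(quiet, mc.IndividualEffects(0, 0, 0),
                                 mc.regimen_single_iv(0.8), times)
        sub = make_subject(times=times, cmts=[2] * 8, y=pr.c_met)
        out = mc.cwres([sub], quiet)
        assert np.abs(out["CWRES"]).max() < 0.05

    def test_standardized_under_true_model(self, pop):
        df = mc.generate_study(StudyDesign(n_per_group=100), pop, seed=13)
        out = mc.cwres(df, pop)
        assert abs(out["CWRES"].mean()) < 0.1
        assert 0.85 < out["CWRES"].std() < 1.15

    def test_scrambled_data_inflates_residuals(self, pop, small_study):
        good = mc.cwres(small_study, pop)
        scrambled = small_study.copy()
        obs = scrambled["EVID"] == 0
        rng = np.random.default_rng(4)
        scrambled.loc[obs, "DV"] = rng.permutation(
            scrambled.loc[obs, "DV"].to_numpy())
        bad = mc.cwres(scrambled, pop)
        assert bad["CWRES"].abs().mean() > 2 * good["CWRES"].abs().mean()
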