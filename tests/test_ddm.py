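import numpy as np
import pytest
from scipy.integrate import quad

from accumulate.ddm import (
    DDMParams,
    ParameterError,
    ddm_loglik,
    ddm_omission_prob,
    ddm_simulate,
    ddm_trial_density,
    wiener_absorption_prob,
    wiener_fpt_cdf,
    wiener_fpt_density,
    wiener_survival,
)
from accumulate.tasks import NBACK, OMITTED
from accumulate.trial_data import make_dataset

PARAMS = DDMParams(
    v={"target": 1.5, "lure": 0.6, "novel": 1.2},
    a=1.4, z_rel=0.5, Ter=0.3, st0=0.1, p_gf=0.03,
)


class TestDensity:
    def test_symmetric_zero_drift_splits_mass_in_half(self):
        val, _ = quad(lambda t: wiener_fpt_density(t, 1.2, 0.5, 0.0, "upper"),
                      0, 60, limit=300)
        assert val == pytest.approx(0.5, abs=1e-7)

    @pytest.mark.parametrize(
        "a,w,v", [(1.0, 0.5, 1.0), (1.5, 0.4, 0.8), (0.8, 0.6, -0.5),
                  (2.0, 0.3, 2.0)])
    def test_absorption_probability_matches_closed_form(self, a, w, v):
        val, _ = quad(lambda t: wiener_fpt_density(t, a, w, v, "lower"),
                      0, 100, limit=300)
        assert val == pytest.approx(wiener_absorption_prob(a, w, v, "lower"),
                                    abs=1e-6)

    def test_series_representations_agree_in_switching_region(self):
        tau = np.linspace(0.02, 3.0, 100)
        small = wiener_fpt_density(tau, 1.0, 0.42, 0.7, "lower",
                                   method="small")
        large = wiener_fpt_density(tau, 1.0, 0.42, 0.7, "lower",
                                   method="large")
        assert np.max(np.abs(small - large)) < 1e-8

    def test_defective_densities_integrate_to_one(self, rng):
        for _ in range(8):
            a = rng.uniform(0.6, 2.5)
            w = rng.uniform(0.2, 0.8)
            v = rng.uniform(-2.0, 2.0)
            up, _ = quad(lambda t: wiener_fpt_density(t, a, w, v, "upper"),
                         0, 200, limit=400)
            lo, _ = quad(lambda t: wiener_fpt_density(t, a, w, v, "lower"),
                         0, 200, limit=400)
            assert up + lo == pytest.approx(1.0, abs=1e-4)

    def test_cdf_and_survival_are_consistent(self):
        for t in (0.2, 0.7, 1.5, 4.0):
            S = wiener_survival(t, 1.5, 0.4, 0.8)
            Fl = wiener_fpt_cdf(t, 1.5, 0.4, 0.8, "lower")
            Fu = wiener_fpt_cdf(t, 1.5, 0.4, 0.8, "upper")
            assert S == pytest.approx(1 - Fl - Fu, abs=1e-9)

    def test_upper_probability_monotone_in_drift(self):
        vs = np.linspace(-2, 2, 15)
        ps = wiener_absorption_prob(1.3, 0.45, vs, "upper")
        assert np.all(np.diff(ps) > 0)


class TestTrialDensity:
    def test_zero_t0_variability_reduces_to_plain_density(self):
        p = DDMParams(v={"target": 1.2}, a=1.3, z_rel=0.5, Ter=0.3, st0=0.0)
        rt = 0.85
        got = ddm_trial_density(rt, "target_resp", p, "target", NBACK)
        want = wiener_fpt_density(rt - 0.3, 1.3, 0.5, 1.2, "upper")
        assert got == pytest.approx(want, rel=1e-12)

    def test_t0_quadrature_matches_dense_trapezoid(self):
        p = PARAMS
        rt = 0.9
        got = ddm_trial_density(rt, "target_resp", p, "target", NBACK)
        ts = np.linspace(p.Ter - p.st0 / 2, p.Ter + p.st0 / 2, 10_001)
        dens = wiener_fpt_density(rt - ts, p.a, p.z_rel, p.v["target"],
                                  "upper")
        want = (1 - p.p_gf) * np.trapezoid(dens, ts) / p.st0
        assert got == pytest.approx(want, abs=1e-5)

    def test_omission_probability_vanishes_without_censoring(self):
        p = DDMParams(v={"target": 1.2}, a=1.3, z_rel=0.5, Ter=0.3,
                      st0=0.0, p_gf=0.0)
        assert ddm_omission_prob(p, "target", NBACK, window=50.0) == \
            pytest.approx(0.0, abs=1e-8)

    def test_early_rt_contributes_zero(self):
        got = ddm_trial_density(0.2, "target_resp", PARAMS, "target", NBACK)
        assert got == 0.0


class TestLoglik:
    def test_empty_dataset_gives_zero(self):
        ds = make_dataset("s", "nback", [], [], [])
        assert ddm_loglik(ds, PARAMS) == 0.0

    def test_single_trial_definition(self):
        p = DDMParams(v={"target": 1.2}, a=1.3, z_rel=0.5, Ter=0.3,
                      st0=0.0, p_gf=0.05)
        ds = make_dataset("s", "nback", ["target"], ["target_resp"], [0.8])
        want = np.log(0.95 * wiener_fpt_density(0.5, 1.3, 0.5, 1.2, "upper"))
        assert ddm_loglik(ds, p) == pytest.approx(want, rel=1e-10)

    def test_matches_naive_per_trial_oracle(self):
        ds = ddm_simulate(PARAMS, NBACK, 80, seed=17)
        total = 0.0
        for trial in ds.iter_trials():
            if trial.omitted:
                total += np.log(ddm_omission_prob(PARAMS, trial.condition,
                                                  NBACK, 2.0))
            else:
                total += np.log(ddm_trial_density(
                    trial.rt, trial.response, PARAMS, trial.condition, NBACK))
        assert ddm_loglik(ds, PARAMS) == pytest.approx(total, rel=1e-9)

    def test_missing_condition_raises(self):
        ds = ddm_simulate(PARAMS, NBACK, 10, seed=1)
        bad = DDMParams(v={"target": 1.0}, a=1.3, z_rel=0.5, Ter=0.3)
        with pytest.raises(ParameterError, match="lure"):
            ddm_loglik(ds, bad)


class TestSimulator:
    def test_same_seed_reproduces_dataset(self):
        a = ddm_simulate(PARAMS, NBACK, 40, seed=3)
        b = ddm_simulate(PARAMS, NBACK, 40, seed=3)
        assert a.trials.equals(b.trials)

    def test_unbiased_diffusion_splits_choices_evenly(self):
        p = DDMParams(v={"target": 0.0}, a=1.2, z_rel=0.5, Ter=0.25)
        ds = ddm_simulate(p, NBACK, {"target": 100_000}, window=10.0,
                          seed=11, dt=1e-3, tmax=30.0)
        resp = ds.trials[ds.trials["response"] != OMITTED]
        upper = (resp["response"] == "target_resp").mean()
        assert upper == pytest.approx(0.5, abs=0.01)

    def test_accuracy_matches_absorption_probability(self):
        p = DDMParams(v={"target": 1.0}, a=1.4, z_rel=0.5, Ter=0.25)
        # fine dt keeps the discretization bias inside the tolerance
        ds = ddm_simulate(p, NBACK, {"target": 150_000}, window=30.0,
                          seed=13, dt=2e-4, tmax=30.0)
        resp = ds.trials[ds.trials["response"] != OMITTED]
        acc = resp["correct"].mean()
        want = wiener_absorption_prob(1.4, 0.5, 1.0, "upper")
        assert acc == pytest.approx(want, abs=0.006)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ParameterError):
            DDMParams(v={"target": 1.0}, a=-1.0, z_rel=0.5, Ter=0.3)
        with pytest.raises(ParameterError):
            DDMParams(v={"target": 1.0}, a=1.0, z_rel=1.2, Ter=0.3)
        with pytest.raises(ParameterError):
            DDMParams(v={"target": 1.0}, a=1.0, z_rel=0.5, Ter=0.1, st0=0.4)
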