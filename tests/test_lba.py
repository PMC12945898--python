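import numpy as np
import pytest
from scipy.integrate import quad
from scipy.special import ndtr

from accumulate.lba import (
    LBAParams,
    ParameterError,
    lba_defective_density,
    lba_loglik,
    lba_never_finish_prob,
    lba_node_cdf,
    lba_node_density,
    lba_omission_prob,
    lba_response_probs,
    lba_simulate,
)
from accumulate.tasks import NBACK, OMITTED


def random_params(rng) -> LBAParams:
    return LBAParams(
        v_match={c: rng.uniform(1.0, 3.5) for c in NBACK.conditions},
        v_mismatch={c: rng.uniform(-0.5, 1.5) for c in NBACK.conditions},
        A=rng.uniform(0.1, 1.0),
        B={r: rng.uniform(0.3, 1.5) for r in NBACK.responses},
        t0=rng.uniform(0.1, 0.4),
        p_gf=rng.uniform(0.0, 0.1),
        sv_mismatch=rng.uniform(0.6, 1.5),
    )


class TestNodeDistributions:
    def test_zero_startpoint_total_mass_is_positive_rate_probability(self):
        # with A = 0 the finish time is b/rate, so P(finish) = P(rate > 0)
        assert lba_node_cdf(1e9, 1.0, 0.0, 1.0, 1.0) == pytest.approx(
            ndtr(1.0), abs=1e-9)

    def test_density_integrates_to_cdf(self):
        val, _ = quad(lambda t: lba_node_density(t, 1.3, 0.5, 2.0, 1.0),
                      0, 50, limit=200)
        assert val == pytest.approx(lba_node_cdf(50, 1.3, 0.5, 2.0, 1.0),
                                    abs=1e-6)

    def test_cdf_monotone_and_bounded(self, rng):
        t = np.linspace(0.01, 20, 300)
        F = lba_node_cdf(t, 1.2, 0.7, 1.5, 1.0)
        assert np.all(np.diff(F) >= -1e-12)
        assert np.all((F >= 0) & (F <= 1))

    def test_cdf_matches_simulated_finish_times(self, rng):
        b, A, v, sv = 1.2, 0.6, 2.0, 1.0
        n = 1_000_000
        rate = rng.normal(v, sv, n)
        start = rng.uniform(0, A, n)
        finite = rate > 0
        ft = (b - start[finite]) / rate[finite]
        grid = np.quantile(ft, np.linspace(0.02, 0.98, 40))
        emp = np.searchsorted(np.sort(ft), grid) / n
        ana = lba_node_cdf(grid, b, A, v, sv)
        assert np.max(np.abs(emp - ana)) < 0.005

    def test_invalid_sv_raises(self):
        with pytest.raises(ParameterError):
            lba_node_density(0.5, 1.0, 0.5, 1.0, 0.0)


class TestDefectiveDensity:
    def test_identical_accumulators_split_mass_equally(self):
        p = LBAParams(
            v_match={"target": 1.5}, v_mismatch={"target": 1.5},
            A=0.5, B={r: 0.8 for r in NBACK.responses}, t0=0.2,
        )
        probs = lba_response_probs(p, "target", NBACK, window=None)
        nf = lba_never_finish_prob(p, "target", NBACK)
        both = list(probs.values())
        assert both[0] == pytest.approx(both[1], abs=1e-9)
        assert both[0] == pytest.approx((1 - nf) / 2, abs=1e-7)

    def test_total_probability_mass_is_one(self, rng):
        for _ in range(10):
            p = random_params(rng)
            probs = lba_response_probs(p, "lure", NBACK, window=None)
            nf = lba_never_finish_prob(p, "lure", NBACK)
            assert sum(probs.values()) + nf == pytest.approx(1.0, abs=1e-4)

    def test_win_probabilities_match_simulation(self, true_lba_params):
        p = true_lba_params
        n = 1_000_000
        ds = lba_simulate(p, NBACK, {"target": n}, window=2.0, seed=99)
        sim = ds.trials["response"].value_counts(normalize=True)
        probs = lba_response_probs(p, "target", NBACK, window=2.0)
        for r in NBACK.responses:
            expected = (1 - p.p_gf) * probs[r]
            assert sim.get(r, 0.0) == pytest.approx(expected, abs=0.005)

    def test_scaling_invariance_of_win_probabilities(self):
        # multiplying v, sv, A, B jointly by k > 0 leaves choice
        # probabilities fixed (decision times scale as 1/k), which is why
        # one rate SD can be pinned as the scaling constant
        def win_prob(v1, sv1, b1, v2, sv2, b2, A):
            val, _ = quad(
                lambda t: float(lba_node_density(t, b1, A, v1, sv1)
                                * (1 - lba_node_cdf(t, b2, A, v2, sv2))),
                0, 80, limit=300)
            return val

        args = (2.0, 1.0, 1.3, 0.8, 1.2, 1.3, 0.4)
        k = 2.5
        scaled = (2.0 * k, 1.0 * k, 1.3 * k, 0.8 * k, 1.2 * k, 1.3 * k,
                  0.4 * k)
        assert win_prob(*scaled) == pytest.approx(win_prob(*args), abs=1e-5)


class TestOmissions:
    def test_mixture_formula(self, monkeypatch):
        import accumulate.lba as lba_mod

        p = LBAParams(v_match={"target": 2.0}, v_mismatch={"target": 0.8},
                      A=0.4, B={r: 0.9 for r in NBACK.responses}, t0=0.25,
                      p_gf=0.1)
        monkeypatch.setattr(
            lba_mod, "lba_response_probs",
            lambda *a, **k: {"target_resp": 0.5, "nontarget_resp": 0.3})
        assert lba_omission_prob(p, "target", NBACK, 2.0) == pytest.approx(
            0.1 + 0.9 * 0.2)

    def test_certain_go_failure_means_certain_omission(self):
        p = LBAParams(v_match={"target": 5.0}, v_mismatch={"target": 0.1},
                      A=0.1, B={r: 0.5 for r in NBACK.responses}, t0=0.1,
                      p_gf=1.0)
        assert lba_omission_prob(p, "target", NBACK, 2.0) == 1.0

    def test_window_below_t0_warns_and_returns_one(self):
        p = LBAParams(v_match={"target": 2.0}, v_mismatch={"target": 0.5},
                      A=0.3, B={r: 0.8 for r in NBACK.responses}, t0=0.5)
        with pytest.warns(UserWarning):
            assert lba_omission_prob(p, "target", NBACK, 0.4) == 1.0

    def test_omission_probability_matches_simulation(self, true_lba_params):
        p = true_lba_params
        ds = lba_simulate(p, NBACK, {"lure": 1_000_000}, window=2.0, seed=7)
        sim_om = float((ds.trials["response"] == OMITTED).mean())
        ana = lba_omission_prob(p, "lure", NBACK, 2.0)
        assert sim_om == pytest.approx(ana, abs=0.005)


class TestLoglik:
    def test_empty_dataset_gives_zero(self, true_lba_params):
        from accumulate.trial_data import make_dataset

        ds = make_dataset("s", "nback", [], [], [])
        assert lba_loglik(ds, true_lba_params) == 0.0

    def test_single_omission_equals_log_omission_prob(self, true_lba_params):
        from accumulate.trial_data import make_dataset

        ds = make_dataset("s", "nback", ["target"], [OMITTED], [None])
        expected = np.log(
            lba_omission_prob(true_lba_params, "target", NBACK, 2.0))
        assert lba_loglik(ds, true_lba_params) == pytest.approx(expected)

    def test_matches_naive_per_trial_oracle(self, nback_dataset,
                                            true_lba_params):
        p = true_lba_params
        total = 0.0
        for trial in nback_dataset.iter_trials():
            if trial.omitted:
                total += np.log(lba_omission_prob(p, trial.condition, NBACK,
                                                  2.0))
            else:
                dens = lba_defective_density(
                    trial.rt - p.t0, trial.response, p, trial.condition, NBACK)
                total += np.log((1 - p.p_gf) * dens)
        assert lba_loglik(nback_dataset, p) == pytest.approx(total, rel=1e-9)

    def test_missing_condition_raises(self, nback_dataset):
        p = LBAParams(v_match={"target": 2.0}, v_mismatch={"target": 0.5},
                      A=0.3, B={r: 0.8 for r in NBACK.responses}, t0=0.3)
        with pytest.raises(ParameterError, match="lure"):
            lba_loglik(nback_dataset, p)

    def test_generating_parameters_beat_perturbed_rates(self, rng):
        # basic identifiability: the true v_match beats +-50% distortions
        wins = 0
        n_rep = 10
        for i in range(n_rep):
            p = random_params(np.random.default_rng(100 + i))
            ds = lba_simulate(p, NBACK, 150, seed=200 + i)
            ll_true = lba_loglik(ds, p)
            for fac in (0.5, 1.5):
                q = LBAParams(
                    v_match={c: v * fac for c, v in p.v_match.items()},
                    v_mismatch=dict(p.v_mismatch), A=p.A, B=dict(p.B),
                    t0=p.t0, p_gf=p.p_gf, sv_mismatch=p.sv_mismatch)
                wins += ll_true > lba_loglik(ds, q)
        assert wins >= 0.9 * 2 * n_rep


class TestSimulator:
    def test_same_seed_reproduces_dataset(self, true_lba_params):
        a = lba_simulate(true_lba_params, NBACK, 50, seed=3)
        b = lba_simulate(true_lba_params, NBACK, 50, seed=3)
        assert a.trials.equals(b.trials)

    def test_rt_quantiles_match_analytic_distribution(self, true_lba_params):
        # compare simulated decision-time quintiles with inversion of the
        # analytic defective CDF (conditional on the correct response)
        p = true_lba_params
        n = 100_000
        ds = lba_simulate(p, NBACK, {"novel": n}, window=10.0, seed=21)
        sub = ds.trials
        rts = sub.loc[sub["response"] == "nontarget_resp", "rt"].to_numpy()

        grid = np.linspace(1e-4, 9.0, 4000)
        dens = lba_defective_density(grid, "nontarget_resp", p, "novel", NBACK)
        cdf = np.cumsum(dens) * (grid[1] - grid[0])
        cdf /= cdf[-1]
        for q in (0.1, 0.3, 0.5, 0.7, 0.9):
            ana = grid[np.searchsorted(cdf, q)] + p.t0
            emp = np.quantile(rts, q)
            assert emp == pytest.approx(ana, abs=0.01)
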