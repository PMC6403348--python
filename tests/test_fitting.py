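"""RT likelihood, joint fitting, and cross-validated prediction."""

import numpy as np
import pytest
from scipy import stats

from conjrl import (
    cv_predictive_likelihood,
    fit_model,
    make_trial_sequence,
    rt_log_likelihood,
    run_model,
    simulate_behavior,
)
from conjrl.fitting import SIGMA_FLOOR, BehavioralDataset
from conjrl.models import ModelParams
from conjrl.synth import GenerativeBehaviorConfig
from conjrl.task import TrialSequence


def make_dataset(seq, log_rt, responded=None):
    responded = np.ones(len(seq), dtype=int) if responded is None else responded
    log_rt = np.where(responded == 1, log_rt, np.nan)
    outcome = np.where(responded == 1, "hit", "miss")
    return BehavioralDataset(seq, log_rt, responded, outcome)


class TestRtLogLikelihood:
    def test_hand_example_two_residuals(self):
        """Two trials with residuals (+1, -1) at sigma = 1:
        LL = 2 log(1/sqrt(2 pi)) - 1 ~ -2.8379."""
        seq = make_trial_sequence(1, 1, 1.0, 0.0, seed=0)  # 4 trials
        trace = run_model(seq, ModelParams("no_learning"))
        data = make_dataset(seq, np.array([1.0, -1.0, 0.0, 0.0]),
                            responded=np.array([1, 1, 0, 0]))
        ll, _, _ = rt_log_likelihood(data, trace, beta=(0.0,), sigma=1.0)
        assert ll == pytest.approx(2 * np.log(1 / np.sqrt(2 * np.pi)) - 1.0, abs=1e-10)
        assert ll == pytest.approx(-2.8379, abs=5e-5)

    def test_matches_normal_density_sum_oracle(self):
        rng = np.random.default_rng(3)
        seq = make_trial_sequence(1, 5, seed=4)
        trace = run_model(seq, ModelParams("conjunctive", alpha=0.4))
        y = rng.normal(-1.0, 0.3, len(seq))
        data = make_dataset(seq, y)
        beta, sigma = (-0.9, -0.35), 0.27
        ll, _, _ = rt_log_likelihood(data, trace, beta, sigma)
        mu = beta[0] + beta[1] * trace.values
        oracle = sum(stats.norm.logpdf(yi, mi, sigma) for yi, mi in zip(y, mu))
        assert ll == pytest.approx(oracle, abs=1e-10)

    def test_profiled_sigma_is_rms_residual(self):
        rng = np.random.default_rng(5)
        seq = make_trial_sequence(1, 5, seed=6)
        trace = run_model(seq, ModelParams("conjunctive", alpha=0.2))
        y = rng.normal(0, 1, len(seq))
        data = make_dataset(seq, y)
        ll, beta, sigma = rt_log_likelihood(data, trace, (0.1, -0.2), sigma="profile")
        resid = y - (0.1 - 0.2 * trace.values)
        assert sigma == pytest.approx(np.sqrt(np.mean(resid**2)), abs=1e-12)

    def test_rejects_bad_sigma_and_empty(self, seq3, vs_trace):
        data = make_dataset(seq3, np.zeros(len(seq3)))
        with pytest.raises(ValueError):
            rt_log_likelihood(data, vs_trace, (0.0, 0.0), sigma=-1.0)
        none = make_dataset(seq3, np.zeros(len(seq3)), responded=np.zeros(len(seq3), int))
        with pytest.raises(ValueError):
            rt_log_likelihood(none, vs_trace, (0.0, 0.0))


class TestFitModel:
    def test_no_learning_equals_intercept_only_gaussian(self, conj_subject):
        fr = fit_model(conj_subject, "no_learning")
        y = conj_subject.log_rt[conj_subject.included]
        assert fr.params.beta[0] == pytest.approx(y.mean(), abs=1e-10)
        assert fr.params.sigma == pytest.approx(np.sqrt(np.mean((y - y.mean()) ** 2)), abs=1e-10)

    def test_noiseless_identifiability(self, seq3):
        cfg = GenerativeBehaviorConfig(
            params=ModelParams("conjunctive", alpha=0.3),
            rt_value_slope=-0.4,
            rt_noise_sd=0.0,
            seed=11,
        )
        data = simulate_behavior(seq3, cfg)
        fr = fit_model(data, "conjunctive", seed=2)
        assert fr.params.alpha == pytest.approx(0.3, abs=1e-3)
        assert fr.params.beta[1] == pytest.approx(-0.4, abs=1e-3)
        assert fr.params.sigma == pytest.approx(SIGMA_FLOOR, abs=1e-9)

    def test_self_consistency_of_reported_ll(self, conj_subject):
        fr = fit_model(conj_subject, "conjunctive", seed=0, n_restarts=5)
        trace = run_model(conj_subject.sequence, fr.params)
        ll, _, _ = rt_log_likelihood(conj_subject, trace, fr.params.beta, fr.params.sigma)
        assert ll == pytest.approx(fr.log_likelihood, abs=1e-8)
        assert sum(fr.per_run_ll.values()) == pytest.approx(fr.log_likelihood, abs=1e-8)

    def test_value_spread_nests_conjunctive(self, conj_subject, vs_subject):
        for data in (conj_subject, vs_subject):
            c = fit_model(data, "conjunctive", seed=0, n_restarts=10)
            v = fit_model(data, "value_spread", seed=0, n_restarts=10)
            assert v.log_likelihood >= c.log_likelihood - 1e-6

    def test_free_v0_never_hurts_in_sample(self, conj_subject):
        base = fit_model(conj_subject, "conjunctive", seed=0, n_restarts=10)
        free = fit_model(conj_subject, "conjunctive", seed=0, n_restarts=10, free_v0=True)
        assert free.log_likelihood >= base.log_likelihood - 1e-6

    def test_fitted_slope_negative_for_value_speeded_rts(self, vs_subject):
        fr = fit_model(vs_subject, "value_spread", seed=0, n_restarts=10)
        assert fr.params.beta[1] < 0

    def test_omega_recovery_across_subjects(self, seq3):
        """Fitted omega tracks the generating omega across 30 subjects."""
        rng = np.random.default_rng(0)
        gen, fit = [], []
        for s in range(30):
            om = float(rng.uniform())
            cfg = GenerativeBehaviorConfig(
                params=ModelParams("value_spread", alpha=0.3, omega=om),
                rt_value_slope=-0.4,
                rt_noise_sd=0.15,
                seed=1000 + s,
            )
            data = simulate_behavior(seq3, cfg)
            fit.append(fit_model(data, "value_spread", seed=s, n_restarts=10).params.omega)
            gen.append(om)
        assert np.corrcoef(gen, fit)[0, 1] >= 0.7


class TestCrossValidation:
    def test_no_learning_matches_closed_form(self, conj_subject):
        cv = cv_predictive_likelihood(conj_subject, "no_learning")
        runs = np.unique(conj_subject.sequence.run_indices)
        total = 0.0
        for r in runs:
            train = conj_subject.subset_runs([x for x in runs if x != r])
            test = conj_subject.subset_runs([r])
            y_tr = train.log_rt[train.included]
            mu, sd = y_tr.mean(), np.sqrt(np.mean((y_tr - y_tr.mean()) ** 2))
            y_te = test.log_rt[test.included]
            total += stats.norm.logpdf(y_te, mu, sd).sum()
        assert cv.total_ll == pytest.approx(total, abs=1e-10)

    def test_duplicate_runs_in_sample_equals_out_of_sample(self):
        """With identical runs, training and held-out distributions match."""
        from conjrl.task import Trial

        one = make_trial_sequence(1, 10, seed=3)
        trials = list(one.trials) + [
            Trial(1, t.trial_index, t.stimulus, t.target) for t in one.trials
        ]
        seq = TrialSequence(trials, 2, 10, 0.7, 0.3)
        rng = np.random.default_rng(4)
        trace = run_model(seq, ModelParams("conjunctive", alpha=0.3))
        y_one = -0.9 - 0.4 * trace.values[: len(one)] + 0.1 * rng.standard_normal(len(one))
        y = np.concatenate([y_one, y_one])  # identical duplicate runs
        data = make_dataset(seq, y)
        cv = cv_predictive_likelihood(data, "conjunctive", seed=0, n_restarts=10)
        fr = fit_model(data.subset_runs([0]), "conjunctive", seed=0, n_restarts=10)
        in_sample_per_trial = fr.log_likelihood / fr.n_included
        assert cv.per_trial_ll == pytest.approx(in_sample_per_trial, abs=1e-8)

    def test_model_recovery_sign_test(self, seq3):
        """Conjunctive beats the null model out of sample for conjunctive data."""
        wins, n = 0, 20
        for s in range(n):
            cfg = GenerativeBehaviorConfig(
                params=ModelParams("conjunctive", alpha=0.3),
                rt_value_slope=-0.4,
                rt_noise_sd=0.15,
                seed=2000 + s,
            )
            data = simulate_behavior(seq3, cfg)
            a = cv_predictive_likelihood(data, "conjunctive", seed=s, n_restarts=10)
            b = cv_predictive_likelihood(data, "no_learning", seed=s)
            wins += a.per_trial_ll > b.per_trial_ll
        # one-sided sign test: P(X >= wins | p = .5) < .05 needs wins >= 15
        assert stats.binomtest(wins, n, 0.5, alternative="greater").pvalue < 0.05

    def test_single_run_rejected(self, seq1):
        data = make_dataset(seq1, np.zeros(len(seq1)))
        with pytest.raises(ValueError):
            cv_predictive_likelihood(data, "no_learning")


class TestBehavioralDataset:
    def test_log_rt_mask_invariant_enforced(self, seq3):
        log_rt = np.zeros(len(seq3))
        responded = np.ones(len(seq3), dtype=int)
        responded[0] = 0  # responded = 0 but finite log_rt -> invalid
        with pytest.raises(ValueError):
            BehavioralDataset(seq3, log_rt, responded, np.array(["x"] * len(seq3)))

    def test_tsv_round_trip(self, conj_subject, tmp_path):
        path = tmp_path / "behavior.tsv"
        conj_subject.write_tsv(path)
        back = BehavioralDataset.read_tsv(path)
        np.testing.assert_array_equal(back.responded, conj_subject.responded)
        mask = conj_subject.included
        np.testing.assert_allclose(back.log_rt[mask], conj_subject.log_rt[mask], atol=1e-12)
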