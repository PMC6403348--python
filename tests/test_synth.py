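"""Generative behavior, pattern, and localizer simulators."""

import numpy as np
import pytest

from conjrl import make_trial_sequence, run_model, simulate_behavior
from conjrl.models import ModelParams
from conjrl.synth import (
    GenerativeBehaviorConfig,
    GenerativePatternConfig,
    calibrate_threshold,
    simulate_localizer,
    simulate_patterns,
    simulate_striatal_betas,
)


class TestSimulateBehavior:
    def test_noiseless_rt_ordering_matches_values(self, seq3, vs_params):
        """With no RT noise and a negative slope, high-value stimuli (AB, C)
        are answered faster than low-value ones (AC, B)."""
        cfg = GenerativeBehaviorConfig(
            params=vs_params, rt_value_slope=-0.4, rt_noise_sd=0.0, seed=0
        )
        data = simulate_behavior(seq3, cfg)
        df = data.to_frame()
        hits = df[df.target == 1]
        mean_rt = hits.groupby("stimulus")["rt_ms"].mean()
        assert mean_rt["AB"] < mean_rt["AC"] and mean_rt["C"] < mean_rt["B"]

    def test_adaptive_threshold_holds_hit_rate_near_half(self):
        """With no learnable signal the threshold tracks the median RT and
        the long-run hit rate settles at ~50%."""
        seq = make_trial_sequence(10, 10, seed=3)
        cfg = GenerativeBehaviorConfig(
            params=ModelParams("no_learning"), rt_value_slope=0.0, rt_noise_sd=0.15, seed=1
        )
        data = simulate_behavior(seq, cfg)
        targets = data.sequence.targets == 1
        hit_rate = np.mean(np.asarray(data.outcome)[targets] == "hit")
        n = targets.sum()
        se = np.sqrt(0.25 / n)
        assert abs(hit_rate - 0.5) < 4 * se + 0.05  # threshold-lag slack

    def test_reward_rule(self, seq3, vs_params):
        cfg = GenerativeBehaviorConfig(params=vs_params, seed=2)
        data = simulate_behavior(seq3, cfg)
        out = np.asarray(data.outcome)
        assert np.all(data.reward[out == "hit"] == 0.25)
        assert np.all(data.reward[out == "false_alarm"] == -0.25)
        assert np.all(data.reward[np.isin(out, ["miss", "correct_rejection"])] == 0.0)
        # responses and RTs coincide
        assert np.array_equal(np.isfinite(data.log_rt), data.responded == 1)

    def test_false_alarms_increase_with_value(self, seq3, vs_params):
        """Anticipation is value-dependent: more false alarms after AB than B."""
        rates = {"AB": [], "B": []}
        for s in range(25):
            cfg = GenerativeBehaviorConfig(params=vs_params, seed=500 + s)
            df = simulate_behavior(seq3, cfg).to_frame()
            nt = df[df.target == 0]
            for stim in rates:
                rates[stim].append((nt[nt.stimulus == stim].outcome == "false_alarm").mean())
        assert np.mean(rates["AB"]) > np.mean(rates["B"])

    def test_determinism(self, seq3, vs_params):
        cfg = GenerativeBehaviorConfig(params=vs_params, seed=11)
        a = simulate_behavior(seq3, cfg).to_frame()
        b = simulate_behavior(seq3, cfg).to_frame()
        assert a.equals(b)
        c = simulate_behavior(seq3, GenerativeBehaviorConfig(params=vs_params, seed=12)).to_frame()
        assert not a.equals(c)

    def test_calibration_converges_to_median_rt(self):
        cfg = GenerativeBehaviorConfig(rt_noise_sd=0.05, seed=3)
        thr = calibrate_threshold(cfg, n_trials=200)
        median_rt = np.exp(cfg.rt_intercept)
        assert abs(thr - median_rt) < 0.06  # within two calibration steps


class TestSimulatePatterns:
    def test_round_trip_identity_only(self, seq3, vs_trace):
        """a > 0, b = 0: within-stimulus coding present, overlap absent."""
        from conjrl import build_psa_design, compute_psm, permutation_test

        cfg = GenerativePatternConfig(
            n_units=60, within_stimulus_strength=1.0, overlap_strength=0.0,
            noise_sd=0.5, seed=21,
        )
        psm = compute_psm(simulate_patterns(seq3, vs_trace, cfg))
        design = build_psa_design(seq3, vs_trace)
        res = permutation_test(psm, design, ["within_stimulus", "overlap"], n_perm=500, seed=0)
        assert res["within_stimulus"].p_value < 0.05
        assert res["overlap"].p_value > 0.05

    def test_round_trip_overlap(self, seq3, vs_trace):
        from conjrl import build_psa_design, compute_psm, permutation_test

        cfg = GenerativePatternConfig(
            n_units=60, within_stimulus_strength=0.5, overlap_strength=0.6,
            noise_sd=0.5, seed=22,
        )
        psm = compute_psm(simulate_patterns(seq3, vs_trace, cfg))
        design = build_psa_design(seq3, vs_trace)
        res = permutation_test(psm, design, ["overlap"], n_perm=500, seed=0)
        assert res["overlap"].observed > 0 and res["overlap"].p_value < 0.05

    def test_pure_noise_null_calibrated(self, seq3, vs_trace):
        from conjrl import build_psa_design, compute_psm, fit_psm_regression

        cfg = GenerativePatternConfig(
            n_units=60, within_stimulus_strength=0.0, overlap_strength=0.0,
            value_coding_slope=0.0, noise_sd=1.0, seed=23,
        )
        psm = compute_psm(simulate_patterns(seq3, vs_trace, cfg))
        design = build_psa_design(seq3, vs_trace)
        coef = fit_psm_regression(psm, design)
        # no planted structure: every coefficient is tiny
        assert np.all(np.abs(coef.drop("intercept")) < 0.01)

    def test_determinism_and_config_validation(self, seq3, vs_trace):
        cfg = GenerativePatternConfig(n_units=20, seed=4)
        a = simulate_patterns(seq3, vs_trace, cfg).data
        b = simulate_patterns(seq3, vs_trace, cfg).data
        np.testing.assert_array_equal(a, b)
        with pytest.raises(ValueError):
            GenerativePatternConfig(n_units=5)
        with pytest.raises(ValueError):
            GenerativePatternConfig(noise_sd=np.nan)


class TestSimulateStriatalBetas:
    def test_noiseless_weights_recovered_exactly(self, seq3):
        from conjrl import build_pe_regressors, striatal_beta_regression

        regs = build_pe_regressors(
            seq3, ModelParams("feature", alpha=0.4), ModelParams("conjunctive", alpha=0.4)
        )
        betas = simulate_striatal_betas(
            regs, {"w_target": 2.0, "w_feature": 1.0, "w_conj": 0.5}, noise_sd=0.0, seed=0
        )
        stacked = np.tile(betas, 2)
        ids = np.repeat([0, 1], len(regs))
        res = striatal_beta_regression(stacked, regs, ids)
        np.testing.assert_allclose(res.mean, [0.0, 2.0, 1.0, 0.5], atol=1e-10)

    def test_null_conjunctive_weight_calibrated(self, seq3):
        from conjrl import build_pe_regressors, striatal_beta_regression

        regs = build_pe_regressors(
            seq3, ModelParams("feature", alpha=0.4), ModelParams("conjunctive", alpha=0.4)
        )
        rng = np.random.default_rng(1)
        rejections = 0
        n_rep = 200
        for rep in range(n_rep):
            betas, ids = [], []
            for s in range(8):
                betas.append(
                    simulate_striatal_betas(
                        regs, {"w_target": 1.0, "w_feature": 0.3, "w_conj": 0.0},
                        noise_sd=0.5, seed=int(rng.integers(2**31)),
                    )
                )
                ids.append(np.full(len(regs), s))
            res = striatal_beta_regression(np.concatenate(betas), regs, np.concatenate(ids))
            rejections += res.p[3] < 0.05
        rate = rejections / n_rep
        assert abs(rate - 0.05) < 4 * np.sqrt(0.05 * 0.95 / n_rep)


class TestSimulateLocalizer:
    def test_noiseless_templates_equal_prototypes(self):
        from conjrl import build_templates
        from conjrl.synth import category_prototypes

        cfg = GenerativePatternConfig(n_units=30, noise_sd=0.0, seed=5)
        loc = simulate_localizer(["face", "house"], 4, cfg)
        tpl = build_templates(loc)
        protos = category_prototypes(["face", "house"], 30, seed=5)
        for cat in ("face", "house"):
            np.testing.assert_allclose(tpl[cat], protos[cat], atol=1e-12)

    def test_label_permutation_destroys_specificity(self):
        """Relabelling every block with the wrong category (a cyclic
        derangement) leaves templates with no match to the true prototypes."""
        from conjrl import build_templates
        from conjrl.synth import category_prototypes

        cfg = GenerativePatternConfig(n_units=40, noise_sd=0.1, seed=7)
        loc = simulate_localizer(["face", "house", "body"], 6, cfg)
        protos = category_prototypes(["face", "house", "body"], 40, seed=7)
        relabel = {"face": "house", "house": "body", "body": "face"}
        shuffled = loc.meta.copy()
        shuffled["category"] = shuffled["category"].map(relabel)
        from conjrl.psa import PatternDataset

        tpl_true = build_templates(loc)
        tpl_shuf = build_templates(PatternDataset("loc", loc.data, shuffled))

        def match(tpl):
            return np.mean(
                [np.corrcoef(tpl[c], protos[c])[0, 1] for c in ("face", "house", "body")]
            )

        assert match(tpl_true) > 0.9
        assert match(tpl_shuf) < 0.3

    def test_category_floor(self):
        with pytest.raises(ValueError):
            simulate_localizer(["face"], 3, GenerativePatternConfig(n_units=20))
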