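"""Pattern-similarity matrices, the pair-level design, and permutation inference."""

import numpy as np
import pandas as pd
import pytest

from conjrl import (
    build_psa_design,
    compute_psm,
    fit_psm_regression,
    make_trial_sequence,
    permutation_test,
    region_contrast,
    run_model,
)
from conjrl.models import ModelParams
from conjrl.psa import R_CLIP, PatternDataset


def make_patterns(data, seq=None, region="r"):
    n = data.shape[0]
    if seq is None:
        meta = pd.DataFrame(
            {"run": 0, "trial": range(n), "stimulus": "AB", "target": 0}
        )
    else:
        meta = seq.to_frame()
    return PatternDataset(region, data, meta)


class TestComputePsm:
    def test_identical_rows_clip_to_finite_z(self):
        rng = np.random.default_rng(0)
        row = rng.standard_normal(30)
        X = np.vstack([row, row, rng.standard_normal(30)])
        psm = compute_psm(make_patterns(X))
        assert psm.z[0] == pytest.approx(np.arctanh(R_CLIP))

    def test_orthogonal_rows_give_zero(self):
        a = np.array([1.0, -1.0, 1.0, -1.0])
        b = np.array([1.0, 1.0, -1.0, -1.0])
        X = np.vstack([a, b, a + b])
        psm = compute_psm(make_patterns(X))
        assert psm.z[0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_correlation_oracle(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((10, 50))
        psm = compute_psm(make_patterns(X))
        k = 0
        for i in range(10):
            for j in range(i + 1, 10):
                r = np.corrcoef(X[i], X[j])[0, 1]
                assert psm.z[k] == pytest.approx(np.arctanh(np.clip(r, -R_CLIP, R_CLIP)), abs=1e-12)
                k += 1

    def test_zero_variance_trial_flagged(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((4, 20))
        X[1] = 3.14  # constant pattern
        psm = compute_psm(make_patterns(X))
        bad = (psm.i == 1) | (psm.j == 1)
        assert not psm.valid[bad].any() and psm.valid[~bad].all()

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            compute_psm(make_patterns(np.zeros((2, 20)) + np.eye(2, 20)))


class TestBuildPsaDesign:
    def test_pair_codings_match_task_structure(self, seq3, vs_trace):
        design = build_psa_design(seq3, vs_trace)
        stim = np.array(seq3.stimulus_names)
        i, j = design.i, design.j
        # recover pre-z-scored codings from the raw pair structure
        from conjrl.task import feature_overlap

        for a, b, want_within, want_overlap in [
            ("AB", "B", 0, 1),
            ("B", "C", 0, -1),
            ("AB", "AB", 1, 0),
        ]:
            mask = ((stim[i] == a) & (stim[j] == b)) | ((stim[i] == b) & (stim[j] == a))
            assert mask.any()
            w = design.columns["within_stimulus"][mask]
            o = design.columns["overlap"][mask]
            # all pairs of the same type share one (z-scored) value
            assert w.nunique() == 1 and o.nunique() == 1
            # codes order correctly after z-scoring: overlap +1 > 0 > -1
        raw_overlap = np.where(
            stim[i] == stim[j],
            0.0,
            [float(feature_overlap(a, b)) * 2 - 1 for a, b in zip(stim[i], stim[j])],
        )
        z = design.columns["overlap"].to_numpy()
        assert np.corrcoef(raw_overlap, z)[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_columns_z_scored(self, seq3, vs_trace):
        design = build_psa_design(seq3, vs_trace, include_epoch_interaction=True)
        M = design.matrix()
        np.testing.assert_allclose(M.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(M.std(axis=0), 1.0, atol=1e-10)

    def test_value_pe_orthogonal_to_response_and_target(self, seq3, vs_trace):
        design = build_psa_design(seq3, vs_trace)
        n = len(design.i)
        for col in ("value_similarity", "pe_similarity"):
            v = design.columns[col].to_numpy()
            # z-scored columns: orthogonality as mean cross-product per pair
            assert abs(v @ design.columns["response"].to_numpy()) / n < 1e-8
            assert abs(v @ design.columns["target"].to_numpy()) / n < 1e-8

    def test_equal_values_max_similarity_before_scaling(self, seq3, vs_trace):
        v = vs_trace.updated_values
        i, j = np.triu_indices(len(seq3), k=1)
        raw = -np.abs(v[i] - v[j])
        equal = np.isclose(v[i], v[j])
        if equal.any():
            assert np.max(raw) == pytest.approx(raw[equal].max())

    def test_value_columns_require_trace(self, seq3):
        with pytest.raises(ValueError):
            build_psa_design(seq3, None, include_value=True)
        design = build_psa_design(seq3, None, include_value=False, include_pe=False)
        assert "value_similarity" not in design.names

    def test_epoch_interaction_requires_value(self, seq3, vs_trace):
        with pytest.raises(ValueError):
            build_psa_design(
                seq3, vs_trace, include_value=False, include_pe=False,
                include_epoch_interaction=True,
            )


class TestFitPsmRegression:
    def test_noiseless_recovery(self, seq3, vs_trace):
        design = build_psa_design(seq3, vs_trace)
        X = design.matrix()
        y = 0.3 * design.columns["within_stimulus"].to_numpy() + 0.1 * design.columns[
            "overlap"
        ].to_numpy()
        psm_like = compute_psm  # noqa: F841 - construct a PSM container directly
        from conjrl.psa import PatternSimilarityMatrix

        psm = PatternSimilarityMatrix(
            design.i, design.j, y, np.ones(len(y), dtype=bool), "synthetic", len(seq3)
        )
        coef = fit_psm_regression(psm, design)
        assert coef["within_stimulus"] == pytest.approx(0.3, abs=1e-10)
        assert coef["overlap"] == pytest.approx(0.1, abs=1e-10)

    def test_matches_normal_equations_oracle(self, seq3, vs_trace):
        rng = np.random.default_rng(3)
        design = build_psa_design(seq3, vs_trace)
        from conjrl.psa import PatternSimilarityMatrix

        y = rng.standard_normal(len(design.i))
        psm = PatternSimilarityMatrix(
            design.i, design.j, y, np.ones(len(y), dtype=bool), "synthetic", len(seq3)
        )
        coef = fit_psm_regression(psm, design).to_numpy()
        X = np.column_stack([np.ones(len(y)), design.matrix()])
        oracle = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(coef, oracle, atol=1e-10)

    def test_rank_deficiency_names_columns(self, seq3, vs_trace):
        design = build_psa_design(seq3, vs_trace)
        design.columns["dup"] = design.columns["overlap"]
        from conjrl.psa import PatternSimilarityMatrix

        y = np.zeros(len(design.i))
        psm = PatternSimilarityMatrix(
            design.i, design.j, y, np.ones(len(y), dtype=bool), "synthetic", len(seq3)
        )
        with pytest.raises(ValueError, match="dup"):
            fit_psm_regression(psm, design)


class TestPermutationInference:
    def test_saturated_effect_attains_minimum_p(self, seq1):
        trace = run_model(seq1, ModelParams("conjunctive", alpha=0.3))
        design = build_psa_design(seq1, trace)
        from conjrl.psa import PatternSimilarityMatrix

        y = 5.0 * design.columns["within_stimulus"].to_numpy()
        psm = PatternSimilarityMatrix(
            design.i, design.j, y, np.ones(len(y), dtype=bool), "synthetic", len(seq1)
        )
        res = permutation_test(psm, design, ["within_stimulus"], n_perm=999, seed=0)
        assert res["within_stimulus"].p_value == pytest.approx(1 / 1000)

    def test_monotone_rescaling_invariance(self, seq1):
        """Scaling design columns leaves permutation p-values unchanged."""
        trace = run_model(seq1, ModelParams("conjunctive", alpha=0.3))
        d1 = build_psa_design(seq1, trace)
        d2 = build_psa_design(seq1, trace)
        # positive linear rescaling: betas shrink by 1/3 for observed and null
        # alike, so the permutation p-value is unchanged
        d2.columns["within_stimulus"] = 3.0 * d2.columns["within_stimulus"]
        rng = np.random.default_rng(4)
        from conjrl.psa import PatternSimilarityMatrix

        y = rng.standard_normal(len(d1.i)) + 0.5 * d1.columns["within_stimulus"].to_numpy()
        psm = PatternSimilarityMatrix(
            d1.i, d1.j, y, np.ones(len(y), dtype=bool), "synthetic", len(seq1)
        )
        p1 = permutation_test(psm, d1, ["within_stimulus"], n_perm=500, seed=7)
        p2 = permutation_test(psm, d2, ["within_stimulus"], n_perm=500, seed=7)
        assert p1["within_stimulus"].p_value == p2["within_stimulus"].p_value

    def test_n_perm_floor(self, seq1):
        trace = run_model(seq1, ModelParams("conjunctive", alpha=0.3))
        design = build_psa_design(seq1, trace)
        from conjrl.psa import PatternSimilarityMatrix

        y = np.zeros(len(design.i))
        psm = PatternSimilarityMatrix(
            design.i, design.j, y, np.ones(len(y), dtype=bool), "synthetic", len(seq1)
        )
        with pytest.raises(ValueError):
            permutation_test(psm, design, ["overlap"], n_perm=50)

    def test_identical_regions_give_null_contrast(self, seq1):
        trace = run_model(seq1, ModelParams("conjunctive", alpha=0.3))
        design = build_psa_design(seq1, trace)
        rng = np.random.default_rng(5)
        from conjrl.psa import PatternSimilarityMatrix

        y = rng.standard_normal(len(design.i))
        psm = PatternSimilarityMatrix(
            design.i, design.j, y, np.ones(len(y), dtype=bool), "a", len(seq1)
        )
        res = region_contrast(psm, psm, design, "overlap", n_perm=400, seed=0)
        assert res.observed == 0.0
        assert 0.3 < res.p_value < 0.7

    def test_planted_region_difference_detected(self, seq3):
        """A region with overlap structure vs one without: contrast p < .05."""
        from conjrl.synth import GenerativePatternConfig, simulate_patterns

        trace = run_model(seq3, ModelParams("value_spread", alpha=0.3, omega=0.44))
        design = build_psa_design(seq3, trace)
        with_b = GenerativePatternConfig(
            n_units=200, within_stimulus_strength=0.5, overlap_strength=0.8,
            noise_sd=0.3, seed=11,
        )
        no_b = GenerativePatternConfig(
            n_units=200, within_stimulus_strength=0.5, overlap_strength=0.0,
            noise_sd=0.3, seed=12,
        )
        psm_a = compute_psm(simulate_patterns(seq3, trace, with_b, region="a"))
        psm_b = compute_psm(simulate_patterns(seq3, trace, no_b, region="b"))
        res = region_contrast(psm_a, psm_b, design, "overlap", n_perm=999, seed=1)
        assert res.observed > 0 and res.p_value < 0.05
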