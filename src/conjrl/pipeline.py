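"""End-to-end orchestration of the synthetic study.

``run_full_analysis`` executes every stage -- behavior simulation, model
fitting, cross-validated and Bayesian model comparison, prediction-error
regressor construction and striatal decomposition, pattern-similarity
analysis of a conjunctive (hippocampus-like) and a feature-mixing
(cortex-like) synthetic region, the pattern-content analysis, and the
run-level brain-behavior coupling -- and writes per-stage TSV/JSON outputs
plus a consolidated report.  Identical config and seed give identical
outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .comparison import conjunctive_index_table, group_bms, pairwise_model_test
from .fitting import BehavioralDataset, FitResult, cv_predictive_likelihood, fit_model
from .models import ModelParams, run_model
from .pe_regressors import (
    brain_behavior_coupling,
    build_pe_regressors,
    striatal_beta_regression,
)
from .pattern_content import build_templates, content_contrast, template_similarity
from .psa import build_psa_design, compute_psm, fit_psm_regression, permutation_test, region_contrast
from .synth import (
    GenerativeBehaviorConfig,
    GenerativePatternConfig,
    simulate_behavior,
    simulate_content_patterns,
    simulate_localizer,
    simulate_patterns,
    simulate_striatal_betas,
)
from .task import make_trial_sequence

__all__ = ["AnalysisConfig", "run_full_analysis"]

MODELS_DEFAULT = ("no_learning", "feature", "conjunctive", "value_spread")


@dataclass
class AnalysisConfig:
    """Study conditions for the full synthetic analysis.

    Defaults are the task's printed design (3 runs x 10 trials per
    stimulus, 70%/30% target rates) with a value-spread generator at the
    group-mean spread (omega = 0.44) and moderate RT noise.
    """

    n_subjects: int = 30
    n_runs: int = 3
    trials_per_stimulus: int = 10
    p_high: float = 0.7
    p_low: float = 0.3
    gen_model: str = "value_spread"
    gen_alpha: float = 0.3
    gen_omega: float = 0.44
    gen_rt_slope: float = -0.4
    gen_rt_noise_sd: float = 0.15
    models: tuple = MODELS_DEFAULT
    n_restarts: int = 20
    n_mc_bms: int = 1_000_000
    n_perm: int = 10_000
    # planted striatal weights and pattern strengths
    w_target: float = 1.0
    w_feature: float = 0.25
    w_conj: float = 0.12
    beta_noise_sd: float = 0.5
    n_units: int = 60
    pattern_noise_sd: float = 0.5
    coupling_slope: float = -0.5
    seed: int = 0

    def to_json(self, path: "str | Path") -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: "str | Path") -> "AnalysisConfig":
        d = json.loads(Path(path).read_text())
        if "models" in d:
            d["models"] = tuple(d["models"])
        return cls(**d)


# ---------------------------------------------------------------------------
# stages


def simulate_stage(cfg: AnalysisConfig):
    """Shared trial sequence plus per-subject simulated behavior."""
    seq = make_trial_sequence(
        cfg.n_runs, cfg.trials_per_stimulus, cfg.p_high, cfg.p_low, seed=cfg.seed
    )
    gen_params = ModelParams(cfg.gen_model, alpha=cfg.gen_alpha, omega=cfg.gen_omega)
    datasets: dict[int, BehavioralDataset] = {}
    for s in range(cfg.n_subjects):
        bcfg = GenerativeBehaviorConfig(
            params=gen_params,
            rt_value_slope=cfg.gen_rt_slope,
            rt_noise_sd=cfg.gen_rt_noise_sd,
            seed=cfg.seed * 100_003 + s,
        )
        datasets[s] = simulate_behavior(seq, bcfg)
    return seq, datasets


def fit_stage(cfg: AnalysisConfig, datasets: dict[int, BehavioralDataset]):
    """Per-subject in-sample fits and leave-one-run-out predictive likelihoods."""
    fits: dict[int, dict[str, FitResult]] = {}
    cv_total = np.zeros((len(datasets), len(cfg.models)))
    cv_per_trial = np.zeros_like(cv_total)
    for s, data in datasets.items():
        fits[s] = {}
        for m, model in enumerate(cfg.models):
            fits[s][model] = fit_model(
                data, model, n_restarts=cfg.n_restarts, seed=cfg.seed + s
            )
            cv = cv_predictive_likelihood(
                data, model, n_restarts=cfg.n_restarts, seed=cfg.seed + s
            )
            cv_total[s, m] = cv.total_ll
            cv_per_trial[s, m] = cv.per_trial_ll
    return fits, cv_total, cv_per_trial


def compare_stage(cfg: AnalysisConfig, cv_total: np.ndarray, cv_per_trial: np.ndarray):
    """Group BMS (three- and four-model), pairwise tests, summary table."""
    models = list(cfg.models)
    out: dict = {}
    bms4 = group_bms(cv_total, models, n_mc=cfg.n_mc_bms, seed=cfg.seed)
    out["bms_four_model"] = bms4.to_dict()
    core3 = [m for m in ("no_learning", "feature", "conjunctive") if m in models]
    if len(core3) == 3:
        idx = [models.index(m) for m in core3]
        bms3 = group_bms(cv_total[:, idx], core3, n_mc=cfg.n_mc_bms, seed=cfg.seed)
        out["bms_three_model"] = bms3.to_dict()
    pairs = {}
    if cv_per_trial.shape[0] >= 5:  # signed-rank test needs at least 5 pairs
        for a, b in [("value_spread", "conjunctive"), ("value_spread", "feature"), ("conjunctive", "no_learning")]:
            if a in models and b in models:
                res = pairwise_model_test(
                    cv_per_trial[:, models.index(a)], cv_per_trial[:, models.index(b)]
                )
                pairs[f"{a}_vs_{b}"] = {"T": res.statistic, "p": res.p_value, "n": res.n}
    out["pairwise"] = pairs
    out["mean_cv_per_trial"] = dict(zip(models, cv_per_trial.mean(axis=0).tolist()))
    return out


def group_median_params(fits: dict[int, dict[str, FitResult]], model: str) -> ModelParams:
    """Group-median learning parameters for regressor construction."""
    alphas = [fits[s][model].params.alpha for s in fits]
    omegas = [fits[s][model].params.omega for s in fits]
    return ModelParams(model, alpha=float(np.median(alphas)), omega=float(np.median(omegas)))


def striatal_stage(cfg: AnalysisConfig, seq, fits):
    """Build PE regressors at group-median parameters; decompose planted betas."""
    feat_p = group_median_params(fits, "feature")
    conj_p = group_median_params(fits, "conjunctive")
    regs = build_pe_regressors(seq, feat_p, conj_p)
    betas, subject_ids = [], []
    for s in range(cfg.n_subjects):
        b = simulate_striatal_betas(
            regs,
            {"w_target": cfg.w_target, "w_feature": cfg.w_feature, "w_conj": cfg.w_conj},
            noise_sd=cfg.beta_noise_sd,
            seed=cfg.seed * 100_019 + s,
        )
        betas.append(b)
        subject_ids.append(np.full(len(regs), s))
    group = striatal_beta_regression(
        np.concatenate(betas), regs, np.concatenate(subject_ids)
    )
    r_ft = float(np.corrcoef(regs.z_feature_pe, regs.z_conj_diff)[0, 1])
    r_tgt = float(np.corrcoef(regs.target, regs.z_conj_diff)[0, 1])
    return regs, group, {"r_feature_conjdiff": r_ft, "r_target_conjdiff": r_tgt}


def psa_stage(cfg: AnalysisConfig, seq, fits):
    """PSA of a conjunctive-coding and a feature-mixing synthetic region."""
    vs_params = group_median_params(fits, "value_spread")
    trace = run_model(seq, vs_params)
    design = build_psa_design(seq, trace, include_epoch_interaction=True)
    hip_cfg = GenerativePatternConfig(
        n_units=cfg.n_units,
        within_stimulus_strength=1.0,
        overlap_strength=0.0,
        value_coding_slope=1.0,
        epoch_drift=0.8,
        noise_sd=cfg.pattern_noise_sd,
        seed=cfg.seed * 100_043 + 1,
    )
    ctx_cfg = GenerativePatternConfig(
        n_units=cfg.n_units,
        within_stimulus_strength=0.5,
        overlap_strength=0.6,
        value_coding_slope=1.0,
        epoch_drift=0.0,
        noise_sd=cfg.pattern_noise_sd,
        seed=cfg.seed * 100_043 + 2,
    )
    hip = compute_psm(simulate_patterns(seq, trace, hip_cfg, region="conjunctive_region"))
    ctx = compute_psm(simulate_patterns(seq, trace, ctx_cfg, region="cortical_region"))
    coef = pd.DataFrame(
        {"conjunctive_region": fit_psm_regression(hip, design),
         "cortical_region": fit_psm_regression(ctx, design)}
    )
    cols = ["within_stimulus", "overlap", "value_similarity", "pe_similarity", "value_x_epoch"]
    perms = {
        "conjunctive_region": permutation_test(
            hip, design, cols, n_perm=cfg.n_perm, seed=cfg.seed,
            sides={"value_x_epoch": -1},
        ),
        "cortical_region": permutation_test(
            ctx, design, cols, n_perm=cfg.n_perm, seed=cfg.seed
        ),
    }
    contrast = region_contrast(
        ctx, hip, design, "overlap", n_perm=cfg.n_perm, seed=cfg.seed
    )
    return coef, perms, contrast


def content_stage(cfg: AnalysisConfig, seq):
    """Localizer templates vs conjunctive- and additive-mode task patterns."""
    categories = ["face", "house", "body"]
    # counterbalanced feature-to-category mapping across the three runs
    rotations = [
        {"A": "face", "B": "house", "C": "body"},
        {"A": "house", "B": "body", "C": "face"},
        {"A": "body", "B": "face", "C": "house"},
    ]
    mapping = {r: rotations[r % 3] for r in range(cfg.n_runs)}
    pcfg = GenerativePatternConfig(
        n_units=cfg.n_units, noise_sd=cfg.pattern_noise_sd, seed=cfg.seed * 100_057
    )
    localizer = simulate_localizer(categories, blocks_per_category=6, cfg=pcfg)
    templates = build_templates(localizer)
    conj = template_similarity(
        seq_patterns := simulate_content_patterns(
            seq, categories, mapping, "conjunctive", pcfg, region="conjunctive_region"
        ),
        templates,
        mapping,
    )
    addv = template_similarity(
        simulate_content_patterns(
            seq, categories, mapping, "additive", pcfg, region="cortical_region"
        ),
        templates,
        mapping,
    )
    contrast = content_contrast(conj, addv, n_perm=max(1000, cfg.n_perm // 10), seed=cfg.seed)
    return conj, addv, contrast


def coupling_stage(cfg: AnalysisConfig, seq, fits):
    """Plant and recover the run-level overlap -> conjunctive-PE coupling.

    Each subject's three runs sample low / medium / high overlap-formation
    strengths (shuffled order, jittered), guaranteeing within-subject
    variance of the predictor; the planted conjunctive-PE weight falls
    linearly with that strength.  The coupling region uses twice the unit
    count and lower noise than the group PSA so that single-run (40-trial)
    coefficient estimates carry usable signal, mimicking a well-measured
    ROI.
    """
    vs_params = group_median_params(fits, "value_spread")
    feat_p = group_median_params(fits, "feature")
    conj_p = group_median_params(fits, "conjunctive")
    rng = np.random.default_rng([cfg.seed, 77])
    runs = sorted(set(seq.run_indices.tolist()))
    b_levels = np.array([0.05, 0.4, 0.75])
    overlap_hat, conj_hat, subject_ids = [], [], []
    for s in range(cfg.n_subjects):
        b_order = rng.permutation(len(runs)) % len(b_levels)
        for k, r in enumerate(runs):
            sub_trials = [t for t in seq.trials if t.run_index == r]
            from .task import TrialSequence  # local: build per-run subsequence

            sub_seq = TrialSequence(
                sub_trials, 1, seq.trials_per_stimulus, seq.p_high, seq.p_low
            )
            trace = run_model(sub_seq, vs_params)
            b_sr = float(np.clip(b_levels[b_order[k]] + rng.normal(0, 0.05), 0.0, 1.0))
            w_conj_sr = cfg.w_conj + cfg.coupling_slope * b_sr + 0.02 * rng.standard_normal()
            pat_cfg = GenerativePatternConfig(
                n_units=2 * cfg.n_units,
                within_stimulus_strength=0.8,
                overlap_strength=b_sr,
                noise_sd=0.7 * cfg.pattern_noise_sd,
                seed=int(rng.integers(2**31)),
            )
            psm = compute_psm(simulate_patterns(sub_seq, trace, pat_cfg))
            design = build_psa_design(sub_seq, trace)
            overlap_hat.append(float(fit_psm_regression(psm, design)["overlap"]))
            regs = build_pe_regressors(sub_seq, feat_p, conj_p)
            betas = simulate_striatal_betas(
                regs,
                {"w_target": cfg.w_target, "w_feature": cfg.w_feature, "w_conj": w_conj_sr},
                noise_sd=cfg.beta_noise_sd,
                seed=int(rng.integers(2**31)),
            )
            X = np.column_stack(
                [np.ones(len(regs)), regs.target, regs.z_feature_pe, regs.z_conj_diff]
            )
            coefs, *_ = np.linalg.lstsq(X, betas, rcond=None)
            conj_hat.append(float(coefs[3]))
            subject_ids.append(s)
    return brain_behavior_coupling(
        np.array(overlap_hat), np.array(conj_hat), np.array(subject_ids)
    )


# ---------------------------------------------------------------------------


def _fits_table(fits: dict[int, dict[str, FitResult]]) -> pd.DataFrame:
    rows = []
    for s, per_model in fits.items():
        for model, fr in per_model.items():
            rows.append(
                {
                    "subject": s,
                    "model": model,
                    "alpha": fr.params.alpha,
                    "omega": fr.params.omega,
                    "beta0": fr.params.beta[0],
                    "beta1": fr.params.beta[1] if len(fr.params.beta) > 1 else np.nan,
                    "sigma": fr.params.sigma,
                    "log_likelihood": fr.log_likelihood,
                    "n_included": fr.n_included,
                }
            )
    return pd.DataFrame(rows)


def run_full_analysis(cfg: AnalysisConfig, out_dir: "str | Path") -> dict:
    """Run every stage and write per-stage outputs plus a consolidated report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_json(out / "config.json")
    report: dict = {"seed": cfg.seed}

    stage = "simulate"
    try:
        seq, datasets = simulate_stage(cfg)
        seq.to_frame().to_csv(out / "trial_sequence.tsv", sep="\t", index=False)
        behavior = pd.concat(
            [d.to_frame().assign(subject=s) for s, d in datasets.items()], ignore_index=True
        )
        behavior.to_csv(out / "behavior.tsv", sep="\t", index=False)

        stage = "fit"
        fits, cv_total, cv_per_trial = fit_stage(cfg, datasets)
        fits_df = _fits_table(fits)
        fits_df.to_csv(out / "fits.tsv", sep="\t", index=False)
        cv_df = pd.DataFrame(cv_per_trial, columns=list(cfg.models))
        cv_df.insert(0, "subject", sorted(datasets))
        cv_df.to_csv(out / "cv_per_trial.tsv", sep="\t", index=False)

        stage = "compare"
        comparison = compare_stage(cfg, cv_total, cv_per_trial)
        (out / "model_comparison.json").write_text(json.dumps(comparison, indent=2))
        index_df = conjunctive_index_table(datasets, fits)
        index_df.to_csv(out / "conjunctive_index.tsv", sep="\t", index=False)
        report["model_comparison"] = comparison

        stage = "pe_regressors"
        regs, group, reg_corrs = striatal_stage(cfg, seq, fits)
        regs.to_frame().to_csv(out / "pe_regressors.tsv", sep="\t", index=False)
        striatal = {
            "coef_names": group.names,
            "mean": group.mean.tolist(),
            "t": group.t.tolist(),
            "p": group.p.tolist(),
            "df": group.df,
            **reg_corrs,
        }
        (out / "striatal_regression.json").write_text(json.dumps(striatal, indent=2))
        report["striatal"] = striatal

        stage = "psa"
        coef, perms, contrast = psa_stage(cfg, seq, fits)
        coef.to_csv(out / "psa_coefficients.tsv", sep="\t")
        psa_p = {
            region: {c: {"beta": r.observed, "p": r.p_value} for c, r in res.items()}
            for region, res in perms.items()
        }
        psa_p["overlap_contrast_cortical_minus_conjunctive"] = {
            "difference": contrast.observed,
            "p": contrast.p_value,
        }
        (out / "psa_permutation.json").write_text(json.dumps(psa_p, indent=2))
        report["psa"] = psa_p

        stage = "content"
        conj, addv, ccontrast = content_stage(cfg, seq)
        content = {
            "conjunctive_region": conj.condition_means,
            "cortical_region": addv.condition_means,
            "single_minus_two_conjunctive": conj.single_minus_two,
            "single_minus_two_cortical": addv.single_minus_two,
            "p_condition_conjunctive": ccontrast.condition_effect_a,
            "p_region_difference": ccontrast.region_difference,
        }
        (out / "pattern_content.json").write_text(json.dumps(content, indent=2))
        report["content"] = content

        stage = "coupling"
        coupling = coupling_stage(cfg, seq, fits)
        coup = {
            "slope_mean": coupling.slope_mean,
            "t": coupling.t,
            "p": coupling.p,
            "df": coupling.df,
        }
        (out / "coupling.json").write_text(json.dumps(coup, indent=2))
        report["coupling"] = coup
    except Exception as exc:  # noqa: BLE001 - name the failing stage
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    report["mean_omega"] = float(
        fits_df.query("model == 'value_spread'")["omega"].mean()
    )
    (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
    return report
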