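"""Generative synthetic data for every analysis stage.

The behavior generator emulates the speeded target-detection task: log
reaction times fall linearly with the model-derived stimulus value, an
adaptive response-time threshold tracks the 50% hit rate, and anticipatory
(false-alarm) responses on non-target trials become more likely as the
stimulus value grows.  The pattern generators plant the representational
structures the similarity analyses probe -- stimulus-identity stability,
feature overlap, value coding and its drift over a run -- as explicit
generative strengths, so recovery of each coefficient can be checked
against the planted truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .fitting import BehavioralDataset
from .models import ModelParams, ValueTrace, run_model
from .pe_regressors import PERegressorSet
from .psa import PatternDataset
from .task import STIMULI, STIMULUS_FEATURES, TrialSequence

__all__ = [
    "GenerativeBehaviorConfig",
    "GenerativePatternConfig",
    "calibrate_threshold",
    "simulate_behavior",
    "simulate_patterns",
    "simulate_striatal_betas",
    "simulate_localizer",
    "category_prototypes",
    "simulate_content_patterns",
]

# named substreams off the master seed
_SUB_BEHAVIOR, _SUB_PATTERN, _SUB_BETAS, _SUB_LOCALIZER, _SUB_CONTENT, _SUB_CALIB = range(6)


def _rng(seed: int, substream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(substream)])


@dataclass
class GenerativeBehaviorConfig:
    """Conditions generating a subject's behavior.

    ``params`` supplies the generating learning model; ``rt_value_slope``
    is the beta1 of the RT regression (log-units per unit value, negative =
    faster for higher values).  Thresholds and steps are in seconds; the
    calibration phase uses 30 ms steps and the task phase 10 ms.
    """

    params: ModelParams = field(
        default_factory=lambda: ModelParams("value_spread", alpha=0.3, omega=0.44)
    )
    rt_intercept: float = float(np.log(0.4))
    rt_value_slope: float = -0.4
    rt_noise_sd: float = 0.15
    threshold_init: float | None = None
    threshold_step_calibration: float = 0.030
    threshold_step_task: float = 0.010
    fa_intercept: float = -2.0
    fa_slope: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rt_noise_sd < 0:
            raise ValueError("rt_noise_sd must be non-negative")
        if self.threshold_step_calibration <= 0 or self.threshold_step_task <= 0:
            raise ValueError("threshold steps must be positive")


def calibrate_threshold(cfg: GenerativeBehaviorConfig, n_trials: int = 60) -> float:
    """Pre-task threshold calibration toward a 50% hit rate.

    Emulates the practice phase: reaction times are drawn at baseline value
    (no predictive information), and the threshold moves down 30 ms after a
    fast-enough response and up 30 ms after a slow one, converging on the
    median RT.
    """
    rng = _rng(cfg.seed, _SUB_CALIB)
    thr = 0.5
    for _ in range(n_trials):
        rt = float(np.exp(cfg.rt_intercept + cfg.rt_noise_sd * rng.standard_normal()))
        if rt <= thr:
            thr -= cfg.threshold_step_calibration
        else:
            thr += cfg.threshold_step_calibration
    return max(thr, 0.05)


def simulate_behavior(seq: TrialSequence, cfg: GenerativeBehaviorConfig) -> BehavioralDataset:
    """Simulate one subject's responses, RTs, outcomes and threshold trace.

    Target trials always draw a response with
    ``log rt = rt_intercept + rt_value_slope * v_t + Normal(0, rt_noise_sd)``;
    the trial is a hit (25c) if the RT beats the adaptive threshold and a
    (slow) miss otherwise.  On non-target trials the subject anticipates --
    a false alarm, -25c -- with probability
    ``sigmoid(fa_intercept + fa_slope * v_t)``, otherwise correctly
    rejects.  The threshold moves +-10 ms after each target trial to hold
    the hit rate near 50%.
    """
    rng = _rng(cfg.seed, _SUB_BEHAVIOR)
    trace = run_model(seq, cfg.params)
    thr = cfg.threshold_init if cfg.threshold_init is not None else calibrate_threshold(cfg)
    n = len(seq)
    log_rt = np.full(n, np.nan)
    responded = np.zeros(n, dtype=int)
    outcome = np.empty(n, dtype=object)
    reward = np.zeros(n)
    threshold = np.empty(n)
    for t, trial in enumerate(seq):
        threshold[t] = thr
        latent = cfg.rt_intercept + cfg.rt_value_slope * trace.values[t]
        rt = float(np.exp(latent + cfg.rt_noise_sd * rng.standard_normal()))
        if trial.target == 1:
            responded[t] = 1
            log_rt[t] = np.log(rt)
            if rt <= thr:
                outcome[t] = "hit"
                reward[t] = 0.25
                thr -= cfg.threshold_step_task
            else:
                outcome[t] = "miss"
                thr += cfg.threshold_step_task
        else:
            p_fa = 1.0 / (1.0 + np.exp(-(cfg.fa_intercept + cfg.fa_slope * trace.values[t])))
            if rng.random() < p_fa:
                responded[t] = 1
                log_rt[t] = np.log(rt)
                outcome[t] = "false_alarm"
                reward[t] = -0.25
            else:
                outcome[t] = "correct_rejection"
        thr = max(thr, 0.05)
    return BehavioralDataset(seq, log_rt, responded, outcome, threshold, reward)


@dataclass
class GenerativePatternConfig:
    """Strengths of the planted representational structure.

    ``within_stimulus_strength`` scales a per-stimulus prototype (identity
    coding), ``overlap_strength`` scales shared feature components, and
    ``value_coding_slope`` scales a value-coding component whose *direction*
    rotates with the trial value inside a fixed 2-d plane -- trials with
    similar values therefore have aligned value components, which is the
    structure the value-similarity regressor tests.  ``epoch_drift`` in
    [0, 1] adds a stimulus-specific rotation that grows over the run, so
    value-similar trials of different stimuli drift apart late in learning.
    """

    n_units: int = 60
    within_stimulus_strength: float = 1.0
    overlap_strength: float = 0.0
    value_coding_slope: float = 0.0
    epoch_drift: float = 0.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_units < 10:
            raise ValueError("n_units must be at least 10")
        for name in (
            "within_stimulus_strength",
            "overlap_strength",
            "value_coding_slope",
            "epoch_drift",
            "noise_sd",
        ):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


def _unit_vectors(rng: np.random.Generator, k: int, n_units: int) -> np.ndarray:
    v = rng.standard_normal((k, n_units))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def simulate_patterns(
    seq: TrialSequence,
    trace: "ValueTrace | None",
    cfg: GenerativePatternConfig,
    region: str = "synthetic",
) -> PatternDataset:
    """Generate per-trial multivoxel-like patterns with planted structure.

    ``pattern_t = a * prototype(stim_t) + b * sum_f component(f)
    + c * (cos(theta_t) * e1 + sin(theta_t) * e2) + noise`` with fixed
    seeded unit-norm prototypes/components and an orthonormal value plane
    (e1, e2).  The value angle ``theta_t = v_t * pi + d * progress_t * phi(stim_t)`` rotates with the trial value, so
    value-similar trials carry aligned components; with ``epoch_drift``
    d > 0 a stimulus-specific offset ``phi`` grows with the trial's
    position in its run and scrambles that alignment late in learning.
    """
    if cfg.value_coding_slope != 0.0 and trace is None:
        raise ValueError("value coding requested but no value trace given")
    rng = _rng(cfg.seed, _SUB_PATTERN)
    protos = dict(zip(STIMULI, _unit_vectors(rng, len(STIMULI), cfg.n_units)))
    comps = dict(zip("ABC", _unit_vectors(rng, 3, cfg.n_units)))
    plane, _ = np.linalg.qr(rng.standard_normal((cfg.n_units, 2)))
    e1, e2 = plane[:, 0], plane[:, 1]
    phi = {name: k * np.pi / 2.0 for k, name in enumerate(STIMULI, start=1)}

    n = len(seq)
    X = np.zeros((n, cfg.n_units))
    trial_in_run = np.array([t.trial_index for t in seq.trials], dtype=float)
    runs = seq.run_indices
    for r in np.unique(runs):
        m = runs == r
        span = trial_in_run[m].max()
        trial_in_run[m] = trial_in_run[m] / span if span > 0 else 0.0
    for t, trial in enumerate(seq):
        name = trial.stimulus.name
        x = cfg.within_stimulus_strength * protos[name].copy()
        for f in STIMULUS_FEATURES[name]:
            x = x + cfg.overlap_strength * comps[f]
        if cfg.value_coding_slope != 0.0:
            theta = trace.values[t] * np.pi + cfg.epoch_drift * trial_in_run[t] * phi[name]
            x = x + cfg.value_coding_slope * (np.cos(theta) * e1 + np.sin(theta) * e2)
        X[t] = x
    X += cfg.noise_sd * rng.standard_normal(X.shape)
    meta = seq.to_frame()
    return PatternDataset(region, X, meta)


def simulate_striatal_betas(
    regs: PERegressorSet,
    weights: dict[str, float],
    noise_sd: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Per-trial activation betas as a weighted sum of the PE regressors.

    ``beta_t = w_target * target_t + w_feature * z_feature_pe_t
    + w_conj * z_conj_diff_t + Normal(0, noise_sd)``.
    """
    rng = _rng(seed, _SUB_BETAS)
    w_t = float(weights.get("w_target", 0.0))
    w_f = float(weights.get("w_feature", 0.0))
    w_c = float(weights.get("w_conj", 0.0))
    mu = w_t * regs.target + w_f * regs.z_feature_pe + w_c * regs.z_conj_diff
    return mu + noise_sd * rng.standard_normal(len(regs))


def category_prototypes(
    categories: "list[str]", n_units: int, seed: int
) -> dict[str, np.ndarray]:
    """Fixed unit-norm prototype per localizer category, deterministic in seed."""
    rng = _rng(seed, _SUB_LOCALIZER)
    vecs = _unit_vectors(rng, len(categories), n_units)
    return dict(zip(sorted(categories), vecs))


def simulate_localizer(
    categories: "list[str]",
    blocks_per_category: int,
    cfg: GenerativePatternConfig,
) -> PatternDataset:
    """Localizer miniblocks: category prototype + noise per block.

    Prototypes come from :func:`category_prototypes` with the same seed, so
    task-pattern generators can share them and the task/template analyses
    interlock.
    """
    if len(categories) < 2:
        raise ValueError("need at least 2 categories")
    protos = category_prototypes(list(categories), cfg.n_units, cfg.seed)
    rng = _rng(cfg.seed, _SUB_LOCALIZER + 100)
    rows, labels = [], []
    for cat in sorted(categories):
        for b in range(blocks_per_category):
            rows.append(protos[cat] + cfg.noise_sd * rng.standard_normal(cfg.n_units))
            labels.append({"category": cat, "block": b})
    return PatternDataset("localizer", np.array(rows), pd.DataFrame(labels))


def simulate_content_patterns(
    seq: TrialSequence,
    categories: "list[str]",
    mapping: dict[int, dict[str, str]],
    mode: Literal["conjunctive", "additive"],
    cfg: GenerativePatternConfig,
    region: str | None = None,
    two_feature_gain: float = 1.5,
) -> PatternDataset:
    """Task patterns embodying the two pattern-content hypotheses.

    In ``additive`` (cortical) mode a trial's pattern is the sum of the
    category prototypes of its mapped features -- two-feature patterns are
    mixtures of their components, boosted by ``two_feature_gain`` to model
    the stronger cortical drive of compound stimuli.  In ``conjunctive``
    (hippocampus-like) mode two-feature patterns use a dedicated prototype
    orthogonalized against both feature templates, so they share no
    variance with the localizer categories; single-feature patterns remain
    template + noise.  ``mapping`` follows :func:`template_similarity`:
    ``mapping[run][feature]`` is the category that feature plays in that
    run; feature A maps to ``mapping[run]["A"]``.
    """
    if mode not in ("conjunctive", "additive"):
        raise ValueError(f"unknown mode {mode!r}")
    protos = category_prototypes(list(categories), cfg.n_units, cfg.seed)
    rng = _rng(cfg.seed, _SUB_CONTENT)
    # per-(run, stimulus) conjunctive prototypes, orthogonal to the mapped templates
    conj_protos: dict[tuple[int, str], np.ndarray] = {}
    X = np.zeros((len(seq), cfg.n_units))
    for t, trial in enumerate(seq.trials):
        run, name = trial.run_index, trial.stimulus.name
        run_map = mapping[run]
        feats = sorted(STIMULUS_FEATURES[name])
        templates = [protos[run_map[f]] for f in feats]
        if mode == "additive" or len(feats) == 1:
            gain = two_feature_gain if (mode == "additive" and len(feats) > 1) else 1.0
            signal = gain * np.sum(templates, axis=0)
        else:
            key = (run, name)
            if key not in conj_protos:
                v = rng.standard_normal(cfg.n_units)
                basis = np.array(templates)
                q, _ = np.linalg.qr(basis.T)
                v = v - q @ (q.T @ v)
                conj_protos[key] = v / np.linalg.norm(v)
            signal = conj_protos[key]
        X[t] = signal + cfg.noise_sd * rng.standard_normal(cfg.n_units)
    meta = seq.to_frame()
    return PatternDataset(region or f"{mode}_region", X, meta)
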