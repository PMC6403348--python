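"""Prediction-error regressors and the striatal decomposition analyses.

The striatal outcome response is decomposed into a target effect, a
feature-model prediction-error effect, and a *conjunctive* component: the
per-trial difference between the feature-model and conjunctive-model
prediction errors.  Constructing the conjunctive regressor as a difference
removes the variance the two learning systems share, so its coefficient
measures what conjunctive learning explains over and above feature
learning.  Group inference uses two-stage summary statistics (per-subject
least squares, then one-sample t-tests across subjects), which is
equivalent to random-intercept inference for balanced designs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .models import ModelParams, run_model
from .task import TrialSequence

__all__ = [
    "PERegressorSet",
    "build_pe_regressors",
    "striatal_beta_regression",
    "brain_behavior_coupling",
    "zscore",
]


def zscore(x: np.ndarray) -> np.ndarray:
    """Mean-0, SD-1 standardisation; rejects constant input."""
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("cannot z-score a constant (zero-variance) vector")
    return (x - x.mean()) / sd


@dataclass
class PERegressorSet:
    """Trial-wise parametric regressors for the striatal analysis.

    ``z_feature_pe`` is the z-scored feature-model prediction-error trace;
    ``z_conj_diff`` is the z-scored per-trial difference of the feature and
    conjunctive traces, with the subtraction order recorded in ``sign``.
    """

    target: np.ndarray
    z_feature_pe: np.ndarray
    z_conj_diff: np.ndarray
    sign: str
    feature_params: ModelParams
    conj_params: ModelParams

    def __len__(self) -> int:
        return len(self.target)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "target": self.target,
                "z_feature_pe": self.z_feature_pe,
                "z_conj_diff": self.z_conj_diff,
            }
        )


def build_pe_regressors(
    seq: TrialSequence,
    feature_params: ModelParams,
    conj_params: ModelParams,
    sign: Literal["feature_minus_conj", "conj_minus_feature"] = "feature_minus_conj",
) -> PERegressorSet:
    """Build the z-scored feature-PE and difference regressors for a sequence.

    Both models are run over the same trial sequence; the feature-model
    prediction errors are z-scored directly, and the difference of the two
    PE traces (order set by ``sign``) is z-scored to form the conjunctive
    regressor.  Identical traces make the difference zero-variance and are
    rejected.
    """
    if feature_params.model_kind != "feature":
        raise ValueError("feature_params must have model_kind='feature'")
    if conj_params.model_kind != "conjunctive":
        raise ValueError("conj_params must have model_kind='conjunctive'")
    if sign not in ("feature_minus_conj", "conj_minus_feature"):
        raise ValueError(f"unknown sign convention {sign!r}")
    feat = run_model(seq, feature_params).prediction_errors
    conj = run_model(seq, conj_params).prediction_errors
    diff = feat - conj if sign == "feature_minus_conj" else conj - feat
    return PERegressorSet(
        target=seq.targets.astype(float),
        z_feature_pe=zscore(feat),
        z_conj_diff=zscore(diff),
        sign=sign,
        feature_params=feature_params,
        conj_params=conj_params,
    )


@dataclass
class GroupCoefficients:
    """Two-stage group inference on per-trial regressions."""

    names: list[str]
    subject_coefs: pd.DataFrame  # one row per subject, one column per name
    mean: np.ndarray
    t: np.ndarray
    p: np.ndarray
    df: int
    excluded_subjects: list


def _one_sample_t(coefs: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    n = coefs.shape[0]
    mean = coefs.mean(axis=0)
    se = coefs.std(axis=0, ddof=1) / np.sqrt(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, mean / se, np.sign(mean) * np.inf)
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    return t, p, n - 1


def striatal_beta_regression(
    betas: np.ndarray,
    regs: PERegressorSet,
    subject_ids: np.ndarray,
) -> GroupCoefficients:
    """Regress per-trial activation betas on (target, feature PE, conjunctive PE).

    Stage 1 fits ordinary least squares per subject on the design
    (intercept, target, z_feature_pe, z_conj_diff); stage 2 runs one-sample
    t-tests of each coefficient across subjects.  Rank-deficient per-subject
    designs are excluded and reported.
    """
    betas = np.asarray(betas, dtype=float)
    subject_ids = np.asarray(subject_ids)
    if not (len(betas) == len(subject_ids)):
        raise ValueError("betas and subject_ids must have equal length")
    n_per = len(regs)
    names = ["intercept", "target", "z_feature_pe", "z_conj_diff"]
    X_full = np.column_stack(
        [np.ones(n_per), regs.target, regs.z_feature_pe, regs.z_conj_diff]
    )
    rows, kept, excluded = [], [], []
    for sid in pd.unique(subject_ids):
        mask = subject_ids == sid
        y = betas[mask]
        if len(y) % n_per != 0 and len(y) != n_per:
            raise ValueError(f"subject {sid!r}: {len(y)} betas do not align with the regressors")
        X = X_full if len(y) == n_per else np.tile(X_full, (len(y) // n_per, 1))
        if np.linalg.matrix_rank(X) < X.shape[1]:
            excluded.append(sid)
            continue
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        rows.append(coef)
        kept.append(sid)
    if len(rows) < 2:
        raise ValueError("need at least 2 subjects with full-rank designs")
    coefs = np.asarray(rows)
    t, p, df = _one_sample_t(coefs)
    return GroupCoefficients(
        names,
        pd.DataFrame(coefs, columns=names, index=pd.Index(kept, name="subject")),
        coefs.mean(axis=0),
        t,
        p,
        df,
        excluded,
    )


@dataclass
class CouplingResult:
    """Run-level brain-behavior coupling (two-stage random-slope analog)."""

    slope_mean: float
    t: float
    p: float
    df: int
    subject_slopes: pd.DataFrame
    dropped_subjects: list


def brain_behavior_coupling(
    overlap_beta: np.ndarray,
    conj_beta: np.ndarray,
    subject_ids: np.ndarray,
) -> CouplingResult:
    """Relate run-level pattern-overlap coefficients to conjunctive-PE coefficients.

    Within each subject, both variables are mean-centred across runs and the
    conjunctive-PE coefficient is regressed on the overlap coefficient; the
    per-subject slopes are then tested against zero with a one-sample
    t-test.  Subjects with a single run, or with no overlap variance after
    centring, contribute nothing and are reported as dropped.
    """
    x = np.asarray(overlap_beta, dtype=float)
    y = np.asarray(conj_beta, dtype=float)
    subject_ids = np.asarray(subject_ids)
    if not (len(x) == len(y) == len(subject_ids)):
        raise ValueError("inputs must be aligned per (subject, run)")
    slopes, kept, dropped = [], [], []
    for sid in pd.unique(subject_ids):
        mask = subject_ids == sid
        if mask.sum() < 2:
            dropped.append(sid)
            continue
        xc = x[mask] - x[mask].mean()
        yc = y[mask] - y[mask].mean()
        sxx = float(np.sum(xc**2))
        if sxx == 0:
            dropped.append(sid)
            continue
        slopes.append(float(np.sum(xc * yc)) / sxx)
        kept.append(sid)
    if len(slopes) < 2:
        raise ValueError("need at least 2 subjects with usable runs")
    s = np.asarray(slopes)
    t, p, df = _one_sample_t(s[:, None])
    return CouplingResult(
        float(s.mean()),
        float(t[0]),
        float(p[0]),
        df,
        pd.DataFrame({"slope": s}, index=pd.Index(kept, name="subject")),
        dropped,
    )
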