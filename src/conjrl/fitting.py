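"""Joint maximum-likelihood fitting of learning parameters and the RT regression.

Log reaction times are modelled as Gaussian around a linear function of the
model-derived stimulus value,

    log rt_t ~ Normal(beta0 + beta1 * v_t, sigma^2),

and the learning parameters (alpha, and omega for the value-spread model)
are fit jointly with the regression by maximising the Gaussian
log-likelihood.  For fixed learning parameters the regression weights and
sigma have closed-form ML solutions (ordinary least squares and the RMS
residual), so the optimiser searches only the low-dimensional learning-
parameter box with the regression profiled out analytically.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .models import ModelParams, ValueTrace, run_model
from .task import Stimulus, Trial, TrialSequence

__all__ = [
    "BehavioralDataset",
    "FitResult",
    "CVResult",
    "rt_log_likelihood",
    "fit_model",
    "cv_predictive_likelihood",
]

#: Floor on the profiled residual SD (log-units); avoids a degenerate
#: likelihood on noiseless synthetic data.
SIGMA_FLOOR = 1e-4

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass
class BehavioralDataset:
    """Per-trial behavior aligned with a :class:`TrialSequence`.

    ``log_rt`` is the log reaction time in log-seconds and is NaN exactly
    where ``responded`` is 0.  ``outcome`` labels each trial hit / miss /
    false_alarm / correct_rejection; ``threshold`` records the adaptive
    response-time threshold (seconds) in force on each trial.
    """

    sequence: TrialSequence
    log_rt: np.ndarray
    responded: np.ndarray
    outcome: np.ndarray
    threshold: np.ndarray | None = None
    reward: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.sequence)
        self.log_rt = np.asarray(self.log_rt, dtype=float)
        self.responded = np.asarray(self.responded, dtype=int)
        self.outcome = np.asarray(self.outcome, dtype=object)
        for name in ("log_rt", "responded", "outcome"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match the trial sequence")
        finite = np.isfinite(self.log_rt)
        if not np.array_equal(finite, self.responded == 1):
            raise ValueError("log_rt must be finite exactly on responded trials")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def included(self) -> np.ndarray:
        """Boolean mask of trials entering the likelihood (responded trials)."""
        return self.responded == 1

    @property
    def n_included(self) -> int:
        return int(self.included.sum())

    def subset_runs(self, runs: Sequence[int]) -> "BehavioralDataset":
        """Restrict to the given run indices (order preserved)."""
        keep = np.isin(self.sequence.run_indices, list(runs))
        sub_trials = [t for t, k in zip(self.sequence.trials, keep) if k]
        sub_seq = TrialSequence(
            sub_trials,
            n_runs=len(set(runs)),
            trials_per_stimulus=self.sequence.trials_per_stimulus,
            p_high=self.sequence.p_high,
            p_low=self.sequence.p_low,
        )
        return BehavioralDataset(
            sub_seq,
            self.log_rt[keep],
            self.responded[keep],
            self.outcome[keep],
            None if self.threshold is None else np.asarray(self.threshold)[keep],
            None if self.reward is None else np.asarray(self.reward)[keep],
        )

    def to_frame(self) -> pd.DataFrame:
        df = self.sequence.to_frame()
        rt_ms = np.where(self.responded == 1, np.exp(self.log_rt) * 1000.0, np.nan)
        df["responded"] = self.responded
        df["rt_ms"] = rt_ms
        df["outcome"] = self.outcome
        if self.threshold is not None:
            df["threshold_ms"] = np.asarray(self.threshold) * 1000.0
        if self.reward is not None:
            df["reward"] = self.reward
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, **seq_kwargs) -> "BehavioralDataset":
        seq = TrialSequence.from_frame(df, **seq_kwargs)
        df = df.sort_values(["run", "trial"], kind="stable")
        responded = df["responded"].to_numpy(dtype=int)
        rt_ms = df["rt_ms"].to_numpy(dtype=float)
        log_rt = np.where(responded == 1, np.log(rt_ms / 1000.0), np.nan)
        outcome = df["outcome"].to_numpy(dtype=object) if "outcome" in df else np.where(
            responded == 1, "response", "no_response"
        )
        threshold = (
            df["threshold_ms"].to_numpy(dtype=float) / 1000.0 if "threshold_ms" in df else None
        )
        return cls(seq, log_rt, responded, outcome, threshold)

    def write_tsv(self, path: "str | Path") -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: "str | Path", **seq_kwargs) -> "BehavioralDataset":
        return cls.from_frame(pd.read_csv(path, sep="\t"), **seq_kwargs)


def _design(values: np.ndarray, model_kind: str) -> np.ndarray:
    """Regression design: intercept plus value column (intercept-only for no_learning)."""
    if model_kind == "no_learning":
        return np.ones((len(values), 1))
    return np.column_stack([np.ones(len(values)), values])


def _gaussian_ll(residuals: np.ndarray, sigma: float) -> float:
    n = len(residuals)
    return float(n * (-_LOG_SQRT_2PI - np.log(sigma)) - np.sum(residuals**2) / (2.0 * sigma**2))


def rt_log_likelihood(
    data: BehavioralDataset,
    trace: ValueTrace,
    beta: Sequence[float],
    sigma: "float | Literal['profile']" = "profile",
) -> tuple[float, tuple[float, ...], float]:
    """Gaussian log-likelihood of the included log RTs given a value trace.

    Returns ``(log_likelihood, beta, sigma)``.  With ``sigma="profile"`` the
    residual SD is set to its ML value (RMS residual over included trials,
    floored at :data:`SIGMA_FLOOR`).  ``beta`` is (intercept,) for the
    no-learning model and (intercept, slope) otherwise.
    """
    if len(trace) != len(data):
        raise ValueError("value trace not aligned with the behavioral dataset")
    mask = data.included
    n = int(mask.sum())
    if n == 0:
        raise ValueError("no included trials: cannot evaluate the likelihood")
    X = _design(trace.values[mask], trace.model_kind)
    beta = tuple(float(b) for b in beta)
    if len(beta) != X.shape[1]:
        raise ValueError(f"beta has length {len(beta)}, design expects {X.shape[1]}")
    resid = data.log_rt[mask] - X @ np.asarray(beta)
    if sigma == "profile":
        sigma_val = max(float(np.sqrt(np.mean(resid**2))), SIGMA_FLOOR)
    else:
        sigma_val = float(sigma)
        if sigma_val <= 0:
            raise ValueError(f"sigma must be positive, got {sigma_val}")
    return _gaussian_ll(resid, sigma_val), beta, sigma_val


def _profiled_fit(
    log_rt: np.ndarray, values: np.ndarray, model_kind: str
) -> tuple[float, np.ndarray, float]:
    """OLS + profiled sigma for fixed learning parameters.

    Returns (log-likelihood, beta, sigma).  A rank-deficient design (e.g. a
    constant value trace) falls back to the minimum-norm solution.
    """
    X = _design(values, model_kind)
    beta, *_ = np.linalg.lstsq(X, log_rt, rcond=None)
    resid = log_rt - X @ beta
    sigma = max(float(np.sqrt(np.mean(resid**2))), SIGMA_FLOOR)
    return _gaussian_ll(resid, sigma), beta, sigma


@dataclass
class FitResult:
    """Outcome of a per-subject maximum-likelihood fit."""

    params: ModelParams
    log_likelihood: float
    per_run_ll: dict[int, float]
    n_included: int
    n_restarts: int
    converged: bool

    def to_dict(self) -> dict:
        return {
            "model_kind": self.params.model_kind,
            "alpha": self.params.alpha,
            "omega": self.params.omega,
            "v0": self.params.v0,
            "beta": list(self.params.beta) if self.params.beta is not None else None,
            "sigma": self.params.sigma,
            "log_likelihood": self.log_likelihood,
            "per_run_ll": {str(k): v for k, v in self.per_run_ll.items()},
            "n_included": self.n_included,
            "n_restarts": self.n_restarts,
            "converged": self.converged,
        }


def _free_param_spec(model_kind: str, free_v0: bool) -> list[tuple[str, tuple[float, float]]]:
    spec: list[tuple[str, tuple[float, float]]] = []
    if model_kind in ("base_rate", "feature", "conjunctive", "value_spread"):
        spec.append(("alpha", (0.0, 1.0)))
    if model_kind == "value_spread":
        spec.append(("omega", (0.0, 1.0)))
    if free_v0 and model_kind != "no_learning":
        spec.append(("v0", (0.0, 1.0)))
    return spec


def _params_from_vector(model_kind: str, names: list[str], x: np.ndarray) -> ModelParams:
    kw = dict(zip(names, (float(v) for v in x)))
    return ModelParams(model_kind=model_kind, **kw)


def _per_run_ll(
    data: BehavioralDataset, trace: ValueTrace, beta: np.ndarray, sigma: float
) -> dict[int, float]:
    runs = data.sequence.run_indices
    out: dict[int, float] = {}
    for r in np.unique(runs):
        mask = (runs == r) & data.included
        if not mask.any():
            out[int(r)] = 0.0
            continue
        X = _design(trace.values[mask], trace.model_kind)
        resid = data.log_rt[mask] - X @ beta
        out[int(r)] = _gaussian_ll(resid, sigma)
    return out


def fit_model(
    data: BehavioralDataset,
    model_kind: str,
    *,
    n_restarts: int = 20,
    seed: int = 0,
    free_v0: bool = False,
    reset_between_runs: bool = True,
) -> FitResult:
    """Fit one learning model to a subject's log RTs by maximum likelihood.

    The learning parameters are optimised by bounded L-BFGS-B from
    ``n_restarts`` seeded starting points; the regression weights and sigma
    are profiled analytically at every evaluation.  Ties between restarts go
    to the first-found maximum.
    """
    if data.n_included == 0:
        raise ValueError("no responded trials to fit")
    mask = data.included
    log_rt = data.log_rt[mask]

    spec = _free_param_spec(model_kind, free_v0)
    names = [s[0] for s in spec]
    bounds = [s[1] for s in spec]

    def objective(x: np.ndarray) -> float:
        params = _params_from_vector(model_kind, names, x)
        trace = run_model(data.sequence, params, reset_between_runs=reset_between_runs)
        ll, _, _ = _profiled_fit(log_rt, trace.values[mask], model_kind)
        return -ll

    if not spec:  # no_learning: closed form, nothing to search
        best_x = np.empty(0)
        converged = True
        n_used = 0
    else:
        rng = np.random.default_rng(seed)
        starts = [np.array([0.3] + [0.5] * (len(spec) - 1))]
        lo = np.array([b[0] for b in bounds])
        hi = np.array([b[1] for b in bounds])
        starts += [lo + rng.random(len(spec)) * (hi - lo) for _ in range(max(0, n_restarts - 1))]
        best_x, best_f, converged, n_used = None, np.inf, False, len(starts)
        for x0 in starts:
            res = optimize.minimize(objective, x0, method="L-BFGS-B", bounds=bounds)
            if res.fun < best_f - 1e-12:
                best_x, best_f = res.x, float(res.fun)
                converged = bool(res.success)
        if best_x is None:  # pragma: no cover - all restarts returned inf
            raise RuntimeError("all restarts failed")

    params = _params_from_vector(model_kind, names, best_x)
    trace = run_model(data.sequence, params, reset_between_runs=reset_between_runs)
    ll, beta, sigma = _profiled_fit(log_rt, trace.values[mask], model_kind)
    fitted = replace(params, beta=tuple(float(b) for b in beta), sigma=sigma)
    per_run = _per_run_ll(data, trace, np.asarray(beta), sigma)
    return FitResult(fitted, ll, per_run, int(mask.sum()), n_used, converged)


@dataclass
class CVResult:
    """Cross-validated predictive likelihood under leave-one-run-out."""

    model_kind: str
    total_ll: float
    n_trials: int
    per_run_ll: dict[int, float]
    per_run_n: dict[int, int]

    @property
    def per_trial_ll(self) -> float:
        """Predictive log-likelihood per included held-out trial (nats)."""
        return self.total_ll / self.n_trials


def cv_predictive_likelihood(
    data: BehavioralDataset,
    model_kind: str,
    *,
    n_restarts: int = 20,
    seed: int = 0,
    free_v0: bool = False,
) -> CVResult:
    """Leave-one-run-out predictive log-likelihood of a model.

    For each held-out run, all parameters -- learning parameters, regression
    weights and sigma -- are fit on the remaining runs and the Gaussian
    likelihood is evaluated on the held-out run's responded trials.  The
    total is normalised per included held-out trial so subjects with
    different response counts are comparable.
    """
    runs = np.unique(data.sequence.run_indices)
    if len(runs) < 2:
        raise ValueError("cross-validation needs at least two runs")
    per_run_ll: dict[int, float] = {}
    per_run_n: dict[int, int] = {}
    for held_out in runs:
        train = data.subset_runs([r for r in runs if r != held_out])
        test = data.subset_runs([held_out])
        fit = fit_model(
            train, model_kind, n_restarts=n_restarts, seed=seed, free_v0=free_v0
        )
        trace = run_model(test.sequence, fit.params)
        ll, _, _ = rt_log_likelihood(test, trace, fit.params.beta, fit.params.sigma)
        per_run_ll[int(held_out)] = ll
        per_run_n[int(held_out)] = test.n_included
    total = float(sum(per_run_ll.values()))
    n = int(sum(per_run_n.values()))
    if n == 0:
        raise ValueError("no included held-out trials")
    return CVResult(model_kind, total, n, per_run_ll, per_run_n)
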