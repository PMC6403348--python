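"""Model comparison: random-effects Bayesian model selection and paired tests.

``group_bms`` implements the variational random-effects scheme in which model
frequencies in the population follow a Dirichlet distribution whose
concentration is updated from per-subject log model evidences.  Exceedance
probabilities (the probability that a model is the most frequent) are
estimated by Monte-Carlo sampling of the posterior Dirichlet, and protected
exceedance probabilities correct them by the Bayesian omnibus risk -- the
posterior probability that all models are equally frequent:

    pEP_k = xp_k * (1 - BOR) + BOR / K.

Cross-validated per-subject predictive log-likelihoods serve as the default
evidence proxy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, gammaln, logsumexp

from .fitting import BehavioralDataset, FitResult, rt_log_likelihood
from .models import run_model

__all__ = [
    "BMSResult",
    "group_bms",
    "pairwise_model_test",
    "conjunctive_learning_index",
    "conjunctive_index_table",
]


@dataclass
class BMSResult:
    """Posterior summaries of the random-effects model comparison."""

    model_names: list[str]
    dirichlet_alpha: np.ndarray
    expected_freq: np.ndarray
    xp: np.ndarray
    bor: float
    pep: np.ndarray
    n_mc_samples: int
    seed: int
    converged: bool

    def to_dict(self) -> dict:
        return {
            "model_names": self.model_names,
            "dirichlet_alpha": self.dirichlet_alpha.tolist(),
            "expected_freq": self.expected_freq.tolist(),
            "xp": self.xp.tolist(),
            "bor": self.bor,
            "pep": self.pep.tolist(),
            "n_mc_samples": self.n_mc_samples,
            "seed": self.seed,
            "converged": self.converged,
        }


def _validate_evidence(log_evidence: np.ndarray) -> np.ndarray:
    L = np.asarray(log_evidence, dtype=float)
    if L.ndim != 2:
        raise ValueError("log evidence must be a subjects x models matrix")
    if L.shape[0] < 2 or L.shape[1] < 2:
        raise ValueError("need at least 2 subjects and 2 models")
    if not np.all(np.isfinite(L)):
        raise ValueError("log evidence contains non-finite entries")
    return L


def _vb_dirichlet(
    L: np.ndarray, alpha0: np.ndarray, tol: float = 1e-6, max_iter: int = 10_000
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Variational update of the Dirichlet over model frequencies.

    Returns (posterior concentration, responsibilities, converged flag).
    """
    alpha = alpha0.copy()
    g = np.full_like(L, 1.0 / L.shape[1])
    converged = False
    for _ in range(max_iter):
        log_u = L + (digamma(alpha) - digamma(alpha.sum()))[None, :]
        g = np.exp(log_u - logsumexp(log_u, axis=1, keepdims=True))
        new_alpha = alpha0 + g.sum(axis=0)
        if np.max(np.abs(new_alpha - alpha)) < tol:
            alpha = new_alpha
            converged = True
            break
        alpha = new_alpha
    return alpha, g, converged


def _dirichlet_log_norm(a: np.ndarray) -> float:
    return float(gammaln(a.sum()) - gammaln(a).sum())


def _free_energy(L: np.ndarray, alpha0: np.ndarray, alpha: np.ndarray, g: np.ndarray) -> float:
    """Variational free energy of the random-effects (alternative) model."""
    e_log_r = digamma(alpha) - digamma(alpha.sum())
    f = float(np.sum(g * L))
    f += float(np.sum(g * e_log_r[None, :]))
    f += _dirichlet_log_norm(alpha0) + float(np.sum((alpha0 - 1) * e_log_r))
    with np.errstate(divide="ignore", invalid="ignore"):
        f -= float(np.nansum(g * np.log(np.where(g > 0, g, 1.0))))
    f -= _dirichlet_log_norm(alpha) + float(np.sum((alpha - 1) * e_log_r))
    return f


def _null_evidence(L: np.ndarray) -> float:
    """Log evidence of the null: all models equally frequent (r fixed at 1/K)."""
    n, k = L.shape
    return float(np.sum(logsumexp(L, axis=1) - np.log(k)))


def exceedance_probability(
    alpha: np.ndarray, n_mc: int, seed: int
) -> np.ndarray:
    """Monte-Carlo exceedance probabilities of a Dirichlet distribution."""
    rng = np.random.default_rng(seed)
    xp = np.zeros(len(alpha))
    # sample in blocks to bound memory at ~8 MB per block
    block = 100_000
    remaining = int(n_mc)
    while remaining > 0:
        m = min(block, remaining)
        samples = rng.dirichlet(alpha, size=m)
        winners = np.argmax(samples, axis=1)
        xp += np.bincount(winners, minlength=len(alpha))
        remaining -= m
    return xp / n_mc


def group_bms(
    log_evidence: np.ndarray,
    model_names: "list[str] | None" = None,
    *,
    alpha0: float = 1.0,
    n_mc: int = 1_000_000,
    seed: int = 0,
) -> BMSResult:
    """Random-effects Bayesian model selection over a subjects x models evidence matrix.

    Parameters
    ----------
    log_evidence
        Per-subject log model evidences (e.g. cross-validated predictive
        log-likelihoods), one row per subject, one column per model.
    alpha0
        Symmetric prior Dirichlet concentration (1 = uniform prior over
        frequencies).
    n_mc
        Monte-Carlo sample count for the exceedance probabilities.
    """
    L = _validate_evidence(log_evidence)
    n, k = L.shape
    if model_names is None:
        model_names = [f"model_{i}" for i in range(k)]
    if len(model_names) != k:
        raise ValueError("model_names length does not match the evidence matrix")
    a0 = np.full(k, float(alpha0))
    alpha, g, converged = _vb_dirichlet(L, a0)
    expected_freq = alpha / alpha.sum()
    xp = exceedance_probability(alpha, n_mc, seed)
    f1 = _free_energy(L, a0, alpha, g)
    f0 = _null_evidence(L)
    # BOR = posterior probability of the null given equal prior odds
    bor = float(1.0 / (1.0 + np.exp(f1 - f0)))
    pep = xp * (1.0 - bor) + bor / k
    return BMSResult(
        list(model_names), alpha, expected_freq, xp, bor, pep, int(n_mc), int(seed), converged
    )


@dataclass
class PairwiseTestResult:
    statistic: float
    p_value: float
    n: int
    degenerate: bool


def pairwise_model_test(ll_a: np.ndarray, ll_b: np.ndarray) -> PairwiseTestResult:
    """Two-sided Wilcoxon signed-rank test on paired per-subject likelihoods.

    Exact null enumeration for n <= 25 (no ties), normal approximation
    otherwise.  All-zero differences are degenerate and flagged rather than
    tested.
    """
    a = np.asarray(ll_a, dtype=float)
    b = np.asarray(ll_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be paired 1-d arrays of equal length")
    if len(a) < 5:
        raise ValueError("need at least 5 pairs")
    d = a - b
    if np.all(d == 0):
        return PairwiseTestResult(np.nan, np.nan, len(a), True)
    method = "exact" if len(d) <= 25 and len(np.unique(np.abs(d[d != 0]))) == len(d[d != 0]) else "approx"
    res = stats.wilcoxon(d, alternative="two-sided", method=method)
    return PairwiseTestResult(float(res.statistic), float(res.pvalue), len(a), False)


@dataclass
class ConjunctiveIndex:
    """Per-run conjunctive-learning index and engagement nuisance.

    ``index`` = per-run LL(conjunctive) - LL(value_spread), each evaluated at
    that model's own subject-level maximum-likelihood parameters; in-sample
    it is <= 0 by nesting, and values nearer 0 indicate more purely
    conjunctive behavior.  ``engagement`` = LL(value_spread) -
    LL(no_learning), a per-run measure of how much learning helps at all.
    """

    subject: int
    run: int
    index: float
    engagement: float


def _per_run_ll_at(data: BehavioralDataset, fit: FitResult, run: int) -> float:
    sub = data.subset_runs([run])
    trace = run_model(sub.sequence, fit.params)
    ll, _, _ = rt_log_likelihood(sub, trace, fit.params.beta, fit.params.sigma)
    return ll


def conjunctive_learning_index(
    data: BehavioralDataset,
    fits: dict[str, FitResult],
    run: int,
    subject: int = 0,
) -> ConjunctiveIndex:
    """Conjunctive-learning index for one run of one subject.

    ``fits`` must contain FitResults (subject-level, fit across runs) for
    'conjunctive', 'value_spread' and 'no_learning'.
    """
    for name in ("conjunctive", "value_spread", "no_learning"):
        if name not in fits:
            raise ValueError(f"missing fit for {name!r}")
    ll_conj = _per_run_ll_at(data, fits["conjunctive"], run)
    ll_vs = _per_run_ll_at(data, fits["value_spread"], run)
    ll_null = _per_run_ll_at(data, fits["no_learning"], run)
    return ConjunctiveIndex(subject, int(run), ll_conj - ll_vs, ll_vs - ll_null)


def conjunctive_index_table(
    datasets: dict[int, BehavioralDataset],
    fits_by_subject: dict[int, dict[str, FitResult]],
) -> pd.DataFrame:
    """Conjunctive-learning index for every (subject, run)."""
    rows = []
    for subject, data in datasets.items():
        for run in np.unique(data.sequence.run_indices):
            idx = conjunctive_learning_index(
                data, fits_by_subject[subject], int(run), subject
            )
            rows.append(
                {
                    "subject": subject,
                    "run": idx.run,
                    "index": idx.index,
                    "engagement": idx.engagement,
                }
            )
    return pd.DataFrame(rows)
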