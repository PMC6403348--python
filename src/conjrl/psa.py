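"""Pattern-similarity analysis: trial-pair regression with permutation inference.

A pattern-similarity matrix (PSM) holds the Fisher-transformed correlation
between the multivoxel activity patterns of every pair of trials.  The PSM
is regressed on pair-level predictors derived from the task and the
value-learning model -- within-stimulus identity, feature overlap,
prediction-error and value similarity, plus response/target/run/time
nuisance terms -- and coefficients are tested against null distributions
built by shuffling the pair similarities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .models import ValueTrace
from .task import TrialSequence, feature_overlap

__all__ = [
    "PatternDataset",
    "PatternSimilarityMatrix",
    "PSADesign",
    "compute_psm",
    "build_psa_design",
    "fit_psm_regression",
    "permutation_test",
    "region_contrast",
]

#: Correlations are clipped to this magnitude before the Fisher transform so
#: that identical patterns map to a finite z.
R_CLIP = 1.0 - 1e-7


@dataclass
class PatternDataset:
    """Trials x units activation matrix for one region, with trial metadata."""

    region: str
    data: np.ndarray
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("pattern data must be a 2-d trials x units array")
        if self.data.shape[1] < 2:
            raise ValueError("need at least 2 units")
        if len(self.meta) != self.data.shape[0]:
            raise ValueError("metadata rows must match pattern rows")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("pattern data contains non-finite entries")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]


@dataclass
class PatternSimilarityMatrix:
    """Upper-triangle trial-pair similarities (Fisher-z), with an exclusion mask."""

    i: np.ndarray
    j: np.ndarray
    z: np.ndarray
    valid: np.ndarray
    region: str
    n_trials: int

    def __len__(self) -> int:
        return len(self.z)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"i": self.i, "j": self.j, "fisher_z": self.z, "valid": self.valid}
        )


def _pair_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    iu = np.triu_indices(n, k=1)
    return iu[0], iu[1]


def compute_psm(patterns: PatternDataset) -> PatternSimilarityMatrix:
    """Pairwise pattern correlations for all trial pairs, Fisher-transformed.

    Zero-variance trial patterns produce undefined correlations; every pair
    involving such a trial is flagged invalid and excluded from regression.
    """
    X = patterns.data
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 trials for a similarity matrix")
    sd = X.std(axis=1)
    ok = sd > 0
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.where(ok, np.linalg.norm(Xc, axis=1), 1.0)
    U = Xc / norms[:, None]
    R = U @ U.T
    i, j = _pair_indices(n)
    r = np.clip(R[i, j], -R_CLIP, R_CLIP)
    z = np.arctanh(r)
    valid = ok[i] & ok[j]
    z[~valid] = np.nan
    return PatternSimilarityMatrix(i, j, z, valid, patterns.region, n)


@dataclass
class PSADesign:
    """Pair-level design matrix: z-scored named columns over all trial pairs."""

    columns: pd.DataFrame
    i: np.ndarray
    j: np.ndarray
    orthogonalized: list[str]
    notes: dict = field(default_factory=dict)

    @property
    def names(self) -> list[str]:
        return list(self.columns.columns)

    def matrix(self, names: "Sequence[str] | None" = None) -> np.ndarray:
        cols = self.columns if names is None else self.columns[list(names)]
        return cols.to_numpy(dtype=float)


def _zscore_cols(df: pd.DataFrame) -> pd.DataFrame:
    out = {}
    for name in df.columns:
        x = df[name].to_numpy(dtype=float)
        sd = x.std()
        if sd == 0:
            raise ValueError(f"design column {name!r} is constant and cannot be z-scored")
        out[name] = (x - x.mean()) / sd
    return pd.DataFrame(out)


def _residualize(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ coef


def build_psa_design(
    seq: TrialSequence,
    trace: "ValueTrace | None" = None,
    *,
    include_value: bool = True,
    include_pe: bool = True,
    include_epoch_interaction: bool = False,
    split_overlap: bool = False,
) -> PSADesign:
    """Build the pair-level regressor set for a trial sequence.

    Columns (all z-scored; an intercept is added at fit time):

    * ``within_stimulus`` -- 1 for repetitions of the identical stimulus.
    * ``overlap`` -- +1 for different stimuli sharing a feature, -1 for
      different stimuli sharing none, 0 for same-stimulus pairs (or, with
      ``split_overlap``, separate ``overlap_share`` / ``overlap_noshare``
      indicators for visualization-style models).
    * ``pe_similarity`` / ``value_similarity`` -- negated absolute
      differences of the trial prediction errors / updated values, so
      positive coefficients mean similarity coding; both are residualized
      against the response and target columns (plus intercept) before
      z-scoring.
    * ``response`` -- +1 when the two trials demand the same response (both
      target or both non-target), -1 otherwise.
    * ``target`` -- +1 both-target, -1 both-non-target, 0 mixed.
    * ``run_<r>`` -- indicator for both trials falling in run r.
    * ``time_linear`` / ``time_quadratic`` -- elapsed time between the two
      trials (global trial index difference) and its square.
    * ``time_x_within`` -- elapsed time restricted to within-stimulus pairs.
    * ``value_x_epoch`` (optional) -- the value-similarity column crossed
      with an epoch code (+1 both trials late in their run, -1 both early,
      0 mixed; split at the run's median trial index).
    """
    n = len(seq)
    if (include_value or include_pe) and trace is None:
        raise ValueError("value/PE columns requested but no value trace given")
    if trace is not None and len(trace) != n:
        raise ValueError("value trace not aligned with the trial sequence")

    i, j = _pair_indices(n)
    stim = np.array(seq.stimulus_names)
    targ = seq.targets
    runs = seq.run_indices
    trial_in_run = np.array([t.trial_index for t in seq.trials])
    global_pos = np.arange(n)

    within = (stim[i] == stim[j]).astype(float)
    ov_lookup = {
        (a, b): feature_overlap(a, b) for a in set(stim) for b in set(stim)
    }
    share = np.array([ov_lookup[(a, b)] for a, b in zip(stim[i], stim[j])], dtype=float)
    overlap = np.where(within == 1, 0.0, np.where(share == 1, 1.0, -1.0))

    same_target = targ[i] == targ[j]
    response = np.where(same_target, 1.0, -1.0)
    target = np.where(
        same_target & (targ[i] == 1), 1.0, np.where(same_target & (targ[i] == 0), -1.0, 0.0)
    )

    raw: dict[str, np.ndarray] = {"within_stimulus": within}
    if split_overlap:
        raw["overlap_share"] = np.where((within == 0) & (share == 1), 1.0, 0.0)
        raw["overlap_noshare"] = np.where((within == 0) & (share == 0), 1.0, 0.0)
    else:
        raw["overlap"] = overlap

    orthogonalized: list[str] = []
    nuisance = np.column_stack([np.ones(len(i)), response, target])
    if include_pe:
        pe = trace.prediction_errors
        pe_sim = -np.abs(pe[i] - pe[j])
        raw["pe_similarity"] = _residualize(pe_sim, nuisance)
        orthogonalized.append("pe_similarity")
    if include_value:
        v = trace.updated_values if trace.updated_values is not None else trace.values
        val_sim = -np.abs(v[i] - v[j])
        val_orth = _residualize(val_sim, nuisance)
        raw["value_similarity"] = val_orth
        orthogonalized.append("value_similarity")

    raw["response"] = response
    raw["target"] = target
    if len(np.unique(runs)) > 1:  # single-run designs have no session structure
        for r in np.unique(runs):
            raw[f"run_{r}"] = ((runs[i] == r) & (runs[j] == r)).astype(float)
    elapsed = np.abs(global_pos[i] - global_pos[j]).astype(float)
    raw["time_linear"] = elapsed
    raw["time_quadratic"] = elapsed**2
    raw["time_x_within"] = elapsed * within

    if include_epoch_interaction:
        if not include_value:
            raise ValueError("the epoch interaction requires the value column")
        late = np.zeros(n, dtype=bool)
        for r in np.unique(runs):
            m = runs == r
            late[m] = trial_in_run[m] > np.median(trial_in_run[m])
        epoch = np.where(
            late[i] & late[j], 1.0, np.where(~late[i] & ~late[j], -1.0, 0.0)
        )
        raw["value_x_epoch"] = raw["value_similarity"] * epoch

    cols = _zscore_cols(pd.DataFrame(raw))
    return PSADesign(
        cols,
        i,
        j,
        orthogonalized,
        notes={
            "value_pe_sign": "negated_absolute_difference (positive = similarity coding)",
            "epoch_coding": "+1 both-late / -1 both-early / 0 mixed, median split per run",
        },
    )


def _fit_matrix(design: PSADesign, valid: np.ndarray) -> tuple[np.ndarray, list[str]]:
    X = design.matrix()[valid]
    X = np.column_stack([np.ones(len(X)), X])
    names = ["intercept"] + design.names
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the offending columns by greedy elimination
        bad = []
        keep: list[int] = []
        for k in range(X.shape[1]):
            if np.linalg.matrix_rank(X[:, keep + [k]]) > len(keep):
                keep.append(k)
            else:
                bad.append(names[k])
        raise ValueError(f"design is rank deficient; offending columns: {bad}")
    return X, names


def fit_psm_regression(psm: PatternSimilarityMatrix, design: PSADesign) -> pd.Series:
    """Ordinary least squares of the pair similarities on the design columns."""
    if len(psm) != len(design.i):
        raise ValueError("PSM pairs do not match the design pairs")
    X, names = _fit_matrix(design, psm.valid)
    y = psm.z[psm.valid]
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return pd.Series(coef, index=names, name=psm.region)


@dataclass
class PermutationResult:
    column: str
    observed: float
    p_value: float
    null: np.ndarray
    n_perm: int
    side: int


def _null_betas(
    X: np.ndarray, y: np.ndarray, col_idx: np.ndarray, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Null coefficient distributions from shuffles of the similarity vector.

    Returns an (n_perm, len(col_idx)) array; blocks bound peak memory.
    """
    pinv = np.linalg.pinv(X)[col_idx]  # (k, n)
    out = np.empty((n_perm, len(col_idx)))
    block = 1000
    done = 0
    while done < n_perm:
        m = min(block, n_perm - done)
        perms = np.empty((len(y), m))
        for b in range(m):
            perms[:, b] = y[rng.permutation(len(y))]
        out[done : done + m] = (pinv @ perms).T
        done += m
    return out


def permutation_test(
    psm: PatternSimilarityMatrix,
    design: PSADesign,
    columns: Sequence[str],
    n_perm: int = 10_000,
    seed: int = 0,
    sides: "dict[str, int] | None" = None,
) -> dict[str, PermutationResult]:
    """One-sided permutation tests on PSM regression coefficients.

    The similarity vector is shuffled uniformly ``n_perm`` times and the
    regression refit each time; for each requested column the one-sided
    p-value is ``(1 + #{null >= observed}) / (1 + n_perm)`` in the tested
    direction (``sides[column]`` = +1 for positive effects, -1 for
    negative; default +1).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    observed = fit_psm_regression(psm, design)
    X, names = _fit_matrix(design, psm.valid)
    y = psm.z[psm.valid]
    col_idx = np.array([names.index(c) for c in columns])
    rng = np.random.default_rng(seed)
    nulls = _null_betas(X, y, col_idx, n_perm, rng)
    sides = sides or {}
    results = {}
    for k, c in enumerate(columns):
        s = int(sides.get(c, 1))
        obs = float(observed[c])
        null = nulls[:, k]
        p = (1.0 + np.sum(s * null >= s * obs)) / (1.0 + n_perm)
        results[c] = PermutationResult(c, obs, float(p), null, n_perm, s)
    return results


def region_contrast(
    psm_a: PatternSimilarityMatrix,
    psm_b: PatternSimilarityMatrix,
    design: PSADesign,
    column: str,
    n_perm: int = 10_000,
    seed: int = 0,
    side: int = 1,
) -> PermutationResult:
    """One-sided permutation test for a coefficient difference between regions.

    Each shuffle permutes both regions' similarity vectors independently and
    records the difference of the column's refit coefficients; identical
    regions therefore give an observed difference of 0 against a symmetric
    null (p near .5), not a degenerate one.
    """
    if psm_a.n_trials != psm_b.n_trials or not np.array_equal(
        psm_a.valid, psm_b.valid
    ):
        raise ValueError("regions must share the same trial-pair set and exclusions")
    coef_a = fit_psm_regression(psm_a, design)
    coef_b = fit_psm_regression(psm_b, design)
    obs = float(coef_a[column] - coef_b[column])
    X, names = _fit_matrix(design, psm_a.valid)
    ya = psm_a.z[psm_a.valid]
    yb = psm_b.z[psm_b.valid]
    col_idx = np.array([names.index(column)])
    rng = np.random.default_rng(seed)
    pinv = np.linalg.pinv(X)[col_idx]
    null = np.empty(n_perm)
    for b in range(n_perm):
        d = pinv @ ya[rng.permutation(len(ya))] - pinv @ yb[rng.permutation(len(yb))]
        null[b] = float(d[0])
    p = (1.0 + np.sum(side * null >= side * obs)) / (1.0 + n_perm)
    return PermutationResult(column, obs, float(p), null, n_perm, side)
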