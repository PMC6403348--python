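"""Pattern-content analysis: task patterns against localizer category templates.

Category templates are the mean pattern across localizer miniblocks of each
visual category.  Each task trial's pattern is correlated (Fisher-z) with
the template of the category its *single* diagnostic feature maps to in
that run: B and AB score against B's category, C and AC against C's.
Because a two-feature trial and its single-feature partner are always
scored against the same template within a run, any single- vs two-feature
difference reflects the task representation, not the localizer.  A
conjunctive (pattern-separated) region shows higher similarity for
single-feature trials; a feature-mixing cortical region shows equal or
higher similarity for two-feature trials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .psa import PatternDataset, R_CLIP

__all__ = [
    "TemplateSet",
    "ContentResult",
    "build_templates",
    "template_similarity",
    "content_contrast",
]

#: Which stimulus is scored against which feature's template.
_SCORING_FEATURE = {"B": "B", "AB": "B", "C": "C", "AC": "C"}

#: Condition labels by stimulus.
_CONDITION = {"B": "single_feature", "C": "single_feature", "AB": "two_feature", "AC": "two_feature"}


@dataclass
class TemplateSet:
    """Category -> mean localizer pattern."""

    templates: dict[str, np.ndarray]
    n_units: int
    source_blocks: dict[str, int]
    degenerate: list[str]

    def __getitem__(self, category: str) -> np.ndarray:
        return self.templates[category]

    @property
    def categories(self) -> list[str]:
        return list(self.templates)


def build_templates(localizer: PatternDataset) -> TemplateSet:
    """Per-category mean across localizer blocks.

    Requires a ``category`` column in the localizer metadata and at least
    one block per category present.  Templates with zero variance (e.g.
    exact cancellation across blocks) are kept but flagged degenerate,
    since they cannot enter a correlation.
    """
    if "category" not in localizer.meta.columns:
        raise ValueError("localizer metadata needs a 'category' column")
    cats = localizer.meta["category"].to_numpy()
    templates: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    degenerate: list[str] = []
    for cat in pd.unique(cats):
        mask = cats == cat
        if not mask.any():
            raise ValueError(f"category {cat!r} has no blocks")
        t = localizer.data[mask].mean(axis=0)
        templates[str(cat)] = t
        counts[str(cat)] = int(mask.sum())
        if t.std() == 0:
            degenerate.append(str(cat))
    return TemplateSet(templates, localizer.data.shape[1], counts, degenerate)


def _corr_z(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    nx, ny = np.linalg.norm(xc), np.linalg.norm(yc)
    if nx == 0 or ny == 0:
        return np.nan
    r = float(np.clip(xc @ yc / (nx * ny), -R_CLIP, R_CLIP))
    return float(np.arctanh(r))


@dataclass
class ContentResult:
    """Task-to-template similarity summaries for one region."""

    region: str
    trial_table: pd.DataFrame  # run, trial, stimulus, condition, fisher_z
    condition_means: dict[str, float]
    per_run_means: pd.DataFrame  # run x condition

    @property
    def single_minus_two(self) -> float:
        return self.condition_means["single_feature"] - self.condition_means["two_feature"]


def template_similarity(
    task: PatternDataset,
    templates: TemplateSet,
    mapping: dict[int, dict[str, str]],
) -> ContentResult:
    """Correlate each task trial with its run-mapped category template.

    ``mapping[run][feature]`` names the localizer category that feature B or
    C plays in that run (the category-to-feature assignment is
    counterbalanced across runs).  AB trials use B's category and AC trials
    use C's, so condition contrasts are template-matched by construction.
    """
    meta = task.meta
    for col in ("run", "stimulus"):
        if col not in meta.columns:
            raise ValueError(f"task metadata needs a {col!r} column")
    rows = []
    for idx in range(task.n_trials):
        run = int(meta["run"].iloc[idx])
        stim = str(meta["stimulus"].iloc[idx])
        feature = _SCORING_FEATURE[stim]
        run_map = mapping.get(run)
        if run_map is None or feature not in run_map:
            raise ValueError(f"no category mapped for feature {feature!r} in run {run}")
        category = run_map[feature]
        if category not in templates.templates:
            raise ValueError(f"unmapped category {category!r}")
        z = _corr_z(task.data[idx], templates[category])
        rows.append(
            {
                "run": run,
                "trial": int(meta["trial"].iloc[idx]) if "trial" in meta.columns else idx,
                "stimulus": stim,
                "condition": _CONDITION[stim],
                "category": category,
                "fisher_z": z,
            }
        )
    table = pd.DataFrame(rows)
    per_run = table.pivot_table(index="run", columns="condition", values="fisher_z", aggfunc="mean")
    condition_means = {
        cond: float(per_run[cond].mean()) for cond in per_run.columns
    }
    return ContentResult(task.region, table, condition_means, per_run)


@dataclass
class ContentContrast:
    """Permutation p-values for condition and region effects."""

    condition_effect_a: float  # single > two within region a
    condition_effect_b: float
    region_difference: float  # (single - two)_a > (single - two)_b
    interaction: float  # alias of region_difference, kept for clarity
    n_perm: int
    seed: int


def _condition_diff(table: pd.DataFrame, cond: np.ndarray) -> float:
    z = table["fisher_z"].to_numpy()
    return float(np.nanmean(z[cond == "single_feature"]) - np.nanmean(z[cond == "two_feature"]))


def content_contrast(
    result_a: ContentResult,
    result_b: ContentResult,
    n_perm: int = 10_000,
    seed: int = 0,
) -> ContentContrast:
    """Permutation tests of the single- vs two-feature effect and its region difference.

    Nulls are built by shuffling the condition labels of trials within each
    run, with independent shuffles for the two regions so that the
    region-difference null is non-degenerate even for identical inputs.
    All p-values are one-sided for single > two-feature (and for the effect
    being larger in region A than region B).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    ta, tb = result_a.trial_table, result_b.trial_table
    if not np.array_equal(ta["run"].to_numpy(), tb["run"].to_numpy()) or not np.array_equal(
        ta["stimulus"].to_numpy(), tb["stimulus"].to_numpy()
    ):
        raise ValueError("regions must share the same run/trial structure")
    cond = ta["condition"].to_numpy()
    runs = ta["run"].to_numpy()
    obs_a = _condition_diff(ta, cond)
    obs_b = _condition_diff(tb, cond)
    obs_diff = obs_a - obs_b
    rng = np.random.default_rng(seed)
    count_a = count_b = count_diff = 0
    run_masks = [np.flatnonzero(runs == r) for r in np.unique(runs)]

    def shuffle_labels() -> np.ndarray:
        out = cond.copy()
        for m in run_masks:
            out[m] = out[m][rng.permutation(len(m))]
        return out

    for _ in range(n_perm):
        na = _condition_diff(ta, shuffle_labels())
        nb = _condition_diff(tb, shuffle_labels())
        count_a += na >= obs_a
        count_b += nb >= obs_b
        count_diff += (na - nb) >= obs_diff
    return ContentContrast(
        condition_effect_a=(1.0 + count_a) / (1.0 + n_perm),
        condition_effect_b=(1.0 + count_b) / (1.0 + n_perm),
        region_difference=(1.0 + count_diff) / (1.0 + n_perm),
        interaction=(1.0 + count_diff) / (1.0 + n_perm),
        n_perm=n_perm,
        seed=seed,
    )
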