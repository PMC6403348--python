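"""Value-learning models and per-trial value / prediction-error traces.

All four learning models share the delta rule

    V(s) <- V(s) + alpha * (R - V(s)),

where R is the binary target indicator (values code the stimulus-target
association, never the monetary outcome).  The models differ in the state
space over which values are maintained:

* ``no_learning`` -- no values at all; the trace is constant v0.
* ``base_rate``   -- one shared value for all four stimuli.
* ``feature``     -- one value per feature A, B, C; the prediction for a
  compound stimulus is the *sum* of its features' values, and every present
  feature receives the full alpha*delta update.
* ``conjunctive`` -- one value per stimulus; only the presented stimulus
  updates.
* ``value_spread`` -- conjunctive learning plus leakage: a fraction omega of
  the update is also applied to every other stimulus sharing a feature with
  the presented one.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .task import STIMULI, STIMULUS_FEATURES, Stimulus, TrialSequence, feature_overlap

__all__ = ["ModelKind", "ModelParams", "ValueTrace", "initial_state", "value_update", "run_model"]

ModelKind = Literal["no_learning", "base_rate", "feature", "conjunctive", "value_spread"]

MODEL_KINDS: tuple[str, ...] = (
    "no_learning",
    "base_rate",
    "feature",
    "conjunctive",
    "value_spread",
)

_FEATURES: tuple[str, ...] = ("A", "B", "C")


@dataclass(frozen=True)
class ModelParams:
    """Parameters of a learning model plus the RT regression it feeds.

    Attributes
    ----------
    model_kind
        Which state representation is learned over.
    alpha
        Learning rate in [0, 1].
    omega
        Spread weight in [0, 1]; used by ``value_spread`` only.
    v0
        Initial value assigned to every state at the start of each run.
    beta
        RT regression weights (intercept, value slope); None until fitted.
    sigma
        Residual SD of log RT; None until fitted/profiled.
    """

    model_kind: str
    alpha: float = 0.0
    omega: float = 0.0
    v0: float = 0.0
    beta: tuple[float, float] | None = None
    sigma: float | None = None

    def __post_init__(self) -> None:
        if self.model_kind not in MODEL_KINDS:
            raise ValueError(
                f"unknown model_kind {self.model_kind!r}; expected one of {MODEL_KINDS}"
            )
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")
        if not (0.0 <= self.omega <= 1.0):
            raise ValueError(f"omega must lie in [0, 1], got {self.omega}")
        if self.sigma is not None and self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")

    @property
    def n_free_rl_params(self) -> int:
        return {"no_learning": 0, "base_rate": 1, "feature": 1, "conjunctive": 1, "value_spread": 2}[
            self.model_kind
        ]


def initial_state(params: ModelParams) -> dict[str, float]:
    """Fresh value state for the given model, every key at v0."""
    kind = params.model_kind
    if kind == "feature":
        keys: tuple[str, ...] = _FEATURES
    elif kind in ("conjunctive", "value_spread"):
        keys = STIMULI
    elif kind == "base_rate":
        keys = ("__all__",)
    else:  # no_learning keeps an (unused) single key so predict() is uniform
        keys = ("__all__",)
    return {k: float(params.v0) for k in keys}


def _predict(state: dict[str, float], stimulus: str, kind: str) -> float:
    """Model-predicted value of the presented stimulus before the update."""
    if kind == "feature":
        return sum(state[f] for f in sorted(STIMULUS_FEATURES[stimulus]))
    if kind in ("conjunctive", "value_spread"):
        return state[stimulus]
    return state["__all__"]


def value_update(
    state: dict[str, float],
    stimulus: "Stimulus | str",
    R: int,
    params: ModelParams,
) -> dict[str, float]:
    """Apply one trial's delta-rule update and return the new state.

    The prediction error is delta = R - V(stimulus) with V computed under
    the model's state representation (sum of feature values for the feature
    model).  The input state is not mutated.
    """
    if R not in (0, 1):
        raise ValueError(f"R must be 0 or 1, got {R!r}")
    name = stimulus.name if isinstance(stimulus, Stimulus) else str(stimulus)
    if name not in STIMULUS_FEATURES:
        raise ValueError(f"unknown stimulus {name!r}")
    kind = params.model_kind
    expected = set(initial_state(params))
    if set(state) != expected:
        raise ValueError(
            f"state keys {sorted(state)} do not match model {kind!r} (need {sorted(expected)})"
        )

    new = dict(state)
    if kind == "no_learning":
        return new
    delta = R - _predict(state, name, kind)
    a_d = params.alpha * delta
    if kind == "base_rate":
        new["__all__"] += a_d
    elif kind == "feature":
        for f in STIMULUS_FEATURES[name]:
            new[f] += a_d
    elif kind == "conjunctive":
        new[name] += a_d
    else:  # value_spread
        new[name] += a_d
        for other in STIMULI:
            if feature_overlap(name, other):
                new[other] += a_d * params.omega
    return new


@dataclass
class ValueTrace:
    """Per-trial stimulus values and prediction errors.

    ``values[t]`` is V(stimulus_t) immediately before trial t's update,
    ``prediction_errors[t] = target_t - values[t]`` exactly, and
    ``updated_values[t]`` is V(stimulus_t) immediately *after* the update
    (used by the pattern-similarity value regressor).
    """

    values: np.ndarray
    prediction_errors: np.ndarray
    model_kind: str
    updated_values: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.prediction_errors = np.asarray(self.prediction_errors, dtype=float)
        if self.values.shape != self.prediction_errors.shape:
            raise ValueError("values and prediction_errors must have equal length")
        if self.updated_values is not None:
            self.updated_values = np.asarray(self.updated_values, dtype=float)
            if self.updated_values.shape != self.values.shape:
                raise ValueError("updated_values must match values in length")

    def __len__(self) -> int:
        return len(self.values)


def run_model(
    seq: TrialSequence,
    params: ModelParams,
    *,
    reset_between_runs: bool = True,
) -> ValueTrace:
    """Run a learning model over a trial sequence.

    The state is re-initialised to v0 at the start of every run by default
    (the stimulus-to-category mappings change between runs, so learning
    cannot meaningfully carry over); pass ``reset_between_runs=False`` for
    sensitivity checks.
    """
    if len(seq) == 0:
        raise ValueError("empty trial sequence")
    values = np.empty(len(seq))
    pes = np.empty(len(seq))
    post = np.empty(len(seq))
    state = initial_state(params)
    current_run = seq.trials[0].run_index
    for i, trial in enumerate(seq):
        if reset_between_runs and trial.run_index != current_run:
            state = initial_state(params)
            current_run = trial.run_index
        v = _predict(state, trial.stimulus.name, params.model_kind)
        values[i] = v
        pes[i] = trial.target - v
        state = value_update(state, trial.stimulus, trial.target, params)
        post[i] = _predict(state, trial.stimulus.name, params.model_kind)
    return ValueTrace(values, pes, params.model_kind, post)
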