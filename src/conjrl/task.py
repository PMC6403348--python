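"""Task structure: stimuli, trials, and pseudo-random trial sequences.

The task presents four compound stimuli built from three features A, B, C:
two-feature stimuli AB and AC and single-feature stimuli B and C.  A "go"
target follows AB and C with high probability (0.7 by default) and AC and B
with low probability (0.3).  Each feature alone predicts the target exactly
50% of the time, so above-chance anticipation requires learning values for
the stimulus *conjunctions*, not the features.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

__all__ = [
    "STIMULI",
    "STIMULUS_FEATURES",
    "Stimulus",
    "Trial",
    "TrialSequence",
    "feature_overlap",
    "make_trial_sequence",
    "read_trial_sequence",
    "write_trial_sequence",
]

#: Canonical stimulus order used throughout the package.
STIMULI: tuple[str, ...] = ("AB", "AC", "B", "C")

#: Feature composition of each stimulus.
STIMULUS_FEATURES: dict[str, frozenset[str]] = {
    "AB": frozenset({"A", "B"}),
    "AC": frozenset({"A", "C"}),
    "B": frozenset({"B"}),
    "C": frozenset({"C"}),
}


@dataclass(frozen=True)
class Stimulus:
    """One of the four task stimuli, identified by name.

    The feature set is derived from the name; only AB, AC, B and C exist.
    """

    name: str

    def __post_init__(self) -> None:
        if self.name not in STIMULUS_FEATURES:
            raise ValueError(f"unknown stimulus {self.name!r}; expected one of {STIMULI}")

    @property
    def features(self) -> frozenset[str]:
        return STIMULUS_FEATURES[self.name]


def _as_name(s: "Stimulus | str") -> str:
    name = s.name if isinstance(s, Stimulus) else s
    if name not in STIMULUS_FEATURES:
        raise ValueError(f"unknown stimulus {name!r}; expected one of {STIMULI}")
    return name


def feature_overlap(s1: "Stimulus | str", s2: "Stimulus | str") -> int:
    """Overlap indicator O(s, s'): 1 iff distinct stimuli share a feature.

    A stimulus never overlaps itself (the spread update applies only to
    *other* stimuli), so O(s, s) = 0.

    >>> feature_overlap("AB", "AC"), feature_overlap("AB", "C")
    (1, 0)
    """
    n1, n2 = _as_name(s1), _as_name(s2)
    if n1 == n2:
        return 0
    return int(bool(STIMULUS_FEATURES[n1] & STIMULUS_FEATURES[n2]))


@dataclass(frozen=True)
class Trial:
    """A single trial: which stimulus was shown and whether the target appeared."""

    run_index: int
    trial_index: int
    stimulus: Stimulus
    target: int

    def __post_init__(self) -> None:
        if self.target not in (0, 1):
            raise ValueError(f"target must be 0 or 1, got {self.target}")
        if self.run_index < 0 or self.trial_index < 0:
            raise ValueError("run_index and trial_index must be non-negative")


@dataclass
class TrialSequence:
    """An ordered list of trials spanning one or more runs.

    Every run contains exactly ``trials_per_stimulus`` presentations of each
    of the four stimuli, in shuffled order.
    """

    trials: list[Trial]
    n_runs: int
    trials_per_stimulus: int
    p_high: float
    p_low: float

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self) -> Iterable[Trial]:
        return iter(self.trials)

    @property
    def n_trials_per_run(self) -> int:
        return 4 * self.trials_per_stimulus

    def to_frame(self) -> pd.DataFrame:
        """Trial table with columns run, trial, stimulus, target."""
        return pd.DataFrame(
            {
                "run": [t.run_index for t in self.trials],
                "trial": [t.trial_index for t in self.trials],
                "stimulus": [t.stimulus.name for t in self.trials],
                "target": [t.target for t in self.trials],
            }
        )

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        p_high: float = 0.7,
        p_low: float = 0.3,
    ) -> "TrialSequence":
        """Rebuild a sequence from a run/trial/stimulus/target table."""
        required = {"run", "trial", "stimulus", "target"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"trial table missing columns: {sorted(missing)}")
        df = df.sort_values(["run", "trial"], kind="stable")
        trials = [
            Trial(int(r.run), int(r.trial), Stimulus(str(r.stimulus)), int(r.target))
            for r in df.itertuples(index=False)
        ]
        n_runs = int(df["run"].nunique())
        counts = df.groupby(["run", "stimulus"]).size()
        tps = int(counts.iloc[0])
        if not (counts == tps).all():
            raise ValueError("unbalanced stimulus counts across runs")
        return cls(trials, n_runs, tps, p_high, p_low)

    @property
    def stimulus_names(self) -> list[str]:
        return [t.stimulus.name for t in self.trials]

    @property
    def targets(self) -> np.ndarray:
        return np.array([t.target for t in self.trials], dtype=int)

    @property
    def run_indices(self) -> np.ndarray:
        return np.array([t.run_index for t in self.trials], dtype=int)


def _target_assignment(
    p: float,
    n: int,
    mode: Literal["exact", "bernoulli"],
    rng: np.random.Generator,
    strict: bool,
) -> np.ndarray:
    """Binary target vector for one stimulus within one run."""
    if mode == "bernoulli":
        return (rng.random(n) < p).astype(int)
    k_float = p * n
    k = int(round(k_float))
    if strict and abs(k_float - k) > 1e-9:
        raise ValueError(
            f"exact mode: p*trials_per_stimulus = {k_float} is not an integer"
        )
    out = np.zeros(n, dtype=int)
    out[:k] = 1
    rng.shuffle(out)
    return out


def make_trial_sequence(
    n_runs: int = 3,
    trials_per_stimulus: int = 10,
    p_high: float = 0.7,
    p_low: float = 0.3,
    mode: Literal["exact", "bernoulli"] = "exact",
    seed: int | None = 0,
    strict: bool = False,
) -> TrialSequence:
    """Generate a pseudo-random trial sequence for the task.

    Parameters
    ----------
    n_runs, trials_per_stimulus
        Design size; the default 3 runs x 10 trials/stimulus gives 40 trials
        per run and 120 in total.
    p_high, p_low
        Target probability for the target-predictive stimuli (AB, C) and the
        non-predictive ones (AC, B).
    mode
        ``"exact"`` places round(p * trials_per_stimulus) targets per
        stimulus per run (the printed design counts hold in every run);
        ``"bernoulli"`` draws each target independently.
    seed
        Seed for the trial shuffling and target placement; the same seed
        reproduces the sequence bit-identically.
    strict
        In exact mode, reject non-integer p * trials_per_stimulus instead of
        rounding.
    """
    if not (0.0 <= p_low <= p_high <= 1.0):
        raise ValueError(f"need 0 <= p_low <= p_high <= 1, got {p_low}, {p_high}")
    if n_runs < 1 or trials_per_stimulus < 1:
        raise ValueError("n_runs and trials_per_stimulus must be positive")
    if mode not in ("exact", "bernoulli"):
        raise ValueError(f"unknown mode {mode!r}")

    rng = np.random.default_rng(seed)
    p_of = {"AB": p_high, "C": p_high, "AC": p_low, "B": p_low}
    trials: list[Trial] = []
    for run in range(n_runs):
        names: list[str] = []
        targets: list[int] = []
        for name in STIMULI:
            names.extend([name] * trials_per_stimulus)
            targets.extend(
                _target_assignment(p_of[name], trials_per_stimulus, mode, rng, strict)
            )
        order = rng.permutation(len(names))
        for i, idx in enumerate(order):
            trials.append(Trial(run, i, Stimulus(names[idx]), int(targets[idx])))
    return TrialSequence(trials, n_runs, trials_per_stimulus, p_high, p_low)


def write_trial_sequence(seq: TrialSequence, path: "str | Path", *, seed: int | None = None) -> None:
    """Write the trial table as TSV with a JSON sidecar of generation parameters."""
    path = Path(path)
    seq.to_frame().to_csv(path, sep="\t", index=False)
    sidecar = {
        "n_runs": seq.n_runs,
        "trials_per_stimulus": seq.trials_per_stimulus,
        "p_high": seq.p_high,
        "p_low": seq.p_low,
        "seed": seed,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def read_trial_sequence(path: "str | Path") -> TrialSequence:
    """Read a TSV trial table (run, trial, stimulus, target) back into a sequence."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    p_high, p_low = 0.7, 0.3
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        p_high = float(meta.get("p_high", p_high))
        p_low = float(meta.get("p_low", p_low))
    return TrialSequence.from_frame(df, p_high=p_high, p_low=p_low)
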