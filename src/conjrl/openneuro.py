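"""Loading real behavioral trial tables (OpenNeuro ds001590-style).

The task's behavioral data ship as per-subject delimited trial tables.
Column naming varies across BIDS exports, so the loader accepts a small
set of synonyms per field and normalises units: reaction times given in
milliseconds (values > 50) are converted to seconds before the log
transform.  Only the fields the fitting pipeline needs are read: run,
trial order, stimulus identity, target indicator, and reaction time.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .fitting import BehavioralDataset
from .task import TrialSequence

__all__ = ["load_behavior_table", "load_subject_directory"]

_SYNONYMS = {
    "run": ["run", "run_id", "block"],
    "trial": ["trial", "trial_index", "trial_number", "order"],
    "stimulus": ["stimulus", "stim", "cue", "condition"],
    "target": ["target", "target_present", "is_target", "go"],
    "rt": ["rt", "rt_ms", "reaction_time", "response_time"],
}

_STIM_ALIASES = {
    "ab": "AB", "ac": "AC", "b": "B", "c": "C",
    "ab+": "AB", "ac-": "AC", "b-": "B", "c+": "C",
}


def _find_column(df: pd.DataFrame, field: str) -> str:
    lower = {c.lower(): c for c in df.columns}
    for name in _SYNONYMS[field]:
        if name in lower:
            return lower[name]
    raise ValueError(f"no column found for {field!r}; tried {_SYNONYMS[field]}")


def load_behavior_table(path: "str | Path", p_high: float = 0.7, p_low: float = 0.3) -> BehavioralDataset:
    """Read one subject's trial table (TSV/CSV) into a BehavioralDataset.

    Trials without a recorded reaction time are treated as non-responses.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t" if path.suffix.lower() in (".tsv", ".txt") else ",")
    cols = {f: _find_column(df, f) for f in _SYNONYMS}
    stim = (
        df[cols["stimulus"]].astype(str).str.strip().str.lower().map(_STIM_ALIASES)
    )
    if stim.isna().any():
        bad = df[cols["stimulus"]][stim.isna()].unique()
        raise ValueError(f"unrecognised stimulus labels: {bad}")
    runs = pd.factorize(df[cols["run"]], sort=True)[0]
    table = pd.DataFrame(
        {
            "run": runs,
            "trial": df[cols["trial"]].astype(int),
            "stimulus": stim.to_numpy(),
            "target": df[cols["target"]].astype(float).round().astype(int),
        }
    )
    # 0-base trial indices within each run
    table["trial"] = table.groupby("run")["trial"].rank(method="first").astype(int) - 1
    seq = TrialSequence.from_frame(table, p_high=p_high, p_low=p_low)
    table_sorted = table.sort_values(["run", "trial"], kind="stable")
    order = table_sorted.index.to_numpy()

    rt = pd.to_numeric(df[cols["rt"]], errors="coerce").to_numpy(dtype=float)[order]
    rt = np.where(rt > 50.0, rt / 1000.0, rt)  # ms -> s where needed
    responded = (np.isfinite(rt) & (rt > 0)).astype(int)
    log_rt = np.where(responded == 1, np.log(np.where(responded == 1, rt, 1.0)), np.nan)
    outcome = np.where(responded == 1, "response", "no_response")
    return BehavioralDataset(seq, log_rt, responded, outcome)


def load_subject_directory(directory: "str | Path", pattern: str = "*.tsv") -> dict[str, BehavioralDataset]:
    """Load every matching trial table under a directory, keyed by file stem."""
    directory = Path(directory)
    out: dict[str, BehavioralDataset] = {}
    for path in sorted(directory.glob(pattern)):
        out[path.stem] = load_behavior_table(path)
    if not out:
        raise FileNotFoundError(f"no trial tables matching {pattern!r} under {directory}")
    return out
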