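"""Pattern-similarity analysis of two synthetic regions.

A conjunctive-coding region (identity-stable, no feature overlap, value
coding that drifts apart late in each run) against a feature-mixing
cortex-like region (shared feature components, stable value coding).
Reports permutation p-values for every effect of interest and the
between-region overlap contrast.  Requires 02_fit_models.py.
"""

import json
from pathlib import Path

import pandas as pd

from conjrl.pipeline import AnalysisConfig, psa_stage
from conjrl.task import TrialSequence

OUT = Path("results/analysis")


def main() -> None:
    cfg = AnalysisConfig.from_json(OUT / "config.json")
    seq = TrialSequence.from_frame(
        pd.read_csv(OUT / "trial_sequence.tsv", sep="\t"), p_high=cfg.p_high, p_low=cfg.p_low
    )
    import importlib, sys

    sys.path.insert(0, str(Path(__file__).parent))
    comparison = importlib.import_module("03_model_comparison")
    fits = comparison.rebuild_fits(pd.read_csv(OUT / "fits.tsv", sep="\t"))

    coef, perms, contrast = psa_stage(cfg, seq, fits)
    coef.to_csv(OUT / "psa_coefficients.tsv", sep="\t")
    payload = {
        region: {c: {"beta": r.observed, "p": r.p_value} for c, r in res.items()}
        for region, res in perms.items()
    }
    payload["overlap_contrast_cortical_minus_conjunctive"] = {
        "difference": contrast.observed,
        "p": contrast.p_value,
    }
    (OUT / "psa_permutation.json").write_text(json.dumps(payload, indent=2))

    for region, res in perms.items():
        print(f"\n{region}:")
        for c, r in res.items():
            direction = "(one-sided, negative)" if r.side < 0 else ""
            print(f"  {c:18s} beta = {r.observed:8.4f}  p = {r.p_value:.4f} {direction}")
    print(
        f"\noverlap contrast (cortical - conjunctive): "
        f"{contrast.observed:.4f}, p = {contrast.p_value:.4f}"
    )
    print(f"wrote {OUT}/psa_coefficients.tsv and psa_permutation.json")


if __name__ == "__main__":
    main()
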