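"""Decompose simulated striatal responses into target, feature-PE and
conjunctive-PE components.

Builds the z-scored feature-PE regressor and the feature-minus-conjunctive
difference regressor at group-median fitted parameters, plants weights on
all three components in per-trial betas, and recovers them with the
two-stage group regression.  Requires 02_fit_models.py.
"""

import json
from pathlib import Path

import pandas as pd

from conjrl.pipeline import AnalysisConfig, striatal_stage
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

    regs, group, corrs = striatal_stage(cfg, seq, fits)
    regs.to_frame().to_csv(OUT / "pe_regressors.tsv", sep="\t", index=False)
    payload = {
        "coef_names": group.names,
        "mean": group.mean.tolist(),
        "t": group.t.tolist(),
        "p": group.p.tolist(),
        "planted": {"w_target": cfg.w_target, "w_feature": cfg.w_feature, "w_conj": cfg.w_conj},
        **corrs,
    }
    (OUT / "striatal_regression.json").write_text(json.dumps(payload, indent=2))

    print("regressor correlations: feature-PE vs conj-diff r = "
          f"{corrs['r_feature_conjdiff']:.2f}; target vs conj-diff r = {corrs['r_target_conjdiff']:.2f}")
    print("\ngroup decomposition (planted -> recovered, t):")
    planted = [None, cfg.w_target, cfg.w_feature, cfg.w_conj]
    for name, w, m, t in zip(group.names, planted, group.mean, group.t):
        tag = f"(planted {w})" if w is not None else ""
        print(f"  {name:14s} {m:7.3f} t = {t:6.1f} {tag}")
    print(f"\nwrote {OUT}/pe_regressors.tsv and striatal_regression.json")


if __name__ == "__main__":
    main()
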