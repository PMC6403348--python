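"""Pattern-content analysis: task patterns against localizer templates.

Generates a localizer, builds category templates, and scores conjunctive-
mode (pattern-separated) and additive-mode (feature-mixing) task patterns
against run-mapped feature templates.  The diagnostic is the single- vs
two-feature similarity difference and its between-region contrast.
"""

import json
from pathlib import Path

import pandas as pd

from conjrl.pipeline import AnalysisConfig, content_stage
from conjrl.task import TrialSequence

OUT = Path("results/analysis")


def main() -> None:
    cfg = AnalysisConfig.from_json(OUT / "config.json")
    seq = TrialSequence.from_frame(
        pd.read_csv(OUT / "trial_sequence.tsv", sep="\t"), p_high=cfg.p_high, p_low=cfg.p_low
    )
    conj, addv, contrast = content_stage(cfg, seq)
    payload = {
        "conjunctive_region": conj.condition_means,
        "cortical_region": addv.condition_means,
        "p_condition_conjunctive": contrast.condition_effect_a,
        "p_condition_cortical": contrast.condition_effect_b,
        "p_region_difference": contrast.region_difference,
    }
    (OUT / "pattern_content.json").write_text(json.dumps(payload, indent=2))

    for label, res in [("conjunctive (separated)", conj), ("cortical (additive)", addv)]:
        m = res.condition_means
        print(
            f"{label:24s} single = {m['single_feature']:.3f}  "
            f"two-feature = {m['two_feature']:.3f}  diff = {res.single_minus_two:+.3f}"
        )
    print(
        f"single > two in conjunctive region: p = {contrast.condition_effect_a:.4f}; "
        f"region difference: p = {contrast.region_difference:.4f}"
    )
    print(f"wrote {OUT}/pattern_content.json")


if __name__ == "__main__":
    main()
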