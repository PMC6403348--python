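"""Compare the fitted models: signed-rank tests, random-effects BMS, index.

Pairwise Wilcoxon tests on cross-validated predictive likelihoods, the
protected exceedance probabilities of the three- and four-model
random-effects comparisons, and the per-run conjunctive-learning index.
Requires 02_fit_models.py.
"""

import json
from pathlib import Path

import pandas as pd

from conjrl.comparison import conjunctive_index_table
from conjrl.fitting import FitResult
from conjrl.models import ModelParams
from conjrl.pipeline import AnalysisConfig, compare_stage

OUT = Path("results/analysis")


def rebuild_fits(fits_df: pd.DataFrame) -> dict[int, dict[str, FitResult]]:
    out: dict[int, dict[str, FitResult]] = {}
    for row in fits_df.itertuples(index=False):
        beta = (row.beta0,) if pd.isna(row.beta1) else (row.beta0, row.beta1)
        params = ModelParams(
            row.model, alpha=row.alpha, omega=row.omega, beta=beta, sigma=row.sigma
        )
        out.setdefault(int(row.subject), {})[row.model] = FitResult(
            params, row.log_likelihood, {}, int(row.n_included), 0, True
        )
    return out


def main() -> None:
    cfg = AnalysisConfig.from_json(OUT / "config.json")
    cv_total = pd.read_csv(OUT / "cv_total.tsv", sep="\t")[list(cfg.models)].to_numpy()
    cv_per_trial = pd.read_csv(OUT / "cv_per_trial.tsv", sep="\t")[list(cfg.models)].to_numpy()
    comparison = compare_stage(cfg, cv_total, cv_per_trial)
    (OUT / "model_comparison.json").write_text(json.dumps(comparison, indent=2))

    print("four-model pEP:")
    bms4 = comparison["bms_four_model"]
    for name, pep in zip(bms4["model_names"], bms4["pep"]):
        print(f"  {name:14s} {100 * pep:6.1f}%")
    bms3 = comparison["bms_three_model"]
    print("three-model pEP:")
    for name, pep in zip(bms3["model_names"], bms3["pep"]):
        print(f"  {name:14s} {100 * pep:6.1f}%")
    print("\npairwise Wilcoxon on CV likelihood per trial:")
    for pair, res in comparison["pairwise"].items():
        print(f"  {pair}: T = {res['T']:.0f}, p = {res['p']:.4g}")

    # per-run conjunctive-learning index at the subject-level ML parameters
    import sys

    sys.path.insert(0, str(Path(__file__).parent))
    from importlib import import_module

    fit_models = import_module("02_fit_models")
    datasets = fit_models.load_datasets(cfg)
    fits = rebuild_fits(pd.read_csv(OUT / "fits.tsv", sep="\t"))
    index_df = conjunctive_index_table(datasets, fits)
    index_df.to_csv(OUT / "conjunctive_index.tsv", sep="\t", index=False)
    print(
        f"\nconjunctive index: mean {index_df['index'].mean():.3f} "
        f"(<= 0 by nesting; nearer 0 = more purely conjunctive)"
    )
    print(f"wrote {OUT}/model_comparison.json and conjunctive_index.tsv")


if __name__ == "__main__":
    main()
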