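"""Fit the models to real behavioral trial tables (OpenNeuro ds001590).

Optional reproduction path: point --data at a directory of per-subject
delimited trial tables downloaded from the accession (one TSV per subject
with run / trial / stimulus / target / RT columns).  Fits all four models,
runs the cross-validated comparison and the random-effects BMS, and prints
the mean fitted spread weight and protected exceedance probabilities.

Without data this script only explains how to obtain it; nothing here is
exercised by the test suite.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from conjrl import cv_predictive_likelihood, fit_model, group_bms, pairwise_model_test
from conjrl.openneuro import load_subject_directory

OUT = Path("results/analysis")
MODELS = ("no_learning", "feature", "conjunctive", "value_spread")


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data", type=Path, default=None,
                        help="directory of per-subject trial tables (TSV)")
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()

    if args.data is None or not args.data.exists():
        print("no data directory given or found.")
        print("download the behavioral trial tables from OpenNeuro accession")
        print("ds001590, export them as per-subject TSVs with columns")
        print("run / trial / stimulus / target / rt, then rerun:")
        print("  python analysis/08_real_data.py --data <dir>")
        return

    datasets = load_subject_directory(args.data)
    print(f"loaded {len(datasets)} subjects from {args.data}")
    subjects = sorted(datasets)
    omegas, cv_total, cv_per_trial = [], [], []
    for s_idx, sid in enumerate(subjects):
        data = datasets[sid]
        omegas.append(fit_model(data, "value_spread", seed=args.seed + s_idx).params.omega)
        row_t, row_p = [], []
        for model in MODELS:
            cv = cv_predictive_likelihood(data, model, seed=args.seed + s_idx)
            row_t.append(cv.total_ll)
            row_p.append(cv.per_trial_ll)
        cv_total.append(row_t)
        cv_per_trial.append(row_p)
    cv_total = np.array(cv_total)
    cv_per_trial = np.array(cv_per_trial)

    bms4 = group_bms(cv_total, list(MODELS), seed=args.seed)
    three = ["no_learning", "feature", "conjunctive"]
    idx = [MODELS.index(m) for m in three]
    bms3 = group_bms(cv_total[:, idx], three, seed=args.seed)

    print(f"\nmean fitted omega = {np.mean(omegas):.3f} (SD {np.std(omegas):.3f})")
    print("four-model pEP: " + ", ".join(
        f"{n} {100 * p:.1f}%" for n, p in zip(bms4.model_names, bms4.pep)))
    print("three-model pEP: " + ", ".join(
        f"{n} {100 * p:.1f}%" for n, p in zip(bms3.model_names, bms3.pep)))
    vs, cj = MODELS.index("value_spread"), MODELS.index("conjunctive")
    w = pairwise_model_test(cv_per_trial[:, vs], cv_per_trial[:, cj])
    print(f"value_spread vs conjunctive: T = {w.statistic:.0f}, p = {w.p_value:.4f}")

    OUT.mkdir(parents=True, exist_ok=True)
    (OUT / "real_data_comparison.json").write_text(json.dumps({
        "n_subjects": len(subjects),
        "mean_omega": float(np.mean(omegas)),
        "bms_four_model": bms4.to_dict(),
        "bms_three_model": bms3.to_dict(),
    }, indent=2))
    print(f"wrote {OUT}/real_data_comparison.json")


if __name__ == "__main__":
    main()
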