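#!/usr/bin/env python
"""Cohort-level inference: group tests, logistic models, ROC/DeLong, nomogram.

Runs the full inferential chain on the synthetic cohort from step 01 —
normality-gated group comparisons, chi-square/Fisher contingency tests,
univariate screening into a multivariate logistic model, per-marker and
combined ROC with DeLong comparisons and Youden operating points, Spearman
associations, and the nomogram rendering of the final model.  Tables land in
results/, the ROC figure in scratch/.
"""

import argparse
import shutil
from pathlib import Path

import pandas as pd

from aptdki.pipeline import run_stats_stage

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)  # chain is deterministic
    ap.parse_args()

    res_dir = ROOT / "results" / "analysis"
    cohort_path = res_dir / "cohort.csv"
    if not cohort_path.exists():
        raise SystemExit("cohort.csv missing; run 01_simulate_inputs.py first")
    records = pd.read_csv(cohort_path)

    files = run_stats_stage(records, res_dir / "stats", make_plots=True)
    # keep binary figure out of results/
    fig = files.pop("roc_figure", None)
    if fig:
        scratch = ROOT / "scratch" / "analysis"
        scratch.mkdir(parents=True, exist_ok=True)
        shutil.move(fig, scratch / "roc_curves.png")

    uni = pd.read_csv(files["univariate_logit"]).set_index("predictor")
    print("univariate odds ratios (screen at p < 0.05):")
    cols = ["odds_ratio", "ci_lower", "ci_upper", "p"]
    print(uni[cols].round(3).to_string())

    roc = pd.read_csv(files["roc_summary"])
    print("\ndiagnostic performance:")
    print(roc[roc.score.isin(["aptw", "mk", "md", "combination"])]
          .drop(columns=[c for c in ("z",) if c in roc], errors="ignore")
          .round(3).to_string(index=False))
    comps = roc[roc.score.str.startswith("combination_vs")]
    if len(comps):
        print("\nDeLong comparisons vs the combined model:")
        print(comps[["score", "auc", "z", "p"]]
              .rename(columns={"auc": "auc_diff"}).round(3).to_string(index=False))


if __name__ == "__main__":
    main()
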