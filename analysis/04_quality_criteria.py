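"""Score every pipeline on the six quality criteria.

Computes, for each feature type x parameter combination: robustness to
acquisition settings (percentage of incongruent subjects, with the penalty
Omega as an intermediate), head-motion sensitivity (variance explained by
mean FD), subject discriminability (ICC(A,1) over the selected
coefficients), maximal fingerprinting accuracy under the ICC-ranked subset
sweep, parsimony of the selected subset, and generalizability across
parcellation variants.  Writes results/quality.csv.
"""

import sys
import time
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from gspbench import FEATURE_TYPES, evaluate_quality
from gspbench.io import load_cohort, load_feature_table

OUT = ROOT / "results" / "quality.csv"


def main() -> None:
    cohort = load_cohort(str(ROOT / "scratch" / "cohort.h5"))
    tables = {v: load_feature_table(str(ROOT / "scratch" /
                                        f"features_{v.replace('-', 'm')}.h5"))
              for v in ("S3", "S3-", "S1")}
    t0 = time.time()
    report = evaluate_quality(cohort, FEATURE_TYPES, tables=tables)
    OUT.parent.mkdir(exist_ok=True)
    report.to_csv(OUT, index=False, float_format="%.6g")
    print(f"{len(report)} cases scored in {time.time() - t0:.0f} s -> {OUT.name}")
    summary = report.groupby("feature_type").agg(
        acc_full=("accuracy_full", "mean"),
        acc_max=("accuracy_max", "mean"),
        pct_used=("pct_coeffs_used", "mean"),
        pct_incong=("pct_incongruent", "mean"),
        pfd=("pfd_selected", "mean"),
        gen=("generalization_change", "mean"),
    ).round(1)
    print(summary.to_string())
    indiv = report.groupby("individuality")["accuracy_full"].mean().round(1)
    print(f"\nmean full-set accuracy by structural individuality:\n"
          f"{indiv.to_string()}")


if __name__ == "__main__":
    main()
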