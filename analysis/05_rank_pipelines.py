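"""Consensus ranking of all candidate pipelines.

Min-max-normalizes the six quality criteria to [0, 100] over the
concatenated cases, averages them into a consensus score, writes
results/ranking.csv and the per-feature-type top-20-by-accuracy subset
(results/top20.csv, spider-plot export), and prints the winners.
"""

import sys
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from gspbench import rank_pipelines

OUT_RANK = ROOT / "results" / "ranking.csv"
OUT_TOP = ROOT / "results" / "top20.csv"


def main() -> None:
    report = pd.read_csv(ROOT / "results" / "quality.csv")
    ranked, top = rank_pipelines(report, top_n=20)
    ranked = ranked.sort_values("consensus", ascending=False)
    ranked.to_csv(OUT_RANK, index=False, float_format="%.6g")
    top.to_csv(OUT_TOP, index=False, float_format="%.6g")
    print(f"wrote {OUT_RANK.name} ({len(ranked)} cases) and {OUT_TOP.name}")
    print("\nmean consensus by feature type:")
    print(ranked.groupby("feature_type")["consensus"].mean().round(1)
          .sort_values(ascending=False).to_string())
    cols = ["feature_type", "property", "individuality", "operator",
            "zscore", "normalize", "extra", "accuracy_max", "consensus"]
    print("\ntop 5 pipelines by consensus:")
    print(ranked[cols].head(5).to_string(index=False))


if __name__ == "__main__":
    main()
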