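"""Extract all five GSP feature types over the full parameter grid.

For each parcellation variant (S3, S3-, S1) and every scan, computes PSD,
energy, alignment, liberality and SDI feature vectors across the complete
factor grid (128 / 128 / 1280 / 1280 / 512 parameter combinations) and
stores the feature tables under scratch/.
"""

import sys
import time
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from gspbench import FEATURE_TYPES, compute_feature_table
from gspbench.io import load_cohort, save_feature_table

VARIANTS = ("S3", "S3-", "S1")


def main() -> None:
    cohort = load_cohort(str(ROOT / "scratch" / "cohort.h5"))
    for variant in VARIANTS:
        t0 = time.time()
        table = compute_feature_table(cohort, FEATURE_TYPES, variant=variant)
        path = ROOT / "scratch" / f"features_{variant.replace('-', 'm')}.h5"
        save_feature_table(table, str(path))
        n_combos = sum(len(table.combos(ft)) for ft in FEATURE_TYPES)
        print(f"{variant}: R={table.n_regions}, {n_combos} combinations x "
              f"{len(table.scans)} scans in {time.time() - t0:.0f} s -> {path.name}")


if __name__ == "__main__":
    main()
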