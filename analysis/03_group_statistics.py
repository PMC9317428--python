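"""Per-feature responder vs non-responder comparison (full cohort).

Two-sample pooled-variance t-tests on every imaging feature across the
whole 58-patient cohort, reported in the study-table style: feature,
group mean (SD) per group, p-value; the significant subset (p < 0.05,
unadjusted) is printed and both tables are written to results/.
Requires results/features.csv from 02_extract_features.py.
"""

import argparse
from pathlib import Path

import pandas as pd

from mpmri.features import compare_groups

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--alpha", type=float, default=0.05)
    args = ap.parse_args()

    out = ROOT / "results"
    features = pd.read_csv(out / "features.csv", index_col="patient_id")
    labels = pd.read_csv(out / "labels.csv", index_col="patient_id")["pcr"]
    clinical_cols = {"age_over_40", "premenopausal", "stage_iii", "grade_iii"}
    imaging = features[[c for c in features.columns if c not in clinical_cols]]

    stats = compare_groups(imaging, labels)
    stats.to_csv(out / "group_comparison.csv")
    sig = stats[stats["p"] < args.alpha].sort_values("p")
    sig.to_csv(out / "group_comparison_significant.csv")

    print(f"{len(sig)} of {len(stats)} imaging features differ between "
          f"groups at p < {args.alpha} (no multiple-testing adjustment):")
    for name, row in sig.head(15).iterrows():
        print(f"  {name}: pCR {row.mean_pcr:.4g} ({row.sd_pcr:.3g}) vs "
              f"non-pCR {row.mean_non_pcr:.4g} ({row.sd_non_pcr:.3g}), "
              f"p = {row.p:.4f}")


if __name__ == "__main__":
    main()
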