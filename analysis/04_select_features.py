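"""Balance the cohort and run the two-step feature selection.

Keeps all 12 responders plus a random 12-patient subset of the
non-responders, then removes low-variance (min-max scaled variance <=
0.1) and mutually correlated (|r| > 0.8, lower raw variance dropped)
imaging features.  Writes the retained list and the removal log to
results/.  Requires results/features.csv from 02_extract_features.py.
"""

import argparse
from pathlib import Path

import pandas as pd

from mpmri.features import select_features
from mpmri.models import balance

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    out = ROOT / "results"
    features = pd.read_csv(out / "features.csv", index_col="patient_id")
    labels = pd.read_csv(out / "labels.csv", index_col="patient_id")["pcr"]
    clinical_cols = {"age_over_40", "premenopausal", "stage_iii", "grade_iii"}
    imaging = features[[c for c in features.columns if c not in clinical_cols]]

    keep = balance(labels, seed=args.seed)
    res = select_features(imaging.loc[keep])

    pd.Series(res.retained, name="feature").to_csv(out / "selected_features.csv",
                                                   index=False)
    res.removed.to_csv(out / "selection_log.csv", index=False)

    n_lowvar = (res.removed["reason"] == "low_variance").sum()
    n_corr = (res.removed["reason"] == "correlated").sum()
    print(f"balanced cohort: {len(keep)} patients "
          f"({int(labels.loc[keep].sum())} per class)")
    print(f"selection (min-max scaled variance): {imaging.shape[1]} -> "
          f"{len(res.retained)} features "
          f"({n_lowvar} low-variance, {n_corr} correlated removed)")
    # the variance-threshold scaling is the one unstated choice that moves
    # this count the most; report the raw-units alternative alongside
    res_raw = select_features(imaging.loc[keep], scaling="raw")
    print(f"selection (raw-units variance):      {imaging.shape[1]} -> "
          f"{len(res_raw.retained)} features")


if __name__ == "__main__":
    main()
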