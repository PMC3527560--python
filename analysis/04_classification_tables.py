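"""Pairwise classification of the study groups (the headline tables).

Evaluates every group pair with every method (hippocampal volumes, TBM,
VBM, modulated VBM, and all features combined) using SMOTE-balanced
stratified 90/10 splits repeated many times, reporting CCR mean +/- SD with
pooled sensitivity/specificity, plus a single-ROI TBM table for the
C-vs-FTD contrast.

Requires the corrected feature table from 03_morphometry_features.py.

Run:  python analysis/04_classification_tables.py [--seed 1 --repetitions 500]
"""
import argparse
import warnings
from pathlib import Path

import pandas as pd

from ftdmorph.classification import (
    DEFAULT_PAIRS,
    SplitScheme,
    evaluate_repeated_splits,
    method_feature_columns,
)
from ftdmorph.features import FeatureTable
from ftdmorph.synthetic import ROI_NAMES

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--repetitions", type=int, default=500)
args = parser.parse_args()
warnings.filterwarnings("ignore")

results = Path("results")
table = FeatureTable.from_tsv(results / "features_corrected.tsv")
scheme = SplitScheme(n_repetitions=args.repetitions, seed=args.seed)

rows = []
for pair in DEFAULT_PAIRS:
    counts = table.df["group"].value_counts()
    if counts.get(pair[0], 0) < 3 or counts.get(pair[1], 0) < 3:
        continue
    for method in ("HV", "TBM", "VBM", "VBMmod", "all"):
        res = evaluate_repeated_splits(
            table, pair, scheme, features=method_feature_columns(table, method),
            method=method,
        )
        rows.append({
            "pair": f"{pair[0]} vs {pair[1]}", "method": method,
            "ccr": res.ccr_mean, "ccr_sd": res.ccr_sd,
            "ss": res.sensitivity, "sp": res.specificity,
        })
df = pd.DataFrame(rows)
df.to_csv(results / "classification_all_pairs.tsv", sep="\t", index=False, float_format="%.3f")
wide = df.pivot(index="pair", columns="method", values="ccr").round(2)
print("CCR by pair and method:")
print(wide.to_string())

single = []
for roi in ROI_NAMES:
    res = evaluate_repeated_splits(
        table, ("C", "FTD"), scheme, features=[f"TBM_{roi}"], method="TBM"
    )
    single.append({"roi": roi, "ccr": res.ccr_mean, "ccr_sd": res.ccr_sd,
                   "ss": res.sensitivity, "sp": res.specificity})
sdf = pd.DataFrame(single).sort_values("ccr", ascending=False)
sdf.to_csv(results / "classification_single_roi_c_ftd.tsv", sep="\t",
           index=False, float_format="%.3f")
print("\nsingle-ROI TBM, C vs FTD:")
print(sdf.to_string(index=False))
print(f"\nwrote {results/'classification_all_pairs.tsv'} and "
      f"{results/'classification_single_roi_c_ftd.tsv'}")
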