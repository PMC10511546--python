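#!/usr/bin/env python
"""Brain-age delta and its bias screens on the test cohort.

Computes delta = predicted - actual age per model, summarises it overall
and by developmental band, and screens every model's delta against actual
age (Pearson r), the motion proxy EFC and IQ (partial correlations
controlling age), and sex (age-adjusted linear model), applying the
Bonferroni threshold alpha = 0.05/60.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from brainage_msn.delta import compute_delta, covariate_screen, delta_summary
from brainage_msn.features import FEATURE_SET_NAMES
from brainage_msn.synthetic import MorphometryTable, QATable

ap = argparse.ArgumentParser()
ap.add_argument("--cohort-dir", type=Path, default=Path("results/cohort"))
ap.add_argument("--models-dir", type=Path, default=Path("results/models"))
args = ap.parse_args()

morpho = MorphometryTable.from_csv(args.cohort_dir / "cohort_harmonised.csv")
qa = QATable.from_csv(args.cohort_dir / "qa.csv")
preds = pd.read_csv(args.models_dir / "test_predictions.csv")

meta = morpho.frame.set_index("subject_id").loc[preds["subject_id"]]
efc = qa.frame.set_index("subject_id")["efc"].loc[preds["subject_id"]]
cov = pd.DataFrame({"efc": efc.to_numpy(), "iq": meta["iq"].to_numpy(),
                    "sex": meta["sex"].to_numpy()})

tables = {}
for name in FEATURE_SET_NAMES:
    t = compute_delta(preds[name].to_numpy(), preds["age"].to_numpy(),
                      preds["subject_id"].to_numpy(), covariates=cov)
    tables[name] = t
    t.to_csv(args.models_dir / f"delta_{name}.csv", index=False)

pooled = np.concatenate([t["delta"] for t in tables.values()])
print(f"delta across all models: mean {pooled.mean():.2f} "
      f"sd {pooled.std(ddof=1):.2f} median {np.median(pooled):.2f}")
s = delta_summary(tables["cortical_thickness"])
for band, stats_ in s["bands"].items():
    print(f"  thickness, {band}: n={stats_['n']} mean delta {stats_['mean']:+.2f}")
r_age = np.corrcoef(tables["cortical_thickness"]["delta"],
                    tables["cortical_thickness"]["actual_age"])[0, 1]
print(f"thickness delta vs age: Pearson r = {r_age:+.2f} "
      f"(negative = regression-to-the-mean age bias)")

screen, mean_r = covariate_screen(tables)
screen.to_csv(args.models_dir / "bias_screen.tsv", sep="\t", index=False)
print(f"mean Pearson r across models: EFC {mean_r['efc']:+.3f}, IQ {mean_r['iq']:+.3f}")
n_sig = int(screen["significant"].sum())
print(f"{n_sig}/{len(screen)} screen tests significant at alpha=0.000833")
print(f"wrote {args.models_dir}/bias_screen.tsv and per-model delta tables")
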