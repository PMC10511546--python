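#!/usr/bin/env python
"""Single evaluation of each selected model on the held-out test cohort.

Retrains each feature set's chosen algorithm/kernel on the full training
cohort (internal training + validation) and scores it once on the test
cohort: MAE in years and predicted R^2.  Test predictions are saved for
the delta analyses.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from brainage_msn.evaluation import evaluate_predictions
from brainage_msn.features import FEATURE_SET_NAMES, assemble_feature_set
from brainage_msn.models import fit_model
from brainage_msn.msn import build_msn_for_table
from brainage_msn.synthetic import MorphometryTable

ap = argparse.ArgumentParser()
ap.add_argument("--cohort-dir", type=Path, default=Path("results/cohort"))
ap.add_argument("--models-dir", type=Path, default=Path("results/models"))
ap.add_argument("--rvr-max-iter", type=int, default=200)
args = ap.parse_args()

morpho = MorphometryTable.from_csv(args.cohort_dir / "cohort_harmonised.csv")
graphs = build_msn_for_table(morpho)
ages = morpho.frame["age"].to_numpy()

split = pd.read_csv(args.models_dir / "split.csv").set_index("subject_id")
part = split["partition"].loc[morpho.subject_ids].to_numpy()
tri = np.flatnonzero(part != "test")
tei = np.flatnonzero(part == "test")

selection = pd.read_csv(args.models_dir / "selection.tsv", sep="\t")
chosen = selection[selection["chosen"]].set_index("feature_set")

rows, preds = [], {}
for name in FEATURE_SET_NAMES:
    algorithm, kernel = chosen.loc[name, ["algorithm", "kernel"]]
    fs = assemble_feature_set(name, morpho, graphs)
    model = fit_model(algorithm, fs.matrix[tri], ages[tri],
                      kernel=kernel, max_iter=args.rvr_max_iter)
    test_pred = model.predict(fs.matrix[tei])
    preds[name] = test_pred
    trn = evaluate_predictions(model.predict(fs.matrix[tri]), ages[tri])
    tst = evaluate_predictions(test_pred, ages[tei])
    rows.append({"feature_set": name, "algorithm": algorithm, "kernel": kernel,
                 "train_mae": trn.mae, "train_pred_r2": trn.pred_r2,
                 "test_mae": tst.mae, "test_pred_r2": tst.pred_r2})
    print(f"{name:22s} test MAE {tst.mae:.2f} yrs, test R2 {tst.pred_r2:+.2f}")

table = pd.DataFrame(rows)
table.to_csv(args.models_dir / "test_performance.tsv", sep="\t", index=False)
pred_frame = pd.DataFrame({"subject_id": morpho.subject_ids[tei], "age": ages[tei], **preds})
pred_frame.to_csv(args.models_dir / "test_predictions.csv", index=False)
best = table.sort_values("test_pred_r2", ascending=False).iloc[0]
print(f"best on test: {best['feature_set']} (R2 {best['test_pred_r2']:+.2f})")
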