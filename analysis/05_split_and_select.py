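#!/usr/bin/env python
"""Age-stratified split and algorithm/kernel selection per feature set.

Splits the harmonised cohort 3:1 into training and held-out test subjects
by equal sampling from 0.5-year age bins (bins below 9 years collapsed),
refines the training cohort 5:1 into internal training and validation,
then fits every feature set with GPR and RVR under both radial kernels on
internal training and picks the cell with the best validation predicted
R^2.  Writes split.csv and selection.tsv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from brainage_msn.evaluation import MODEL_CELLS, evaluate_predictions, select_model
from brainage_msn.features import (
    FEATURE_SET_NAMES,
    assemble_feature_set,
    internal_split,
    stratified_undersample,
)
from brainage_msn.models import fit_model
from brainage_msn.msn import build_msn_for_table
from brainage_msn.synthetic import MorphometryTable

ap = argparse.ArgumentParser()
ap.add_argument("--cohort-dir", type=Path, default=Path("results/cohort"))
ap.add_argument("--out", type=Path, default=Path("results/models"))
ap.add_argument("--seed", type=int, default=1)
ap.add_argument("--rvr-max-iter", type=int, default=200)
args = ap.parse_args()

morpho = MorphometryTable.from_csv(args.cohort_dir / "cohort_harmonised.csv")
graphs = build_msn_for_table(morpho)
ages = morpho.frame["age"].to_numpy()

split = internal_split(
    stratified_undersample(ages, morpho.subject_ids, seed=args.seed),
    seed=args.seed + 1)
args.out.mkdir(parents=True, exist_ok=True)
split.to_csv(args.out / "split.csv")
part = split.frame.set_index("subject_id")["partition"].loc[morpho.subject_ids].to_numpy()
tri = np.flatnonzero(part == "internal_train")
vi = np.flatnonzero(part == "internal_validation")
print("cohort split:", split.counts())

rows = []
for name in FEATURE_SET_NAMES:
    fs = assemble_feature_set(name, morpho, graphs)
    grid = {}
    for algorithm, kernel in MODEL_CELLS:
        model = fit_model(algorithm, fs.matrix[tri], ages[tri], kernel=kernel,
                          max_iter=args.rvr_max_iter)
        val = evaluate_predictions(model.predict(fs.matrix[vi]), ages[vi])
        trn = evaluate_predictions(model.predict(fs.matrix[tri]), ages[tri])
        grid[(algorithm, kernel)] = val
        rows.append({"feature_set": name, "algorithm": algorithm, "kernel": kernel,
                     "train_mae": trn.mae, "train_pred_r2": trn.pred_r2,
                     "validation_mae": val.mae, "validation_pred_r2": val.pred_r2})
    algorithm, kernel = select_model(grid)
    for r in rows[-4:]:
        r["chosen"] = (r["algorithm"], r["kernel"]) == (algorithm, kernel)
    print(f"{name:22s} -> {algorithm}/{kernel} "
          f"(validation R2 {grid[(algorithm, kernel)].pred_r2:+.2f})")

pd.DataFrame(rows).to_csv(args.out / "selection.tsv", sep="\t", index=False)
print(f"wrote {args.out}/selection.tsv")
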