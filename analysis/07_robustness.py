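#!/usr/bin/env python
"""Resampling confidence intervals and permutation null models.

For each feature set's selected model: repeat the stratified split 20
times (scaled down from the release setting of 100) to get the mean and
percentile 95% CI of test predicted R^2, then compare that mean against a
null distribution built by permuting training-cohort ages (49 permutations
here, 1000 at release scale) and rescoring on the untouched test cohort.
Significance is Bonferroni-corrected over the 10 models (alpha < 0.005).
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from brainage_msn.evaluation import permutation_nhst, resample_performance
from brainage_msn.features import FEATURE_SET_NAMES, assemble_feature_set
from brainage_msn.msn import build_msn_for_table
from brainage_msn.synthetic import MorphometryTable

ap = argparse.ArgumentParser()
ap.add_argument("--cohort-dir", type=Path, default=Path("results/cohort"))
ap.add_argument("--models-dir", type=Path, default=Path("results/models"))
ap.add_argument("--n-partitions", type=int, default=20)
ap.add_argument("--n-permutations", type=int, default=49)
ap.add_argument("--seed", type=int, default=1)
ap.add_argument("--rvr-max-iter", type=int, default=200)
args = ap.parse_args()

morpho = MorphometryTable.from_csv(args.cohort_dir / "cohort_harmonised.csv")
graphs = build_msn_for_table(morpho)
ages = morpho.frame["age"].to_numpy()
split = pd.read_csv(args.models_dir / "split.csv").set_index("subject_id")
part = split["partition"].loc[morpho.subject_ids].to_numpy()
tri = np.flatnonzero(part != "test")
tei = np.flatnonzero(part == "test")
chosen = pd.read_csv(args.models_dir / "selection.tsv", sep="\t")
chosen = chosen[chosen["chosen"]].set_index("feature_set")

rows = []
for name in FEATURE_SET_NAMES:
    algorithm, kernel = chosen.loc[name, ["algorithm", "kernel"]]
    fs = assemble_feature_set(name, morpho, graphs)
    rob = resample_performance(
        fs.matrix, ages, algorithm, kernel, n_partitions=args.n_partitions,
        seed=args.seed, model_kwargs={"max_iter": args.rvr_max_iter})
    p, _ = permutation_nhst(
        fs.matrix, ages, tri, tei, algorithm, kernel,
        observed_stat=rob.mean_pred_r2, n_perm=args.n_permutations,
        seed=args.seed + 1, model_kwargs={"max_iter": args.rvr_max_iter})
    sig = p < 0.05 / len(FEATURE_SET_NAMES)
    rows.append({"feature_set": name, "mean_pred_r2": rob.mean_pred_r2,
                 "ci_low": rob.ci_low, "ci_high": rob.ci_high,
                 "p_value": p, "significant": sig})
    print(f"{name:22s} mean R2 {rob.mean_pred_r2:+.2f} "
          f"CI [{rob.ci_low:+.2f}, {rob.ci_high:+.2f}] p={p:.3f}"
          f"{' *' if sig else ''}")

pd.DataFrame(rows).to_csv(args.models_dir / "robustness.tsv", sep="\t", index=False)
print(f"wrote {args.models_dir}/robustness.tsv "
      f"(* = significant at Bonferroni alpha 0.005)")
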