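#!/usr/bin/env python
"""Build each subject's morphometric similarity network.

Z-scores the 7 features across the 68 regions per subject, correlates
regional feature profiles, and summarises the networks: edge count, the
distribution of global strength, and its relationship with age.  One
example subject's full matrix and edge list are written for inspection.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from brainage_msn.msn import build_msn_for_table, nodal_strength, vectorize_edges
from brainage_msn.synthetic import MorphometryTable

ap = argparse.ArgumentParser()
ap.add_argument("--cohort-dir", type=Path, default=Path("results/cohort"))
ap.add_argument("--out", type=Path, default=Path("results/msn"))
args = ap.parse_args()

morpho = MorphometryTable.from_csv(args.cohort_dir / "cohort_harmonised.csv")
graphs = build_msn_for_table(morpho)

global_strength = np.array([nodal_strength(g)[1] for g in graphs])
ages = morpho.frame["age"].to_numpy()
r = np.corrcoef(global_strength, ages)[0, 1]

args.out.mkdir(parents=True, exist_ok=True)
graphs[0].to_csv(args.out / f"msn_{graphs[0].subject_id}.csv")
graphs[0].edge_frame().to_csv(args.out / f"edges_{graphs[0].subject_id}.tsv",
                              sep="\t", index=False)
pd.DataFrame({"subject_id": morpho.subject_ids, "age": ages,
              "global_strength": global_strength}).to_csv(
    args.out / "global_strength.csv", index=False)

print(f"built {len(graphs)} networks; {vectorize_edges(graphs[0]).size} edges each")
print(f"global strength: mean {global_strength.mean():.4f} sd {global_strength.std():.4f}")
print(f"corr(global strength, age) = {r:+.3f}")
print(f"example matrix and summaries under {args.out}/")
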