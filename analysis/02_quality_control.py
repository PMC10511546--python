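#!/usr/bin/env python
"""Within-site QA z-scoring and the zero-or-one failure inclusion rule.

Reads results/cohort/qa.csv, z-scores the six spatial quality metrics
within site (re-signed quality-positive), fails a metric at z < -1.5, and
keeps subjects failing at most one metric.  Writes the QC report and the
included-subject cohort.
"""

import argparse
from pathlib import Path

from brainage_msn.preprocessing import apply_qc_filter, zscore_qa_within_site
from brainage_msn.synthetic import MorphometryTable, QATable

ap = argparse.ArgumentParser()
ap.add_argument("--cohort-dir", type=Path, default=Path("results/cohort"))
args = ap.parse_args()

qa = QATable.from_csv(args.cohort_dir / "qa.csv")
qc = zscore_qa_within_site(qa)
qc.to_csv(args.cohort_dir / "qc_report.tsv", sep="\t", index=False)
included = apply_qc_filter(qc)

morpho = MorphometryTable.from_csv(args.cohort_dir / "cohort_raw.csv")
kept = morpho.subset(included)
kept.to_csv(args.cohort_dir / "cohort_included.csv")

n_failed = qc["n_failed"].value_counts().sort_index()
print("failure-count distribution:", dict(n_failed))
print(f"included {len(kept)}/{len(morpho)} subjects "
      f"({len(morpho) - len(kept)} excluded by the >1-failure rule)")
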