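"""Feature-set assembly and age-stratified cohort splitting.

Ten design matrices are used for age prediction: the seven individual
regional morphometric features (68 columns each), all of them concatenated
(476 columns), MSN nodal strength (68) and MSN edge weights (2278).  A
"combined" set concatenates any named subset.

The cohort is divided into training and held-out test subjects by
stratified under-sampling on age: subjects are binned into 0.5-year age
bins (bins below 9 years collapsed into one, reflecting the thin lower
tail), equal quotas are drawn from each bin, and bins too small for their
quota hand the deficit to the remaining bins round-robin.  The remainder
forms the test cohort.  The training cohort is further divided 5:1 into
internal training and validation subsets by simple random sampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas import DK_REGIONS, FEATURES, N_EDGES
from .msn import MSNGraph, nodal_strength, vectorize_edges
from .synthetic import MorphometryTable

__all__ = [
    "FEATURE_SET_NAMES",
    "FeatureSet",
    "assemble_feature_set",
    "SplitAssignment",
    "stratified_undersample",
    "internal_split",
]

#: The ten standard feature sets, in reporting order.
FEATURE_SET_NAMES: tuple[str, ...] = (
    *FEATURES,
    "all_individual",
    "msn_nodal_strength",
    "msn_edge_weights",
)


@dataclass
class FeatureSet:
    """Named subjects x features design matrix, row-aligned with metadata."""

    name: str
    matrix: np.ndarray
    feature_names: list[str]
    subject_ids: np.ndarray

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    def rows(self, subject_ids) -> np.ndarray:
        """Rows for the given subjects, in the given order."""
        lookup = {s: i for i, s in enumerate(self.subject_ids)}
        idx = np.array([lookup[s] for s in subject_ids])
        return self.matrix[idx]


def assemble_feature_set(
    name: str,
    morpho: MorphometryTable,
    graphs: list[MSNGraph] | None = None,
    components: list[str] | None = None,
) -> FeatureSet:
    """Build one of the named design matrices.

    ``graphs`` (one MSN per subject, in table row order) is required for
    the MSN-based sets; ``components`` names the parts of a ``combined``
    set, concatenated in the order given.
    """
    sids = morpho.subject_ids
    if name == "combined":
        if not components:
            raise ValueError("combined feature set requires a components list")
        parts = [assemble_feature_set(c, morpho, graphs) for c in components]
        return FeatureSet(
            name="combined:" + "+".join(components),
            matrix=np.hstack([p.matrix for p in parts]),
            feature_names=[f"{p.name}::{fn}" for p in parts for fn in p.feature_names],
            subject_ids=sids,
        )
    if name in FEATURES:
        mat = morpho.feature_matrix(name).to_numpy(dtype=float)
        names = [f"{r}__{name}" for r in DK_REGIONS]
    elif name == "all_individual":
        vals = morpho.values_array()  # (n, 68, 7)
        mat = vals.transpose(0, 2, 1).reshape(len(morpho), -1)  # feature-major blocks
        names = [f"{r}__{f}" for f in FEATURES for r in DK_REGIONS]
    elif name in ("msn_nodal_strength", "msn_edge_weights"):
        if graphs is None:
            raise ValueError(f"{name} requires MSN graphs")
        if len(graphs) != len(morpho):
            raise ValueError("one MSN per subject required, in table order")
        if name == "msn_nodal_strength":
            mat = np.stack([nodal_strength(g)[0] for g in graphs])
            names = [f"strength__{r}" for r in DK_REGIONS]
        else:
            mat = np.stack([vectorize_edges(g) for g in graphs])
            i, j = np.triu_indices(len(DK_REGIONS), k=1)
            names = [f"edge__{DK_REGIONS[a]}__{DK_REGIONS[b]}" for a, b in zip(i, j)]
            assert mat.shape[1] == N_EDGES
    else:
        raise ValueError(f"unknown feature set {name!r}")
    return FeatureSet(name=name, matrix=mat, feature_names=names, subject_ids=sids)


@dataclass
class SplitAssignment:
    """Partition of the included subjects with its provenance.

    ``frame`` columns: subject_id, partition (train/test, or
    internal_train/internal_validation/test after refinement), bin.
    """

    frame: pd.DataFrame
    bin_edges: np.ndarray
    seed: int

    def ids(self, partition: str) -> np.ndarray:
        if partition == "train":  # union of the two internal cohorts
            keep = self.frame["partition"].isin(["train", "internal_train", "internal_validation"])
        else:
            keep = self.frame["partition"] == partition
        return self.frame.loc[keep, "subject_id"].to_numpy()

    def counts(self) -> dict[str, int]:
        return self.frame["partition"].value_counts().to_dict()

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def _age_bins(ages: np.ndarray, bin_width: float, collapse_below: float) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = ages.min(), ages.max()
    start = max(collapse_below, lo)
    upper = np.arange(start, hi + bin_width, bin_width)
    edges = np.concatenate([[lo - 1e-9], upper]) if lo < collapse_below else np.concatenate([[lo - 1e-9], upper[1:]])
    # ensure final edge covers the max age
    while edges[-1] <= hi:
        edges = np.append(edges, edges[-1] + bin_width)
    labels = np.digitize(ages, edges) - 1
    return labels, edges


def stratified_undersample(
    ages: np.ndarray,
    subject_ids: np.ndarray | None = None,
    train_fraction: float = 0.75,
    bin_width: float = 0.5,
    collapse_below: float = 9.0,
    seed: int = 0,
) -> SplitAssignment:
    """Age-stratified under-sampled train/test split.

    Targets ``floor(n * train_fraction)`` training subjects drawn with
    equal per-bin quotas; bins smaller than their quota contribute all
    members and the deficit is redistributed round-robin over bins that
    still have members to give.  The remainder is the test cohort.
    Deterministic given ``seed``.
    """
    ages = np.asarray(ages, dtype=float)
    n = ages.size
    if subject_ids is None:
        subject_ids = np.array([f"sub-{i:05d}" for i in range(n)])
    target = int(np.floor(n * train_fraction))
    labels, edges = _age_bins(ages, bin_width, collapse_below)
    bin_ids = np.unique(labels)
    if bin_ids.size == 0 or n == 0:
        raise ValueError("no subjects to split")
    rng = np.random.default_rng(seed)

    members = {b: rng.permutation(np.flatnonzero(labels == b)) for b in bin_ids}
    taken = {b: 0 for b in bin_ids}
    remaining = target
    # round-robin: one slot per pass to every bin that still has members
    while remaining > 0:
        open_bins = [b for b in bin_ids if taken[b] < members[b].size]
        if not open_bins:
            break
        for b in open_bins:
            if remaining == 0:
                break
            if taken[b] < members[b].size:
                taken[b] += 1
                remaining -= 1

    train_idx = np.concatenate([members[b][: taken[b]] for b in bin_ids]) if target else np.array([], int)
    partition = np.full(n, "test", dtype=object)
    partition[train_idx] = "train"
    frame = pd.DataFrame({"subject_id": subject_ids, "partition": partition, "bin": labels})
    return SplitAssignment(frame=frame, bin_edges=edges, seed=seed)


def internal_split(
    assignment: SplitAssignment, train_fraction: float = 5 / 6, seed: int = 0
) -> SplitAssignment:
    """Refine the training cohort into internal training / validation.

    Simple random split; ``floor(train_fraction * n_train)`` subjects go to
    internal training, the remainder to validation.
    """
    frame = assignment.frame.copy()
    train_mask = frame["partition"].isin(["train", "internal_train", "internal_validation"])
    train_pos = np.flatnonzero(train_mask.to_numpy())
    n_train = train_pos.size
    if n_train < 6:
        raise ValueError(f"training cohort of {n_train} is too small to subdivide")
    n_internal = int(np.floor(train_fraction * n_train))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_train)
    internal = train_pos[perm[:n_internal]]
    valid = train_pos[perm[n_internal:]]
    frame.loc[frame.index[internal], "partition"] = "internal_train"
    frame.loc[frame.index[valid], "partition"] = "internal_validation"
    return SplitAssignment(frame=frame, bin_edges=assignment.bin_edges, seed=seed)
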