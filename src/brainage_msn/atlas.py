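"""Desikan-Killiany atlas labels and the morphometric feature vocabulary.

The cortical parcellation has 34 regions per hemisphere (68 total); each
region carries seven Freesurfer-style morphometric measures. Orderings here
are canonical for the whole package: every matrix with a region or feature
axis uses these sequences.
"""

from __future__ import annotations

_DK_BASE = (
    "bankssts",
    "caudalanteriorcingulate",
    "caudalmiddlefrontal",
    "cuneus",
    "entorhinal",
    "frontalpole",
    "fusiform",
    "inferiorparietal",
    "inferiortemporal",
    "insula",
    "isthmuscingulate",
    "lateraloccipital",
    "lateralorbitofrontal",
    "lingual",
    "medialorbitofrontal",
    "middletemporal",
    "paracentral",
    "parahippocampal",
    "parsopercularis",
    "parsorbitalis",
    "parstriangularis",
    "pericalcarine",
    "postcentral",
    "posteriorcingulate",
    "precentral",
    "precuneus",
    "rostralanteriorcingulate",
    "rostralmiddlefrontal",
    "superiorfrontal",
    "superiorparietal",
    "superiortemporal",
    "supramarginal",
    "temporalpole",
    "transversetemporal",
)

#: 68 region labels, left hemisphere first, fixed lexicographic-by-construction order.
DK_REGIONS: tuple[str, ...] = tuple(f"{hemi}_{name}" for hemi in ("lh", "rh") for name in _DK_BASE)

#: The seven regional morphometric features, in the canonical order used everywhere.
FEATURES: tuple[str, ...] = (
    "surface_area",
    "curvature_index",
    "folding_index",
    "gaussian_curvature",
    "mean_curvature",
    "cortical_thickness",
    "cortical_volume",
)

N_REGIONS: int = len(DK_REGIONS)
N_FEATURES: int = len(FEATURES)
#: Off-diagonal upper-triangle edge count of the 68-node similarity matrix.
N_EDGES: int = N_REGIONS * (N_REGIONS - 1) // 2


def value_columns() -> list[str]:
    """Wide-table column names ``<region>__<feature>``, region-major order."""
    return [f"{r}__{f}" for r in DK_REGIONS for f in FEATURES]
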