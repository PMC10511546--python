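"""Synthetic multi-site developmental cohort generator.

Emulates the structure of a multi-site paediatric structural-MRI release
(17 acquisition sites, ages ~6.5-16.9 years, male-skewed sex ratio,
IQ ~110 +/- 15): per-subject regional morphometry across the 68
Desikan-Killiany regions x 7 Freesurfer-style features, six spatial image
quality metrics per subject, and the subject metadata the downstream
pipeline needs (age, sex, site, IQ).

Generative model for the morphometry value of subject *s* (age *a*, site
*t*), region *r*, feature *f*::

    x[s,r,f] = ( baseline[r,f]
                 + lin[f]*a + quad[f]*a^2              # feature-wise age trend
                 + g_s * u[r,f](a)                     # age-rotating latent factor
                 + o[s,f]                              # subject-level offset
                 + site_loc[t,f] ) * site_scale[t,f]
               + eps[s,r,f]                            # iid Gaussian noise

with u[r,f](a) = lambda[f] * (cos(theta_a) * U0[r,f] + sin(theta_a) * U1[r,f]),
theta_a = coupling_age_slope * (a - age_ref).  The latent factor makes the
correlation between regional feature profiles drift with age, so
morphometric-similarity edges carry age signal; the subject offset o[s,f]
models stable individual differences that do not average away across
regions and therefore bound how well any regional feature can predict age.

Every random draw comes from a single seeded generator; the full parameter
set actually used is returned as :class:`GroundTruth` so recovery tests can
compare estimates against the injected truth.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import DK_REGIONS, FEATURES, N_FEATURES, N_REGIONS, value_columns

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "MorphometryTable",
    "QATable",
    "QA_METRICS",
    "QA_HIGHER_IS_WORSE",
    "generate_cohort",
]

#: Six spatial anatomical quality metrics (QAP-style names); ``efc`` is the
#: entropy focus criterion used downstream as a motion proxy.
QA_METRICS: tuple[str, ...] = ("cnr", "efc", "fber", "fwhm", "qi1", "snr")

#: Orientation of each raw metric: True means larger raw values indicate
#: *worse* image quality (these get sign-flipped during within-site z-scoring
#: so that larger z always means better quality).
QA_HIGHER_IS_WORSE: dict[str, bool] = {
    "cnr": False,
    "efc": True,
    "fber": False,
    "fwhm": True,
    "qi1": True,
    "snr": False,
}

# Plausible raw-value anchors for the QA metrics (site mean, between-site SD,
# within-site SD) on scales typical for T1w quality reports.
_QA_LEVELS: dict[str, tuple[float, float, float]] = {
    "cnr": (13.0, 2.0, 1.5),
    "efc": (0.45, 0.05, 0.03),
    "fber": (500.0, 150.0, 80.0),
    "fwhm": (4.2, 0.5, 0.25),
    "qi1": (0.02, 0.008, 0.006),
    "snr": (9.0, 1.5, 1.0),
}


def _as_feature_map(values: dict[str, float] | None, default: float = 0.0) -> dict[str, float]:
    out = {f: default for f in FEATURES}
    if values:
        unknown = set(values) - set(FEATURES)
        if unknown:
            raise ValueError(f"unknown feature name(s) in config: {sorted(unknown)}")
        out.update(values)
    return out


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic cohort.

    Defaults reproduce the study-population marginals (n, sites, age
    distribution, sex ratio, IQ) and place the strongest age signal on
    cortical thickness and volume, with near-null signal on the curvature
    features; the latent-factor coupling gives morphometric-similarity
    edges an intermediate amount of age information.
    """

    n_subjects: int = 327
    n_sites: int = 17
    age_range: tuple[float, float] = (6.5, 16.9)
    age_mean: float = 12.4
    age_sd: float = 2.5
    male_fraction: float = 259 / 327
    iq_mean: float = 110.0
    iq_sd: float = 15.0
    iq_missing_fraction: float = 19 / 327

    #: Population mean of each feature at the cohort mean age (native units).
    feature_means: dict[str, float] = field(default_factory=lambda: {
        "surface_area": 2500.0,
        "curvature_index": 0.50,
        "folding_index": 15.0,
        "gaussian_curvature": 0.150,
        "mean_curvature": 0.120,
        "cortical_thickness": 2.60,
        "cortical_volume": 6500.0,
    })
    #: Between-region SD of the baseline (regional heterogeneity of the atlas).
    feature_region_sd: dict[str, float] = field(default_factory=lambda: {
        "surface_area": 500.0,
        "curvature_index": 0.10,
        "folding_index": 3.0,
        "gaussian_curvature": 0.030,
        "mean_curvature": 0.025,
        "cortical_thickness": 0.30,
        "cortical_volume": 1300.0,
    })
    #: Linear age slope per feature, native units / year (thickness and
    #: volume thin with age; curvature essentially flat).
    age_trend_linear: dict[str, float] = field(default_factory=lambda: {
        "surface_area": 15.0,
        "curvature_index": 0.002,
        "folding_index": 0.08,
        "gaussian_curvature": 0.0004,
        "mean_curvature": 0.0003,
        "cortical_thickness": -0.035,
        "cortical_volume": -90.0,
    })
    #: Quadratic age term, native units / year^2 (off by default).
    age_trend_quadratic: dict[str, float] = field(default_factory=dict)
    #: SD of the per-subject, per-feature offset shared across regions
    #: (stable individual differences; limits attainable prediction accuracy).
    subject_effect_sd: dict[str, float] = field(default_factory=lambda: {
        "surface_area": 150.0,
        "curvature_index": 0.035,
        "folding_index": 1.0,
        "gaussian_curvature": 0.010,
        "mean_curvature": 0.008,
        "cortical_thickness": 0.060,
        "cortical_volume": 180.0,
    })
    #: Measurement noise SD per feature (iid across subject x region).
    noise_sd: dict[str, float] = field(default_factory=lambda: {
        "surface_area": 120.0,
        "curvature_index": 0.050,
        "folding_index": 1.5,
        "gaussian_curvature": 0.020,
        "mean_curvature": 0.015,
        "cortical_thickness": 0.100,
        "cortical_volume": 400.0,
    })

    #: Explicit per-site additive offsets (n_sites x 7, feature order as
    #: :data:`~brainage_msn.atlas.FEATURES`); drawn from ``site_location_sd``
    #: when None.
    site_location_effects: list[list[float]] | None = None
    #: Explicit per-site multiplicative factors; drawn log-normally with
    #: ``site_scale_log_sd`` when None.
    site_scale_effects: list[list[float]] | None = None
    #: SD of drawn site offsets, expressed as a fraction of the feature's
    #: noise SD (batch effects comparable to measurement noise).
    site_location_sd_frac: float = 1.0
    site_scale_log_sd: float = 0.08

    #: Rotation rate of the latent-factor region loadings, radians / year.
    coupling_age_slope: float = 0.08
    #: Loading magnitude per feature, as a multiple of that feature's noise
    #: SD.  Loadings concentrate on thickness and volume (the features whose
    #: regional organisation matures most in this age window) so that
    #: similarity edges inherit age information from their co-variation
    #: while curvature-type features stay essentially age-null.
    coupling_strength_frac: dict[str, float] = field(default_factory=lambda: {
        "surface_area": 0.3,
        "curvature_index": 0.1,
        "folding_index": 0.1,
        "gaussian_curvature": 0.1,
        "mean_curvature": 0.1,
        "cortical_thickness": 0.8,
        "cortical_volume": 0.8,
    })
    #: Latent factor score distribution g_s ~ N(mean, sd).
    coupling_factor_mean: float = 1.0
    coupling_factor_sd: float = 0.5
    #: Age at which the loading rotation (and trend anchoring) is centred.
    age_ref: float = 12.4

    #: Fraction of subjects given deliberately degraded QA metrics, and the
    #: size of the degradation in within-site SD units.
    qa_degrade_fraction: float = 14 / 361
    qa_degrade_shift: float = 3.0

    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        if self.n_sites <= 0:
            raise ValueError("n_sites must be positive")
        if not (0.0 < self.male_fraction < 1.0):
            raise ValueError("male_fraction must lie in (0, 1)")
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("age_range must satisfy min < max")
        if self.age_sd < 0:
            raise ValueError("age_sd must be >= 0")
        if self.iq_sd < 0:
            raise ValueError("iq_sd must be >= 0")
        for name in ("noise_sd", "subject_effect_sd", "feature_region_sd"):
            for f, v in _as_feature_map(getattr(self, name)).items():
                if v < 0:
                    raise ValueError(f"{name}[{f}] must be >= 0")
        if not (0.0 <= self.qa_degrade_fraction < 1.0):
            raise ValueError("qa_degrade_fraction must lie in [0, 1)")
        for eff, shape_name in (
            (self.site_location_effects, "site_location_effects"),
            (self.site_scale_effects, "site_scale_effects"),
        ):
            if eff is not None:
                arr = np.asarray(eff, dtype=float)
                if arr.shape != (self.n_sites, N_FEATURES):
                    raise ValueError(
                        f"{shape_name} must have shape ({self.n_sites}, {N_FEATURES}), got {arr.shape}"
                    )
                if shape_name == "site_scale_effects" and np.any(arr <= 0):
                    raise ValueError("site_scale_effects must be strictly positive")


@dataclass
class GroundTruth:
    """Exact generative parameters used for one cohort draw.

    Stores everything a recovery test needs: the realised baseline matrix,
    trend coefficients, site effects, latent-factor loadings, noise levels
    and the identities of QA-degraded subjects.  JSON round-trips exactly.
    """

    baseline: np.ndarray            # (68, 7) intercepts at age 0 equivalent
    age_trend_linear: np.ndarray    # (7,)
    age_trend_quadratic: np.ndarray  # (7,)
    subject_effect_sd: np.ndarray   # (7,)
    noise_sd: np.ndarray            # (7,)
    site_location: np.ndarray       # (n_sites, 7)
    site_scale: np.ndarray          # (n_sites, 7)
    coupling_loadings0: np.ndarray  # (68, 7), already scaled by lambda
    coupling_loadings1: np.ndarray  # (68, 7)
    coupling_age_slope: float
    coupling_factor_mean: float
    coupling_factor_sd: float
    age_ref: float
    degraded_subjects: list[str]
    seed: int

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            payload[f.name] = v.tolist() if isinstance(v, np.ndarray) else v
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "GroundTruth":
        text = Path(source).read_text() if isinstance(source, Path) else source
        if isinstance(source, str) and not source.lstrip().startswith("{"):
            text = Path(source).read_text()
        payload = json.loads(text)
        kwargs = {}
        for f in dataclasses.fields(cls):
            v = payload[f.name]
            if f.name in ("degraded_subjects",):
                kwargs[f.name] = list(v)
            elif isinstance(v, list):
                kwargs[f.name] = np.asarray(v, dtype=float)
            else:
                kwargs[f.name] = v
        return cls(**kwargs)


class MorphometryTable:
    """Subjects x (68 regions x 7 features) morphometry plus metadata.

    Internally one wide :class:`pandas.DataFrame`: metadata columns
    (subject_id, site_id, age, sex, iq) followed by 476 value columns named
    ``<region>__<feature>``.
    """

    META_COLUMNS = ("subject_id", "site_id", "age", "sex", "iq")

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in self.META_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"missing metadata columns: {missing}")
        expected = value_columns()
        missing_vals = [c for c in expected if c not in frame.columns]
        if missing_vals:
            raise ValueError(f"missing {len(missing_vals)} morphometry columns, e.g. {missing_vals[:3]}")
        cols = list(self.META_COLUMNS) + expected
        frame = frame.loc[:, cols].reset_index(drop=True)
        if frame[expected].isna().any().any():
            raise ValueError("morphometry values must not contain missing entries")
        self.frame = frame

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def meta(self) -> pd.DataFrame:
        return self.frame[list(self.META_COLUMNS)]

    @property
    def subject_ids(self) -> np.ndarray:
        return self.frame["subject_id"].to_numpy()

    def values_array(self) -> np.ndarray:
        """Morphometry as a (n_subjects, 68, 7) array in canonical order."""
        v = self.frame[value_columns()].to_numpy(dtype=float)
        return v.reshape(len(self.frame), N_REGIONS, N_FEATURES)

    def feature_matrix(self, feature: str) -> pd.DataFrame:
        """One feature as an n_subjects x 68 frame (columns = region labels)."""
        if feature not in FEATURES:
            raise KeyError(f"unknown feature {feature!r}")
        cols = [f"{r}__{feature}" for r in DK_REGIONS]
        out = self.frame[cols].copy()
        out.columns = list(DK_REGIONS)
        out.index = self.frame["subject_id"]
        return out

    def with_values(self, values: np.ndarray) -> "MorphometryTable":
        """Copy of the table with the (n, 68, 7) value block replaced."""
        if values.shape != (len(self), N_REGIONS, N_FEATURES):
            raise ValueError(f"values must have shape {(len(self), N_REGIONS, N_FEATURES)}")
        frame = self.frame.copy()
        frame[value_columns()] = values.reshape(len(self), -1)
        return MorphometryTable(frame)

    def subset(self, subject_ids) -> "MorphometryTable":
        keep = self.frame["subject_id"].isin(set(subject_ids))
        return MorphometryTable(self.frame.loc[keep])

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "MorphometryTable":
        return cls(pd.read_csv(path))


class QATable:
    """Per-subject spatial quality metrics (six, including ``efc``)."""

    def __init__(self, frame: pd.DataFrame):
        needed = ["subject_id", "site_id", *QA_METRICS]
        missing = [c for c in needed if c not in frame.columns]
        if missing:
            raise ValueError(f"QA table missing columns: {missing}")
        self.frame = frame.loc[:, needed].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "QATable":
        return cls(pd.read_csv(path))


def _truncnorm_params(target_mean, target_sd, lo, hi):
    """Parent (mu, sigma) whose truncation to [lo, hi] has the target moments.

    Truncation shrinks the SD, so the parent parameters are solved
    numerically; this keeps the *realised* cohort marginals on target.
    """
    from scipy.optimize import fsolve

    def moments(params):
        mu, sigma = params
        sigma = abs(sigma)
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        d = stats.truncnorm(a, b, loc=mu, scale=sigma)
        return d.mean() - target_mean, d.std() - target_sd

    sol, info, ier, _ = fsolve(moments, x0=(target_mean, target_sd), full_output=True)
    if ier != 1:  # infeasible targets: fall back to the naive parameters
        return target_mean, target_sd
    return float(sol[0]), float(abs(sol[1]))


def _truncated_normal_ages(rng, n, mean, sd, lo, hi) -> np.ndarray:
    if sd == 0:
        return np.full(n, mean)
    mu, sigma = _truncnorm_params(mean, sd, lo, hi)
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    dist = stats.truncnorm(a, b, loc=mu, scale=sigma)
    return dist.ppf(rng.uniform(size=n))


def _assign_sites(rng, n_subjects: int, n_sites: int) -> np.ndarray:
    """Uneven site sizes (Dirichlet weights), each site guaranteed >= 2
    subjects whenever n_subjects allows it."""
    sites = np.arange(n_sites)
    counts = np.zeros(n_sites, dtype=int)
    guaranteed = min(2, n_subjects // n_sites)
    counts += guaranteed
    remaining = n_subjects - counts.sum()
    if remaining > 0:
        weights = rng.dirichlet(np.full(n_sites, 3.0))
        extra = rng.multinomial(remaining, weights)
        counts += extra
    assignment = np.repeat(sites, counts)
    rng.shuffle(assignment)
    return assignment[:n_subjects]


def generate_cohort(config: GeneratorConfig) -> tuple[MorphometryTable, QATable, GroundTruth]:
    """Draw one synthetic cohort.

    Deterministic given ``config.seed``; returns the morphometry table, the
    QA table and the :class:`GroundTruth` parameters actually used.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects

    # --- metadata -------------------------------------------------------
    site_idx = _assign_sites(rng, n, config.n_sites)
    ages = _truncated_normal_ages(
        rng, n, config.age_mean, config.age_sd, *config.age_range
    )
    sex = np.where(rng.uniform(size=n) < config.male_fraction, "M", "F")
    iq = rng.normal(config.iq_mean, config.iq_sd, size=n)
    iq[rng.uniform(size=n) < config.iq_missing_fraction] = np.nan
    subject_ids = np.array([f"sub-{i:05d}" for i in range(n)])
    site_ids = np.array([f"site{t:02d}" for t in site_idx])

    # --- generative parameters -----------------------------------------
    means = np.array([_as_feature_map(config.feature_means)[f] for f in FEATURES])
    region_sd = np.array([_as_feature_map(config.feature_region_sd)[f] for f in FEATURES])
    lin = np.array([_as_feature_map(config.age_trend_linear)[f] for f in FEATURES])
    quad = np.array([_as_feature_map(config.age_trend_quadratic)[f] for f in FEATURES])
    subj_sd = np.array([_as_feature_map(config.subject_effect_sd)[f] for f in FEATURES])
    noise_sd = np.array([_as_feature_map(config.noise_sd)[f] for f in FEATURES])

    # intercepts so that the population mean at age_ref equals feature_means
    baseline = (
        means
        - lin * config.age_ref
        - quad * config.age_ref**2
        + region_sd * rng.standard_normal((N_REGIONS, N_FEATURES))
    )

    if config.site_location_effects is not None:
        site_loc = np.asarray(config.site_location_effects, dtype=float)
    else:
        site_loc = (
            config.site_location_sd_frac
            * noise_sd
            * rng.standard_normal((config.n_sites, N_FEATURES))
        )
    if config.site_scale_effects is not None:
        site_scale = np.asarray(config.site_scale_effects, dtype=float)
    else:
        site_scale = np.exp(
            config.site_scale_log_sd * rng.standard_normal((config.n_sites, N_FEATURES))
        )

    coupling_frac = config.coupling_strength_frac
    if not isinstance(coupling_frac, dict):
        coupling_frac = {f: float(coupling_frac) for f in FEATURES}
    lam = np.array([_as_feature_map(coupling_frac)[f] for f in FEATURES]) * noise_sd
    U0 = lam * rng.standard_normal((N_REGIONS, N_FEATURES))
    U1 = lam * rng.standard_normal((N_REGIONS, N_FEATURES))

    # --- assemble values -------------------------------------------------
    theta = config.coupling_age_slope * (ages - config.age_ref)
    g = rng.normal(config.coupling_factor_mean, config.coupling_factor_sd, size=n)
    subj_offset = subj_sd * rng.standard_normal((n, N_FEATURES))
    noise = noise_sd * rng.standard_normal((n, N_REGIONS, N_FEATURES))

    trend = lin[None, :] * ages[:, None] + quad[None, :] * ages[:, None] ** 2  # (n, 7)
    loadings = (
        np.cos(theta)[:, None, None] * U0[None, :, :]
        + np.sin(theta)[:, None, None] * U1[None, :, :]
    )  # (n, 68, 7)
    signal = (
        baseline[None, :, :]
        + trend[:, None, :]
        + g[:, None, None] * loadings
        + subj_offset[:, None, :]
        + site_loc[site_idx][:, None, :]
    )
    values = signal * site_scale[site_idx][:, None, :] + noise

    meta = pd.DataFrame(
        {"subject_id": subject_ids, "site_id": site_ids, "age": ages, "sex": sex, "iq": iq}
    )
    wide = pd.DataFrame(values.reshape(n, -1), columns=value_columns())
    morpho = MorphometryTable(pd.concat([meta, wide], axis=1))

    # --- QA metrics ------------------------------------------------------
    qa_cols = {}
    site_means = {}
    for m in QA_METRICS:
        base, between_sd, within_sd = _QA_LEVELS[m]
        site_means[m] = rng.normal(base, between_sd, size=config.n_sites)
        qa_cols[m] = rng.normal(site_means[m][site_idx], within_sd, size=n)

    n_degraded = int(round(config.qa_degrade_fraction * n))
    degraded_idx = rng.choice(n, size=n_degraded, replace=False) if n_degraded else np.array([], dtype=int)
    for i in degraded_idx:
        n_bad = rng.integers(2, 5)  # degrade 2-4 of the six metrics
        bad_metrics = rng.choice(len(QA_METRICS), size=n_bad, replace=False)
        for j in bad_metrics:
            m = QA_METRICS[j]
            within_sd = _QA_LEVELS[m][2]
            direction = 1.0 if QA_HIGHER_IS_WORSE[m] else -1.0
            qa_cols[m][i] += direction * config.qa_degrade_shift * within_sd

    qa = QATable(pd.DataFrame({"subject_id": subject_ids, "site_id": site_ids, **qa_cols}))

    truth = GroundTruth(
        baseline=baseline,
        age_trend_linear=lin,
        age_trend_quadratic=quad,
        subject_effect_sd=subj_sd,
        noise_sd=noise_sd,
        site_location=site_loc,
        site_scale=site_scale,
        coupling_loadings0=U0,
        coupling_loadings1=U1,
        coupling_age_slope=config.coupling_age_slope,
        coupling_factor_mean=config.coupling_factor_mean,
        coupling_factor_sd=config.coupling_factor_sd,
        age_ref=config.age_ref,
        degraded_subjects=[subject_ids[i] for i in sorted(degraded_idx)],
        seed=config.seed,
    )
    return morpho, qa, truth
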