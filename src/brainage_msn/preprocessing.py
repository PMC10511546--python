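"""Quality-control filtering and ComBat site harmonisation.

QC: the six spatial QA metrics are z-scored within acquisition site (so
sites with different scanners remain comparable), re-signed so that larger
values always mean better quality, and a subject fails a metric when its
quality z falls below ``z_cut`` (default -1.5 SD).  Subjects failing more
than ``max_fail`` metrics (default 1, i.e. the zero-or-one rule) are
excluded.

Harmonisation: location/scale batch correction with empirical-Bayes
shrinkage (ComBat), fitted per morphometric feature on the subjects x 68
regions matrix, with age included in the standardisation design so that
age-related biological variation is protected rather than removed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas import FEATURES
from .synthetic import QA_HIGHER_IS_WORSE, QA_METRICS, MorphometryTable, QATable

__all__ = [
    "zscore_qa_within_site",
    "apply_qc_filter",
    "HarmonizationModel",
    "fit_harmonization",
    "apply_harmonization",
    "harmonize_table",
]

logger = logging.getLogger(__name__)


def zscore_qa_within_site(
    qa: QATable,
    higher_is_worse: dict[str, bool] | None = None,
    ddof: int = 0,
    z_cut: float = -1.5,
    max_fail: int = 1,
) -> pd.DataFrame:
    """Within-site z-scoring of the QA metrics, oriented quality-positive.

    Each metric is centred and scaled within its site (population SD by
    default, ``ddof`` configurable), then metrics whose raw orientation is
    higher-is-worse are sign-flipped so a larger z always indicates better
    quality.  Returns a QC table with columns ``z_<metric>``, ``n_failed``
    (count of metrics with z < z_cut) and ``included``.
    """
    if higher_is_worse is None:
        higher_is_worse = QA_HIGHER_IS_WORSE
    frame = qa.frame
    out = frame[["subject_id", "site_id"]].copy()
    for m in QA_METRICS:
        raw = frame[m].astype(float)
        grouped = raw.groupby(frame["site_id"])
        counts = grouped.transform("size")
        if (counts < 2).any():
            bad = frame.loc[counts < 2, "site_id"].iloc[0]
            raise ValueError(f"site {bad!r} has fewer than 2 subjects; cannot z-score metric {m!r}")
        mu = grouped.transform("mean")
        sd = grouped.transform(lambda s: s.std(ddof=ddof))
        if (sd == 0).any():
            bad = frame.loc[(sd == 0).to_numpy(), "site_id"].iloc[0]
            raise ValueError(f"metric {m!r} has zero SD within site {bad!r}")
        z = (raw - mu) / sd
        if higher_is_worse.get(m, False):
            z = -z
        out[f"z_{m}"] = z
    zcols = [f"z_{m}" for m in QA_METRICS]
    out["n_failed"] = (out[zcols] < z_cut).sum(axis=1)
    out["included"] = out["n_failed"] <= max_fail
    return out


def apply_qc_filter(qc: pd.DataFrame, z_cut: float = -1.5, max_fail: int = 1) -> list[str]:
    """Subjects passing the zero-or-``max_fail`` rule at the given cut.

    Recomputes failure counts from the z columns so the cut can be varied
    after scoring; logs how many subjects were excluded.
    """
    if len(qc) == 0:
        raise ValueError("empty QC table")
    zcols = [f"z_{m}" for m in QA_METRICS]
    n_failed = (qc[zcols].to_numpy() < z_cut).sum(axis=1)
    keep = n_failed <= max_fail
    excluded = int((~keep).sum())
    logger.info("QC filter: %d/%d subjects excluded (>%d metrics below z=%g)",
                excluded, len(qc), max_fail, z_cut)
    return list(qc.loc[keep, "subject_id"])


@dataclass
class HarmonizationModel:
    """Fitted ComBat model for one morphometric feature.

    Location (``gamma_star``) and scale (``delta_star``) estimates per site
    and region, the pooled standardisation model (region intercepts
    ``alpha``, age coefficient ``beta_age``, pooled variance), and the
    empirical-Bayes hyperparameters when shrinkage was used.
    """

    sites: list[str]
    alpha: np.ndarray          # (p,) region intercepts (site-size weighted)
    beta_age: np.ndarray       # (p,) protected age coefficients
    var_pooled: np.ndarray     # (p,)
    gamma_star: np.ndarray     # (n_sites, p) additive site effects (standardised scale)
    delta_star: np.ndarray     # (n_sites, p) multiplicative site effects (variances)
    eb: bool
    identity: bool = False
    hyper: dict | None = None

    def site_index(self, site_ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sites)}
        try:
            return np.array([lookup[s] for s in site_ids])
        except KeyError as exc:
            raise ValueError(f"unseen site id {exc.args[0]!r}") from None


def _standardise(values, site_idx, age, n_sites):
    """Pooled location/scale model with site intercepts and an age covariate."""
    n, p = values.shape
    design = np.zeros((n, n_sites + 1))
    design[np.arange(n), site_idx] = 1.0
    design[:, -1] = age
    xtx = design.T @ design
    try:
        coefs = np.linalg.solve(xtx, design.T @ values)  # (n_sites+1, p)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"singular harmonisation design: {exc}") from exc
    site_counts = np.bincount(site_idx, minlength=n_sites).astype(float)
    alpha = (site_counts / n) @ coefs[:-1]               # grand mean, size-weighted
    beta_age = coefs[-1]
    resid = values - design @ coefs
    var_pooled = (resid**2).mean(axis=0)
    if np.any(var_pooled <= 0):
        raise ValueError("zero pooled variance; cannot standardise")
    return alpha, beta_age, var_pooled


def _eb_iterate(s_site, gamma_hat, delta_hat, gamma_bar, tau2, a_prior, b_prior,
                conv: float = 1e-4, max_iter: int = 1000):
    """Parametric empirical-Bayes iteration for one site (vector over regions)."""
    n = s_site.shape[0]
    g_old, d_old = gamma_hat.copy(), delta_hat.copy()
    for _ in range(max_iter):
        g_new = (tau2 * n * gamma_hat + d_old * gamma_bar) / (tau2 * n + d_old)
        sum2 = ((s_site - g_new[None, :]) ** 2).sum(axis=0)
        d_new = (0.5 * sum2 + b_prior) / (n / 2.0 + a_prior - 1.0)
        change = max(
            np.max(np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-12)),
            np.max(np.abs(d_new - d_old) / np.maximum(np.abs(d_old), 1e-12)),
        )
        g_old, d_old = g_new, d_new
        if change < conv:
            break
    return g_old, d_old


def fit_harmonization(
    values: np.ndarray,
    site_ids,
    age: np.ndarray,
    eb: bool = True,
) -> HarmonizationModel:
    """Fit ComBat location/scale site correction for one feature.

    ``values`` is the subjects x regions matrix of a single morphometric
    feature.  Age enters the standardisation design so the fitted age trend
    is removed before site effects are estimated and restored afterwards.
    With ``eb=True`` (default) per-site effects are shrunk towards their
    across-region prior (normal for locations, inverse-gamma for scale
    variances, moment-matched); ``eb=False`` keeps the raw per-site
    estimates, which is exact for closed-form tests.
    """
    values = np.asarray(values, dtype=float)
    age = np.asarray(age, dtype=float)
    site_ids = np.asarray(site_ids)
    sites = sorted(pd.unique(site_ids).tolist())
    if len(sites) < 2:
        warnings.warn("single site: harmonisation is the identity", stacklevel=2)
        p = values.shape[1]
        return HarmonizationModel(
            sites=sites, alpha=np.zeros(p), beta_age=np.zeros(p),
            var_pooled=np.ones(p), gamma_star=np.zeros((1, p)),
            delta_star=np.ones((1, p)), eb=eb, identity=True,
        )
    site_idx = np.array([sites.index(s) for s in site_ids])
    counts = np.bincount(site_idx, minlength=len(sites))
    if counts.min() < 2:
        raise ValueError(f"site {sites[int(counts.argmin())]!r} has fewer than 2 subjects")

    alpha, beta_age, var_pooled = _standardise(values, site_idx, age, len(sites))
    s_data = (values - alpha[None, :] - np.outer(age, beta_age)) / np.sqrt(var_pooled)[None, :]

    gamma_hat = np.stack([s_data[site_idx == i].mean(axis=0) for i in range(len(sites))])
    delta_hat = np.stack([s_data[site_idx == i].var(axis=0, ddof=1) for i in range(len(sites))])

    if not eb:
        gamma_star, delta_star, hyper = gamma_hat, delta_hat, None
    else:
        gamma_bar = gamma_hat.mean(axis=1)
        tau2 = gamma_hat.var(axis=1, ddof=1)
        m = delta_hat.mean(axis=1)
        s2 = delta_hat.var(axis=1, ddof=1)
        a_prior = (2.0 * s2 + m**2) / s2
        b_prior = (m * s2 + m**3) / s2
        gamma_star = np.empty_like(gamma_hat)
        delta_star = np.empty_like(delta_hat)
        for i in range(len(sites)):
            gamma_star[i], delta_star[i] = _eb_iterate(
                s_data[site_idx == i], gamma_hat[i], delta_hat[i],
                gamma_bar[i], tau2[i], a_prior[i], b_prior[i],
            )
        hyper = {"gamma_bar": gamma_bar, "tau2": tau2, "a_prior": a_prior, "b_prior": b_prior}

    if np.any(delta_star <= 0):
        raise ValueError("non-positive scale estimate")
    return HarmonizationModel(
        sites=sites, alpha=alpha, beta_age=beta_age, var_pooled=var_pooled,
        gamma_star=gamma_star, delta_star=delta_star, eb=eb, hyper=hyper,
    )


def apply_harmonization(
    model: HarmonizationModel,
    values: np.ndarray,
    site_ids,
    age: np.ndarray,
) -> np.ndarray:
    """Remove the fitted site effects, re-adding the protected age fit."""
    values = np.asarray(values, dtype=float)
    age = np.asarray(age, dtype=float)
    if model.identity:
        model.site_index(site_ids)  # still validate ids
        return values.copy()
    if values.shape[1] != model.alpha.shape[0]:
        raise ValueError("region layout differs from the fitted model")
    site_idx = model.site_index(site_ids)
    protected = model.alpha[None, :] + np.outer(age, model.beta_age)
    s_data = (values - protected) / np.sqrt(model.var_pooled)[None, :]
    corrected = (s_data - model.gamma_star[site_idx]) / np.sqrt(model.delta_star[site_idx])
    return corrected * np.sqrt(model.var_pooled)[None, :] + protected


def harmonize_table(
    morpho: MorphometryTable, eb: bool = True
) -> tuple[MorphometryTable, dict[str, HarmonizationModel]]:
    """ComBat each of the seven features of a morphometry table in place.

    Fitted on all supplied subjects (harmonisation precedes any train/test
    split); returns the corrected table and the per-feature models.
    """
    vals = morpho.values_array()
    site_ids = morpho.frame["site_id"].to_numpy()
    age = morpho.frame["age"].to_numpy(dtype=float)
    corrected = np.empty_like(vals)
    models: dict[str, HarmonizationModel] = {}
    for j, feat in enumerate(FEATURES):
        model = fit_harmonization(vals[:, :, j], site_ids, age, eb=eb)
        corrected[:, :, j] = apply_harmonization(model, vals[:, :, j], site_ids, age)
        models[feat] = model
    return morpho.with_values(corrected), models
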