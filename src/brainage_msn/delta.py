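"""Brain-age delta and its bias screens.

Delta is the signed gap predicted_age - actual_age on the held-out test
cohort.  Because regression-to-the-mean inflates predictions for young
subjects and deflates them for old ones, delta is screened against actual
age, and every covariate association (motion proxy EFC, IQ) is assessed
with first-order partial correlations controlling actual age; sex is
screened with a linear model adjusting for age.  The screen applies a
Bonferroni threshold of alpha = 0.05 / 60 = 0.000833 across its tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

__all__ = [
    "AGE_BANDS",
    "compute_delta",
    "delta_summary",
    "partial_correlation",
    "sex_bias_test",
    "covariate_screen",
    "BONFERRONI_ALPHA",
]

#: Developmental bands used for reporting delta profiles.
AGE_BANDS: tuple[tuple[str, float, float], ...] = (
    ("childhood", 5.0, 11.0),
    ("early_adolescence", 11.0, 14.0),
    ("middle_adolescence", 14.0, 17.0),
)

#: Screen-wide Bonferroni threshold (0.05 over the 60 screen tests).
BONFERRONI_ALPHA: float = 0.05 / 60


def _age_band(age: float) -> str:
    for name, lo, hi in AGE_BANDS:
        if lo <= age < hi:
            return name
    return "other"


def compute_delta(
    predictions: np.ndarray,
    actual_ages: np.ndarray,
    subject_ids=None,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Signed delta table (predicted - actual) for one model's test cohort.

    ``covariates`` may carry efc / iq / sex columns aligned row-wise; they
    are merged into the returned table for the downstream screens.
    """
    predictions = np.asarray(predictions, dtype=float).ravel()
    actual_ages = np.asarray(actual_ages, dtype=float).ravel()
    if predictions.shape != actual_ages.shape:
        raise ValueError("predictions and actual ages have different lengths")
    if subject_ids is None:
        subject_ids = [f"sub-{i:05d}" for i in range(predictions.size)]
    out = pd.DataFrame({
        "subject_id": np.asarray(subject_ids),
        "actual_age": actual_ages,
        "predicted_age": predictions,
        "delta": predictions - actual_ages,
    })
    out["age_band"] = [_age_band(a) for a in actual_ages]
    if covariates is not None:
        cov = covariates.reset_index(drop=True)
        for col in ("efc", "iq", "sex"):
            if col in cov.columns:
                out[col] = cov[col].to_numpy()
    return out


def delta_summary(delta_table: pd.DataFrame) -> dict:
    """Group summaries of delta, overall and per developmental band."""
    d = delta_table["delta"]
    by_band = {
        band: {
            "n": int(g.shape[0]),
            "mean": float(g["delta"].mean()),
            "sd": float(g["delta"].std(ddof=1)) if g.shape[0] > 1 else float("nan"),
        }
        for band, g in delta_table.groupby("age_band")
    }
    return {
        "n": int(d.size),
        "mean": float(d.mean()),
        "sd": float(d.std(ddof=1)),
        "median": float(d.median()),
        "bands": by_band,
    }


def partial_correlation(x, y, control, method: str = "pearson") -> tuple[float, float]:
    """First-order partial correlation of x and y given one control.

    Pearson uses the pairwise-correlation formula
    r_xy.c = (r_xy - r_xc r_yc) / sqrt((1 - r_xc^2)(1 - r_yc^2));
    Spearman applies the same formula to ranks.  The p-value comes from the
    t transform with n - 3 degrees of freedom.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    c = np.asarray(control, dtype=float).ravel()
    if not (x.size == y.size == c.size):
        raise ValueError("inputs have different lengths")
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 observations for a first-order partial correlation")
    if not (np.isfinite(x).all() and np.isfinite(y).all() and np.isfinite(c).all()):
        raise ValueError("inputs must be finite (drop missing values first)")
    if method == "spearman":
        x, y, c = (stats.rankdata(v) for v in (x, y, c))
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")
    for name, v in (("x", x), ("y", y), ("control", c)):
        if np.std(v) == 0:
            raise ValueError(f"{name} has zero variance")
    r_xy = np.corrcoef(x, y)[0, 1]
    r_xc = np.corrcoef(x, c)[0, 1]
    r_yc = np.corrcoef(y, c)[0, 1]
    denom = np.sqrt((1 - r_xc**2) * (1 - r_yc**2))
    if denom == 0:
        raise ValueError("a control correlation is exactly +/-1; partial correlation undefined")
    r = float((r_xy - r_xc * r_yc) / denom)
    r = max(min(r, 1.0), -1.0)
    df = n - 3
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1 - r**2))
    p = float(2 * stats.t.sf(abs(t), df))
    return r, p


def sex_bias_test(delta, sex, age) -> tuple[float, float]:
    """OLS delta ~ sex + actual age; the sex coefficient's t and p.

    Sex is coded male = 1, female = 0, so a positive statistic means
    larger delta in males after age adjustment.
    """
    delta = np.asarray(delta, dtype=float).ravel()
    age = np.asarray(age, dtype=float).ravel()
    sex = np.asarray(sex)
    if delta.size < 5:
        raise ValueError("need at least 5 observations")
    male = (sex == "M").astype(float)
    if male.min() == male.max():
        raise ValueError("both sexes must be present")
    X = sm.add_constant(np.column_stack([male, age]))
    fit = sm.OLS(delta, X).fit()
    return float(fit.tvalues[1]), float(fit.pvalues[1])


@dataclass
class _ScreenRow:
    covariate: str
    feature_set: str
    n: int
    statistic: float
    p: float
    method: str
    significant: bool


def covariate_screen(
    delta_tables: dict[str, pd.DataFrame],
    alpha: float = BONFERRONI_ALPHA,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Screen every model's delta against motion (EFC), IQ, and sex.

    Expects one delta table per feature-set model with columns delta,
    actual_age and (optionally) efc, iq, sex.  Continuous covariates get
    Pearson and Spearman partial correlations controlling actual age with
    pairwise deletion of missing values (the per-row n records how many
    subjects entered each test); sex gets the age-adjusted linear model.
    Returns the long-format screen table and the mean Pearson r across
    models per continuous covariate.
    """
    rows: list[_ScreenRow] = []
    pearson_acc: dict[str, list[float]] = {"efc": [], "iq": []}
    for model_name, tab in delta_tables.items():
        for cov in ("efc", "iq"):
            if cov not in tab.columns:
                raise ValueError(f"delta table for {model_name!r} lacks covariate {cov!r}")
            sub = tab[["delta", "actual_age", cov]].dropna()
            for method in ("pearson", "spearman"):
                r, p = partial_correlation(
                    sub["delta"], sub[cov], sub["actual_age"], method=method)
                rows.append(_ScreenRow(cov, model_name, len(sub), r, p, method, p < alpha))
                if method == "pearson":
                    pearson_acc[cov].append(r)
        if "sex" not in tab.columns:
            raise ValueError(f"delta table for {model_name!r} lacks the sex column")
        t, p = sex_bias_test(tab["delta"], tab["sex"], tab["actual_age"])
        rows.append(_ScreenRow("sex", model_name, len(tab), t, p, "ols_t", p < alpha))
    table = pd.DataFrame([r.__dict__ for r in rows])
    mean_r = {cov: float(np.mean(v)) for cov, v in pearson_acc.items() if v}
    return table, mean_r
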