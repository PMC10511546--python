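"""QC filtering and ComBat harmonisation: z-scoring identities, the
zero-or-one failure rule, closed-form site correction and the protection
of the age trend."""

import numpy as np
import pandas as pd
import pytest

from brainage_msn.atlas import FEATURES
from brainage_msn.preprocessing import (
    apply_harmonization,
    apply_qc_filter,
    fit_harmonization,
    harmonize_table,
    zscore_qa_within_site,
)
from brainage_msn.synthetic import QA_METRICS, GeneratorConfig, QATable, generate_cohort

THICK = FEATURES.index("cortical_thickness")


def _qa_frame(values: dict[str, list[float]], sites: list[str]) -> QATable:
    n = len(sites)
    cols = {m: values.get(m, list(np.linspace(0.0, 1.0, n))) for m in QA_METRICS}
    return QATable(pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(n)], "site_id": sites, **cols}))


class TestQCZscoring:
    def test_site_mean_subject_has_zero_z_and_is_included(self):
        sites = ["A"] * 4
        # subject 0 sits exactly at the site mean of every metric
        vals = {m: [0.5, 0.4, 0.6, 0.5] for m in QA_METRICS}
        qc = zscore_qa_within_site(_qa_frame(vals, sites))
        zcols = [f"z_{m}" for m in QA_METRICS]
        assert np.allclose(qc.loc[0, zcols].astype(float), 0.0, atol=1e-12)
        assert bool(qc.loc[0, "included"])

    def test_within_site_mean_zero_sd_one(self):
        m, qa, _ = generate_cohort(GeneratorConfig(n_subjects=80, seed=2))
        qc = zscore_qa_within_site(qa)
        g = qc.groupby("site_id")["z_efc"]
        assert np.allclose(g.mean(), 0.0, atol=1e-10)
        assert np.allclose(g.apply(lambda s: s.std(ddof=0)), 1.0, atol=1e-10)

    def test_orientation_resigned_to_quality_positive(self):
        # efc is higher-is-worse: the subject with the largest raw efc must
        # get the most negative quality z
        sites = ["A"] * 5
        vals = {m: [0.1, 0.2, 0.3, 0.4, 5.0] for m in QA_METRICS}
        qc = zscore_qa_within_site(_qa_frame(vals, sites))
        assert qc["z_efc"].idxmin() == 4
        assert qc["z_snr"].idxmax() == 4  # snr is higher-is-better

    def test_two_failures_excluded_one_failure_included(self):
        # mild background spread keeps natural |z| well under 1.5; subject 0
        # is dragged far down on two higher-is-better metrics
        sites = ["A"] * 5
        base = [10.0, 10.2, 9.8, 10.1, 9.9]
        vals = {m: list(base) for m in QA_METRICS}
        for m in ("snr", "cnr"):
            vals[m] = [4.0, 10.2, 9.8, 10.1, 9.9]
        qc = zscore_qa_within_site(_qa_frame(vals, sites))
        assert int(qc.loc[0, "n_failed"]) == 2
        assert not bool(qc.loc[0, "included"])
        # only one bad metric: included under the zero-or-one rule
        vals["cnr"] = list(base)
        qc1 = zscore_qa_within_site(_qa_frame(vals, sites))
        assert int(qc1.loc[0, "n_failed"]) == 1
        assert bool(qc1.loc[0, "included"])

    def test_small_site_and_zero_sd_errors_name_the_culprit(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            zscore_qa_within_site(_qa_frame({}, ["A", "B", "B", "B"]))
        vals = {m: [1.0, 1.0, 1.0] for m in QA_METRICS}
        with pytest.raises(ValueError, match="zero SD"):
            zscore_qa_within_site(_qa_frame(vals, ["A"] * 3))


class TestQCFilter:
    def test_all_at_site_mean_all_included(self):
        m, qa, _ = generate_cohort(GeneratorConfig(n_subjects=50, seed=3, qa_degrade_fraction=0.0))
        qc = zscore_qa_within_site(qa)
        # z_cut at -inf: everyone passes regardless of quality
        assert len(apply_qc_filter(qc, z_cut=-np.inf)) == 50

    def test_degraded_subjects_are_exactly_the_excluded(self):
        """Constructed cohort: k subjects dropped >= 2 within-site SD on >= 2
        metrics; exactly those k fail the filter."""
        n, per_site = 60, 20
        sites = np.repeat(["A", "B", "C"], per_site)
        # per-metric background: the same evenly spaced pattern rotated by a
        # different offset per metric, so no subject is a natural extreme on
        # more than one metric (evenly spaced z never exceeds ~1.65 anyway)
        pattern = np.linspace(-1.0, 1.0, per_site)
        cols = {}
        for k, m in enumerate(QA_METRICS):
            site_vals = np.roll(pattern, 3 * k)
            cols[m] = 10.0 + np.tile(site_vals, 3)
        bad = [3, 25, 47]
        for i in bad:
            for m in ("snr", "fber", "cnr"):  # higher-is-better metrics
                cols[m][i] -= 8.0  # many within-site SDs below the rest
        qa = QATable(pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(n)], "site_id": sites, **cols}))
        qc = zscore_qa_within_site(qa)
        kept = set(apply_qc_filter(qc))
        excluded = {f"s{i}" for i in range(n)} - kept
        assert excluded == {f"s{i}" for i in bad}
        # and the count agrees with direct enumeration of the z table
        zcols = [f"z_{m}" for m in QA_METRICS]
        assert ((qc[zcols] < -1.5).sum(axis=1) > 1).sum() == len(bad)

    def test_order_invariance(self):
        m, qa, _ = generate_cohort(GeneratorConfig(n_subjects=40, seed=5))
        qc = zscore_qa_within_site(qa)
        shuffled = QATable(qa.frame.sample(frac=1, random_state=0).reset_index(drop=True))
        qc2 = zscore_qa_within_site(shuffled)
        assert set(apply_qc_filter(qc)) == set(apply_qc_filter(qc2))

    def test_empty_table_errors(self):
        with pytest.raises(ValueError):
            apply_qc_filter(pd.DataFrame(columns=["subject_id"] + [f"z_{m}" for m in QA_METRICS]))


class TestHarmonisation:
    def test_single_site_is_identity(self):
        rng = np.random.default_rng(0)
        Y = rng.normal(size=(20, 5))
        with pytest.warns(UserWarning, match="single site"):
            model = fit_harmonization(Y, ["A"] * 20, rng.uniform(6, 17, 20))
        out = apply_harmonization(model, Y, ["A"] * 20, np.zeros(20))
        np.testing.assert_allclose(out, Y, atol=1e-8)

    def test_pure_additive_offset_removed_exactly_without_eb(self):
        """Two sites differing by a constant per-region offset: non-EB ComBat
        equalises the site means to numerical precision."""
        rng = np.random.default_rng(1)
        n_per, p = 30, 6
        age = np.concatenate([rng.uniform(6, 17, n_per)] * 2)
        base = 2.5 - 0.03 * age[:, None] + rng.normal(0, 0.05, (2 * n_per, p))
        delta = rng.normal(0, 0.4, p)
        Y = base.copy()
        Y[n_per:] += delta
        sites = ["A"] * n_per + ["B"] * n_per
        model = fit_harmonization(Y, sites, age, eb=False)
        out = apply_harmonization(model, Y, sites, age)
        # compare age-adjusted site means
        resid = out - np.outer(age, model.beta_age)
        diff = resid[:n_per].mean(axis=0) - resid[n_per:].mean(axis=0)
        assert np.max(np.abs(diff)) < 1e-6

    def test_age_slope_protected(self):
        """Post-harmonisation OLS on thickness recovers the injected slope."""
        import statsmodels.api as sm
        cfg = GeneratorConfig(n_subjects=500, seed=0)
        m, _, truth = generate_cohort(cfg)
        corrected, _ = harmonize_table(m)
        ages = m.frame["age"].to_numpy()
        y = corrected.values_array()[:, :, THICK].mean(axis=1)
        X = sm.add_constant(ages)
        fit = sm.OLS(y, X).fit()
        # cohort-level injected trend includes the realised coupling drift
        theta = truth.coupling_age_slope * (ages - truth.age_ref)
        ey = (truth.age_trend_linear[THICK] * ages
              + truth.coupling_factor_mean * (
                  np.cos(theta) * truth.coupling_loadings0[:, THICK].mean()
                  + np.sin(theta) * truth.coupling_loadings1[:, THICK].mean()))
        target = sm.OLS(ey, X).fit().params[1]
        assert abs(fit.params[1] - target) < 3 * fit.bse[1]

    def test_matches_reference_combat_implementation(self):
        """EB ComBat output equals the Bioconductor reference on a frozen
        fixture (tests/data/combat_sva_reference.csv, synthetic, generated
        from the seeded inputs below)."""
        from pathlib import Path
        rng = np.random.default_rng(42)
        n, p = 40, 6
        site = np.repeat([f"s{i}" for i in range(3)], [15, 12, 13])
        age = rng.uniform(6, 17, n)
        Y = 2.5 - 0.03 * age[:, None] + rng.normal(0, 0.1, (n, p))
        Y += np.array([0.3, -0.2, 0.1])[pd.factorize(site)[0]][:, None]
        Y *= np.array([1.1, 0.9, 1.0])[pd.factorize(site)[0]][:, None]
        model = fit_harmonization(Y, site, age, eb=True)
        out = apply_harmonization(model, Y, site, age)
        ref = pd.read_csv(Path(__file__).parent / "data" / "combat_sva_reference.csv").to_numpy()
        assert np.max(np.abs(out - ref)) < 1e-5

    def test_unseen_site_errors(self):
        rng = np.random.default_rng(3)
        Y = rng.normal(size=(20, 4))
        sites = ["A"] * 10 + ["B"] * 10
        model = fit_harmonization(Y, sites, rng.uniform(6, 17, 20))
        with pytest.raises(ValueError, match="unseen site"):
            apply_harmonization(model, Y[:5], ["C"] * 5, np.zeros(5))

    def test_reduces_site_f_statistic(self):
        """Harmonisation lowers the age-residualised site F on a cohort with
        injected site effects."""
        import statsmodels.api as sm
        from scipy import stats

        m, _, _ = generate_cohort(GeneratorConfig(n_subjects=300, seed=8))
        ages = m.frame["age"].to_numpy()
        sites = m.frame["site_id"].to_numpy()
        corrected, _ = harmonize_table(m)

        def mean_f(tbl):
            v = tbl.values_array()[:, :, THICK]
            X = sm.add_constant(ages)
            resid = v - X @ np.linalg.lstsq(X, v, rcond=None)[0]
            groups = [resid[sites == s] for s in np.unique(sites)]
            return float(np.mean(stats.f_oneway(*groups, axis=0).statistic))

        assert mean_f(corrected) < mean_f(m)
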