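"""Statistical battery: closed-form oracles, boundaries, simulations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from hemiconn.stats import (anova_tukey, bonferroni, partial_correlation,
                            residualize, run_correlation_battery, split_groups)


class TestResidualize:
    def test_orthogonal_covariate_just_centers(self):
        rng = np.random.default_rng(0)
        n = 200
        z = rng.normal(size=n)
        y = rng.normal(size=n)
        # orthogonalize y against [1, z] exactly, then add a mean
        X = np.column_stack([np.ones(n), z])
        y_orth = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        y_in = y_orth + 5.0
        out = residualize(y_in, pd.DataFrame({"z": z}))
        assert np.allclose(out, y_in - y_in.mean(), atol=1e-10)

    def test_perfect_linear_fit_gives_zero(self):
        age = np.linspace(20, 60, 50)
        y = 3.0 + 0.2 * age
        out = residualize(y, pd.DataFrame({"age": age}))
        assert np.max(np.abs(out)) < 1e-9

    def test_center_dummies_zero_group_means(self):
        rng = np.random.default_rng(1)
        centers = np.repeat(["a", "b", "c"], 40)
        y = rng.normal(size=120) + np.repeat([0.0, 2.0, -1.0], 40)
        out = residualize(y, pd.DataFrame({"center": centers}))
        for c in "abc":
            assert abs(out[centers == c].mean()) < 1e-10

    def test_collinear_design_rejected(self):
        y = np.arange(20, dtype=float)
        cov = pd.DataFrame({"a": np.ones(20), "b": 2 * np.ones(20)})
        with pytest.raises(ValueError, match="collinear"):
            residualize(y, cov)


class TestPartialCorrelation:
    def test_single_covariate_closed_form(self):
        """Matches (r_xy - r_xz r_yz)/sqrt((1-r_xz^2)(1-r_yz^2))."""
        rng = np.random.default_rng(2)
        n = 150
        z = rng.normal(size=n)
        x = 0.5 * z + rng.normal(size=n)
        y = -0.3 * z + 0.4 * x + rng.normal(size=n)
        r_xy = np.corrcoef(x, y)[0, 1]
        r_xz = np.corrcoef(x, z)[0, 1]
        r_yz = np.corrcoef(y, z)[0, 1]
        expected = (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
        res = partial_correlation(x, y, pd.DataFrame({"z": z}))
        assert res.r == pytest.approx(expected, abs=1e-10)

    def test_self_correlation_is_one(self):
        x = np.random.default_rng(3).normal(size=50)
        res = partial_correlation(x, x)
        assert res.r == pytest.approx(1.0)
        assert res.p_raw == 0.0

    def test_no_covariates_equals_pearson(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=(2, 80))
        res = partial_correlation(x, y)
        r_sp, p_sp = sps.pearsonr(x, y)
        assert res.r == pytest.approx(r_sp, abs=1e-12)
        assert res.p_raw == pytest.approx(p_sp, rel=1e-9)

    def test_symmetry_and_affine_invariance(self):
        rng = np.random.default_rng(5)
        z = rng.normal(size=100)
        x = z + rng.normal(size=100)
        y = z + rng.normal(size=100)
        cov = pd.DataFrame({"z": z})
        r1 = partial_correlation(x, y, cov).r
        r2 = partial_correlation(y, x, cov).r
        r3 = partial_correlation(3 * x - 7, 0.5 * y + 2,
                                 pd.DataFrame({"z": -2 * z + 1})).r
        assert r1 == pytest.approx(r2, abs=1e-12)
        assert r1 == pytest.approx(r3, abs=1e-10)

    def test_null_distribution(self):
        """Independent x,y: |r| small and p roughly uniform over seeds."""
        ps, rs = [], []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            x, y = rng.normal(size=(2, 1000))
            z = rng.normal(size=1000)
            res = partial_correlation(x, y, pd.DataFrame({"z": z}))
            ps.append(res.p_raw)
            rs.append(res.r)
        assert max(abs(r) for r in rs) < 0.1
        ks = sps.kstest(ps, "uniform")
        assert ks.pvalue > 0.01

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            partial_correlation(np.ones(30), np.random.default_rng(0).normal(size=30))


class TestBonferroni:
    @pytest.mark.parametrize("p,m,expected", [
        (0.01, 5, 0.05),
        (0.3, 4, 1.0),
        (0.2, 1, 0.2),
    ])
    def test_examples(self, p, m, expected):
        assert bonferroni([p], m)[0] == pytest.approx(expected)

    def test_never_decreases_and_preserves_order(self):
        rng = np.random.default_rng(6)
        p = np.sort(rng.random(20))
        q = bonferroni(p)
        assert np.all(q >= p)
        assert np.all(np.diff(q) >= 0)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([1.2])
        with pytest.raises(ValueError, match="family size"):
            bonferroni([0.1, 0.2], family_size=1)


class TestSplitGroups:
    @staticmethod
    def records(**cols):
        base = {"diagnosis": ["MS"] * len(next(iter(cols.values())))}
        base.update(cols)
        return pd.DataFrame(base)

    def test_edss_boundary(self):
        rec = self.records(edss=[2.5, 3.0, 0.0, 7.5])
        labels, n_excl = split_groups(rec, "edss")
        assert list(labels) == ["low_edss", "high_edss", "low_edss", "high_edss"]
        assert n_excl == 0

    def test_sdmt_boundary(self):
        rec = self.records(sdmt=[39, 40, 55])
        labels, _ = split_groups(rec, "sdmt")
        assert list(labels) == ["low_sdmt", "high_sdmt", "high_sdmt"]

    def test_boundary_low_option(self):
        rec = self.records(edss=[3.0])
        labels, _ = split_groups(rec, "edss", boundary_high=False)
        assert list(labels) == ["low_edss"]

    def test_hc_never_excluded(self):
        rec = pd.DataFrame({"diagnosis": ["HC", "MS", "MS"],
                            "edss": [np.nan, np.nan, 4.0]})
        labels, n_excl = split_groups(rec, "edss")
        assert labels.iloc[0] == "HC"
        assert pd.isna(labels.iloc[1])
        assert n_excl == 1


class TestAnovaTukey:
    def test_hand_sums_of_squares(self):
        """F for {1,2,3},{2,3,4},{3,4,5} by explicit SS decomposition."""
        vals = np.array([1, 2, 3, 2, 3, 4, 3, 4, 5], dtype=float)
        labels = np.repeat(["a", "b", "c"], 3)
        # oracle: SSB = 3*((2-3)^2+(3-3)^2+(4-3)^2) = 6, df 2
        #         SSW = 2+2+2 = 6, df 6  ->  F = 3/1 = 3
        res = anova_tukey(vals, labels)
        assert res.f_stat == pytest.approx(3.0, abs=1e-12)
        assert res.p_value == pytest.approx(sps.f.sf(3.0, 2, 6), rel=1e-9)

    def test_identical_groups(self):
        res = anova_tukey(np.full(12, 5.0), np.repeat(["a", "b", "c"], 4))
        assert res.f_stat == 0.0
        assert np.all(res.tukey["p_adj"] == 1.0)
        assert len(res.tukey) == 3

    def test_two_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(0, 1, 30), rng.normal(0.5, 1, 25)
        res = anova_tukey(np.concatenate([a, b]),
                          ["a"] * 30 + ["b"] * 25)
        t, _ = sps.ttest_ind(a, b)
        assert res.f_stat == pytest.approx(t**2, rel=1e-10)

    def test_tukey_kramer_matches_studentized_range(self):
        """Adjusted p for unequal groups vs direct studentized-range oracle."""
        rng = np.random.default_rng(8)
        groups = [rng.normal(0, 1, 20), rng.normal(0.8, 1, 35),
                  rng.normal(-0.4, 1, 15)]
        vals = np.concatenate(groups)
        labels = np.repeat(["a", "b", "c"], [20, 35, 15])
        res = anova_tukey(vals, labels)
        k = 3
        df = len(vals) - k
        mse = sum(((g - g.mean()) ** 2).sum() for g in groups) / df
        sizes = {"a": 20, "b": 35, "c": 15}
        means = {"a": groups[0].mean(), "b": groups[1].mean(),
                 "c": groups[2].mean()}
        for _, row in res.tukey.iterrows():
            g1, g2 = row["group1"], row["group2"]
            se = np.sqrt(mse / 2 * (1 / sizes[g1] + 1 / sizes[g2]))
            q = abs(means[g2] - means[g1]) / se
            p_oracle = sps.studentized_range.sf(q, k, df)
            assert row["p_adj"] == pytest.approx(p_oracle, abs=1e-6)

    def test_planted_separation_flagged(self):
        """Tukey flags only the truly separated pairs at alpha=0.05."""
        n_flagged = np.zeros(3)
        for seed in range(10):
            rng = np.random.default_rng(seed)
            a = rng.normal(0.0, 1, 50)
            b = rng.normal(0.1, 1, 50)   # overlapping with a
            c = rng.normal(2.0, 1, 50)   # far from both
            res = anova_tukey(np.concatenate([a, b, c]),
                              np.repeat(["a", "b", "c"], 50))
            tab = res.tukey.set_index(["group1", "group2"])
            n_flagged += [tab.loc[("a", "b"), "reject"],
                          tab.loc[("a", "c"), "reject"],
                          tab.loc[("b", "c"), "reject"]]
        assert n_flagged[1] == 10 and n_flagged[2] == 10
        assert n_flagged[0] <= 2  # a-b separated only by chance

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="< 2 values"):
            anova_tukey([1.0, 2.0, 3.0], ["a", "a", "b"])


class TestCorrelationBattery:
    def test_misaligned_ids_rejected(self, planted_cohort):
        metrics, records = planted_cohort.metrics, planted_cohort.records
        shuffled = records.copy()
        shuffled.index = [f"x{i}" for i in range(len(shuffled))]
        with pytest.raises(ValueError, match="different subject ids"):
            run_correlation_battery(metrics, shuffled)

    def test_family_sizes(self, planted_cohort):
        results = run_correlation_battery(planted_cohort.harmonized_metrics,
                                          planted_cohort.harmonized_records)
        sizes = {r.family: r.family_size for r in results}
        assert sizes["inter_vs_intra"] == 8   # 4 pairs x {HC, MS}
        assert sizes["inter_measure_agreement"] == 2
        assert sizes["clinical_structure"] == 40  # 8 measures x 5 targets

    def test_planted_conservation_sign(self, planted_cohort):
        """Coupling -0.4 shows as negative commissural-vs-efficiency r."""
        results = run_correlation_battery(planted_cohort.harmonized_metrics,
                                          planted_cohort.harmonized_records)
        fam = {(r.x, r.y): r for r in results if r.family == "inter_vs_intra"}
        for group in ("HC", "MS"):
            r_eff = fam[(f"commissural_ratio [{group}]", "eff_mean")]
            r_spl = fam[(f"commissural_ratio [{group}]", "spl_mean")]
            assert r_eff.r < 0 and r_eff.p_corrected < 0.001
            assert r_spl.r > 0 and r_spl.p_corrected < 0.001
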