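"""Group summaries, ANOVA, Tukey HSD and the blot branch."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from iapflow import (
    ValidationError,
    blot_normalize_and_test,
    one_way_anova,
    percent_difference,
    summarize,
    tukey_hsd,
    two_way_anova_tukey,
)
from iapflow.synthetic import simulate_blots


def studentized_range_oracle(groups):
    """Adjusted Tukey p for every pair, straight from sums of squares and
    the studentized-range distribution."""
    arrays = [np.asarray(v, float) for v in groups.values()]
    names = list(groups)
    k = len(arrays)
    df = sum(a.size for a in arrays) - k
    mse = sum(((a - a.mean()) ** 2).sum() for a in arrays) / df
    out = {}
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(mse / 2.0 * (1.0 / arrays[i].size + 1.0 / arrays[j].size))
            q = abs(arrays[i].mean() - arrays[j].mean()) / se
            out[(names[i], names[j])] = sps.studentized_range.sf(q, k, df)
    return out


def random_2x2(rng, n=6, effects=(0.0, 0.0, 0.0)):
    a_eff, b_eff, ab_eff = effects
    rows = []
    for strain, sa in (("control", -0.5), ("mutant", 0.5)):
        for treatment, sb in (("vehicle", -0.5), ("inhibitor", 0.5)):
            mu = 10.0 + a_eff * sa + b_eff * sb + ab_eff * sa * sb
            for v in rng.normal(mu, 1.0, n):
                rows.append({"strain": strain, "treatment": treatment, "y": v})
    return pd.DataFrame(rows)


class TestSummarize:
    def test_constant_group(self):
        (s,) = summarize({"g": [1.0, 1.0, 1.0, 1.0]})
        assert s.mean == 1.0 and s.sem == 0.0 and s.n == 4

    def test_sem_uses_sample_sd_over_sqrt_n(self):
        (s,) = summarize({"g": [1.0, 2.0, 3.0, 4.0]})
        assert s.mean == pytest.approx(2.5)
        assert s.sem == pytest.approx(1.2909944 / 2.0, rel=1e-6)

    def test_identical_groups_identical_summaries(self):
        a, b = summarize({"x": [1.0, 2.0], "y": [1.0, 2.0]})
        assert (a.mean, a.sem, a.n) == (b.mean, b.sem, b.n)

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            summarize({"g": []})


class TestOneWayAnova:
    def test_textbook_sums_of_squares(self):
        # {1,2,3} vs {4,5,6}: SSB=13.5, SSW=4, df=(1,4) -> F=13.5
        res = one_way_anova({"a": [1, 2, 3], "b": [4, 5, 6]})
        eff = res.effect("group")
        assert eff.F == pytest.approx(13.5, rel=1e-12)
        assert (eff.df_num, eff.df_den) == (1, 4)
        assert eff.p == pytest.approx(sps.f.sf(13.5, 1, 4), rel=1e-12)

    def test_degenerate_zero_variance_reports_zero_p_with_warning(self):
        res = one_way_anova({"a": [1.0, 1.0], "b": [2.0, 2.0]})
        assert res.effect("group").p == 0.0
        assert any("degenerate" in w for w in res.warnings)

    def test_type_one_error_calibrated(self):
        """Null rejection rate at alpha=0.05 stays in [0.04, 0.06]."""
        rng = np.random.default_rng(2024)
        rejections = 0
        n_sim = 2000
        for _ in range(n_sim):
            groups = {g: rng.normal(0.0, 1.0, 8) for g in "abcd"}
            res = one_way_anova(groups, tukey=False)
            rejections += res.effect("group").p < 0.05
        assert 0.04 <= rejections / n_sim <= 0.06

    def test_scale_equivariance(self):
        rng = np.random.default_rng(1)
        groups = {g: rng.normal(5.0, 2.0, 6) for g in "abc"}
        base = one_way_anova(groups)
        scaled = one_way_anova({g: 7.3 * v for g, v in groups.items()})
        assert scaled.effect("group").F == pytest.approx(base.effect("group").F)
        assert scaled.effect("group").p == pytest.approx(base.effect("group").p)
        pd.testing.assert_series_equal(scaled.tukey.significant,
                                       base.tukey.significant)

    def test_decomposition_matches_manual_sums_of_squares(self):
        rng = np.random.default_rng(8)
        groups = {g: rng.normal(0, 1, rng.integers(4, 9)) for g in "abcd"}
        allv = np.concatenate(list(groups.values()))
        ss_total = ((allv - allv.mean()) ** 2).sum()
        ss_within = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
        ss_between = sum(v.size * (v.mean() - allv.mean()) ** 2
                         for v in groups.values())
        assert ss_total == pytest.approx(ss_between + ss_within, rel=1e-9)
        k, N = len(groups), allv.size
        f_manual = (ss_between / (k - 1)) / (ss_within / (N - k))
        res = one_way_anova(groups)
        assert res.effect("group").F == pytest.approx(f_manual, rel=1e-9)


class TestTukey:
    def test_matches_studentized_range_oracle(self):
        groups = {"a": [1.1, 2.0, 2.9], "b": [3.5, 4.4, 5.1], "c": [2.0, 2.2, 3.4]}
        table = tukey_hsd(groups)
        oracle = studentized_range_oracle(groups)
        for (g1, g2), p in oracle.items():
            row = table[(table.group1 == g1) & (table.group2 == g2)].iloc[0]
            assert row.p_adj == pytest.approx(p, abs=1e-6)

    def test_matches_independent_scipy_implementation(self):
        rng = np.random.default_rng(99)
        groups = {g: rng.normal(i, 1, 7) for i, g in enumerate("abcd")}
        table = tukey_hsd(groups)
        ref = sps.tukey_hsd(*groups.values())
        names = list(groups)
        for row in table.itertuples():
            i, j = names.index(row.group1), names.index(row.group2)
            assert row.p_adj == pytest.approx(ref.pvalue[i, j], abs=1e-6)
        ci = ref.confidence_interval(0.95)
        for row in table.itertuples():
            i, j = names.index(row.group1), names.index(row.group2)
            assert row.ci_lower == pytest.approx(ci.low[i, j], abs=1e-9)
            assert row.ci_upper == pytest.approx(ci.high[i, j], abs=1e-9)

    def test_adjusted_p_never_below_pairwise_t(self):
        rng = np.random.default_rng(17)
        groups = {g: rng.normal(0, 1, 6) for g in "abcd"}
        arrays = {g: np.asarray(v) for g, v in groups.items()}
        df = sum(a.size for a in arrays.values()) - len(arrays)
        mse = sum(((a - a.mean()) ** 2).sum() for a in arrays.values()) / df
        table = tukey_hsd(groups)
        for row in table.itertuples():
            a, b = arrays[row.group1], arrays[row.group2]
            se = np.sqrt(mse * (1 / a.size + 1 / b.size))
            t = abs(a.mean() - b.mean()) / se
            p_unadj = 2.0 * sps.t.sf(t, df)
            assert row.p_adj >= p_unadj - 1e-12

    def test_flags_monotone_in_alpha(self):
        rng = np.random.default_rng(23)
        groups = {g: rng.normal(i * 0.8, 1, 6) for i, g in enumerate("abc")}
        strict = tukey_hsd(groups, alpha=0.01)
        loose = tukey_hsd(groups, alpha=0.10)
        assert (strict.significant <= loose.significant).all()


class TestTwoWayAnova:
    def test_balanced_2x2_matches_manual_decomposition(self):
        rng = np.random.default_rng(5)
        df = random_2x2(rng, n=5, effects=(2.0, 1.0, 0.5))
        res = two_way_anova_tukey(df, "y")
        # manual balanced two-way sums of squares
        n = 5
        cells = df.groupby(["strain", "treatment"]).y
        cell_means = cells.mean()
        grand = df.y.mean()
        a_means = df.groupby("strain").y.mean()
        b_means = df.groupby("treatment").y.mean()
        ss_a = 2 * n * ((a_means - grand) ** 2).sum()
        ss_b = 2 * n * ((b_means - grand) ** 2).sum()
        ss_cells = n * ((cell_means - grand) ** 2).sum()
        ss_ab = ss_cells - ss_a - ss_b
        ss_err = ((df.y - df.groupby(["strain", "treatment"]).y.transform("mean")) ** 2).sum()
        dfe = 4 * n - 4
        assert res.effect("strain").F == pytest.approx(ss_a / (ss_err / dfe), rel=1e-9)
        assert res.effect("treatment").F == pytest.approx(ss_b / (ss_err / dfe), rel=1e-9)
        assert res.effect("strain:treatment").F == pytest.approx(
            ss_ab / (ss_err / dfe), rel=1e-9)

    def test_missing_cell_rejected(self):
        rng = np.random.default_rng(0)
        df = random_2x2(rng)
        df = df[~((df.strain == "mutant") & (df.treatment == "inhibitor"))]
        with pytest.raises(ValidationError, match="cell"):
            two_way_anova_tukey(df, "y")

    def test_unbalanced_cells_noted(self):
        rng = np.random.default_rng(0)
        df = random_2x2(rng, n=6)
        df = df.drop(df[(df.strain == "mutant") & (df.treatment == "vehicle")].index[:2])
        res = two_way_anova_tukey(df, "y")
        assert any("type-II" in w for w in res.warnings)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(2)
        df = random_2x2(rng, effects=(1.5, 0.0, 0.0))
        base = two_way_anova_tukey(df, "y")
        scaled = two_way_anova_tukey(df.assign(y=df.y * 3.7), "y")
        for name in ("strain", "treatment", "strain:treatment"):
            assert scaled.effect(name).F == pytest.approx(base.effect(name).F)
        pd.testing.assert_series_equal(scaled.tukey.significant,
                                       base.tukey.significant)

    def test_degenerate_zero_variance_cells(self):
        """Zero within-cell variance with distinct means yields the p -> 0
        limit in the Tukey table rather than NaN."""
        table = tukey_hsd({"a": [1.0, 1.0], "b": [2.0, 2.0], "c": [2.0, 2.0]})
        ab = table[(table.group1 == "a") & (table.group2 == "b")].iloc[0]
        bc = table[(table.group1 == "b") & (table.group2 == "c")].iloc[0]
        assert ab.p_adj == 0.0 and ab.significant
        assert bc.p_adj == 1.0 and not bc.significant


class TestPercentDifference:
    @pytest.mark.parametrize("ref,comp,expect", [
        (100.0, 132.0, 32.0),
        (100.0, 115.0, 15.0),
        (7.3, 7.3, 0.0),
    ])
    def test_examples(self, ref, comp, expect):
        assert percent_difference(ref, comp) == pytest.approx(expect)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValidationError):
            percent_difference(0.0, 5.0)


class TestBlotBranch:
    def test_identity_ratios_show_no_effect(self):
        blots = simulate_blots(0, noise_cv=0.0)
        results = blot_normalize_and_test(blots)
        for res in results.values():
            assert not res.tukey.significant.any()

    def test_noiseless_multiplier_halves_group_mean(self):
        effects = {("control", "inhibitor"): 0.5, ("mutant", "inhibitor"): 0.5}
        blots = simulate_blots(0, effects, noise_cv=0.0)
        results = blot_normalize_and_test(blots)
        for res in results.values():
            means = {s.group: s.mean for s in res.summaries}
            assert means["control:inhibitor"] == pytest.approx(0.5)
            assert means["control:vehicle"] == pytest.approx(1.0)

    def test_zero_total_rejected(self):
        blots = simulate_blots(0)
        blots.loc[0, "total"] = 0.0
        with pytest.raises(ValidationError):
            blot_normalize_and_test(blots)

    def test_strain_effect_power_at_configured_size(self):
        """A 0.6x strain multiplier on one marker, cv=0.1, n=3/group is
        detected in >=80% of 500 seeded replicates."""
        effects = {"pS6-S240/244": {("mutant", "vehicle"): 0.6,
                                    ("mutant", "inhibitor"): 0.6}}
        hits = 0
        n_sim = 500
        for rep in range(n_sim):
            blots = simulate_blots(50_000 + rep, effects, noise_cv=0.10)
            blots = blots[blots.marker == "pS6-S240/244"]
            res = blot_normalize_and_test(blots)["pS6-S240/244"]
            hits += res.effect("strain").p < 0.05
        assert hits / n_sim >= 0.80
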