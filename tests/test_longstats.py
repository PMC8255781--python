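"""Rank machinery: midranks, relative effects, WTS/ATS, Bonferroni."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from _rank_oracle import oracle_midranks, oracle_statistics
from conftest import fixture_datasets
from pharmaeeg.longstats import (LongitudinalDataset, anova_type_statistic,
                                 bonferroni, fit_design, midranks,
                                 posthoc_timepoints, relative_effects,
                                 significance_tier, wald_type_statistic)


def make_ld(df, factors):
    return LongitudinalDataset(df, unit="unit", factors=factors,
                               time="time", value="value")


class TestMidranks:
    def test_distinct(self):
        np.testing.assert_array_equal(midranks([3, 1, 2]), [3, 1, 2])

    def test_ties(self):
        np.testing.assert_array_equal(midranks([1, 1, 2, 2]),
                                      [1.5, 1.5, 3.5, 3.5])

    def test_full_tie(self):
        np.testing.assert_array_equal(midranks([7] * 5), [3] * 5)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            midranks([])

    @given(st.lists(st.integers(-5, 5), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_rank_sum_invariant(self, values):
        r = midranks(values)
        n = len(values)
        assert r.sum() == pytest.approx(n * (n + 1) / 2)
        assert oracle_midranks(values) == pytest.approx(list(r))


class TestRelativeEffects:
    def _two_group(self, a, b):
        rows = [{"unit": f"a{i}", "group": "A", "time": 0, "value": v}
                for i, v in enumerate(a)]
        rows += [{"unit": f"b{i}", "group": "B", "time": 0, "value": v}
                 for i, v in enumerate(b)]
        return make_ld(pd.DataFrame(rows), ("group",))

    def test_separated_groups(self):
        rte = relative_effects(self._two_group([1, 2], [3, 4]))
        assert rte.set_index("group").loc["A", "p_hat"] == pytest.approx(0.25)
        assert rte.set_index("group").loc["B", "p_hat"] == pytest.approx(0.75)

    def test_identical_groups_at_half(self):
        rte = relative_effects(self._two_group([1, 2], [1, 2]))
        np.testing.assert_allclose(rte["p_hat"], 0.5)

    def test_weighted_mean_is_half(self):
        for df, factors, _, _ in fixture_datasets():
            rte = relative_effects(make_ld(df, factors))
            mean = np.average(rte["p_hat"], weights=rte["n_obs"])
            assert mean == pytest.approx(0.5, abs=1e-12)


class TestOracleEquivalence:
    @pytest.mark.parametrize("idx", range(5))
    def test_wts_ats_match_bruteforce(self, idx):
        df, factors, groups, n_levels = fixture_datasets()[idx]
        ld = make_ld(df, factors)
        effects = (["group", "time", "group:time"] if len(n_levels) == 1
                   else ["A", "B", "A:B", "time", "A:time", "B:time", "A:B:time"])
        for effect in effects:
            ref = oracle_statistics(groups, effect, n_levels)
            wts = wald_type_statistic(ld, effect)
            ats = anova_type_statistic(ld, effect)
            assert wts.statistic == pytest.approx(ref["wts"], abs=1e-10)
            assert wts.df == ref["wts_df"]
            assert wts.p_raw == pytest.approx(ref["wts_p"], abs=1e-10)
            assert ats.statistic == pytest.approx(ref["ats"], abs=1e-10)
            assert ats.df == pytest.approx(ref["ats_df"], abs=1e-10)
            assert ats.p_raw == pytest.approx(ref["ats_p"], abs=1e-10)


class TestInvariances:
    def test_label_exchange_symmetry(self):
        df, factors, _, _ = fixture_datasets()[0]
        ld = make_ld(df, factors)
        swapped = df.copy()
        swapped["group"] = swapped["group"].map({"A": "B", "B": "A"})
        ld2 = make_ld(swapped, factors)
        for fn in (wald_type_statistic, anova_type_statistic):
            assert fn(ld, "group").statistic == pytest.approx(
                fn(ld2, "group").statistic, rel=1e-12)

    @pytest.mark.parametrize("transform", [np.exp, lambda x: x**3,
                                           lambda x: np.arctan(x) * 5])
    def test_monotone_transform_invariance(self, transform):
        df, factors, _, _ = fixture_datasets()[4]
        ld = make_ld(df, factors)
        df2 = df.assign(value=transform(df["value"].to_numpy()))
        ld2 = make_ld(df2, factors)
        for effect in ("group", "time", "group:time"):
            assert wald_type_statistic(ld, effect).statistic == pytest.approx(
                wald_type_statistic(ld2, effect).statistic, rel=1e-10)
            assert anova_type_statistic(ld, effect).statistic == pytest.approx(
                anova_type_statistic(ld2, effect).statistic, rel=1e-10)


class TestFitDesign:
    def test_f1_effect_set(self):
        df, factors, _, _ = fixture_datasets()[0]
        fits = fit_design(make_ld(df, factors))
        assert set(fits) == {"group", "time", "group:time"}
        for effect in fits:
            assert {"wts", "ats"} <= set(fits[effect])

    def test_f2_effect_set(self):
        df, factors, _, _ = fixture_datasets()[3]
        fits = fit_design(make_ld(df, factors))
        assert set(fits) == {"A", "B", "A:B", "time", "A:time", "B:time",
                             "A:B:time"}

    def test_single_time_level_reduces_to_group_test(self):
        df, factors, groups, n_levels = fixture_datasets()[0]
        one = df[df["time"] == 0]
        fits = fit_design(make_ld(one, factors))
        assert set(fits) == {"group"}
        direct = wald_type_statistic(make_ld(one, factors), "group")
        assert fits["group"]["wts"].statistic == pytest.approx(direct.statistic)


class TestMissingData:
    def _ld(self, drop_unit=None, drop_cell=None):
        df, factors, _, _ = fixture_datasets()[4]
        if drop_unit:
            df = df[df["unit"] != drop_unit]
        if drop_cell:
            unit, time = drop_cell
            df = df[~((df["unit"] == unit) & (df["time"] == time))]
        return make_ld(df, factors)

    def test_deleting_unit_changes_n(self):
        full = anova_type_statistic(self._ld(), "group")
        less = anova_type_statistic(self._ld(drop_unit="A_0"), "group")
        assert less.n_units == full.n_units - 1

    def test_single_missing_cell_handled_not_imputed(self):
        res = anova_type_statistic(self._ld(drop_cell=("A_0", 2)), "group")
        assert np.isfinite(res.statistic)
        assert res.n_units == 9  # unit retained with available cases

    def test_undersized_group_rejected(self):
        df, factors, _, _ = fixture_datasets()[0]
        df = df[(df["group"] != "B") | (df["unit"] == "B_0")]
        with pytest.raises(ValueError):
            wald_type_statistic(make_ld(df, factors), "group")


class TestBonferroni:
    def test_arithmetic_and_cap(self):
        assert bonferroni(0.01, 7) == pytest.approx(0.07)
        assert bonferroni(0.3, 7) == 1.0   # cap at 1
        assert bonferroni(0.0, 1000) == 0.0
        assert bonferroni(0.001, 24) == pytest.approx(0.024)

    def test_vector_order_preserved(self):
        p = np.array([0.001, 0.01, 0.2, 0.9])
        out = bonferroni(p, 5)
        assert np.all(np.diff(out) >= 0)
        assert np.all(out >= p)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            bonferroni(1.5, 2)
        with pytest.raises(ValueError):
            bonferroni(0.5, 0)

    @given(st.floats(0, 1), st.integers(1, 100))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_never_decreases_and_capped(self, p, m):
        out = bonferroni(p, m)
        assert p <= out <= 1.0


class TestPosthoc:
    def _long(self, shift=0.0, n_bins=4, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for g, n, delta in (("WT", 6, 0.0), ("KO", 6, shift)):
            for i in range(n):
                for t in range(n_bins):
                    rows.append({"unit": f"{g}{i}", "group": g, "time": t,
                                 "value": rng.lognormal(delta if t >= 2 else 0.0,
                                                        0.2)})
        return pd.DataFrame(rows)

    def test_family_size_and_correction(self):
        results = posthoc_timepoints(self._long(), family_size=24)
        for res in results:
            assert res.p_corrected == pytest.approx(min(1.0, 24 * res.p_raw))

    def test_injected_late_difference_found(self):
        results = posthoc_timepoints(self._long(shift=1.5))
        sig = [r for r in results if r.p_corrected < 0.05]
        assert sig, "large injected shift not detected in any bin"
        assert all("time=2" in r.factor or "time=3" in r.factor for r in sig)

    def test_small_bins_skipped_with_warning(self):
        df = self._long().query("~(unit == 'KO0' | unit == 'KO1' | unit == 'KO2' "
                                "| unit == 'KO3' | unit == 'KO4')")
        df = df[~((df["group"] == "KO") & (df["time"] == 0))]
        with pytest.warns(UserWarning):
            results = posthoc_timepoints(df)
        assert all("time=0" not in r.factor for r in results)


def test_significance_tiers():
    assert significance_tier(0.2) == 0
    assert significance_tier(0.01) == 1
    assert significance_tier(0.0005) == 2
    assert significance_tier(5e-6) == 3
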