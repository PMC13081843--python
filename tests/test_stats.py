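import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from placenta3d import stats
from placenta3d.errors import ConfigError, TableValidationError
from placenta3d.synthetic import generate_ct_table


class TestGroupCompare:
    def test_identical_groups_show_no_difference(self):
        g = {"a": [1, 2, 3, 4, 5], "b": [1, 2, 3, 4, 5]}
        rep = stats.group_compare(g, "mannwhitney_pairwise")
        pw = rep.pairwise[0]
        assert pw.p_raw > 0.9
        assert pw.p_adjusted >= pw.p_raw

    def test_bonferroni_formula(self):
        assert stats.bonferroni(0.02, 3) == pytest.approx(0.06)
        assert stats.bonferroni(0.5, 3) == 1.0
        assert stats.bonferroni(0.04, 1) == pytest.approx(0.04)

    def test_adjusted_p_never_below_raw(self):
        rng = np.random.default_rng(0)
        g = {k: rng.normal(size=8) for k in "abc"}
        for method in ("mannwhitney_pairwise", "kruskal_dunn", "ks_dunn"):
            rep = stats.group_compare(g, method)
            for pw in rep.pairwise:
                assert pw.p_raw <= pw.p_adjusted <= 1.0

    def test_obvious_shift_detected_by_every_method(self):
        rng = np.random.default_rng(1)
        g = {"lo": rng.normal(0, 1, 12), "hi": rng.normal(6, 1, 12)}
        for method in ("anova_tukey", "ttest", "mannwhitney_pairwise", "kruskal_dunn"):
            rep = stats.group_compare(g, method)
            assert rep.pairwise[0].p_adjusted < 0.01

    def test_single_group_errors(self):
        with pytest.raises(ConfigError, match="2 groups"):
            stats.group_compare({"a": [1, 2, 3]})

    def test_zero_variance_directs_to_rank_methods(self):
        g = {"a": [1.0, 1.0, 1.0], "b": [2.0, 3.0, 4.0]}
        with pytest.raises(ConfigError, match="rank-based"):
            stats.group_compare(g, "ttest")
        stats.group_compare(g, "mannwhitney_pairwise")  # must not raise

    def test_kruskal_dunn_familywise_error_controlled(self):
        # Monte-Carlo type-I oracle: three null groups, alpha = 0.05
        rng = np.random.default_rng(42)
        false_positives = 0
        n_sim = 200
        for _ in range(n_sim):
            g = {k: rng.normal(size=10) for k in "abc"}
            rep = stats.group_compare(g, "kruskal_dunn", "bonferroni")
            if any(pw.p_adjusted < 0.05 for pw in rep.pairwise):
                false_positives += 1
        assert false_positives / n_sim <= 0.08


class TestFisher:
    def test_diagonal_table_matches_enumeration(self):
        # 2 / C(10,5) = 2/252 for the two extreme tables
        res = stats.fisher_exact([[5, 0], [0, 5]])
        assert res.p_raw == pytest.approx(2 / math.comb(10, 5), rel=1e-9)

    def test_balanced_table_gives_p_one(self):
        assert stats.fisher_exact([[3, 3], [3, 3]]).p_raw == pytest.approx(1.0)

    def test_correction_m_one_leaves_p_unchanged(self):
        res = stats.fisher_exact([[8, 2], [3, 9]], correction_m=1)
        assert res.p_adjusted == res.p_raw

    def test_larger_than_2x2_rejected(self):
        with pytest.raises(TableValidationError, match="2x2"):
            stats.fisher_exact([[1, 2, 3], [4, 5, 6], [7, 8, 9]])

    def test_negative_counts_rejected(self):
        with pytest.raises(TableValidationError):
            stats.fisher_exact([[1, -2], [3, 4]])

    def test_equals_full_enumeration_for_small_tables(self):
        # every 2x2 table with total <= 25 (the full <= 40 sweep runs in the
        # acceptance suite)
        for n in range(1, 26):
            for a in range(n + 1):
                for b in range(n - a + 1):
                    for c in range(n - a - b + 1):
                        d = n - a - b - c
                        t = [[a, b], [c, d]]
                        if (a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0):
                            continue
                        p_impl = stats.fisher_exact(t).p_raw
                        p_oracle = stats.fisher_exact_enumeration(t)
                        assert p_impl == pytest.approx(p_oracle, abs=1e-10), t


class TestOddsRatio:
    def test_balanced_table_or_one_ci_contains_one(self):
        res = stats.odds_ratio_ci([[10, 10], [10, 10]])
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.ci_low < 1.0 < res.ci_high

    def test_hand_computed_wald_interval(self):
        # OR = (20*20)/(5*5) = 16; CI = exp(ln 16 +- 1.96 sqrt(1/20+1/5+1/5+1/20))
        res = stats.odds_ratio_ci([[20, 5], [5, 20]])
        se = math.sqrt(1 / 20 + 1 / 5 + 1 / 5 + 1 / 20)
        from scipy.stats import norm

        z = norm.ppf(0.975)
        assert res.odds_ratio == pytest.approx(16.0, abs=1e-9)
        assert res.ci_low == pytest.approx(16 * math.exp(-z * se), rel=1e-6)
        assert res.ci_high == pytest.approx(16 * math.exp(z * se), rel=1e-6)
        assert not res.continuity_corrected

    def test_zero_cells_use_haldane_anscombe(self):
        res = stats.odds_ratio_ci([[1, 0], [0, 1]])
        assert res.continuity_corrected
        assert res.odds_ratio == pytest.approx((1.5 * 1.5) / (0.5 * 0.5))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.integers(1, 50), min_size=4, max_size=4))
    def test_row_and_column_swap_invariances(self, cells):
        a, b, c, d = cells
        base = stats.odds_ratio_ci([[a, b], [c, d]]).odds_ratio
        both = stats.odds_ratio_ci([[d, c], [b, a]]).odds_ratio
        rows = stats.odds_ratio_ci([[c, d], [a, b]]).odds_ratio
        assert both == pytest.approx(base, rel=1e-12)
        assert rows == pytest.approx(1.0 / base, rel=1e-12)


class TestDeltaDeltaCt:
    def _table(self):
        rows = [
            ("r1", "control", 25.0, 20.0),
            ("r2", "control", 25.4, 20.2),
            ("r3", "control", 24.8, 20.0),
            ("k1", "ko", 26.6, 20.1),
            ("k2", "ko", 26.0, 19.9),
            ("k3", "ko", 27.0, 20.3),
        ]
        return stats.CtTable(
            pd.DataFrame(rows, columns=["sample_id", "group", "ct_target", "ct_housekeeping"]),
            reference_group="control",
        )

    def test_matches_hand_computation(self):
        # spreadsheet-style oracle computed inline with plain arithmetic
        t = self._table()
        out = stats.delta_delta_ct(t).set_index("sample_id")
        dcts = {r[0]: r[2] - r[3] for r in t.data.itertuples(index=False)}
        ref_mean = (dcts["r1"] + dcts["r2"] + dcts["r3"]) / 3
        for sid, dct in dcts.items():
            assert out.loc[sid, "fold_change"] == pytest.approx(
                2 ** (-(dct - ref_mean)), abs=1e-9
            )

    def test_one_cycle_above_reference_halves_expression(self):
        t = generate_ct_table(3, {"ko": 1.0}, noise_sd=0.0, seed=0)
        out = stats.delta_delta_ct(t)
        assert np.allclose(out.loc[out["group"] == "ko", "fold_change"], 0.5)
        assert np.allclose(out.loc[out["group"] == "control", "fold_change"], 1.0)

    def test_reference_group_geometric_mean_fold_is_one(self):
        out = stats.delta_delta_ct(self._table())
        ref = out.loc[out["group"] == "control", "fold_change"]
        assert np.exp(np.log(ref).mean()) == pytest.approx(1.0, abs=1e-9)

    def test_missing_reference_group_errors(self):
        df = self._table().data
        with pytest.raises(TableValidationError, match="reference"):
            stats.CtTable(df, reference_group="absent")

    def test_nonfinite_ct_errors(self):
        df = self._table().data.copy()
        df.loc[0, "ct_housekeeping"] = np.nan
        with pytest.raises(TableValidationError):
            stats.CtTable(df, reference_group="control")
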