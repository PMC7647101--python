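import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from pepdau import (BackgroundConfig, background_from_windows,
                    build_background, fisher_dau, fisher_two_sided,
                    format_aligned, null_peptides, position_frequencies,
                    synth_proteome, ztest_dau)
from pepdau import test_dau as run_test_dau
from pepdau.dau import DAUError, DAUResult, FrequencyMatrix, odds_ratio

AA = "ACDEFGHIKLMNPQRSTVWY"


def exact_fisher_oracle(a, b, c, d):
    """Independent two-sided Fisher oracle: exhaustive hypergeometric
    enumeration in exact rational arithmetic."""
    r1, r2, k = a + b, c + d, a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or k == 0 or k == n:
        return 1.0
    weights = {
        x: math.comb(r1, x) * math.comb(r2, k - x)
        for x in range(max(0, k - r2), min(r1, k) + 1)
    }
    obs = weights[a]
    return float(
        Fraction(sum(w for w in weights.values() if w <= obs),
                 math.comb(n, k))
    )


class TestPositionFrequencies:
    def test_direct_counts(self):
        pset = format_aligned(["AK", "AD"], 0)
        fm = position_frequencies(pset, "identity")
        assert fm.values[0, AA.index("A")] == 1.0
        assert fm.values[1, AA.index("K")] == 0.5
        assert fm.values[1, AA.index("D")] == 0.5

    def test_padding_excluded_from_denominator(self):
        pset = format_aligned(["XA", "AA"], 1)
        fm = position_frequencies(pset, "identity")
        assert fm.totals[0] == 1
        assert fm.values[0, AA.index("A")] == 1.0

    def test_collapsed_counting(self):
        pset = format_aligned(["DK"], 0)
        fm = position_frequencies(pset, "charge3")
        assert fm.values[0, fm.symbols.index("-")] == 1.0
        assert fm.values[1, fm.symbols.index("+")] == 1.0

    def test_all_padding_column_is_nan(self):
        pset = format_aligned(["XAK", "XAD"], 1)
        fm = position_frequencies(pset, "identity")
        assert fm.totals[0] == 0 and np.isnan(fm.values[0]).all()


def _z_background(mean, se, L, symbols=None):
    """Hand-built Z-mode model for arithmetic-level checks."""
    from pepdau.background import BackgroundModel

    symbols = symbols or list(AA)
    S = len(symbols)
    config = BackgroundConfig(upstream=0, downstream=L - 1, T=2, N=100)
    return BackgroundModel(
        config, "identity", symbols,
        mean_freq=np.full((L, S), mean), se=np.full((L, S), se),
    )


class TestZTest:
    def test_z_score_arithmetic(self):
        fm = FrequencyMatrix(list(AA), np.full((1, 20), 30), np.array([100]))
        # observed p = 0.3 everywhere; background mean 0.1, se 0.05 -> Z = 4
        res = ztest_dau(fm, _z_background(0.1, 0.05, 1))
        assert np.allclose(res.statistic, 4.0)
        assert np.allclose(res.diff, 0.2)

    def test_null_case_gives_z_zero_p_one(self):
        fm = FrequencyMatrix(list(AA), np.full((1, 20), 10), np.array([200]))
        res = ztest_dau(fm, _z_background(0.05, 0.02, 1))
        assert np.allclose(res.statistic, 0.0)
        assert np.allclose(res.p_value, 1.0)
        assert not res.significant.any()

    def test_critical_value_1959964_gives_p_005(self):
        fm = FrequencyMatrix(list(AA),
                             np.full((1, 20), 100), np.array([1000]))
        # p = 0.1; choose background so Z = (0.1 - 0.05)/se = 1.959964
        se = 0.05 / 1.959964
        res = ztest_dau(fm, _z_background(0.05, se, 1))
        assert np.all(np.abs(res.p_value - 0.05) < 1e-4)

    def test_zero_se_nonnull_is_degenerate_infinite_z(self):
        fm = FrequencyMatrix(list(AA), np.full((1, 20), 50), np.array([100]))
        res = ztest_dau(fm, _z_background(0.0, 0.0, 1))
        assert np.isposinf(res.statistic).all()
        assert (res.p_value == 0).all()
        assert res.degenerate.all()

    def test_alphabet_mismatch_raises(self):
        fm = FrequencyMatrix(["+", "0", "-"], np.zeros((1, 3), dtype=int),
                             np.array([0]))
        with pytest.raises(DAUError, match="alphabet mismatch"):
            ztest_dau(fm, _z_background(0.1, 0.05, 1))

    def test_requires_z_mode_background(self, small_proteome):
        config = BackgroundConfig(upstream=0, downstream=0,
                                  test_mode="fisher", max_windows=100)
        bg = build_background(small_proteome, config, "identity")
        fm = FrequencyMatrix(list(AA), np.zeros((1, 20), dtype=int),
                             np.array([0]))
        with pytest.raises(DAUError, match="Z-mode"):
            ztest_dau(fm, bg)


class TestFisherTwoSided:
    @pytest.mark.parametrize(
        "table, expected",
        [
            ((10, 0, 0, 10), 2 / 184756),  # enumeration over fixed margins
            ((5, 5, 5, 5), 1.0),
            ((0, 0, 5, 5), 1.0),  # zero margin convention
        ],
    )
    def test_reference_tables(self, table, expected):
        assert fisher_two_sided(*table) == pytest.approx(expected,
                                                         abs=1e-15)

    def test_asymmetric_table_matches_exact_oracle(self):
        assert abs(fisher_two_sided(8, 2, 2, 8)
                   - exact_fisher_oracle(8, 2, 2, 8)) < 1e-12

    @given(st.integers(0, 12), st.integers(0, 12),
           st.integers(0, 12), st.integers(0, 12))
    def test_matches_exact_oracle_on_small_tables(self, a, b, c, d):
        assert abs(fisher_two_sided(a, b, c, d)
                   - exact_fisher_oracle(a, b, c, d)) < 1e-12

    @given(st.integers(0, 40), st.integers(0, 40),
           st.integers(0, 40), st.integers(0, 40))
    def test_agrees_with_scipy_convention(self, a, b, c, d):
        ours = fisher_two_sided(a, b, c, d)
        theirs = stats.fisher_exact([[a, b], [c, d]])[1]
        assert ours == pytest.approx(theirs, abs=1e-10)

    def test_large_table_log_space_path(self):
        # forces the log-space branch (total > exact-arithmetic limit)
        a, b, c, d = 40, 360, 2000, 48000
        ours = fisher_two_sided(a, b, c, d)
        theirs = stats.fisher_exact([[a, b], [c, d]])[1]
        assert ours == pytest.approx(theirs, rel=1e-9)

    def test_p_nonincreasing_away_from_mode_within_each_tail(self):
        """Within one tail, moving the table away from the distribution mode
        (larger |ad - bc|) never increases the two-sided p-value."""
        rng = np.random.default_rng(0)
        for _ in range(50):
            r1, r2 = rng.integers(2, 25, 2)
            k = int(rng.integers(1, r1 + r2))
            lo, hi = max(0, k - r2), min(r1, k)
            ps = [fisher_two_sided(a, r1 - a, k - a, r2 - k + a)
                  for a in range(lo, hi + 1)]
            mode = int(np.argmax([
                math.comb(r1, a) * math.comb(r2, k - a)
                for a in range(lo, hi + 1)
            ]))
            left, right = ps[: mode + 1], ps[mode:]
            assert all(x <= y + 1e-12 for x, y in zip(left, left[1:]))
            assert all(x >= y - 1e-12 for x, y in zip(right, right[1:]))

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            fisher_two_sided(-1, 2, 3, 4)


class TestOddsRatio:
    def test_finite(self):
        assert odds_ratio(8, 2, 2, 8) == 16.0

    def test_infinite_and_undefined(self):
        assert math.isinf(odds_ratio(5, 0, 2, 8))
        assert math.isnan(odds_ratio(0, 5, 0, 5))


class TestFisherDau:
    def test_cellwise_tables_match_direct_computation(self):
        pset = format_aligned(["DK", "DA", "KA", "DD"], 0)
        bg = background_from_windows(["AK", "AD", "KD", "AA", "DK"],
                                     "identity", anchor_column=0)
        fm = position_frequencies(pset, "identity")
        res = fisher_dau(fm, bg)
        a = int(fm.counts[0, AA.index("D")])          # 3
        c = int(bg.counts[0, AA.index("D")])          # 1
        expected = fisher_two_sided(a, 4 - a, c, 5 - c)
        assert res.p_value[0, AA.index("D")] == expected
        assert res.diff[0, AA.index("D")] == pytest.approx(3 / 4 - 1 / 5)

    def test_result_shape_with_grouping(self, small_proteome):
        config = BackgroundConfig(upstream=2, downstream=2,
                                  test_mode="fisher", max_windows=2000)
        bg = build_background(small_proteome, config, "charge3")
        pset = null_peptides(small_proteome, 50, 5, seed=1)
        res = run_test_dau(pset, bg, "charge3")
        assert res.p_value.shape == (5, 3)

    def test_scheme_mismatch_raises(self, small_proteome):
        config = BackgroundConfig(upstream=2, downstream=2,
                                  test_mode="fisher", max_windows=2000)
        bg = build_background(small_proteome, config, "charge3")
        pset = null_peptides(small_proteome, 20, 5, seed=2)
        with pytest.raises(DAUError, match="scheme mismatch"):
            run_test_dau(pset, bg, "identity")


class TestTestDau:
    def test_z_mode_identity_shape(self, small_proteome):
        config = BackgroundConfig(upstream=3, downstream=3, T=20, N=50,
                                  rng_seed=3)
        bg = build_background(small_proteome, config, "identity")
        pset = null_peptides(small_proteome, 50, 7, seed=3)
        res = run_test_dau(pset, bg, "identity")
        assert res.p_value.shape == (7, 20)
        assert res.metadata["test_mode"] == "ztest"
        assert res.metadata["n_input"] == 50

    def test_planted_symbol_most_significant_in_column(self, small_proteome):
        from pepdau import MotifSpec, plant_motif_peptides

        spec = MotifSpec(L=9, anchor_column=4, effects=[(4, "D", 0.7)])
        pset, _ = plant_motif_peptides(spec, 400, seed=5)
        config = BackgroundConfig(upstream=4, downstream=4, T=100, N=400,
                                  rng_seed=5)
        bg = build_background(small_proteome, config, "identity")
        res = run_test_dau(pset, bg, "identity")
        j = AA.index("D")
        assert res.significant[4, j]
        assert np.nanargmax(np.abs(res.statistic[4])) == j

    def test_na_cells_kept_in_result_shape(self, small_proteome):
        pset = format_aligned(["XAK", "XAD"], 1)
        config = BackgroundConfig(upstream=1, downstream=1, T=10, N=30,
                                  rng_seed=4)
        bg = build_background(small_proteome, config, "identity")
        res = run_test_dau(pset, bg, "identity")
        assert res.na[0].all()
        assert not res.significant[0].any()
        assert res.p_value.shape == (3, 20)

    def test_bh_adjustment_never_creates_significance(self, small_proteome):
        pset = null_peptides(small_proteome, 100, 7, seed=6)
        config = BackgroundConfig(upstream=3, downstream=3, T=20, N=100,
                                  rng_seed=6)
        bg = build_background(small_proteome, config, "identity")
        raw = run_test_dau(pset, bg, "identity")
        adj = run_test_dau(pset, bg, "identity", adjust="bh")
        assert (adj.significant <= raw.significant).all()
        np.testing.assert_array_equal(adj.p_value, raw.p_value)  # raw kept


class TestResultExport:
    @pytest.fixture()
    def result(self, small_proteome) -> DAUResult:
        pset = null_peptides(small_proteome, 60, 5, seed=8)
        config = BackgroundConfig(upstream=2, downstream=2, T=15, N=60,
                                  rng_seed=8)
        bg = build_background(small_proteome, config, "identity")
        return run_test_dau(pset, bg, "identity")

    def test_tsv_has_one_row_per_cell(self, result, tmp_path):
        import pandas as pd

        path = tmp_path / "res.tsv"
        result.to_tsv(path)
        df = pd.read_csv(path, sep="\t")
        assert len(df) == 5 * 20
        assert list(df.columns) == ["position", "symbol", "diff",
                                    "statistic", "p_value", "significant",
                                    "na"]

    def test_json_round_trip(self, result, tmp_path):
        path = tmp_path / "res.json"
        result.to_json(path)
        back = DAUResult.from_json(path)
        np.testing.assert_allclose(back.p_value, result.p_value, atol=1e-9)
        np.testing.assert_array_equal(back.significant, result.significant)
        assert back.symbols == result.symbols

    def test_positions_centred_on_anchor(self, result):
        assert result.positions() == [-2, -1, 0, 1, 2]
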