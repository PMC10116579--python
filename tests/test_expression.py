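"""Spatial expression summaries, ECDFs, and the two significance tests."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from orcensus.expression import (
    Ecdf,
    LabeledCell,
    LamellaMeasurement,
    ecdf,
    ks_bruteforce,
    ks_two_sample,
    normalized_position,
    summarize_expression,
    summary_table,
    t_test_two_sample,
)


def _cell(dist, length, lam="l1", kind="primary", rid="r1"):
    return LabeledCell("s1", lam, kind, dist, length, rid)


class TestNormalizedPosition:
    @pytest.mark.parametrize("dist,length,expected", [(0, 800, 0.0), (800, 800, 1.0), (300, 800, 0.375)])
    def test_examples(self, dist, length, expected):
        assert normalized_position(_cell(dist, length)) == pytest.approx(expected)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.floats(1, 1e4), st.floats(0, 1), st.floats(0, 1))
    def test_in_unit_interval_and_monotone(self, length, f1, f2):
        p1 = normalized_position(_cell(f1 * length, length))
        p2 = normalized_position(_cell(f2 * length, length))
        assert 0 <= p1 <= 1
        if f1 < f2:
            assert p1 <= p2

    def test_zero_length_errors(self):
        cell = _cell(0, 1)
        object.__setattr__(cell, "parent_lamella_length", 0.0)
        with pytest.raises(ValueError, match="zero-length"):
            normalized_position(cell)


class TestSummaries:
    def test_density_on_single_lamella(self):
        cells = [_cell(i * 10.0, 5000.0) for i in range(10)]
        s = summarize_expression(cells, [LamellaMeasurement("l1", 5.0)])
        assert s.density_mean == pytest.approx(2.0)
        assert s.density_sem == 0.0
        assert s.total_length_mm == 5.0

    def test_primary_secondary_percentages(self):
        cells = [_cell(1, 100, kind="primary") for _ in range(8)] + [
            _cell(1, 100, kind="secondary") for _ in range(2)
        ]
        s = summarize_expression(cells, [LamellaMeasurement("l1", 1.0)])
        assert (s.pct_primary, s.pct_secondary) == (80.0, 20.0)
        assert s.pct_primary + s.pct_secondary == pytest.approx(100.0, abs=1e-9)

    def test_density_invariant_under_lamella_split(self):
        """Splitting a lamella's cells over two lamellae of equal length
        and density leaves the mean density unchanged."""
        one = summarize_expression(
            [_cell(1, 5000) for _ in range(10)], [LamellaMeasurement("l1", 5.0)]
        )
        two = summarize_expression(
            [_cell(1, 2500, lam="a") for _ in range(5)]
            + [_cell(1, 2500, lam="b") for _ in range(5)],
            [LamellaMeasurement("a", 2.5), LamellaMeasurement("b", 2.5)],
        )
        assert two.density_mean == pytest.approx(one.density_mean)

    def test_summary_table_row_schema(self):
        cells = [_cell(1, 100, rid="ora2"), _cell(2, 100, rid="v2r1", kind="secondary")]
        df = summary_table(cells, [LamellaMeasurement("l1", 1.0)])
        assert list(df.columns) == [
            "receptor_id", "density_mean", "density_sem", "n_cells",
            "pct_primary", "pct_secondary", "total_length_mm",
        ]
        assert list(df.receptor_id) == ["ora2", "v2r1"]

    def test_errors(self):
        with pytest.raises(ValueError, match="empty lamella"):
            summarize_expression([], [])
        with pytest.raises(ValueError, match="unknown lamella"):
            summarize_expression([_cell(1, 100, lam="nope")], [LamellaMeasurement("l1", 1.0)])


def _welch_oracle(x, y):
    """Closed-form Welch t and Welch-Satterthwaite df."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    v1, v2 = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
    t = (x.mean() - y.mean()) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (len(x) - 1) + v2**2 / (len(y) - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return t, p


class TestTTest:
    def test_identical_samples(self):
        r = t_test_two_sample([1, 2, 3], [1, 2, 3])
        assert (r.statistic, r.p_value) == (0.0, 1.0)

    @pytest.mark.parametrize(
        "x,y",
        [
            ((1, 2, 3), (2, 3, 4)),
            ((0.1, 0.5, 0.9, 1.3), (2.0, 2.2)),
            (tuple(np.linspace(0, 1, 10)), tuple(np.linspace(0.3, 2, 7))),
        ],
    )
    def test_matches_closed_form_welch(self, x, y):
        r = t_test_two_sample(x, y)
        t, p = _welch_oracle(x, y)
        assert r.statistic == pytest.approx(t, abs=1e-9)
        assert r.p_value == pytest.approx(p, abs=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_large_shift_is_significant(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, 20)
        y = rng.normal(10, 1, 20)
        assert t_test_two_sample(x, y).p_value < 1e-6

    def test_degenerate_constant_samples(self):
        r = t_test_two_sample([2, 2, 2], [2, 2, 2])
        assert r.p_value == 1.0
        r = t_test_two_sample([2, 2, 2], [3, 3, 3])
        assert r.p_value == 0.0


class TestEcdf:
    def test_single_value(self):
        e = ecdf([0.5])
        assert e(0.5) == 1.0 and e(0.49) == 0.0

    def test_tie_accumulation(self):
        e = ecdf([1, 1, 2])
        assert e(1) == pytest.approx(2 / 3)
        assert e(2) == 1.0
        assert e(0) == 0.0

    def test_empty_errors(self):
        with pytest.raises(ValueError, match="empty"):
            ecdf([])

    @pytest.mark.parametrize("seed", range(20))
    def test_dkw_bound_uniform(self, seed):
        """sup|F_n(x) - x| < 0.07 for n=1000 uniforms (DKW-scale check)."""
        rng = np.random.default_rng(seed)
        u = rng.uniform(size=1000)
        e = ecdf(u)
        grid = np.linspace(0, 1, 2001)
        assert np.max(np.abs(e(grid) - grid)) < 0.07


class TestKsTwoSample:
    def test_identical_samples(self):
        r = ks_two_sample([1, 2, 3], [1, 2, 3])
        assert (r.statistic, r.p_value) == (0.0, 1.0)

    def test_separated_2x2_exact_third(self):
        """Fully separated (2,2) samples: D=1, exact p = 1/3 (2 of the 6
        rank arrangements reach D=1)."""
        r = ks_two_sample([0.1, 0.2], [0.8, 0.9])
        assert r.statistic == 1.0
        assert r.p_value == pytest.approx(1 / 3, abs=1e-12)

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_bruteforce_enumeration(self, seed):
        """Exact p equals literal enumeration of all rank arrangements,
        including tied data."""
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 5, size=int(rng.integers(2, 6))).astype(float)
        y = rng.integers(0, 5, size=int(rng.integers(2, 6))).astype(float)
        mine = ks_two_sample(x, y)
        brute = ks_bruteforce(x, y)
        assert mine.statistic == pytest.approx(brute.statistic)
        assert mine.p_value == pytest.approx(brute.p_value, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scipy_exact_continuous(self, seed):
        rng = np.random.default_rng(100 + seed)
        x, y = rng.normal(size=30), rng.normal(0.4, 1, size=40)
        mine = ks_two_sample(x, y)
        ref = stats.ks_2samp(x, y, method="exact")
        assert mine.statistic == pytest.approx(ref.statistic, abs=1e-12)
        assert mine.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_power_monotone_in_effect_size(self):
        rng = np.random.default_rng(0)
        rates = []
        for shift in (0.1, 0.4, 0.8):
            rej = sum(
                ks_two_sample(rng.normal(size=40), rng.normal(shift, 1, 40)).p_value < 0.05
                for _ in range(200)
            )
            rates.append(rej / 200)
        assert rates[0] < rates[1] < rates[2]
        assert rates[2] > 0.7

    def test_beta_contrast_detected(self):
        """Beta(2,5) vs Beta(5,2) radial profiles at n=200 are separated at
        p < 0.001 (the apical-vs-uniform contrast of the study)."""
        rng = np.random.default_rng(1)
        x = rng.beta(2, 5, 200)
        y = rng.beta(5, 2, 200)
        assert ks_two_sample(x, y).p_value < 1e-3

    def test_null_calibration_never_anticonservative(self):
        """P(p < alpha) <= alpha under the null (exact test property)."""
        rng = np.random.default_rng(3)
        for alpha in (0.05, 0.1):
            rej = sum(
                ks_two_sample(rng.uniform(size=30), rng.uniform(size=30)).p_value < alpha
                for _ in range(400)
            )
            assert rej / 400 <= alpha + 2.5 * np.sqrt(alpha * (1 - alpha) / 400)
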