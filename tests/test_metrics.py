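"""Evaluation metrics against hand values and brute-force oracles."""

import math
import statistics

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vegniche.metrics import (
    CoverPair,
    PairedSeries,
    UndefinedMetricError,
    annual_median_pairs,
    czekanowski,
    evaluate,
    nae,
    nrmse,
    one_to_one,
)

# ---------------------------------------------------------------------------
# brute-force oracles: deliberately elementary, no numpy vector tricks
# ---------------------------------------------------------------------------


def oracle_nae(P, O):
    p_bar = sum(P) / len(P)
    o_bar = sum(O) / len(O)
    return (p_bar - o_bar) / o_bar


def oracle_nrmse(P, O):
    o_bar = sum(O) / len(O)
    sq = sum((p - o) ** 2 for p, o in zip(P, O))
    return math.sqrt(sq / len(P)) / o_bar


def oracle_one_to_one(P, O):
    sxy = sum(p * o for p, o in zip(P, O))
    sxx = sum(o * o for o in O)
    slope = sxy / sxx
    resid = sum((p - slope * o) ** 2 for p, o in zip(P, O))
    se = math.sqrt(resid / (len(P) - 1) / sxx)
    corr = statistics.correlation(P, O)
    return slope, se, corr


def oracle_czekanowski(P, O):
    num = sum(abs(p - o) for p, o in zip(P, O))
    den = sum(p + o for p, o in zip(P, O))
    return 1.0 - num / den


def pairs(P, O):
    return PairedSeries.from_arrays(P, O)


class TestNAE:
    def test_unbiased_is_zero(self):
        assert nae(pairs([1.0, 2.0], [2.0, 1.0])) == pytest.approx(0.0)

    @pytest.mark.parametrize(
        "P, O, expected",
        [([0.9], [1.0], -0.1), ([1.038], [1.0], 0.038)],
    )
    def test_hand_values(self, P, O, expected):
        assert nae(pairs(P, O)) == pytest.approx(expected)

    def test_zero_observed_mean_undefined(self):
        with pytest.raises(UndefinedMetricError):
            nae(pairs([1.0], [0.0]))


class TestNRMSE:
    def test_perfect_fit(self):
        assert nrmse(pairs([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])) == 0.0

    @pytest.mark.parametrize(
        "P, O, expected",
        [([0.0, 2.0], [1.0, 1.0], 1.0), ([1.0], [2.0], 0.5)],
    )
    def test_hand_values(self, P, O, expected):
        assert nrmse(pairs(P, O)) == pytest.approx(expected)


class TestOneToOne:
    def test_identity_line(self):
        slope, se, corr = one_to_one(pairs([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]))
        assert slope == pytest.approx(1.0)
        assert se == pytest.approx(0.0, abs=1e-12)
        assert corr == pytest.approx(1.0)

    def test_proportional_data_recovers_factor(self):
        O = [1.0, 2.0, 5.0]
        slope, se, corr = one_to_one(pairs([0.7 * o for o in O], O))
        assert slope == pytest.approx(0.7)
        assert corr == pytest.approx(1.0)

    @given(c=st.floats(0.01, 10), n=st.integers(2, 30))
    @settings(max_examples=100, deadline=None)
    def test_slope_exact_on_any_proportional_data(self, c, n):
        rng = np.random.default_rng(n)
        O = rng.uniform(0.1, 5.0, size=n)
        slope, _, _ = one_to_one(PairedSeries.from_arrays(c * O, O))
        assert slope == pytest.approx(c, rel=1e-12)

    def test_anticorrelated_toy_set(self):
        slope, _, corr = one_to_one(pairs([3.0, 2.0, 1.0], [1.0, 2.0, 3.0]))
        assert corr == pytest.approx(-1.0)
        assert slope == pytest.approx(10.0 / 14.0)

    def test_degenerate_observed_rejected(self):
        with pytest.raises(UndefinedMetricError):
            one_to_one(pairs([1.0, 2.0], [0.0, 0.0]))
        with pytest.raises(UndefinedMetricError):
            one_to_one(pairs([1.0], [1.0]))


class TestCzekanowski:
    def test_identical_communities(self):
        pair = CoverPair({"a": 0.6, "b": 0.4}, {"a": 0.6, "b": 0.4})
        assert czekanowski(pair) == pytest.approx(1.0)

    def test_disjoint_supports(self):
        pair = CoverPair({"a": 0.5, "b": 0.5}, {"c": 1.0})
        assert czekanowski(pair) == pytest.approx(0.0)

    def test_absent_species_count_as_zero(self):
        pair = CoverPair({"a": 1.0}, {"a": 0.5, "b": 0.5})
        # sum|P-O| = 0.5 + 0.5, sum(P+O) = 2
        assert czekanowski(pair) == pytest.approx(0.5)

    def test_all_zero_undefined(self):
        with pytest.raises(UndefinedMetricError):
            czekanowski(CoverPair({"a": 0.0}, {"a": 0.0}))

    @given(
        n=st.integers(2, 10), c=st.floats(0.01, 100), seed=st.integers(0, 10_000)
    )
    @settings(max_examples=150, deadline=None)
    def test_symmetry_and_scale_invariance(self, n, c, seed):
        rng = np.random.default_rng(seed)
        P = dict(zip(map(str, range(n)), rng.uniform(0, 1, n)))
        O = dict(zip(map(str, range(n)), rng.uniform(0.01, 1, n)))
        forward = czekanowski(CoverPair(P, O))
        backward = czekanowski(CoverPair(O, P))
        scaled = czekanowski(
            CoverPair({k: c * v for k, v in P.items()},
                      {k: c * v for k, v in O.items()})
        )
        assert forward == pytest.approx(backward, rel=1e-12)
        assert forward == pytest.approx(scaled, rel=1e-9)


class TestOracleEquivalence:
    def test_all_metrics_match_brute_force(self):
        """1000 random paired series agree with elementary
        re-implementations to 1e-12."""
        rng = np.random.default_rng(20240901)
        for _ in range(1000):
            n = int(rng.integers(2, 40))
            O = rng.uniform(0.05, 10.0, size=n)
            P = np.abs(O + rng.normal(0, 1.0, size=n))
            series = PairedSeries.from_arrays(P, O)
            assert nae(series) == pytest.approx(oracle_nae(P, O), abs=1e-12)
            assert nrmse(series) == pytest.approx(oracle_nrmse(P, O), abs=1e-12)
            slope, se, corr = one_to_one(series)
            o_slope, o_se, o_corr = oracle_one_to_one(list(P), list(O))
            assert slope == pytest.approx(o_slope, abs=1e-12)
            assert se == pytest.approx(o_se, abs=1e-12)
            assert corr == pytest.approx(o_corr, abs=1e-12)
            names = [str(i) for i in range(n)]
            pair = CoverPair(dict(zip(names, P)), dict(zip(names, O)))
            assert czekanowski(pair) == pytest.approx(
                oracle_czekanowski(P, O), abs=1e-12
            )


class TestAnnualMedianPairs:
    def test_median_pairing(self):
        modeled = pd.DataFrame({"year": [2001] * 12, "value": [5.0] * 12})
        obs = pd.DataFrame({"year": [2001] * 3, "value": [2.0, 4.0, 6.0]})
        series = annual_median_pairs(modeled, obs)
        assert series.predicted == (5.0,)
        assert series.observed == (4.0,)

    def test_identical_single_values(self):
        modeled = pd.DataFrame({"year": [2001], "value": [3.3]})
        obs = pd.DataFrame({"year": [2001], "value": [3.3]})
        series = annual_median_pairs(modeled, obs)
        assert series.predicted == series.observed == (3.3,)

    def test_years_outside_span_excluded(self, caplog):
        modeled = pd.DataFrame({"year": [2001, 2002], "value": [1.0, 2.0]})
        obs = pd.DataFrame({"year": [2001, 2050], "value": [1.5, 9.9]})
        with caplog.at_level("INFO"):
            series = annual_median_pairs(modeled, obs)
        assert len(series) == 1
        assert "2050" in caplog.text

    def test_no_overlap_is_error(self):
        modeled = pd.DataFrame({"year": [2001], "value": [1.0]})
        obs = pd.DataFrame({"year": [1990], "value": [1.0]})
        with pytest.raises(UndefinedMetricError):
            annual_median_pairs(modeled, obs)

    def test_mean_mode(self):
        modeled = pd.DataFrame({"year": [2001] * 2, "value": [1.0, 3.0]})
        obs = pd.DataFrame({"year": [2001] * 2, "value": [2.0, 6.0]})
        series = annual_median_pairs(modeled, obs, agg="mean")
        assert series.predicted == (2.0,)
        assert series.observed == (4.0,)


class TestEvaluateBundle:
    def test_bundle_contains_all_metrics(self):
        series = pairs([1.0, 2.0, 3.0], [1.1, 1.9, 3.2])
        pair = CoverPair({"a": 0.5, "b": 0.5}, {"a": 0.6, "b": 0.4})
        report = evaluate(series=series, cover_pair=pair, meta={"site": "demo"})
        d = report.as_dict()
        for field in ("nae", "nrmse", "slope", "slope_se", "correlation", "czi"):
            assert field in d
        assert d["meta_site"] == "demo"

    def test_nothing_to_evaluate(self):
        with pytest.raises(ValueError):
            evaluate()
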