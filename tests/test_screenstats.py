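"""Spot scoring, normalization, z-scores, rank product and PAM."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import pdist, squareform

import csma
from csma.errors import DegenerateDataError, PinNormalizationError


def spot_frame(**overrides):
    base = pd.DataFrame(
        {
            "spot_id": [0, 1, 2, 3],
            "n_cells": [50, 50, 50, 50],
            "cum_dapi": [1e6] * 4,
            "cum_ki67": [4e5, 4e5, 4e5, 4e5],
            "cum_cparp": [1e5] * 4,
            "sample_id": ["A", "B", "NEG_CTRL", "NEG_CTRL"],
            "pin_id": [0, 0, 0, 0],
        }
    )
    for k, v in overrides.items():
        base[k] = v
    return base


class TestAggregation:
    def test_excluded_cells_do_not_contribute(self, null_spot_cells):
        cells = null_spot_cells.copy()
        cells.loc[cells.index[:10], "excluded"] = True
        spots = csma.aggregate_spots(cells)
        assert spots.n_cells.iloc[0] == len(cells) - 10
        expected = cells.loc[~cells.excluded, "ki67_int"].sum()
        assert spots.cum_ki67.iloc[0] == pytest.approx(expected)


class TestPinNormalize:
    def test_single_pin_is_identity(self):
        spots = spot_frame()
        out = csma.pin_normalize(spots)
        for ch in ("cum_dapi", "cum_ki67", "cum_cparp"):
            np.testing.assert_allclose(out[ch], spots[ch])

    def test_planted_bias_removed(self):
        rng = np.random.default_rng(0)
        n = 120
        spots = pd.DataFrame(
            {
                "spot_id": np.arange(n),
                "n_cells": 50,
                "cum_dapi": rng.lognormal(14, 0.1, n),
                "cum_ki67": rng.lognormal(13, 0.1, n),
                "cum_cparp": rng.lognormal(12, 0.1, n),
                "sample_id": ["NEG_CTRL" if i % 5 == 0 else f"S{i}" for i in range(n)],
                "pin_id": np.arange(n) % 4,
            }
        )
        biased = spots.copy()
        m = biased.pin_id == 3
        for ch in ("cum_dapi", "cum_ki67", "cum_cparp"):
            biased.loc[m, ch] *= 2.0
        out = csma.pin_normalize(biased)
        med = out[out.sample_id == "NEG_CTRL"].groupby("pin_id").cum_ki67.median()
        assert med[3] == pytest.approx(med.drop(3).mean(), rel=0.05)

    def test_missing_pin_controls_named_in_error(self):
        spots = spot_frame(pin_id=[0, 7, 0, 0])
        with pytest.raises(PinNormalizationError, match="pin 7"):
            csma.pin_normalize(spots)


class TestSpotIndex:
    def test_equal_channels_give_zero(self):
        spots = spot_frame(cum_ki67=[1e5] * 4)
        out = csma.spot_index(spots, pseudo=0.0)
        np.testing.assert_allclose(out["index"], 0.0)

    def test_doubling_ki67_adds_exactly_one(self):
        a = csma.spot_index(spot_frame(), pseudo=0.0)
        b = csma.spot_index(spot_frame(cum_ki67=[8e5, 8e5, 8e5, 8e5]), pseudo=0.0)
        np.testing.assert_allclose(b["index"] - a["index"], 1.0)

    def test_low_count_and_degenerate_spots_flagged(self):
        spots = spot_frame(n_cells=[50, 5, 50, 50], cum_dapi=[1e6, 1e6, 0.0, 1e6])
        out = csma.spot_index(spots)
        assert not out.index_defined.iloc[1] and np.isnan(out["index"].iloc[1])
        assert not out.index_defined.iloc[2] and np.isnan(out["index"].iloc[2])
        assert out.index_defined.iloc[0] and out.index_defined.iloc[3]


class TestZScores:
    def test_closed_form_population_sd(self):
        z = csma.zscore_array(pd.Series([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(z, [-1.224745, 0.0, 1.224745], atol=1e-6)

    def test_constant_vector_rejected(self):
        with pytest.raises(DegenerateDataError):
            csma.zscore_array(pd.Series([2.0, 2.0, 2.0]))

    @given(
        st.lists(
            st.floats(min_value=-1e6, max_value=1e6, allow_nan=False),
            min_size=4,
            max_size=40,
            unique=True,
        )
    )
    @settings(deadline=None, derandomize=True, max_examples=30)
    def test_standardization_moments(self, values):
        z = csma.zscore_array(pd.Series(values))
        assert z.mean() == pytest.approx(0.0, abs=1e-9)
        assert z.std(ddof=0) == pytest.approx(1.0, rel=1e-9)


class TestCombineAndCall:
    def test_inhibitory_call(self):
        z = pd.DataFrame({"a": [-2.5], "b": [-2.1]}, index=["s1"])
        out = csma.combine_and_call(z)
        assert out.combined_z.iloc[0] == pytest.approx(-2.3)
        assert out.hit.iloc[0] == "inhibitory"

    def test_boundary_is_not_a_hit(self):
        z = pd.DataFrame({"a": [1.99], "b": [1.99]}, index=["s1"])
        assert csma.combine_and_call(z).hit.iloc[0] == "none"
        z2 = pd.DataFrame({"a": [2.0], "b": [2.0]}, index=["s1"])
        assert csma.combine_and_call(z2).hit.iloc[0] == "promoting"

    def test_missing_array_scored_and_flagged(self):
        z = pd.DataFrame({"a": [-3.0, 1.0], "b": [np.nan, 1.0]}, index=["s1", "s2"])
        out = csma.combine_and_call(z)
        assert out.combined_z.loc["s1"] == pytest.approx(-3.0)
        assert bool(out.flagged_missing.loc["s1"]) and not bool(out.flagged_missing.loc["s2"])


class TestConcordance:
    def test_identical_and_negated(self):
        a = pd.Series([0.1, -1.0, 2.0, 0.5])
        assert csma.replicate_concordance(a, a) == pytest.approx(1.0)
        assert csma.replicate_concordance(a, -a) == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        a = pd.Series([1.0, 2.0, 3.0])
        with pytest.raises(DegenerateDataError):
            csma.replicate_concordance(a, pd.Series([1.0, 1.0, 1.0]))


class TestRankProduct:
    def test_small_example_geometric_means(self):
        scores = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [1.0, 3.0, 2.0]})
        out = csma.rank_product(scores)
        np.testing.assert_allclose(out.rp, [1.0, np.sqrt(6), np.sqrt(6)])

    def test_exact_null_probability_matches_enumeration(self):
        """P(RP <= 1) at n=3, k=2 equals brute-force 1/9."""
        scores = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [1.0, 3.0, 2.0]})
        out = csma.rank_product(scores)
        # independent oracle: enumerate all 9 rank pairs
        pairs = list(itertools.product([1, 2, 3], repeat=2))
        brute = np.mean([np.sqrt(r1 * r2) <= 1.0 for r1, r2 in pairs])
        assert brute == pytest.approx(1 / 9)
        assert out.rp_p.iloc[0] == pytest.approx(brute)

    def test_identical_rankings_preserve_order(self):
        scores = pd.DataFrame({"a": [3.0, -1.0, 0.5, 2.0], "b": [9.0, -2.0, 0.1, 5.0]})
        out = csma.rank_product(scores)
        assert list(np.argsort(out.rp)) == list(np.argsort(scores["a"]))

    def test_up_and_down_directions_are_mirrored(self):
        scores = pd.DataFrame({"a": [3.0, -1.0, 0.5], "b": [9.0, -2.0, 0.1]})
        down = csma.rank_product(scores, direction="down")
        up = csma.rank_product(scores, direction="up")
        assert down.rp.idxmin() == 1 and up.rp.idxmin() == 0

    def test_missing_score_gets_worst_rank_and_flag(self):
        scores = pd.DataFrame({"a": [1.0, 2.0, np.nan], "b": [1.0, 2.0, 3.0]})
        out = csma.rank_product(scores, n_perm=200, seed=0)
        assert bool(out.rp_missing.iloc[2])
        assert out.rp.iloc[2] == pytest.approx(np.sqrt(3.0 * 3.0))

    def test_single_condition_rejected(self):
        with pytest.raises(ValueError):
            csma.rank_product(pd.DataFrame({"a": [1.0, 2.0]}))

    def test_ties_get_average_ranks(self):
        scores = pd.DataFrame({"a": [1.0, 1.0, 2.0], "b": [1.0, 2.0, 3.0]})
        out = csma.rank_product(scores)
        np.testing.assert_allclose(out.rp.iloc[:2], [np.sqrt(1.5), np.sqrt(3.0)])


class TestPAM:
    def test_cost_matches_exhaustive_search(self):
        rng = np.random.default_rng(1)
        for trial in range(5):
            X = rng.normal(size=(10, 3))
            res = csma.pam_cluster(X, k=2)
            D = squareform(pdist(X))
            brute = min(
                D[:, list(p)].min(axis=1).sum()
                for p in itertools.combinations(range(len(X)), 2)
            )
            assert res.cost == pytest.approx(brute)

    def test_separated_clouds_split_correctly(self):
        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal(0, 0.3, (6, 2)), rng.normal(8, 0.3, (6, 2))])
        res = csma.pam_cluster(X, k=2)
        assert len(set(res.labels[:6])) == 1 and len(set(res.labels[6:])) == 1
        assert res.labels[0] != res.labels[6]

    def test_k_equals_n_costs_zero(self):
        X = np.random.default_rng(3).normal(size=(5, 2))
        res = csma.pam_cluster(X, k=5)
        assert res.cost == pytest.approx(0.0)
        assert sorted(res.medoid_indices) == list(range(5))

    def test_deterministic(self):
        X = np.random.default_rng(4).normal(size=(30, 4))
        a = csma.pam_cluster(X, k=3)
        b = csma.pam_cluster(X, k=3)
        assert np.array_equal(a.labels, b.labels)
        assert np.array_equal(a.medoid_indices, b.medoid_indices)
        assert np.array_equal(a.order, b.order)

    def test_invalid_k_rejected(self):
        X = np.zeros((4, 2))
        with pytest.raises(ValueError):
            csma.pam_cluster(X, k=6)

    def test_correlation_metric(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=8)
        X = np.vstack([base + rng.normal(0, 0.05, 8) for _ in range(4)]
                      + [-base + rng.normal(0, 0.05, 8) for _ in range(4)])
        res = csma.pam_cluster(X, k=2, metric="correlation")
        assert len(set(res.labels[:4])) == 1 and res.labels[0] != res.labels[4]
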