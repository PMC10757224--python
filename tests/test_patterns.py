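"""Stratification, deciles, profiles, trajectories, atypicality, clustering."""

import numpy as np
import pandas as pd
import pytest

from tensorbasket.model import ScoreArray, fit_tpca
from tensorbasket.patterns import (
    cluster_loadings,
    correlation_distance_matrix,
    deciles,
    flag_atypical,
    group_profile,
    stratify,
    trajectory_by_decile,
)
from tensorbasket.preprocess import apply_exclusions, rescale_annual
from tensorbasket.simulate import SyntheticConfig, simulate_tensor
from tensorbasket.tensor import PurchaseTensor


def _scores(values: np.ndarray) -> ScoreArray:
    n = values.shape[0]
    return ScoreArray(values.reshape(n, 1, 1), [f"c{i:04d}" for i in range(n)])


class TestStratify:
    def test_ten_eighty_ten_split(self):
        rng = np.random.default_rng(0)
        labels = stratify(_scores(rng.permutation(1000).astype(float)), (1, 1), 0.10)
        assert labels.counts() == {"high": 100, "typical": 800, "low": 100}

    def test_q_zero_all_typical(self):
        labels = stratify(_scores(np.arange(20.0)), (1, 1), 0.0)
        assert labels.counts()["typical"] == 20

    def test_floor_semantics_with_ties(self):
        labels = stratify(_scores(np.zeros(5)), (1, 1), 0.10)
        assert labels.counts() == {"high": 0, "typical": 5, "low": 0}

    def test_extremes_match_score_order(self):
        s = np.array([5.0, -1.0, 3.0, 0.0, 10.0, -7.0, 2.0, 1.0, 4.0, -2.0])
        labels = stratify(_scores(s), (1, 1), 0.20)
        assert set(labels.ids("high")) == {"c0004", "c0000"}
        assert set(labels.ids("low")) == {"c0005", "c0009"}

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        s = rng.normal(size=200)
        a = stratify(_scores(s), (1, 1), 0.10)
        b = stratify(_scores(np.exp(3 * s)), (1, 1), 0.10)
        assert list(a.labels) == list(b.labels)

    def test_q_half_rejected(self):
        with pytest.raises(ValueError):
            stratify(_scores(np.arange(10.0)), (1, 1), 0.5)


class TestDeciles:
    def test_even_split(self):
        rng = np.random.default_rng(1)
        d = deciles(_scores(rng.permutation(100).astype(float)), (1, 1))
        assert d.value_counts().tolist() == [10] * 10

    def test_monotone_in_score(self):
        rng = np.random.default_rng(2)
        s = rng.normal(size=73)
        d = deciles(_scores(s), (1, 1))
        order = np.argsort(s, kind="stable")
        assert np.all(np.diff(d.to_numpy()[order]) >= 0)

    def test_remainder_goes_to_lowest_ranks(self):
        d = deciles(_scores(np.arange(103.0)), (1, 1))
        sizes = d.value_counts().sort_index()
        assert sizes.tolist() == [11, 11, 11] + [10] * 7

    def test_small_cohort_rejected(self):
        with pytest.raises(ValueError):
            deciles(_scores(np.arange(9.0)), (1, 1))

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(6)
        s = rng.normal(size=150)
        a = deciles(_scores(s), (1, 1))
        b = deciles(_scores(s**3), (1, 1))  # strictly increasing on R
        assert a.tolist() == b.tolist()


class TestGroupProfile:
    def test_all_customers_give_zero_profile(self, tiny_tensor):
        profile = group_profile(tiny_tensor, tiny_tensor.customer_ids)
        assert np.abs(profile.z_profile.to_numpy()).max() < 1e-12

    def test_hand_computed_cell(self):
        values = np.zeros((3, 1, 1))
        values[:, 0, 0] = [1.0, 2.0, 3.0]
        tensor = PurchaseTensor(values, ["a", "b", "c"], ["g"], np.arange(1, 2))
        profile = group_profile(tensor, ["c"])
        assert profile.z_profile.iloc[0, 0] == pytest.approx(1.2247, abs=1e-4)

    def test_constant_cell_is_zero(self):
        values = np.ones((3, 1, 2))
        tensor = PurchaseTensor(values, ["a", "b", "c"], ["g"], np.arange(1, 3))
        profile = group_profile(tensor, ["a"])
        assert not profile.z_profile.to_numpy().any()

    def test_empty_members_rejected(self, tiny_tensor):
        with pytest.raises(ValueError):
            group_profile(tiny_tensor, [])

    def test_high_low_profiles_mirror_for_block_seasonal_pair(self):
        # comparable-scale components so the (ready-vs-fresh, summer-winter)
        # pair is visible against the others in the group means
        config = SyntheticConfig(
            n_customers=1000, mode="gaussian", seed=4,
            latent_sds=(30.0, 29.0, 28.0, 27.0, 26.0, 25.0, 24.0, 23.0, 22.0),
        )
        tensor, _ = simulate_tensor(config)
        res = fit_tpca(tensor, 3, 3)
        st = stratify(res.project(), (2, 3), 0.10)
        hi = group_profile(tensor, st.ids("high")).z_profile.to_numpy().ravel()
        lo = group_profile(tensor, st.ids("low")).z_profile.to_numpy().ravel()
        cosine = hi @ lo / (np.linalg.norm(hi) * np.linalg.norm(lo))
        assert cosine <= -0.8


class TestTrajectories:
    def test_full_subset_is_100_percent(self, tiny_tensor):
        d = pd.Series([1, 5, 10], index=tiny_tensor.customer_ids)
        traj = trajectory_by_decile(tiny_tensor, d, tiny_tensor.group_labels)
        filled = traj.to_numpy()[~np.isnan(traj.to_numpy())]
        np.testing.assert_allclose(filled, 100.0)

    def test_hand_computed_two_by_two(self):
        # two customers, two weeks, subset = first group
        values = np.array(
            [[[6.0, 1.0], [2.0, 3.0]],   # pct: 75, 25
             [[1.0, 0.0], [3.0, 0.0]]],  # pct: 25, undefined (zero week)
        )
        tensor = PurchaseTensor(values, ["a", "b"], ["g1", "g2"], np.arange(1, 3))
        labels = pd.Series([10, 1], index=["a", "b"])
        traj = trajectory_by_decile(tensor, labels, ["g1"])
        assert traj.loc[10].tolist() == [75.0, 25.0]
        assert traj.loc[1, 1] == 25.0 and np.isnan(traj.loc[1, 2])

    def test_seasonal_deciles_separate_summer_and_winter(self):
        tensor, _ = simulate_tensor(SyntheticConfig(n_customers=1000, seed=4))
        kept, _ = apply_exclusions(tensor)
        scaled = rescale_annual(kept)
        res = fit_tpca(scaled, 3, 3)
        dec = deciles(res.project(), (2, 3))
        subset = ["ready-to-eat meals", "ready-to-eat snacks"]
        traj = trajectory_by_decile(scaled, dec, subset)
        summer = [w for w in scaled.week_labels if 14 <= w <= 39]
        winter = [w for w in scaled.week_labels if w < 14 or w > 39]
        gap10 = traj.loc[10, summer].mean() - traj.loc[10, winter].mean()
        gap1 = traj.loc[1, summer].mean() - traj.loc[1, winter].mean()
        # expected direction from the fitted loadings: a high (2,3) score adds
        # (Σ ready a2) · b3 to the trajectory, and b3 is winter-peaked when it
        # correlates positively with cos(2πw/52)
        ready = sum(res.U1[scaled.group_labels.index(g), 1] for g in subset)
        winter_peaked = np.corrcoef(
            res.U2[:, 2], np.cos(2 * np.pi * (scaled.week_labels - 1) / 52)
        )[0, 1]
        expected_sign = np.sign(ready) * np.sign(-winter_peaked)
        assert np.sign(gap10 - gap1) == expected_sign
        assert abs(gap10 - gap1) > 5.0  # clearly separated seasonal deciles

    def test_empty_subset_rejected(self, tiny_tensor):
        with pytest.raises(ValueError):
            trajectory_by_decile(tiny_tensor, pd.Series(dtype=int), [])


class TestFlagAtypical:
    def test_unit_loading_column_flags_single_label(self, tiny_tensor):
        res = fit_tpca(tiny_tensor, 2, 2)
        res.U1 = np.array([[1.0, 0.0], [0.0, 0.1]])
        res.U2 = np.zeros((4, 2))
        weeks, groups = flag_atypical(res, 0.3)
        assert groups == ["ga"] and weeks == []

    def test_small_loadings_flag_nothing(self, tiny_tensor):
        res = fit_tpca(tiny_tensor, 2, 2)
        res.U1 = np.full((2, 2), 0.25)
        res.U2 = np.full((4, 2), 0.25)
        assert flag_atypical(res, 0.3) == ([], [])

    def test_holiday_boost_weeks_flagged(self):
        # pronounced holiday spikes: the rescaling couples the population-level
        # boost into customer-level variance at the holiday columns
        config = SyntheticConfig(n_customers=800, holiday_boost=0.5, seed=21)
        tensor, _ = simulate_tensor(config)
        kept, _ = apply_exclusions(tensor)
        scaled = rescale_annual(kept)
        res = fit_tpca(scaled, 5, 5)
        weeks, _ = flag_atypical(res, 0.3)
        assert set(config.holiday_weeks) <= set(weeks)

    def test_nonpositive_threshold_rejected(self, tiny_tensor):
        res = fit_tpca(tiny_tensor, 2, 2)
        with pytest.raises(ValueError):
            flag_atypical(res, 0.0)


def naive_average_linkage(D: np.ndarray):
    """O(n³) agglomerative average linkage; returns the merge sequence."""
    n = D.shape[0]
    clusters = {i: [i] for i in range(n)}
    dist = {(i, j): D[i, j] for i in range(n) for j in range(i + 1, n)}
    merges = []
    next_id = n
    while len(clusters) > 1:
        (a, b), h = min(dist.items(), key=lambda kv: kv[1])
        merged = clusters.pop(a) + clusters.pop(b)
        for c in clusters:
            key_a = (min(a, c), max(a, c))
            key_b = (min(b, c), max(b, c))
            d_new = sum(D[x, y] for x in merged for y in clusters[c]) / (
                len(merged) * len(clusters[c])
            )
            dist[(min(next_id, c), max(next_id, c))] = d_new
            dist.pop(key_a, None)
            dist.pop(key_b, None)
        dist.pop((min(a, b), max(a, b)), None)
        clusters[next_id] = merged
        merges.append((h, tuple(sorted(merged))))
        next_id += 1
    return merges


class TestClusterLoadings:
    def test_identical_rows_merge_first_at_zero(self):
        X = np.array([[1.0, 2.0, 3.0], [2.0, 4.0, 6.0], [3.0, 1.0, -2.0],
                      [0.0, 5.0, 1.0]])
        # rows 0 and 1 are perfectly correlated → distance 0
        order, Z = cluster_loadings(X)
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}
        assert len(order) == 4

    def test_matches_naive_average_linkage(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(6, 5))
        D = correlation_distance_matrix(X)
        _, Z = cluster_loadings(X)
        naive = naive_average_linkage(D)
        heights = sorted(m[0] for m in naive)
        np.testing.assert_allclose(sorted(Z[:, 2]), heights, atol=1e-10)

    def test_constant_row_kept_at_max_distance(self):
        X = np.array([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0], [3.0, 2.0, 1.0]])
        D = correlation_distance_matrix(X)
        assert np.allclose(D[0, 1:], 1.0)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            cluster_loadings(np.ones((1, 4)))
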