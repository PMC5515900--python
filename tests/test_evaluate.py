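"""Projection, importance maps and the signed-rank test."""

import itertools

import numpy as np
import pytest
from scipy import stats

from rpca_eeg.evaluate import (
    discriminant_project, importance_map, joint_minmax, map_distance,
    wilcoxon_signed_rank,
)
from rpca_eeg.selection import fscore


def two_clusters(rng, gap=8.0, n=30, p=20):
    y = np.repeat(["a", "b"], n // 2)
    X = rng.standard_normal((n, p))
    X[y == "b", 0] += gap
    return X, y


class TestProjection:
    def test_separated_clusters_split_on_axis_one(self, rng):
        X, y = two_clusters(rng)
        res = discriminant_project(X, y)
        gap = res.class_centroids["b"][0] - res.class_centroids["a"][0]
        spread = max(res.coords[y == c][:, 0].std() for c in "ab")
        assert abs(gap) > 10 * spread

    def test_permuted_labels_destroy_separation(self, rng):
        X, y = two_clusters(rng, gap=3.0)
        res = discriminant_project(X, y)
        obs_gap = abs(res.boundary_normal[0])
        perm_gaps = []
        for _ in range(200):
            yp = rng.permutation(y)
            perm_gaps.append(abs(discriminant_project(X, yp).boundary_normal[0]))
        assert obs_gap > np.percentile(perm_gaps, 95)

    def test_identical_clusters_no_gap(self, rng):
        X = rng.standard_normal((40, 10))
        y = np.repeat(["a", "b"], 20)
        res = discriminant_project(X, y)
        gap = np.linalg.norm(res.boundary_normal)
        spread = res.coords[:, 0].std()
        assert gap < spread

    def test_axes_orthonormal_and_sign_fixed(self, rng):
        X, y = two_clusters(rng)
        res = discriminant_project(X, y)
        assert np.allclose(res.axes @ res.axes.T, np.eye(2), atol=1e-8)
        for axis in res.axes:
            first = axis[np.flatnonzero(np.abs(axis) > 1e-12)[0]]
            assert first > 0

    def test_boundary_geometry(self, rng):
        X, y = two_clusters(rng)
        res = discriminant_project(X, y)
        mid = (res.class_centroids["a"] + res.class_centroids["b"]) / 2
        assert np.allclose(res.boundary_point, mid)
        assert np.allclose(res.boundary_normal,
                           res.class_centroids["b"] - res.class_centroids["a"])

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            discriminant_project(rng.standard_normal((6, 3)), np.array(["a"] * 6))


class TestMaps:
    def test_identical_maps_distance_zero(self):
        a = np.random.default_rng(0).random(110)
        assert map_distance(a, a) == 0.0

    def test_unit_basis_distance_sqrt_two(self):
        a = np.zeros(110)
        b = np.zeros(110)
        a[0] = 1.0
        b[1] = 1.0
        assert map_distance(a, b) == pytest.approx(np.sqrt(2))

    def test_symmetry_and_length_check(self, rng):
        a, b = rng.random(110), rng.random(110)
        assert map_distance(a, b) == map_distance(b, a)
        with pytest.raises(ValueError):
            map_distance(a, rng.random(5))

    def test_joint_minmax_scope(self):
        maps = {"x": np.array([0.0, 5.0]), "y": np.array([10.0, 2.0])}
        out = joint_minmax(maps)
        stacked = np.concatenate(list(out.values()))
        assert stacked.min() == 0.0 and stacked.max() == 1.0
        assert out["y"][0] == 1.0 and out["x"][0] == 0.0

    def test_sparse_map_concentrates_on_true_support(self, small_config):
        """RPCA-S importance lands on ground-truth support more than RPCA-L."""
        from dataclasses import replace
        from rpca_eeg.benchmark import route_manners
        from rpca_eeg.synthetic import generate_feature_dataset

        wins = 0
        dist_wins = 0
        n_seeds = 10
        for seed in range(n_seeds):
            cfg = replace(small_config, seed=seed, n_days=1, trials_per_day=12,
                          effect_size=1.0, noise_sd=0.5)
            ds = generate_feature_dataset(cfg, include_baseline=True)
            support = ds.support
            maps = {}
            for segment in ("music", "baseline"):
                trials, _, labels = ds.as_arrays(segment=segment)
                routed = route_manners(trials, lambda_rule="sqrt")
                for manner, vecs in routed.items():
                    maps[(segment, manner)] = importance_map(fscore(vecs, labels))
            norm = joint_minmax({str(k): v for k, v in maps.items()})
            s_map = norm[str(("music", "rpca_sparse"))]
            l_map = norm[str(("music", "rpca_low_rank"))]
            control = norm[str(("baseline", "original"))]
            if s_map[support].sum() > l_map[support].sum():
                wins += 1
            if map_distance(s_map, control) > map_distance(l_map, control):
                dist_wins += 1
        assert wins >= 0.9 * n_seeds
        assert dist_wins >= 0.9 * n_seeds


def exhaustive_two_sided_p(d: np.ndarray) -> float:
    """Oracle: exact two-sided p by enumerating all 2^n sign assignments."""
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    dist = []
    for signs in itertools.product([0, 1], repeat=d.size):
        dist.append(sum(r for s, r in zip(signs, ranks) if s))
    dist = np.array(dist)
    p_low = np.mean(dist <= w_obs)
    p_high = np.mean(dist >= w_obs)
    return min(1.0, 2 * min(p_low, p_high))


class TestWilcoxon:
    def test_all_positive_n12_minimal_p(self):
        x = np.arange(1.0, 13.0)
        stat, p = wilcoxon_signed_rank(x)
        assert p == pytest.approx(2 / 2**12)

    def test_symmetric_pairs_statistic_at_null_center(self):
        x = np.array([1.0, -1.0, 2.0, -2.0, 3.0, -3.0, 4.0, -4.0])
        stat, p = wilcoxon_signed_rank(x)
        n = 8
        assert stat == pytest.approx(n * (n + 1) / 4)
        assert p > 0.9

    def test_matches_exhaustive_enumeration_n8(self, rng):
        d = rng.standard_normal(8) + 0.4
        while np.unique(np.abs(d)).size < 8 or np.any(d == 0):
            d = rng.standard_normal(8) + 0.4
        _, p = wilcoxon_signed_rank(d)
        assert p == pytest.approx(exhaustive_two_sided_p(d))

    def test_paired_form_equals_difference_form(self, rng):
        x, y = rng.random(10), rng.random(10)
        assert wilcoxon_signed_rank(x, y) == wilcoxon_signed_rank(x - y)

    def test_all_ties_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank(np.zeros(10))
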