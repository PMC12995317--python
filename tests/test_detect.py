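"""Window recursion, class labelling, agnostic banding, estimator API."""

import math

import numpy as np
import pytest
from sklearn.base import clone

import blockspin as bs
from conftest import planted_partition


class TestEmpiricalCorrelations:
    def test_hand_values(self):
        r = bs.empirical_correlations(np.array([[1, 1, -1], [1, -1, -1]]))
        assert r.ybar[0, 1] == pytest.approx(0.0)
        assert r.ybar[0, 2] == pytest.approx(-1.0)
        assert r.ybar[1, 2] == pytest.approx(0.0)
        assert r.n == 2

    def test_single_row_all_plus(self):
        r = bs.empirical_correlations(np.ones((1, 4), dtype=int))
        off = r.ybar[~np.eye(4, dtype=bool)]
        assert np.all(off == 1.0)

    def test_flip_invariance(self):
        x = np.array([[1, -1, 1, -1]])
        r = bs.empirical_correlations(np.vstack([x, -x]))
        assert np.all(r.ybar[~np.eye(4, dtype=bool)] == r.ybar.T[~np.eye(4, dtype=bool)])
        assert r.ybar[0, 2] == 1.0

    def test_parity_invariant(self):
        """n * ybar_ij is an integer with the parity of n."""
        m = bs.fixtures.three_party_model((2, 2, 2))
        s = bs.draw_sample(m, 17, seed=0)
        r = bs.empirical_correlations(s)
        prods = r.ybar * 17
        iu = np.triu_indices(6, k=1)
        assert np.allclose(prods[iu], np.round(prods[iu]), atol=1e-9)
        assert np.all((np.round(prods[iu]).astype(int) - 17) % 2 == 0)

    def test_rejects_invalid(self):
        with pytest.raises(bs.BlockSpinError):
            bs.empirical_correlations(np.array([[1, 0, 1]]))


class TestLevelSpec:
    def test_strictly_decreasing_required(self):
        with pytest.raises(bs.BlockSpinError):
            bs.LevelSpec(levels=[0.1, 0.2], halfwidths=0.01)

    def test_overlapping_windows_rejected(self):
        with pytest.raises(bs.BlockSpinError):
            bs.LevelSpec(levels=[0.2, 0.1], halfwidths=0.06)

    def test_from_high_theory(self, three_party_small):
        th = bs.pair_limit_high(three_party_small)
        spec = bs.LevelSpec.from_high_theory(th, N=120)
        assert spec.q == 3
        np.testing.assert_allclose(
            spec.levels, np.sort(np.diag(th.level_matrix))[::-1] / 120, atol=1e-12
        )
        delta = bs.separation_constants(th).value
        assert spec.halfwidths[0] == pytest.approx(delta / 480)


class TestIdentifyGroups:
    def test_population_limit_high_temperature(self, separated_high):
        """Exact correlations of a certified model recover the planted blocks.

        N=330 is the smallest multiple of 3 at which the oracle certifies
        |E(X_i X_j) - level| <= delta/(8N) for every pair of this model, i.e.
        half the window half-width; recovery is then exact by construction.
        """
        N = 330
        m = separated_high(N)
        th = bs.pair_limit_high(m)
        delta = bs.separation_constants(th).value
        exact = bs.sufficient_pair_correlations(m)
        lim = th.pair_limit(N)
        err = max(
            abs(exact[m.structure.members(l)[0], m.structure.members(k)[-1]] - lim[l, k])
            for l in range(3)
            for k in range(3)
        )
        assert err <= delta / (8 * N)  # oracle certification
        res = bs.identify_groups(
            bs.CorrelationMatrix(ybar=exact, n=1),
            bs.LevelSpec.from_high_theory(th, N=N),
        )
        assert res.status == "success"
        assert res.as_partition() == planted_partition(m)

    def test_population_limit_low_temperature(self, polarised_low):
        L = bs.find_minima(polarised_low)
        exact = bs.sufficient_pair_correlations(polarised_low)
        res = bs.identify_groups(
            bs.CorrelationMatrix(ybar=exact, n=1), bs.LevelSpec.from_landscape(L)
        )
        assert res.status == "success"
        assert res.as_partition() == planted_partition(polarised_low)

    def test_single_level_single_class(self):
        rng = np.random.default_rng(0)
        y = np.eye(8) + 0.0
        iu = np.triu_indices(8, k=1)
        vals = 0.5 + 0.01 * rng.uniform(-1, 1, size=iu[0].size)
        y[iu] = vals
        y.T[iu] = vals
        res = bs.identify_groups(
            bs.CorrelationMatrix(ybar=y, n=100),
            bs.LevelSpec(levels=[0.5], halfwidths=0.02),
        )
        assert res.status == "success" and res.n_classes == 1
        assert res.classes[0].size == 8

    def test_unassigned_individuals_flagged(self):
        y = np.zeros((4, 4))
        y[0, 1] = y[1, 0] = 0.5
        res = bs.identify_groups(
            bs.CorrelationMatrix(ybar=y, n=10),
            bs.LevelSpec(levels=[0.5], halfwidths=0.01),
        )
        assert res.status == "inconsistent_sample"
        assert res.diagnostics["unassigned"] == [2, 3]

    def test_window_boundaries_closed(self):
        # dyadic values so |y - level| == halfwidth holds exactly in floats
        y = np.zeros((4, 4))
        for i, j, v in [(0, 1, 0.5 + 0.0078125), (2, 3, 0.5 - 0.0078125)]:
            y[i, j] = y[j, i] = v
        res = bs.identify_groups(
            bs.CorrelationMatrix(ybar=y, n=100),
            bs.LevelSpec(levels=[0.5], halfwidths=0.0078125),
        )
        assert res.status == "success" and res.n_classes == 2

    def test_permutation_equivariance(self, separated_high):
        m = separated_high(30)
        s = bs.draw_sample(m, 500, seed=21)
        spec = bs.LevelSpec(levels=[0.2, 0.1], halfwidths=0.04)
        base = bs.identify_groups(bs.empirical_correlations(s), spec)
        rng = np.random.default_rng(5)
        perm = rng.permutation(30)
        permuted = bs.identify_groups(
            bs.empirical_correlations(s.data[:, perm]), spec
        )
        remapped = frozenset(
            frozenset(int(np.flatnonzero(perm == i)[0]) for i in cls)
            for cls in base.classes
        )
        assert permuted.as_partition() == remapped
        assert permuted.status == base.status

    def test_levels_disjoint_and_exclusion_monotone(self, separated_high):
        """Each pair lands in at most one window and later levels never touch
        vertices used by earlier ones (recursion invariants)."""
        N = 330
        m = separated_high(N)
        th = bs.pair_limit_high(m)
        exact = bs.sufficient_pair_correlations(m)
        res = bs.identify_groups(
            bs.CorrelationMatrix(ybar=exact, n=1),
            bs.LevelSpec.from_high_theory(th, N=N),
        )
        assert res.diagnostics["mixed_level_classes"] == 0
        counts = res.diagnostics["per_level_edge_counts"]
        k = N // 3
        assert counts == [k * (k - 1) // 2] * 3
        assert sorted(res.class_level) == [0, 1, 2]


class TestLabelClasses:
    def test_worked_example_level_order(self, separated_high):
        """The class at the top correlation level maps to the most cohesive group."""
        N = 330
        m = separated_high(N)
        th = bs.pair_limit_high(m)
        exact = bs.sufficient_pair_correlations(m)
        res = bs.identify_groups(
            bs.CorrelationMatrix(ybar=exact, n=1),
            bs.LevelSpec.from_high_theory(th, N=N),
        )
        res = bs.label_classes(res, th, sizes=m.sizes)
        assert not res.ambiguous
        for k in range(res.n_classes):
            g = res.labels_hat[k]
            np.testing.assert_array_equal(res.classes[k], m.structure.members(g))

    def test_equal_level_distinct_sizes_resolved_by_size(self):
        """Two groups tuned to share a correlation level are told apart by size."""
        m = bs.build_model((10, 20), np.diag([1 / 3, 0.5]))
        th = bs.pair_limit_high(m)
        d = np.diag(th.level_matrix)
        assert abs(d[0] - d[1]) < 1e-12  # levels coincide by construction
        exact = bs.sufficient_pair_correlations(m)
        res = bs.identify_groups(
            bs.CorrelationMatrix(ybar=exact, n=1),
            bs.LevelSpec.from_high_theory(th, N=30),
        )
        assert res.status == "success" and res.n_classes == 2
        res = bs.label_classes(res, th, sizes=m.sizes)
        assert not res.ambiguous
        sizes = {int(res.labels_hat[k]): res.classes[k].size for k in range(2)}
        assert sizes == {0: 10, 1: 20}

    def test_equal_level_equal_sizes_flagged_ambiguous(self, polarised_low):
        L = bs.find_minima(polarised_low)
        exact = bs.sufficient_pair_correlations(polarised_low)
        res = bs.identify_groups(
            bs.CorrelationMatrix(ybar=exact, n=1), bs.LevelSpec.from_landscape(L)
        )
        res = bs.label_classes(res, L, sizes=polarised_low.sizes)
        assert res.ambiguous
        assert sorted(res.labels_hat) == [0, 1]

    def test_class_count_mismatch_raises(self, polarised_low):
        L = bs.find_minima(polarised_low)
        y = np.zeros((20, 20))
        iu = np.triu_indices(20, k=1)
        y[iu] = L.gram[0, 0]
        y.T[iu] = L.gram[0, 0]
        res = bs.identify_groups(
            bs.CorrelationMatrix(ybar=y, n=2), bs.LevelSpec.from_landscape(L)
        )
        assert res.n_classes == 1
        with pytest.raises(bs.BlockSpinError):
            bs.label_classes(res, L, sizes=polarised_low.sizes)


class TestFiniteSampleRecovery:
    def test_low_temperature_recovery_with_bound(self, polarised_low):
        """Seeded replicates at the bound-derived sample size recover the
        planted two-block partition; empirical failures respect the bound."""
        L = bs.find_minima(polarised_low)
        sep = bs.separation_constants(L)
        n = bs.min_observations("low", polarised_low.N, sep, eps=0.2)
        summary = bs.recovery_experiment(polarised_low, n=n, reps=25, seed=123)
        assert summary.rate >= 0.8
        bound = bs.failure_bound("low", polarised_low.N, n, sep)
        fail_rate = 1 - summary.rate
        se = math.sqrt(max(fail_rate * (1 - fail_rate), 0.25 / 25) / 25)
        assert fail_rate <= bound + 3 * se

    def test_high_temperature_agnostic_from_sample(self):
        """Banding detection recovers the three-party blocks from a finite
        sample at small N (where 1/N theory windows are still biased)."""
        m = bs.fixtures.three_party_model((10, 10, 10))
        s = bs.draw_sample(m, 200_000, seed=11)
        res = bs.identify_groups_agnostic(bs.empirical_correlations(s))
        assert res.status == "success"
        assert res.as_partition() == planted_partition(m)


class TestAgnostic:
    def test_matches_theory_windows_on_exact_correlations(self, separated_high):
        N = 330
        m = separated_high(N)
        th = bs.pair_limit_high(m)
        delta = bs.separation_constants(th).value
        exact = bs.sufficient_pair_correlations(m)
        corr = bs.CorrelationMatrix(ybar=exact, n=1)
        res_theory = bs.identify_groups(corr, bs.LevelSpec.from_high_theory(th, N=N))
        res_agn = bs.identify_groups_agnostic(corr, min_gap=delta / (2 * N))
        assert res_agn.as_partition() == res_theory.as_partition()

    def test_all_equal_single_class(self):
        y = np.full((6, 6), 0.3)
        np.fill_diagonal(y, 1.0)
        res = bs.identify_groups_agnostic(bs.CorrelationMatrix(ybar=y, n=10))
        assert res.n_classes == 1 and res.classes[0].size == 6

    def test_structureless_noise_single_class(self):
        rng = np.random.default_rng(3)
        noise = rng.choice([-1, 1], size=(5000, 12))
        res = bs.identify_groups_agnostic(bs.empirical_correlations(noise))
        assert res.status == "success"
        assert res.n_classes == 1


class TestEstimatorAPI:
    def test_fit_sets_labels(self, polarised_low):
        s = bs.draw_sample(polarised_low, 5000, seed=7)
        det = bs.CommunityDetector(model=polarised_low).fit(s.data)
        assert det.labels_.shape == (20,)
        assert det.result_.status == "success"
        assert set(det.labels_) == {0, 1}

    def test_get_set_params_and_clone(self, polarised_low):
        det = bs.CommunityDetector(model=polarised_low, regime="low")
        params = det.get_params()
        assert params["regime"] == "low"
        cloned = clone(det)  # sklearn deep-copies constructor params
        np.testing.assert_array_equal(cloned.get_params()["model"].J, polarised_low.J)

    def test_fit_predict(self, polarised_low):
        s = bs.draw_sample(polarised_low, 5000, seed=7)
        labels = bs.CommunityDetector(model=polarised_low).fit_predict(s.data)
        assert labels.shape == (20,)

    def test_agnostic_estimator(self):
        rng = np.random.default_rng(8)
        noise = rng.choice([-1, 1], size=(3000, 10))
        det = bs.AgnosticCommunityDetector().fit(noise)
        assert det.result_.n_classes == 1
        assert clone(det).get_params() == {"min_gap": None}

    def test_critical_regime_refused(self):
        m = bs.build_model((3, 3), np.eye(2))
        s = np.ones((5, 6), dtype=int)
        with pytest.raises(bs.CriticalRegimeError):
            bs.CommunityDetector(model=m).fit(s)
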