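import numpy as np
import pytest

from budprofiler.clustering import (
    ClusterProfile,
    agglomerate,
    bhattacharyya,
    class_profile,
    group_distance_test,
    merge_profiles,
    ml_merge_score,
    write_treeview,
)


def _cp(n, mean, var, members=()):
    return ClusterProfile(n=n, mean=np.atleast_1d(np.asarray(mean, float)),
                          var=np.atleast_1d(np.asarray(var, float)),
                          members=members)


class TestMergeProfiles:
    def test_identical_merge_doubles_n(self):
        c = _cp(10, [1.0, 2.0], [0.5, 0.7])
        m = merge_profiles(c, _cp(10, [1.0, 2.0], [0.5, 0.7]))
        assert m.n == 20
        np.testing.assert_allclose(m.mean, [1.0, 2.0])
        np.testing.assert_allclose(m.var, [0.5, 0.7])

    def test_1d_moment_oracle(self):
        # direct pooled-moment computation: two n=10 clusters at 0 and 10
        m = merge_profiles(_cp(10, 0.0, 1.0), _cp(10, 10.0, 1.0))
        assert m.mean[0] == pytest.approx(5.0)
        assert m.var[0] == pytest.approx(26.0)

    def test_sequence_equals_pooled_moments(self):
        rng = np.random.default_rng(0)
        samples = [rng.normal(rng.uniform(-3, 3), rng.uniform(0.5, 2), 40)
                   for _ in range(4)]
        parts = [
            _cp(len(s), s.mean(), s.var()) for s in samples
        ]
        merged = parts[0]
        for p in parts[1:]:
            merged = merge_profiles(merged, p)
        pooled = np.concatenate(samples)
        assert merged.mean[0] == pytest.approx(pooled.mean(), rel=1e-12)
        assert merged.var[0] == pytest.approx(pooled.var(), rel=1e-9)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            merge_profiles(_cp(1, [0.0], [1.0]), _cp(1, [0.0, 1.0], [1.0, 1.0]))


class TestMlMergeScore:
    def test_identical_clusters_zero(self):
        c = _cp(5, [1.0, -2.0], [0.3, 0.4])
        assert ml_merge_score(c, _cp(5, [1.0, -2.0], [0.3, 0.4])) == (
            pytest.approx(0.0, abs=1e-9)
        )

    def test_monotone_in_mean_separation(self):
        scores = [
            ml_merge_score(_cp(5, 0.0, 1.0), _cp(5, d, 1.0))
            for d in (0.0, 0.5, 1.0, 2.0, 4.0)
        ]
        assert all(b > a for a, b in zip(scores, scores[1:]))

    def test_matches_plugin_loglikelihood_oracle(self):
        # explicit log-density summation over samples with exact moments
        def exact_moment_sample(n, mu, var, rng):
            x = rng.normal(size=n)
            x = (x - x.mean()) / x.std()
            return mu + np.sqrt(var) * x

        rng = np.random.default_rng(1)
        x1 = exact_moment_sample(10, 0.0, 1.0, rng)
        x2 = exact_moment_sample(10, 10.0, 1.0, rng)
        c1 = _cp(10, x1.mean(), x1.var())
        c2 = _cp(10, x2.mean(), x2.var())

        def loglik(x, mu, var):
            return np.sum(
                -0.5 * np.log(2 * np.pi * var) - (x - mu) ** 2 / (2 * var)
            )

        pooled = np.concatenate([x1, x2])
        two = loglik(x1, x1.mean(), x1.var()) + loglik(x2, x2.mean(), x2.var())
        one = loglik(pooled, pooled.mean(), pooled.var())
        assert ml_merge_score(c1, c2) == pytest.approx(two - one, rel=1e-9)

    def test_nonnegative_on_random_pairs(self):
        rng = np.random.default_rng(2)
        for _ in range(2000):
            d = rng.integers(1, 6)
            c1 = _cp(rng.integers(1, 20), rng.normal(size=d),
                     rng.uniform(0.1, 3, d))
            c2 = _cp(rng.integers(1, 20), rng.normal(size=d),
                     rng.uniform(0.1, 3, d))
            assert ml_merge_score(c1, c2) >= -1e-9

    def test_zero_variance_floored(self):
        c1 = _cp(3, 0.0, 0.0)
        c2 = _cp(3, 1.0, 0.0)
        assert np.isfinite(ml_merge_score(c1, c2))


class TestAgglomerate:
    def test_identical_pair_merges_first(self):
        profiles = [
            _cp(1, [0.0, 0.0], [1.0, 1.0], ("a",)),
            _cp(1, [5.0, 5.0], [1.0, 1.0], ("b",)),
            _cp(1, [5.0, 5.0], [1.0, 1.0], ("c",)),
        ]
        dend = agglomerate(profiles)
        first = dend.merges[0]
        assert {first[0], first[1]} == {1, 2}

    def test_four_class_recovery(self):
        from sklearn.metrics import adjusted_rand_score

        from budprofiler.synthetic import simulate_profile_collection

        rng = np.random.default_rng(3)
        class_defs = [
            (rng.normal(0, 2.0, 120), np.full(120, 0.4), 8) for _ in range(4)
        ]
        means, variances, labels = simulate_profile_collection(class_defs, seed=4)
        profiles = [
            _cp(1, means.loc[i].to_numpy(), variances.loc[i].to_numpy(), (i,))
            for i in means.index
        ]
        dend = agglomerate(profiles)
        ari = adjusted_rand_score(labels.to_numpy(), dend.cut(4))
        assert ari > 0.95

    def test_matches_bruteforce_greedy_oracle(self):
        rng = np.random.default_rng(5)
        profiles = [
            _cp(1, rng.normal(size=3), rng.uniform(0.2, 1, 3), (f"p{i}",))
            for i in range(5)
        ]
        dend = agglomerate([ClusterProfile(p.n, p.mean.copy(), p.var.copy(),
                                           p.members) for p in profiles])
        # oracle: recompute all pair scores from scratch at every step
        active = dict(enumerate(profiles))
        next_id = 5
        merges = []
        while len(active) > 1:
            best = None
            for i in sorted(active):
                for j in sorted(active):
                    if i >= j:
                        continue
                    s = ml_merge_score(active[i], active[j])
                    if best is None or (s, (i, j)) < best[:2]:
                        best = (s, (i, j))
            s, (i, j) = best
            merges.append((i, j, s))
            active[next_id] = merge_profiles(active[i], active[j])
            del active[i], active[j]
            next_id += 1
        got = [(a, b, s) for a, b, s, _ in dend.merges]
        for (a, b, s), (oa, ob, os) in zip(got, merges):
            assert {a, b} == {oa, ob}
            assert s == pytest.approx(os, rel=1e-9)

    def test_merge_conservation(self):
        rng = np.random.default_rng(6)
        profiles = [
            _cp(rng.integers(1, 5), rng.normal(size=4), rng.uniform(0.2, 1, 4))
            for _ in range(8)
        ]
        total = sum(p.n for p in profiles)
        dend = agglomerate(profiles)
        assert dend.merges[-1][3].n == total
        members = dend.node_members()
        root = dend.internal_nodes()[-1]
        assert members[root] == frozenset(range(8))

    def test_alternative_metrics_same_interface(self):
        rng = np.random.default_rng(7)
        profiles = [
            _cp(1, rng.normal(size=6), rng.uniform(0.2, 1, 6), (f"p{i}",))
            for i in range(6)
        ]
        for metric in ("euclidean", "correlation"):
            dend = agglomerate(profiles, metric=metric)
            assert len(dend.merges) == 5
            assert len(dend.cut(3)) == 6
        with pytest.raises(ValueError):
            agglomerate(profiles, metric="manhattan")

    def test_leaf_order_covers_all_leaves(self):
        rng = np.random.default_rng(8)
        profiles = [
            _cp(1, rng.normal(size=3), np.ones(3)) for _ in range(7)
        ]
        dend = agglomerate(profiles)
        assert sorted(dend.leaf_order()) == list(range(7))


class TestClassProfile:
    def test_single_shared_label_set(self):
        profiles = {f"p{i}": _cp(1, [float(i)], [1.0], (f"p{i}",))
                    for i in range(3)}
        labels = {f"p{i}": frozenset({"nucleus"}) for i in range(3)}
        out = class_profile(profiles, labels)
        assert len(out) == 1
        assert out[frozenset({"nucleus"})].n == 3

    def test_exact_set_rule(self):
        profiles = {p: _cp(1, [0.0], [1.0], (p,)) for p in "abc"}
        labels = {"a": frozenset({"A"}), "b": frozenset({"A"}),
                  "c": frozenset({"A", "B"})}
        out = class_profile(profiles, labels)
        assert len(out) == 2
        assert out[frozenset({"A"})].n == 2
        assert out[frozenset({"A", "B"})].n == 1

    def test_merge_fold_order_invariant(self):
        rng = np.random.default_rng(9)
        profiles = {
            f"p{i}": _cp(1, rng.normal(size=4), rng.uniform(0.2, 1, 4), (f"p{i}",))
            for i in range(5)
        }
        labels = {p: frozenset({"X"}) for p in profiles}
        out1 = class_profile(profiles, labels)[frozenset({"X"})]
        rev = dict(reversed(list(profiles.items())))
        out2 = class_profile(rev, labels)[frozenset({"X"})]
        np.testing.assert_allclose(out1.mean, out2.mean, atol=1e-9)
        np.testing.assert_allclose(out1.var, out2.var, atol=1e-9)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            class_profile({}, {})


class TestBhattacharyya:
    def test_identical_zero(self):
        c = _cp(3, [1.0, 2.0], [0.5, 0.8])
        assert bhattacharyya(c, _cp(99, [1.0, 2.0], [0.5, 0.8])) == (
            pytest.approx(0.0, abs=1e-12)
        )

    def test_1d_equal_variance_closed_form(self):
        # delta mu^2 / (8 sigma^2) with sigma^2 = 1, delta = 2 -> 0.5
        assert bhattacharyya(_cp(1, 0.0, 1.0), _cp(1, 2.0, 1.0)) == (
            pytest.approx(0.5)
        )

    def test_symmetric(self):
        rng = np.random.default_rng(10)
        for _ in range(10):
            a = _cp(2, rng.normal(size=5), rng.uniform(0.2, 2, 5))
            b = _cp(7, rng.normal(size=5), rng.uniform(0.2, 2, 5))
            assert bhattacharyya(a, b) == pytest.approx(bhattacharyya(b, a))

    def test_independent_of_member_count(self):
        a = _cp(1, [0.0], [1.0])
        b = _cp(1, [3.0], [2.0])
        a_big = _cp(500, [0.0], [1.0])
        b_big = _cp(9, [3.0], [2.0])
        assert bhattacharyya(a, b) == pytest.approx(bhattacharyya(a_big, b_big))


class TestGroupDistanceTest:
    def _classes(self, rng, centers, spread=0.3):
        return {
            f"c{i}": _cp(3, rng.normal(mu, spread, 4), np.full(4, 0.5))
            for i, mu in enumerate(centers)
        }

    def test_exact_enumeration_three_classes(self):
        rng = np.random.default_rng(11)
        cps = self._classes(rng, [0.0, 0.1, 5.0])
        groups = {"g1": ["c0", "c1"], "g2": ["c2"]}
        w, b, p_exact = group_distance_test(cps, groups, exact=True)
        # oracle: all 3! assignments of classes to group slots
        import itertools

        keys = sorted(cps)
        dm = {
            (x, y): bhattacharyya(cps[x], cps[y])
            for x in keys for y in keys
        }

        def stat(g1, g2):
            within = [dm[(a, b2)] for i, a in enumerate(g1) for b2 in g1[i + 1:]]
            between = [dm[(a, b2)] for a in g1 for b2 in keys if b2 not in g1]
            between += [dm[(a, b2)] for a in g2 for b2 in keys if b2 not in g2]
            wv = np.mean(within) if within else 0.0
            bv = np.mean(between) if between else 0.0
            return wv - bv

        obs = stat(["c0", "c1"], ["c2"])
        null = [
            stat([keys[p[0]], keys[p[1]]], [keys[p[2]]])
            for p in itertools.permutations(range(3))
        ]
        expected_p = (sum(s <= obs for s in null) + 1) / (len(null) + 1)
        assert w - b == pytest.approx(obs)
        assert p_exact == pytest.approx(expected_p)

    def test_true_grouping_significant(self):
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(400 + seed)
            cps = {}
            for g in range(3):
                for m in range(3):
                    cps[f"g{g}m{m}"] = _cp(
                        2, rng.normal(5.0 * g, 0.3, 6), np.full(6, 0.5)
                    )
            groups = {f"g{g}": [f"g{g}m{m}" for m in range(3)] for g in range(3)}
            w, b, p = group_distance_test(cps, groups, n_perm=300, seed=seed)
            if w < b and p < 0.05:
                hits += 1
        assert hits >= 4

    def test_singleton_group_no_within(self):
        rng = np.random.default_rng(12)
        cps = self._classes(rng, [0.0, 1.0])
        w, b, p = group_distance_test(
            cps, {"g1": ["c0"], "g2": ["c1"]}, n_perm=100, seed=0
        )
        assert w == 0.0

    def test_requires_two_groups(self):
        rng = np.random.default_rng(13)
        with pytest.raises(ValueError):
            group_distance_test(self._classes(rng, [0.0]), {"g": ["c0"]})


def test_write_treeview(tmp_path):
    rng = np.random.default_rng(14)
    profiles = [
        _cp(1, rng.normal(size=4), np.ones(4), (f"prot{i}",)) for i in range(6)
    ]
    dend = agglomerate(profiles)
    base = tmp_path / "clusters"
    write_treeview(dend, profiles, str(base), column_names=list("wxyz"))
    gtr = (tmp_path / "clusters.gtr").read_text().strip().splitlines()
    cdt = (tmp_path / "clusters.cdt").read_text().strip().splitlines()
    assert len(gtr) == 5  # n - 1 merges
    assert len(cdt) == 2 + 6  # header + eweight + leaves
    assert cdt[0].split("\t")[4:] == list("wxyz")
    assert all(len(line.split("\t")) == 4 for line in gtr)
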