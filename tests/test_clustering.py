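import numpy as np
import pytest

from xmv1 import clustering
from xmv1.clustering import (ClusterModel, best_match_accuracy,
                             cluster_profiles, explained_variance, fit,
                             homogeneity, prune, reaggregate, type_fractions)


def archetype_profiles(rng, n_per=20, noise=0.1, n_types=3, length=60):
    """Well-separated bump archetypes plus small iid noise."""
    t = np.arange(length)
    archetypes = [np.exp(-0.5 * ((t - c) / 4.0) ** 2)
                  for c in np.linspace(8, length - 8, n_types)]
    X, labels = [], []
    for k, arch in enumerate(archetypes):
        X.append(arch + noise * rng.standard_normal((n_per, length)))
        labels += [f"type{k}"] * n_per
    return np.vstack(X), np.array(labels)


class TestClusterProfiles:
    def test_separated_archetypes_give_pure_clusters(self, rng):
        X, truth = archetype_profiles(rng)
        model = cluster_profiles(X, n_over=10)
        for lab in np.unique(model.labels):
            members = truth[model.labels == lab]
            assert len(set(members)) == 1, f"cluster {lab} mixes archetypes"

    def test_singleton_cut_homogeneity_one(self, rng):
        X = rng.standard_normal((8, 20))
        model = cluster_profiles(X, n_over=8)
        assert sorted(model.homogeneity.values()) == [1.0] * 8

    def test_duplicated_dataset_same_centroids(self, rng):
        X, _ = archetype_profiles(rng, n_per=10)
        m1 = cluster_profiles(X, n_over=3)
        m2 = cluster_profiles(np.vstack([X, X]), n_over=3)
        c1 = sorted(np.round(c, 6).tobytes() for c in m1.centroids.values())
        c2 = sorted(np.round(c, 6).tobytes() for c in m2.centroids.values())
        assert c1 == c2

    def test_nan_profiles_named(self, rng):
        X = rng.standard_normal((30, 10))
        X[4, 2] = np.nan
        with pytest.raises(ValueError, match="4"):
            cluster_profiles(X, n_over=5)

    def test_too_few_neurons(self, rng):
        with pytest.raises(ValueError):
            cluster_profiles(rng.standard_normal((5, 10)), n_over=10)

    def test_deterministic(self, rng):
        X, _ = archetype_profiles(rng)
        a = cluster_profiles(X, n_over=6).labels
        b = cluster_profiles(X, n_over=6).labels
        assert np.array_equal(a, b)


class TestHomogeneity:
    def test_identical_members_one(self):
        X = np.tile(np.arange(10.0), (4, 1))
        h = homogeneity(X, np.ones(4, int))
        assert h[1] == pytest.approx(1.0)

    def test_orthogonal_zero_mean_profiles_zero(self):
        a = np.array([1.0, -1.0, 1.0, -1.0])
        b = np.array([1.0, 1.0, -1.0, -1.0])
        h = homogeneity(np.vstack([a, b]), np.ones(2, int))
        assert abs(h[1]) < 1e-12

    def test_random_profiles_near_zero(self, rng):
        # Monte-Carlo under independence: mean pairwise corr ~ 0
        X = rng.standard_normal((50, 200))
        h = homogeneity(X, np.ones(50, int))
        assert abs(h[1]) < 0.1

    def test_zero_variance_contributes_zero_with_warning(self):
        X = np.vstack([np.zeros(6), np.arange(6.0), np.arange(6.0)])
        with pytest.warns(UserWarning):
            h = homogeneity(X, np.ones(3, int))
        assert np.isclose(h[1], 1.0 / 3.0)  # one real pair of three


class TestPrune:
    def _model(self, X, labels):
        m = ClusterModel(labels=np.asarray(labels))
        for lab in np.unique(labels):
            m.centroids[int(lab)] = X[np.asarray(labels) == lab].mean(axis=0)
        m.homogeneity = homogeneity(X, np.asarray(labels))
        return m

    def test_all_homogeneous_nothing_pruned(self, rng):
        X, _ = archetype_profiles(rng, noise=0.05)
        model = cluster_profiles(X, n_over=3)
        pruned = prune(model, X, 0.4)
        assert (pruned.labels != 0).all()
        assert len(pruned.kept_labels) == 3

    def test_noise_cluster_pruned(self, rng):
        X, _ = archetype_profiles(rng, n_per=15, n_types=2)
        noise = 1.0 * rng.standard_normal((20, X.shape[1]))
        X = np.vstack([X, noise])
        model = cluster_profiles(X, n_over=8)
        # the clusters holding noise cells are heterogeneous ...
        noise_clusters = {lab for lab in np.unique(model.labels[-20:])
                          if np.mean(model.labels[-20:] == lab) > 0.5
                          or np.sum(model.labels == lab) == np.sum(model.labels[-20:] == lab)}
        for lab in noise_clusters:
            assert model.homogeneity[lab] < 0.4
        pruned = prune(model, X, 0.4)
        # ... so the bulk of iid-noise cells ends in the pool
        assert (pruned.labels[-20:] == 0).mean() >= 0.8

    def test_threshold_one_prunes_everything(self, rng):
        X, _ = archetype_profiles(rng)
        model = cluster_profiles(X, n_over=4)
        pruned = prune(model, X, 1.0)
        assert (pruned.labels == 0).all()

    def test_pruning_monotonicity(self, rng):
        X, _ = archetype_profiles(rng, noise=0.3)
        model = cluster_profiles(X, n_over=8)
        kept = [len(prune(model, X, thr).kept_labels)
                for thr in (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)]
        assert all(a >= b for a, b in zip(kept, kept[1:]))

    def test_manual_exclusion(self, rng):
        X, _ = archetype_profiles(rng, noise=0.05)
        model = cluster_profiles(X, n_over=3)
        pruned = prune(model, X, 0.4, manual_exclusions=[1])
        assert len(pruned.kept_labels) == 2


class TestReaggregate:
    def test_pooled_neuron_equal_to_centroid_assigned(self, rng):
        X, _ = archetype_profiles(rng, noise=0.05)
        model = prune(cluster_profiles(X, n_over=3), X, 0.4)
        cent = model.centroids[model.kept_labels[0]]
        X2 = np.vstack([X, cent])
        labels2 = np.concatenate([model.labels, [0]])
        m2 = ClusterModel(labels=labels2, centroids=model.centroids,
                          homogeneity=model.homogeneity)
        out = reaggregate(m2, X2, 0.4)
        assert out.labels[-1] == model.kept_labels[0]

    def test_orthogonal_neuron_stays_pooled(self, rng):
        X, _ = archetype_profiles(rng, noise=0.05)
        model = prune(cluster_profiles(X, n_over=3), X, 0.4)
        probe = rng.standard_normal(X.shape[1])  # uncorrelated noise
        X2 = np.vstack([X, probe])
        m2 = ClusterModel(labels=np.concatenate([model.labels, [0]]),
                          centroids=model.centroids,
                          homogeneity=model.homogeneity)
        out = reaggregate(m2, X2, 0.4)
        assert out.labels[-1] == 0

    def test_centroids_stable_under_recomputation(self, rng):
        # re-aggregation barely moves centroids on default-like data
        X, _ = archetype_profiles(rng, n_per=25, noise=0.15)
        pool_members = np.vstack([
            X[:5] + 0.3 * rng.standard_normal((5, X.shape[1]))])
        X2 = np.vstack([X, pool_members])
        model = prune(cluster_profiles(X, n_over=3), X, 0.4)
        m2 = ClusterModel(labels=np.concatenate([model.labels, [0] * 5]),
                          centroids=model.centroids,
                          homogeneity=model.homogeneity)
        out = reaggregate(m2, X2, 0.4)
        for lab in out.kept_labels:
            new_cent = X2[out.labels == lab].mean(axis=0)
            old = out.centroids[lab]
            rms = np.sqrt(np.mean((new_cent - old) ** 2))
            assert rms < 0.05 * np.sqrt(np.mean(old**2)) + 0.05


class TestExplainedVariance:
    def test_perfect_fit_100(self):
        X = np.tile(np.arange(8.0), (6, 1))
        X[3:] *= -1
        model = ClusterModel(labels=np.array([1, 1, 1, 2, 2, 2]))
        model.centroids = {1: X[0], 2: X[3]}
        assert np.isclose(explained_variance(X, model), 100.0)

    def test_singleton_clusters_100(self, rng):
        X = rng.standard_normal((5, 12))
        model = cluster_profiles(X, n_over=5)
        assert np.isclose(explained_variance(X, model), 100.0)

    def test_fitted_beats_shuffled_assignment(self, rng):
        X, _ = archetype_profiles(rng, noise=0.3)
        model = cluster_profiles(X, n_over=3)
        ev = explained_variance(X, model)
        sh = ClusterModel(labels=rng.permutation(model.labels),
                          centroids=model.centroids)
        assert ev > explained_variance(X, sh)

    def test_scale_invariance(self, rng):
        X, _ = archetype_profiles(rng, noise=0.2)
        model = cluster_profiles(X, n_over=3)
        ev1 = explained_variance(X, model)
        model2 = cluster_profiles(3.7 * X, n_over=3)
        ev2 = explained_variance(3.7 * X, model2)
        assert np.isclose(ev1, ev2, atol=1e-8)


class TestTypeFractions:
    def test_single_type(self):
        assert type_fractions(np.array([1, 1, 1]), {1: "loud_ON"}) == {"loud_ON": 1.0}

    def test_fractions_sum_to_one(self, rng):
        labels = rng.integers(1, 5, size=200)
        tm = {i: f"t{i}" for i in range(1, 5)}
        fr = type_fractions(labels, tm)
        assert abs(sum(fr.values()) - 1.0) < 1e-12

    def test_pool_excluded(self):
        fr = type_fractions(np.array([0, 0, 1, 2]), {1: "a", 2: "b"})
        assert fr == {"a": 0.5, "b": 0.5}

    def test_unmapped_cluster_rejected(self):
        with pytest.raises(ValueError):
            type_fractions(np.array([1, 2]), {1: "a"})

    def test_injected_fraction_recovered(self, rng):
        # 48% of clustered cells from one archetype -> recovered fraction
        n = 200
        n_a = 96
        X, truth = archetype_profiles(rng, n_per=1, n_types=2, noise=0.05)
        arch_a, arch_b = X[0], X[1]
        P = np.vstack([
            arch_a + 0.05 * rng.standard_normal((n_a, X.shape[1])),
            arch_b + 0.05 * rng.standard_normal((n - n_a, X.shape[1])),
        ])
        model = fit(P, n_over=8)
        tm = {}
        for lab in model.kept_labels:
            members = np.where(model.labels == lab)[0]
            tm[lab] = "A" if (members < n_a).mean() > 0.5 else "B"
        fr = type_fractions(model.labels, tm)
        assert abs(fr.get("A", 0) - 0.48) < 0.05


class TestPipelineRecovery:
    def test_accuracy_on_synthetic_population(self):
        from xmv1 import preprocess, synthetic

        ds = synthetic.make_dataset(n_neurons=200, n_repetitions=10, seed=21)
        dec = preprocess.run(ds.traces)
        prof = preprocess.epoch_and_average(dec.r, ds.trials, 31.5)
        X = prof.concatenate(sorted(prof.profiles))
        model = fit(X, n_over=25)
        acc = best_match_accuracy(ds.truth_labels, model.labels)
        assert acc >= 0.9
        # every injected responsive type maps to at least one kept cluster
        mapped = set()
        for lab in model.kept_labels:
            members = np.asarray(ds.truth_labels)[model.labels == lab]
            vals, counts = np.unique(members, return_counts=True)
            mapped.add(vals[np.argmax(counts)])
        injected = set(ds.truth_labels) - {"nonresponsive"}
        assert injected <= mapped
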