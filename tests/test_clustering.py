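"""Trajectory standardization, k-means recovery and cluster matching."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import tmtbridge as tb
from tmtbridge.clustering import brute_force_match_distance
from tmtbridge.errors import ClusteringError

from conftest import archetype_cluster_config, planted_nonflat


def fit(cfg, seed=17, restarts=50):
    truth, matrices, design = tb.simulate(cfg)
    bridged = tb.normalize(matrices, design)
    ids = planted_nonflat(truth)
    traj = tb.build_trajectories(bridged, ids, "untreated")
    model = tb.kmeans_cluster(traj, k=5, seed=seed, n_restarts=restarts)
    return truth, traj, model


class TestTrajectories:
    def test_columns_standardized_to_median_zero_sd_one(self):
        cfg = archetype_cluster_config(n_proteins=300, noise=0.2)
        _, traj, _ = fit(cfg)
        for col in traj.columns:
            assert np.median(traj[col]) == pytest.approx(0.0, abs=1e-9)
            assert np.std(traj[col], ddof=0) == pytest.approx(1.0, abs=1e-9)

    def test_same_archetype_proteins_have_identical_vectors_noiseless(self):
        cfg = archetype_cluster_config(n_proteins=200, noise=0.0)
        truth, traj, _ = fit(cfg)
        for _, members in traj.groupby(truth.loc[traj.index, "archetype"]):
            assert (members.nunique() == 1).all()

    def test_empty_set_rejected(self, noiseless_run):
        _, _, _, _, bridged = noiseless_run
        with pytest.raises(ClusteringError):
            tb.build_trajectories(bridged, set(), "untreated")

    def test_zero_spread_column_rejected(self, noiseless_run):
        _, truth, _, _, bridged = noiseless_run
        flats = sorted(truth.index[truth["archetype"] == "flat"])[:10]
        # flat noiseless proteins: all fold changes identically zero
        with pytest.raises(ClusteringError, match="zero spread"):
            tb.build_trajectories(bridged, flats, "untreated")


class TestKMeans:
    def test_separable_archetypes_recovered_with_zero_inertia(self):
        cfg = archetype_cluster_config(n_proteins=200, noise=0.0)
        truth, traj, model = fit(cfg)
        assert model.inertia == pytest.approx(0.0, abs=1e-9)
        ari = adjusted_rand_score(truth.loc[traj.index, "archetype"], model.assignments)
        assert ari == 1.0

    def test_noisy_recovery_stays_high(self):
        for seed in (1, 2, 3):
            cfg = archetype_cluster_config(n_proteins=600, seed=seed, noise=0.25)
            truth, traj, model = fit(cfg)
            ari = adjusted_rand_score(truth.loc[traj.index, "archetype"], model.assignments)
            assert ari >= 0.8

    def test_determinism_under_fixed_seed(self):
        cfg = archetype_cluster_config(n_proteins=300, noise=0.25)
        _, _, m1 = fit(cfg)
        _, _, m2 = fit(cfg)
        assert m1.inertia == m2.inertia
        pd.testing.assert_series_equal(m1.assignments, m2.assignments)

    def test_one_dimensional_toy_partition(self):
        # {0,0,1,1,10,10} with k=3: the only zero-inertia partition is
        # {0,0},{1,1},{10,10}, confirmed by exhaustive enumeration.
        traj = pd.DataFrame({"x": [0.0, 0.0, 1.0, 1.0, 10.0, 10.0]},
                            index=[f"P{i}" for i in range(6)])
        model = tb.kmeans_cluster(traj, k=3, seed=0, n_restarts=10)
        assert model.inertia == pytest.approx(0.0, abs=1e-12)
        labels = model.assignments
        assert labels["P0"] == labels["P1"]
        assert labels["P2"] == labels["P3"]
        assert labels["P4"] == labels["P5"]
        assert len({labels["P0"], labels["P2"], labels["P4"]}) == 3

    def test_fewer_distinct_points_than_k_rejected(self):
        traj = pd.DataFrame({"x": [0.0, 0.0, 1.0, 1.0]}, index=list("abcd"))
        with pytest.raises(ClusteringError, match="distinct"):
            tb.kmeans_cluster(traj, k=3)

    def test_best_of_restarts_no_worse_than_single_restart(self):
        cfg = archetype_cluster_config(n_proteins=400, noise=0.4)
        truth, matrices, design = tb.simulate(cfg)
        bridged = tb.normalize(matrices, design)
        traj = tb.build_trajectories(bridged, planted_nonflat(truth), "untreated")
        best = tb.kmeans_cluster(traj, k=5, seed=17, n_restarts=50)
        singles = [tb.kmeans_cluster(traj, k=5, seed=s, n_restarts=1) for s in range(5)]
        assert all(best.inertia <= s.inertia + 1e-9 for s in singles)


@pytest.fixture(scope="module")
def model():
    cfg = archetype_cluster_config(n_proteins=300, noise=0.1)
    return fit(cfg)[2]


class TestMatching:
    def test_identity_match(self, model):
        res = tb.match_clusters(model, model)
        assert res.mapping == {i: i for i in range(5)}
        assert res.total_distance == pytest.approx(0.0)
        sizes = model.sizes
        for _, row in res.overlap.iterrows():
            assert row["shared"] == sizes[row["cluster_a"]]
            assert row["only_a"] == 0 and row["only_b"] == 0

    def test_label_permutation_recovered_exactly(self, model):
        perm = [3, 0, 4, 2, 1]
        inverse = np.argsort(perm)
        permuted = tb.ClusterModel(
            k=5,
            centroids=model.centroids[inverse],
            assignments=model.assignments.map(lambda l: perm[l]),
            inertia=model.inertia,
        )
        res = tb.match_clusters(model, permuted)
        assert res.permutation() == perm
        assert res.total_distance == pytest.approx(0.0)
        assert (res.overlap["only_a"] == 0).all()

    def test_assignment_is_globally_minimal(self):
        a = fit(archetype_cluster_config(n_proteins=300, noise=0.3, seed=8))[2]
        b = fit(archetype_cluster_config(n_proteins=300, noise=0.3, seed=9))[2]
        res = tb.match_clusters(a, b)
        assert res.total_distance == pytest.approx(brute_force_match_distance(a, b))

    def test_k_mismatch_rejected(self, model):
        other = tb.ClusterModel(
            k=4, centroids=model.centroids[:4],
            assignments=model.assignments[model.assignments < 4],
        )
        with pytest.raises(ClusteringError, match="mismatch"):
            tb.match_clusters(model, other)

    def test_planted_archetype_swap_counted_in_overlap(self):
        # Same condition clustered twice on data where 10% of proteins swap
        # archetype between two generative runs: shared counts must match the
        # planted ledger.
        cfg_a = archetype_cluster_config(n_proteins=500, noise=0.0, seed=21)
        truth_a, matrices_a, design = tb.simulate(cfg_a)
        swapped = truth_a.copy()
        members = sorted(swapped.index[swapped["archetype"] == "down_steady"])
        moved = members[: len(members) // 2]
        swapped.loc[moved, "archetype"] = "early_jump"
        swapped.loc[moved, "base_log2"] = 12.0
        for col, vals in zip(
            ("offset_M", "offset_EM", "offset_LM"), (0.0, 2.0, 2.0)
        ):
            swapped.loc[moved, col] = vals
        matrices_b, _ = tb.simulate_multiplexes(swapped, cfg_a)

        models = []
        for truth, matrices in ((truth_a, matrices_a), (swapped, matrices_b)):
            bridged = tb.normalize(matrices, design)
            traj = tb.build_trajectories(bridged, planted_nonflat(truth), "untreated")
            models.append(tb.kmeans_cluster(traj, k=5, seed=17, n_restarts=50))
        res = tb.match_clusters(*models)
        down_label = models[0].assignments[members[-1]]
        row = res.overlap[res.overlap["cluster_a"] == down_label].iloc[0]
        assert row["shared"] == len(members) - len(moved)
        assert row["only_a"] == len(moved)
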