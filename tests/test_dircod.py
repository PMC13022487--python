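import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from protoseg import (
    SyntheticConfig,
    assign_by_pattern,
    detect_communities,
    generate_cohort,
    impute_knn,
    iterate_dircod,
    select_differential_proteins,
)
from protoseg.containers import NOISE
from protoseg.dircod import CommunityHistory

from conftest import make_matrix


class TestImputeKnn:
    def test_identity_on_complete_matrix(self, rng):
        m = make_matrix(rng.normal(size=(30, 5)))
        out = impute_knn(m)
        np.testing.assert_array_equal(out.values, m.values)

    def test_constant_neighborhood_imputes_constant(self, rng):
        # everyone identical on P0 except the focal row; P1 separates rows
        values = np.full((40, 2), 2.0)
        values[:, 1] = rng.normal(size=40) * 0.01
        mask = np.ones((40, 2), dtype=bool)
        mask[0, 0] = False
        m = make_matrix(values, mask)
        out = impute_knn(m, n_neighbors=15)
        assert out.values[0, 0] == pytest.approx(2.0)
        assert out.mask.all()

    def test_observed_entries_unchanged(self, rng):
        values = rng.normal(size=(50, 6))
        mask = rng.random((50, 6)) > 0.1
        m = make_matrix(values, mask)
        out = impute_knn(m)
        np.testing.assert_array_equal(out.values[m.mask], values[m.mask])

    def test_underobserved_protein_is_error(self, rng):
        values = rng.normal(size=(20, 2))
        mask = np.ones((20, 2), dtype=bool)
        mask[:10, 0] = False  # only 10 observed < 15 neighbours
        with pytest.raises(ValueError, match="P0"):
            impute_knn(make_matrix(values, mask), n_neighbors=15)

    def test_beats_column_mean_on_low_rank_data(self, rng):
        # rank-1 + noise: neighbours carry signal a column mean cannot
        n, p = 500, 50
        z = rng.normal(size=n)
        w = rng.normal(size=p)
        truth = np.outer(z, w) + 0.3 * rng.normal(size=(n, p))
        mask = rng.random((n, p)) > 0.1
        m = make_matrix(truth, mask)
        out = impute_knn(m)
        holdout = ~mask
        rmse_knn = np.sqrt(np.mean((out.values[holdout] - truth[holdout]) ** 2))
        col_mean = np.nanmean(m.values, axis=0)
        mean_filled = np.broadcast_to(col_mean, truth.shape)
        rmse_mean = np.sqrt(np.mean((mean_filled[holdout] - truth[holdout]) ** 2))
        assert rmse_knn < rmse_mean


def two_blob_matrix(rng, n=600, p=20, shift=6.0):
    values = rng.normal(size=(n, p))
    values[: n // 2, : p // 2] += shift
    truth = np.r_[np.zeros(n // 2), np.ones(n // 2)]
    return make_matrix(values), truth


class TestDetectCommunities:
    def test_two_blobs_recovered(self, rng):
        m, truth = two_blob_matrix(rng)
        comm = detect_communities(m, seed=4)
        labels = [comm[p] for p in m.participant_ids]
        assert len(set(labels)) == 2
        assert adjusted_rand_score(truth, labels) >= 0.95

    def test_fixed_seed_is_deterministic(self, rng):
        m, _ = two_blob_matrix(rng, n=200)
        c1 = detect_communities(m, seed=9)
        c2 = detect_communities(m, seed=9)
        assert c1 == c2

    def test_empty_selection_is_error(self, rng):
        m, _ = two_blob_matrix(rng, n=100)
        with pytest.raises(ValueError):
            detect_communities(m, selected=[])

    def test_tiny_cohort_degenerates_to_single_community(self, rng):
        m = make_matrix(rng.normal(size=(8, 4)))
        comm = detect_communities(m, k=15)
        assert set(comm.values()) == {0}


class TestSelectDifferentialProteins:
    def test_shifted_protein_selected(self, rng):
        n = 3000
        values = rng.normal(size=(n, 5))
        comm = {f"S{i}": (1 if i < 500 else 0) for i in range(n)}
        values[:500, 2] += 3.0
        m = make_matrix(values)
        got = select_differential_proteins(m, comm)
        assert "P2" in got

    def test_null_family_wise_selection_rate(self, rng):
        # i.i.d. data: Bonferroni keeps the family-wise selection rate <= alpha
        hits = 0
        reps = 40
        for r in range(reps):
            values = rng.normal(size=(300, 20))
            comm = {f"S{i}": i % 3 for i in range(300)}
            m = make_matrix(values)
            if select_differential_proteins(m, comm, alpha=0.05):
                hits += 1
        assert hits / reps <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / reps)

    def test_selection_ignores_masked_cells(self, rng):
        # observed values identical across communities; only the *pattern*
        # of missingness differs -> must not be selected
        n = 400
        values = np.tile(rng.normal(size=(n, 1)), (1, 2))
        rng.shuffle(values[:, 1])
        mask = np.ones((n, 2), dtype=bool)
        mask[:100, 1] = False  # community 1 heavily missing on P1
        comm = {f"S{i}": (1 if i < 200 else 0) for i in range(n)}
        m = make_matrix(values, mask)
        assert select_differential_proteins(m, comm) == []

    def test_small_community_pairs_skipped(self, rng):
        values = rng.normal(size=(50, 3))
        comm = {f"S{i}": (1 if i < 5 else 0) for i in range(50)}
        m = make_matrix(values)
        # community 1 has < 20 observations: nothing selected from it
        assert select_differential_proteins(m, comm) == []


class TestIterateDircod:
    def test_t1_uses_all_proteins(self, rng):
        m, _ = two_blob_matrix(rng, n=100)
        hist = iterate_dircod(m, m, T=1, seed=0)
        assert len(hist) == 1
        assert hist[0].selected_proteins == m.protein_ids

    def test_same_seed_identical_history(self, rng):
        m, _ = two_blob_matrix(rng, n=300)
        h1 = iterate_dircod(m, m, T=3, seed=5)
        h2 = iterate_dircod(m, m, T=3, seed=5)
        assert [h.selected_proteins for h in h1] == [h.selected_proteins for h in h2]
        assert [h.community_of for h in h1] == [h.community_of for h in h2]

    def test_signal_proteins_retained(self, rng):
        # 10 of 40 proteins carry all the signal: selection stabilizes to
        # a superset of them within a few iterations
        n = 1000
        values = rng.normal(size=(n, 40))
        values[: n // 2, :10] += 4.0
        m = make_matrix(values)
        hist = iterate_dircod(m, m, T=5, seed=2)
        signal = {f"P{j}" for j in range(10)}
        assert signal <= set(hist[-1].selected_proteins)

    def test_protein_subsets_nest_into_full_set(self, rng):
        m, _ = two_blob_matrix(rng, n=300)
        hist = iterate_dircod(m, m, T=4, seed=1)
        full = set(m.protein_ids)
        for h in hist:
            assert set(h.selected_proteins) <= full


class TestAssignByPattern:
    def history_from(self, label_rows):
        """label_rows[t][i] = community of participant i at iteration t."""
        T = len(label_rows)
        n = len(label_rows[0])
        return [
            CommunityHistory(
                t + 1,
                ["P0"],
                {f"S{i}": label_rows[t][i] for i in range(n)},
            )
            for t in range(T)
        ]

    def test_identical_patterns_share_cluster(self):
        hist = self.history_from([[0, 0, 1, 1]] * 5)
        got = assign_by_pattern(hist, min_cluster_size=1)
        assert got.labels["S0"] == got.labels["S1"]
        assert got.labels["S2"] == got.labels["S3"]
        assert got.labels["S0"] != got.labels["S2"]

    def test_never_coassigned_split(self):
        hist = self.history_from([[0, 1], [0, 1], [1, 0]])
        got = assign_by_pattern(hist, min_cluster_size=1)
        assert got.labels["S0"] != got.labels["S1"]

    def test_small_components_become_noise(self):
        hist = self.history_from([[0] * 10 + [1]] * 3)
        got = assign_by_pattern(hist, min_cluster_size=5)
        assert got.labels["S10"] == NOISE
        assert len(got.cluster_ids) == 1

    def test_threshold_tolerates_label_churn(self):
        # one deviant iteration in ten: co-assignment 0.9 still links
        rows = [[0, 0, 1, 1]] * 9 + [[0, 2, 1, 1]]
        got = assign_by_pattern(self.history_from(rows), min_cluster_size=1,
                                pattern_threshold=0.9)
        assert got.labels["S0"] == got.labels["S1"]

    def test_planted_clusters_recovered(self, rng):
        cfg = SyntheticConfig(
            n_participants=900, n_proteins=45, n_clusters=3,
            shift_proteins_per_cluster=15, shift_magnitude=3.0, seed=17,
        )
        m, _, truth = generate_cohort(cfg)
        hist = iterate_dircod(m, m, T=5, seed=3)
        got = assign_by_pattern(hist, min_cluster_size=50)
        true = [truth[p] for p in m.participant_ids]
        pred = list(got.label_vector(m.participant_ids))
        assert len(got.cluster_ids) == 3
        assert adjusted_rand_score(true, pred) >= 0.9

    def test_empty_history_is_error(self):
        with pytest.raises(ValueError):
            assign_by_pattern([])
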