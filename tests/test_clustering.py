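import numpy as np
import pandas as pd
import pytest

from copulamri import (
    FEATURE_NAMES,
    ConsensusMatrix,
    cluster_consensus_means,
    hierarchical_cluster,
    loocv_consensus,
    select_k,
    standardize_features,
)


def blob_table(n_blobs, per_blob=20, sep=30.0, spread=0.5, seed=0):
    """Tight, well-separated feature blobs: within-spread << between-distance."""
    rng = np.random.default_rng(seed)
    centers = rng.normal(0, sep, size=(n_blobs, 9))
    rows = np.vstack([c + rng.normal(0, spread, size=(per_blob, 9)) for c in centers])
    ids = [f"P{i:03d}" for i in range(n_blobs * per_blob)]
    truth = np.repeat(np.arange(n_blobs), per_blob)
    return (
        pd.DataFrame(rows, index=pd.Index(ids, name="patient_id"),
                     columns=list(FEATURE_NAMES)),
        truth,
    )


def labels_agree(a, b):
    """Exact agreement up to relabeling."""
    a, b = np.asarray(a), np.asarray(b)
    mapping = {}
    for x, y in zip(a, b):
        if mapping.setdefault(x, y) != y:
            return False
    return len(set(mapping.values())) == len(mapping)


class TestStandardize:
    def test_zero_mean_unit_variance(self, rng):
        t = pd.DataFrame(rng.normal(5, 3, size=(20, 9)), columns=list(FEATURE_NAMES))
        z = standardize_features(t)
        np.testing.assert_allclose(z.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(z.std(axis=0, ddof=0), 1, atol=1e-12)

    def test_constant_column_zeroed(self, rng):
        t = pd.DataFrame(rng.normal(size=(10, 9)), columns=list(FEATURE_NAMES))
        t["variance"] = 8.25
        z = standardize_features(t)
        assert (z["variance"] == 0).all()

    def test_machine_noise_column_treated_as_constant(self, rng):
        # constant up to float rounding must not be inflated to unit variance
        t = pd.DataFrame(rng.normal(size=(10, 9)), columns=list(FEATURE_NAMES))
        t["sum_average"] = 11.0 + rng.normal(0, 1e-15, size=10)
        z = standardize_features(t)
        assert (z["sum_average"] == 0).all()

    def test_idempotent(self, rng):
        t = pd.DataFrame(rng.normal(5, 3, size=(20, 9)), columns=list(FEATURE_NAMES))
        once = standardize_features(t)
        pd.testing.assert_frame_equal(standardize_features(once), once, atol=1e-12)


class TestHierarchicalCluster:
    def test_recovers_three_blobs_exactly(self):
        table, truth = blob_table(3)
        assign = hierarchical_cluster(table, k=3)
        assert labels_agree(truth, assign.labels)

    def test_k_equal_n_minus_one_gives_single_pair(self, rng):
        t = pd.DataFrame(rng.normal(size=(10, 9)), columns=list(FEATURE_NAMES))
        assign = hierarchical_cluster(t, k=9)
        sizes = sorted(np.bincount(assign.labels)[1:])
        assert sizes == [1] * 8 + [2]

    def test_duplicated_rows_co_cluster(self, rng):
        t = pd.DataFrame(rng.normal(size=(8, 9)), columns=list(FEATURE_NAMES))
        doubled = pd.concat([t, t]).set_axis([f"P{i}" for i in range(16)])
        assign = hierarchical_cluster(doubled, k=5)
        for i in range(8):
            assert assign.labels[i] == assign.labels[i + 8]

    def test_order_invariance(self):
        table, _ = blob_table(3)
        shuffled = table.sample(frac=1.0, random_state=1)
        a = hierarchical_cluster(table, k=3)
        b = hierarchical_cluster(shuffled, k=3)
        sa = pd.Series(a.labels, index=a.patient_ids)
        sb = pd.Series(b.labels, index=b.patient_ids)
        assert labels_agree(sa.sort_index().to_numpy(), sb.sort_index().to_numpy())

    def test_k_out_of_range(self):
        table, _ = blob_table(2, per_blob=3)
        with pytest.raises(ValueError, match="out of range"):
            hierarchical_cluster(table, k=6)


class TestSelectK:
    @pytest.mark.parametrize("n_blobs", [2, 3])
    def test_blob_tables_voted_correctly(self, n_blobs):
        for seed in range(5):
            table, _ = blob_table(n_blobs, seed=seed)
            k, votes = select_k(table)
            assert k == n_blobs, votes

    def test_vote_table_bookkeeping(self):
        table, _ = blob_table(3)
        k, votes = select_k(table)
        assert all(2 <= v <= 10 for v in votes.values())
        assert len(votes) >= 10

    def test_noise_returns_some_k_in_range(self, rng):
        t = pd.DataFrame(rng.normal(size=(30, 9)), columns=list(FEATURE_NAMES))
        k, _ = select_k(t)
        assert 2 <= k <= 10

    def test_k_max_capped_by_cohort(self):
        table, _ = blob_table(2, per_blob=4)
        with pytest.raises(ValueError, match="k_max"):
            select_k(table, k_max=10)


class TestLoocvConsensus:
    def test_blockwise_exact_for_separable_blobs(self):
        table, truth = blob_table(3, per_blob=10)
        cm = loocv_consensus(table, k=3)
        same = truth[:, None] == truth[None, :]
        np.testing.assert_array_equal(cm.m[same], 1.0)
        np.testing.assert_array_equal(cm.m[~same], 0.0)

    def test_symmetry_and_unit_diagonal(self, rng):
        t = pd.DataFrame(rng.normal(size=(12, 9)), columns=list(FEATURE_NAMES))
        cm = loocv_consensus(t, k=3)
        np.testing.assert_array_equal(cm.m, cm.m.T)
        np.testing.assert_array_equal(np.diag(cm.m), 1.0)

    def test_co_presence_is_n_minus_two(self, rng):
        t = pd.DataFrame(rng.normal(size=(12, 9)), columns=list(FEATURE_NAMES))
        cm = loocv_consensus(t, k=2)
        off = ~np.eye(12, dtype=bool)
        assert (cm.co_presence[off] == 10).all()

    def test_too_small_cohort_rejected(self, rng):
        t = pd.DataFrame(rng.normal(size=(3, 9)), columns=list(FEATURE_NAMES))
        with pytest.raises(ValueError, match="at least 4"):
            loocv_consensus(t, k=2)


class TestClusterConsensusMeans:
    def test_all_ones_consensus(self):
        n = 6
        cm = ConsensusMatrix(patient_ids=[str(i) for i in range(n)],
                             m=np.ones((n, n)), co_presence=np.full((n, n), n - 2))
        means = cluster_consensus_means(cm, [1, 1, 1, 2, 2, 2])
        assert means == {1: 1.0, 2: 1.0}

    def test_hand_built_two_cluster_matrix(self):
        m = np.eye(4)
        m[0, 1] = m[1, 0] = 0.8
        m[2, 3] = m[3, 2] = 0.4
        m[0, 2] = m[2, 0] = 0.1
        cm = ConsensusMatrix(patient_ids=list("abcd"), m=m,
                             co_presence=np.full((4, 4), 2))
        means = cluster_consensus_means(cm, [1, 1, 2, 2])
        assert means[1] == pytest.approx(0.8)
        assert means[2] == pytest.approx(0.4)

    def test_singleton_cluster_reported_missing(self):
        cm = ConsensusMatrix(patient_ids=list("abc"), m=np.eye(3),
                             co_presence=np.ones((3, 3), dtype=int))
        means = cluster_consensus_means(cm, [1, 1, 2])
        assert np.isnan(means[2])
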