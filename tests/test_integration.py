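import numpy as np
import pytest

import mvda
from mvda import ValidationError
from mvda.patients import Membership
from mvda.integration import (
    generalized_kl,
    gli_integrate,
    mf_integrate,
    stack_memberships,
    view_contributions,
)


def _pids(n):
    return [f"p{i:03d}" for i in range(n)]


def _membership(partition, pids, name):
    return Membership.from_partition(np.asarray(partition), pids, name)


def _mono(history, scale=None):
    h = np.asarray(history)
    tol = 1e-8 * max(1.0, scale if scale is not None else h[0])
    return np.all(np.diff(h) <= tol)


class TestStackMemberships:
    def test_shapes_and_column_sums(self):
        pids = _pids(10)
        m1 = _membership(np.arange(10) % 3, pids, "v1")
        m2 = _membership(np.arange(10) % 4, pids, "v2")
        st = stack_memberships([m1, m2])
        assert st.X.shape == (7, 10)
        np.testing.assert_array_equal(st.X.sum(axis=0), 2.0)
        assert st.row_view.tolist() == [0] * 3 + [1] * 4

    def test_prior_counts_as_one_more_view(self):
        pids = _pids(10)
        m1 = _membership(np.arange(10) % 3, pids, "v1")
        m2 = _membership(np.arange(10) % 4, pids, "v2")
        prior = _membership(np.arange(10) % 4, pids, "prior")
        st = stack_memberships([m1, m2], prior=prior)
        assert st.X.shape == (11, 10)
        np.testing.assert_array_equal(st.X.sum(axis=0), 3.0)

    def test_single_view_is_transpose(self):
        pids = _pids(6)
        m = _membership([0, 0, 1, 1, 2, 2], pids, "v")
        st = stack_memberships([m])
        np.testing.assert_array_equal(st.X, m.matrix.T)

    def test_patient_mismatch_rejected(self):
        m1 = _membership([0, 1], ["a", "b"], "v1")
        m2 = _membership([0, 1], ["b", "c"], "v2")
        with pytest.raises(ValidationError, match="patient"):
            stack_memberships([m1, m2])


class TestMFIntegrate:
    def test_rank_one_matrix_factored_exactly(self):
        pids = _pids(8)
        m = Membership("v", np.ones((8, 1), dtype=int), pids, ["c"])
        st = stack_memberships([m])
        meta = mf_integrate(st, 1, seed=0)
        assert meta.objective_history[-1] < 1e-6

    def test_identical_views_recover_partition(self):
        pids = _pids(200)
        part = np.repeat(np.arange(3), [70, 70, 60])
        ms = [_membership(part, pids, f"v{j}") for j in range(2)]
        meta = mf_integrate(stack_memberships(ms), [3], seed=0)
        assert mvda.nmi(meta.partition, part) == pytest.approx(1.0)

    def test_objective_non_increasing(self):
        rng = np.random.default_rng(0)
        pids = _pids(50)
        ms = [
            _membership(rng.integers(0, 4, 50), pids, f"v{j}") for j in range(3)
        ]
        meta = mf_integrate(stack_memberships(ms), [2, 3, 4], seed=1)
        assert _mono(meta.objective_history)

    def test_matches_sklearn_nmf_objective(self):
        """Independent cross-check: our multiplicative updates reach a
        reconstruction error comparable to sklearn's NMF."""
        from sklearn.decomposition import NMF

        rng = np.random.default_rng(2)
        pids = _pids(60)
        ms = [
            _membership(rng.integers(0, 3, 60), pids, f"v{j}") for j in range(2)
        ]
        st = stack_memberships(ms)
        meta = mf_integrate(st, [3], seed=0)
        sk = NMF(n_components=3, init="random", random_state=0, max_iter=1000)
        w = sk.fit_transform(st.X)
        sk_err = np.linalg.norm(st.X - w @ sk.components_) ** 2
        assert meta.objective_history[-1] <= sk_err * 1.05 + 1e-9

    def test_permuting_patients_permutes_partition(self):
        rng = np.random.default_rng(3)
        n = 40
        pids = _pids(n)
        part = rng.integers(0, 3, n)
        ms = [_membership(part, pids, f"v{j}") for j in range(2)]
        meta = mf_integrate(stack_memberships(ms), [3], seed=5)
        perm = rng.permutation(n)
        ms_p = [
            Membership("v%d" % j, m.matrix[perm], [pids[i] for i in perm], m.cluster_ids)
            for j, m in enumerate(ms)
        ]
        meta_p = mf_integrate(stack_memberships(ms_p), [3], seed=5)
        assert mvda.nmi(meta.partition[perm], meta_p.partition) == pytest.approx(1.0)


class TestGLIIntegrate:
    def test_generalized_kl_of_x_with_itself_is_zero(self):
        x = np.random.default_rng(4).random((5, 7))
        assert generalized_kl(x, x) == pytest.approx(0.0, abs=1e-12)

    def test_zero_divergence_fixed_point(self):
        pids = _pids(90)
        part = np.repeat(np.arange(3), 30)
        ms = [_membership(part, pids, f"v{j}") for j in range(2)]
        meta = gli_integrate(stack_memberships(ms), 3, seed=0)
        assert meta.objective_history[-1] < 1e-6
        assert mvda.nmi(meta.partition, part) == pytest.approx(1.0)

    def test_best_so_far_objective_non_increasing(self):
        rng = np.random.default_rng(5)
        pids = _pids(60)
        ms = [
            _membership(rng.integers(0, 4, 60), pids, f"v{j}") for j in range(3)
        ]
        meta = gli_integrate(stack_memberships(ms), 4, seed=2)
        assert np.all(np.diff(meta.objective_history) <= 0)

    def test_row_stochastic_consensus(self):
        pids = _pids(30)
        ms = [_membership(np.arange(30) % 3, pids, "v")]
        meta = gli_integrate(stack_memberships(ms), 3, seed=0)
        np.testing.assert_allclose(meta.H_or_B.sum(axis=1), 1.0, atol=1e-8)

    def test_k_above_total_clusters_rejected(self):
        pids = _pids(10)
        ms = [_membership(np.arange(10) % 2, pids, "v")]
        with pytest.raises(ValidationError):
            gli_integrate(stack_memberships(ms), 5, seed=0)


class TestViewContributions:
    def test_exclusive_view_column_is_one(self):
        p = np.array([[0.0, 1.0], [0.0, 0.5], [2.0, 0.0]])
        t = view_contributions(p, np.array([0, 0, 1]), ["a", "b"])
        assert t.loc["b", t.columns[0]] == pytest.approx(1.0)
        np.testing.assert_allclose(t.sum(axis=0), 1.0)

    def test_symmetric_mass_splits_evenly(self):
        p = np.array([[1.0], [1.0]])
        t = view_contributions(p, np.array([0, 1]), ["a", "b"])
        np.testing.assert_allclose(t.to_numpy(), [[0.5], [0.5]])

    def test_zero_column_uniform_with_warning(self):
        p = np.array([[1.0, 0.0], [1.0, 0.0]])
        with pytest.warns(RuntimeWarning, match="all-zero"):
            t = view_contributions(p, np.array([0, 1]), ["a", "b"])
        np.testing.assert_allclose(t.iloc[:, 1], [0.5, 0.5])

    def test_negative_p_rejected(self):
        with pytest.raises(ValidationError):
            view_contributions(np.array([[-1.0]]), np.array([0]), ["a"])


class TestIntegrateDispatch:
    def test_mf_and_gli_agree_on_identical_views(self, small_dataset):
        pids = _pids(120)
        part = np.repeat(np.arange(4), 30)
        dataset, _ = small_dataset
        ms = [_membership(part, dataset.patient_ids, f"v{j}") for j in range(2)]
        mf = mvda.integrate(dataset, ms, method="MF", k_range=[4], seed=0)
        gli = mvda.integrate(dataset, ms, method="GLI", k_range=[4], seed=0)
        assert mvda.nmi(mf.partition, gli.partition) == pytest.approx(1.0)

    def test_semi_supervised_requires_labels(self, small_dataset):
        dataset, _ = small_dataset
        unlabeled = mvda.MultiViewDataset(views=dataset.views, labels=None)
        m = _membership(np.arange(120) % 4, dataset.patient_ids, "v")
        meta = mvda.integrate(unlabeled, [m], method="MF", k_range=[4], seed=0)
        assert meta.mode == "unsupervised"
        with pytest.raises(ValidationError, match="labels"):
            mvda.integrate(unlabeled, [m], method="MF", mode="semi_supervised")

    def test_semi_supervised_reduces_impurity(self, small_dataset):
        dataset, truth = small_dataset
        wins = 0
        for seed in range(5):
            ms = [
                mvda.cluster_patients(v, "kmeans", 4, seed=seed)
                for v in dataset.views
            ]
            unsup = mvda.integrate(dataset, ms, method="MF", k_range=[4], seed=seed)
            semi = mvda.integrate(
                dataset, ms, method="MF", mode="semi_supervised", k_range=[4], seed=seed
            )
            iu = mvda.impurity(unsup.partition, dataset.labels.labels)
            is_ = mvda.impurity(semi.partition, dataset.labels.labels)
            wins += is_ <= iu
        assert wins >= 4
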