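"""DAPC, admixture sampler, replicate alignment and Evanno delta-K."""

import numpy as np
import pytest

from popgenkit import (
    SimParams,
    admixture_fit,
    align_q_matrices,
    dapc_find_clusters,
    dapc_fit,
    evanno_delta_k,
    simulate_dataset,
)
from popgenkit.core import ValidationError

from conftest import make_table


def _accuracy(assignment, truth_labels):
    """Best label-permutation agreement between two hard clusterings."""
    from itertools import permutations

    labels = sorted(set(truth_labels))
    best = 0.0
    assigned = np.asarray(assignment)
    truth = np.asarray(truth_labels)
    for perm in permutations(sorted(set(assigned))):
        mapping = dict(zip(perm, labels))
        acc = np.mean([mapping.get(a) == t for a, t in zip(assigned, truth)])
        best = max(best, acc)
    return best


class TestDapc:
    def test_bic_selects_three_clusters(self, study_dataset):
        table, _, _ = study_dataset
        bic = dapc_find_clusters(table, range(1, 7), n_pcs=40, seed=0)
        assert int(bic.idxmin()) == 3

    def test_panmictic_selects_one(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0.2, 0.8, 300)
        geno = (
            (rng.random((300, 60)) < p[:, None]).astype(int)
            + (rng.random((300, 60)) < p[:, None])
        ).astype(np.int8)
        bic = dapc_find_clusters(make_table(geno), range(1, 6), n_pcs=30, seed=0)
        assert int(bic.idxmin()) == 1

    def test_degenerate_k_equals_n_guarded(self):
        rng = np.random.default_rng(0)
        geno = rng.integers(0, 3, (50, 6)).astype(np.int8)
        bic = dapc_find_clusters(make_table(geno), [6], n_pcs=4, seed=0)
        assert np.isfinite(bic.loc[6])

    def test_fixed_difference_assignment_certain(self):
        geno = np.array([[0] * 6 + [2] * 6] * 30, dtype=np.int8)
        t = make_table(geno)
        fit = dapc_fit(t, 2, n_pcs=5, seed=0)
        labels = fit.assignment.to_numpy()
        assert len(set(labels[:6])) == 1 and len(set(labels[6:])) == 1
        assert labels[0] != labels[6]
        assert fit.memberships.to_numpy().max(axis=1).min() > 0.99

    def test_study_design_cluster_sizes(self, study_dataset):
        table, frame, _ = study_dataset
        fit = dapc_fit(table, 3, n_pcs=40, seed=0)
        acc = _accuracy(fit.assignment, frame.frame["cluster_id"])
        assert acc >= 0.95
        assert sorted(fit.cluster_sizes().tolist()) == [10, 28, 51]

    def test_invariance_to_locus_permutation_and_dosage_flip(self, study_dataset):
        table, _, _ = study_dataset
        sub = table.subset_loci(np.arange(200))
        base = dapc_fit(sub, 3, n_pcs=20, seed=0).assignment

        rng = np.random.default_rng(0)
        perm = rng.permutation(200)
        loci = sub.loci.iloc[perm].copy()
        # restore valid per-contig position ordering after the row shuffle
        order = np.lexsort((loci["pos"].to_numpy(), loci["contig"].to_numpy()))
        shuffled = sub.subset_loci(perm[order])
        assert (dapc_fit(shuffled, 3, n_pcs=20, seed=0).assignment == base).all()

        flipped = sub.copy()
        flip = rng.random(200) < 0.5
        g = flipped.genotypes
        rows = np.flatnonzero(flip)
        mask = g[rows] != -1
        g[rows] = np.where(mask, 2 - g[rows], g[rows])
        assert (dapc_fit(flipped, 3, n_pcs=20, seed=0).assignment == base).all()


class TestAdmixture:
    def test_fixed_difference_q_sharp(self):
        geno = np.array([[0] * 8 + [2] * 8] * 40, dtype=np.int8)
        t = make_table(geno)
        res = admixture_fit(t, 2, burn_in=200, n_iter=800, n_reps=2, seed=0)
        q = res.q_consensus.to_numpy()
        own = np.concatenate([q[:8].max(axis=1), q[8:].max(axis=1)])
        assert (own >= 0.95).all()

    def test_panmictic_q_symmetric(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(0.3, 0.7, 200)
        geno = (
            (rng.random((200, 30)) < p[:, None]).astype(int)
            + (rng.random((200, 30)) < p[:, None])
        ).astype(np.int8)
        t = make_table(geno)
        res = admixture_fit(t, 2, burn_in=300, n_iter=1200, n_reps=3, seed=1)
        q = res.q_consensus.to_numpy()
        assert np.abs(q - 0.5).mean() < 0.1
        assert np.abs(q - 0.5).max() < 0.25

    def test_rows_sum_to_one_and_loglik_finite(self, study_dataset):
        table, _, _ = study_dataset
        sub = table.subset_loci(np.arange(100))
        res = admixture_fit(sub, 3, burn_in=100, n_iter=400, n_reps=2, seed=2)
        for qrep in res.q_replicates:
            np.testing.assert_allclose(qrep.to_numpy().sum(axis=1), 1.0, atol=1e-9)
        assert all(np.isfinite(res.loglik))
        assert all(np.isfinite(tr).all() for tr in res.loglik_traces)

    def test_k1_supported(self):
        t = make_table(np.array([[0, 1, 2, 1]] * 20, dtype=np.int8))
        res = admixture_fit(t, 1, burn_in=50, n_iter=200, n_reps=2, seed=0)
        np.testing.assert_allclose(res.q_consensus.to_numpy(), 1.0)
        assert np.isfinite(res.loglik[0])

    def test_intermediate_population_splits_assignment(self):
        # two source clusters plus an intermediate one: at K=2 the
        # intermediate group lands near 50/50
        rng = np.random.default_rng(8)
        L = 300
        p1 = rng.uniform(0.05, 0.95, L)
        p2 = 1.0 - p1
        pm = 0.5 * (p1 + p2)

        def draw(p, n):
            return (
                (rng.random((L, n)) < p[:, None]).astype(int)
                + (rng.random((L, n)) < p[:, None])
            ).astype(np.int8)

        geno = np.hstack([draw(p1, 12), draw(p2, 12), draw(pm, 8)])
        t = make_table(geno)
        res = admixture_fit(t, 2, burn_in=300, n_iter=1200, n_reps=2, seed=3)
        q_mid = res.q_consensus.to_numpy()[24:]
        assert np.abs(q_mid - 0.5).mean() < 0.15


class TestAlignment:
    def test_alignment_recovers_permutation(self):
        rng = np.random.default_rng(0)
        q = rng.dirichlet(np.ones(3), size=30)
        perm = [2, 0, 1]
        aligned = align_q_matrices([q, q[:, perm]])
        np.testing.assert_allclose(aligned[1], q, atol=1e-12)

    def test_idempotent_and_not_worse(self):
        rng = np.random.default_rng(1)
        qs = [rng.dirichlet(np.ones(3), size=20) for _ in range(3)]
        aligned = align_q_matrices(qs)
        again = align_q_matrices(aligned)
        for x, y in zip(aligned, again):
            np.testing.assert_allclose(x, y)
        score = lambda mats: sum(float((mats[0] * m).sum()) for m in mats[1:])
        assert score(aligned) >= score(qs) - 1e-12


class TestEvanno:
    def test_hand_arithmetic(self):
        d = 2.5 * np.sqrt(2.0)
        lls = {1: [-1000.0, -1000.0], 2: [-900.0 - d, -900.0 + d], 3: [-890.0, -890.0]}
        delta = evanno_delta_k(lls)
        assert list(delta.index) == [2]
        assert delta.loc[2] == pytest.approx(18.0)

    def test_linear_loglik_gives_zero(self):
        lls = {k: [-1000.0 + 50 * k + eps for eps in (-1.0, 1.0)] for k in range(1, 5)}
        delta = evanno_delta_k(lls)
        np.testing.assert_allclose(delta.to_numpy(), 0.0, atol=1e-9)

    def test_interior_k_only(self):
        lls = {k: [float(-k), float(-k - 1)] for k in range(1, 5)}
        delta = evanno_delta_k(lls)
        assert list(delta.index) == [2, 3]

    def test_zero_sd_is_error(self):
        lls = {1: [-10.0, -10.0], 2: [-5.0, -5.0], 3: [-4.0, -4.0]}
        with pytest.raises(ValidationError):
            evanno_delta_k(lls)

    def test_nonconsecutive_scan_rejected(self):
        lls = {1: [-10.0, -9.0], 3: [-5.0, -4.0], 5: [-4.0, -3.0]}
        with pytest.raises(ValidationError):
            evanno_delta_k(lls)
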