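import numpy as np
import pytest

import descnet as dn
from descnet._glasso import glasso
from descnet._utils import spearman_corr
from descnet.network import (
    EDGE_EPS,
    SnmSettings,
    detect_communities,
    fit_snm,
    implied_correlation_snm,
    partials_from_precision,
    strength_centrality,
    temporal_centrality_dynamics,
)
from descnet.textprep import CorrelationStructure


def _corr(M, n=500):
    return CorrelationStructure(
        words=[f"w{i}" for i in range(M.shape[0])],
        matrix=np.asarray(M, float), n_effective=n,
    )


class TestGlassoKernel:
    """The in-package path solver against sklearn's reference solver."""

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_sklearn(self, seed):
        from sklearn.covariance import graphical_lasso

        rng = np.random.default_rng(seed)
        X = rng.standard_normal((150, 12))
        X[:, 1] += 0.8 * X[:, 0]
        X[:, 5] -= 0.6 * X[:, 4]
        S = np.corrcoef(X, rowvar=False)
        for lam in (0.3, 0.1, 0.03):
            K_ref = graphical_lasso(S, alpha=lam, tol=1e-8, max_iter=800)[1]
            K_ours = glasso(S, lam, tol=1e-8, max_iter=800)
            assert np.max(np.abs(K_ours - K_ref)) < 1e-3
            iu = np.triu_indices(12, 1)
            assert np.array_equal(np.abs(K_ours[iu]) > 1e-6,
                                  np.abs(K_ref[iu]) > 1e-6)


class TestFitSnm:
    def test_lambda_max_gives_empty_network(self):
        M = np.eye(4)
        M[0, 1] = M[1, 0] = 0.3
        sol = fit_snm(_corr(M), n=100,
                      settings=SnmSettings(n_lambdas=1, refit=False))
        assert sol.edge_count == 0
        assert np.all(sol.partials == 0)

    def test_small_lambda_matches_partial_correlation_formula(self):
        r12, r13, r23 = 0.5, 0.3, 0.4
        M = np.array([[1, r12, r13], [r12, 1, r23], [r13, r23, 1.0]])
        K = glasso(M, 1e-7)
        P = partials_from_precision(K)
        expect = (r12 - r13 * r23) / np.sqrt((1 - r13**2) * (1 - r23**2))
        assert P[0, 1] == pytest.approx(expect, abs=1e-3)

    def test_chain_support_recovery(self):
        struct = dn.chain_precision(3, 0.4)
        A = np.linalg.cholesky(struct.latent_correlation())
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((2000, 3)) @ A.T
            sol = fit_snm(_corr(spearman_corr(X), n=2000), n=2000)
            iu = np.triu_indices(3, 1)
            support = {(i, j) for i, j in zip(*np.triu_indices(3, 1))
                       if abs(sol.partials[i, j]) > EDGE_EPS}
            hits += support == {(0, 1), (1, 2)}
        assert hits >= 45  # >= 90% of seeds

    def test_edge_count_monotone_in_lambda(self, rng):
        X = rng.standard_normal((200, 10))
        X[:, 1] += X[:, 0]
        M = spearman_corr(X)
        lams = np.geomspace(np.abs(M - np.eye(10)).max(), 0.01, 12)
        counts = []
        for lam in lams:
            K = glasso(M, lam)
            iu = np.triu_indices(10, 1)
            counts.append(int(np.sum(np.abs(K[iu]) > EDGE_EPS)))
        assert all(b >= a for a, b in zip(counts, counts[1:]))

    def test_sign_agreement_with_truth(self):
        struct = dn.random_sparse_precision(30, density=0.08, partial=0.35, seed=5)
        A = np.linalg.cholesky(struct.latent_correlation())
        rng = np.random.default_rng(11)
        X = rng.standard_normal((2000, 30)) @ A.T
        sol = fit_snm(_corr(spearman_corr(X), n=2000), n=2000)
        P_true = struct.partials()
        iu = np.triu_indices(30, 1)
        found = (np.abs(sol.partials[iu]) > EDGE_EPS) & (np.abs(P_true[iu]) > EDGE_EPS)
        agree = np.sign(sol.partials[iu][found]) == np.sign(P_true[iu][found])
        assert agree.mean() >= 0.95

    def test_penalized_implied_covariance_within_lambda_band(self, rng):
        """Stationarity of the lasso: the penalized working covariance
        deviates from the input matrix by at most lambda elementwise, so
        the penalized model's reconstruction error is bounded by the
        selected penalty."""
        X = rng.standard_normal((300, 15))
        X[:, 1] += 0.7 * X[:, 0]
        X[:, 4] += 0.5 * X[:, 3]
        M = spearman_corr(X)
        for lam in (0.2, 0.08):
            K = glasso(M, lam, tol=1e-8, max_iter=500)
            Sigma = np.linalg.inv(K)
            off = ~np.eye(15, dtype=bool)
            assert np.max(np.abs(Sigma - M)[off]) <= lam + 1e-5

    def test_ebic_curve_reproducible(self, rng):
        X = rng.standard_normal((100, 8))
        M = spearman_corr(X)
        a = fit_snm(_corr(M, 100), n=100)
        b = fit_snm(_corr(M, 100), n=100)
        np.testing.assert_array_equal(a.partials, b.partials)
        assert a.lambda_ == b.lambda_


class TestImpliedSnm:
    def test_diagonal_precision_gives_identity(self):
        sol = dn.NetworkSolution(
            words=list("abc"), precision=np.diag([2.0, 1.0, 0.5]),
            partials=np.zeros((3, 3)), lambda_=0.1, gamma=0.25,
            n_effective=100, edge_count=0)
        R = implied_correlation_snm(sol)
        np.testing.assert_allclose(R.matrix, np.eye(3))

    def test_two_by_two_hand_inverse(self):
        K = np.array([[2.0, -1.0], [-1.0, 2.0]])
        sol = dn.NetworkSolution(
            words=["a", "b"], precision=K,
            partials=partials_from_precision(K), lambda_=0.1, gamma=0.25,
            n_effective=100, edge_count=1)
        R = implied_correlation_snm(sol)
        assert R.matrix[0, 1] == pytest.approx(0.5)

    def test_psd_unit_diagonal_for_random_spd(self, rng):
        for _ in range(5):
            A = rng.standard_normal((6, 6))
            K = A @ A.T + 6 * np.eye(6)
            sol = dn.NetworkSolution(
                words=[f"w{i}" for i in range(6)], precision=K,
                partials=partials_from_precision(K), lambda_=0.0, gamma=0.25,
                n_effective=100,
                edge_count=int(np.sum(np.abs(partials_from_precision(K)[
                    np.triu_indices(6, 1)]) > EDGE_EPS)))
            R = implied_correlation_snm(sol).matrix
            assert np.linalg.eigvalsh(R).min() > -1e-10
            np.testing.assert_allclose(np.diag(R), 1.0)


class TestStrengthCentrality:
    def test_isolated_node_zero(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.5
        s = strength_centrality(W)
        assert s[2] == 0.0

    def test_absolute_value_convention(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.2
        W[0, 2] = W[2, 0] = -0.3
        assert strength_centrality(W)[0] == pytest.approx(0.5)

    def test_permutation_equivariance(self, rng):
        W = rng.uniform(-1, 1, (6, 6))
        W = 0.5 * (W + W.T)
        np.fill_diagonal(W, 0.0)
        perm = rng.permutation(6)
        s = strength_centrality(W)
        s_p = strength_centrality(W[np.ix_(perm, perm)])
        np.testing.assert_allclose(s_p, s[perm])

    def test_asymmetric_rejected(self):
        W = np.zeros((3, 3))
        W[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            strength_centrality(W)


class TestCommunities:
    def _two_cliques(self):
        M = np.eye(8)
        for block in (range(4), range(4, 8)):
            for i in block:
                for j in block:
                    if i != j:
                        M[i, j] = 1.0
        # valid correlation-like structure for the test
        return _corr(np.clip(M, -1, 1))

    def test_two_disconnected_cliques(self):
        part = detect_communities(self._two_cliques(), seed=0)
        assert part.n_communities == 2
        labels = [part.assignment[f"w{i}"] for i in range(8)]
        assert len(set(labels[:4])) == 1 and len(set(labels[4:])) == 1

    def test_planted_two_block_recovery(self):
        from itertools import combinations

        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            p = 60
            M = np.eye(p)
            for i, j in combinations(range(p), 2):
                same = (i < 30) == (j < 30)
                M[i, j] = M[j, i] = 0.4 if same else 0.02
            part = detect_communities(_corr(M), seed=seed)
            labels = np.array([part.assignment[f"w{i}"] for i in range(p)])
            truth = np.array([0] * 30 + [1] * 30)
            # adjusted Rand via pair counting
            n11 = sum((labels[i] == labels[j]) and (truth[i] == truth[j])
                      for i, j in combinations(range(p), 2))
            n00 = sum((labels[i] != labels[j]) and (truth[i] != truth[j])
                      for i, j in combinations(range(p), 2))
            npairs = p * (p - 1) // 2
            ri = (n11 + n00) / npairs
            hits += ri > 0.95
        assert hits >= 18  # >= 90% of seeds

    def test_modularity_beats_single_community(self):
        S = self._two_cliques()
        part = detect_communities(S, seed=1)
        assert part.modularity >= 0.0  # single community has Q = 0

    def test_modularity_matches_direct_recomputation(self):
        S = self._two_cliques()
        part = detect_communities(S, seed=3)
        W = S.matrix.copy()
        np.fill_diagonal(W, 0.0)
        W[W < 0] = 0.0
        two_m = W.sum()
        k = W.sum(axis=1)
        labels = np.array([part.assignment[w] for w in S.words])
        Q = sum(
            (W[i, j] - k[i] * k[j] / two_m) / two_m
            for i in range(8) for j in range(8) if labels[i] == labels[j]
        )
        assert part.modularity == pytest.approx(Q, abs=1e-10)

    def test_empty_graph_rejected(self):
        M = np.eye(4)
        with pytest.raises(ValueError, match="empty"):
            detect_communities(_corr(M), seed=0)


class TestTemporalDynamics:
    SETTINGS = SnmSettings(n_lambdas=25, patience=5)

    def _corpus(self, seed, shift=None):
        struct = dn.random_sparse_precision(20, density=0.15, partial=0.3, seed=77)
        spec = dn.SyntheticSpec(n_videos=200, vocab_size=20, structure=struct,
                                participants_per_video=15, seed=seed)
        table, _ = dn.generate_temporal_corpus(spec, shift=shift)
        vocab = dn.filter_vocabulary(table, min_participants=2,
                                     min_video_fraction=0.01)
        return table, vocab

    def test_null_dynamics_centered_on_zero(self):
        means = []
        for seed in range(6):
            table, vocab = self._corpus(seed)
            traj = temporal_centrality_dynamics(table, vocab,
                                                snm_settings=self.SETTINGS)
            for d in traj.delta[1:]:
                means.append(np.mean(list(d.values())))
        se = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(np.mean(means)) <= 2.5 * max(se, 0.05)

    def test_word_absent_at_previous_timepoint_baselined_at_zero(self):
        table, vocab = self._corpus(3)
        # remove word w0007 from pause 1 entirely: absent at t1/t2
        df = table.records
        df = df[~((df["word"] == "w0007") & (df["pause"] == 1))]
        table2 = dn.DescriptionTable(df.copy(), provenance="edited")
        traj = temporal_centrality_dynamics(table2, vocab,
                                            snm_settings=self.SETTINGS)
        if "w0007" in traj.delta[2]:
            assert traj.delta[2]["w0007"] == pytest.approx(
                traj.centrality[2]["w0007"])

    def test_planted_shift_ranks_in_top_deltas(self):
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            struct = dn.random_sparse_precision(20, density=0.15, partial=0.3,
                                                seed=77)
            spec = dn.SyntheticSpec(n_videos=200, vocab_size=20,
                                    structure=struct,
                                    participants_per_video=15, seed=seed)
            table, _ = dn.generate_temporal_corpus(spec, shift=(4, 3, 1.8))
            vocab = dn.filter_vocabulary(table)
            traj = temporal_centrality_dynamics(table, vocab,
                                                snm_settings=self.SETTINGS)
            d3 = traj.delta[2]
            ranked = sorted(d3, key=lambda w: -d3[w])
            hits += "w0005" in ranked[:5]
        assert hits >= 7

    def test_timepoint_with_too_few_words_named_in_error(self, hand_table):
        vocab = dn.filter_vocabulary(hand_table, min_participants=1)
        with pytest.raises(ValueError, match="t1"):
            temporal_centrality_dynamics(hand_table, vocab)
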