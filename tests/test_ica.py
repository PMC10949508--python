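"""Restart-ensemble ICA, correlation distance, clustering, centroids,
activities."""

import numpy as np
import pytest

from fmodules import (
    FitnessMatrix,
    SyntheticConfig,
    cluster_components,
    component_distance,
    compute_activities,
    decompose,
    generate,
    robust_centroids,
    run_ica_ensemble,
)
from fmodules.ica import ComponentEnsemble, pairwise_distances

from conftest import pearson


def make_ensemble(components, n_runs=1, dimension=None):
    comps = np.asarray(components, float)
    comps = comps / np.linalg.norm(comps, axis=1, keepdims=True)
    n = comps.shape[0]
    return ComponentEnsemble(
        components=comps,
        run_index=np.zeros(n, int),
        seeds=np.zeros(n, int),
        converged=np.ones(n, bool),
        n_runs=n_runs,
        dimension=dimension or n,
        tol=1e-7,
    )


def reference_dbscan(D, eps, min_samples):
    """Definition-level DBSCAN on a precomputed distance matrix.

    Core points have >= min_samples points (self included) within eps;
    clusters are connected components of cores under the eps relation,
    plus border points attached to any core neighbour.
    """
    n = D.shape[0]
    neighbors = [set(np.flatnonzero(D[i] <= eps)) for i in range(n)]
    core = [len(neighbors[i]) >= min_samples for i in range(n)]
    labels = [-1] * n
    cluster = 0
    for i in range(n):
        if not core[i] or labels[i] != -1:
            continue
        stack = [i]
        labels[i] = cluster
        while stack:
            j = stack.pop()
            if not core[j]:
                continue
            for nb in neighbors[j]:
                if labels[nb] == -1:
                    labels[nb] = cluster
                    if core[nb]:
                        stack.append(nb)
        cluster += 1
    return labels


class TestComponentDistance:
    def test_identical_vectors_distance_zero(self, rng):
        x = rng.normal(size=20)
        assert component_distance(x, x, "signed") == pytest.approx(0, abs=1e-14)
        assert component_distance(x, x, "absolute") == pytest.approx(0, abs=1e-14)

    def test_negated_vector_two_signed_zero_absolute(self, rng):
        x = rng.normal(size=20)
        assert component_distance(x, -x, "signed") == pytest.approx(2, abs=1e-14)
        assert component_distance(x, -x, "absolute") == pytest.approx(0, abs=1e-14)

    def test_matches_textbook_pearson_on_fixed_vectors(self):
        x = np.array([0.3, -1.2, 0.8, 2.1, -0.4, 0.0, 1.1, -2.2, 0.5, 0.9])
        y = np.array([1.0, -0.7, 0.2, 1.8, -1.1, 0.4, 0.9, -1.5, 0.0, 1.2])
        rho = pearson(x, y)
        assert component_distance(x, y, "signed") == pytest.approx(
            1 - rho, abs=1e-12
        )
        assert component_distance(x, y, "absolute") == pytest.approx(
            1 - abs(rho), abs=1e-12
        )

    def test_symmetry_and_range(self, rng):
        for _ in range(25):
            x, y = rng.normal(size=(2, 15))
            for mode, hi in (("signed", 2.0), ("absolute", 1.0)):
                d_xy = component_distance(x, y, mode)
                d_yx = component_distance(y, x, mode)
                assert d_xy == pytest.approx(d_yx, abs=1e-12)
                assert 0 <= d_xy <= hi

    def test_zero_variance_is_hard_error(self):
        with pytest.raises(ValueError, match="variance"):
            component_distance(np.ones(10), np.arange(10.0))

    def test_pairwise_matrix_agrees_with_scalar(self, rng):
        comps = rng.normal(size=(8, 30))
        for mode in ("signed", "absolute"):
            D = pairwise_distances(comps, mode)
            for i in range(8):
                for j in range(8):
                    if i != j:
                        assert D[i, j] == pytest.approx(
                            component_distance(comps[i], comps[j], mode),
                            abs=1e-12,
                        )


class TestClusterComponents:
    def test_one_dense_cluster_plus_scatter(self, rng):
        base = rng.normal(size=100)
        copies = base + rng.normal(scale=0.001, size=(60, 100))
        scatter = rng.normal(size=(10, 100))
        ens = make_ensemble(
            np.vstack([copies, scatter]), n_runs=100
        )
        clusters = cluster_components(ens, eps=0.1, min_size=50)
        assert len(clusters) == 1
        assert len(clusters[0]) == 60

    def test_min_size_gate(self, rng):
        base = rng.normal(size=100)
        copies = base + rng.normal(scale=0.001, size=(60, 100))
        ens = make_ensemble(copies, n_runs=100)
        assert cluster_components(ens, eps=0.1, min_size=61) == []

    def test_agrees_with_definition_level_dbscan(self, rng):
        # 3 planted directions x 55 jittered copies each, plus noise
        comps = []
        for _ in range(3):
            base = rng.normal(size=60)
            comps.append(base + rng.normal(scale=0.02, size=(55, 60)))
        comps.append(rng.normal(size=(20, 60)))
        ens = make_ensemble(np.vstack(comps), n_runs=100)
        clusters = cluster_components(ens, eps=0.1, min_size=50)

        D = pairwise_distances(ens.components, "absolute")
        labels = reference_dbscan(D, eps=0.1, min_samples=50)
        oracle = {}
        for i, lab in enumerate(labels):
            if lab != -1:
                oracle.setdefault(lab, set()).add(i)
        oracle_clusters = sorted(
            (frozenset(v) for v in oracle.values() if len(v) >= 50),
            key=lambda s: min(s),
        )
        got = [frozenset(int(i) for i in c) for c in clusters]
        assert got == oracle_clusters

    def test_sign_flipped_copies_share_a_cluster(self, rng):
        base = rng.normal(size=80)
        jitter = base + rng.normal(scale=0.001, size=(30, 80))
        ens = make_ensemble(
            np.vstack([jitter, -jitter]), n_runs=10
        )
        clusters = cluster_components(ens, eps=0.1, min_size=5)
        assert len(clusters) == 1 and len(clusters[0]) == 60


class TestRobustCentroids:
    def test_opposite_sign_pair_centroid(self, small_matrix, rng):
        v = rng.normal(size=10)
        v /= np.linalg.norm(v)
        ens = make_ensemble([v, -v])
        dec = robust_centroids([np.array([0, 1])], ens, small_matrix)
        c = dec.M[:, 0]
        # aligned average is +-v, with largest-|weight| entry positive
        assert abs(abs(pearson(c, v)) - 1) < 1e-12
        assert c[np.argmax(np.abs(c))] > 0

    def test_identical_members_centroid_is_member(self, small_matrix, rng):
        v = rng.normal(size=10)
        v /= np.linalg.norm(v)
        ens = make_ensemble([v, v, v])
        dec = robust_centroids([np.array([0, 1, 2])], ens, small_matrix)
        sign = np.sign(v[np.argmax(np.abs(v))])
        np.testing.assert_allclose(dec.M[:, 0], sign * v, atol=1e-12)

    def test_averaging_beats_median_member(self, rng):
        """Centroid correlates with the planted direction at least as well
        as the median jittered member does (noise averaging)."""
        F = FitnessMatrix(
            [f"g{i}" for i in range(200)],
            [f"s{j}" for j in range(5)],
            rng.normal(size=(200, 5)),
        )
        planted = rng.normal(size=200)
        planted /= np.linalg.norm(planted)
        wins = 0
        for _ in range(10):
            members = planted + rng.normal(scale=0.1, size=(50, 200))
            ens = make_ensemble(members)
            dec = robust_centroids([np.arange(50)], ens, F)
            c_rho = abs(pearson(dec.M[:, 0], planted))
            member_rhos = sorted(
                abs(pearson(m, planted)) for m in ens.components
            )
            wins += c_rho >= member_rhos[25]
        assert wins >= 9


class TestComputeActivities:
    def test_exact_recovery_noiseless(self, rng):
        M = rng.normal(size=(60, 3))
        A0 = rng.normal(size=(3, 10))
        F = FitnessMatrix(
            [f"g{i}" for i in range(60)],
            [f"s{j}" for j in range(10)],
            M @ A0,
        )
        A, residual = compute_activities(F, M, center=False)
        np.testing.assert_allclose(A, A0, atol=1e-8)
        assert residual < 1e-8

    def test_orthonormal_projection_identity(self, rng):
        M, _ = np.linalg.qr(rng.normal(size=(50, 4)))
        F = FitnessMatrix(
            [f"g{i}" for i in range(50)],
            [f"s{j}" for j in range(8)],
            rng.normal(size=(50, 8)),
        )
        A, _ = compute_activities(F, M, center=False)
        np.testing.assert_allclose(A, M.T @ F.values, atol=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        M = rng.normal(size=(100, 4))
        A0 = rng.normal(size=(4, 20))
        noisy = M @ A0 + rng.normal(scale=0.3, size=(100, 20))
        F = FitnessMatrix(
            [f"g{i}" for i in range(100)],
            [f"s{j}" for j in range(20)],
            noisy,
        )
        A, _ = compute_activities(F, M, center=False)
        oracle = np.linalg.solve(M.T @ M, M.T @ noisy)
        np.testing.assert_allclose(A, oracle, atol=1e-8)

    def test_rank_deficient_m_is_hard_error(self, rng):
        col = rng.normal(size=50)
        M = np.column_stack([col, 2 * col, rng.normal(size=50)])
        F = FitnessMatrix(
            [f"g{i}" for i in range(50)],
            ["s1", "s2"],
            rng.normal(size=(50, 2)),
        )
        with pytest.raises(ValueError, match=r"\(0, 1\)"):
            compute_activities(F, M)


class TestRunIcaEnsemble:
    def test_determinism_same_base_seed(self, easy_synthetic):
        F, _ = easy_synthetic
        e1 = run_ica_ensemble(F, k=5, n_runs=3, base_seed=17)
        e2 = run_ica_ensemble(F, k=5, n_runs=3, base_seed=17)
        np.testing.assert_array_equal(e1.components, e2.components)

    def test_components_unit_norm(self, easy_synthetic):
        F, _ = easy_synthetic
        ens = run_ica_ensemble(F, k=4, n_runs=2, base_seed=0)
        np.testing.assert_allclose(
            np.linalg.norm(ens.components, axis=1), 1.0, atol=1e-10
        )

    def test_rank_one_structure_found_every_run(self):
        cfg = SyntheticConfig(
            n_genes=100,
            n_samples=12,
            n_modules=1,
            module_size_range=(6, 6),
            shared_gene_fraction=0.0,
            noise_sd=0.0,
            seed=4,
        )
        F, truth = generate(cfg)
        # tiny noise floor so whitening is well posed at k=2
        rng = np.random.default_rng(0)
        F = FitnessMatrix(
            F.gene_ids,
            F.sample_ids,
            F.values + rng.normal(scale=1e-6, size=F.shape),
        )
        ens = run_ica_ensemble(F, k=2, n_runs=3, base_seed=1)
        planted = truth.planted_M[:, 0]
        for r in range(3):
            rhos = [
                abs(pearson(c, planted))
                for c, run in zip(ens.components, ens.run_index)
                if run == r
            ]
            assert max(rhos) > 0.999

    def test_dimension_bounds_are_hard_errors(self, easy_synthetic):
        F, _ = easy_synthetic
        with pytest.raises(ValueError, match="n_samples"):
            run_ica_ensemble(F, k=F.n_samples + 1)
        with pytest.raises(ValueError, match="n_samples"):
            run_ica_ensemble(F, k=1)

    def test_missing_values_are_hard_error(self):
        fm = FitnessMatrix(
            ["g1", "g2", "g3"],
            ["s1", "s2", "s3"],
            [[1.0, 2.0, 1.0], [np.nan, 0.0, 1.0], [0.5, 0.5, 0.1]],
        )
        with pytest.raises(ValueError, match="filter_complete_genes"):
            run_ica_ensemble(fm, k=2)


class TestDecompose:
    def test_bitwise_determinism(self, easy_synthetic):
        F, _ = easy_synthetic
        d1 = decompose(F, 5, n_runs=8, base_seed=23)
        d2 = decompose(F, 5, n_runs=8, base_seed=23)
        np.testing.assert_array_equal(d1.M, d2.M)
        np.testing.assert_array_equal(d1.A, d2.A)
        assert d1.cluster_sizes == d2.cluster_sizes

    def test_planted_recovery_gene_weight_correlation(self):
        """Spec regime: K=8 disjoint modules, every planted module matched
        by a robust component at |rho| > 0.9."""
        F, truth = generate(
            SyntheticConfig(seed=33, shared_gene_fraction=0.0)
        )
        dec = decompose(F, 8, n_runs=20, base_seed=7)
        assert dec.n_components >= 8
        for k in range(8):
            planted = truth.planted_M[:, k]
            best = max(
                abs(pearson(dec.M[:, j], planted))
                for j in range(dec.n_components)
            )
            assert best > 0.9

    def test_reconstruction_improves_with_components(self, easy_synthetic):
        """Residual never increases as robust components are added."""
        F, _ = easy_synthetic
        dec = decompose(F, 5, n_runs=8, base_seed=2)
        X = F.values - F.values.mean(axis=0, keepdims=True)
        prev = np.linalg.norm(X)
        for m in range(1, dec.n_components + 1):
            Msub = dec.M[:, :m]
            A = np.linalg.lstsq(Msub, X, rcond=None)[0]
            res = np.linalg.norm(X - Msub @ A)
            assert res <= prev + 1e-9
            prev = res

    def test_m_never_exceeds_k(self, easy_synthetic):
        F, _ = easy_synthetic
        for k in (3, 5, 8):
            dec = decompose(F, k, n_runs=6, base_seed=5)
            assert dec.n_components <= k
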