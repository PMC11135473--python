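import numpy as np
import pandas as pd
import pytest

from envgp import (
    EnvCovariateTable,
    MarkerMatrix,
    PhenotypeTable,
    ValidationError,
)
from envgp.kernels import (
    DesignMatrices,
    KernelMatrix,
    build_designs,
    env_kernel_from_covariates,
    env_kernel_noec,
    ge_kernel,
    genomic_relationship,
    genotype_kernel,
)


def designs_from_obs(obs_keys, geno_ids, env_ids):
    n = len(obs_keys)
    Z = np.zeros((n, len(geno_ids)))
    X = np.zeros((n, len(env_ids)))
    for r, (e, g) in enumerate(obs_keys):
        Z[r, geno_ids.index(g)] = 1
        X[r, env_ids.index(e)] = 1
    return DesignMatrices(Z, X, obs_keys, geno_ids, env_ids, np.zeros(n))


class TestGenomicRelationship:
    def test_two_genotype_hand_example(self):
        # per column: sample sd sqrt(2), standardized dosages +/- 1/sqrt(2);
        # each marker contributes the outer product [[.5,-.5],[-.5,.5]] and
        # G averages them over p = 2 markers
        m = MarkerMatrix(["G1", "G2"], ["m1", "m2"], [[0, 2], [2, 0]])
        G = genomic_relationship(m)
        np.testing.assert_allclose(G.values, [[0.5, -0.5], [-0.5, 0.5]], atol=1e-12)

    def test_identical_genotypes_rejected(self):
        m = MarkerMatrix(["G1", "G2"], ["m1", "m2"], [[1, 2], [1, 2]])
        with pytest.raises(ValidationError, match="constant"):
            genomic_relationship(m)

    def test_matches_per_marker_accumulation_oracle(self):
        rng = np.random.default_rng(7)
        J, p = 6, 30
        vals = rng.integers(0, 3, size=(J, p))
        m = MarkerMatrix([f"G{j}" for j in range(J)], [f"m{k}" for k in range(p)], vals)
        G = genomic_relationship(m)
        X = vals.astype(float)
        keep = X.std(axis=0, ddof=1) > 0
        X = X[:, keep]
        acc = np.zeros((J, J))
        for k in range(X.shape[1]):
            col = (X[:, k] - X[:, k].mean()) / X[:, k].std(ddof=1)
            acc += np.outer(col, col)
        np.testing.assert_allclose(G.values, acc / X.shape[1], atol=1e-12)

    def test_mean_diagonal_near_one_under_hwe(self):
        rng = np.random.default_rng(12)
        freqs = rng.uniform(0.1, 0.5, 400)
        vals = rng.binomial(2, freqs, size=(80, 400))
        m = MarkerMatrix([f"G{j}" for j in range(80)], [f"m{k}" for k in range(400)], vals)
        G = genomic_relationship(m)
        assert abs(np.mean(np.diag(G.values)) - 1.0) < 0.15

    def test_monomorphic_markers_dropped_with_warning(self):
        m = MarkerMatrix(["G1", "G2", "G3"], ["m1", "m2"], [[0, 1], [2, 1], [1, 1]])
        with pytest.warns(UserWarning, match="monomorphic"):
            G = genomic_relationship(m)
        assert G.n == 3


class TestEnvKernels:
    def test_noec_two_env_example(self):
        d = designs_from_obs([("E1", "G1"), ("E1", "G2"), ("E2", "G1")],
                             ["G1", "G2"], ["E1", "E2"])
        K = env_kernel_noec(d)
        np.testing.assert_allclose(
            K.values, [[0.5, 0.5, 0], [0.5, 0.5, 0], [0, 0, 0.5]]
        )

    def test_noec_diagonal_is_one_over_I(self):
        obs = [(f"E{i}", "G1") for i in range(1, 5)]
        d = designs_from_obs(obs, ["G1"], [f"E{i}" for i in range(1, 5)])
        K = env_kernel_noec(d)
        np.testing.assert_allclose(np.diag(K.values), 0.25)

    def test_covariate_kernel_hand_example(self):
        d = designs_from_obs([("E1", "G1"), ("E2", "G1")], ["G1"], ["E1", "E2"])
        w = np.array([[-1.0], [1.0]]) / np.sqrt(2)  # standardized over I=2
        K = env_kernel_from_covariates(w, d)
        # K_EC = ww'/1 = [[.5,-.5],[-.5,.5]]; expansion divides by I=2
        np.testing.assert_allclose(K.values, [[0.25, -0.25], [-0.25, 0.25]])

    def test_covariate_kernel_matches_matrix_product_oracle(self):
        rng = np.random.default_rng(3)
        env_ids = [f"E{i}" for i in range(4)]
        obs = [(e, f"G{j}") for e in env_ids for j in range(3)]
        d = designs_from_obs(obs, [f"G{j}" for j in range(3)], env_ids)
        W = rng.normal(size=(4, 5))
        W = (W - W.mean(0)) / W.std(0, ddof=1)
        K = env_kernel_from_covariates(W, d)
        expected = d.X_E @ (W @ W.T / 5) @ d.X_E.T / 4
        np.testing.assert_allclose(K.values, expected, atol=1e-12)

    def test_empty_selection_rejected(self):
        d = designs_from_obs([("E1", "G1"), ("E2", "G1")], ["G1"], ["E1", "E2"])
        with pytest.raises(ValidationError, match="fall back"):
            env_kernel_from_covariates(np.empty((2, 0)), d)


class TestGEKernel:
    def test_all_ones_is_identity_under_hadamard(self):
        labels = list(range(3))
        ones = KernelMatrix(labels, np.ones((3, 3)), "Kg")
        ke = KernelMatrix(labels, np.diag([1.0, 2.0, 3.0]), "KE_noec")
        K = ge_kernel(ones, ke)
        np.testing.assert_allclose(K.values, ke.values)

    def test_zero_kernel_annihilates(self):
        labels = list(range(3))
        kg = KernelMatrix(labels, np.eye(3), "Kg")
        zero = KernelMatrix(labels, np.zeros((3, 3)), "KE_noec")
        np.testing.assert_allclose(ge_kernel(kg, zero).values, 0)

    def test_hadamard_product_stays_psd(self):
        rng = np.random.default_rng(9)
        labels = list(range(6))
        A = rng.normal(size=(6, 6)); B = rng.normal(size=(6, 6))
        kg = KernelMatrix(labels, A @ A.T, "Kg")
        ke = KernelMatrix(labels, B @ B.T, "KE_noec")
        K = ge_kernel(kg, ke)  # constructor enforces PSD
        w = np.linalg.eigvalsh(K.values)
        assert w[0] >= -1e-8 * max(w[-1], 1.0)

    def test_label_mismatch_rejected(self):
        kg = KernelMatrix([0, 1], np.eye(2), "Kg")
        ke = KernelMatrix([1, 0], np.eye(2), "KE_noec")
        with pytest.raises(ValidationError, match="labels"):
            ge_kernel(kg, ke)


class TestGenotypeKernel:
    def test_hand_expansion(self):
        G = KernelMatrix(["G1", "G2"], np.array([[1.0, -1.0], [-1.0, 1.0]]), "G")
        d = designs_from_obs([("E1", "G1"), ("E1", "G2"), ("E2", "G1")],
                             ["G1", "G2"], ["E1", "E2"])
        K = genotype_kernel(G, d)
        np.testing.assert_allclose(K.values, [[1, -1, 1], [-1, 1, -1], [1, -1, 1]])

    def test_identity_design_returns_G(self):
        rng = np.random.default_rng(1)
        A = rng.normal(size=(3, 3))
        G = KernelMatrix(["G1", "G2", "G3"], A @ A.T, "G")
        d = designs_from_obs([("E1", "G1"), ("E1", "G2"), ("E1", "G3")],
                             ["G1", "G2", "G3"], ["E1"])
        np.testing.assert_allclose(genotype_kernel(G, d).values, G.values)

    def test_expansion_consistency(self):
        rng = np.random.default_rng(5)
        A = rng.normal(size=(3, 3))
        G = KernelMatrix(["G1", "G2", "G3"], A @ A.T, "G")
        obs = [("E1", "G1"), ("E1", "G3"), ("E2", "G1"), ("E2", "G2")]
        d = designs_from_obs(obs, ["G1", "G2", "G3"], ["E1", "E2"])
        K = genotype_kernel(G, d)
        gi = {g: i for i, g in enumerate(["G1", "G2", "G3"])}
        for a, (ea, ga) in enumerate(obs):
            for b, (eb, gb) in enumerate(obs):
                assert K.values[a, b] == pytest.approx(G.values[gi[ga], gi[gb]])


class TestBuildDesigns:
    def test_balanced_design(self, small_phen, small_markers, small_covs):
        d = build_designs(small_phen, "GY", small_markers, small_covs)
        assert d.n_obs == 6
        assert d.Z_g.sum(axis=0).tolist() == [2, 2, 2]
        assert d.X_E.sum(axis=0).tolist() == [3, 3]
        assert (d.Z_g.sum(axis=1) == 1).all() and (d.X_E.sum(axis=1) == 1).all()

    def test_unbalanced_design_column_sums(self, small_markers, small_covs):
        df = pd.DataFrame(
            [("E1", "G1", "GY", 1.0), ("E1", "G2", "GY", 2.0), ("E2", "G1", "GY", 3.0)],
            columns=["env", "geno", "trait", "value"],
        )
        d = build_designs(PhenotypeTable(df), "GY", small_markers, small_covs)
        assert d.n_obs == 3
        assert d.X_E.sum(axis=0).tolist() == [2, 1]

    def test_unknown_genotype_named(self, small_markers, small_covs):
        df = pd.DataFrame(
            [("E1", "G9", "GY", 1.0), ("E2", "G1", "GY", 2.0)],
            columns=["env", "geno", "trait", "value"],
        )
        with pytest.raises(ValidationError, match="G9"):
            build_designs(PhenotypeTable(df), "GY", small_markers, small_covs)
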