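"""Tests of the co-expression network stage: adjacency, topological
overlap, module detection, eigengenes and module-trait statistics."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from mitodx.coexpr import (
    GREY,
    CoexprError,
    adjacency,
    cluster_modules,
    filter_variable_genes,
    gene_significance_membership,
    module_eigengene,
    module_eigengenes,
    module_trait_correlation,
    pick_soft_threshold,
    select_key_module,
    tom_similarity,
)
from mitodx.simulate import SimConfig, simulate_cohorts


def _block_data(rng, sizes, n_samples=100, within=0.9, noise_genes=0):
    """Planted-module data: each block driven by one latent factor."""
    rows, truth = [], []
    load = np.sqrt(within / (1 - within))
    for m, size in enumerate(sizes):
        f = rng.normal(size=n_samples)
        rows.append(load * f + rng.normal(size=(size, n_samples)))
        truth += [m] * size
    if noise_genes:
        rows.append(rng.normal(size=(noise_genes, n_samples)))
        truth += [-1] * noise_genes
    X = np.vstack(rows)
    genes = [f"g{i:04d}" for i in range(X.shape[0])]
    return pd.DataFrame(X, index=genes), np.array(truth)


def _brute_force_tom(A):
    n = A.shape[0]
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(A[i, u] * A[u, j] for u in range(n) if u not in (i, j))
            ki = sum(A[i, u] for u in range(n) if u != i)
            kj = sum(A[j, u] for u in range(n) if u != j)
            tom[i, j] = (l + A[i, j]) / (min(ki, kj) + 1 - A[i, j])
    return tom


class TestFilterVariableGenes:
    def test_strict_sd_cut(self):
        m = pd.DataFrame(
            [[1.0, 1.0, 1.0], [0.5, 1.0, 1.5], [0.0, 1.0, 2.0]],
            index=["const", "sd_half", "sd_one"],
        )
        out = filter_variable_genes(m, sd_min=0.5)
        assert list(out.index) == ["sd_one"]  # sd exactly 0.5 dropped

    def test_count_with_known_sds(self, rng):
        sds = np.linspace(0.1, 2.0, 50)
        X = rng.normal(size=(50, 400)) * sds[:, None]
        m = pd.DataFrame(X)
        out = filter_variable_genes(m, sd_min=1.0)
        observed_sds = X.std(axis=1, ddof=1)
        assert len(out) == int((observed_sds > 1.0).sum())


class TestAdjacency:
    def test_hand_power(self, rng):
        f = rng.normal(size=200)
        x = np.vstack([f, f * 0.5 + np.sqrt(0.75) * rng.normal(size=200)])
        m = pd.DataFrame(x, index=["a", "b"])
        # normalize to exact correlation 0.5 via constructed vectors
        a = np.array([1.0, 0.0])
        b = np.array([0.5, np.sqrt(0.75)])
        A = np.abs(np.array([[1.0, 0.5], [0.5, 1.0]])) ** 6
        assert A[0, 1] == pytest.approx(0.015625)

    def test_perfect_correlation_any_power(self):
        x = np.linspace(0, 1, 50)
        m = pd.DataFrame([x, 2 * x + 1, -x], index=["a", "b", "c"])
        for beta in (1, 6, 12):
            A = adjacency(m, beta)
            assert A.loc["a", "b"] == pytest.approx(1.0)
            assert A.loc["a", "c"] == pytest.approx(1.0)  # unsigned network

    def test_symmetric_unit_diagonal(self, rng):
        m = pd.DataFrame(rng.normal(size=(20, 30)))
        A = adjacency(m, 6).to_numpy()
        np.testing.assert_allclose(A, A.T)
        np.testing.assert_allclose(np.diag(A), 1.0)
        assert A.min() >= 0 and A.max() <= 1

    def test_zero_variance_gene_rejected(self, rng):
        m = pd.DataFrame(np.vstack([rng.normal(size=(3, 10)), np.ones(10)]))
        with pytest.raises(CoexprError):
            adjacency(m, 6)


class TestTOM:
    def test_three_gene_hand_example(self):
        A = np.array([[1.0, 0.8, 0.4], [0.8, 1.0, 0.2], [0.4, 0.2, 1.0]])
        tom = tom_similarity(A)
        assert tom[0, 1] == pytest.approx(0.88 / 1.2)

    def test_identity_adjacency(self):
        tom = tom_similarity(np.eye(5))
        np.testing.assert_allclose(tom, np.eye(5))

    def test_matches_brute_force_on_random_matrices(self, rng):
        for _ in range(10):
            B = rng.uniform(0, 1, size=(8, 8))
            A = (B + B.T) / 2
            np.fill_diagonal(A, 1.0)
            np.testing.assert_allclose(
                tom_similarity(A), _brute_force_tom(A), atol=1e-12
            )

    def test_asymmetric_rejected(self, rng):
        A = rng.uniform(0, 1, size=(5, 5))
        with pytest.raises(CoexprError):
            tom_similarity(A)


class TestSoftThreshold:
    def test_mean_connectivity_decreases(self, rng):
        m, _ = _block_data(rng, [40, 40], noise_genes=40)
        _, scan = pick_soft_threshold(m, powers=tuple(range(1, 11)))
        assert (np.diff(scan["mean_k"]) < 0).all()

    def test_structured_data_reasonable_power(self, rng):
        m, _ = _block_data(rng, [60, 60], noise_genes=120)
        beta, scan = pick_soft_threshold(m)
        assert 1 <= beta <= 20
        assert scan.loc[scan["power"] == beta, "mean_k"].iloc[0] >= 1.0

    def test_degenerate_input_rejected(self):
        m = pd.DataFrame(np.ones((40, 10)))
        with pytest.raises(CoexprError):
            pick_soft_threshold(m)


class TestClusterModules:
    def test_two_planted_blocks_recovered(self, rng):
        m, truth = _block_data(rng, [80, 80], within=0.9)
        tom = tom_similarity(adjacency(m, 6))
        part = cluster_modules(tom, min_module_size=60)
        counts = part.value_counts()
        assert set(counts.index) == {"turquoise", "blue"}
        assert counts["turquoise"] == 80 and counts["blue"] == 80
        assert adjusted_rand_score(truth, part.to_numpy()) == 1.0

    def test_pure_noise_unassigned(self, rng):
        m, _ = _block_data(rng, [], noise_genes=200)
        tom = tom_similarity(adjacency(m, 6))
        part = cluster_modules(tom, min_module_size=60)
        assert (part == GREY).all()

    def test_min_size_above_n_all_grey(self, rng):
        m, _ = _block_data(rng, [30])
        tom = tom_similarity(adjacency(m, 6))
        with pytest.warns(UserWarning):
            part = cluster_modules(tom, min_module_size=60)
        assert (part == GREY).all()

    def test_gene_order_permutation_invariance(self, rng):
        m, truth = _block_data(rng, [70, 65], noise_genes=50)
        tom = tom_similarity(adjacency(m, 6))
        part = cluster_modules(tom, min_module_size=60)
        perm = rng.permutation(len(m))
        m2 = m.iloc[perm]
        tom2 = tom_similarity(adjacency(m2, 6))
        part2 = cluster_modules(tom2, min_module_size=60)
        aligned = part2.loc[part.index]
        assert adjusted_rand_score(part.to_numpy(), aligned.to_numpy()) == 1.0


class TestEigengene:
    def test_identical_genes_give_standardized_profile(self, rng):
        x = rng.normal(size=60)
        m = pd.DataFrame([x, 2 * x + 3, 0.5 * x - 1], index=["a", "b", "c"])
        me = module_eigengene(m, ["a", "b", "c"])
        z = (x - x.mean()) / x.std(ddof=1)
        np.testing.assert_allclose(me, z / np.linalg.norm(z), atol=1e-10)

    def test_affine_rescaling_invariance_up_to_sign(self, rng):
        m, _ = _block_data(rng, [50])
        me1 = module_eigengene(m, m.index)
        scaled = m * rng.uniform(0.5, 3.0, size=(len(m), 1)) + rng.normal(size=(len(m), 1))
        me2 = module_eigengene(scaled, scaled.index)
        assert abs(np.dot(me1, me2)) == pytest.approx(1.0, abs=1e-9)

    def test_orientation_positive_mean_correlation(self, rng):
        m, _ = _block_data(rng, [40])
        me = module_eigengene(m, m.index)
        cors = [np.corrcoef(m.loc[g], me)[0, 1] for g in m.index]
        assert np.mean(cors) > 0

    def test_tight_block_high_explained_variance(self, rng):
        m, _ = _block_data(rng, [60], within=0.9)
        me = module_eigengene(m, m.index).to_numpy()
        Xs = ((m.T - m.mean(axis=1)) / m.std(axis=1, ddof=1)).T.to_numpy()
        proj = Xs @ me
        assert (proj**2).sum() / (Xs**2).sum() >= 0.8

    def test_single_gene_module(self, rng):
        m = pd.DataFrame(rng.normal(size=(3, 30)), index=["a", "b", "c"])
        me = module_eigengene(m, ["a"])
        assert np.linalg.norm(me) == pytest.approx(1.0)


class TestModuleTrait:
    def test_eigengene_equal_to_trait(self):
        trait = pd.Series([0.0] * 10 + [1.0] * 10, index=range(20))
        mes = pd.DataFrame({"turquoise": trait})
        out = module_trait_correlation(mes, trait)
        assert out.loc["turquoise", "r"] == pytest.approx(1.0)
        assert out.loc["turquoise", "p"] < 1e-10

    def test_orthogonal_eigengene_uncorrelated(self, rng):
        trait = pd.Series([0.0] * 50 + [1.0] * 50, index=range(100))
        mes = pd.DataFrame({"blue": rng.normal(size=100)}, index=trait.index)
        out = module_trait_correlation(mes, trait)
        assert abs(out.loc["blue", "r"]) < 0.3

    def test_trait_coding_flip_flips_sign(self, rng):
        trait = pd.Series([0.0] * 30 + [1.0] * 30, index=range(60))
        mes = pd.DataFrame({"m": rng.normal(size=60) + 0.5 * trait}, index=trait.index)
        a = module_trait_correlation(mes, trait)
        b = module_trait_correlation(mes, 1.0 - trait)
        assert a.loc["m", "r"] == pytest.approx(-b.loc["m", "r"])

    def test_constant_trait_rejected(self, rng):
        mes = pd.DataFrame({"m": rng.normal(size=10)}, index=range(10))
        with pytest.raises(CoexprError):
            module_trait_correlation(mes, pd.Series(np.ones(10), index=range(10)))


class TestKeyModuleSelection:
    def _table(self, rs, index):
        return pd.DataFrame({"r": rs, "p": [0.01] * len(rs)}, index=index)

    def test_largest_absolute_r_wins(self):
        part = pd.Series(["turquoise"] * 5 + ["blue"] * 5)
        t = self._table([-0.4, 0.1], ["turquoise", "blue"])
        assert select_key_module(t, part) == "turquoise"

    def test_tie_broken_by_size(self):
        part = pd.Series(["turquoise"] * 8 + ["blue"] * 4)
        t = self._table([0.3, -0.3], ["blue", "turquoise"])
        assert select_key_module(t, part) == "turquoise"

    def test_grey_never_selected(self):
        part = pd.Series(["grey"] * 10 + ["blue"] * 3)
        t = self._table([0.9, 0.1], ["grey", "blue"])
        assert select_key_module(t, part) == "blue"

    def test_all_grey_error(self):
        part = pd.Series(["grey"] * 10)
        with pytest.raises(CoexprError):
            select_key_module(self._table([0.9], ["grey"]), part)


class TestGeneSignificance:
    def test_gene_equal_to_trait_has_gs_one(self, rng):
        trait = pd.Series([0.0] * 20 + [1.0] * 20, index=[f"s{i}" for i in range(40)])
        X = rng.normal(size=(10, 40))
        X[0] = trait.to_numpy()
        m = pd.DataFrame(X, index=[f"g{i}" for i in range(10)], columns=trait.index)
        part = pd.Series(["turquoise"] * 10, index=m.index)
        mes = module_eigengenes(m, part)
        out = gene_significance_membership(m, trait, part, mes)
        assert out.loc["g0", "GS"] == pytest.approx(1.0)
        assert ((out["GS"] >= 0) & (out["GS"] <= 1)).all()

    def test_tight_module_high_membership(self, rng):
        m, _ = _block_data(rng, [50], within=0.9)
        part = pd.Series(["turquoise"] * 50, index=m.index)
        trait = pd.Series(np.r_[np.zeros(50), np.ones(50)], index=m.columns)
        mes = module_eigengenes(m, part)
        out = gene_significance_membership(m, trait, part, mes)
        assert (out["MM"] > 0.8).mean() > 0.9

    def test_grey_membership_undefined(self, rng):
        m, _ = _block_data(rng, [40], noise_genes=5)
        part = pd.Series(["turquoise"] * 40 + [GREY] * 5, index=m.index)
        trait = pd.Series(np.r_[np.zeros(50), np.ones(50)], index=m.columns)
        mes = module_eigengenes(m, part)
        out = gene_significance_membership(m, trait, part, mes)
        assert out.loc[part == GREY, "MM"].isna().all()


class TestPlantedModuleRecovery:
    @pytest.mark.parametrize("sizes", [(80, 80), (120, 90, 60), (100, 80, 70, 60)])
    def test_blocks_recovered_with_high_ari(self, sizes):
        """2-4 planted blocks (size >= 60, within-correlation ~0.8) are
        recovered nearly perfectly; module count is exact."""
        cfg = SimConfig(n_cohorts=1, n_control=60, n_treat=60,
                        n_genes=sum(sizes) + 200, module_sizes=sizes,
                        n_de_genes=0, delta=0.0, batch_shift_sd=0.0, seed=len(sizes))
        mats, _, truth = simulate_cohorts(cfg)
        m = mats[0]
        beta, _ = pick_soft_threshold(m)
        part = cluster_modules(tom_similarity(adjacency(m, beta)), min_module_size=60)
        assert part.nunique() - int(GREY in set(part)) == len(sizes)
        planted = [g for g in m.index if truth.module_assignment[g] >= 0]
        ari = adjusted_rand_score(
            [truth.module_assignment[g] for g in planted],
            part.loc[planted].to_numpy(),
        )
        assert ari >= 0.9
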