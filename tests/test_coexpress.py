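import numpy as np
import pandas as pd
import pytest
from scipy import stats

from intgen.coexpress import (
    ModuleSet,
    NetworkParams,
    detect_modules,
    hub_genes,
    module_eigengene,
    module_membership,
    signed_adjacency,
    topological_overlap,
)
from intgen.diffexpr import log_cpm
from intgen.simulate import SimConfig, simulate_expression


def _df(values, genes=None, samples=None):
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    return pd.DataFrame(values, index=genes, columns=samples)


class TestAdjacency:
    def test_anticorrelated_pair_is_zero(self):
        x = np.arange(10.0)
        vals = np.vstack([x, -x])
        a = signed_adjacency(vals, power=6)
        assert a[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_unit_interval_zero_diag(self):
        rng = np.random.default_rng(2)
        a = signed_adjacency(rng.normal(size=(15, 12)), power=12)
        assert np.allclose(a, a.T)
        assert np.all((a >= 0) & (a <= 1))
        assert np.all(np.diag(a) == 0)

    def test_tom_in_unit_interval(self):
        rng = np.random.default_rng(3)
        a = signed_adjacency(rng.normal(size=(20, 10)), power=6)
        tom = topological_overlap(a)
        assert np.all((tom >= 0) & (tom <= 1 + 1e-12))
        assert np.allclose(np.diag(tom), 1.0)


class TestEigengene:
    def test_identical_profiles(self):
        rng = np.random.default_rng(1)
        profile = rng.normal(size=10)
        vals = np.tile(profile, (5, 1))
        labels = pd.Series([1] * 5, index=[f"g{i}" for i in range(5)])
        eig = module_eigengene(_df(vals), labels)
        r = np.corrcoef(eig.loc[1], profile)[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-10)
        assert r > 0  # sign-oriented toward the module average

    def test_sign_equivariance(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(size=(6, 12))
        labels = pd.Series([1] * 6, index=[f"g{i}" for i in range(6)])
        e1 = module_eigengene(_df(vals), labels)
        e2 = module_eigengene(_df(-vals), labels)
        assert np.allclose(e1.to_numpy(), -e2.to_numpy(), atol=1e-10)

    def test_pc1_dominates_pc2_brute_force(self):
        """PC1 variance explained >= PC2, checked against a brute-force
        eigendecomposition of the standardized covariance."""
        rng = np.random.default_rng(5)
        factor = rng.normal(size=14)
        vals = 0.8 * factor[None, :] + rng.normal(0, 0.5, size=(8, 14))
        labels = pd.Series([1] * 8, index=[f"g{i}" for i in range(8)])
        eig = module_eigengene(_df(vals), labels)
        z = (vals - vals.mean(1, keepdims=True)) / vals.std(1, keepdims=True)
        evals = np.sort(np.linalg.eigvalsh(z.T @ z))[::-1]
        assert evals[0] >= evals[1]
        # eigengene spans the top eigenvector of z'z
        top = np.linalg.eigh(z.T @ z)[1][:, -1]
        assert abs(np.corrcoef(eig.loc[1], top)[0, 1]) == pytest.approx(1.0, abs=1e-8)

    def test_singleton_module(self):
        vals = np.arange(8.0)[None, :]
        labels = pd.Series([1], index=["g0"])
        eig = module_eigengene(_df(vals), labels)
        z = (vals[0] - vals[0].mean()) / vals[0].std()
        assert np.allclose(eig.loc[1], z / np.linalg.norm(z))


class TestMembership:
    def test_gene_identical_to_eigengene(self):
        rng = np.random.default_rng(6)
        profile = rng.normal(size=12)
        vals = np.vstack([profile, rng.normal(size=12)])
        labels = pd.Series([1, 0], index=["g0", "g1"])
        eig = module_eigengene(_df(vals), labels)
        kme, mmp = module_membership(_df(vals), eig)
        assert kme.loc["g0", 1] == pytest.approx(1.0)
        assert mmp.loc["g0", 1] < 1e-6

    def test_rank_then_pearson_equals_spearman(self):
        rng = np.random.default_rng(7)
        vals = rng.normal(size=(10, 15))
        labels = pd.Series([1] * 5 + [0] * 5, index=[f"g{i}" for i in range(10)])
        eig = module_eigengene(_df(vals), labels)
        kme, _ = module_membership(_df(vals), eig)
        for i in range(10):
            direct = stats.spearmanr(vals[i], eig.loc[1]).statistic
            assert kme.iloc[i, 0] == pytest.approx(direct, abs=1e-10)

    def test_null_mmp_uniform(self):
        """Independent noise genes vs an eigengene: MMP ~ Uniform(0,1)."""
        rng = np.random.default_rng(8)
        noise = rng.normal(size=(1000, 20))
        eig_profile = rng.normal(size=20)
        labels = pd.Series([1], index=["anchor"])
        eig = module_eigengene(_df(eig_profile[None, :], genes=["anchor"]), labels)
        _, mmp = module_membership(_df(noise), eig)
        assert stats.kstest(mmp[1], "uniform").pvalue > 0.01

    def test_too_few_samples_rejected(self):
        vals = np.random.default_rng(0).normal(size=(3, 3))
        genes = ["a", "b", "c"]
        labels = pd.Series([1, 1, 1], index=genes)
        eig = module_eigengene(_df(vals, genes=genes), labels)
        with pytest.raises(ValueError, match=">= 4 samples"):
            module_membership(_df(vals, genes=genes), eig)


class TestHubs:
    def test_star_topology_center_first(self):
        rng = np.random.default_rng(9)
        center = rng.normal(size=30)
        spokes = [
            0.7 * center + np.sqrt(1 - 0.49) * rng.normal(size=30) for _ in range(6)
        ]
        vals = np.vstack([center] + spokes)
        genes = ["center"] + [f"spoke{i}" for i in range(6)]
        labels = pd.Series([1] * 7, index=genes)
        top = hub_genes(_df(vals, genes=genes), labels, module=1, top_n=3)
        assert top["gene"].iloc[0] == "center"

    def test_top_n_equal_module_size(self):
        rng = np.random.default_rng(10)
        vals = rng.normal(size=(5, 12))
        genes = [f"g{i}" for i in range(5)]
        labels = pd.Series([1] * 5, index=genes)
        top = hub_genes(_df(vals, genes=genes), labels, module=1, top_n=5)
        assert set(top["gene"]) == set(genes)

    def test_k_in_matches_brute_force(self):
        rng = np.random.default_rng(11)
        vals = rng.normal(size=(10, 16))
        genes = [f"g{i}" for i in range(10)]
        labels = pd.Series([1] * 10, index=genes)
        top = hub_genes(
            _df(vals, genes=genes), labels, module=1, top_n=10,
            params=NetworkParams(soft_power=6),
        )
        adj = signed_adjacency(vals, 6)
        brute = {g: adj[i].sum() for i, g in enumerate(genes)}
        for _, row in top.iterrows():
            assert row["k_in"] == pytest.approx(brute[row["gene"]], abs=1e-10)

    def test_oversized_top_n_warns(self):
        rng = np.random.default_rng(12)
        vals = rng.normal(size=(3, 10))
        labels = pd.Series([1] * 3, index=["a", "b", "c"])
        with pytest.warns(UserWarning, match="exceeds module size"):
            top = hub_genes(_df(vals, genes=["a", "b", "c"]), labels, 1, top_n=10)
        assert len(top) == 3


class TestDetection:
    def test_planted_modules_recovered(self, planted_modules):
        from sklearn.metrics import adjusted_rand_score

        cfg, cm, truth = planted_modules
        ms = detect_modules(log_cpm(cm), NetworkParams(min_module_size=30))
        true_labels = [truth.module_assignment[g] for g in ms.labels.index]
        assert adjusted_rand_score(true_labels, ms.labels.to_numpy()) >= 0.8

    def test_sample_permutation_invariance(self):
        cfg = SimConfig(n_genes=200, n_modules=1, module_size=40, de_fraction=0, seed=13)
        cm, _ = simulate_expression(cfg)
        lcpm = log_cpm(cm)
        ms1 = detect_modules(lcpm, NetworkParams(min_module_size=20))
        rng = np.random.default_rng(13)
        perm = rng.permutation(lcpm.values.columns)
        from intgen.diffexpr import LogCPMMatrix

        lcpm2 = LogCPMMatrix(lcpm.values[perm], lcpm.library_sizes[perm])
        ms2 = detect_modules(lcpm2, NetworkParams(min_module_size=20))
        assert (ms1.labels == ms2.labels.loc[ms1.labels.index]).all()

    def test_all_background_rarely_forms_modules(self):
        """Without planted structure, large modules almost never appear."""
        hits = 0
        runs = 10
        for seed in range(runs):
            cfg = SimConfig(n_genes=300, n_modules=0, de_fraction=0, seed=100 + seed)
            cm, _ = simulate_expression(cfg)
            ms = detect_modules(log_cpm(cm), NetworkParams(min_module_size=30))
            if ms.labels.max() > 0:
                hits += 1
        assert hits <= 1

    def test_constant_gene_removed_with_warning(self):
        cfg = SimConfig(n_genes=100, n_modules=1, module_size=40, de_fraction=0, seed=14)
        cm, _ = simulate_expression(cfg)
        lcpm = log_cpm(cm)
        lcpm.values.iloc[0] = 3.0  # constant expression
        with pytest.warns(UserWarning, match="constant"):
            ms = detect_modules(lcpm, NetworkParams(min_module_size=20))
        assert ms.labels.iloc[0] == 0
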