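import numpy as np
import pandas as pd
import pytest
from scipy import stats

from intgen.diffexpr import (
    LogCPMMatrix,
    bh_fdr,
    fit_de,
    flatten_exons,
    log_cpm,
    relative_exon_usage,
    simes_p,
)
from intgen.diffexpr import test_exon_usage as exon_usage_test
from intgen.io import CountMatrix
from intgen.simulate import SimConfig, simulate_exon_counts, simulate_expression


def _lcpm_from_values(values: np.ndarray, samples, index) -> LogCPMMatrix:
    df = pd.DataFrame(values, index=index, columns=samples)
    return LogCPMMatrix(df, pd.Series(1e6, index=samples))


class TestLogCPM:
    def test_zero_count_value(self):
        counts = pd.DataFrame({"s1": [0, 10**6 - 0]}, index=["g1", "g2"])
        lcpm = log_cpm(counts, pseudocount=0.5)
        expected = np.log2(0.5 / ((1e6 + 1) / 1e6))
        assert lcpm.values.loc["g1", "s1"] == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(-1.0000014, abs=1e-6)

    def test_scale_invariance_of_profile(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.integers(1, 100, (20, 2)), columns=["a", "b"])
        doubled = counts.copy()
        doubled["a"] = counts["a"] * 2
        # large pseudocount-free comparison: differences between genes within
        # the doubled sample match the original (ratios preserved)
        l1 = log_cpm(counts, 1e-9).values["a"]
        l2 = log_cpm(doubled, 1e-9).values["a"]
        diff = (l2 - l1).to_numpy()
        assert np.allclose(diff - diff[0], 0.0, atol=1e-6)

    def test_hand_computed_two_by_two(self):
        counts = pd.DataFrame({"s1": [3, 7], "s2": [10, 0]}, index=["g1", "g2"])
        lcpm = log_cpm(counts, pseudocount=0.5)
        # s1 libsize 10: g1 = log2(3.5 / ((10+1)/1e6))
        assert lcpm.values.loc["g1", "s1"] == pytest.approx(
            np.log2(3.5 / (11 / 1e6)), abs=1e-12
        )
        assert lcpm.values.loc["g2", "s2"] == pytest.approx(
            np.log2(0.5 / (11 / 1e6)), abs=1e-12
        )

    def test_all_zero_sample_rejected(self):
        counts = pd.DataFrame({"s1": [0, 0]}, index=["g1", "g2"])
        with pytest.raises(ValueError, match="all-zero"):
            log_cpm(counts)


class TestFitDE:
    def _meta(self, n_per_group):
        samples = [f"t{i}" for i in range(n_per_group)] + [
            f"c{i}" for i in range(n_per_group)
        ]
        return pd.DataFrame(
            {"group": ["tumor"] * n_per_group + ["control"] * n_per_group},
            index=samples,
        )

    def test_identical_groups_are_null(self):
        meta = self._meta(4)
        vals = np.tile(np.arange(8.0), (5, 1))
        vals += np.random.default_rng(1).normal(0, 0.1, vals.shape)
        vals[0] = 1.0  # identical values in both groups
        lcpm = _lcpm_from_values(vals, meta.index, [f"g{i}" for i in range(5)])
        de = fit_de(lcpm, meta)
        row = de[de["gene"] == "g0"].iloc[0]
        assert row["logFC"] == pytest.approx(0.0, abs=1e-12)
        assert row["direction"] == "ns"

    def test_planted_logfc_recovery(self, planted_expression):
        """>=90% of planted |log2FC|~2 genes recovered at FDR <= 0.01."""
        cfg, cm, truth = planted_expression
        de = fit_de(log_cpm(cm), cm.metadata, covariates=["sex", "platform"])
        sig = set(de.loc[de["direction"] != "ns", "gene"])
        planted = set(truth.de_genes)
        assert len(sig & planted) / len(planted) >= 0.90

    def test_null_false_discovery_proportion(self):
        """Realized FDP at FDR 0.01 stays <= 0.03 over 2000 null genes."""
        cfg = SimConfig(n_genes=2000, de_fraction=0.0, n_modules=0, seed=17)
        cm, _ = simulate_expression(cfg)
        de = fit_de(log_cpm(cm), cm.metadata)
        assert (de["fdr"] <= 0.01).mean() <= 0.03

    def test_permuted_labels_give_uniform_p(self):
        """Null genes with permuted group labels: p-values pass a KS test."""
        cfg = SimConfig(n_genes=2000, de_fraction=0.0, n_modules=0, seed=23)
        cm, _ = simulate_expression(cfg)
        rng = np.random.default_rng(23)
        meta = cm.metadata.copy()
        meta["group"] = rng.permutation(meta["group"].to_numpy())
        de = fit_de(log_cpm(cm), meta)
        assert stats.kstest(de["p"], "uniform").pvalue > 0.01

    def test_rank_deficient_design_reports_columns(self):
        meta = self._meta(3)
        meta["dup"] = meta["group"]  # perfectly collinear covariate
        vals = np.random.default_rng(0).normal(size=(4, 6))
        lcpm = _lcpm_from_values(vals, meta.index, [f"g{i}" for i in range(4)])
        with pytest.raises(ValueError, match="collinear"):
            fit_de(lcpm, meta, covariates=["dup"])

    def test_bh_monotone_in_p(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=500)
        fdr = bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(fdr[order]) >= -1e-12)
        assert np.all(fdr >= p)


class TestFlattenExons:
    def test_boundary_splitting(self):
        bins = flatten_exons(
            [("g", "A", [(1, 100)]), ("g", "B", [(1, 150)])]
        )
        assert [(b[2], b[3]) for b in bins] == [(1, 100), (101, 150)]

    def test_identical_isoforms(self):
        bins = flatten_exons(
            [("g", "A", [(1, 50), (100, 200)]), ("g", "B", [(1, 50), (100, 200)])]
        )
        assert [(b[2], b[3]) for b in bins] == [(1, 50), (100, 200)]

    def test_overlap_within_isoform_rejected(self):
        with pytest.raises(ValueError, match="overlapping exons"):
            flatten_exons([("g", "A", [(1, 100), (50, 150)])])

    def test_three_isoform_gene_matches_brute_force(self):
        isoforms = [
            ("g", "A", [(1, 100), (200, 300)]),
            ("g", "B", [(50, 120), (200, 250)]),
            ("g", "C", [(1, 60), (240, 320)]),
        ]
        bins = flatten_exons(isoforms)
        # brute force: per-base coverage, split at every boundary
        covered = np.zeros(400, dtype=bool)
        for _, _, exons in isoforms:
            for s, e in exons:
                covered[s : e + 1] = True
        boundaries = sorted(
            {s for _, _, ex in isoforms for s, _ in ex}
            | {e + 1 for _, _, ex in isoforms for _, e in ex}
        )
        expected = []
        for lo, hi in zip(boundaries, boundaries[1:]):
            if covered[lo : hi].all():
                expected.append((lo, hi - 1))
        assert [(b[2], b[3]) for b in bins] == expected
        # bins are disjoint and cover the union
        total = sum(e - s + 1 for _, _, s, e in bins)
        assert total == int(covered.sum())


class TestRelativeUsage:
    def test_equal_exons(self):
        vals = np.full((4, 3), 5.0)
        lcpm = _lcpm_from_values(vals, ["a", "b", "c"], [f"g:bin{k}" for k in range(4)])
        rel = relative_exon_usage(lcpm)
        assert np.allclose(rel.to_numpy(), -2.0)

    def test_single_exon_warns_and_zero(self):
        lcpm = _lcpm_from_values(np.array([[3.0, 4.0]]), ["a", "b"], ["g:bin0"])
        with pytest.warns(UserWarning, match="single-exon"):
            rel = relative_exon_usage(lcpm)
        assert np.allclose(rel.to_numpy(), 0.0)

    def test_normalization_identity(self):
        rng = np.random.default_rng(7)
        vals = rng.normal(5, 2, size=(5, 4))
        lcpm = _lcpm_from_values(vals, list("abcd"), [f"g:bin{k}" for k in range(5)])
        rel = relative_exon_usage(lcpm)
        sums = (2.0 ** rel.to_numpy()).sum(axis=0)
        assert np.allclose(sums, 1.0, atol=1e-12)


class TestExonUsage:
    def test_simes_direct_evaluation(self):
        assert simes_p([0.01, 0.02, 0.9]) == pytest.approx(0.03)

    def test_simes_bounds(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            p = rng.uniform(size=rng.integers(1, 8))
            s = simes_p(p)
            assert min(p) <= s <= 1.0
            assert s >= min(p)  # Simes never beats the minimum raw p
            assert s >= min(p) / len(p) * 1  # trivially
            assert s <= 1.0

    def test_identical_exon_logfc_is_null(self):
        rng = np.random.default_rng(5)
        n = 12
        meta = pd.DataFrame(
            {"group": ["tumor"] * 6 + ["control"] * 6},
            index=[f"s{i}" for i in range(n)],
        )
        shift = np.where(meta["group"] == "tumor", 2.0, 0.0)
        base = rng.normal(5, 1, size=(3, 1))  # per-exon level, constant in samples
        vals = base + shift[None, :]  # every exon shares the same logFC
        vals += rng.normal(0, 0.05, vals.shape)
        lcpm = _lcpm_from_values(vals, meta.index, [f"g:bin{k}" for k in range(3)])
        exon_df, gene_df = exon_usage_test(lcpm, meta)
        assert np.all(np.abs(exon_df["usage_logFC"]) < 0.2)
        assert gene_df["F_p"].iloc[0] > 0.1

    def test_planted_usage_shift_recovery(self):
        """Planted usage-shift genes reach Simes FDR < 0.05 with >=80%
        sensitivity at high depth."""
        cfg = SimConfig(
            n_genes=150, n_modules=0, splice_fraction=0.2, n_samples_per_group=15, seed=31,
            nb_dispersion=0.05,
        )
        cm, truth = simulate_exon_counts(cfg, n_exons_per_gene=4)
        exon_df, gene_df = exon_usage_test(log_cpm(cm), cm.metadata)
        hits = set(gene_df.loc[gene_df["simes_fdr"] < 0.05, "gene"])
        planted = set(truth.splice_genes)
        assert len(hits & planted) / len(planted) >= 0.80
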