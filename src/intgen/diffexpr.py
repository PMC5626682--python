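"""Differential expression and differential exon usage.

Gene-level: per-gene least-squares fit of log2-CPM on a design of group
plus covariates, with per-gene residual variances shrunk toward the grand
mean (prior df 4) before forming moderated t-statistics; BH FDR over all
tested genes.

Exon-level: relative exonic usage log2(2^x / sum_j 2^{x_j}); per-exon
usage log-fold changes (exon logFC minus the mean logFC of the gene's
other exons) with t-tests, a gene-level F-test for logFC heterogeneity,
and a gene-level combination of the per-exon p-values by the Simes method.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests

from intgen.io import CountMatrix

log = logging.getLogger(__name__)

_LN2 = np.log(2.0)


@dataclass
class LogCPMMatrix:
    """log2 counts-per-million, plus the library sizes used."""

    values: pd.DataFrame  # feature x sample
    library_sizes: pd.Series  # per sample


def log_cpm(counts: CountMatrix | pd.DataFrame, pseudocount: float = 0.5) -> LogCPMMatrix:
    """log2((count + pc) / ((libsize + 2 pc) / 1e6)) with libsize = column sum."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    lib = mat.sum(axis=0).astype(float)
    zero = lib[lib == 0]
    if len(zero):
        raise ValueError(f"all-zero sample(s): {list(zero.index)}")
    vals = np.log2(
        (mat.to_numpy(dtype=float) + pseudocount)
        / ((lib.to_numpy() + 2 * pseudocount) / 1e6)
    )
    return LogCPMMatrix(
        pd.DataFrame(vals, index=mat.index, columns=mat.columns), lib
    )


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# design matrices


def build_design(
    metadata: pd.DataFrame,
    group_col: str = "group",
    tumor_label: str = "tumor",
    covariates: Sequence[str] = (),
) -> pd.DataFrame:
    """Intercept + tumor indicator + dummy-coded covariate columns."""
    cols = {"intercept": np.ones(len(metadata))}
    cols[f"{group_col}[{tumor_label}]"] = (
        metadata[group_col] == tumor_label
    ).to_numpy(dtype=float)
    design = pd.DataFrame(cols, index=metadata.index)
    for cov in covariates:
        dummies = pd.get_dummies(metadata[cov], prefix=cov, drop_first=True, dtype=float)
        design = pd.concat([design, dummies], axis=1)
    return design


def _check_full_rank(X: pd.DataFrame) -> None:
    mat = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1]:
        # pivoted QR flags the dependent columns
        from scipy.linalg import qr

        _, _, piv = qr(mat, pivoting=True)
        bad = [X.columns[j] for j in piv[rank:]]
        raise ValueError(f"design is rank-deficient; collinear columns: {bad}")


@dataclass
class _LinearFit:
    coef: np.ndarray  # feature x p
    se2_unit: float  # c' (X'X)^-1 c for the contrast
    s2: np.ndarray  # per-feature residual variance
    df: float  # residual df
    s2_post: np.ndarray  # moderated variance
    df_total: float  # residual + prior df


def _fit_lm(
    values: np.ndarray, X: np.ndarray, contrast: np.ndarray, prior_df: float
) -> _LinearFit:
    n, p = X.shape
    if n - p < 1:
        raise ValueError("no residual degrees of freedom")
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = values @ X @ xtx_inv  # feature x p
    resid = values - beta @ X.T
    df = float(n - p)
    s2 = (resid**2).sum(axis=1) / df
    s2_prior = float(np.mean(s2)) if len(s2) else 0.0
    s2_post = (prior_df * s2_prior + df * s2) / (prior_df + df)
    return _LinearFit(
        coef=beta,
        se2_unit=float(contrast @ xtx_inv @ contrast),
        s2=s2,
        df=df,
        s2_post=s2_post,
        df_total=df + prior_df,
    )


def fit_de(
    lcpm: LogCPMMatrix,
    metadata: pd.DataFrame,
    covariates: Sequence[str] = (),
    group_col: str = "group",
    tumor_label: str = "tumor",
    fdr_de: float = 0.01,
    prior_df: float = 4.0,
) -> pd.DataFrame:
    """Per-gene moderated-t differential expression (tumor minus control).

    Returns a frame with columns gene, logFC, t, p, fdr, direction where
    direction is ``ns`` unless fdr <= ``fdr_de``, ``up`` for significant
    genes with logFC >= 0 and ``down`` otherwise.
    """
    meta = metadata.loc[lcpm.values.columns]
    counts_per_group = meta[group_col].value_counts()
    if (counts_per_group < 2).any():
        raise ValueError("need >= 2 samples per group")
    design = build_design(meta, group_col, tumor_label, covariates)
    _check_full_rank(design)
    X = design.to_numpy(dtype=float)
    contrast = np.zeros(X.shape[1])
    contrast[list(design.columns).index(f"{group_col}[{tumor_label}]")] = 1.0

    fit = _fit_lm(lcpm.values.to_numpy(dtype=float), X, contrast, prior_df)
    logfc = fit.coef @ contrast
    se = np.sqrt(fit.s2_post * fit.se2_unit)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, logfc / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), fit.df_total)
    fdr = bh_fdr(p)
    direction = np.where(
        fdr > fdr_de, "ns", np.where(logfc >= 0, "up", "down")
    )
    return pd.DataFrame(
        {
            "gene": lcpm.values.index,
            "logFC": logfc,
            "t": t,
            "p": p,
            "fdr": fdr,
            "direction": direction,
        }
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# exon machinery


def flatten_exons(
    gene_models: Sequence[tuple[str, str, Sequence[tuple[int, int]]]],
) -> list[tuple[str, int, int, int]]:
    """Flatten isoform exons into disjoint counting bins.

    ``gene_models`` holds (gene, isoform, [(start, end), ...]) with 1-based
    inclusive coordinates on one chromosome per gene.  Output bins are
    disjoint, cover the union of the input exons, split at every input
    boundary, and are numbered 5'->3' as (gene, bin_index, start, end).
    """
    by_gene: dict[str, list[tuple[str, list[tuple[int, int]]]]] = {}
    for gene, isoform, exons in gene_models:
        exons = sorted((int(s), int(e)) for s, e in exons)
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 <= e1:
                raise ValueError(
                    f"isoform {isoform!r} of gene {gene!r} has overlapping exons "
                    f"[{s1},{e1}] and [{s2},{e2}]"
                )
        by_gene.setdefault(gene, []).append((isoform, exons))

    bins: list[tuple[str, int, int, int]] = []
    for gene, isoforms in by_gene.items():
        boundaries: set[int] = set()
        covered: list[tuple[int, int]] = []
        for _, exons in isoforms:
            for s, e in exons:
                boundaries.add(s)
                boundaries.add(e + 1)  # half-open cut point
                covered.append((s, e))
        cuts = sorted(boundaries)
        covered.sort()
        merged: list[list[int]] = []
        for s, e in covered:
            if merged and s <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        idx = 0
        for lo, hi in zip(cuts, cuts[1:]):
            seg = (lo, hi - 1)
            if any(m[0] <= seg[0] and seg[1] <= m[1] for m in merged):
                bins.append((gene, idx, seg[0], seg[1]))
                idx += 1
    return bins


def _genes_from_exon_ids(index: pd.Index) -> np.ndarray:
    return np.array([str(x).rsplit(":", 1)[0] for x in index], dtype=object)


def relative_exon_usage(
    exon_lcpm: LogCPMMatrix, genes: Sequence[str] | None = None
) -> pd.DataFrame:
    """Relative usage rel_i = log2(2^{x_i} / sum_{j in gene} 2^{x_j}).

    Per gene and sample sum_j 2^{rel_j} = 1 exactly (up to rounding).
    Exon ids are expected as ``gene:bin`` unless ``genes`` is given.
    Single-exon genes get rel = 0 (with a warning).
    """
    x = exon_lcpm.values
    gene_ids = np.asarray(genes, dtype=object) if genes is not None else _genes_from_exon_ids(x.index)
    out = np.empty_like(x.to_numpy(dtype=float))
    xv = x.to_numpy(dtype=float)
    single = []
    for gene, idx in pd.Series(range(len(gene_ids)), index=gene_ids).groupby(level=0):
        rows = idx.to_numpy()
        if len(rows) == 1:
            out[rows[0]] = 0.0
            single.append(gene)
            continue
        block = xv[rows]
        lse = logsumexp(block * _LN2, axis=0) / _LN2
        out[rows] = block - lse[None, :]
    if single:
        warnings.warn(
            f"{len(single)} single-exon gene(s) have relative usage fixed at 0",
            stacklevel=2,
        )
    return pd.DataFrame(out, index=x.index, columns=x.columns)


def simes_p(pvals: Sequence[float]) -> float:
    """Simes combination: min_k (m * p_(k) / k), clipped at 1."""
    p = np.sort(np.asarray(pvals, dtype=float))
    m = len(p)
    if m == 0:
        raise ValueError("no p-values to combine")
    return float(min(1.0, np.min(m * p / np.arange(1, m + 1))))


def test_exon_usage(
    exon_lcpm: LogCPMMatrix,
    metadata: pd.DataFrame,
    covariates: Sequence[str] = (),
    group_col: str = "group",
    tumor_label: str = "tumor",
    prior_df: float = 4.0,
    genes: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Differential exon usage with gene-level Simes combination.

    Per exon, the usage logFC is the exon's group logFC minus the mean
    logFC of the same gene's other exons; its t-statistic uses the
    moderated exon variances.  Per gene, an F-test for heterogeneity of
    exon logFCs and the Simes combination of the per-exon p-values are
    reported, with BH FDR over the Simes p-values.  Genes with fewer than
    two exons are skipped (logged).
    """
    meta = metadata.loc[exon_lcpm.values.columns]
    design = build_design(meta, group_col, tumor_label, covariates)
    _check_full_rank(design)
    X = design.to_numpy(dtype=float)
    contrast = np.zeros(X.shape[1])
    contrast[list(design.columns).index(f"{group_col}[{tumor_label}]")] = 1.0
    fit = _fit_lm(exon_lcpm.values.to_numpy(dtype=float), X, contrast, prior_df)
    lfc = fit.coef @ contrast
    var = fit.s2_post * fit.se2_unit  # variance of each exon's logFC

    gene_ids = (
        np.asarray(genes, dtype=object)
        if genes is not None
        else _genes_from_exon_ids(exon_lcpm.values.index)
    )
    exon_rows = []
    gene_rows = []
    skipped = 0
    for gene, idx in pd.Series(range(len(gene_ids)), index=gene_ids).groupby(level=0):
        rows = idx.to_numpy()
        K = len(rows)
        if K < 2:
            skipped += 1
            continue
        l = lfc[rows]
        v = var[rows]
        mean_others = (l.sum() - l) / (K - 1)
        usage = l - mean_others
        var_usage = v + (v.sum() - v) / (K - 1) ** 2
        t = usage / np.sqrt(var_usage)
        p = 2.0 * stats.t.sf(np.abs(t), fit.df_total)
        for j, r in enumerate(rows):
            exon_rows.append(
                (gene, str(exon_lcpm.values.index[r]), usage[j], t[j], p[j])
            )
        # heterogeneity F: inverse-variance weighted dispersion of exon logFCs
        w = 1.0 / v
        lbar = float(np.sum(w * l) / np.sum(w))
        F = float(np.sum(w * (l - lbar) ** 2) / (K - 1))
        f_p = float(stats.f.sf(F, K - 1, fit.df_total))
        gene_rows.append((gene, K, F, f_p, simes_p(p)))
    if skipped:
        log.info("skipped %d gene(s) with < 2 exons", skipped)

    exon_df = pd.DataFrame(
        exon_rows, columns=["gene", "bin", "usage_logFC", "t", "p"]
    )
    gene_df = pd.DataFrame(
        gene_rows, columns=["gene", "n_exons", "F", "F_p", "simes_p"]
    )
    gene_df["simes_fdr"] = bh_fdr(gene_df["simes_p"].to_numpy()) if len(gene_df) else []
    return exon_df, gene_df
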