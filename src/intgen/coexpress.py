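"""Signed co-expression modules, eigengenes, membership p-values, hubs.

The network is the signed weighted one: adjacency a_ij = ((1 + cor_ij)/2)^beta,
so anti-correlated genes get adjacency near 0 rather than near 1.  Genes are
clustered by average-linkage hierarchical clustering of the topological-
overlap dissimilarity with a single static cut; clusters below the minimum
size are left unassigned (label 0).  The module eigengene is the first
principal component of the module's standardized expression; membership is
the Spearman correlation of each network gene with each eigengene, with a
two-sided p-value (the module-membership p-value, MMP).  Hub genes are
ranked by intramodular connectivity k_in = sum of within-module adjacency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform


@dataclass
class NetworkParams:
    correlation: str = "pearson"  # or "spearman"
    soft_power: float = 12.0
    min_module_size: int = 30
    merge_height: float = 0.99  # static cut on TOM dissimilarity

    def __post_init__(self) -> None:
        if self.correlation not in ("pearson", "spearman"):
            raise ValueError("correlation must be 'pearson' or 'spearman'")
        if self.soft_power < 1:
            raise ValueError("soft_power must be >= 1")


@dataclass
class ModuleSet:
    """Module labels (0 = unassigned), eigengenes, kME/MMP, connectivity."""

    labels: pd.Series  # gene -> module id
    eigengenes: pd.DataFrame  # module x sample, unit-norm rows
    kme: pd.DataFrame  # gene x module Spearman correlations
    mmp: pd.DataFrame  # gene x module two-sided p-values
    k_in: pd.Series  # gene -> intramodular connectivity

    @property
    def module_ids(self) -> list[int]:
        return [int(m) for m in self.eigengenes.index]

    def members(self, module: int) -> list[str]:
        return list(self.labels.index[self.labels == module])

    def to_frame(self) -> pd.DataFrame:
        """One row per gene: module, kME/MMP against its own module, k_in."""
        rows = []
        for gene, module in self.labels.items():
            if module in self.module_ids:
                kme = float(self.kme.loc[gene, module])
                mmp = float(self.mmp.loc[gene, module])
            else:
                kme = np.nan
                mmp = np.nan
            rows.append((gene, int(module), kme, mmp, float(self.k_in.get(gene, np.nan))))
        return pd.DataFrame(rows, columns=["gene", "module", "kme", "mmp", "k_in"])


def _correlation(values: np.ndarray, method: str) -> np.ndarray:
    if method == "spearman":
        values = np.apply_along_axis(stats.rankdata, 1, values)
    return np.corrcoef(values)


def signed_adjacency(values: np.ndarray, power: float, method: str = "pearson") -> np.ndarray:
    """a_ij = ((1 + cor_ij) / 2)^power with zero diagonal."""
    cor = _correlation(values, method)
    a = ((1.0 + cor) / 2.0) ** power
    np.fill_diagonal(a, 0.0)
    return np.clip(a, 0.0, 1.0)


def topological_overlap(adj: np.ndarray) -> np.ndarray:
    """Standard TOM: (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij), diag 1."""
    k = adj.sum(axis=0)
    l = adj @ adj
    denom = np.minimum.outer(k, k) + 1.0 - adj
    tom = (l + adj) / denom
    np.fill_diagonal(tom, 1.0)
    return tom


def detect_modules(lcpm, params: NetworkParams | None = None) -> ModuleSet:
    """Detect signed co-expression modules from a log-CPM matrix.

    Constant-expression genes (undefined correlation) are dropped with a
    warning and labelled 0.  Requires >= 8 samples.
    """
    params = params or NetworkParams()
    values = lcpm.values if hasattr(lcpm, "values") and isinstance(lcpm.values, pd.DataFrame) else lcpm
    if values.shape[1] < 8:
        raise ValueError("need >= 8 samples to estimate a co-expression network")
    genes = np.asarray(values.index, dtype=object)
    mat = values.to_numpy(dtype=float)
    sd = mat.std(axis=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"removing {int(constant.sum())} constant-expression gene(s) "
            "(undefined correlation)",
            stacklevel=2,
        )
    keep = ~constant
    labels = pd.Series(0, index=pd.Index(genes, name="gene"), dtype=int)
    adj = None
    if keep.sum() >= max(2, params.min_module_size):
        adj = signed_adjacency(mat[keep], params.soft_power, params.correlation)
        diss = 1.0 - topological_overlap(adj)
        np.fill_diagonal(diss, 0.0)
        Z = linkage(squareform(diss, checks=False), method="average")
        raw = fcluster(Z, t=params.merge_height, criterion="distance")
        # keep clusters meeting the size threshold, relabel by decreasing size
        sizes = pd.Series(raw).value_counts()
        kept = [c for c in sizes.index if sizes[c] >= params.min_module_size]
        kept.sort(key=lambda c: (-sizes[c], c))
        remap = {c: i + 1 for i, c in enumerate(kept)}
        labels.iloc[np.flatnonzero(keep)] = [remap.get(c, 0) for c in raw]

    eig = module_eigengene(values, labels)
    kme, mmp = module_membership(values, eig)
    # intramodular connectivity from the module submatrices
    k_in = pd.Series(0.0, index=labels.index)
    if labels.max() > 0 and adj is not None:
        full_adj = adj
        kept_genes = genes[keep]
        pos = {g: i for i, g in enumerate(kept_genes)}
        for module in range(1, int(labels.max()) + 1):
            mem = [g for g in kept_genes if labels[g] == module]
            rows = [pos[g] for g in mem]
            sub = full_adj[np.ix_(rows, rows)]
            k_in.loc[mem] = sub.sum(axis=1)  # diag already zero
    return ModuleSet(labels, eig, kme, mmp, k_in)


def module_eigengene(values: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """First principal component per module of the standardized block.

    Genes are standardized across samples; the eigengene is the first right
    singular vector, sign-oriented so that its correlation with the
    module's average standardized profile is positive.  Rows are unit-norm.
    """
    modules = sorted(int(m) for m in labels.unique() if m > 0)
    out = {}
    mat = values.to_numpy(dtype=float)
    gene_index = {g: i for i, g in enumerate(values.index)}
    for module in modules:
        rows = [gene_index[g] for g in labels.index[labels == module]]
        block = mat[rows]
        mu = block.mean(axis=1, keepdims=True)
        sd = block.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        z = (block - mu) / sd
        _, _, vt = np.linalg.svd(z, full_matrices=False)
        eig = vt[0]
        avg = z.mean(axis=0)
        if np.dot(eig, avg) < 0:
            eig = -eig
        out[module] = eig / np.linalg.norm(eig)
    return pd.DataFrame(out, index=values.columns).T.rename_axis("module")


def _spearman_p_exact(r_obs: float, x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact permutation p for the Spearman correlation (n <= 8)."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    n = len(rx)
    rys = (ry - ry.mean()) / ry.std()
    rxs = (rx - rx.mean()) / rx.std()
    count = 0
    total = 0
    for perm in permutations(range(n)):
        r = float(np.mean(rxs[list(perm)] * rys))
        total += 1
        if abs(r) >= abs(r_obs) - 1e-12:
            count += 1
    return count / total


def module_membership(
    values: pd.DataFrame, eigengenes: pd.DataFrame, exact_max_n: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman kME of every network gene vs every module eigengene + MMP.

    The MMP is the two-sided significance of the Spearman correlation via
    the t-approximation with n - 2 df; for tiny cohorts (n <= ``exact_max_n``,
    at most 8) an exact permutation p is used instead.
    """
    n = values.shape[1]
    if n < 4:
        raise ValueError("need >= 4 samples for a meaningful Spearman p-value")
    if eigengenes.empty:
        empty = pd.DataFrame(index=values.index, columns=[], dtype=float)
        return empty, empty.copy()
    ranks = np.apply_along_axis(stats.rankdata, 1, values.to_numpy(dtype=float))
    erank = np.apply_along_axis(stats.rankdata, 1, eigengenes.to_numpy(dtype=float))

    def _std(a: np.ndarray) -> np.ndarray:
        mu = a.mean(axis=1, keepdims=True)
        sd = a.std(axis=1, keepdims=True)
        sd[sd == 0] = np.inf  # constant -> zero correlation
        return (a - mu) / sd

    zg = _std(ranks)
    ze = _std(erank)
    kme = zg @ ze.T / n  # gene x module Spearman correlations
    r = np.clip(kme, -1.0, 1.0)
    if 0 < n <= min(exact_max_n, 8):
        vals = values.to_numpy(dtype=float)
        evals = eigengenes.to_numpy(dtype=float)
        mmp = np.empty_like(r)
        for i in range(r.shape[0]):
            for j in range(r.shape[1]):
                mmp[i, j] = _spearman_p_exact(r[i, j], vals[i], evals[j])
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            t = r * np.sqrt((n - 2) / np.clip(1.0 - r**2, 1e-300, None))
        mmp = 2.0 * stats.t.sf(np.abs(t), n - 2)
        mmp[np.abs(r) >= 1.0] = 0.0
    cols = [int(m) for m in eigengenes.index]
    return (
        pd.DataFrame(kme, index=values.index, columns=cols),
        pd.DataFrame(mmp, index=values.index, columns=cols),
    )


def hub_genes(
    lcpm,
    labels: pd.Series,
    module: int,
    top_n: int = 20,
    params: NetworkParams | None = None,
    adjacency: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Top ``top_n`` module genes by intramodular connectivity.

    ``adjacency`` (gene x gene, labelled) short-circuits recomputation.
    Ties break lexicographically on gene id.
    """
    members = [g for g in labels.index if labels[g] == module]
    if not members:
        raise ValueError(f"module {module} does not exist or is empty")
    if top_n > len(members):
        warnings.warn(
            f"top_n={top_n} exceeds module size {len(members)}; returning all",
            stacklevel=2,
        )
        top_n = len(members)
    if adjacency is not None:
        sub = adjacency.loc[members, members].to_numpy(dtype=float).copy()
    else:
        params = params or NetworkParams()
        values = lcpm.values if hasattr(lcpm, "values") and isinstance(lcpm.values, pd.DataFrame) else lcpm
        block = values.loc[members].to_numpy(dtype=float)
        sub = signed_adjacency(block, params.soft_power, params.correlation)
    np.fill_diagonal(sub, 0.0)
    k_in = pd.Series(sub.sum(axis=1), index=members, name="k_in")
    order = sorted(members, key=lambda g: (-k_in[g], g))[:top_n]
    return pd.DataFrame({"gene": order, "k_in": [k_in[g] for g in order]})
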