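"""Fisher-exact projection of gene sets onto targets, and the FDR score.

Given a gene signature, a universe and a family of target sets (modules,
DEG classes), each signature-by-target overlap is tested with the exact
hypergeometric test.  One-sided p is the upper tail P[X >= k]; two-sided p
sums the probabilities of all tables at most as probable as the observed
one (the "minlike" convention used by common exact-test implementations).
BH FDR is computed over all records of a call.

The FDR score maps each two-sided record to a signed heat-map value:
-log2(FDR) for over-enrichment (odds ratio > 1), +log2(FDR) for
under-enrichment (odds ratio < 1), 0 whenever FDR > 0.05, with absolute
values capped (default 50).
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from intgen.diffexpr import bh_fdr
from intgen.io import GeneSignature

_MINLIKE_GAMMA = 1.0 + 1e-7  # relative tolerance when comparing table probabilities


def table_pvalues(n_sig: int, n_tgt: int, N: int) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Exact p-values for every possible overlap k of a 2x2 table.

    Returns (support, pmf, p_greater, p_two_sided) where support runs over
    all feasible k given ``n_sig`` signature genes, ``n_tgt`` target genes
    and a universe of ``N``.
    """
    lo = max(0, n_sig + n_tgt - N)
    hi = min(n_sig, n_tgt)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, N, n_sig, n_tgt)
    p_greater = np.minimum(1.0, pmf[::-1].cumsum()[::-1])
    p_two = np.array(
        [pmf[pmf <= pmf[i] * _MINLIKE_GAMMA].sum() for i in range(len(support))]
    )
    return support, pmf, p_greater, np.minimum(1.0, p_two)


def _one_table(k: int, n_sig: int, n_tgt: int, N: int, sided: str) -> tuple[float, float, float]:
    """(p, odds_ratio, fold_enrichment) for one observed overlap."""
    support, _, p_greater, p_two = table_pvalues(n_sig, n_tgt, N)
    i = k - support[0]
    if not 0 <= i < len(support):
        raise ValueError(f"overlap k={k} infeasible for table ({n_sig}, {n_tgt}, {N})")
    p = float(p_greater[i] if sided == "one_greater" else p_two[i])
    a = k
    b = n_sig - k
    c = n_tgt - k
    d = N - n_sig - n_tgt + k
    if min(a, b, c, d) < 0:
        raise ValueError("inconsistent 2x2 table")
    if b == 0 or c == 0:
        # Haldane 0.5 correction only when a zero cell makes the OR undefined
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    expected = n_sig * n_tgt / N
    fold = k / expected if expected > 0 else np.nan
    return p, float(odds), float(fold)


def fisher_projection(
    signatures: GeneSignature | Iterable[GeneSignature],
    targets: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    sided: str = "two",
) -> pd.DataFrame:
    """Test every signature against every target set within the universe.

    Signature and target sets are intersected with the universe before
    counting.  Returns one record per (signature, target) with overlap
    counts, odds ratio, fold enrichment (k N / (n_sig n_tgt)), p and a BH
    FDR computed jointly over all records of this call.
    """
    if sided not in ("one_greater", "two"):
        raise ValueError("sided must be 'one_greater' or 'two'")
    if isinstance(signatures, GeneSignature):
        signatures = [signatures]
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    N = len(universe)
    rows = []
    for sig in signatures:
        sig_set = set(sig.members) & universe
        if not sig_set:
            raise ValueError(f"signature {sig.name!r} is disjoint from the universe")
        for tname, tgenes in targets.items():
            tgt = set(tgenes) & universe
            k = len(sig_set & tgt)
            p, odds, fold = _one_table(k, len(sig_set), len(tgt), N, sided)
            rows.append(
                (sig.name, tname, k, len(sig_set), len(tgt), N, odds, fold, p)
            )
    out = pd.DataFrame(
        rows,
        columns=[
            "signature",
            "target",
            "k",
            "n_sig",
            "n_tgt",
            "N",
            "odds_ratio",
            "fold_enrichment",
            "p",
        ],
    )
    out["fdr"] = bh_fdr(out["p"].to_numpy())
    return out


def classify_enrichment(
    records: pd.DataFrame,
    over_fold: float = 2.0,
    under_fold: float = 0.6,
    fdr_cut: float = 0.01,
) -> pd.DataFrame:
    """Add a call column: over (fold > over_fold, fdr < cut), under, or ns.

    Both inequalities are strict, so fold exactly at a threshold is ns.
    """
    out = records.copy()
    fold = out["fold_enrichment"].to_numpy(dtype=float)
    fdr = out["fdr"].to_numpy(dtype=float)
    call = np.where(
        (fold > over_fold) & (fdr < fdr_cut),
        "over",
        np.where((fold < under_fold) & (fdr < fdr_cut), "under", "ns"),
    )
    out["call"] = call
    return out


def fdr_score(
    records: pd.DataFrame, cap: float = 50.0, significance: float = 0.05
) -> pd.DataFrame:
    """Signed, capped -log2(FDR) scores for two-sided enrichment records.

    Score is 0 whenever FDR > ``significance``; otherwise +min(cap,
    -log2(FDR)) for odds ratio > 1 and the negative of that for odds
    ratio < 1.  An odds ratio of exactly 1 has no direction and scores 0.
    FDR = 0 scores at the cap.
    """
    out = records.copy()
    fdr = out["fdr"].to_numpy(dtype=float)
    odds = out["odds_ratio"].to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        magnitude = np.minimum(cap, -np.log2(np.clip(fdr, 0.0, None)))
    magnitude = np.where(fdr == 0.0, cap, magnitude)
    sign = np.sign(odds - 1.0)
    score = np.where(fdr > significance, 0.0, sign * magnitude)
    out["fdr_score"] = score
    return out


def score_matrix(records: pd.DataFrame) -> pd.DataFrame:
    """Pivot scored records to a signature x target matrix of FDR scores."""
    return records.pivot(index="signature", columns="target", values="fdr_score")
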