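"""Allele-specific expression against an empirical reference-bias null.

RNA-seq read alignment favors the reference allele, so at a balanced
heterozygous site the observed reference fraction sits above 1/2 (around
0.54 after filtering).  The pipeline therefore (1) filters sites: >= 30
supporting reads, outside repeat/low-mappability masks, and excluding
A/G and the reverse-complement T/C allele pairs (likely RNA editing);
(2) estimates the null reference fraction p0 as the median of per-site
pooled fractions within each group; (3) tests each locus against p0 with
a quasi-binomial (dispersion-inflated Wald) test and controls the BH FDR
within each group.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from intgen.diffexpr import bh_fdr
from intgen.io import RegionMask

_AG_SETS = ({"A", "G"}, {"T", "C"})


def filter_ase_sites(
    table: pd.DataFrame,
    mask: RegionMask | None = None,
    min_depth: int = 30,
) -> pd.DataFrame:
    """Flag each record; a record passes iff no flag is set.

    Flags: ``low_depth`` (ref + alt reads < ``min_depth``), ``masked``
    (0-based position inside a mask interval; table positions are
    1-based), ``ag_pair`` ({ref, alt} equals {A,G} or {T,C}).
    """
    out = table.copy()
    depth = out["ref_count"].to_numpy() + out["alt_count"].to_numpy()
    out["depth"] = depth
    out["low_depth"] = depth < min_depth
    if mask is None:
        out["masked"] = False
    else:
        out["masked"] = mask.contains_many(
            out["chrom"].to_numpy(dtype=object), out["pos"].to_numpy() - 1
        )
    pairs = [{r, a} for r, a in zip(out["ref"], out["alt"])]
    out["ag_pair"] = [p in _AG_SETS for p in pairs]
    out["passes"] = ~(out["low_depth"] | out["masked"] | out["ag_pair"])
    return out


def estimate_null_fraction(
    flagged: pd.DataFrame, group: str, min_sites: int = 50
) -> tuple[float, int]:
    """Median per-site pooled reference fraction among passing sites.

    Per site the pooled fraction is sum(ref) / sum(depth) over the group's
    samples; the median is robust to a minority of truly imbalanced loci
    contaminating the null set.  Returns (p0, n_sites used).
    """
    sub = flagged[(flagged["passes"]) & (flagged["group"] == group)]
    pooled = sub.groupby(["chrom", "pos"]).agg(
        ref=("ref_count", "sum"), depth=("depth", "sum")
    )
    pooled = pooled[pooled["depth"] > 0]
    if len(pooled) < min_sites:
        raise ValueError(
            f"only {len(pooled)} passing sites in group {group!r}; "
            f"need >= {min_sites} to estimate the null fraction"
        )
    fractions = pooled["ref"] / pooled["depth"]
    return float(fractions.median()), int(len(pooled))


def quasibinomial_test(
    flagged: pd.DataFrame,
    p0: float | dict[str, float],
    groups: tuple[str, str] = ("tumor", "control"),
    fdr_ase: float = 0.05,
    require_both_groups: bool = True,
) -> pd.DataFrame:
    """Per-locus per-group quasi-binomial test of the reference fraction.

    For each locus within a group with per-sample reference counts y_s out
    of depths n_s: pooled p_hat = sum y / sum n; Pearson dispersion
    phi_hat = max(1, (1/(S-1)) sum (y_s - n_s p_hat)^2 / (n_s p_hat (1 - p_hat)))
    for S >= 2 (phi_hat = 1 for a single sample); Wald statistic
    z = (p_hat - p0) / sqrt(phi_hat p_hat (1 - p_hat) / sum n); two-sided
    normal p; BH FDR across loci within each group.  A pooled fraction of
    exactly 0 or 1 is continuity-corrected to (sum y + 0.5)/(sum n + 1).

    ``p0`` may be a single float or a per-group mapping.  By default only
    loci passing filters in at least one sample of *each* group are tested.
    """
    sub = flagged[flagged["passes"]].copy()
    sub["locus"] = sub["chrom"].astype(str) + ":" + sub["pos"].astype(str)
    if require_both_groups:
        per_group = sub.groupby("locus")["group"].agg(lambda g: set(g))
        keep = per_group[per_group.apply(lambda s: all(g in s for g in groups))].index
        sub = sub[sub["locus"].isin(set(keep))]

    rows = []
    for group in groups:
        p0_g = p0[group] if isinstance(p0, dict) else float(p0)
        gsub = sub[sub["group"] == group]
        for locus, block in gsub.groupby("locus"):
            y = block["ref_count"].to_numpy(dtype=float)
            n = block["depth"].to_numpy(dtype=float)
            S = len(y)
            total_n = n.sum()
            p_hat = y.sum() / total_n
            if p_hat in (0.0, 1.0):
                p_hat = (y.sum() + 0.5) / (total_n + 1.0)
            if S >= 2:
                pearson = ((y - n * p_hat) ** 2 / (n * p_hat * (1 - p_hat))).sum()
                phi = max(1.0, pearson / (S - 1))
            else:
                phi = 1.0
            se = np.sqrt(phi * p_hat * (1 - p_hat) / total_n)
            z = (p_hat - p0_g) / se
            p = 2.0 * stats.norm.sf(abs(z))
            rows.append((locus, group, S, p_hat, phi, z, p))
    out = pd.DataFrame(
        rows, columns=["locus", "group", "n_samples", "p_hat", "phi", "z", "p"]
    )
    out["fdr"] = np.nan
    for group in groups:
        sel = out["group"] == group
        if sel.any():
            out.loc[sel, "fdr"] = bh_fdr(out.loc[sel, "p"].to_numpy())
    p0_arr = np.array(
        [p0[g] if isinstance(p0, dict) else float(p0) for g in out["group"]]
    )
    significant = out["fdr"].to_numpy() <= fdr_ase
    out["preferred_allele"] = np.where(
        ~significant,
        "none",
        np.where(out["p_hat"].to_numpy() > p0_arr, "ref", "alt"),
    )
    out["neglog10_fdr"] = -np.log10(np.clip(out["fdr"].to_numpy(dtype=float), 1e-300, None))
    return out
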