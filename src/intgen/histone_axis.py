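"""The DE-ranked gene axis with binary mark tracks and smoothing curves.

Genes tested for differential expression are laid out on one axis ordered
by signed significance, each signature contributes a 0/1 track (1 = gene
carries the mark), and each track is smoothed with a sliding window of
2*flank + 1 genes (201 at the default flank of 100), truncated at the
axis ends.  Up-DEG-vs-signature enrichment uses the one-sided Fisher test
with the DE-tested universe as background.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from intgen.enrichment import fisher_projection
from intgen.io import GeneSignature

ORDER_MODES = ("signed_significance", "paper_literal")


@dataclass
class RankedAxis:
    """Ordered gene axis with per-gene DE annotations and signature tracks."""

    table: pd.DataFrame  # ordered; columns gene, logFC, fdr, neglog10_fdr, direction
    tracks: dict[str, np.ndarray] = field(default_factory=dict)
    curves: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def genes(self) -> list[str]:
        return list(self.table["gene"])

    def to_frame(self) -> pd.DataFrame:
        out = self.table.copy()
        for name, track in self.tracks.items():
            out[f"track_{name}"] = track
        for name, curve in self.curves.items():
            out[f"curve_{name}"] = curve
        return out


def rank_genes(de: pd.DataFrame, order_mode: str = "signed_significance") -> RankedAxis:
    """Order the DE-tested universe along a single significance axis.

    ``signed_significance`` (default) sorts by sign(logFC) * (-log10 fdr)
    ascending (ties by logFC then gene id), placing the most significant
    down-genes at one end and the most significant up-genes at the other.
    ``paper_literal`` keeps the alternative reading: up-genes (logFC >= 0)
    ascending by significance first, then down-genes descending.
    """
    if order_mode not in ORDER_MODES:
        raise ValueError(f"order_mode must be one of {ORDER_MODES}")
    if de["fdr"].isna().any():
        raise ValueError("NaN FDR in DE results")
    tab = de.copy()
    with np.errstate(divide="ignore"):
        tab["neglog10_fdr"] = -np.log10(np.clip(tab["fdr"].to_numpy(dtype=float), 1e-300, None))
    up = tab["logFC"].to_numpy(dtype=float) >= 0
    if order_mode == "signed_significance":
        s = np.where(up, 1.0, -1.0) * tab["neglog10_fdr"].to_numpy()
        tab = tab.assign(_s=s).sort_values(
            ["_s", "logFC", "gene"], kind="mergesort"
        ).drop(columns="_s")
    else:
        tab_up = tab[up].sort_values(["neglog10_fdr", "gene"], kind="mergesort")
        tab_down = tab[~up].sort_values(
            ["neglog10_fdr", "gene"], ascending=[False, True], kind="mergesort"
        )
        tab = pd.concat([tab_up, tab_down])
    cols = ["gene", "logFC", "fdr", "neglog10_fdr"]
    if "direction" in tab.columns:
        cols.append("direction")
    return RankedAxis(tab[cols].reset_index(drop=True))


def mark_track(axis: RankedAxis, signature: GeneSignature) -> np.ndarray:
    """Binary vector along the axis: 1 iff the gene carries the mark."""
    members = set(signature.members)
    track = np.fromiter(
        (1 if g in members else 0 for g in axis.genes), dtype=np.int8, count=len(axis.genes)
    )
    axis.tracks[signature.name] = track
    return track


def sliding_window_curve(track: np.ndarray, flank: int = 100) -> np.ndarray:
    """Mean of the track over [i - flank, i + flank], truncated at the ends.

    Interior windows contain exactly 2*flank + 1 entries.
    """
    if flank < 1:
        raise ValueError("flank must be >= 1")
    track = np.asarray(track, dtype=float)
    L = len(track)
    if L < 2:
        raise ValueError("track must have length >= 2")
    csum = np.concatenate([[0.0], np.cumsum(track)])
    idx = np.arange(L)
    lo = np.maximum(0, idx - flank)
    hi = np.minimum(L - 1, idx + flank)
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)


def smooth_tracks(axis: RankedAxis, flank: int = 100) -> None:
    """Attach a smoothed curve for every track on the axis."""
    for name, track in axis.tracks.items():
        axis.curves[name] = sliding_window_curve(track, flank)


def axis_enrichment(
    axis: RankedAxis, signature: GeneSignature, universe=None
) -> pd.DataFrame:
    """One-sided Fisher enrichment of the signature among up-DEGs."""
    if "direction" not in axis.table.columns:
        raise ValueError("axis table lacks direction calls")
    universe = set(universe) if universe is not None else set(axis.genes)
    up = set(axis.table.loc[axis.table["direction"] == "up", "gene"])
    return fisher_projection(signature, {"up_deg": up}, universe, sided="one_greater")
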