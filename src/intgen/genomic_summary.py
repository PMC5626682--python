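"""Mutation burden, recurrence, panel coverage and CNV recurrence tracks."""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from intgen.enrichment import fisher_projection
from intgen.io import GeneSignature

CNV_CLASSES = ("gain", "loss", "cnLOH")


def variant_burden(
    variants: pd.DataFrame, n_samples: int, samples: Sequence[str] | None = None
) -> tuple[pd.Series, float]:
    """Per-sample protein-altering somatic variant counts and the cohort mean.

    Samples without any variant still count toward the denominator; the
    mean is total / n_samples rounded to one decimal.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    som = (
        variants[variants["somatic"].astype(bool)]
        if "somatic" in variants.columns
        else variants
    )
    counts = som.groupby("sample").size()
    if samples is not None:
        counts = counts.reindex(samples, fill_value=0)
    elif len(counts) < n_samples:
        pass  # zero-variant samples are unobservable without an explicit list
    total = int(som.shape[0])
    mean = round(total / n_samples, 1)
    return counts.astype(int), mean


def recurrent_genes(
    variants: pd.DataFrame, min_samples: int = 2, include_germline: bool = False
) -> pd.DataFrame:
    """Genes mutated in >= ``min_samples`` distinct samples.

    Two hits in the same sample do not make a gene recurrent.  Germline
    records are excluded unless ``include_germline`` (a germline hit in a
    known predisposition gene can be counted alongside somatic ones).
    """
    tab = variants if include_germline else variants[variants["somatic"].astype(bool)]
    counts = tab.groupby("gene")["sample"].nunique()
    rec = counts[counts >= min_samples].sort_values(ascending=False)
    return pd.DataFrame({"gene": rec.index, "n_samples": rec.to_numpy()}).reset_index(
        drop=True
    )


def geneset_fisher(
    hit_genes: Iterable[str],
    annotation: GeneSignature | Iterable[str],
    universe: Iterable[str],
) -> pd.DataFrame:
    """One-sided Fisher enrichment of hit genes in an annotation set."""
    if not isinstance(annotation, GeneSignature):
        annotation = GeneSignature("annotation", "", frozenset(annotation))
    return fisher_projection(
        annotation, {"hits": set(hit_genes)}, universe, sided="one_greater"
    )


def _round_half_up_percent(fraction: float) -> int:
    return int(math.floor(fraction * 100.0 + 0.5))


def epigene_coverage(
    variants: pd.DataFrame,
    segments: pd.DataFrame,
    gene_coords: Mapping[str, tuple[str, int, int]],
    panel: Sequence[str],
    samples: Sequence[str],
) -> tuple[pd.DataFrame, int]:
    """Which samples carry a hit in any panel gene, and the covered percent.

    A sample hits a panel gene through a variant in that gene or through a
    gain/loss/cnLOH segment overlapping the gene's coordinates (1-based
    inclusive).  Returns the boolean sample x gene matrix and the fraction
    of samples with >= 1 hit as an integer percent (round half up).
    """
    missing = [g for g in panel if g not in gene_coords]
    if missing:
        raise ValueError(f"panel gene(s) without coordinates: {missing}")
    hit = pd.DataFrame(False, index=list(samples), columns=list(panel))
    var_hits = variants[variants["gene"].isin(panel)]
    for _, row in var_hits.iterrows():
        if row["sample"] in hit.index:
            hit.loc[row["sample"], row["gene"]] = True
    cnv = segments[segments["class"].isin(CNV_CLASSES)]
    for _, row in cnv.iterrows():
        if row["sample"] not in hit.index:
            continue
        for gene in panel:
            chrom, gstart, gend = gene_coords[gene]
            if row["chrom"] == chrom and row["start"] <= gend and row["end"] >= gstart:
                hit.loc[row["sample"], gene] = True
    fraction = float(hit.any(axis=1).mean()) if len(hit) else 0.0
    return hit, _round_half_up_percent(fraction)


def cnv_recurrence_track(
    segments: pd.DataFrame,
    chrom_lengths: Mapping[str, int],
    n_samples: int,
    bin_size: int = 1_000_000,
) -> pd.DataFrame:
    """Per-bin per-class fraction of samples with an overlapping segment.

    Bins tile each chromosome without overlap; a sample counts once per
    bin per class on any (>= 1 bp) overlap.  Fractions render as tracks
    where each line is a fixed share (e.g. 20%) of the cohort.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    beyond = segments.apply(
        lambda r: r["chrom"] in chrom_lengths and r["end"] > chrom_lengths[r["chrom"]],
        axis=1,
    ) if len(segments) else pd.Series(dtype=bool)
    if len(segments) and beyond.any():
        bad = segments[beyond].iloc[0]
        raise ValueError(
            f"segment {bad['chrom']}:{bad['start']}-{bad['end']} exceeds "
            f"chromosome length {chrom_lengths[bad['chrom']]}"
        )
    unknown = set(segments["chrom"]) - set(chrom_lengths) if len(segments) else set()
    if unknown:
        raise ValueError(f"segment chromosome(s) without a stated length: {sorted(unknown)}")

    rows = []
    for chrom, length in chrom_lengths.items():
        n_bins = int(np.ceil(length / bin_size))
        starts = np.arange(n_bins, dtype=np.int64) * bin_size + 1
        ends = np.minimum(starts + bin_size - 1, length)
        fractions = {klass: np.zeros(n_bins) for klass in CNV_CLASSES}
        csub = segments[segments["chrom"] == chrom] if len(segments) else segments
        for klass in CNV_CLASSES:
            ksub = csub[csub["class"] == klass] if len(csub) else csub
            if not len(ksub):
                continue
            carriers = [set() for _ in range(n_bins)]
            for _, seg in ksub.iterrows():
                first = int((seg["start"] - 1) // bin_size)
                last = int((seg["end"] - 1) // bin_size)
                for b in range(first, min(last, n_bins - 1) + 1):
                    carriers[b].add(seg["sample"])
            fractions[klass] = np.array([len(c) / n_samples for c in carriers])
        for b in range(n_bins):
            rows.append(
                (
                    chrom,
                    int(starts[b]),
                    int(ends[b]),
                    fractions["gain"][b],
                    fractions["loss"][b],
                    fractions["cnLOH"][b],
                )
            )
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "gain", "loss", "cnLOH"]
    )
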