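"""Readers and writers for the plain-text formats the pipeline touches.

Coordinate conventions: BED masks are 0-based half-open; SEG segments and
allele-count positions are 1-based inclusive.  Conversions happen only
inside the readers, never downstream.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from intgen import __version__
from intgen.config import StudyConfig

SEG_CLASSES = frozenset({"gain", "loss", "cnLOH", "normal", "undecided"})
_NUCLEOTIDES = frozenset("ACGT")


# ---------------------------------------------------------------------------
# containers


@dataclass
class CountMatrix:
    """Nonnegative integer gene(or exon-bin) x sample counts plus metadata.

    ``counts`` is indexed by feature id with one column per sample;
    ``metadata`` is indexed by sample (same order as the count columns) and
    must carry a ``group`` column plus any covariates.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dups = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicated feature identifiers: {dups[:5]}")
        if "group" not in self.metadata.columns:
            raise ValueError("sample metadata lacks required column 'group'")
        missing = [s for s in self.counts.columns if s not in self.metadata.index]
        if missing:
            raise ValueError(f"samples missing from metadata: {missing}")
        vals = self.counts.to_numpy()
        if np.isnan(vals.astype(float)).any():
            r, c = np.argwhere(np.isnan(vals.astype(float)))[0]
            raise ValueError(
                f"NaN count at gene {self.counts.index[r]!r}, sample {self.counts.columns[c]!r}"
            )
        if (vals < 0).any():
            r, c = np.argwhere(vals < 0)[0]
            raise ValueError(
                f"negative count at gene {self.counts.index[r]!r}, sample {self.counts.columns[c]!r}"
            )
        if not np.allclose(vals, np.round(vals)):
            raise ValueError("counts must be integers")
        # align metadata rows with count columns
        self.metadata = self.metadata.loc[list(self.counts.columns)]

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def features(self) -> list[str]:
        return list(self.counts.index)


@dataclass(frozen=True)
class GeneSignature:
    """A named gene set (GMT record); members are deduplicated."""

    name: str
    description: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"signature {self.name!r} has no members")


@dataclass
class RegionMask:
    """Per-chromosome sorted, merged 0-based half-open intervals."""

    intervals: dict[str, np.ndarray] = field(default_factory=dict)

    @classmethod
    def from_intervals(cls, triples: Iterable[tuple[str, int, int]]) -> "RegionMask":
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in triples:
            if start >= end:
                raise ValueError(f"empty/inverted interval {chrom}:{start}-{end}")
            by_chrom.setdefault(chrom, []).append((int(start), int(end)))
        merged: dict[str, np.ndarray] = {}
        for chrom, ivals in by_chrom.items():
            ivals.sort()
            out: list[list[int]] = []
            for s, e in ivals:
                if out and s <= out[-1][1]:
                    out[-1][1] = max(out[-1][1], e)
                else:
                    out.append([s, e])
            merged[chrom] = np.asarray(out, dtype=np.int64)
        return cls(merged)

    def contains(self, chrom: str, pos0: int) -> bool:
        """Membership of a single 0-based position."""
        ivals = self.intervals.get(chrom)
        if ivals is None or len(ivals) == 0:
            return False
        i = int(np.searchsorted(ivals[:, 0], pos0, side="right")) - 1
        return i >= 0 and pos0 < ivals[i, 1]

    def contains_many(self, chroms: Sequence[str], pos0: Sequence[int]) -> np.ndarray:
        pos0 = np.asarray(pos0, dtype=np.int64)
        out = np.zeros(len(pos0), dtype=bool)
        chroms = np.asarray(chroms, dtype=object)
        for chrom in pd.unique(chroms):
            ivals = self.intervals.get(chrom)
            if ivals is None or len(ivals) == 0:
                continue
            sel = chroms == chrom
            p = pos0[sel]
            idx = np.searchsorted(ivals[:, 0], p, side="right") - 1
            hit = (idx >= 0) & (p < ivals[np.clip(idx, 0, None), 1])
            out[sel] = hit
        return out

    def total_length(self) -> int:
        return int(sum((iv[:, 1] - iv[:, 0]).sum() for iv in self.intervals.values()))


# ---------------------------------------------------------------------------
# TSV helpers


def _header_lines(config: StudyConfig | None) -> str:
    lines = [f"# intgen {__version__}"]
    if config is not None:
        lines.append(f"# config_hash={config.config_hash()} seed={config.seed}")
    return "\n".join(lines) + "\n"


def write_tsv(
    df: pd.DataFrame,
    path: str | Path,
    config: StudyConfig | None = None,
    index: bool = False,
    index_label: str | None = None,
) -> None:
    """Write a TSV with leading '#' header lines recording version/config."""
    with open(path, "w") as fh:
        fh.write(_header_lines(config))
        df.to_csv(fh, sep="\t", index=index, index_label=index_label)


def _read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


# ---------------------------------------------------------------------------
# counts


def read_counts(path: str | Path, metadata_path: str | Path) -> CountMatrix:
    """Read a feature x sample count TSV plus per-sample metadata.

    First column of ``path`` holds feature ids; remaining columns are
    samples.  ``metadata_path`` must have a ``sample`` column (or the first
    column is taken as sample id) and a ``group`` column.
    """
    counts = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    meta = _read_table(metadata_path)
    if "sample" in meta.columns:
        meta = meta.set_index("sample")
    else:
        meta = meta.set_index(meta.columns[0])
    meta.index = meta.index.astype(str)
    counts.columns = counts.columns.astype(str)
    return CountMatrix(counts, meta)


def write_counts(
    cm: CountMatrix,
    path: str | Path,
    metadata_path: str | Path,
    config: StudyConfig | None = None,
) -> None:
    write_tsv(cm.counts, path, config, index=True, index_label="feature")
    write_tsv(
        cm.metadata.reset_index(names="sample"), metadata_path, config, index=False
    )


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gene_sets(path: str | Path) -> list[GeneSignature]:
    """Parse a GMT file: name, description, tab-separated members."""
    sigs: list[GeneSignature] = []
    seen: set[str] = set()
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: GMT line has no members")
            name, desc = parts[0], parts[1]
            members = frozenset(m for m in parts[2:] if m)
            if name in seen:
                raise ValueError(f"duplicate signature name {name!r}")
            seen.add(name)
            sigs.append(GeneSignature(name, desc, members))
    return sigs


def write_gene_sets(sigs: Iterable[GeneSignature], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sig in sigs:
            fh.write("\t".join([sig.name, sig.description, *sorted(sig.members)]) + "\n")


# ---------------------------------------------------------------------------
# allele counts

ALLELE_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "sample",
    "group",
    "ref_count",
    "alt_count",
]


def read_allele_counts(path: str | Path) -> pd.DataFrame:
    """Read per-sample per-locus ref/alt read depths (positions 1-based)."""
    tab = _read_table(path)
    missing = [c for c in ALLELE_COLUMNS if c not in tab.columns]
    if missing:
        raise ValueError(f"allele-count table lacks columns: {missing}")
    tab = tab[ALLELE_COLUMNS].copy()
    for col in ("ref", "alt"):
        bad = ~tab[col].astype(str).isin(_NUCLEOTIDES)
        if bad.any():
            raise ValueError(
                f"non-ACGT {col} allele at row {int(np.argmax(bad.to_numpy()))}: "
                f"{tab.loc[bad, col].iloc[0]!r}"
            )
    if (tab["ref"] == tab["alt"]).any():
        raise ValueError("ref == alt at one or more loci")
    for col in ("ref_count", "alt_count"):
        if (tab[col] < 0).any() or tab[col].isna().any():
            raise ValueError(f"negative or missing {col}")
    tab["pos"] = tab["pos"].astype(np.int64)
    return tab


def write_allele_counts(
    tab: pd.DataFrame, path: str | Path, config: StudyConfig | None = None
) -> None:
    write_tsv(tab[ALLELE_COLUMNS], path, config)


# ---------------------------------------------------------------------------
# SEG segments

SEG_COLUMNS = ["sample", "chrom", "start", "end", "class", "log2ratio"]


def read_segments(path: str | Path) -> pd.DataFrame:
    """Read a SEG-style segment table (1-based inclusive coordinates)."""
    tab = _read_table(path)
    missing = [c for c in SEG_COLUMNS if c not in tab.columns]
    if missing:
        raise ValueError(f"segment table lacks columns: {missing}")
    tab = tab[SEG_COLUMNS].copy()
    unknown = set(tab["class"].unique()) - SEG_CLASSES
    if unknown:
        raise ValueError(f"unknown segment class(es): {sorted(unknown)}")
    if (tab["start"] > tab["end"]).any():
        raise ValueError("segment with start > end")
    tab["start"] = tab["start"].astype(np.int64)
    tab["end"] = tab["end"].astype(np.int64)
    return tab


def write_segments(
    tab: pd.DataFrame, path: str | Path, config: StudyConfig | None = None
) -> None:
    write_tsv(tab[SEG_COLUMNS], path, config)


# ---------------------------------------------------------------------------
# BED masks


def read_mask(path: str | Path) -> RegionMask:
    """Read a BED3 file (0-based half-open) into a merged RegionMask."""
    triples: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: BED line with <3 fields")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise ValueError(f"{path}:{ln}: start >= end ({start} >= {end})")
            triples.append((chrom, start, end))
    return RegionMask.from_intervals(triples)


def write_mask(mask: RegionMask, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(mask.intervals):
            for s, e in mask.intervals[chrom]:
                fh.write(f"{chrom}\t{s}\t{e}\n")


# ---------------------------------------------------------------------------
# variants

VARIANT_COLUMNS = ["sample", "gene", "chrom", "pos", "ref", "alt", "effect", "somatic"]
EFFECT_CLASSES = frozenset({"missense", "nonsense", "splice", "indel", "mnv"})


def read_variants(path: str | Path) -> pd.DataFrame:
    """Read a protein-altering variant call table."""
    tab = _read_table(path)
    missing = [c for c in VARIANT_COLUMNS if c not in tab.columns]
    if missing:
        raise ValueError(f"variant table lacks columns: {missing}")
    tab = tab[VARIANT_COLUMNS].copy()
    unknown = set(tab["effect"].unique()) - EFFECT_CLASSES
    if unknown:
        raise ValueError(f"unknown effect class(es): {sorted(unknown)}")
    tab["somatic"] = tab["somatic"].astype(bool)
    return tab


def write_variants(
    tab: pd.DataFrame, path: str | Path, config: StudyConfig | None = None
) -> None:
    write_tsv(tab[VARIANT_COLUMNS], path, config)
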