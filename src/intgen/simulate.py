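"""Synthetic study bundles with planted truth.

Emulates the statistical structure of a two-group (tumor vs control)
transcriptomics study: negative-binomial gene counts with planted
differential expression and co-expressed modules; exon-bin counts with
planted usage shifts; allele counts with a mechanistic reference-allele
bias plus planted imbalanced loci; binary mark signatures coupled to DE
direction; and variant/segment tables with planted recurrence.

Every generator takes its randomness from ``SimConfig.seed`` expanded into
per-stage substreams, so a fixed seed yields a byte-identical bundle.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from intgen.config import StudyConfig
from intgen.io import (
    CountMatrix,
    GeneSignature,
    write_allele_counts,
    write_counts,
    write_gene_sets,
    write_segments,
    write_variants,
)


def stage_seed(seed: int, stage: str) -> int:
    """Derive a per-stage substream seed below 2**31 by stable hashing."""
    return (int(seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class SimTruth:
    """Planted structure: what downstream stages should recover."""

    de_genes: dict[str, float] = field(default_factory=dict)
    module_assignment: dict[str, int] = field(default_factory=dict)
    mark_membership: dict[str, set[str]] = field(default_factory=dict)
    splice_genes: dict[str, int] = field(default_factory=dict)  # gene -> shifted bin
    ase_loci: dict[str, float] = field(default_factory=dict)  # "chrom:pos" -> true frac
    recurrent_genes: set[str] = field(default_factory=set)
    recurrent_regions: list[tuple[str, int, int, str]] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        obj = {
            "de_genes": self.de_genes,
            "module_assignment": self.module_assignment,
            "mark_membership": {k: sorted(v) for k, v in self.mark_membership.items()},
            "splice_genes": self.splice_genes,
            "ase_loci": self.ase_loci,
            "recurrent_genes": sorted(self.recurrent_genes),
            "recurrent_regions": self.recurrent_regions,
        }
        Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True))


@dataclass
class SimConfig:
    """Generator parameters.

    Defaults emulate a desk-scale version of a ~25-vs-22-sample study:
    2000 genes (a quarter differentially expressed, mean |log2FC| 2),
    negative-binomial dispersion 0.1 (Var = mu + 0.1 mu^2), two planted
    co-expressed 50-gene modules driven by a shared Gaussian latent factor,
    log-normal library sizes (sigma 0.3), and allele counts whose ~0.54
    reference fraction arises mechanistically from dropping each
    alternate-allele read with probability 2 - 1/0.54 ~= 0.148.
    """

    n_genes: int = 2000
    n_samples_per_group: int = 20
    n_modules: int = 2
    module_size: int = 50
    de_fraction: float = 0.25
    de_logfc_mean: float = 2.0
    nb_dispersion: float = 0.1
    latent_factor_sd: float = 0.8
    library_size_sigma: float = 0.3
    mean_library_size: float = 2e6
    mark_prob_in_updeg: float = 0.9
    mark_prob_background: float = 0.1
    n_ase_sites: int = 5000
    n_ase_samples_per_group: int = 5
    ase_depth_mean: float = 60.0
    ase_depth_floor: int = 30
    ref_bias: float = 0.54
    alt_read_loss: float | None = None  # derived from ref_bias when None
    ag_fraction: float = 0.1
    n_ase_signal: int = 0
    ase_signal_fraction: float = 0.8
    splice_fraction: float = 0.05
    n_recurrent_genes: int = 5
    background_mutations_per_sample: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "de_fraction",
            "mark_prob_in_updeg",
            "mark_prob_background",
            "ag_fraction",
            "splice_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not 0.0 < self.ref_bias < 1.0:
            raise ValueError("ref_bias must lie in (0, 1)")
        if self.ase_depth_mean < 1:
            raise ValueError("ase_depth_mean must be >= 1")
        if self.module_size * self.n_modules > self.n_genes:
            raise ValueError(
                f"{self.n_modules} modules of {self.module_size} genes exceed "
                f"{self.n_genes} total genes"
            )

    @property
    def effective_alt_loss(self) -> float:
        """Alternate-read dropout probability realizing ``ref_bias``.

        With true fraction 1/2 and each alt read kept with probability
        1 - q, the expected observed reference fraction is
        0.5 / (0.5 + 0.5 (1 - q)), so q = 2 - 1/ref_bias.
        """
        if self.alt_read_loss is not None:
            return float(self.alt_read_loss)
        return 2.0 - 1.0 / self.ref_bias


def _gene_names(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def _sample_frame(n_per_group: int, rng: np.random.Generator) -> pd.DataFrame:
    samples = [f"T{i:03d}" for i in range(n_per_group)] + [
        f"C{i:03d}" for i in range(n_per_group)
    ]
    groups = ["tumor"] * n_per_group + ["control"] * n_per_group
    sex = rng.choice(["F", "M"], size=2 * n_per_group)
    platform = rng.choice(["plateA", "plateB"], size=2 * n_per_group)
    return pd.DataFrame(
        {"group": groups, "sex": sex, "platform": platform},
        index=pd.Index(samples, name="sample"),
    )


def _nb_counts(
    mu: np.ndarray, dispersion: float, rng: np.random.Generator
) -> np.ndarray:
    """Gamma-Poisson mixture with Var = mu + dispersion * mu^2."""
    if dispersion <= 0:
        return rng.poisson(mu)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mu * dispersion)
    return rng.poisson(lam)


def simulate_expression(cfg: SimConfig) -> tuple[CountMatrix, SimTruth]:
    """Two-group negative-binomial gene counts with planted DE and modules.

    log2 mean = baseline + group effect (planted log2FC for DE genes)
    + module latent factor (shared per-module Gaussian factor, loading 1
    for members) + log2 library-size offset.
    """
    rng = np.random.default_rng(stage_seed(cfg.seed, "expression"))
    genes = _gene_names(cfg.n_genes)
    meta = _sample_frame(cfg.n_samples_per_group, rng)
    n_samples = len(meta)
    is_tumor = (meta["group"] == "tumor").to_numpy()

    baseline = rng.normal(5.0, 1.5, size=cfg.n_genes)  # log2 expression level
    # planted DE
    n_de = int(round(cfg.de_fraction * cfg.n_genes))
    de_idx = rng.choice(cfg.n_genes, size=n_de, replace=False)
    signs = rng.choice([1.0, -1.0], size=n_de)
    magnitudes = np.abs(rng.normal(cfg.de_logfc_mean, 0.25, size=n_de))
    logfc = np.zeros(cfg.n_genes)
    logfc[de_idx] = signs * magnitudes
    # planted modules occupy the first genes not used cleverly: random choice
    module_labels = np.zeros(cfg.n_genes, dtype=int)
    module_pool = rng.permutation(cfg.n_genes)[: cfg.n_modules * cfg.module_size]
    for m in range(cfg.n_modules):
        module_labels[module_pool[m * cfg.module_size : (m + 1) * cfg.module_size]] = (
            m + 1
        )
    factors = rng.normal(
        0.0, cfg.latent_factor_sd, size=(cfg.n_modules, n_samples)
    )

    lib = cfg.mean_library_size * rng.lognormal(
        0.0, cfg.library_size_sigma, size=n_samples
    )
    lib_offset = np.log2(lib / cfg.mean_library_size)

    log2_mu = np.tile(baseline[:, None], (1, n_samples))
    log2_mu += logfc[:, None] * is_tumor[None, :]
    member = module_labels > 0
    log2_mu[member] += factors[module_labels[member] - 1]
    log2_mu += lib_offset[None, :]

    counts = _nb_counts(2.0**log2_mu, cfg.nb_dispersion, rng)
    cm = CountMatrix(
        pd.DataFrame(counts, index=pd.Index(genes, name="feature"), columns=meta.index),
        meta,
    )
    truth = SimTruth(
        de_genes={genes[i]: float(logfc[i]) for i in de_idx},
        module_assignment={g: int(module_labels[i]) for i, g in enumerate(genes)},
    )
    return cm, truth


def simulate_exon_counts(
    cfg: SimConfig, n_exons_per_gene: int = 4
) -> tuple[CountMatrix, SimTruth]:
    """Exon-bin counts with planted usage shifts.

    Each gene's total count is negative-binomial (matched between groups);
    reads are split across exon bins multinomially.  For splicing-truth
    genes one bin's relative share doubles in the tumor group (others
    renormalized), so total gene output is unchanged while usage shifts.
    Exon ids encode gene and bin as ``gene:binNN``.
    """
    if n_exons_per_gene < 2:
        raise ValueError("n_exons_per_gene must be >= 2")
    rng = np.random.default_rng(stage_seed(cfg.seed, "exons"))
    genes = _gene_names(cfg.n_genes)
    meta = _sample_frame(cfg.n_samples_per_group, rng)
    n_samples = len(meta)
    is_tumor = (meta["group"] == "tumor").to_numpy()

    baseline = rng.normal(7.0, 1.0, size=cfg.n_genes)
    lib = rng.lognormal(0.0, cfg.library_size_sigma, size=n_samples)

    n_splice = int(round(cfg.splice_fraction * cfg.n_genes))
    splice_idx = rng.choice(cfg.n_genes, size=n_splice, replace=False)
    shifted_bin = rng.integers(0, n_exons_per_gene, size=n_splice)

    K = n_exons_per_gene
    base_share = np.full(K, 1.0 / K)
    rows = []
    index = []
    truth = SimTruth()
    splice_map = dict(zip(splice_idx, shifted_bin))
    for gi, gene in enumerate(genes):
        mu_total = 2.0 ** baseline[gi] * lib
        totals = _nb_counts(mu_total, cfg.nb_dispersion, rng)
        shares_ctrl = base_share
        if gi in splice_map:
            b = splice_map[gi]
            shares_tum = base_share.copy()
            shares_tum[b] = min(2.0 * base_share[b], 0.9)
            other = np.arange(K) != b
            shares_tum[other] *= (1.0 - shares_tum[b]) / shares_tum[other].sum()
            truth.splice_genes[gene] = int(b)
        else:
            shares_tum = base_share
        gene_counts = np.empty((K, n_samples), dtype=np.int64)
        for s in range(n_samples):
            p = shares_tum if is_tumor[s] else shares_ctrl
            gene_counts[:, s] = rng.multinomial(totals[s], p)
        rows.append(gene_counts)
        index.extend(f"{gene}:bin{k:02d}" for k in range(K))

    counts = pd.DataFrame(
        np.vstack(rows), index=pd.Index(index, name="feature"), columns=meta.index
    )
    return CountMatrix(counts, meta), truth


_NON_AG_PAIRS = [
    ("A", "C"),
    ("A", "T"),
    ("C", "A"),
    ("C", "G"),
    ("G", "C"),
    ("G", "T"),
    ("T", "A"),
    ("T", "G"),
]
_AG_PAIRS = [("A", "G"), ("G", "A"), ("T", "C"), ("C", "T")]


def simulate_allele_counts(cfg: SimConfig) -> tuple[pd.DataFrame, SimTruth]:
    """Per-locus per-sample ref/alt depths with a mechanistic reference bias.

    Null loci are simulated at true fraction 1/2; each alternate-allele
    read is then independently discarded with probability
    ``cfg.effective_alt_loss``, producing the observed reference bias as a
    process rather than as a binomial parameter.  Planted signal loci use
    ``cfg.ase_signal_fraction`` as their true reference fraction (the same
    dropout applies).  A configurable fraction of loci carries A/G (or the
    reverse-complement T/C) alleles to exercise the exclusion filter.
    """
    import warnings

    if cfg.ase_depth_mean < 30:
        warnings.warn(
            "ase_depth_mean below 30 reads: most sites will fail the depth filter",
            stacklevel=2,
        )
    rng = np.random.default_rng(stage_seed(cfg.seed, "ase"))
    loss = cfg.effective_alt_loss
    n_sites = cfg.n_ase_sites
    n_per_group = cfg.n_ase_samples_per_group
    samples = [f"T{i:03d}" for i in range(n_per_group)] + [
        f"C{i:03d}" for i in range(n_per_group)
    ]
    groups = ["tumor"] * n_per_group + ["control"] * n_per_group

    chroms = rng.choice([f"chr{c}" for c in range(1, 23)], size=n_sites)
    positions = rng.integers(1, 50_000_000, size=n_sites)
    is_ag = rng.random(n_sites) < cfg.ag_fraction
    pair_idx_nonag = rng.integers(0, len(_NON_AG_PAIRS), size=n_sites)
    pair_idx_ag = rng.integers(0, len(_AG_PAIRS), size=n_sites)

    true_frac = np.full(n_sites, 0.5)
    signal_idx = rng.choice(n_sites, size=cfg.n_ase_signal, replace=False)
    true_frac[signal_idx] = cfg.ase_signal_fraction

    records = []
    truth = SimTruth()
    for i in range(n_sites):
        ref, alt = _AG_PAIRS[pair_idx_ag[i]] if is_ag[i] else _NON_AG_PAIRS[pair_idx_nonag[i]]
        locus = f"{chroms[i]}:{positions[i]}"
        truth.ase_loci[locus] = float(true_frac[i])
        for sample, group in zip(samples, groups):
            depth = max(int(rng.poisson(cfg.ase_depth_mean)), cfg.ase_depth_floor)
            ref_reads = rng.binomial(depth, true_frac[i])
            alt_reads = depth - ref_reads
            kept_alt = rng.binomial(alt_reads, 1.0 - loss) if alt_reads else 0
            records.append(
                (chroms[i], int(positions[i]), ref, alt, sample, group, int(ref_reads), int(kept_alt))
            )
    tab = pd.DataFrame(
        records,
        columns=["chrom", "pos", "ref", "alt", "sample", "group", "ref_count", "alt_count"],
    )
    return tab, truth


_CHROM_LENGTHS = {"chr7": 159_000_000, "chr11": 135_000_000, "chr1": 249_000_000}


def default_chrom_lengths() -> dict[str, int]:
    """Chromosome lengths used by the simulated segment tables."""
    return dict(_CHROM_LENGTHS)


def simulate_marks_and_variants(
    cfg: SimConfig, truth: SimTruth
) -> tuple[list[GeneSignature], pd.DataFrame, pd.DataFrame]:
    """Mark signatures coupled to DE direction, plus variant/segment tables.

    Each simulated repressive-mark signature includes every up-DE gene with
    probability ``mark_prob_in_updeg`` and every other gene with
    probability ``mark_prob_background`` (mimicking repressive chromatin
    marks over genes de-repressed in the tumor).  A proliferation-like
    signature is coupled to planted module 1 the same way.  The variant
    table plants ``n_recurrent_genes`` genes mutated in >= 2 tumors over a
    Poisson background; the segment table plants recurrent gain/loss/cnLOH
    regions.
    """
    rng = np.random.default_rng(stage_seed(cfg.seed, "marks"))
    genes = sorted(truth.module_assignment) or _gene_names(cfg.n_genes)
    up_genes = {g for g, lfc in truth.de_genes.items() if lfc > 0}

    def coupled_signature(name: str, inside: set[str]) -> GeneSignature:
        members = {
            g
            for g in genes
            if rng.random()
            < (cfg.mark_prob_in_updeg if g in inside else cfg.mark_prob_background)
        }
        if not members:
            members = {genes[0]}
        truth.mark_membership[name] = set(members)
        return GeneSignature(name, "simulated signature", frozenset(members))

    module1 = {g for g, m in truth.module_assignment.items() if m == 1}
    signatures = [
        coupled_signature("repressive_mark_beta", up_genes),
        coupled_signature("active_mark_beta", set(genes) - up_genes),
        coupled_signature("proliferation_juvenile", module1),
    ]

    # variants: planted recurrent genes + Poisson background
    n_tumors = cfg.n_samples_per_group
    tumor_samples = [f"T{i:03d}" for i in range(n_tumors)]
    recurrent = rng.choice(genes, size=cfg.n_recurrent_genes, replace=False)
    effects = ["missense", "nonsense", "splice", "indel", "mnv"]
    rows = []
    for g in recurrent:
        hit = rng.choice(n_tumors, size=rng.integers(2, max(3, n_tumors // 5)), replace=False)
        for s in hit:
            rows.append(
                (
                    tumor_samples[s],
                    g,
                    "chr1",
                    int(rng.integers(1, _CHROM_LENGTHS["chr1"])),
                    "C",
                    "T",
                    effects[rng.integers(0, len(effects))],
                    True,
                )
            )
        truth.recurrent_genes.add(str(g))
    for s in tumor_samples:
        n_bg = rng.poisson(cfg.background_mutations_per_sample)
        bg_genes = rng.choice(genes, size=n_bg, replace=False)
        for g in bg_genes:
            rows.append(
                (
                    s,
                    g,
                    "chr1",
                    int(rng.integers(1, _CHROM_LENGTHS["chr1"])),
                    "G",
                    "A",
                    effects[rng.integers(0, len(effects))],
                    True,
                )
            )
    variants = pd.DataFrame(
        rows, columns=["sample", "gene", "chrom", "pos", "ref", "alt", "effect", "somatic"]
    )

    # segments: planted recurrent regions
    planted_regions = [
        ("chr7", 1, 60_000_000, "gain", 0.4),
        ("chr11", 1, 50_000_000, "loss", 0.2),
        ("chr11", 60_000_001, 100_000_000, "cnLOH", 0.2),
    ]
    seg_rows = []
    for chrom, start, end, klass, frac in planted_regions:
        carriers = rng.choice(
            n_tumors, size=max(1, int(round(frac * n_tumors))), replace=False
        )
        for s in carriers:
            seg_rows.append(
                (
                    tumor_samples[s],
                    chrom,
                    start,
                    end,
                    klass,
                    0.4 if klass == "gain" else (-0.4 if klass == "loss" else 0.0),
                )
            )
        truth.recurrent_regions.append((chrom, start, end, klass))
    segments = pd.DataFrame(
        seg_rows, columns=["sample", "chrom", "start", "end", "class", "log2ratio"]
    )
    return signatures, variants, segments


def write_bundle(
    cfg: SimConfig, outdir: str | Path, study: StudyConfig | None = None
) -> SimTruth:
    """Generate and write a full synthetic study bundle to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cm, truth = simulate_expression(cfg)
    exon_cm, exon_truth = simulate_exon_counts(cfg)
    allele_tab, ase_truth = simulate_allele_counts(cfg)
    sigs, variants, segments = simulate_marks_and_variants(cfg, truth)
    truth.splice_genes = exon_truth.splice_genes
    truth.ase_loci = ase_truth.ase_loci

    write_counts(cm, outdir / "counts.tsv", outdir / "metadata.tsv", study)
    write_counts(exon_cm, outdir / "exon_counts.tsv", outdir / "exon_metadata.tsv", study)
    write_allele_counts(allele_tab, outdir / "allele_counts.tsv", study)
    write_gene_sets(sigs, outdir / "signatures.gmt")
    write_variants(variants, outdir / "variants.tsv", study)
    write_segments(segments, outdir / "segments.seg", study)
    truth.to_json(outdir / "truth.json")
    return truth
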