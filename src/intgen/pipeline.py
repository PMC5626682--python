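"""End-to-end orchestration: simulate -> de/splice -> network -> project
-> axis -> ase -> summaries, with one config and deterministic seeding.

Each stage reads its inputs from and writes its outputs to a single run
directory; a JSON manifest records the stage order, the resolved config
hash and the seed.  The global seed is expanded into per-stage substreams
by stable hashing of stage names, so stage-level results do not depend on
stage order.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from intgen import __version__
from intgen.ase import estimate_null_fraction, filter_ase_sites, quasibinomial_test
from intgen.coexpress import NetworkParams, detect_modules
from intgen.config import StudyConfig
from intgen.diffexpr import fit_de, log_cpm, test_exon_usage
from intgen.enrichment import classify_enrichment, fdr_score, fisher_projection, score_matrix
from intgen.genomic_summary import (
    cnv_recurrence_track,
    recurrent_genes,
    variant_burden,
)
from intgen.histone_axis import mark_track, rank_genes, smooth_tracks
from intgen.io import (
    read_allele_counts,
    read_counts,
    read_gene_sets,
    read_mask,
    read_segments,
    read_variants,
    write_tsv,
)
from intgen.simulate import SimConfig, default_chrom_lengths, write_bundle

log = logging.getLogger(__name__)

STAGES = (
    "simulate",
    "de",
    "splice",
    "network",
    "project",
    "axis",
    "ase",
    "burden",
    "cnv-tracks",
)

_REQUIRES = {
    "de": ["counts.tsv", "metadata.tsv"],
    "splice": ["exon_counts.tsv", "exon_metadata.tsv"],
    "network": ["counts.tsv", "metadata.tsv"],
    "project": ["modules.tsv", "de_results.tsv", "signatures.gmt"],
    "axis": ["de_results.tsv", "signatures.gmt"],
    "ase": ["allele_counts.tsv"],
    "burden": ["variants.tsv"],
    "cnv-tracks": ["segments.seg"],
}

_PRODUCER = {
    "counts.tsv": "simulate",
    "metadata.tsv": "simulate",
    "exon_counts.tsv": "simulate",
    "exon_metadata.tsv": "simulate",
    "allele_counts.tsv": "simulate",
    "signatures.gmt": "simulate",
    "variants.tsv": "simulate",
    "segments.seg": "simulate",
    "de_results.tsv": "de",
    "modules.tsv": "network",
}


def run_pipeline(
    config: StudyConfig,
    outdir: str | Path,
    stages: tuple[str, ...] | list[str] | str = "all",
    sim_config: SimConfig | None = None,
) -> dict:
    """Run the requested stages in canonical order; return the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if stages == "all":
        stages = list(STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    stages = [s for s in STAGES if s in stages]

    for stage in stages:
        for dep in _REQUIRES.get(stage, []):
            if not (outdir / dep).exists() and _PRODUCER.get(dep) not in stages:
                raise FileNotFoundError(
                    f"stage {stage!r} needs {dep}; run stage "
                    f"{_PRODUCER.get(dep, '?')!r} first"
                )

    manifest = {
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": [],
    }
    for stage in stages:
        log.info("running stage %s", stage)
        _RUNNERS[stage](config, outdir, sim_config)
        manifest["stages"].append(stage)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


# ---------------------------------------------------------------------------
# stage runners


def _stage_simulate(config: StudyConfig, outdir: Path, sim_config) -> None:
    cfg = sim_config or SimConfig(seed=config.seed)
    write_bundle(cfg, outdir, config)
    (outdir / "sim_config.json").write_text(
        json.dumps(dataclasses.asdict(cfg), indent=1)
    )


def _stage_de(config: StudyConfig, outdir: Path, _=None) -> None:
    cm = read_counts(outdir / "counts.tsv", outdir / "metadata.tsv")
    covs = [c for c in ("sex", "platform") if c in cm.metadata.columns]
    de = fit_de(log_cpm(cm), cm.metadata, covariates=covs, fdr_de=config.fdr_de)
    write_tsv(de, outdir / "de_results.tsv", config)
    log.info(
        "de: %d genes, %d up / %d down at FDR <= %g",
        len(de),
        int((de["direction"] == "up").sum()),
        int((de["direction"] == "down").sum()),
        config.fdr_de,
    )


def _stage_splice(config: StudyConfig, outdir: Path, _=None) -> None:
    cm = read_counts(outdir / "exon_counts.tsv", outdir / "exon_metadata.tsv")
    covs = [c for c in ("sex", "platform") if c in cm.metadata.columns]
    exon_df, gene_df = test_exon_usage(log_cpm(cm), cm.metadata, covariates=covs)
    write_tsv(exon_df, outdir / "exon_usage.tsv", config)
    write_tsv(gene_df, outdir / "splice_genes.tsv", config)


def _stage_network(config: StudyConfig, outdir: Path, _=None) -> None:
    cm = read_counts(outdir / "counts.tsv", outdir / "metadata.tsv")
    params = NetworkParams(
        soft_power=config.soft_power,
        min_module_size=config.min_module_size,
        merge_height=config.merge_height,
    )
    modules = detect_modules(log_cpm(cm), params)
    write_tsv(modules.to_frame(), outdir / "modules.tsv", config)
    write_tsv(
        modules.eigengenes, outdir / "eigengenes.tsv", config, index=True,
        index_label="module",
    )


def _stage_project(config: StudyConfig, outdir: Path, _=None) -> None:
    modules = pd.read_csv(outdir / "modules.tsv", sep="\t", comment="#")
    de = pd.read_csv(outdir / "de_results.tsv", sep="\t", comment="#")
    sigs = read_gene_sets(outdir / "signatures.gmt")
    universe = set(de["gene"])
    targets = {
        f"module_{m}": set(modules.loc[modules["module"] == m, "gene"])
        for m in sorted(modules["module"].unique())
        if m > 0
    }
    deg_targets = {
        "up_deg": set(de.loc[de["direction"] == "up", "gene"]),
        "down_deg": set(de.loc[de["direction"] == "down", "gene"]),
    }
    rec = fisher_projection(sigs, {**targets, **deg_targets}, universe, sided="two")
    rec = classify_enrichment(rec, config.over_fold, config.under_fold, config.fdr_de)
    rec = fdr_score(rec, cap=config.fdr_score_cap, significance=config.fdr_enrich)
    write_tsv(rec, outdir / "enrichment.tsv", config)
    write_tsv(
        score_matrix(rec), outdir / "fdr_score_matrix.tsv", config, index=True,
        index_label="signature",
    )


def _stage_axis(config: StudyConfig, outdir: Path, _=None) -> None:
    de = pd.read_csv(outdir / "de_results.tsv", sep="\t", comment="#")
    sigs = read_gene_sets(outdir / "signatures.gmt")
    axis = rank_genes(de)
    for sig in sigs:
        mark_track(axis, sig)
    smooth_tracks(axis, flank=config.window_flank)
    write_tsv(axis.to_frame(), outdir / "axis.tsv", config)


def _stage_ase(config: StudyConfig, outdir: Path, _=None) -> None:
    tab = read_allele_counts(outdir / "allele_counts.tsv")
    mask = read_mask(outdir / "mask.bed") if (outdir / "mask.bed").exists() else None
    flagged = filter_ase_sites(tab, mask, min_depth=config.min_ase_depth)
    p0 = {}
    for group in flagged["group"].unique():
        p0[group], n_used = estimate_null_fraction(flagged, group)
        log.info("ase: null reference fraction in %s = %.4f (%d sites)", group, p0[group], n_used)
    groups = tuple(sorted(p0, reverse=True))  # ('tumor', 'control') when present
    results = quasibinomial_test(flagged, p0, groups=groups, fdr_ase=config.fdr_ase)
    write_tsv(results, outdir / "ase_results.tsv", config)


def _stage_burden(config: StudyConfig, outdir: Path, _=None) -> None:
    variants = read_variants(outdir / "variants.tsv")
    samples = sorted(variants["sample"].unique())
    counts, mean = variant_burden(variants, len(samples), samples)
    burden = counts.rename("n_variants").reset_index()
    write_tsv(burden, outdir / "burden.tsv", config)
    rec = recurrent_genes(variants)
    write_tsv(rec, outdir / "recurrent_genes.tsv", config)
    log.info("burden: mean %.1f protein-altering somatic variants per sample", mean)


def _stage_cnv_tracks(config: StudyConfig, outdir: Path, _=None) -> None:
    segments = read_segments(outdir / "segments.seg")
    n_samples = max(1, segments["sample"].nunique())
    track = cnv_recurrence_track(
        segments, default_chrom_lengths(), n_samples, bin_size=config.cnv_bin
    )
    write_tsv(track, outdir / "cnv_tracks.tsv", config)


_RUNNERS = {
    "simulate": _stage_simulate,
    "de": _stage_de,
    "splice": _stage_splice,
    "network": _stage_network,
    "project": _stage_project,
    "axis": _stage_axis,
    "ase": _stage_ase,
    "burden": _stage_burden,
    "cnv-tracks": _stage_cnv_tracks,
}
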