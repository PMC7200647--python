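"""End-to-end orchestration: inputs -> trees -> discordant sites -> reports.

`run_pipeline` reproduces the full analysis on one panel: per-strain coding
effect counts, the panel distance matrix and NJ tree, per-chromosome trees
and chromosome-level branch support, per-cluster discordant-site tables,
gene density ranking, hotspot bins with cross-cluster sharing, and the
heterozygosity co-localization table.  Every output file is TSV/newick/BED
text with a header naming the tool version, a hash of the configuration and
the seed, so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .coding import effect_counts, read_bed_cds
from .discordance import (
    ClusterSpec,
    bin_sites,
    call_discordant_sites,
    cross_cluster_hotspot_overlap,
    discordant_site_summary,
    genes_with_discordant_sites,
    het_discordant_colocalization,
    propose_clusters,
)
from .distance import distance_matrix
from .genotypes import heterozygous_site_count, homozygous_variant_set, read_vcf
from .nj import neighbor_joining
from .tree import branch_support

logger = logging.getLogger("ancpoly.pipeline")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    vcf: str
    bed: str
    chrom_sizes: str
    outdir: str
    cds_fasta: str | None = None
    strains: list[str] | None = None  # None -> all VCF samples
    clusters: dict[str, list[str]] | None = None  # None -> auto-detect
    autosomes: list[str] | None = None  # None -> all chromosomes in chrom_sizes
    bin_size: int = 1_000_000
    hotspot_sd_multiplier: float = 2.0
    min_clusters: int = 1
    min_support: float = 80.0
    max_within_distance: float | None = None
    het_mode: str = "max_strain"
    het_denominator: int | None = None  # None -> genome length
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def fatal(self) -> bool:
        return bool(self.errors)


def read_chrom_sizes(path: str | os.PathLike) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, length = line.split()[:2]
            sizes[name] = int(length)
    if not sizes:
        raise ValueError(f"no chromosomes in {path}")
    return sizes


def validate_inputs(config: RunConfig) -> ValidationReport:
    """Cross-check VCF samples, strain list, clusters, BED and chrom.sizes."""
    report = ValidationReport()
    for label in ("vcf", "bed", "chrom_sizes"):
        path = getattr(config, label)
        if not os.path.exists(path):
            report.errors.append(f"missing input file: {label}={path}")
    if report.fatal:
        return report

    from cyvcf2 import VCF

    samples = list(VCF(config.vcf).samples)
    strains = config.strains or samples
    for strain in strains:
        if strain not in samples:
            report.errors.append(f"strain {strain} absent from VCF samples")
    unused = sorted(set(samples) - set(strains))
    if unused:
        report.warnings.append(f"unused VCF samples: {', '.join(unused)}")
    if config.clusters:
        for name, members in config.clusters.items():
            for member in members:
                if member not in strains:
                    report.errors.append(f"cluster {name} member {member} not in strain list")
            if len(members) < 2:
                report.errors.append(f"cluster {name} has fewer than 2 members")
    sizes = read_chrom_sizes(config.chrom_sizes)
    try:
        annotations = read_bed_cds(config.bed)
    except ValueError as exc:
        report.errors.append(f"bad BED: {exc}")
        return report
    for ann in annotations:
        if ann.chrom not in sizes:
            report.errors.append(f"BED transcript {ann.transcript_id} on unknown {ann.chrom}")
        elif max(e for _, e in ann.cds_intervals) > sizes[ann.chrom]:
            report.errors.append(f"BED transcript {ann.transcript_id} beyond chromosome end")
    for chrom in config.autosomes or []:
        if chrom not in sizes:
            report.errors.append(f"autosome {chrom} not in chrom.sizes")
    return report


def _write_tsv(frame: pd.DataFrame, path: str, header: list[str]) -> None:
    with open(path, "w") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        frame.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; returns a summary dict (also written as JSON)."""
    logging.basicConfig(level=config.log_level)
    os.makedirs(config.outdir, exist_ok=True)
    header = [
        f"ancpoly {__version__}",
        f"config {config.config_hash()}",
        f"seed {config.seed}",
    ]
    with open(os.path.join(config.outdir, "config.yaml"), "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=True)

    report = validate_inputs(config)
    for warning in report.warnings:
        logger.warning(warning)
    if report.fatal:
        raise StageError("validate", "; ".join(report.errors))

    summary: dict = {"version": __version__, "seed": config.seed}

    def out(name: str) -> str:
        return os.path.join(config.outdir, name)

    # -- stage: load -------------------------------------------------------
    try:
        matrix = read_vcf(config.vcf, config.strains)
        sizes = read_chrom_sizes(config.chrom_sizes)
        annotations = read_bed_cds(config.bed)
    except Exception as exc:
        raise StageError("load", str(exc)) from exc
    logger.info("load: %d strains x %d sites", len(matrix.strains), len(matrix.sites))
    summary["n_sites"] = len(matrix.sites)

    # -- stage: effects (optional) ----------------------------------------
    if config.cds_fasta:
        try:
            from Bio import SeqIO

            seqs = {r.id: str(r.seq) for r in SeqIO.parse(config.cds_fasta, "fasta")}
            effects = effect_counts(matrix, annotations, seqs)
        except Exception as exc:
            raise StageError("effects", str(exc)) from exc
        _write_tsv(effects, out("effect_counts.tsv"), header)
        logger.info("effects: %d strains", len(effects))

    # -- stage: heterozygosity --------------------------------------------
    denominator = config.het_denominator or sum(sizes.values())
    het_rows = []
    for strain in matrix.strains:
        count, prop = heterozygous_site_count(matrix, strain, denominator)
        het_rows.append(
            {"strain": strain, "het_sites": count, "proportion_pct": 100.0 * prop}
        )
    het_frame = pd.DataFrame(het_rows)
    _write_tsv(het_frame, out("heterozygosity.tsv"), header)

    # -- stage: distances --------------------------------------------------
    try:
        sets = [homozygous_variant_set(matrix, s) for s in matrix.strains]
        dmatrix = distance_matrix(sets)
    except Exception as exc:
        raise StageError("distances", str(exc)) from exc
    dmatrix.to_tsv(out("distances.tsv"), header)
    logger.info("distances: %d x %d", len(matrix.strains), len(matrix.strains))

    # -- stage: trees ------------------------------------------------------
    try:
        tree = neighbor_joining(dmatrix)
        autosomes = config.autosomes or list(sizes)
        chrom_trees = [
            neighbor_joining(distance_matrix(sets, restrict_to=c)) for c in autosomes
        ]
        support = branch_support(tree, chrom_trees)
    except Exception as exc:
        raise StageError("trees", str(exc)) from exc
    tree.write_newick(out("tree.nwk"), support=support)
    os.makedirs(out("chromosome_trees"), exist_ok=True)
    for chrom, ctree in zip(autosomes, chrom_trees):
        ctree.write_newick(os.path.join(out("chromosome_trees"), f"{chrom}.nwk"))
    logger.info("trees: 1 panel tree + %d chromosome trees", len(chrom_trees))

    # -- stage: clusters ---------------------------------------------------
    if config.clusters:
        clusters = [
            ClusterSpec(name, tuple(members)) for name, members in config.clusters.items()
        ]
    else:
        clusters = propose_clusters(
            tree, support, dmatrix,
            min_support=config.min_support,
            max_within_distance=config.max_within_distance,
        )
        logger.info("clusters: proposed %d", len(clusters))
    if not clusters:
        raise StageError("clusters", "no substrain clusters configured or detected")
    summary["clusters"] = {c.name: list(c.members) for c in clusters}

    # -- stage: discordance ------------------------------------------------
    try:
        tables = {c.name: call_discordant_sites(matrix, tree, c) for c in clusters}
    except Exception as exc:
        raise StageError("discordance", str(exc)) from exc
    stats = discordant_site_summary(tables, min_clusters=config.min_clusters)
    union = pd.concat(tables.values(), ignore_index=True)
    _write_tsv(union, out("discordant_sites.tsv"), header)
    with open(out("discordant_sites.bed"), "w") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        for row in union.itertuples():
            fh.write(f"{row.chrom}\t{row.pos - 1}\t{row.pos}\t{row.cluster}\n")
    summary["discordant_counts"] = stats.counts
    summary["discordant_union"] = len(stats.union)
    summary["discordant_min_clusters"] = len(stats.min_cluster_sites)
    for name, count in stats.counts.items():
        logger.info("discordance: %s -> %d sites", name, count)

    # -- stage: gene density ----------------------------------------------
    selected = union[
        union.apply(
            lambda r: (r["chrom"], int(r["pos"])) in stats.min_cluster_sites, axis=1
        )
    ] if config.min_clusters > 1 else union
    genes = genes_with_discordant_sites(selected, annotations)
    _write_tsv(genes, out("gene_density.tsv"), header)
    summary["n_genes_with_discordant_sites"] = len(genes)
    summary["top_gene"] = genes.iloc[0]["gene_id"] if len(genes) else None

    # -- stage: hotspots ---------------------------------------------------
    bins = {
        name: bin_sites(t, sizes, config.bin_size, config.hotspot_sd_multiplier)
        for name, t in tables.items()
    }
    for name, frame in bins.items():
        spots = frame[frame["is_hotspot"]]
        with open(out(f"hotspots_{name}.bed"), "w") as fh:
            for line in header:
                fh.write(f"# {line}\n")
            for row in spots.itertuples():
                fh.write(f"{row.chrom}\t{row.bin_start}\t{row.bin_start + row.bin_size}\t{name}\n")
    if len(bins) >= 2:
        pairs, mean_jaccard = cross_cluster_hotspot_overlap(bins)
        _write_tsv(pairs, out("hotspot_jaccard.tsv"), header)
        summary["hotspot_jaccard_mean"] = mean_jaccard
        logger.info("hotspots: mean cross-cluster Jaccard %.3f", mean_jaccard)

    # -- stage: co-localization -------------------------------------------
    coloc, rho, het_strain = het_discordant_colocalization(
        matrix, union, sizes, config.bin_size, het_mode=config.het_mode
    )
    _write_tsv(coloc, out("het_colocalization.tsv"), header)
    summary["het_discordant_spearman"] = None if np.isnan(rho) else rho
    summary["het_strain_used"] = het_strain
    logger.info("co-localization: Spearman rho %s (het: %s)", rho, het_strain)

    with open(out("summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
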