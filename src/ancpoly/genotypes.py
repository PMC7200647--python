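"""Genotype matrices for multi-sample SNV calls and the homozygous-only filter.

A :class:`GenotypeMatrix` holds per-(strain, site) diploid calls against one
reference genome.  Downstream distance and discordance analyses use only
homozygous non-reference calls: heterozygous calls in deeply inbred strains
are enriched for artifacts of collapsed read mapping (copy-number differences
force reads from two paralogous copies onto one reference locus, which
surfaces as heterozygosity), so they are excluded from mutation sets and kept
only for the residual-heterozygosity analyses.  Half-calls (e.g. ./1) are
treated as missing.

Calls are stored as two int8 allele-index planes (``a1``, ``a2``), -1 for
missing; index 0 is the reference allele and k >= 1 the k-th alternate.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class Site:
    """A biallelic or multiallelic SNV site on reference coordinates."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alts: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos must be >= 1")
        if not self.alts:
            raise ValueError("alt_alleles must be non-empty")
        if self.ref in self.alts:
            raise ValueError("ref allele must not appear among alts")
        if len(set(self.alts)) != len(self.alts):
            raise ValueError("duplicate alt alleles")

    @property
    def alleles(self) -> tuple[str, ...]:
        return (self.ref,) + self.alts


@dataclass(frozen=True)
class StrainVariantSet:
    """The homozygous non-reference mutations of one strain."""

    strain: str
    mutations: frozenset  # of (chrom, pos, alt_allele)


@dataclass
class GenotypeMatrix:
    strains: list[str]
    sites: list[Site]
    a1: np.ndarray  # (n_strains, n_sites) int8 allele indices, -1 = missing
    a2: np.ndarray
    n_skipped_non_snv: int = 0
    n_skipped_malformed: int = 0

    def __post_init__(self) -> None:
        if len(set(self.strains)) != len(self.strains):
            raise ValueError("strain names must be unique")
        shape = (len(self.strains), len(self.sites))
        if self.a1.shape != shape or self.a2.shape != shape:
            raise ValueError("allele planes do not match strains x sites")

    # -- masks -------------------------------------------------------------
    @property
    def is_hom(self) -> np.ndarray:
        return (self.a1 == self.a2) & (self.a1 >= 0)

    @property
    def is_het(self) -> np.ndarray:
        return (self.a1 >= 0) & (self.a2 >= 0) & (self.a1 != self.a2)

    @property
    def is_missing(self) -> np.ndarray:
        return (self.a1 < 0) | (self.a2 < 0)

    def strain_index(self, strain: str) -> int:
        try:
            return self.strains.index(strain)
        except ValueError:
            raise KeyError(f"unknown strain: {strain}") from None

    def call(self, strain: str, site_index: int):
        """Readable call: ('hom', base) | ('het', (b1, b2)) | ('missing',)."""
        i = self.strain_index(strain)
        x, y = int(self.a1[i, site_index]), int(self.a2[i, site_index])
        if x < 0 or y < 0:
            return ("missing",)
        alleles = self.sites[site_index].alleles
        if x == y:
            return ("hom", alleles[x])
        return ("het", tuple(sorted((alleles[x], alleles[y]))))


def read_vcf(path: str | os.PathLike, strain_names: Sequence[str] | None = None) -> GenotypeMatrix:
    """Load a multi-sample VCF into a :class:`GenotypeMatrix`.

    Only SNV records (single-base REF and ALTs) are retained; skipped
    non-SNV and malformed records are counted on the returned matrix.
    Multiallelic records become one :class:`Site` with several alts; phasing
    is ignored; half-calls are stored as missing.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    available = list(vcf.samples)
    if strain_names is None:
        strain_names = available
    missing = [s for s in strain_names if s not in available]
    if missing:
        raise ValueError(f"samples absent from VCF: {', '.join(missing)}")
    cols = [available.index(s) for s in strain_names]

    sites: list[Site] = []
    rows_a1: list[np.ndarray] = []
    rows_a2: list[np.ndarray] = []
    n_non_snv = 0
    n_malformed = 0
    for record in vcf:
        alts = tuple(record.ALT)
        if (
            len(record.REF) != 1
            or record.REF not in _BASES
            or not alts
            or any(len(a) != 1 or a not in _BASES for a in alts)
        ):
            n_non_snv += 1
            continue
        try:
            site = Site(record.CHROM, record.POS, record.REF, alts)
            gts = record.genotypes
            a1 = np.full(len(cols), -1, dtype=np.int8)
            a2 = np.full(len(cols), -1, dtype=np.int8)
            for out_idx, col in enumerate(cols):
                gt = gts[col]
                if len(gt) < 3:  # haploid or malformed entry -> missing
                    continue
                x, y = int(gt[0]), int(gt[1])
                if x < 0 or y < 0:
                    continue
                if x > len(alts) or y > len(alts):
                    raise ValueError("allele index out of range")
                a1[out_idx], a2[out_idx] = min(x, y), max(x, y)
        except Exception:
            n_malformed += 1
            continue
        sites.append(site)
        rows_a1.append(a1)
        rows_a2.append(a2)

    order = sorted(range(len(sites)), key=lambda i: (sites[i].chrom, sites[i].pos))
    sites = [sites[i] for i in order]
    a1 = (
        np.stack([rows_a1[i] for i in order], axis=1)
        if sites
        else np.zeros((len(strain_names), 0), dtype=np.int8)
    )
    a2 = (
        np.stack([rows_a2[i] for i in order], axis=1)
        if sites
        else np.zeros((len(strain_names), 0), dtype=np.int8)
    )
    if n_non_snv or n_malformed:
        logger.info(
            "read_vcf: skipped %d non-SNV and %d malformed records", n_non_snv, n_malformed
        )
    return GenotypeMatrix(
        list(strain_names), sites, a1, a2,
        n_skipped_non_snv=n_non_snv, n_skipped_malformed=n_malformed,
    )


def homozygous_variant_set(matrix: GenotypeMatrix, strain: str) -> StrainVariantSet:
    """Sites where `strain` is homozygous for a non-reference allele."""
    i = matrix.strain_index(strain)
    row1, row2 = matrix.a1[i], matrix.a2[i]
    idx = np.nonzero((row1 == row2) & (row1 > 0))[0]
    mutations = frozenset(
        (matrix.sites[j].chrom, matrix.sites[j].pos, matrix.sites[j].alts[row1[j] - 1])
        for j in idx
    )
    return StrainVariantSet(strain, mutations)


def heterozygous_site_count(
    matrix: GenotypeMatrix, strain: str, denominator: int
) -> tuple[int, float]:
    """Count of heterozygous calls and their proportion of callable bases.

    The denominator (number of callable target bases) is a configuration
    choice -- exome target size vs called bases -- and must be supplied.
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    i = matrix.strain_index(strain)
    count = int(matrix.is_het[i].sum())
    return count, count / denominator
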