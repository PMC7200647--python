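"""Forward simulation of inbred-strain panels with known per-site truth.

The generator emulates the breeding history behind a laboratory strain panel:

* an *ancestral pool* that is monomorphic everywhere except inside designated
  polymorphic loci (MHC-like, olfactory-like islands), where K distinct
  founder haplotypes segregate at a configured per-base density;
* per-lineage *inbreeding*: each strain starts as a diploid draw of two pool
  haplotypes and loses heterozygosity locus-by-locus following the full-sib
  recurrence, with a per-locus balancing-retention multiplier that can delay
  fixation (retention R(t) = min(1, (1 - F_t) * multiplier)); fixation is one
  draw per locus, emulating haplotype-block inheritance, which is what makes
  discordant sites aggregate within loci;
* *substrain splits*: cluster members share all fixations and mutations up to
  the split generation and then fix still-heterozygous loci and accumulate
  de novo mutations independently;
* *de novo mutations*, Poisson per branch with collision-free positions
  panel-wide (so tree-concordance of de novo characters is guaranteed by
  construction; ``allow_recurrent`` lifts this for robustness testing);
* optional *gene flow*: replacement of a recipient's genomic segment by the
  donor's haplotype, the alternative mechanism for tree-incongruent sharing.

Every emitted variant site carries exactly one truth origin label
(ancestral_polymorphism | de_novo | gene_flow).  Outputs are the exact input
formats the analysis pipeline consumes: multi-sample VCF 4.2, BED12 CDS,
chrom.sizes, a reference CDS FASTA, and a truth JSON.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .coding import CdsAnnotation, write_bed_cds
from .genotypes import GenotypeMatrix, Site
from .inbreeding import balancing_multiplier, retention_curve

_BASES = np.array(["A", "C", "G", "T"])

SCENARIOS = ("ancestral", "geneflow", "null", "mixed")
ORIGIN_ANCESTRAL = "ancestral_polymorphism"
ORIGIN_DENOVO = "de_novo"
ORIGIN_GENEFLOW = "gene_flow"


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class ChromSpec:
    name: str
    length: int


@dataclass(frozen=True)
class GeneSpec:
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]  # 0-based half-open, genomic order

    def to_annotation(self) -> CdsAnnotation:
        ordered = self.exons if self.strand == "+" else self.exons[::-1]
        return CdsAnnotation(self.gene_id, self.gene_id, self.chrom, self.strand, ordered)


@dataclass(frozen=True)
class LocusSpec:
    """An ancestral polymorphic locus (one fixation block)."""

    name: str
    chrom: str
    start: int
    end: int
    n_haplotypes: int
    density: float
    retention_multiplier: float = 1.0


@dataclass(frozen=True)
class GeneFlowEvent:
    donor: str
    recipient: str
    chrom: str
    start: int
    end: int


@dataclass(frozen=True)
class ClusterPlan:
    name: str
    members: tuple[str, ...]
    split_generation: int


@dataclass(frozen=True)
class SimConfig:
    chromosomes: tuple[ChromSpec, ...]
    genes: tuple[GeneSpec, ...]
    loci: tuple[LocusSpec, ...]
    clusters: tuple[ClusterPlan, ...]
    singletons: tuple[str, ...]
    reference_strain: str
    total_generations: int
    mutation_rate: float
    gene_flow_events: tuple[GeneFlowEvent, ...] = ()
    designated_gene: str | None = None
    seed: int = 0
    allow_recurrent: bool = False

    def __post_init__(self) -> None:
        sizes = {c.name: c.length for c in self.chromosomes}
        if self.mutation_rate < 0:
            raise ValueError("mutation_rate must be >= 0")
        for locus in self.loci:
            if locus.chrom not in sizes or not 0 <= locus.start < locus.end <= sizes[locus.chrom]:
                raise ValueError(f"locus {locus.name} outside chromosome bounds")
            if locus.n_haplotypes < 2:
                raise ValueError(f"locus {locus.name}: need >= 2 ancestral haplotypes")
            if not 0 < locus.density <= 1:
                raise ValueError(f"locus {locus.name}: density must be in (0, 1]")
        for cluster in self.clusters:
            if not 0 < cluster.split_generation <= self.total_generations:
                raise ValueError(
                    f"cluster {cluster.name}: split generation must fall inside the history"
                )
        names = self.strains
        if len(set(names)) != len(names):
            raise ValueError("strain names must be unique")
        if self.reference_strain not in names:
            raise ValueError("reference strain must be one of the panel strains")
        by_recipient: dict[str, list[GeneFlowEvent]] = {}
        for ev in self.gene_flow_events:
            if ev.donor == ev.recipient:
                raise ValueError("gene flow donor and recipient must differ")
            if ev.donor not in names or ev.recipient not in names:
                raise ValueError("gene flow strains must be panel strains")
            if ev.chrom not in sizes or not 0 <= ev.start < ev.end <= sizes[ev.chrom]:
                raise ValueError("gene flow segment outside chromosome bounds")
            by_recipient.setdefault(ev.recipient, []).append(ev)
        for recipient, events in by_recipient.items():
            spans = sorted((e.chrom, e.start, e.end) for e in events)
            for (c1, s1, e1), (c2, s2, e2) in zip(spans, spans[1:]):
                if c1 == c2 and s2 < e1:
                    raise ValueError(f"overlapping gene flow events on {recipient}")

    @property
    def strains(self) -> tuple[str, ...]:
        members = tuple(m for cl in self.clusters for m in cl.members)
        extra = () if self.reference_strain in members + self.singletons else (self.reference_strain,)
        return members + self.singletons + extra

    @property
    def genome_length(self) -> int:
        return sum(c.length for c in self.chromosomes)

    def chrom_sizes(self) -> dict[str, int]:
        return {c.name: c.length for c in self.chromosomes}


def default_config(
    scenario: str = "ancestral",
    seed: int = 0,
    *,
    n_chromosomes: int = 20,
    chromosome_length: int = 2_000_000,
    genes_per_chromosome: int = 25,
    total_generations: int = 100,
    generations_after_split: int = 37,
    mutation_rate: float = 2.5e-6,
    n_ordinary_loci: int = 9,
    locus_length: int = 200_000,
    ordinary_blocks: int = 4,
    ordinary_density_range: tuple[float, float] = (2e-4, 1e-3),
    mhc_blocks: int = 4,
    mhc_block_length: int = 50_000,
    mhc_density: float = 0.02,
    retention_target: float = 0.10,
    geneflow_segments: int = 4,
    geneflow_segment_length: int = 500_000,
) -> SimConfig:
    """Study-panel configuration for one of the four scenarios.

    Defaults are desk-scale study conditions: a 25-strain panel (five
    substrain clusters of sizes 2, 4, 2, 2, 2, twelve singleton strains and
    one reference strain) over 20 chromosomes of 2 Mb; ~10^4 homozygous SNVs
    per strain (mutation_rate * genome * generations); polymorphic loci
    covering 5% of the genome -- nine "olfactory-like" 200 kb regions plus
    one high-density MHC-like region hosting the designated
    high-polymorphism gene, each region composed of adjacent 50 kb fixation
    blocks emulating haplotype-block inheritance; a
    substrain split 37 generations before observation (the F37 anchor); and
    balancing retention tuned so 10% of founder heterozygosity survives to
    observation inside the loci.  The gene-flow scenario replaces the loci
    with donor segments of matched total span per recipient.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    layout_rng = np.random.default_rng([seed, 0])
    width = max(2, len(str(n_chromosomes)))
    chromosomes = tuple(
        ChromSpec(f"chr{i + 1:0{width}d}", chromosome_length) for i in range(n_chromosomes)
    )

    # -- polymorphic loci --------------------------------------------------
    multiplier = balancing_multiplier(retention_target, total_generations)
    loci: list[LocusSpec] = []
    mhc_chrom = chromosomes[min(15, n_chromosomes) - 1].name
    mhc_start = int(chromosome_length * 0.4)
    with_loci = scenario in ("ancestral", "mixed")
    if with_loci:
        for b in range(mhc_blocks):
            start = mhc_start + b * mhc_block_length
            loci.append(
                LocusSpec(
                    f"mhc_block{b + 1}", mhc_chrom, start, start + mhc_block_length,
                    n_haplotypes=4, density=mhc_density, retention_multiplier=multiplier,
                )
            )
        densities = np.geomspace(*ordinary_density_range, num=max(n_ordinary_loci, 1))
        block = max(1, locus_length // ordinary_blocks)
        for i in range(n_ordinary_loci):
            chrom = chromosomes[i % max(1, n_chromosomes - 1)]
            start = int(layout_rng.uniform(0.1, 0.7) * (chrom.length - locus_length))
            for b in range(ordinary_blocks):
                loci.append(
                    LocusSpec(
                        f"locus{i + 1}_block{b + 1}", chrom.name,
                        start + b * block, start + (b + 1) * block,
                        n_haplotypes=(2, 3, 4)[i % 3], density=float(densities[i]),
                        retention_multiplier=multiplier,
                    )
                )

    # -- gene models -------------------------------------------------------
    mhc_span = (mhc_start, mhc_start + mhc_blocks * mhc_block_length)
    genes: list[GeneSpec] = []
    slot = chromosome_length // genes_per_chromosome
    counter = 0
    for chrom in chromosomes:
        for s in range(genes_per_chromosome):
            slot_start = s * slot
            if chrom.name == mhc_chrom and with_loci and not (
                slot_start + slot <= mhc_span[0] or slot_start >= mhc_span[1]
            ):
                continue
            counter += 1
            n_exons = int(layout_rng.integers(1, 4))
            total = 3 * int(layout_rng.integers(300, 801))
            cuts = np.sort(layout_rng.choice(np.arange(1, total // 3), n_exons - 1, replace=False)) * 3 if n_exons > 1 else np.array([], dtype=int)
            exon_lens = np.diff(np.concatenate([[0], cuts, [total]]))
            gaps = layout_rng.integers(100, 500, size=n_exons - 1) if n_exons > 1 else np.array([], dtype=int)
            span = int(exon_lens.sum() + gaps.sum())
            offset = int(layout_rng.integers(0, max(1, slot - span - 1)))
            exons = []
            cursor = slot_start + offset
            for i, length in enumerate(exon_lens):
                exons.append((cursor, cursor + int(length)))
                cursor += int(length) + (int(gaps[i]) if i < len(gaps) else 0)
            strand = "+" if layout_rng.random() < 0.5 else "-"
            genes.append(GeneSpec(f"gene{counter:04d}", chrom.name, strand, tuple(exons)))
    designated = None
    if with_loci:
        designated = "geneMHC"
        exon_len = min(600, mhc_block_length // 3 // 3 * 3)
        exons = tuple(
            (
                mhc_start + b * mhc_block_length + int(mhc_block_length * 0.4),
                mhc_start + b * mhc_block_length + int(mhc_block_length * 0.4) + exon_len,
            )
            for b in range(mhc_blocks)
        )
        genes.append(GeneSpec(designated, mhc_chrom, "+", exons))

    # -- panel plan --------------------------------------------------------
    split = total_generations - generations_after_split
    sizes = (2, 4, 2, 2, 2)
    clusters = tuple(
        ClusterPlan(
            f"C{i + 1}",
            tuple(f"C{i + 1}{chr(ord('a') + j)}" for j in range(size)),
            split,
        )
        for i, size in enumerate(sizes)
    )
    singletons = tuple(f"S{i + 1:02d}" for i in range(12))

    # -- gene flow ---------------------------------------------------------
    events: list[GeneFlowEvent] = []
    if scenario in ("geneflow", "mixed"):
        n_segments = geneflow_segments if scenario == "geneflow" else max(1, geneflow_segments // 2)
        for i, cluster in enumerate(clusters):
            recipient = cluster.members[0]
            donor = singletons[i % len(singletons)]
            placed: list[tuple[str, int, int]] = []
            while len(placed) < n_segments:
                chrom = chromosomes[int(layout_rng.integers(len(chromosomes)))]
                length = min(geneflow_segment_length, chrom.length)
                start = int(layout_rng.integers(0, max(1, chrom.length - length)))
                if all(c != chrom.name or start + length <= s or start >= e for c, s, e in placed):
                    placed.append((chrom.name, start, start + length))
            events.extend(GeneFlowEvent(donor, recipient, c, s, e) for c, s, e in sorted(placed))

    return SimConfig(
        chromosomes=chromosomes,
        genes=tuple(genes),
        loci=tuple(loci),
        clusters=clusters,
        singletons=singletons,
        reference_strain="REF",
        total_generations=total_generations,
        mutation_rate=mutation_rate,
        gene_flow_events=tuple(events),
        designated_gene=designated,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# deterministic background sequence


def _splitmix64(x: np.ndarray) -> np.ndarray:
    x = (x + np.uint64(0x9E3779B97F4A7C15)).astype(np.uint64)
    x ^= x >> np.uint64(30)
    x = (x * np.uint64(0xBF58476D1CE4E5B9)).astype(np.uint64)
    x ^= x >> np.uint64(27)
    x = (x * np.uint64(0x94D049BB133111EB)).astype(np.uint64)
    return x ^ (x >> np.uint64(31))


def background_codes(offsets: np.ndarray, seed: int) -> np.ndarray:
    """Deterministic background base codes (0..3) at global genome offsets."""
    key = int.from_bytes(
        hashlib.blake2b(f"ancpoly-bg:{seed}".encode(), digest_size=8).digest(), "big"
    )
    with np.errstate(over="ignore"):
        h = _splitmix64(np.asarray(offsets, dtype=np.uint64) ^ np.uint64(key))
    return (h % np.uint64(4)).astype(np.uint8)


# ---------------------------------------------------------------------------
# panel


@dataclass
class StrainGenome:
    """Non-background state of one strain, keyed by global genome offset."""

    hom: dict  # offset -> base code (uint8) of a homozygous non-background allele
    het: dict  # offset -> (code_hap1, code_hap2), differing


@dataclass
class PoolLocus:
    spec: LocusSpec
    offsets: np.ndarray  # global offsets of polymorphic positions, sorted
    alt_codes: np.ndarray  # uint8 alternate base code per position
    carriers: np.ndarray  # (n_positions, K) bool: which haplotypes carry the alt


@dataclass
class Panel:
    config: SimConfig
    pool: list[PoolLocus]
    genomes: dict[str, StrainGenome]
    fixation: dict  # strain -> locus name -> ("fixed", hap, generation) | ("het", (h1, h2))
    geneflow_changed: set = field(default_factory=set)
    _starts_cache: np.ndarray | None = field(default=None, repr=False)
    _poly_cache: set | None = field(default=None, repr=False)
    _matrix_cache: GenotypeMatrix | None = field(default=None, repr=False)

    # -- coordinates -------------------------------------------------------
    @property
    def _starts(self) -> np.ndarray:
        if self._starts_cache is None:
            lengths = [c.length for c in self.config.chromosomes]
            self._starts_cache = np.concatenate([[0], np.cumsum(lengths)])
        return self._starts_cache

    def to_offset(self, chrom: str, pos: int) -> int:
        names = [c.name for c in self.config.chromosomes]
        return int(self._starts[names.index(chrom)]) + pos - 1

    def to_coord(self, offsets: np.ndarray) -> tuple[list[str], np.ndarray]:
        starts = self._starts
        idx = np.searchsorted(starts, np.asarray(offsets), side="right") - 1
        names = [self.config.chromosomes[i].name for i in idx]
        return names, np.asarray(offsets) - starts[idx] + 1

    # -- truth -------------------------------------------------------------
    @property
    def poly_offsets(self) -> set:
        if self._poly_cache is None:
            self._poly_cache = {int(o) for locus in self.pool for o in locus.offsets}
        return self._poly_cache

    def site_origin(self, offset: int) -> str:
        if offset in self.geneflow_changed:
            return ORIGIN_GENEFLOW
        if offset in self.poly_offsets:
            return ORIGIN_ANCESTRAL
        return ORIGIN_DENOVO

    def truth(self) -> dict:
        """Machine-readable ground truth for the emitted panel."""
        matrix = self.genotype_matrix()
        names = [c.name for c in self.config.chromosomes]
        chrom_start = {n: int(s) for n, s in zip(names, self._starts[:-1])}
        origins = {
            f"{site.chrom}:{site.pos}": self.site_origin(chrom_start[site.chrom] + site.pos - 1)
            for site in matrix.sites
        }
        return {
            "origins": origins,
            "polymorphic_loci": [
                {
                    "name": l.name, "chrom": l.chrom, "start": l.start, "end": l.end,
                    "n_haplotypes": l.n_haplotypes, "density": l.density,
                    "retention_multiplier": l.retention_multiplier,
                }
                for l in self.config.loci
            ],
            "clusters": {c.name: list(c.members) for c in self.config.clusters},
            "designated_gene": self.config.designated_gene,
            "reference_strain": self.config.reference_strain,
            "residual_het_sites": {
                strain: len(genome.het) for strain, genome in self.genomes.items()
            },
            "seed": self.config.seed,
        }

    # -- genotype matrix ---------------------------------------------------
    def genotype_matrix(self) -> GenotypeMatrix:
        """The panel as a GenotypeMatrix, identical to emitting + re-reading."""
        if self._matrix_cache is not None:
            return self._matrix_cache
        cfg = self.config
        strains = list(cfg.strains)
        all_offsets = sorted(
            {o for g in self.genomes.values() for o in g.hom} |
            {o for g in self.genomes.values() for o in g.het}
        )
        offsets = np.array(all_offsets, dtype=np.int64)
        m = len(offsets)
        bg = background_codes(offsets, cfg.seed)
        b1 = np.tile(bg, (len(strains), 1))
        b2 = b1.copy()
        pos_of = {int(o): j for j, o in enumerate(offsets)}
        for i, strain in enumerate(strains):
            genome = self.genomes[strain]
            for off, code in genome.hom.items():
                b1[i, pos_of[off]] = b2[i, pos_of[off]] = code
            for off, (c1, c2) in genome.het.items():
                b1[i, pos_of[off]], b2[i, pos_of[off]] = c1, c2

        ref_row = strains.index(cfg.reference_strain)
        ref_codes = b1[ref_row].copy()  # het reference positions: haplotype-1 allele
        present = np.zeros((4, m), dtype=bool)
        for b in range(4):
            present[b] = ((b1 == b) | (b2 == b)).any(axis=0)
        is_alt = present.copy()
        is_alt[ref_codes, np.arange(m)] = False
        keep = is_alt.any(axis=0)

        offsets, bg = offsets[keep], bg[keep]
        b1, b2, ref_codes, is_alt = b1[:, keep], b2[:, keep], ref_codes[keep], is_alt[:, keep]
        m = len(offsets)
        alt_rank = np.cumsum(is_alt, axis=0) - is_alt  # exclusive prefix count
        cols = np.arange(m)

        def codes(plane: np.ndarray) -> np.ndarray:
            out = 1 + alt_rank[plane, cols[None, :]]
            return np.where(plane == ref_codes, 0, out).astype(np.int8)

        a1, a2 = codes(b1), codes(b2)
        a1, a2 = np.minimum(a1, a2), np.maximum(a1, a2)

        chroms, positions = self.to_coord(offsets)
        sites = []
        for j in range(m):
            alts = tuple(_BASES[b] for b in range(4) if is_alt[b, j])
            sites.append(Site(chroms[j], int(positions[j]), str(_BASES[ref_codes[j]]), alts))
        self._matrix_cache = GenotypeMatrix(strains, sites, a1, a2)
        return self._matrix_cache


# ---------------------------------------------------------------------------
# simulation steps


def simulate_ancestral_pool(config: SimConfig, rng: np.random.Generator) -> list[PoolLocus]:
    """Founder haplotype pool: monomorphic outside loci, K haplotypes inside."""
    starts = np.concatenate([[0], np.cumsum([c.length for c in config.chromosomes])])
    names = [c.name for c in config.chromosomes]
    pool = []
    for locus in config.loci:
        base = starts[names.index(locus.chrom)]
        length = locus.end - locus.start
        n = int(rng.binomial(length, locus.density))
        local = np.sort(rng.choice(length, size=n, replace=False))
        offsets = (base + locus.start + local).astype(np.int64)
        bg = background_codes(offsets, config.seed)
        alt = (bg + 1 + rng.integers(0, 3, size=n).astype(np.uint8)) % np.uint8(4)
        k = locus.n_haplotypes
        carriers = rng.integers(0, 2, size=(n, k)).astype(bool)
        bad = ~carriers.any(axis=1) | carriers.all(axis=1)
        while bad.any():
            carriers[bad] = rng.integers(0, 2, size=(int(bad.sum()), k)).astype(bool)
            bad = ~carriers.any(axis=1) | carriers.all(axis=1)
        pool.append(PoolLocus(locus, offsets, alt.astype(np.uint8), carriers))
    return pool


def _fixation_generation(u: float, retention: np.ndarray) -> int | None:
    """First generation t with R(t) < u, or None if heterozygosity survives."""
    below = np.nonzero(retention < u)[0]
    return int(below[0]) if len(below) else None


def _apply_locus(genome: StrainGenome, locus: PoolLocus, state: tuple, seed: int) -> None:
    offs = locus.offsets
    alts = locus.alt_codes
    if state[0] == "fixed":
        hap = state[1]
        for off, alt in zip(offs[locus.carriers[:, hap]], alts[locus.carriers[:, hap]]):
            genome.hom[int(off)] = int(alt)
    else:
        h1, h2 = state[1]
        c1, c2 = locus.carriers[:, h1], locus.carriers[:, h2]
        both = c1 & c2
        for off, alt in zip(offs[both], alts[both]):
            genome.hom[int(off)] = int(alt)
        only = c1 ^ c2
        bg = background_codes(offs[only], seed)
        for off, alt, bgc, in_h1 in zip(offs[only], alts[only], bg, c1[only]):
            pair = (int(alt), int(bgc)) if in_h1 else (int(bgc), int(alt))
            genome.het[int(off)] = pair


def simulate_panel(config: SimConfig) -> Panel:
    """Run the full generator: pool, lineages, splits, mutations, gene flow."""
    rng = np.random.default_rng([config.seed, 1])
    pool = simulate_ancestral_pool(config, rng)
    total = config.total_generations
    curves = {
        locus.spec.name: retention_curve(total, locus.spec.retention_multiplier)
        for locus in pool
    }

    # lineages: (lineage_members, split_generation or None for singletons)
    lineages: list[tuple[tuple[str, ...], int | None]] = [
        (cl.members, cl.split_generation) for cl in config.clusters
    ]
    for name in config.singletons:
        lineages.append(((name,), None))
    if config.reference_strain not in {m for ms, _ in lineages for m in ms}:
        lineages.append(((config.reference_strain,), None))

    fixation: dict[str, dict] = {s: {} for s in config.strains}
    locus_state: dict[str, dict[str, tuple]] = {s: {} for s in config.strains}

    for members, split in lineages:
        for locus in pool:
            curve = curves[locus.spec.name]
            k = locus.spec.n_haplotypes
            h1, h2 = (int(x) for x in rng.choice(k, size=2, replace=False))
            u = float(rng.random())
            fix_gen = _fixation_generation(u, curve)
            horizon = split if split is not None else total
            if fix_gen is not None and fix_gen <= horizon:
                hap = h1 if rng.random() < 0.5 else h2
                state = ("fixed", hap, fix_gen)
                for m in members:
                    locus_state[m][locus.spec.name] = state
            elif split is None:
                state = ("fixed", h1 if rng.random() < 0.5 else h2, fix_gen) if fix_gen is not None else ("het", (h1, h2))
                locus_state[members[0]][locus.spec.name] = state
            else:
                # heterozygous at the split: members fix (or not) independently
                r_split = curve[split]
                for m in members:
                    um = float(rng.random())
                    # survival past t (> split) iff um <= R(t) / R(split)
                    cond = curve / r_split
                    fix_m = _fixation_generation(um, cond[: total + 1])
                    if fix_m is not None and fix_m <= total:
                        hap = h1 if rng.random() < 0.5 else h2
                        locus_state[m][locus.spec.name] = ("fixed", hap, max(fix_m, split + 1))
                    else:
                        locus_state[m][locus.spec.name] = ("het", (h1, h2))

    # -- de novo mutations -------------------------------------------------
    genome_len = config.genome_length
    mu = config.mutation_rate
    branch_counts: list[tuple[tuple[str, ...], int]] = []
    for members, split in lineages:
        if split is None:
            branch_counts.append((members, int(rng.poisson(mu * genome_len * total))))
        else:
            branch_counts.append((members, int(rng.poisson(mu * genome_len * split))))
            for m in members:
                branch_counts.append(((m,), int(rng.poisson(mu * genome_len * (total - split)))))
    need = sum(n for _, n in branch_counts)
    draw = rng.integers(0, genome_len, size=int(need * 1.2) + 64)
    if not config.allow_recurrent:
        draw = np.unique(draw)
        poly = np.fromiter(
            (o for locus in pool for o in locus.offsets), dtype=np.int64,
            count=sum(len(l.offsets) for l in pool),
        )
        draw = draw[~np.isin(draw, poly)]
        draw = draw[rng.permutation(len(draw))]
    if len(draw) < need:  # pragma: no cover - astronomically unlikely
        raise RuntimeError("de novo position pool exhausted; increase genome size")
    positions = draw[:need].astype(np.int64)
    bg = background_codes(positions, config.seed)
    alts = (bg + 1 + rng.integers(0, 3, size=need).astype(np.uint8)) % np.uint8(4)

    denovo: dict[str, list[tuple[int, int]]] = {s: [] for s in config.strains}
    cursor = 0
    for members, count in branch_counts:
        chunk = list(zip(positions[cursor : cursor + count], alts[cursor : cursor + count]))
        cursor += count
        for m in members:
            denovo[m].extend(chunk)

    # -- assemble genomes ----------------------------------------------------
    genomes: dict[str, StrainGenome] = {}
    for strain in config.strains:
        genome = StrainGenome(hom={}, het={})
        for locus in pool:
            _apply_locus(genome, locus, locus_state[strain][locus.spec.name], config.seed)
        for off, alt in denovo[strain]:
            genome.hom[int(off)] = int(alt)
        genomes[strain] = genome
        fixation[strain] = dict(locus_state[strain])

    panel = Panel(config=config, pool=pool, genomes=genomes, fixation=fixation)
    if config.gene_flow_events:
        apply_gene_flow(panel, config.gene_flow_events)
    return panel


def apply_gene_flow(panel: Panel, events: Sequence[GeneFlowEvent]) -> Panel:
    """Replace each recipient's segment by the donor's haplotype, in place.

    Sites where the replacement changed the recipient's state are recorded
    and labeled ``gene_flow`` in the truth output.
    """
    for ev in events:
        lo = panel.to_offset(ev.chrom, ev.start + 1)
        hi = panel.to_offset(ev.chrom, ev.end)  # inclusive offset of last base
        donor = panel.genomes[ev.donor]
        recipient = panel.genomes[ev.recipient]

        def in_range(off: int) -> bool:
            return lo <= off <= hi

        donor_hom = {o: c for o, c in donor.hom.items() if in_range(o)}
        donor_het = {o: p for o, p in donor.het.items() if in_range(o)}
        rec_hom = {o: c for o, c in recipient.hom.items() if in_range(o)}
        rec_het = {o: p for o, p in recipient.het.items() if in_range(o)}

        changed = set()
        for off in set(donor_hom) | set(rec_hom):
            if donor_hom.get(off) != rec_hom.get(off):
                changed.add(off)
        for off in set(donor_het) | set(rec_het):
            if donor_het.get(off) != rec_het.get(off):
                changed.add(off)

        for off in rec_hom:
            del recipient.hom[off]
        for off in rec_het:
            del recipient.het[off]
        recipient.hom.update(donor_hom)
        recipient.het.update(donor_het)
        panel.geneflow_changed.update(int(o) for o in changed)
    return panel


def simulate_retention(
    generations: int, n_loci: int, multiplier: float = 1.0, seed: int = 0
) -> float:
    """Monte-Carlo fraction of initially heterozygous loci still segregating.

    Uses the same survival draw as strain derivation, so this is the
    simulator's empirical counterpart of 1 - F_t (times the balancing cap).
    """
    rng = np.random.default_rng([seed, 2])
    curve = retention_curve(generations, multiplier)
    u = rng.random(n_loci)
    return float(np.mean(u <= curve[generations]))


# ---------------------------------------------------------------------------
# emission


def _ref_base_codes(panel: Panel, offsets: np.ndarray) -> np.ndarray:
    """Reference-strain base codes at arbitrary offsets (background elsewhere)."""
    codes = background_codes(offsets, panel.config.seed).copy()
    ref = panel.genomes[panel.config.reference_strain]
    for j, off in enumerate(np.asarray(offsets, dtype=np.int64)):
        o = int(off)
        if o in ref.hom:
            codes[j] = ref.hom[o]
        elif o in ref.het:
            codes[j] = ref.het[o][0]
    return codes


def emit_panel(panel: Panel, outdir: str | os.PathLike) -> dict[str, str]:
    """Write VCF + BED12 + chrom.sizes + CDS FASTA + truth JSON.

    Returns a dict of output paths.  The emitted files parse back through the
    pipeline readers into the same genotype matrix (round-trip identity).
    """
    os.makedirs(outdir, exist_ok=True)
    cfg = panel.config
    paths = {
        "vcf": os.path.join(outdir, "panel.vcf"),
        "bed": os.path.join(outdir, "cds.bed"),
        "chrom_sizes": os.path.join(outdir, "panel.chrom.sizes"),
        "cds_fasta": os.path.join(outdir, "cds.fasta"),
        "truth": os.path.join(outdir, "truth.json"),
    }

    with open(paths["chrom_sizes"], "w") as fh:
        for chrom in cfg.chromosomes:
            fh.write(f"{chrom.name}\t{chrom.length}\n")

    write_bed_cds((g.to_annotation() for g in cfg.genes), paths["bed"])

    starts = np.concatenate([[0], np.cumsum([c.length for c in cfg.chromosomes])])
    names = [c.name for c in cfg.chromosomes]
    with open(paths["cds_fasta"], "w") as fh:
        for gene in cfg.genes:
            base = starts[names.index(gene.chrom)]
            chunks = []
            for s, e in gene.exons:
                offs = np.arange(base + s, base + e, dtype=np.int64)
                chunks.append("".join(_BASES[_ref_base_codes(panel, offs)]))
            seq = "".join(chunks)
            if gene.strand == "-":
                seq = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
            fh.write(f">{gene.gene_id}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")

    matrix = panel.genotype_matrix()
    with open(paths["vcf"], "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=ancpoly-simulate seed={cfg.seed}\n")
        for chrom in cfg.chromosomes:
            fh.write(f"##contig=<ID={chrom.name},length={chrom.length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.strains)
            + "\n"
        )
        for j, site in enumerate(matrix.sites):
            gts = []
            for i in range(len(matrix.strains)):
                x, y = matrix.a1[i, j], matrix.a2[i, j]
                gts.append("./." if x < 0 else f"{x}/{y}")
            fh.write(
                f"{site.chrom}\t{site.pos}\t.\t{site.ref}\t{','.join(site.alts)}"
                f"\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )

    with open(paths["truth"], "w") as fh:
        json.dump(panel.truth(), fh, indent=None, separators=(",", ":"), sort_keys=True)
        fh.write("\n")
    return paths


def load_truth(path: str | os.PathLike) -> dict:
    with open(path) as fh:
        return json.load(fh)
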