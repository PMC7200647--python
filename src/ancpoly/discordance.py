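"""Discordant-site detection and its downstream genomic summaries.

A *discordant site* is a homozygous variant position whose allele pattern is
inconsistent with the strain phylogeny: within a cluster of closely related
substrains the site is variable, and at least two of the within-cluster
alleles are each also carried by strains outside the cluster.  Such a
character requires >= 2 independent mutations under parsimony on any tree in
which the cluster is a clade, which is what makes it evidence for ancestral
polymorphism (incomplete lineage sorting) or gene flow rather than ordinary
descent.

Only homozygous calls carry alleles here: a site is evaluable for a cluster
only when *all* cluster members have homozygous calls (heterozygous or
missing members would fabricate within-cluster variation), and outside
strains contribute alleles only through homozygous calls.

Downstream operations assign called sites to genes (density per kb of merged
CDS), tile them into fixed-width chromosome bins with a dispersion-based
hotspot flag, quantify hotspot sharing between clusters (Jaccard), and
measure co-localization with residual heterozygous variants -- the analyses
that distinguish shared ancestral polymorphism from stochastic gene flow.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .coding import CdsAnnotation
from .distance import DistanceMatrix
from .genotypes import GenotypeMatrix
from .tree import BranchSupport, PhyloTree

TABLE_COLUMNS = [
    "cluster",
    "chrom",
    "pos",
    "alleles_in_cluster",
    "alleles_outside",
    "gene_ids",
    "bin_id",
]


@dataclass(frozen=True)
class ClusterSpec:
    """A named group of >= 2 substrains expected to form a clade."""

    name: str
    members: tuple[str, ...]
    source: str = "config"

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError(f"cluster {self.name} needs at least 2 members")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"cluster {self.name} has duplicate members")


def call_discordant_sites(
    matrix: GenotypeMatrix,
    tree: PhyloTree | None,
    cluster: ClusterSpec,
) -> pd.DataFrame:
    """Sites discordant for `cluster`: variable within it, shared outside.

    A site qualifies iff (a) all cluster members are homozygous and carry
    >= 2 distinct alleles, and (b) at least two of those within-cluster
    alleles are each observed (homozygous) in >= 1 strain outside the
    cluster.  For biallelic sites this reduces to: both alleles occur inside
    and outside the cluster.  If `tree` is given, the cluster is verified to
    be a clade of it first.
    """
    members = list(cluster.members)
    unknown = [m for m in members if m not in matrix.strains]
    if unknown:
        raise ValueError(f"cluster {cluster.name}: unknown strains {unknown}")
    if tree is not None and not tree.is_clade(members):
        raise ValueError(f"cluster {cluster.name} is not a clade of the tree")

    mi = np.array([matrix.strain_index(m) for m in members])
    oi = np.array([i for i in range(len(matrix.strains)) if matrix.strains[i] not in members])
    n_sites = len(matrix.sites)
    if n_sites == 0 or len(oi) == 0:
        return pd.DataFrame(columns=TABLE_COLUMNS)

    hom = matrix.is_hom
    a1 = matrix.a1
    members_all_hom = hom[mi].all(axis=0)

    max_alleles = max(len(s.alleles) for s in matrix.sites)
    inside_has = np.zeros((max_alleles, n_sites), dtype=bool)
    outside_has = np.zeros((max_alleles, n_sites), dtype=bool)
    for a in range(max_alleles):
        inside_has[a] = ((a1[mi] == a) & hom[mi]).any(axis=0)
        outside_has[a] = ((a1[oi] == a) & hom[oi]).any(axis=0)
    inside_count = inside_has.sum(axis=0)
    shared_count = (inside_has & outside_has).sum(axis=0)
    discordant = members_all_hom & (inside_count >= 2) & (shared_count >= 2)

    rows = []
    for j in np.nonzero(discordant)[0]:
        site = matrix.sites[j]
        inside = sorted(site.alleles[a] for a in range(len(site.alleles)) if inside_has[a, j])
        outside = sorted(site.alleles[a] for a in range(len(site.alleles)) if outside_has[a, j])
        rows.append(
            {
                "cluster": cluster.name,
                "chrom": site.chrom,
                "pos": site.pos,
                "alleles_in_cluster": ",".join(inside),
                "alleles_outside": ",".join(outside),
                "gene_ids": "",
                "bin_id": -1,
            }
        )
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


@dataclass
class DiscordantSummary:
    counts: dict[str, int]
    union: set
    min_cluster_sites: set  # sites discordant in >= min_clusters clusters
    min_clusters: int


def discordant_site_summary(
    tables: Mapping[str, pd.DataFrame], min_clusters: int = 1
) -> DiscordantSummary:
    """Per-cluster counts plus union / >=k-cluster site sets on (chrom, pos)."""
    if not tables:
        raise ValueError("at least one cluster table is required")
    counts = {name: len(t) for name, t in tables.items()}
    membership: dict[tuple, int] = {}
    for t in tables.values():
        for chrom, pos in zip(t["chrom"], t["pos"]):
            membership[(chrom, int(pos))] = membership.get((chrom, int(pos)), 0) + 1
    union = set(membership)
    in_k = {site for site, k in membership.items() if k >= min_clusters}
    return DiscordantSummary(counts, union, in_k, min_clusters)


def _merged_cds_by_gene(
    annotations: Sequence[CdsAnnotation],
) -> dict[str, tuple[str, list[tuple[int, int]]]]:
    """Union of each gene's CDS intervals (merged), keyed by gene_id."""
    raw: dict[str, tuple[str, list[tuple[int, int]]]] = {}
    for ann in annotations:
        chrom, ivals = raw.setdefault(ann.gene_id, (ann.chrom, []))
        if chrom != ann.chrom:
            raise ValueError(f"gene {ann.gene_id} annotated on two chromosomes")
        ivals.extend(ann.cds_intervals)
    merged: dict[str, tuple[str, list[tuple[int, int]]]] = {}
    for gene, (chrom, ivals) in raw.items():
        ivals = sorted(ivals)
        out = [list(ivals[0])]
        for s, e in ivals[1:]:
            if s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        merged[gene] = (chrom, [(s, e) for s, e in out])
    return merged


def genes_with_discordant_sites(
    table: pd.DataFrame, annotations: Sequence[CdsAnnotation]
) -> pd.DataFrame:
    """Genes holding >= 1 discordant site, ranked by density per kb of CDS.

    The density denominator is the merged union of the gene's CDS intervals;
    a site inside the CDS of several genes counts for each of them; a site
    discordant in several clusters counts once per gene (distinct positions).
    Ties are broken by gene_id for a deterministic ranking.
    """
    merged = _merged_cds_by_gene(annotations)
    trees: dict[str, IntervalTree] = {}
    lengths: dict[str, int] = {}
    for gene, (chrom, ivals) in merged.items():
        lengths[gene] = sum(e - s for s, e in ivals)
        tree = trees.setdefault(chrom, IntervalTree())
        for s, e in ivals:
            tree.addi(s, e, gene)

    sites = {(c, int(p)) for c, p in zip(table["chrom"], table["pos"])}
    per_gene: dict[str, set] = {}
    for chrom, pos in sites:
        for hit in trees.get(chrom, IntervalTree()).at(pos - 1):
            per_gene.setdefault(hit.data, set()).add((chrom, pos))

    rows = [
        {
            "gene_id": gene,
            "discordant_count": len(found),
            "cds_length_bases": lengths[gene],
            "density_per_kb": 1000.0 * len(found) / lengths[gene],
        }
        for gene, found in per_gene.items()
    ]
    frame = pd.DataFrame(
        rows, columns=["gene_id", "discordant_count", "cds_length_bases", "density_per_kb"]
    )
    return frame.sort_values(
        ["density_per_kb", "gene_id"], ascending=[False, True], ignore_index=True
    )


def bin_sites(
    table: pd.DataFrame,
    chrom_sizes: Mapping[str, int],
    bin_size: int = 1_000_000,
    hotspot_sd_multiplier: float = 2.0,
) -> pd.DataFrame:
    """Tile chromosomes into fixed bins; count sites; flag hotspot bins.

    Bins cover each chromosome from 0 to its length.  A non-empty bin is a
    hotspot when its count >= mean + `hotspot_sd_multiplier` * SD, the
    moments taken over all bins of chromosomes that carry >= 1 site
    (population SD).  Returns columns chrom, bin_start, bin_size, count,
    is_hotspot.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    rows = []
    index: dict[tuple, int] = {}
    for chrom in chrom_sizes:
        length = chrom_sizes[chrom]
        for start in range(0, length, bin_size):
            index[(chrom, start)] = len(rows)
            rows.append({"chrom": chrom, "bin_start": start, "bin_size": bin_size, "count": 0})
    occupied_chroms = set()
    for chrom, pos in {(c, int(p)) for c, p in zip(table["chrom"], table["pos"])}:
        if chrom not in chrom_sizes:
            raise ValueError(f"site on unknown chromosome {chrom}")
        if pos > chrom_sizes[chrom]:
            raise ValueError(f"site {chrom}:{pos} beyond chromosome end")
        rows[index[(chrom, (pos - 1) // bin_size * bin_size)]]["count"] += 1
        occupied_chroms.add(chrom)
    frame = pd.DataFrame(rows, columns=["chrom", "bin_start", "bin_size", "count"])
    counts = frame.loc[frame["chrom"].isin(occupied_chroms), "count"]
    if len(counts):
        threshold = counts.mean() + hotspot_sd_multiplier * counts.std(ddof=0)
        frame["is_hotspot"] = (frame["count"] >= threshold) & (frame["count"] > 0)
    else:
        frame["is_hotspot"] = False
    return frame


def hotspot_bins(bins: pd.DataFrame) -> set:
    return {
        (chrom, int(start))
        for chrom, start in zip(
            bins.loc[bins["is_hotspot"], "chrom"], bins.loc[bins["is_hotspot"], "bin_start"]
        )
    }


def cross_cluster_hotspot_overlap(
    bins_by_cluster: Mapping[str, pd.DataFrame],
) -> tuple[pd.DataFrame, float]:
    """Pairwise Jaccard of hotspot bin sets across clusters, plus the mean.

    All clusters must be binned on the identical grid.  The Jaccard of two
    empty hotspot sets is defined as 0 (no evidence of sharing).
    """
    names = sorted(bins_by_cluster)
    if len(names) < 2:
        raise ValueError("need >= 2 clusters")
    grids = {
        name: tuple(map(tuple, bins_by_cluster[name][["chrom", "bin_start", "bin_size"]].values))
        for name in names
    }
    if len(set(grids.values())) != 1:
        raise ValueError("bin grids differ between clusters")
    spots = {name: hotspot_bins(bins_by_cluster[name]) for name in names}
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            union = spots[a] | spots[b]
            jac = len(spots[a] & spots[b]) / len(union) if union else 0.0
            rows.append({"cluster_a": a, "cluster_b": b, "jaccard": jac})
    frame = pd.DataFrame(rows, columns=["cluster_a", "cluster_b", "jaccard"])
    return frame, float(frame["jaccard"].mean())


def het_discordant_colocalization(
    matrix: GenotypeMatrix,
    table: pd.DataFrame,
    chrom_sizes: Mapping[str, int],
    bin_size: int = 1_000_000,
    het_mode: str = "max_strain",
) -> tuple[pd.DataFrame, float, str]:
    """Per-bin discordant vs heterozygous counts and their Spearman rho.

    `het_mode` selects whose heterozygous calls are counted: "pooled" sums
    over all strains, "max_strain" (default) uses the single strain with the
    most heterozygous calls -- mirroring a one-strain chromosome display --
    and any strain name selects that strain.  The correlation is computed
    over bins where either count is positive; with < 3 such bins it is
    undefined and returned as NaN.
    """
    het = matrix.is_het
    if het_mode == "pooled":
        strain_rows = list(range(len(matrix.strains)))
        used = "pooled"
    elif het_mode == "max_strain":
        per_strain = het.sum(axis=1)
        best = int(np.argmax(per_strain))
        strain_rows = [best]
        used = matrix.strains[best]
    else:
        strain_rows = [matrix.strain_index(het_mode)]
        used = het_mode

    disc_bins = bin_sites(table, chrom_sizes, bin_size)[["chrom", "bin_start", "count"]]
    disc_bins = disc_bins.rename(columns={"count": "discordant_count"})
    het_counts = dict.fromkeys(
        zip(disc_bins["chrom"], disc_bins["bin_start"]), 0
    )
    het_per_site = het[strain_rows].sum(axis=0)
    for j in np.nonzero(het_per_site)[0]:
        site = matrix.sites[j]
        key = (site.chrom, (site.pos - 1) // bin_size * bin_size)
        if key in het_counts:
            het_counts[key] += int(het_per_site[j])
    disc_bins["het_count"] = [
        het_counts[(c, s)] for c, s in zip(disc_bins["chrom"], disc_bins["bin_start"])
    ]
    nonempty = disc_bins[(disc_bins["discordant_count"] > 0) | (disc_bins["het_count"] > 0)]
    if len(nonempty) < 3:
        rho = float("nan")
    else:
        rho = float(
            stats.spearmanr(nonempty["discordant_count"], nonempty["het_count"]).statistic
        )
    return disc_bins, rho, used


def propose_clusters(
    tree: PhyloTree,
    support: BranchSupport,
    dmatrix: DistanceMatrix,
    min_support: float = 80.0,
    max_within_distance: float | None = None,
) -> list[ClusterSpec]:
    """Recover substrain clusters as well-supported, tight clades.

    Candidates are sides of reference-tree splits whose subtending edge has
    support >= `min_support` and whose members are mutually closer than
    `max_within_distance` (default: half the median off-diagonal distance).
    Larger candidates win; overlapping smaller ones are dropped, so the
    result is a disjoint list.
    """
    if max_within_distance is None:
        off = dmatrix.values[~np.eye(len(dmatrix.strains), dtype=bool)]
        max_within_distance = 0.5 * float(np.median(off))
    idx = {name: i for i, name in enumerate(dmatrix.strains)}
    percent = support.percent
    candidates = []
    for split in tree.bipartitions():
        if percent.get(split, 0.0) < min_support:
            continue
        for side in split:
            members = sorted(side)
            rows = [idx[m] for m in members]
            within = dmatrix.values[np.ix_(rows, rows)]
            if within.max() <= max_within_distance:
                candidates.append(tuple(members))
    candidates.sort(key=lambda m: (-len(m), m))
    chosen: list[tuple[str, ...]] = []
    taken: set[str] = set()
    for members in candidates:
        if not taken.intersection(members):
            chosen.append(members)
            taken.update(members)
    chosen.sort()
    return [
        ClusterSpec(f"cluster{i + 1}", members, source="auto")
        for i, members in enumerate(chosen)
    ]
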