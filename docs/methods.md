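# Methods

## Scope and model

`ancpoly` analyses multi-sample SNV calls for a panel of inbred strains
against one reference genome. The reference is a coordinate system, never a
taxon: a reference-derived strain in the panel is an ordinary sample (in the
simulator, the designated reference strain is a normal lineage whose genome
defines the VCF REF alleles and which appears as an all-`0/0` sample).

Three ideas carry the analysis:

1. **Homozygous-only mutation sets.** Inbred strains are expected to be
   homozygous nearly everywhere; heterozygous calls are disproportionately
   collapsed-mapping artifacts (reads from a duplicated segment forced onto
   a single reference copy). Distances and discordance therefore use only
   homozygous non-reference calls, keyed as (chrom, pos, alt). A site where
   two strains are fixed for *different* alternates contributes 2 to their
   distance (two mutation events); the per-site alternative (1) is noted in
   the tests as a documented discrepancy.
2. **Tree-incongruence as the unit of evidence.** For a substrain cluster
   (a clade), a site variable within the cluster whose within-cluster
   alleles also occur outside cannot be explained by a single mutation:
   Fitch parsimony needs ≥ 2 changes. The caller implements this allele
   predicate directly; the parsimony score is an independent oracle, not
   part of the call path.
3. **Aggregation separates the hypotheses.** Ancestral polymorphism fixes
   at loci that were polymorphic in the shared ancestor, so discordant-site
   hotspots recur at the same genomic windows across independent clusters
   and keep residual heterozygosity; gene flow places donor segments at
   cluster-specific positions.

## Discordance predicate and missing-call policy

A site is evaluable for a cluster only when **all** cluster members have
homozygous calls — a heterozygous or missing member would fabricate
within-cluster variation. Outside strains contribute alleles only through
homozygous calls. The general (multi-allelic) predicate: ≥ 2 distinct
alleles among members, and ≥ 2 of those alleles each seen in ≥ 1 outside
strain. For biallelic sites this is "both alleles inside and outside". One
direction of the parsimony equivalence holds always (called ⇒ ≥ 2 changes);
the converse is guaranteed for two-member clusters at biallelic sites and is
property-tested there.

## Trees

Distances feed standard neighbor joining. Exact Q ties join the pair whose
smallest-member leaf names sort first, making output platform-independent;
negative branch lengths (possible on non-additive input) are clamped to zero
and counted on the tree object. Branch support for an internal edge is the
percentage of per-chromosome NJ trees whose bipartition sets contain the
same unrooted split; support is a property of splits, not rooted clades.
Trees round-trip through newick with branch lengths at 10 significant
digits; support values travel as internal node labels. The small-parsimony
routine is Hartigan's generalization of Fitch (exact for any node degree),
needed because unrooted trees are stored with a degree-3 root; leaves
without a state are pruned on the fly.

`propose_clusters` automates the choice of substrain clusters: sides of
splits with support ≥ 80% (configurable) whose within-group maximum pairwise
distance is below a threshold (default: half the median off-diagonal
distance — scale-free, appropriate when substrain divergence is clearly
below backbone divergence). Larger candidates win; the result is disjoint.

## Simulator

The generator emulates the breeding history that produces such panels:

* **Ancestral pool.** Outside polymorphic loci all founder haplotypes are
  identical. Inside each locus, K ∈ {2,3,4} haplotypes differ at positions
  drawn binomially at a per-base density; each polymorphic position has one
  alternate allele carried by a proper, non-empty subset of haplotypes.
* **Inbreeding fixation per haplotype block.** Each lineage founds from two
  distinct pool haplotypes per locus and loses heterozygosity by the
  full-sib recurrence F_t = (1 + 2F_{t−1} + F_{t−2})/4 (F_0 = F_1 = 0).
  Fixation is one draw per locus *block* — linkage is what makes discordant
  sites aggregate — with retention R(t) = min(1, (1 − F_t)·m); m is the
  balancing-selection multiplier. Because (1 − F_100) ≈ 7×10⁻¹⁰, useful m
  values are numerically huge, so defaults are derived via
  `balancing_multiplier(target, T)`: the default target retains 10% of
  founder heterozygosity at observation (T = 100), which also implies full
  retention at the substrain split.
* **Substrain splits.** Cluster members share fixations and mutations up to
  the split generation (default T − 37, anchoring the residual-het
  magnitude to ~37 post-split generations), then fix still-heterozygous
  blocks and mutate independently. A block heterozygous at the split fixes
  to either haplotype with probability ½ per member.
* **De novo mutations.** Poisson per branch with rate μ per base per
  generation; positions are sampled collision-free panel-wide (and outside
  pool positions), which *guarantees* de novo characters are concordant
  with the true genealogy — the basis of the null-purity test. A
  `allow_recurrent` switch lifts this for robustness work.
* **Gene flow.** A donor's diploid state replaces the recipient's over a
  segment; changed positions are truth-labeled `gene_flow`. Every emitted
  site carries exactly one origin label (`ancestral_polymorphism`,
  `de_novo`, `gene_flow`; gene flow takes precedence where it changed the
  recipient).

Background (monomorphic) bases come from a counter-based 64-bit hash of the
global genome offset and the run seed, so VCF REF alleles and the emitted
CDS FASTA are consistent without storing a genome. All randomness flows
from one `numpy` generator seeded by the config seed; identical configs give
byte-identical output files.

### Default study conditions

25 strains: five clusters of sizes (2, 4, 2, 2, 2), twelve singletons, one
reference strain. 20 chromosomes × 2 Mb. μ = 2.5×10⁻⁶/base/generation over
T = 100 generations ≈ 10⁴ homozygous SNVs per strain — μ here is an
*effective* desk-scale divergence rate, not a literal germline rate; it
compresses the real decades-long divergence of strain stocks into the
simulated history. Polymorphic loci cover 5% of the genome: nine
"olfactory-like" 200 kb regions (densities geometrically spread over
2×10⁻⁴–10⁻³/base, K cycling 2/3/4) and one MHC-like 200 kb region at
2×10⁻²/base with K = 4, all divided into 50 kb fixation blocks (haplotype
blocks in rodent genomes are tens of kb; coarser blocks make per-window
counts all-or-nothing). The designated high-polymorphism gene (`geneMHC`,
4 × 600 bp exons) spans the four MHC blocks, mimicking a large MHC gene
crossing several haplotype blocks. The gene-flow scenario replaces the loci
with four 500 kb donor segments per cluster recipient — the same 2 Mb span
budget per cluster as the locus regions — so hotspot sharing, not raw
signal, differentiates the scenarios. Residual heterozygosity emerges at
~10⁻⁵–2×10⁻⁵ of genome bases per strain; the real-data analogue (up to
0.02% of *exome target* bases) depends on the callable-base denominator,
which is a configuration input, not something the package asserts.

What the simulator does **not** model: coalescent genealogies, recombination
maps, selection dynamics beyond the retention multiplier, sequencing errors
or read-level artifacts (the collapsed-mapping mechanism is *motivation* for
the homozygous-only filter, not simulated). Passing recovery tests
therefore shows the pipeline is correct and well-calibrated under the stated
generative model, not that real panels are free of artifact-driven calls.

## Numerical and procedural choices

* VCF ingest keeps SNVs only; non-SNV and malformed records are skipped and
  counted. Half-calls (`./1`) are missing. Multiallelic records stay one
  site with ordered alternates. Sites sort lexicographically by
  (chrom, pos); the simulator zero-pads chromosome names accordingly.
* Codon effects use the standard genetic code (Biopython); start-loss is
  reported as nonsynonymous; minus-strand alleles are complemented before
  lookup, and classification is strand-invariant by property test.
* Gene density denominators merge the union of a gene's CDS intervals; a
  site in two genes' CDS counts for both; a site discordant in several
  clusters counts once per gene.
* Hotspots: bins tile each chromosome from 0; a non-empty bin is a hotspot
  when count ≥ mean + 2·SD (population SD) over the bins of chromosomes
  that carry ≥ 1 site. With few bins and a single loaded bin the threshold
  can exceed the maximum (mean + 2·SD > v needs ~n ≥ 6 bins); that is the
  intended behavior of a dispersion-based flag, not a defect. The Jaccard
  of two empty hotspot sets is defined as 0 (no evidence of sharing).
* Co-localization counts heterozygous calls either pooled over strains,
  from the most-heterozygous strain (library default, mirroring
  single-strain chromosome displays), or from a named strain. The bundled
  experiments use pooled counts: on a synthetic panel no strain is special,
  and pooling is the lower-variance estimator of the locus-level het
  density. Spearman ρ is computed over bins with either count positive and
  reported as NaN below 3 such bins.
* The pipeline writes TSV/newick/BED text with headers carrying the tool
  version, a SHA-256 prefix of the configuration and the seed; reruns with
  an identical configuration are byte-identical.

## Problem sizes used by the bundled experiments

Unit tests run on reduced panels (6 × 400 kb chromosomes, shortened
post-split history so the substrain/backbone separation keeps the same
relative margin as the full panel). The acceptance experiments use the full
default conditions: 100 random additive matrices (8–25 leaves), 200
brute-force distance pairs, 500 exhaustive parsimony cases, 10 null panels,
20 ancestral panels, 10 matched gene-flow panels, and 2×10⁵ loci for the
retention Monte-Carlo at t ∈ {10, 37, 100}. The whole suite completes in a
few minutes on one core.

## Known limitations

* The discordance predicate conditions on complete homozygous calls within
  a cluster; heavily missing data shrinks the evaluable site set rather
  than being imputed.
* Branch support from 20 chromosomes is coarse (5% steps) and, on short
  chromosomes with few mutations, individual chromosome trees can be
  unresolved or discordant — mirroring the instability real panels show on
  the shortest autosome.
* `propose_clusters`' distance threshold assumes substrain divergence well
  below backbone divergence; panels of uniformly diverged strains need an
  explicit threshold.
* The effect classifier is SNV-in-CDS only (no splice, UTR, or indel
  categories) by design.
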