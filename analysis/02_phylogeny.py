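#!/usr/bin/env python
"""Build the panel phylogeny and chromosome-level branch support.

Reads the panel VCF written by 01_simulate_panel.py, computes all pairwise
symmetric-difference distances, runs neighbor joining for the whole panel
and separately per chromosome, and scores each internal branch by the
fraction of chromosome trees containing the same split.  Substrain clusters
are expected to come out as clades with high support; the backbone between
unrelated strains has little shared signal and low support.
"""

import argparse
import os

from ancpoly.distance import distance_matrix
from ancpoly.genotypes import homozygous_variant_set, read_vcf
from ancpoly.nj import neighbor_joining
from ancpoly.pipeline import read_chrom_sizes
from ancpoly.simulate import load_truth
from ancpoly.tree import branch_support


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--panel", default="results/panel")
    parser.add_argument("--out", default="results")
    args = parser.parse_args()

    matrix = read_vcf(os.path.join(args.panel, "panel.vcf"))
    sizes = read_chrom_sizes(os.path.join(args.panel, "panel.chrom.sizes"))
    truth = load_truth(os.path.join(args.panel, "truth.json"))

    sets = [homozygous_variant_set(matrix, s) for s in matrix.strains]
    dmatrix = distance_matrix(sets)
    dmatrix.to_tsv(os.path.join(args.out, "distances.tsv"))

    tree = neighbor_joining(dmatrix)
    chrom_trees = [
        neighbor_joining(distance_matrix(sets, restrict_to=c)) for c in sizes
    ]
    support = branch_support(tree, chrom_trees)
    tree.write_newick(os.path.join(args.out, "tree.nwk"), support=support)
    os.makedirs(os.path.join(args.out, "chromosome_trees"), exist_ok=True)
    for chrom, ctree in zip(sizes, chrom_trees):
        ctree.write_newick(os.path.join(args.out, "chromosome_trees", f"{chrom}.nwk"))

    print(f"panel tree over {len(matrix.strains)} strains; "
          f"{len(chrom_trees)} chromosome trees")
    all_leaves = frozenset(matrix.strains)
    for name, members in sorted(truth["clusters"].items()):
        side = frozenset(members)
        split = frozenset({side, all_leaves - side})
        pct = support.percent.get(split)
        clade = "clade" if tree.is_clade(members) else "NOT a clade"
        print(f"cluster {name} ({','.join(members)}): {clade}, "
              f"support {pct if pct is not None else 0:.0f}%")


if __name__ == "__main__":
    main()
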