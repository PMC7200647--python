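#!/usr/bin/env python
"""Do discordant-site-rich regions still carry heterozygous variants?

Counts discordant sites and residual heterozygous calls per 1 Mb bin and
computes their Spearman rank correlation over non-empty bins.  A strong
positive correlation says the regions that fixed discordantly across strains
are the same regions where inbreeding has not yet driven heterozygosity out
-- the co-localization expected if both signals derive from balanced
ancestral polymorphism rather than gene flow.
"""

import argparse
import os

import pandas as pd

from ancpoly.discordance import ClusterSpec, call_discordant_sites, het_discordant_colocalization
from ancpoly.distance import distance_matrix
from ancpoly.genotypes import homozygous_variant_set, read_vcf
from ancpoly.nj import neighbor_joining
from ancpoly.pipeline import read_chrom_sizes
from ancpoly.simulate import load_truth


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--panel", default="results/panel")
    parser.add_argument("--out", default="results")
    parser.add_argument("--bin-size", type=int, default=1_000_000)
    parser.add_argument("--het-mode", default="pooled",
                        help="'pooled', 'max_strain', or a strain name")
    args = parser.parse_args()

    matrix = read_vcf(os.path.join(args.panel, "panel.vcf"))
    sizes = read_chrom_sizes(os.path.join(args.panel, "panel.chrom.sizes"))
    truth = load_truth(os.path.join(args.panel, "truth.json"))

    sets = [homozygous_variant_set(matrix, s) for s in matrix.strains]
    tree = neighbor_joining(distance_matrix(sets))
    union = pd.concat(
        [
            call_discordant_sites(matrix, tree, ClusterSpec(n, tuple(m)))
            for n, m in sorted(truth["clusters"].items())
        ],
        ignore_index=True,
    )

    bins, rho, used = het_discordant_colocalization(
        matrix, union, sizes, args.bin_size, het_mode=args.het_mode
    )
    bins.to_csv(os.path.join(args.out, "het_colocalization.tsv"), sep="\t", index=False)
    nonempty = bins[(bins["discordant_count"] > 0) | (bins["het_count"] > 0)]
    print(f"heterozygous calls counted: {used}")
    print(f"{len(nonempty)} non-empty bins of {len(bins)}")
    print(f"Spearman rho (discordant vs heterozygous per bin): {rho:.3f}")


if __name__ == "__main__":
    main()
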