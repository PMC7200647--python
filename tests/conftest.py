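import numpy as np
import pytest

from ancpoly.genotypes import GenotypeMatrix, Site


def build_matrix(strains, site_specs):
    """Construct a GenotypeMatrix from readable per-site call dicts.

    site_specs: list of (chrom, pos, ref, alts, calls) where calls maps
    strain -> ('hom', base) | ('het', (b1, b2)) | 'missing'; strains absent
    from calls are homozygous reference.
    """
    sites = []
    a1 = np.zeros((len(strains), len(site_specs)), dtype=np.int8)
    a2 = np.zeros_like(a1)
    for j, (chrom, pos, ref, alts, calls) in enumerate(site_specs):
        site = Site(chrom, pos, ref, tuple(alts))
        sites.append(site)
        alleles = list(site.alleles)
        for i, strain in enumerate(strains):
            call = calls.get(strain, ("hom", ref))
            if call == "missing":
                a1[i, j] = a2[i, j] = -1
            elif call[0] == "hom":
                a1[i, j] = a2[i, j] = alleles.index(call[1])
            else:
                x, y = sorted(alleles.index(b) for b in call[1])
                a1[i, j], a2[i, j] = x, y
    return GenotypeMatrix(list(strains), sites, a1, a2)


@pytest.fixture
def matrix_factory():
    return build_matrix


@pytest.fixture(scope="session")
def small_ancestral():
    """A reduced ancestral-scenario panel shared by file-free tests."""
    from ancpoly.simulate import default_config, simulate_panel

    config = default_config(
        "ancestral",
        seed=7,
        n_chromosomes=6,
        chromosome_length=400_000,
        genes_per_chromosome=8,
        n_ordinary_loci=3,
        locus_length=40_000,
        ordinary_blocks=2,
        mhc_block_length=10_000,
        # shorter post-split history than the study panel: the reduced genome
        # has ~600 mutations/strain, so the substrain/backbone distance
        # separation needs the relative divergence scaled down too
        generations_after_split=20,
    )
    panel = simulate_panel(config)
    return config, panel, panel.genotype_matrix()
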