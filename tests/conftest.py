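import numpy as np
import pytest

from snparray import synthetic_data
from snparray.variant_io import GeneModel, Genotype, SiteCall, Variant, VariantClass


@pytest.fixture(scope="session")
def small_cfg():
    return synthetic_data.SimConfig(
        seed=11,
        n_scaffolds=2,
        scaffold_length_bp=60_000,
        n_genes_per_scaffold=4,
        n_samples=48,
        maf_law=("uniform", 0.05, 0.5),
    )


@pytest.fixture(scope="session")
def small_world(small_cfg):
    """Genome + gene models + cohort variants for one small simulated study."""
    genome, genes = synthetic_data.simulate_genome(small_cfg)
    variants, truth = synthetic_data.simulate_population_vcf(genome, small_cfg)
    return genome, genes, variants, truth


def make_snp(
    scaffold="s1",
    pos=100,
    ref="A",
    alt="G",
    gts=(0, 1, 2),
    dp=30,
    gq=60,
):
    """A well-covered SNP with the given genotype vector."""
    gts = np.asarray(gts, dtype=np.int8)
    return Variant(
        scaffold,
        pos,
        ref,
        alt,
        VariantClass.SNP,
        gts,
        np.full(len(gts), dp, dtype=np.int32),
        np.full(len(gts), gq, dtype=np.int32),
    )


def make_call(gt=Genotype.HOM_REF, dp=30, gq=60):
    return SiteCall(gt, dp, gq)


@pytest.fixture
def plus_gene_genome():
    """A hand-built two-exon gene on the + strand with known codons.

    Scaffold layout (1-based):
      1..3000       upstream / intergenic
      3001..3060    exon 1 (CDS, starts ATG)
      3061..3200    intron (140 bp)
      3201..3260    exon 2 (CDS, ends TAA)
      3261..        downstream
    Coding sequence is ATG + (GAA)x18 + TGG + (GAA)x18 + TGG + TAA = 120 bp.
    """
    rng = np.random.default_rng(7)
    coding = "ATG" + "GAA" * 18 + "TGG" + "GAA" * 18 + "TGG" + "TAA"
    assert len(coding) == 120
    exon1, exon2 = coding[:60], coding[60:]
    intron = "GT" + "".join(rng.choice(list("ACGT"), 136)) + "AG"
    pre = "".join(rng.choice(list("ACGT"), 3000))
    post = "".join(rng.choice(list("ACGT"), 5000))
    seq = pre + exon1 + intron + exon2 + post
    gene = GeneModel(
        "g1",
        "chr",
        "+",
        exons=[(3001, 3060), (3201, 3260)],
        cds=[(3001, 3060, 0), (3201, 3260, 0)],
    )
    return {"chr": seq}, [gene]
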