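import pytest

from panguide.fixtures import FamilySpec, implant_family, simulate_genome


@pytest.fixture(scope="session")
def family_genome():
    """A 100 kb genome with a 3-member implanted family:
    reference + allele (0.5% synonymous divergence) + copy (5% divergence)."""
    genome = simulate_genome(100_000, gc=0.5, seed=7)
    spec = FamilySpec(
        n_members=3,
        member_divergence=(0.0, 0.005, 0.05),
        allele_of={"m2": "m1"},
        gene_len=1500,
        n_exons=2,
        snp_rate=0.01,
        seed=3,
    )
    genome, truth = implant_family(genome, spec)
    return genome, truth


@pytest.fixture(scope="session")
def truth_dir(family_genome, tmp_path_factory):
    """The same family written to FASTA/GFF3/VCF/BED on disk."""
    from panguide.fixtures import emit_truth

    genome, truth = family_genome
    outdir = tmp_path_factory.mktemp("truth")
    paths = emit_truth(truth, genome, outdir)
    return paths, genome, truth
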