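import pytest

from kaspanel.simulate import ReferenceModel, simulate_cohort_vcf, simulate_reference, write_fasta


@pytest.fixture(scope="session")
def reference():
    """Two-chromosome synthetic reference (200 kb + 150 kb)."""
    model = ReferenceModel({"Chr01": 200_000, "Chr02": 150_000}, gc_fraction=0.41, seed=1)
    return simulate_reference(model)


@pytest.fixture(scope="session")
def cohort(reference):
    """Clean 12-sample cohort at ~1 variant per 2 kb."""
    return simulate_cohort_vcf(reference, n_samples=12, snp_density=1 / 2000, seed=7)


@pytest.fixture(scope="session")
def reference_fasta(reference, tmp_path_factory):
    path = tmp_path_factory.mktemp("ref") / "reference.fa"
    write_fasta(reference, path)
    return path
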