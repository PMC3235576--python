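import pytest
from hypothesis import settings

from metacred import StudyCounts

# reproducible property tests: no random example generation across runs
settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


def make_counts(a, b, c, d, *, gene="G1", snp="rs1", study_id="s1",
                population="Caucasian", year=2000, genotypes=None):
    """2x2 allele table (a=case minor, b=case major, c=control minor,
    d=control major), optionally with a consistent genotype block."""
    kwargs = {}
    if genotypes is not None:
        (kwargs["case_hom_minor"], kwargs["case_het"], kwargs["case_hom_major"],
         kwargs["control_hom_minor"], kwargs["control_het"],
         kwargs["control_hom_major"]) = genotypes
    return StudyCounts(
        gene=gene, snp=snp, study_id=study_id, population=population, year=year,
        case_minor=a, case_major=b, control_minor=c, control_major=d, **kwargs,
    )


@pytest.fixture
def counts_factory():
    return make_counts
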