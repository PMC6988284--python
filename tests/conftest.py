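import numpy as np
import pytest

from cnvpop.regions import build_cnvrs, genotype_all_biallelic
from cnvpop.simulate import CohortConfig, SyntheticCohort, emit_calls, generate_cohort


SMALL = dict(
    n_pop1=60,
    n_pop2=40,
    n_chroms=2,
    chrom_length=5_000_000,
    n_cnv_loci=30,
    n_diverged_loci=2,
    seed=7,
)


@pytest.fixture(scope="session")
def small_cohort() -> SyntheticCohort:
    """A small two-population cohort with the default error model."""
    return generate_cohort(CohortConfig(**SMALL))


@pytest.fixture(scope="session")
def clean_cohort() -> SyntheticCohort:
    """Same cohort geometry with a zero-error call model (no jitter, no FPs)."""
    return generate_cohort(
        CohortConfig(**{**SMALL, "fp_singleton_rate": 0.0, "boundary_jitter_sd": 0.0})
    )


@pytest.fixture(scope="session")
def clean_calls(clean_cohort):
    return emit_calls(clean_cohort.truth, clean_cohort.config, lrr=clean_cohort.lrr)


@pytest.fixture(scope="session")
def clean_cnvrs(clean_calls):
    return build_cnvrs(clean_calls)


@pytest.fixture(scope="session")
def clean_genotypes(clean_cohort, clean_cnvrs):
    return genotype_all_biallelic(clean_cnvrs, clean_cohort.truth.sample_ids)


@pytest.fixture(scope="session")
def study_cohort() -> SyntheticCohort:
    """Study-scale cohort at the default conditions (315 + 107 samples)."""
    return generate_cohort(CohortConfig(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
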