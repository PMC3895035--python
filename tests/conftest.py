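import dataclasses

import numpy as np
import pytest

from azapd import (
    AcetazolamidePD,
    Covariates,
    IndividualParameters,
    SaemConfig,
    default_population,
    generate_cohort,
    study_design,
)


@pytest.fixture(scope="session")
def published():
    """Published population estimates (the generating truth throughout)."""
    return default_population()


@pytest.fixture(scope="session")
def reference_individual(published):
    """A median subject: population values, no random effects."""
    fx = published.fixed
    return IndividualParameters(
        bicar0_i=fx.bicar0_pop, kout_i=fx.kout, mv0_i=fx.mv0_pop,
        paco2_0_i=fx.paco2_0_pop, pow_mv_paco2_i=fx.pow_mv_paco2)


@pytest.fixture(scope="session")
def median_covariates():
    return Covariates()


@pytest.fixture(scope="session")
def study_cohort(published):
    """One study-design synthetic cohort (n=68), fixed seed."""
    return generate_cohort(published, study_design(seed=1))


@pytest.fixture(scope="session")
def study_fit(published, study_cohort):
    """SAEM fit of the study-design cohort, initialised at the published
    values, fixed seeds; shared by the recovery and diagnostic tests."""
    model = AcetazolamidePD(study_cohort, init=published)
    return model.fit(SaemConfig(seed=4))


def small_noise_population():
    """Truth with no between-subject variability and 1% residual noise."""
    base = default_population()
    return dataclasses.replace(
        base,
        random=dataclasses.replace(
            base.random, omega_bicar0=0.0, omega_kout=0.0, omega_mv0=0.0,
            omega_paco2_0=0.0, omega_pow_mv_paco2=0.0),
        residual=dataclasses.replace(
            base.residual, sigma_bicar=0.01, sigma_mv=0.01, sigma_paco2=0.01),
    )


def assert_close(actual, expected, rtol, label=""):
    actual, expected = float(actual), float(expected)
    rel = abs(actual - expected) / abs(expected)
    assert rel <= rtol, (
        f"{label}: {actual:.6g} vs expected {expected:.6g} "
        f"(rel {rel:.3%} > {rtol:.3%})")
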