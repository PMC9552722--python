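import numpy as np
import pytest

from tsmr import HarmonizedVariant, harmonize, load_fixture


@pytest.fixture(scope="session")
def exposure_set():
    return load_fixture("pyroglutamine_exposure")


@pytest.fixture(scope="session")
def outcome_set():
    return load_fixture("covid19_outcome")


@pytest.fixture(scope="session")
def fixture_variants(exposure_set, outcome_set):
    """The four harmonized pyroglutamine -> COVID-19 instrument pairs."""
    return harmonize(exposure_set, outcome_set).variants


def make_variant(
    snp_id="rs1",
    beta_exp=0.05,
    se_exp=0.004,
    beta_out=-0.03,
    se_out=0.013,
    effect_allele="A",
    other_allele="G",
    **kwargs,
):
    return HarmonizedVariant(
        snp_id=snp_id,
        effect_allele=effect_allele,
        other_allele=other_allele,
        beta_exp=beta_exp,
        se_exp=se_exp,
        beta_out=beta_out,
        se_out=se_out,
        **kwargs,
    )


def random_variants(rng: np.random.Generator, n: int) -> list:
    """Random harmonized variants in a realistic summary-stat scale."""
    return [
        make_variant(
            snp_id=f"rs{i}",
            beta_exp=float(rng.uniform(0.02, 0.08) * rng.choice([-1, 1])),
            se_exp=float(rng.uniform(0.002, 0.008)),
            beta_out=float(rng.normal(0.0, 0.05)),
            se_out=float(rng.uniform(0.008, 0.03)),
        )
        for i in range(n)
    ]
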