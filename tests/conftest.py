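import numpy as np
import pytest

from panelprs.model import ArrayStatus, PrsModel, VariantDefinition
from panelprs.simulate import SimulationConfig, simulate_study


@pytest.fixture
def toy_model() -> PrsModel:
    """Three variants: ALT-effect SNV, REF-effect SNV, ALT-effect deletion."""
    return PrsModel(
        name="toy",
        variants=(
            VariantDefinition("1:100:A:C", "1", 100, "A", "C", "C", 0.5),
            VariantDefinition("1:200:G:T", "1", 200, "G", "T", "G", -0.2),
            VariantDefinition(
                "2:400:TA:T", "2", 400, "TA", "T", "T", 0.1,
                array_status=ArrayStatus.IMPUTED,
            ),
        ),
    )


SMALL_CONFIG = SimulationConfig(
    n_samples=60,
    n_variants=50,
    n_genotyped=20,
    n_indels=8,
    n_proxies=8,
    n_negative=2,
    n_dead=1,
    n_low_depth=4,
    seed=7,
)

ZERO_ERROR_CONFIG = SimulationConfig(
    n_samples=80,
    n_variants=40,
    n_genotyped=15,
    n_indels=5,
    n_proxies=6,
    n_negative=2,
    n_dead=0,
    n_low_depth=0,
    proxy_r2_range=(1.0, 1.0),
    array_error_genotyped=0.0,
    array_error_imputed=0.0,
    per_read_error=0.0,
    low_complexity_call_error=0.0,
    dropout_depth=0,
    seed=11,
)


@pytest.fixture(scope="session")
def small_study():
    """A small but fully featured simulated study (errors, proxies, dropout)."""
    return simulate_study(SMALL_CONFIG)


@pytest.fixture(scope="session")
def zero_error_study():
    """A study in which every observation process is error-free."""
    return simulate_study(ZERO_ERROR_CONFIG)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
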