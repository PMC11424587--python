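import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tsameta import GridConfig, ScenarioConfig, simulate_literature

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_grid() -> GridConfig:
    """Coarser recursion grid for tests where speed matters more than the
    last digit of the boundary."""
    return GridConfig(nodes=801)


@pytest.fixture(scope="session")
def effect_literature() -> list:
    """Six-study literature with a strong minor-allele risk effect."""
    cfg = ScenarioConfig(
        snp_label="rs_eff", ethnicity="Asian", control_maf=0.3, true_or=1.8,
        tau=0.0, n_studies=6, case_sizes=[400] * 6, control_sizes=[400] * 6,
        start_year=2001, seed=101,
    )
    return simulate_literature(cfg)


@pytest.fixture(scope="session")
def null_literature() -> list:
    """Eight-study literature with no true effect."""
    cfg = ScenarioConfig(
        snp_label="rs_null", ethnicity="Caucasian", control_maf=0.25, true_or=1.0,
        tau=0.0, n_studies=8, case_sizes=[150] * 8, control_sizes=[150] * 8,
        start_year=1998, seed=202,
    )
    return simulate_literature(cfg)
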