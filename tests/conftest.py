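import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from sfsi.indices import compute_sfsi_table
from sfsi.synthetic_trial import SimConfig
from sfsi.trial_io import load_reference_means, load_reference_table

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tuber_means():
    return load_reference_means("tuber_yield")


@pytest.fixture(scope="session")
def shoot_means():
    return load_reference_means("shoot_dry_weight")


@pytest.fixture(scope="session")
def tuber_table():
    return load_reference_table("tuber_yield")


@pytest.fixture(scope="session")
def shoot_table():
    return load_reference_table("shoot_dry_weight")


@pytest.fixture(scope="session")
def tuber_index(tuber_means):
    return compute_sfsi_table(tuber_means)


@pytest.fixture(scope="session")
def shoot_index(shoot_means):
    return compute_sfsi_table(shoot_means)


def make_sim_config(n_genotypes=6, hf_mean=1000.0, reduction=0.4, **overrides) -> SimConfig:
    """Small homogeneous-truth simulation config used across test modules."""
    hf = {f"G{i:02d}": hf_mean for i in range(n_genotypes)}
    frac = {g: reduction for g in hf}
    base = dict(
        genotype_hf_means=hf,
        reduction_fractions=frac,
        year_effects=(0.0,) * 2,
        year_by_treatment_effects=(0.0,) * 2,
        replicate_sd=0.0,
        mainplot_sd=0.0,
        residual_sd=50.0,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture
def small_means_table():
    df = pd.DataFrame(
        {
            "genotype": ["A", "B", "C"],
            "x_lf": [800.0, 600.0, 500.0],
            "x_hf": [1000.0, 1000.0, 1000.0],
            "n_lf": [4, 4, 4],
            "n_hf": [4, 4, 4],
        }
    )
    from sfsi.trial_io import GenotypeMeansTable

    return GenotypeMeansTable(trait="trait", data=df)
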