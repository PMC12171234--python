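import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from txmeta.synthdata import CohortConfig, StudyConfig, generate_cohort

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_cohort():
    """Default five-study cohort at a reduced gene count."""
    return generate_cohort(CohortConfig(n_genes=600, seed=7))


@pytest.fixture(scope="session")
def single_study_config():
    """One 10-sample intensity study with one injected outlier."""
    def make(seed, n_outliers=1, shift=0.3, n_genes=400):
        cfg = CohortConfig(
            studies=(
                StudyConfig(
                    "S1", "intensity", "mouse", 5, 5,
                    n_outliers=n_outliers, outlier_shift=shift,
                ),
            ),
            n_genes=n_genes,
            effect_fraction=0.0,
            missing_fraction_per_study=0.0,
            seed=seed,
        )
        return generate_cohort(cfg)
    return make


@pytest.fixture()
def toy_metadata():
    return pd.DataFrame(
        {
            "treatment": ["reference", "reference", "ELS", "ELS"],
            "sex": ["F", "M", "F", "M"],
            "batch": ["b1", "b1", "b2", "b2"],
            "library_size": [10_000_000, 12_000_000, 9_000_000, 11_000_000],
            "organism_part": ["PFC"] * 4,
        },
        index=pd.Index(["s1", "s2", "s3", "s4"], name="sample_id"),
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(123)
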