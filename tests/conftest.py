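import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from lncsig import SimConfig, generate_cohort

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def separable_cohort():
    """Strong planted signal: every downstream stage should succeed cleanly."""
    return generate_cohort(
        SimConfig(
            n_samples=120,
            n_lnc=300,
            n_informative=20,
            effect_size=3.0,
            n_mrna=400,
            n_coexpressed_per_marker=3,
            censor_rate=0.3,
            missing_clinical_rate=0.0,
            seed=11,
        )
    )


@pytest.fixture(scope="session")
def null_cohort():
    """No subtype signal anywhere: expression exchangeable, hazards equal."""
    return generate_cohort(
        SimConfig(
            n_samples=120,
            n_lnc=500,
            n_informative=0,
            effect_size=0.0,
            hazard_ratio_abc=1.0,
            pfs_hazard_mult=1.0,
            n_mrna=0,
            n_coexpressed_per_marker=0,
            censor_rate=0.2,
            missing_clinical_rate=0.0,
            seed=5,
        )
    )


@pytest.fixture()
def tiny_matrix():
    return pd.DataFrame(
        np.array([[1.0, 2.0, 3.0, 4.0], [4.0, 3.0, 2.0, 1.0], [0.5, 0.5, 1.5, 1.5]]),
        index=["g1", "g2", "g3"],
        columns=["s1", "s2", "s3", "s4"],
    )
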