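import numpy as np
import pytest

from habitatdyn import (
    VARIANTS,
    ModelParams,
    default_cohort_config,
    fit,
    generate_cohort,
)


@pytest.fixture(scope="session")
def control_cohort():
    """8 control subjects, 7 visits spaced 1.5 days, 5% observation noise."""
    cfg = default_cohort_config("control", seed=20)
    return generate_cohort(cfg, VARIANTS["D"])


@pytest.fixture(scope="session")
def noiseless_series():
    """One noiseless variant-D series with ground truth attached."""
    cfg = default_cohort_config("control", n_subjects=1, noise_cv=0.0, seed=11)
    return generate_cohort(cfg, VARIANTS["D"])[0]


@pytest.fixture(scope="session")
def calibrated_control(control_cohort):
    """Variant-D calibrations of the control cohort (reduced multistart).

    20 starts suffice here; the full 50-start protocol runs in the
    acceptance suite.
    """
    seeds = np.random.SeedSequence(77).spawn(len(control_cohort))
    return [
        fit(VARIANTS["D"], s, n_starts=20, seed=ss)
        for s, ss in zip(control_cohort, seeds)
    ]


@pytest.fixture
def example_params():
    return ModelParams(k1=1.0, k2=0.5, d12=0.2, d21=0.0, d13=0.0,
                       d23=0.1, theta=100.0)
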