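import numpy as np
import pytest

import mibgquant as mq


@pytest.fixture(scope="session")
def registry():
    return mq.default_collimators()


@pytest.fixture(scope="session")
def cohort():
    """One default 62-patient cohort, fixed seed."""
    return mq.simulate_cohort(seed=42)


@pytest.fixture(scope="session")
def noiseless_cohort():
    return mq.simulate_cohort(mq.CohortModel(count_noise=False, seed=42))


@pytest.fixture(scope="session")
def analysis_cohort(cohort):
    """Standardized cohort with washout columns, ready for the stats layer."""
    return mq.add_washout_columns(mq.standardize_cohort(cohort))


@pytest.fixture()
def layout():
    return mq.PhantomLayout()


def disc_image(center=(128, 100), radius=8.0, value=50.0, background=0.0, minute=15.0):
    """Uniform disc on constant background; the centroid oracle is the
    disc center by symmetry."""
    grid = np.full((256, 256), background)
    rr, cc = np.ogrid[:256, :256]
    grid[(rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2] = value
    return mq.PlanarImage(grid, minute)
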