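import numpy as np
import pytest

import profilespace as ps


@pytest.fixture(scope="session")
def small_geom():
    """1000-vertex, 60-parcel two-hemisphere sphere."""
    return ps.make_sphere_parcellation(1000, 60, seed=1)


@pytest.fixture(scope="session")
def small_cohort():
    return ps.simulate_cohort(120, 100, oc_fraction=0.4,
                              missing_cycle_fraction=0.1, seed=2)


@pytest.fixture(scope="session")
def null_profiles(small_geom, small_cohort):
    eff = ps.GroundTruthEffects.null(small_geom.n_parcels)
    return ps.simulate_profiles(small_geom, small_cohort, eff, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
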