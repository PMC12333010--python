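import numpy as np
import pytest

from thcpd import (
    OH_THC,
    THC,
    TrialDesign,
    default_pk_fixture,
    default_sampling_grid,
    simulate_pk,
    single_dose_regimen,
)


@pytest.fixture(scope="session")
def pk_spec():
    return default_pk_fixture()


@pytest.fixture(scope="session")
def compounds():
    return (THC, OH_THC)


@pytest.fixture(scope="session")
def grid_12h():
    return default_sampling_grid(12.0, 0.05)


@pytest.fixture(scope="session")
def inhaled_conc(pk_spec, compounds, grid_12h):
    """10 mg inhaled THC on a 12 h grid."""
    return simulate_pk(pk_spec, compounds, single_dose_regimen(10.0, "inhaled"),
                       grid_12h)


@pytest.fixture(scope="session")
def oral_conc(pk_spec, compounds, grid_12h):
    """20 mg oral THC on a 12 h grid."""
    return simulate_pk(pk_spec, compounds, single_dose_regimen(20.0, "oral"),
                       grid_12h)


@pytest.fixture
def small_design(grid_12h):
    """A trimmed trial design for fast population tests."""
    return TrialDesign(
        regimen=single_dose_regimen(10.0, "inhaled"),
        sampling_times=grid_12h,
        n_trials=4,
        n_subjects_per_trial=25,
        seed=20240901,
    )


def zero_conc(times):
    from thcpd import ConcSeries

    z = np.zeros_like(np.asarray(times, dtype=float))
    return ConcSeries(times=times, plasma={"THC": z, "11-OH-THC": z.copy()},
                      brain={"THC": z.copy(), "11-OH-THC": z.copy()})


def constant_brain_conc(times, thc=0.0, oh=0.0):
    from thcpd import ConcSeries

    times = np.asarray(times, dtype=float)
    z = np.zeros_like(times)
    return ConcSeries(
        times=times,
        plasma={"THC": z, "11-OH-THC": z.copy()},
        brain={"THC": np.full_like(times, thc), "11-OH-THC": np.full_like(times, oh)},
    )
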