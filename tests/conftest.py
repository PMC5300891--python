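import numpy as np
import pytest

from loopbind import (
    IntegratorSettings,
    MixtureConditions,
    zipcode_defaults,
)


@pytest.fixture(scope="session")
def ref_params():
    return zipcode_defaults()[0]


@pytest.fixture(scope="session")
def ref_conditions():
    return zipcode_defaults()[1]


@pytest.fixture(scope="session")
def base_equilibrium(ref_params, ref_conditions):
    """RK4 equilibrium of the reference system, shared across tests."""
    from loopbind import run_to_equilibrium

    return run_to_equilibrium(ref_params, ref_conditions)


def random_consistent_params(rng: np.random.Generator, base):
    """Rates log-uniform within 10x of the reference, cycle kept consistent."""
    mult = lambda: 10.0 ** rng.uniform(-1.0, 1.0)
    kon3 = base.kon3 * mult()
    koff3 = base.koff3 * mult()
    kon4 = base.kon4 * mult()
    koff4 = base.koff4 * mult()
    kC3 = base.kC3 * mult()
    kC4 = kC3 * kon4 / kon3  # detailed balance around the cycle
    return base.replace(kon3=kon3, koff3=koff3, kon4=kon4, koff4=koff4,
                        kC3=kC3, kC4=kC4)


def settings_for(params, conditions, t_end=2.0e4, tol=1e-9):
    """Integrator settings with the step scaled to the fastest local rate."""
    from loopbind.simulate import _rate_vector
    from loopbind import _core
    from loopbind.model import SpeciesState

    y0 = SpeciesState.all_free(conditions).as_array()
    lam = _core.max_loss_rate(y0, _rate_vector(params))
    dt = min(0.01, 0.2 / max(lam, 1e-12))
    return IntegratorSettings(dt=dt, t_end=t_end, equilibrium_tol=tol,
                              store_every=50)
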