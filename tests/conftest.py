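import pytest

from transpososim.kinetic_models import (
    KineticModel,
    MECHANISMS,
    default_rates,
    wt_substrate,
)
from transpososim.simulator import DEFAULT_T_GRID, solve_master


@pytest.fixture(scope="session")
def rates():
    return default_rates()


@pytest.fixture(scope="session")
def wt_sub():
    return wt_substrate()


@pytest.fixture(scope="session")
def models(rates, wt_sub):
    """Wild-type KineticModel for each mechanism (k_trans zeroed where unused)."""
    out = {}
    for kind, mech in MECHANISMS.items():
        r = rates if kind == "constrained" else rates.with_updates(k_trans=0.0)
        out[kind] = KineticModel(mech, r, wt_sub)
    return out


@pytest.fixture(scope="session")
def timecourses(models):
    return {kind: solve_master(m, DEFAULT_T_GRID) for kind, m in models.items()}
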