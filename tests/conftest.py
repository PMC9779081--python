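import numpy as np
import pytest

from immunopk.data_tables import blood_pk_params, load_blood_pk_table
from immunopk.sixcomp import assemble_params
from immunopk.uptake import load_bundled_rate_tables


@pytest.fixture(scope="session")
def blood_table():
    return load_blood_pk_table()


@pytest.fixture(scope="session")
def rate_table():
    return load_bundled_rate_tables()


@pytest.fixture(scope="session", params=[20, 30, 100])
def particle_params(request):
    """Two-compartment parameters for each bundled particle size."""
    return blood_pk_params(request.param)


@pytest.fixture(scope="session")
def headline_params(rate_table):
    """The 100-nm BNF-Plain in vivo parameter set (y=0.05%, k=40)."""
    return assemble_params(blood_pk_params(100), rate_table, "BNF-Plain")


def random_sixcomp_params(rng: np.random.Generator):
    """A random nonnegative six-compartment parameter draw for property tests."""
    from immunopk.sixcomp import SixCompartmentParams

    return SixCompartmentParams(
        K_el=rng.uniform(0, 1),
        K_bp=rng.uniform(0, 20),
        K_pb=rng.uniform(0, 10),
        K_bt=rng.uniform(0, 0.05),
        K_tb=rng.uniform(0, 0.05),
        K_bm=rng.uniform(0, 0.01),
        K_mb=rng.uniform(0, 0.2),
        K_pm=rng.uniform(0, 0.01),
        K_mp=rng.uniform(0, 0.2),
        K_tm=rng.uniform(0, 0.01),
        K_mt=rng.uniform(0, 0.2),
        k_b=rng.uniform(0, 60),
        k_p=rng.uniform(0, 60),
        k_t=rng.uniform(0, 60),
        X0=100.0,
    )
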