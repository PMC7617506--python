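import numpy as np
import pytest

from teatk.kinetics import TKParams
from teatk.trial import gen_trial


@pytest.fixture(scope="session")
def pop_params() -> TKParams:
    """Population geometric means used as a reference parameter set."""
    return TKParams(cl_tot=1.58, vd=4.35, vd_met=7.36, cl_met=33.7,
                    k_gutabs=23.9, k_ufrac=0.212, f_gluc=0.098)


@pytest.fixture(scope="session")
def default_trial():
    """Default 10-subject synthetic trial (shared across tests)."""
    return gen_trial(seed=42)


@pytest.fixture(scope="session")
def default_fit(default_trial):
    """Reduced-scale reference fit of the default trial (shared).

    4 chains x 8000 iterations (half burn-in) — the package's default
    test scale for convergence and recovery checks.
    """
    from teatk.model import PopTKModel

    return PopTKModel(default_trial).fit(n_chains=4, n_iter=8000, seed=7)


@pytest.fixture(scope="session")
def small_trial():
    """Reduced trial (3 subjects, sparse sampling) for fast MCMC tests."""
    return gen_trial(
        n_subjects=3,
        blood_times=np.array([0.25, 1.0, 2.0, 4.0, 8.0, 24.0]),
        void_edges=np.array([0.0, 3.0, 8.0, 24.0, 48.0]),
        seed=7,
    )


def random_params(rng: np.random.Generator) -> TKParams:
    """Draw a parameter vector spanning the diffuse prior ranges."""
    def ln(gm, gsd):
        return gm * np.exp(np.log(gsd) * rng.standard_normal())

    return TKParams(
        cl_tot=ln(1.0, 3.0),
        vd=ln(2.0, 3.0),
        vd_met=ln(3.0, 3.0),
        cl_met=ln(10.0, 3.0),
        k_gutabs=ln(8.0, 3.0),
        k_ufrac=min(ln(0.3, 2.0), 1.0),
        f_gluc=min(ln(0.2, 2.0), 1.0),
    )
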