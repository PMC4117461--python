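"""Shared fixtures: the reference parameter set and cached integrations.

Trajectory fixtures are module-scoped where reuse across tests is safe (the
Trajectory dataclass is frozen and arrays are never mutated in tests).
"""

import numpy as np
import pytest

import cofluct as cf


@pytest.fixture(scope="session")
def fig2():
    """Reference constants with the swept p at its printed value 1.0253."""
    return cf.fig2_parameters()


@pytest.fixture(scope="session")
def fig2_ss(fig2):
    return cf.steady_state(fig2)


@pytest.fixture(scope="session")
def fast_settings():
    """Horizon sufficient for the [50, 1000] analysis window."""
    return cf.SolverSettings(t_end=2000.0)


@pytest.fixture(scope="session")
def traj_p1(fig2, fast_settings):
    """One oscillatory reference run (p = 1.0, above the oscillation onset)."""
    return cf.integrate(fig2.with_p(1.0), settings=fast_settings)


@pytest.fixture(scope="session")
def frame(fig2):
    return cf.eigen_transform(cf.matrix_at_critical(fig2))


@pytest.fixture(scope="session")
def reduced(fig2, frame):
    a = cf.eliminate_u(fig2, frame)
    return cf.reduced_equation(fig2, frame, a)


def random_valid_params(rng: np.random.Generator) -> cf.ModelParameters:
    """A random parameter set satisfying every model invariant."""
    D1 = rng.uniform(0.1, 1.0)
    D4 = rng.uniform(50.0, 300.0)
    D5 = rng.uniform(50.0, 300.0)
    k2 = rng.uniform(1e-4, 1e-3)
    coeffs = rng.uniform(0.0, 900.0, size=6)
    R = rng.uniform(0.5, 2.0)
    # p above the Z_s positivity bound by a comfortable random margin
    p = (D5 * k2 / D1) * rng.uniform(1.5, 6.0)
    return cf.ModelParameters(D1=D1, D4=D4, D5=D5, k2=k2,
                              a=coeffs[0], b=coeffs[1], c=coeffs[2],
                              d=coeffs[3], e=coeffs[4], f=coeffs[5],
                              p=p, R=R).validate()
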