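import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

import spotanno as sa  # noqa: E402


@pytest.fixture(scope="session")
def small_scenario():
    """A 12x12 lattice, 3 types, well-separated Gaussian-model data."""
    cfg = sa.ScenarioConfig(nx=12, ny=12, K=3, m_per_type=3, p=40,
                            q_true=4, effect=1.5, xi_true=1.0)
    sd = sa.make_scenario("full_types", cfg, seed=7)["full_types"]
    bundle, markers = sa.scenario_bundle(sd)
    return sd, bundle, markers


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_params(rng, m=3, K_eff=2, p=6, q=2, with_marker_structure=True):
    """Random valid ModelParams for kernel tests."""
    rho = (rng.random((m, K_eff)) < 0.5).astype(int)
    rho[0, 0] = 1  # ensure at least one marker
    beta = np.abs(rng.standard_normal((m, K_eff))) * rho
    A = rng.standard_normal((q, q))
    V = A @ A.T + q * np.eye(q)
    return sa.ModelParams(
        alpha=rng.standard_normal(m),
        beta=beta,
        sigma2=rng.uniform(0.5, 2.0, m),
        L=rng.standard_normal((p, q)),
        Lambda=rng.uniform(0.5, 2.0, p),
        mk=rng.standard_normal((K_eff, q)),
        V=V,
        xi=0.5,
        rho=rho,
    )
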