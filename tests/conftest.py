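import numpy as np
import pytest

import braincrit as bc


@pytest.fixture(scope="session")
def conn78() -> bc.Connectome:
    """Hub-heterogeneous 78-node connectome, the model's structural substrate."""
    return bc.generate_connectome(n_nodes=78, density=0.15, hub_fraction=0.15, seed=1)


@pytest.fixture(scope="session")
def conn20() -> bc.Connectome:
    """Small network for integration-accuracy checks."""
    return bc.generate_connectome(n_nodes=20, density=0.3, hub_fraction=0.2, seed=2)


@pytest.fixture(scope="session")
def critical_sweep(conn78) -> dict:
    """Reduced coupling sweep at lambda = 0.6 spanning the synchronization transition.

    20 coupling values at the canonical 0.02 resolution, 5 frequency seeds,
    30 s of analyzed dynamics per run. The PCF maximum over K locates the
    critical coupling; per-window R/chi/SMI/S^amp are pooled over seeds per
    cell. Shared session-wide because it is by far the most expensive
    computation in the suite.
    """
    params = bc.StuartLandauParams(lam=0.6, t_saturate=15.0, t_analyze=30.0)
    return bc.run_model_experiment(
        conn78,
        lam_grid=np.array([0.6]),
        K_grid=np.linspace(0.02, 0.40, 20),
        n_seeds=5,
        params=params,
        cfg=bc.RunConfig(seed=0),
    )
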