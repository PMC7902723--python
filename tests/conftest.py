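import numpy as np
import pytest

from glvfluct import (
    Community,
    InteractionMatrix,
    ModulationSpec,
    PanelSpec,
    PHDriver,
    PHGrid,
    PHResponse,
    SimulationConfig,
    Strain,
    default_grid,
    generate_base_panel,
)
from glvfluct.assembly import build_stable_ensemble


def make_flat_response(r: float, K: float, grid: PHGrid | None = None) -> PHResponse:
    """pH-independent response (constant r and K across the grid)."""
    g = grid or default_grid()
    return PHResponse(g, np.full(len(g), r), np.full(len(g), K))


def make_community(params, c, s0=1e-4, grid=None):
    """Community from [(r, K), ...] plus an interaction matrix."""
    strains = [
        Strain(f"s{i}", f"sp{i}", make_flat_response(r, K, grid))
        for i, (r, K) in enumerate(params)
    ]
    c = np.asarray(c, dtype=float)
    return Community(
        strains,
        np.full(len(strains), s0),
        InteractionMatrix(c, labels=[s.id for s in strains]),
    )


@pytest.fixture(scope="session")
def config():
    return SimulationConfig(seed=0)


@pytest.fixture(scope="session")
def panel():
    return generate_base_panel(PanelSpec(seed=1))


@pytest.fixture(scope="session")
def mod_spec():
    return ModulationSpec(f_p=0.2)


@pytest.fixture(scope="session")
def small_ensemble(panel, config, mod_spec):
    """Ten robust stable communities, shared across tests."""
    ensemble, _ = build_stable_ensemble(
        panel, 10, config, mod_spec, master_seed=42
    )
    return ensemble


@pytest.fixture
def sinusoid_driver(config):
    return PHDriver.sinusoid(config.p0, 0.5, 0.2, clamp_lo=config.ph_min,
                             clamp_hi=config.ph_max)
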