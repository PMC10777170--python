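"""Shared fixtures: small deterministic simulations reused across tests."""

from __future__ import annotations

import numpy as np
import pytest

import pradstack as pr
from pradstack.ddb import ImageGrid, filter_events, reconstruct_stack
from pradstack.focus import focus_stack
from pradstack.paths import fit_spline


@pytest.fixture(scope="session")
def cube_phantom() -> pr.RspVolume:
    return pr.build_cube_phantom()


@pytest.fixture(scope="session")
def straight_water_ps() -> pr.PhaseSpace:
    """Deterministic parallel-beam water-only acquisition (no cubes hit):
    scattering and straggling disabled, slopes zero."""
    phantom = pr.RspVolume(np.ones((100, 80, 80), dtype=np.float32),
                           (2.0, 2.0, 2.0), (0.0, -80.0, -80.0))
    beam = pr.BeamConfig(n_primaries=2000, spot_sigma=1.0,
                         divergence_sigma=0.0, spot_spacing=5.0,
                         field_size=(60.0, 60.0), rng_seed=7)
    cfg = pr.TransportConfig(straggling_enabled=False,
                             scattering_enabled=False, rng_seed=7)
    return pr.transport(phantom, beam, cfg)


@pytest.fixture(scope="session")
def medium_run():
    """Shared full-physics cube-phantom acquisition (10^6 primaries) with its
    DDB stack and focus-stacked result.

    The synthetic nuclear-outlier channel is off here so that tests of the
    focus-stacking operator itself (WET accuracy, noise amplification,
    resolution dominance) see pure MCS + straggling statistics; the outlier
    channel and its 3-sigma removal are exercised by dedicated tests.
    """
    phantom = pr.build_cube_phantom()
    beam = pr.BeamConfig(n_primaries=1_000_000, rng_seed=5)
    cfg = pr.TransportConfig(outlier_fraction=0.0, rng_seed=5)
    ps = pr.transport(phantom, beam, cfg)
    kept = filter_events(ps)
    paths = fit_spline(kept)
    grid = ImageGrid()
    stack = reconstruct_stack(kept, paths, grid)
    result = focus_stack(stack)
    return {"ps": ps, "kept": kept, "paths": paths, "grid": grid,
            "stack": stack, "result": result}
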