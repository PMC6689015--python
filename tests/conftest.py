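import logging

import numpy as np
import pytest

from cine5d import (PhantomConfig, circus_schedule, make_phantom,
                    simulate_acquisition)
from cine5d.benchmarks import _n_interleaves_for_coverage

logging.getLogger("cine5d").setLevel(logging.ERROR)


def tiny_config(**overrides) -> PhantomConfig:
    """16^3 single-coil phantom used by DFT-oracle style tests."""
    defaults = dict(
        matrix_size=(16, 16, 16), fov_mm=(160.0, 160.0, 160.0), n_coils=1,
        resp_depth_mm=0.0, rsa_amplitude=0.0, noise_sigma=0.0,
        chest_wall_x_mm=60.0, body_radii_mm=(70.0, 70.0),
        lv_radii_ed=(30.0, 30.0, 40.0), lv_radii_es=(24.0, 24.0, 32.0),
        rv_radii_ed=(45.0, 36.0, 36.0), rv_radii_es=(37.0, 29.0, 29.0),
        lv_center_mm=(0.0, -15.0, 0.0), rv_center_mm=(0.0, 25.0, 0.0),
        seed=0,
    )
    defaults.update(overrides)
    return PhantomConfig(**defaults)


def small_config(**overrides) -> PhantomConfig:
    """48x48x12 multi-coil phantom (4x4x8 mm) for pipeline tests."""
    defaults = dict(
        matrix_size=(48, 48, 12), fov_mm=(192.0, 192.0, 96.0), n_coils=4,
        resp_depth_mm=10.0, chest_wall_x_mm=64.0, body_radii_mm=(88.0, 88.0),
        lv_radii_ed=(22.0, 22.0, 32.0), lv_radii_es=(17.0, 17.0, 26.0),
        rv_radii_ed=(33.0, 26.0, 27.0), rv_radii_es=(27.0, 21.5, 22.0),
        noise_sigma=0.01, seed=0,
    )
    defaults.update(overrides)
    return PhantomConfig(**defaults)


def simulate_small(config, duration_s=25.0, seed=0, **sim_kwargs):
    phantom = make_phantom(config, duration_s=duration_s + 5)
    grid = config.matrix_size[1:]
    sched = circus_schedule(
        grid, n_interleaves=_n_interleaves_for_coverage(grid, 0.75),
        seed=seed)
    return phantom, simulate_acquisition(phantom, sched, duration_s,
                                         **sim_kwargs)


@pytest.fixture(scope="session")
def small_phantom_bundle():
    """Synchronous-breathing phantom + 25 s acquisition, shared by the
    gating/motion pipeline tests."""
    return simulate_small(small_config())


@pytest.fixture(scope="session")
def static_phantom_bundle():
    """No cardiac or respiratory motion, constant HR, noiseless: per-beat
    volumes should be identical."""
    cfg = small_config(resp_depth_mm=0.0, rsa_amplitude=0.0, noise_sigma=0.0,
                      resp_amp_jitter=0.0, resp_period_jitter=0.0)
    return simulate_small(cfg, duration_s=15.0, freeze_cardiac_at=0.05)
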