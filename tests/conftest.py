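"""Shared fixtures: small phantoms and scan geometries for fast tests."""

import numpy as np
import pytest

import aoreg


@pytest.fixture(scope="session")
def phantom():
    """Quasi-regular textured cone mosaic, 6 um spacing."""
    return aoreg.build_phantom((140.0, 140.0, 90.0), 6.0, seed=1, mosaic_jitter=0.6)


@pytest.fixture(scope="session")
def regular_phantom():
    """Perfectly regular lattice, no texture: exact geometry checks."""
    return aoreg.build_phantom(
        (120.0, 120.0, 90.0), 6.0, seed=0, mosaic_jitter=0.0, texture_contrast=0.0
    )


@pytest.fixture(scope="session")
def scan():
    return aoreg.ScanParams(n_x=64, n_z=48, n_y=48, volume_rate=2.4)


def zero_motion(seed=0):
    return aoreg.MotionParams(
        drift_speed=0.0,
        tremor_amplitude=0.0,
        microsaccade_rate=0.0,
        axial_amplitude=0.0,
        torsion_sd=0.0,
        scale_sd=0.0,
        seed=seed,
    )


def drift_tremor(seed=0, **overrides):
    params = dict(
        drift_speed=30.0,
        tremor_amplitude=2.5,
        microsaccade_rate=0.0,
        axial_amplitude=5.0,
        torsion_sd=0.0,
        scale_sd=0.0,
        seed=seed,
    )
    params.update(overrides)
    return aoreg.MotionParams(**params)


@pytest.fixture(scope="session")
def still_volume(phantom, scan):
    """One motion-free, noise-free acquisition of the textured phantom."""
    trace = aoreg.simulate_motion(0.1, zero_motion(), scan.bscan_rate)
    vol, _ = aoreg.acquire_volume(phantom, trace, scan, origin_um=(20.0, 20.0))
    return vol


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
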