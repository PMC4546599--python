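import dataclasses

import numpy as np
import pytest

from xdfict import (
    RockingCurveModel,
    Sinogram,
    TomogramGrid,
    extract_refraction,
    fbp,
    log_absorption,
    simulate_acquisition,
)
from xdfict.phantoms import artery_preset, make_phantom, soft_only


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def disk_image(n: int, pitch: float, radius: float, value: float = 1.0) -> TomogramGrid:
    c = (n - 1) / 2.0
    ax = (np.arange(n) - c) * pitch
    x, y = np.meshgrid(ax, ax, indexing="ij")
    return TomogramGrid((np.hypot(x, y) <= radius) * value, pitch, "delta")


def dome_image(n: int, pitch: float, radius: float, value: float = 1.0) -> TomogramGrid:
    """Smooth compactly supported dome (no hard edge)."""
    c = (n - 1) / 2.0
    ax = (np.arange(n) - c) * pitch
    x, y = np.meshgrid(ax, ax, indexing="ij")
    u2 = (np.hypot(x, y) / radius) ** 2
    return TomogramGrid(np.clip(1 - u2, 0, None) ** 3 * value, pitch, "delta")


@pytest.fixture
def disk64():
    return disk_image(64, 78.0, 1500.0)


@pytest.fixture
def dome64():
    return dome_image(64, 78.0, 2000.0)


def small_artery_spec(seed: int = 0):
    """Artery preset downscaled to a 128-pixel grid (same 1 cm field)."""
    return dataclasses.replace(artery_preset(seed), grid_size=128, pixel_pitch=78.0)


@pytest.fixture(scope="session")
def artery128():
    """Noiseless simulated acquisition of the 128-px artery phantom."""
    angles = np.linspace(0.0, 180.0, 180, endpoint=False)
    pair = make_phantom(small_artery_spec(0))
    rc = RockingCurveModel()
    i_refr, i_abs = simulate_acquisition(pair, None, rc, angles)
    p0, saturated = extract_refraction(i_refr, i_abs, rc)
    abs_tomo = fbp(log_absorption(i_abs))
    abs_tomo = TomogramGrid(abs_tomo.values, abs_tomo.pixel_pitch, "mu")
    return {
        "pair": pair,
        "rc": rc,
        "angles": angles,
        "i_refr": i_refr,
        "i_abs": i_abs,
        "p0": p0,
        "saturated": saturated,
        "abs_tomo": abs_tomo,
    }


@pytest.fixture(scope="session")
def soft128():
    """Noiseless acquisition of the same phantom without dense inclusions."""
    angles = np.linspace(0.0, 180.0, 180, endpoint=False)
    pair = make_phantom(soft_only(small_artery_spec(0)))
    rc = RockingCurveModel()
    i_refr, i_abs = simulate_acquisition(pair, None, rc, angles)
    p0, saturated = extract_refraction(i_refr, i_abs, rc)
    abs_tomo = fbp(log_absorption(i_abs))
    abs_tomo = TomogramGrid(abs_tomo.values, abs_tomo.pixel_pitch, "mu")
    return {
        "pair": pair,
        "rc": rc,
        "angles": angles,
        "p0": p0,
        "saturated": saturated,
        "abs_tomo": abs_tomo,
    }


def uniform_angles(n: int) -> np.ndarray:
    return np.linspace(0.0, 180.0, n, endpoint=False)
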