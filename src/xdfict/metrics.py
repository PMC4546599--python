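"""Quantitative artefact metrics on phantoms.

The real-specimen evidence for artefact suppression is visual; on
phantoms, where the ground truth δ map is known, two numbers stand in for
it: the RMSE restricted to a band of soft tissue around the dense
inclusions (where the beam-deflection streaks live), and the energy of the
high-frequency residual inside the object support (the "minute and
high-frequency" noise the TV step removes).
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import binary_dilation, gaussian_filter

from .grids import TomogramGrid


def _check_congruent(f: TomogramGrid, truth: TomogramGrid) -> None:
    if f.values.shape != truth.values.shape:
        raise ValueError("grids must be congruent")


def band_mask(dense_mask: np.ndarray, band_px: int = 10, guard_px: int = 2) -> np.ndarray:
    """Pixels within ``band_px`` of the dense mask, excluding the dense
    pixels themselves (the loop makes no claim inside dense objects) and a
    ``guard_px``-wide ring right at the dense boundary, where the
    irreducible band-limited rendering of the hard inclusion edge would
    otherwise dominate the soft-tissue error being measured."""
    dense_mask = np.asarray(dense_mask, dtype=bool)
    dil = binary_dilation(dense_mask, iterations=int(band_px))
    inner = binary_dilation(dense_mask, iterations=int(guard_px)) if guard_px > 0 else dense_mask
    return dil & ~inner


def band_rmse(
    f: TomogramGrid,
    truth: TomogramGrid,
    dense_mask: np.ndarray,
    band_px: int = 10,
    guard_px: int = 2,
) -> float:
    """RMSE of f against the truth over the near-inclusion band."""
    _check_congruent(f, truth)
    band = band_mask(dense_mask, band_px, guard_px)
    if not band.any():
        raise ValueError("near-inclusion band is empty")
    r = f.values[band] - truth.values[band]
    return float(np.sqrt(np.mean(r**2)))


def high_freq_artefact_index(
    f: TomogramGrid,
    truth: TomogramGrid,
    support: np.ndarray,
    sigma_px: float = 2.0,
) -> float:
    """L2 norm of the Gaussian high-pass (σ = ``sigma_px``) of the residual
    f − truth, restricted to the support S."""
    _check_congruent(f, truth)
    support = np.asarray(support, dtype=bool)
    resid = f.values - truth.values
    hp = resid - gaussian_filter(resid, sigma_px)
    return float(np.linalg.norm(hp[support]))
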