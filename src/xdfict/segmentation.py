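"""Dense-object, missing-data, and support segmentation (Step 1 of the
artefact-suppression loop).

The absorption tomogram localizes dense structures (calcifications, bone);
projecting the dense mask yields, per view angle, the detector interval
R_θ whose rays crossed a dense object — the entries of the differential
refraction sinogram that saturation has invalidated.  The object support S
is segmented from the initial phase tomogram and is where reconstructed
soft tissue is allowed to live.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label
from skimage.morphology import disk

from .grids import Sinogram, TomogramGrid
from .projector import radon


@dataclass
class RegionMasks:
    """Dense mask D (grid), missing region R (sinogram domain, per angle),
    and object support S (grid).  Invariants: every ray meeting D lies in
    R, and D ⊆ S."""

    dense: np.ndarray
    missing: np.ndarray
    support: np.ndarray

    def __post_init__(self) -> None:
        self.dense = np.asarray(self.dense, dtype=bool)
        self.missing = np.asarray(self.missing, dtype=bool)
        self.support = np.asarray(self.support, dtype=bool)
        if self.dense.shape != self.support.shape:
            raise ValueError("dense and support masks must share the grid shape")
        if np.any(self.dense & ~self.support):
            raise ValueError("dense mask must be contained in the support")


def segment_dense(
    abs_tomo: TomogramGrid,
    threshold: float | None = None,
    min_size: int = 4,
    contrast_ratio: float = 3.0,
) -> np.ndarray:
    """Threshold the absorption (μ) tomogram to isolate dense structures.

    ``threshold=None`` picks Otsu's threshold, accepted only if the two
    classes it separates actually have dense-object contrast: the mean μ
    of the upper class must exceed ``contrast_ratio`` × the bulk (95th
    percentile) of the positive lower class.  Calcifications and bone
    attenuate several-fold more than any soft tissue, whereas Otsu on a
    soft-only tomogram merely splits the soft histogram.  Without that
    contrast the mask is empty.  Small connected components below
    ``min_size`` pixels are removed as reconstruction speckle.
    """
    if threshold is not None and not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    vals = abs_tomo.values
    if threshold is None:
        threshold = float(threshold_otsu(vals))
        upper = vals >= threshold
        lower_pos = vals[(vals > 0) & ~upper]
        if not upper.any() or lower_pos.size == 0 or (
            vals[upper].mean() < contrast_ratio * np.percentile(lower_pos, 95)
        ):
            return np.zeros_like(vals, dtype=bool)
    mask = vals >= threshold
    if min_size > 1 and mask.any():
        labels, n_lab = ndimage.label(mask)
        sizes = np.bincount(labels.ravel())
        keep = np.flatnonzero(sizes >= min_size)
        keep = keep[keep > 0]
        mask = np.isin(labels, keep)
    return mask


def missing_region(
    dense: np.ndarray,
    angles,
    pitch: float,
    dilation_px: int = 2,
    n_xi: int | None = None,
) -> np.ndarray:
    """Per-angle detector intervals R_θ covered by rays through the dense
    mask, dilated along ξ by ``dilation_px`` bins (the artefact extends
    into the vicinity of dense edges beyond the geometric shadow).

    Returns a boolean array of sinogram shape (n_ξ, n_θ).
    """
    dense = np.asarray(dense, dtype=bool)
    grid = TomogramGrid(dense.astype(np.float64), pitch, "reconstruction")
    shadow = radon(grid, angles, n_xi=n_xi)
    # any ray with at least ~a twentieth of a pixel of dense path is in R;
    # the projector footprint already spreads the geometric shadow by ~1 bin
    r = shadow.values > 0.05 * pitch
    if dilation_px > 0:
        structure = np.ones((2 * int(dilation_px) + 1, 1), dtype=bool)
        r = ndimage.binary_dilation(r, structure=structure)
    return r


def support_region(
    phase_tomo: TomogramGrid,
    rel_threshold: float = 0.1,
    closing_radius: int = 3,
) -> np.ndarray:
    """Object support S from a phase tomogram: threshold at
    ``rel_threshold`` × the robust maximum (99.5th percentile), close with
    a disk, fill holes, keep the largest connected component.

    An all-zero (or nonpositive) tomogram yields an empty support with a
    warning rather than an exception.
    """
    vals = phase_tomo.values
    robust_max = float(np.percentile(vals, 99.5))
    if robust_max <= 0:
        warnings.warn("phase tomogram has no positive content; support is empty", stacklevel=2)
        return np.zeros_like(vals, dtype=bool)
    mask = vals >= rel_threshold * robust_max
    if closing_radius > 0:
        mask = ndimage.binary_closing(mask, structure=disk(closing_radius))
    mask = ndimage.binary_fill_holes(mask)
    labels = label(mask)
    if labels.max() > 1:
        sizes = np.bincount(labels.ravel())[1:]
        mask = labels == (int(np.argmax(sizes)) + 1)
    return mask


def zero_missing(p0: Sinogram, missing: np.ndarray) -> Sinogram:
    """Return p0 with the missing-region entries set to zero (the Step 1
    'set their pixel values as 0' operation)."""
    vals = p0.values.copy()
    vals[missing] = 0.0
    return p0.with_values(vals)
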