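"""XDFI acquisition forward model.

Analyzer-based (dark-field) phase-contrast imaging converts the transverse
refraction angle θ_r of the beam into an intensity modulation through the
slope of the analyzer crystal's rocking curve.  Two working points matter:

* point **A**, on the flank of the curve, where transmissivity depends
  (locally linearly) on the incidence angle — the refraction-sensitive
  setting; and
* point **B**, on the flat top, where no angular modulation occurs — the
  absorption-only setting.

The refraction angle produced by a specimen is the ξ-derivative of the
line integral of its refractive-index decrement δ, i.e. the differential
refraction sinogram.  Soft tissue deflects by ~1e-7 rad and stays inside
the one-to-one (measurable) region of the flank; dense structures such as
calcifications deflect by far more, the analyzer response saturates, and
the recorded value no longer determines the true angle — the corruption
the artefact-suppression loop later repairs.

The rocking curve here is a parametric stand-in (Gaussian flanks joined by
a flat plateau) matching the experimentally relevant features: the stated
FWHM, a flat absorption point B at the peak, and a monotonic flank for
point A.  The dynamical-diffraction curve of the actual Si(440) Laue
analyzer is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import Sinogram
from .phantoms import PhantomPair
from .projector import diff_xi, radon

_SQRT_2LN2 = np.sqrt(2.0 * np.log(2.0))


@dataclass
class BeamGeometry:
    """Monochromator-collimator geometry (Bragg-case, asymmetric cut)."""

    bragg_angle_deg: float
    asymmetry_angle_deg: float
    energy_kev: float | None = None  # metadata only
    incident_divergence_rad: float | None = None  # w_i, metadata only

    def __post_init__(self) -> None:
        # α = 0 is the symmetric-cut crystal (b = 1)
        if not (0.0 <= self.asymmetry_angle_deg < self.bragg_angle_deg < 90.0):
            raise ValueError("require 0 <= asymmetry angle < Bragg angle < 90 degrees")


def asymmetry_factor(geom: BeamGeometry) -> float:
    """Asymmetry factor b = sin(θ_B − α)/sin(θ_B + α) ∈ (0, 1).

    The asymmetric cut expands the beam by 1/b and compresses its
    divergence to w_i·b.
    """
    tb = np.deg2rad(geom.bragg_angle_deg)
    al = np.deg2rad(geom.asymmetry_angle_deg)
    return float(np.sin(tb - al) / np.sin(tb + al))


@dataclass
class RockingCurveModel:
    """Parametric analyzer transmissivity curve.

    Flat plateau of half-width ``plateau_frac × fwhm`` around zero offset,
    Gaussian flanks chosen so the full curve has the configured FWHM.
    Working point A sits on the negative flank (default: at half maximum,
    offset −fwhm/2); ``linear_range`` is the half-width of the angular
    interval around A treated as one-to-one by the extraction step.
    """

    fwhm: float = 2.0e-6  # rad
    peak_transmissivity: float = 0.8
    plateau_frac: float = 0.15
    working_point_a_offset: float | None = None  # rad; default −fwhm/2
    linear_range: float = 5.0e-7  # rad, ± around A

    def __post_init__(self) -> None:
        if not (0.0 < self.peak_transmissivity <= 1.0):
            raise ValueError("peak transmissivity must be in (0, 1]")
        if not (0.0 <= self.plateau_frac < 0.5):
            raise ValueError("plateau fraction must be in [0, 0.5)")
        if self.working_point_a_offset is None:
            self.working_point_a_offset = -self.fwhm / 2.0
        if self.working_point_a_offset >= -self.plateau_halfwidth:
            raise ValueError("working point A must lie on the negative flank")
        if self.working_point_a_offset + self.linear_range > -self.plateau_halfwidth:
            raise ValueError("linear range must stay within the flank (one-to-one) region")

    @property
    def plateau_halfwidth(self) -> float:
        return self.plateau_frac * self.fwhm

    @property
    def flank_sigma(self) -> float:
        # half maximum occurs at plateau edge + σ√(2 ln 2) → total FWHM
        return (self.fwhm / 2.0 - self.plateau_halfwidth) / _SQRT_2LN2


def transmissivity(rc: RockingCurveModel, offset) -> np.ndarray | float:
    """Analyzer transmissivity at angular ``offset`` (rad) from the Bragg
    peak: flat at the plateau (point B), Gaussian on the flanks, → 0 far
    off-Bragg.  Total function; vectorized."""
    off = np.asarray(offset, dtype=np.float64)
    excess = np.maximum(np.abs(off) - rc.plateau_halfwidth, 0.0)
    out = rc.peak_transmissivity * np.exp(-0.5 * (excess / rc.flank_sigma) ** 2)
    return out if out.ndim else float(out)


def transmissivity_slope(rc: RockingCurveModel, offset) -> np.ndarray | float:
    """Analytic derivative dT/dθ of :func:`transmissivity`."""
    off = np.asarray(offset, dtype=np.float64)
    excess = np.maximum(np.abs(off) - rc.plateau_halfwidth, 0.0)
    core = rc.peak_transmissivity * np.exp(-0.5 * (excess / rc.flank_sigma) ** 2)
    out = -np.sign(off) * excess / rc.flank_sigma**2 * core
    return out if out.ndim else float(out)


def invert_transmissivity(rc: RockingCurveModel, t) -> np.ndarray | float:
    """Inverse of the transmissivity on the negative flank (offset < 0).

    Input values are clipped to the open interval the flank attains; used
    by :func:`extract_refraction` after clamping to the linear range."""
    t = np.asarray(t, dtype=np.float64)
    t = np.clip(t, 1e-300, rc.peak_transmissivity)
    off = -(rc.plateau_halfwidth + rc.flank_sigma * np.sqrt(-2.0 * np.log(t / rc.peak_transmissivity)))
    return off if off.ndim else float(off)


def refraction_angles(ph: PhantomPair, angles) -> Sinogram:
    """True refraction-angle sinogram θ_r(ξ, θ) = ∂/∂ξ ℜ_θ δ (radians)."""
    p = diff_xi(radon(ph.delta_map, angles))
    return p.with_values(p.values, kind="refraction_angle_rad")


def simulate_acquisition(
    ph: PhantomPair,
    geom: BeamGeometry | None,
    rc: RockingCurveModel,
    angles,
    photons: float | None = None,
    seed: int | None = None,
) -> tuple[Sinogram, Sinogram]:
    """Simulate the two XDFI acquisitions of a phantom.

    Returns ``(I_refr, I_abs)``: the refraction-modulated image taken at
    working point A and the absorption image taken at point B, both with
    I₀ = 1.  ``I_abs = exp(−∫μ dl)`` (Beer–Lambert; μ in mm⁻¹, paths in
    μm) and ``I_refr = I_abs · T(A + θ_r)``.  If ``photons`` is given,
    Poisson counting noise at that mean photon number per detector bin is
    applied to both images (seeded).

    ``geom`` describes the beamline optics; it scales the physical beam,
    not the simulated pixel data, and is accepted for provenance.
    """
    angles = np.atleast_1d(np.asarray(angles, dtype=np.float64))
    if angles.size == 0:
        raise ValueError("angle list must be non-empty")
    theta_r = refraction_angles(ph, angles)
    mu_li = radon(ph.mu_map, angles)  # mm⁻¹ × μm
    i_abs = np.exp(-mu_li.values * 1.0e-3)
    i_refr = i_abs * transmissivity(rc, rc.working_point_a_offset + theta_r.values)
    if photons is not None:
        rng = np.random.default_rng(seed)
        i_refr = rng.poisson(np.clip(i_refr, 0, None) * photons) / photons
        i_abs = rng.poisson(np.clip(i_abs, 0, None) * photons) / photons
        i_abs = np.maximum(i_abs, 0.5 / photons)  # keep strictly positive
    sino_r = Sinogram(i_refr, ph.delta_map.pixel_pitch, angles, "intensity_refraction")
    sino_a = Sinogram(i_abs, ph.delta_map.pixel_pitch, angles, "intensity_absorption")
    return sino_r, sino_a


def extract_refraction(
    i_refr: Sinogram, i_abs: Sinogram, rc: RockingCurveModel
) -> tuple[Sinogram, np.ndarray]:
    """Recover the differential refraction sinogram p(0) from the two
    intensity images.

    Divides the refraction-modulated image by the absorption image and maps
    the ratio through the inverse of the rocking-curve flank at working
    point A.  Outside the one-to-one region the response is degenerate: the
    ratio (and hence the angle) is clamped to the edge of the linear range
    and flagged in the returned boolean ``saturated`` array — these entries
    are the missing data the suppression loop later discards and estimates.

    Returns ``(p0, saturated)`` with ``p0.kind == "differential"``.
    """
    if np.any(i_abs.values <= 0):
        raise ValueError("absorption image must be strictly positive")
    a = rc.working_point_a_offset
    ratio = i_refr.values / i_abs.values
    lo = transmissivity(rc, a - rc.linear_range)
    hi = transmissivity(rc, a + rc.linear_range)
    saturated = (ratio < lo) | (ratio > hi)
    angle = invert_transmissivity(rc, np.clip(ratio, lo, hi)) - a
    angle = np.clip(angle, -rc.linear_range, rc.linear_range)
    return i_refr.with_values(angle, kind="differential"), saturated


def log_absorption(i_abs: Sinogram) -> Sinogram:
    """Absorption line integrals −ln(I/I₀) in mm⁻¹·μm units, ready for FBP."""
    if np.any(i_abs.values <= 0):
        raise ValueError("absorption image must be strictly positive")
    return i_abs.with_values(-np.log(i_abs.values) * 1.0e3, kind="absorption_line_integral")
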