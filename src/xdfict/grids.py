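"""Image-domain and projection-domain containers.

A :class:`TomogramGrid` is a square 2-D scalar field on a centered grid —
either a refractive-index-decrement map δ(x, y) (dimensionless, ~1e-7), an
attenuation map μ(x, y) (mm⁻¹), or a reconstruction. A :class:`Sinogram`
holds projection-domain data p(ξ, θ) on a detector axis ξ (perpendicular to
the beam) for a set of view angles θ in [0°, 180°).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: recognised tomogram value kinds
TOMO_KINDS = ("delta", "mu", "reconstruction")

#: recognised sinogram kinds.  ``absorption_line_integral`` and plain
#: ``line_integral`` live in value×μm units; ``refraction_angle_rad`` and
#: ``differential`` are refraction angles in radians; the two intensity
#: kinds are raw detector readings (I₀ = 1).
SINO_KINDS = (
    "absorption_line_integral",
    "line_integral",
    "refraction_angle_rad",
    "differential",
    "intensity_refraction",
    "intensity_absorption",
)


@dataclass
class TomogramGrid:
    """Square scalar field with physical pixel pitch and centered origin.

    Parameters
    ----------
    values : (N, N) array
        Pixel values; axis 0 is x, axis 1 is y, origin at the grid center
        ``(N-1)/2`` in index units.
    pixel_pitch : float
        Pixel size in μm.
    value_kind : str
        One of :data:`TOMO_KINDS`.
    """

    values: np.ndarray
    pixel_pitch: float
    value_kind: str = "reconstruction"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError(f"tomogram must be square 2-D, got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("tomogram values must be finite")
        if not (self.pixel_pitch > 0):
            raise ValueError("pixel_pitch must be positive")
        if self.value_kind not in TOMO_KINDS:
            raise ValueError(f"unknown value_kind {self.value_kind!r}")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def coords(self) -> np.ndarray:
        """Centered physical axis (μm), shared by x and y."""
        c = (self.n - 1) / 2.0
        return (np.arange(self.n) - c) * self.pixel_pitch

    def with_values(self, values: np.ndarray, value_kind: str | None = None) -> "TomogramGrid":
        return TomogramGrid(values, self.pixel_pitch, value_kind or self.value_kind)

    def copy(self) -> "TomogramGrid":
        return self.with_values(self.values.copy())


@dataclass
class Sinogram:
    """Projection-domain data p(ξ, θ).

    ``values`` has shape (n_ξ, n_θ); ``angles`` are view angles in degrees,
    strictly increasing within [0°, 180°).  The detector axis ξ is centered:
    bin *j* sits at ``(j - (n_ξ-1)/2) * xi_pitch`` μm.
    """

    values: np.ndarray
    xi_pitch: float
    angles: np.ndarray
    kind: str = "line_integral"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.angles = np.atleast_1d(np.asarray(self.angles, dtype=np.float64))
        if self.values.ndim != 2:
            raise ValueError("sinogram values must be 2-D (n_xi, n_theta)")
        if self.angles.shape[0] != self.values.shape[1]:
            raise ValueError("number of angles must match sinogram columns")
        if self.angles.size == 0:
            raise ValueError("angle set must be non-empty")
        if np.any(np.diff(self.angles) <= 0):
            raise ValueError("angles must be strictly increasing")
        if self.angles[0] < 0 or self.angles[-1] >= 180.0:
            raise ValueError("angles must lie in [0, 180)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("sinogram values must be finite")
        if not (self.xi_pitch > 0):
            raise ValueError("xi_pitch must be positive")
        if self.kind not in SINO_KINDS:
            raise ValueError(f"unknown sinogram kind {self.kind!r}")

    @property
    def n_xi(self) -> int:
        return self.values.shape[0]

    @property
    def n_theta(self) -> int:
        return self.values.shape[1]

    @property
    def xi(self) -> np.ndarray:
        """Centered detector axis in μm."""
        c = (self.n_xi - 1) / 2.0
        return (np.arange(self.n_xi) - c) * self.xi_pitch

    def with_values(self, values: np.ndarray, kind: str | None = None) -> "Sinogram":
        return Sinogram(values, self.xi_pitch, self.angles.copy(), kind or self.kind)

    def copy(self) -> "Sinogram":
        return self.with_values(self.values.copy())


def congruent(a: Sinogram, b: Sinogram) -> bool:
    """True if two sinograms share geometry (shape, pitch, angles)."""
    return (
        a.values.shape == b.values.shape
        and a.xi_pitch == b.xi_pitch
        and np.array_equal(a.angles, b.angles)
    )
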