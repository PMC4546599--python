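"""Synthetic specimen phantoms: paired refractive-index-decrement (δ) and
attenuation (μ) maps with soft-tissue structures plus dense inclusions.

The phantoms emulate the two study scenarios the artefact-suppression
algorithm targets: an arterial-wall-like specimen — concentric soft rings
with an embedded calcification-like blob — and a rat-foot-like specimen
with bone-like inclusions in soft tissue.

Soft structures deliberately use smooth, wide-tapered radial profiles:
analyzer-based imaging only stays linear while refraction angles remain in
the ~1e-7 rad regime, and the transverse derivative of a projected disk
scales like δ·√(2r/w) for edge width w — hard soft-tissue edges would
saturate the analyzer just like calcifications do.  Dense inclusions keep
hard edges by default (an optional ``edge_blur`` exists for sensitivity
studies), because those sharp δ gradients are precisely what produces the
beam-deflection artefact.

All coordinates are physical μm relative to the grid center.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import TomogramGrid


class GeometryError(ValueError):
    """A phantom structure extends outside the inscribed circle."""


@dataclass
class Background:
    """Smooth elliptical dome: value × (1 − u²)^power with
    u² = (x/a)² + (y/b)², clipped at the ellipse boundary."""

    semi_axes: tuple[float, float]  # (a, b) μm
    delta: float
    mu: float
    power: int = 4

    @property
    def extent(self) -> float:
        return max(self.semi_axes)

    def profile(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        a, b = self.semi_axes
        u2 = (x / a) ** 2 + (y / b) ** 2
        return np.clip(1.0 - u2, 0.0, None) ** self.power


@dataclass
class Annulus:
    """Soft ring: plateau between r_inner and r_outer with raised-cosine
    tapers of width ``taper`` falling to zero on both sides."""

    center: tuple[float, float]
    r_inner: float
    r_outer: float
    delta: float
    mu: float
    taper: float

    @property
    def extent(self) -> float:
        return float(np.hypot(*self.center)) + self.r_outer + self.taper

    def profile(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        r = np.hypot(x - self.center[0], y - self.center[1])
        w = self.taper
        up = np.where(
            r <= self.r_inner - w,
            0.0,
            np.where(r >= self.r_inner, 1.0, 0.5 * (1 - np.cos(np.pi * (r - (self.r_inner - w)) / w))),
        )
        dn = np.where(
            r <= self.r_outer,
            1.0,
            np.where(r >= self.r_outer + w, 0.0, 0.5 * (1 + np.cos(np.pi * (r - self.r_outer) / w))),
        )
        return up * dn


@dataclass
class SoftBlob:
    """Soft disk with an inward raised-cosine taper of width ``taper``."""

    center: tuple[float, float]
    radius: float
    delta: float
    mu: float
    taper: float

    @property
    def extent(self) -> float:
        return float(np.hypot(*self.center)) + self.radius

    def profile(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        r = np.hypot(x - self.center[0], y - self.center[1])
        w = self.taper
        return np.where(
            r <= self.radius - w,
            1.0,
            np.where(r >= self.radius, 0.0, 0.5 * (1 + np.cos(np.pi * (r - (self.radius - w)) / w))),
        )


@dataclass
class DenseBlob:
    """Dense inclusion (calcification/bone): hard-edged disk by default."""

    center: tuple[float, float]
    radius: float
    delta: float
    mu: float
    edge_blur: float = 0.0  # optional taper width, μm

    @property
    def extent(self) -> float:
        return float(np.hypot(*self.center)) + self.radius + self.edge_blur

    def profile(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        r = np.hypot(x - self.center[0], y - self.center[1])
        if self.edge_blur <= 0:
            return (r <= self.radius).astype(np.float64)
        w = self.edge_blur
        return np.where(
            r <= self.radius,
            1.0,
            np.where(r >= self.radius + w, 0.0, 0.5 * (1 + np.cos(np.pi * (r - self.radius) / w))),
        )

    def mask(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return np.hypot(x - self.center[0], y - self.center[1]) <= self.radius


@dataclass
class PhantomSpec:
    """Parameters of a paired (δ, μ) phantom.

    The dense inclusions must be separable from the soft tissue by a μ
    threshold and every structure must fit strictly inside the inscribed
    circle of the grid (compact support of all projections).
    """

    grid_size: int = 256
    pixel_pitch: float = 39.0  # μm; 256 × 39 μm ≈ 1 cm field of view
    background: Background | None = None
    rings: list[Annulus] = field(default_factory=list)
    soft_blobs: list[SoftBlob] = field(default_factory=list)
    dense_inclusions: list[DenseBlob] = field(default_factory=list)
    noise_seed: int = 0

    def structures(self):
        out: list = []
        if self.background is not None:
            out.append(self.background)
        return out + list(self.rings) + list(self.soft_blobs) + list(self.dense_inclusions)


@dataclass
class PhantomPair:
    """δ map, μ map and the ground-truth dense-inclusion mask."""

    delta_map: TomogramGrid
    mu_map: TomogramGrid
    dense_mask_truth: np.ndarray

    @property
    def n(self) -> int:
        return self.delta_map.n


def make_phantom(spec: PhantomSpec) -> PhantomPair:
    """Rasterize a :class:`PhantomSpec` into a :class:`PhantomPair`.

    Deterministic given the spec (including its seed).  Raises
    :class:`GeometryError` if any structure leaves the inscribed circle
    (with a 2-pixel compact-support margin).
    """
    n, pitch = spec.grid_size, spec.pixel_pitch
    inscribed = (n / 2.0 - 2.0) * pitch
    for s in spec.structures():
        if s.extent >= inscribed:
            raise GeometryError(
                f"structure {s!r} extends to {s.extent:.0f} μm, beyond the "
                f"inscribed-circle margin {inscribed:.0f} μm"
            )
    c = (n - 1) / 2.0
    ax = (np.arange(n) - c) * pitch
    x, y = np.meshgrid(ax, ax, indexing="ij")

    delta = np.zeros((n, n))
    mu = np.zeros((n, n))
    for s in spec.structures():
        prof = s.profile(x, y)
        delta += s.delta * prof
        mu += s.mu * prof

    dense_mask = np.zeros((n, n), dtype=bool)
    for blob in spec.dense_inclusions:
        dense_mask |= blob.mask(x, y)

    if delta.min() < 0 or mu.min() < 0:
        raise ValueError("phantom δ and μ must be nonnegative everywhere")
    if dense_mask.any():
        soft = ~dense_mask & (mu > 0)
        if soft.any() and mu[dense_mask].min() <= mu[soft].max():
            raise ValueError("dense inclusions are not μ-separable from soft tissue")

    return PhantomPair(
        TomogramGrid(delta, pitch, "delta"),
        TomogramGrid(mu, pitch, "mu"),
        dense_mask,
    )


def soft_only(spec: PhantomSpec) -> PhantomSpec:
    """Copy of a spec with the dense inclusions removed."""
    import dataclasses

    return dataclasses.replace(spec, dense_inclusions=[])


# ---------------------------------------------------------------------------
# Presets.  Scales mirror an ~1 cm arterial segment imaged at ~39 μm pixels.
# δ background 2e-7 and dense δ 1e-6 put soft-tissue refraction in the
# ~1e-7 rad regime while dense edges deflect by several 1e-6 rad, well past
# the analyzer's linear range.  μ in mm⁻¹ (soft ≈ water at ~31 keV, dense
# ≈ calcification/bone, an order of magnitude higher).
# ---------------------------------------------------------------------------


def artery_preset(seed: int = 0) -> PhantomSpec:
    """Arterial-wall-like phantom: soft annulus (vessel wall) inside a smooth
    tissue dome, with one off-center calcification-like dense blob in the
    lumen region."""
    rng = np.random.default_rng(seed)
    # small seeded jitter of the blob position keeps separate seeds distinct;
    # the blob stays inside the lumen (annulus support begins at 700 μm)
    jx, jy = rng.uniform(-60.0, 60.0, size=2)
    return PhantomSpec(
        grid_size=256,
        pixel_pitch=39.0,
        background=Background(semi_axes=(4400.0, 4100.0), delta=2.0e-7, mu=0.030, power=4),
        rings=[
            Annulus(center=(0.0, 0.0), r_inner=1800.0, r_outer=2600.0, delta=4.0e-8, mu=0.008, taper=1200.0)
        ],
        dense_inclusions=[
            DenseBlob(center=(150.0 + jx, 80.0 + jy), radius=420.0, delta=1.0e-6, mu=0.5)
        ],
        noise_seed=seed,
    )


def rat_foot_preset(seed: int = 0) -> PhantomSpec:
    """Rat-foot-like phantom: soft-tissue dome with two hard bone-like
    inclusions and one soft joint-tissue blob."""
    rng = np.random.default_rng(seed + 1)
    jx, jy = rng.uniform(-100.0, 100.0, size=2)
    return PhantomSpec(
        grid_size=256,
        pixel_pitch=39.0,
        background=Background(semi_axes=(4300.0, 4400.0), delta=2.0e-7, mu=0.025, power=4),
        soft_blobs=[
            SoftBlob(center=(-900.0, -1100.0), radius=1000.0, delta=5.0e-8, mu=0.006, taper=750.0)
        ],
        dense_inclusions=[
            DenseBlob(center=(1500.0 + jx, -900.0 + jy), radius=600.0, delta=1.5e-6, mu=0.8),
            DenseBlob(center=(-1200.0, 1400.0), radius=420.0, delta=1.2e-6, mu=0.7),
        ],
        noise_seed=seed,
    )


PRESETS = {"artery": artery_preset, "rat_foot": rat_foot_preset}


def get_preset(name: str, seed: int = 0) -> PhantomSpec:
    try:
        return PRESETS[name](seed)
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None
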