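"""Iterative beam-deflection artefact suppression.

The measured differential refraction sinogram p(0) is valid except on the
per-angle missing-data region R_θ (rays that crossed dense structures,
where the analyzer saturated).  The loop alternates between the sinogram
and tomogram domains, imposing a-priori information in each:

1. Segment the dense mask D from the absorption tomogram, project it to
   get R_θ, zero those entries of p(0); segment the object support S from
   the initial phase tomogram.
2. Initialize f(1) by conventional reconstruction of the zeroed sinogram,
   Gaussian-smoothed.
3. Reproject the current tomogram and differentiate along ξ:
   p(n) = ∂/∂ξ (ℜ_θ f(n)).
4. Replace p(n) with the measured p(0) outside R_θ; inside R_θ, rescale
   p(n) by the per-angle factor k that restores the zero-sum property a
   differentiated compact projection must satisfy.
5. Reconstruct f̃(n) by signum convolution + ART.
6. Zero pixels outside the support S, then TV-denoise with nonnegativity
   (the denoising step that keeps differentiation noise from accumulating
   across iterations).
7. Iterate 3–6 until ‖f(n+1) − f(n)‖/‖f(n)‖ falls below the tolerance.

Exposed as a model/results pair: :class:`ArtefactSuppressionModel` is
built from the data, ``fit()`` runs the loop and returns a
:class:`SuppressionResults` carrying the tomogram, masks, convergence
history and a ``summary()``; :func:`run_suppression` is the functional
wrapper.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .grids import Sinogram, TomogramGrid, congruent
from .projector import diff_xi, radon
from .recon import reconstruct_phase
from .segmentation import RegionMasks, missing_region, segment_dense, support_region, zero_missing
from .tv import tv_denoise, tv_value

logger = logging.getLogger(__name__)

#: ridge fraction for the per-angle rescale factor: denominators smaller
#: than this fraction of the in-R L1 mass are treated as unreliable and
#: pull k toward 1
_K_RIDGE_FRAC = 0.2


@dataclass
class ReconConfig:
    """Tunable parameters of the suppression loop.

    convergence_tol is the Step-7 relative-change threshold (default
    1e-3); init_smoothing_sigma smooths the Step-2 initial tomogram;
    tv_lambda is the TV weight in δ-normalized per-pixel-edge units (the
    loop rescales it by the robust amplitude of the current iterate and
    the pixel pitch, so the configured value is dimensionless).
    """

    convergence_tol: float = 1.0e-3
    max_iters: int = 30
    init_smoothing_sigma: float = 3.0
    art_relaxation: float = 0.25
    art_sweeps: int = 3
    tv_lambda: float = 0.05
    tv_iters: int = 50
    k_cap: float = 3.0
    mann_relaxation: float = 0.5
    dense_threshold: float | None = None
    dilation_px: int = 2
    min_dense_size: int = 4
    support_rel_threshold: float = 0.1
    support_closing_radius: int = 3

    def __post_init__(self) -> None:
        if not (self.convergence_tol > 0):
            raise ValueError("convergence_tol must be positive")
        if self.max_iters < 1:
            raise ValueError("max_iters must be at least 1")


@dataclass
class IterationState:
    """Running state of the loop: iteration index, current tomogram and
    reprojected differential sinogram, per-angle rescale factors, and the
    relative-change history."""

    n: int
    f_n: TomogramGrid
    p_n: Sinogram | None
    k_per_theta: np.ndarray | None
    rel_change_history: list[float] = field(default_factory=list)


def rescale_missing(
    p0: Sinogram,
    p_n: Sinogram,
    missing: np.ndarray,
    k_cap: float = 3.0,
    ridge_frac: float = _K_RIDGE_FRAC,
) -> tuple[Sinogram, np.ndarray]:
    """Measured-data replacement plus per-angle zero-sum rescaling.

    Outside R_θ the measured p(0) is kept untouched; inside R_θ the
    reprojected p(n) is scaled by k(θ) = −∫_R̄ p(0) / ∫_R p(n), the unique
    factor making each angle's total ξ-sum vanish — the identity any
    ξ-derivative of a compactly supported projection must satisfy.  At the
    loop's fixed point the reprojection is consistent with the measured
    data and k(θ) ≈ 1.

    Away from the fixed point the scale equation is ill-conditioned: the
    differential content of a dense inclusion nearly cancels over its own
    shadow, so ∫_R p(n) is a small difference of large values and the raw
    k can be arbitrarily large (or sign-flipped) early in the iteration,
    feeding amplified copies of the current estimate back into the
    reconstruction.  The factor is therefore regularized toward 1: with
    d = ∫_R p(n), m = ∫_R̄ p(0) and ε a fraction of the L1 mass of p(n)
    inside R,

        k = (−m·d + ε²) / (d² + ε²),

    which equals the exact −m/d when |d| ≫ ε and tends smoothly to 1 as
    the denominator degenerates (a vanishing denominator, the spec case,
    gives exactly k = 1), then clipped to [0, ``k_cap``].  The residual
    still needed to zero the total sum is spread uniformly over R_θ, so
    the zero-sum identity holds exactly for every angle regardless.

    Angles with empty R are returned as measured.  Returns the blended
    sinogram and the per-angle k array (k = 1 where R is empty).
    """
    if not congruent(p0, p_n):
        raise ValueError("p0 and p_n must share sinogram geometry")
    missing = np.asarray(missing, dtype=bool)
    if missing.shape != p0.values.shape:
        raise ValueError("missing-region mask must match sinogram shape")
    if not (k_cap > 0):
        raise ValueError("k_cap must be positive")
    out = p0.values.copy()
    k = np.ones(p0.n_theta)
    for j in range(p0.n_theta):
        r = missing[:, j]
        if not r.any():
            continue
        num = p0.values[~r, j].sum()
        den = p_n.values[r, j].sum()
        eps = ridge_frac * np.abs(p_n.values[r, j]).sum()
        if den * den + eps * eps < 1e-300:
            if abs(num) > 1e-300:
                logger.debug(
                    "degenerate rescale at angle %.3f deg: zero reprojected mass "
                    "in R with nonzero measured sum; keeping k=1",
                    p0.angles[j],
                )
            kj = 1.0
        else:
            kj = float(np.clip((-num * den + eps * eps) / (den * den + eps * eps), 0.0, k_cap))
        k[j] = kj
        out[r, j] = kj * p_n.values[r, j]
        shift = -(num + kj * den) / r.sum()
        if shift != 0.0:
            out[r, j] += shift
    return p0.with_values(out), k


def apply_support(f: TomogramGrid, support: np.ndarray) -> TomogramGrid:
    """Zero every pixel outside the object support S."""
    support = np.asarray(support, dtype=bool)
    if support.shape != f.values.shape:
        raise ValueError("support mask must match the grid shape")
    return f.with_values(np.where(support, f.values, 0.0))


class ArtefactSuppressionModel:
    """Artefact-suppression model built from a measured differential
    refraction sinogram and the registered absorption tomogram.

    Parameters
    ----------
    p0 : Sinogram
        Extracted differential refraction sinogram (kind ``differential``);
        saturated entries need not be pre-zeroed — the model zeroes the
        missing region it derives from the absorption data.
    absorption_tomogram : TomogramGrid
        μ reconstruction registered with the phase data, used to segment
        the dense mask.
    config : ReconConfig, optional
    masks : RegionMasks, optional
        Precomputed masks; bypasses the Step-1 segmentation when given.
    """

    def __init__(
        self,
        p0: Sinogram,
        absorption_tomogram: TomogramGrid,
        config: ReconConfig | None = None,
        masks: RegionMasks | None = None,
    ) -> None:
        if p0.kind != "differential":
            raise ValueError("p0 must be a differential refraction sinogram")
        self.p0_raw = p0
        self.absorption_tomogram = absorption_tomogram
        self.config = config or ReconConfig()
        self._masks = masks

    # -- Step 1 -----------------------------------------------------------
    def build_masks(self) -> RegionMasks:
        """Segment D from the absorption tomogram, project it into R_θ,
        and segment the support S from the initial phase tomogram."""
        if self._masks is not None:
            return self._masks
        cfg = self.config
        dense = segment_dense(self.absorption_tomogram, cfg.dense_threshold, cfg.min_dense_size)
        missing = missing_region(
            dense,
            self.p0_raw.angles,
            self.absorption_tomogram.pixel_pitch,
            dilation_px=cfg.dilation_px,
            n_xi=self.p0_raw.n_xi,
        )
        p0m = zero_missing(self.p0_raw, missing)
        init = self._conventional_recon(p0m)
        support = support_region(init, cfg.support_rel_threshold, cfg.support_closing_radius)
        support |= dense  # D ⊆ S by construction
        self._masks = RegionMasks(dense, missing, support)
        return self._masks

    def _conventional_recon(self, p: Sinogram) -> TomogramGrid:
        n = self.absorption_tomogram.n
        return reconstruct_phase(p, n=n, n_sweeps=0)

    def fit(self) -> "SuppressionResults":
        """Run the suppression loop to convergence (or max_iters)."""
        cfg = self.config
        masks = self.build_masks()
        p0 = zero_missing(self.p0_raw, masks.missing)
        n = self.absorption_tomogram.n

        # Step 2: smoothed conventional reconstruction as f(1)
        f = self._conventional_recon(p0)
        if cfg.init_smoothing_sigma > 0:
            f = f.with_values(gaussian_filter(f.values, cfg.init_smoothing_sigma))

        state = IterationState(n=0, f_n=f, p_n=None, k_per_theta=None)
        history: list[dict] = []
        converged = False
        lam_eff: float | None = None
        for it in range(1, cfg.max_iters + 1):
            # Step 3: reproject and differentiate
            p_n = diff_xi(radon(f, p0.angles, n_xi=p0.n_xi))
            # Step 4: measured-data replacement + zero-sum rescale
            p_tilde, k = rescale_missing(p0, p_n, masks.missing, k_cap=cfg.k_cap)
            # Step 5: signum convolution + ART
            f_tilde = reconstruct_phase(
                p_tilde, n=n, relaxation=cfg.art_relaxation, n_sweeps=cfg.art_sweeps
            )
            # Step 6: support masking, then TV denoising with f ≥ 0.
            # λ is a constant multiplier: the δ-normalization scale is
            # frozen at the first pass so the penalty weight does not
            # drift with the iterate.
            f_prime = apply_support(f_tilde, masks.support)
            if lam_eff is None:
                scale = float(np.percentile(np.abs(f_prime.values), 99.5))
                lam_eff = cfg.tv_lambda * scale / f_prime.pixel_pitch if scale > 0 else 0.0
            if cfg.tv_lambda > 0 and lam_eff > 0:
                f_next = tv_denoise(f_prime, lam_eff, n_iter=cfg.tv_iters)
            else:
                f_next = f_prime.with_values(np.clip(f_prime.values, 0.0, None))
            # Krasnoselskii–Mann relaxation of the fixed-point map: damps
            # the oscillatory modes the sinogram-tomogram alternation can
            # excite; beta = 1 recovers the undamped iteration.
            beta = cfg.mann_relaxation
            if beta != 1.0:
                f_next = f_next.with_values(f.values + beta * (f_next.values - f.values))
            # Step 7: relative change
            denom = float(np.linalg.norm(f.values))
            rel = float(np.linalg.norm(f_next.values - f.values)) / denom if denom > 0 else np.inf
            history.append(
                {
                    "iteration": it,
                    "rel_change": rel,
                    "k_min": float(k.min()),
                    "k_max": float(k.max()),
                    "tv": tv_value(f_next),
                }
            )
            state = IterationState(
                n=it, f_n=f_next, p_n=p_n, k_per_theta=k,
                rel_change_history=[h["rel_change"] for h in history],
            )
            f = f_next
            if rel <= cfg.convergence_tol:
                converged = True
                break
        if not converged:
            logger.warning("suppression loop hit max_iters=%d without converging", cfg.max_iters)
        return SuppressionResults(
            model=self, tomogram=f, masks=masks, history=history,
            converged=converged, state=state,
        )


@dataclass
class SuppressionResults:
    """Fitted artefact-suppression result.

    ``tomogram`` is the final δ reconstruction; ``history`` records, per
    outer iteration, the relative change, the per-angle rescale-factor
    range, and the TV of the iterate.
    """

    model: ArtefactSuppressionModel
    tomogram: TomogramGrid
    masks: RegionMasks
    history: list[dict]
    converged: bool
    state: IterationState

    @property
    def n_iter(self) -> int:
        return len(self.history)

    @property
    def rel_change(self) -> np.ndarray:
        return np.array([h["rel_change"] for h in self.history])

    def history_frame(self):
        """Per-iteration diagnostics as a pandas DataFrame."""
        import pandas as pd

        return pd.DataFrame(self.history)

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Beam-deflection artefact suppression",
            "=" * 52,
            f"grid: {self.tomogram.n} x {self.tomogram.n} px @ {self.tomogram.pixel_pitch:g} um",
            f"angles: {self.model.p0_raw.n_theta} over [{self.model.p0_raw.angles[0]:g}, "
            f"{self.model.p0_raw.angles[-1]:g}] deg",
            f"dense pixels: {int(self.masks.dense.sum())}, "
            f"support pixels: {int(self.masks.support.sum())}, "
            f"missing sinogram fraction: {self.masks.missing.mean():.3f}",
            f"iterations: {self.n_iter} (max {cfg.max_iters}), "
            f"converged: {self.converged} (tol {cfg.convergence_tol:g})",
        ]
        if self.history:
            h = self.history[-1]
            lines.append(
                f"final rel_change: {h['rel_change']:.3e}, "
                f"k range: [{h['k_min']:.3f}, {h['k_max']:.3f}], TV: {h['tv']:.4g}"
            )
        return "\n".join(lines)

    def plot_convergence(self, ax=None):
        """Semilog plot of the relative-change history."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.semilogy(np.arange(1, self.n_iter + 1), self.rel_change, "o-")
        ax.axhline(self.model.config.convergence_tol, ls="--", c="gray")
        ax.set_xlabel("iteration")
        ax.set_ylabel(r"$\|f^{(n+1)}-f^{(n)}\| / \|f^{(n)}\|$")
        return ax

    def plot_tomogram(self, ax=None, **imshow_kw):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        im = ax.imshow(self.tomogram.values.T, origin="lower", **imshow_kw)
        ax.figure.colorbar(im, ax=ax, label="delta")
        return ax


def run_suppression(
    p0: Sinogram,
    absorption_tomogram: TomogramGrid,
    config: ReconConfig | None = None,
    masks: RegionMasks | None = None,
) -> tuple[TomogramGrid, SuppressionResults]:
    """Functional wrapper: build the model, fit, return the final tomogram
    and the full results (tomogram, masks, history, convergence status)."""
    res = ArtefactSuppressionModel(p0, absorption_tomogram, config, masks).fit()
    return res.tomogram, res
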