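"""Total-variation denoising with a nonnegativity constraint.

Solves the ROF-type problem

    minimize_{f ≥ 0}  ‖f − g‖² + λ · TV(f)

where TV is the isotropic, forward-difference, pitch-scaled total
variation returned by :func:`tv_value`.  The solver is a Chambolle-style
dual projection scheme (primal-dual iterations with the dual variable
projected onto the λ-ball and the primal prox handling the data term and
the nonnegativity constraint); a best-iterate safeguard makes the reported
objective non-increasing across iterations.
"""

from __future__ import annotations

import numpy as np

from .grids import TomogramGrid


def _grad(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    gx = np.zeros_like(u)
    gy = np.zeros_like(u)
    gx[:-1, :] = u[1:, :] - u[:-1, :]
    gy[:, :-1] = u[:, 1:] - u[:, :-1]
    return gx, gy


def _div(px: np.ndarray, py: np.ndarray) -> np.ndarray:
    d = np.zeros_like(px)
    d[:-1, :] += px[:-1, :]
    d[1:, :] -= px[:-1, :]
    d[:, :-1] += py[:, :-1]
    d[:, 1:] -= py[:, :-1]
    return d


def tv_value(f: TomogramGrid) -> float:
    """Discrete isotropic total variation, pitch-scaled:
    TV(f) = Σ √((Δx f)² + (Δy f)²) · pitch (forward differences divided by
    the pitch, integrated over pixel area)."""
    gx, gy = _grad(f.values)
    return float(np.sum(np.hypot(gx, gy)) * f.pixel_pitch)


def tv_objective(f: TomogramGrid, g: TomogramGrid, lam: float) -> float:
    """The denoising objective ‖f − g‖²_F + λ·TV(f)."""
    return float(np.sum((f.values - g.values) ** 2)) + lam * tv_value(f)


def tv_denoise(
    f_in: TomogramGrid,
    lam: float,
    n_iter: int = 50,
    tol: float = 1e-5,
) -> TomogramGrid:
    """Approximately minimize ‖f − f_in‖² + λ·TV(f) subject to f ≥ 0.

    Parameters
    ----------
    f_in : TomogramGrid
        Noisy input.
    lam : float
        Regularization weight λ ≥ 0 (units: value × pixel, since TV is
        pitch-scaled).  ``lam = 0`` returns the input unchanged.
    n_iter : int
        Maximum primal-dual iterations.
    tol : float
        Relative objective-change stopping tolerance.
    """
    if lam < 0:
        raise ValueError("λ must be nonnegative")
    if lam == 0:
        return f_in.copy()
    g = f_in.values
    w = lam * f_in.pixel_pitch  # weight of the raw-difference TV term
    tau = sigma = 1.0 / np.sqrt(8.0)
    f = np.clip(g, 0.0, None)
    fbar = f.copy()
    px = np.zeros_like(g)
    py = np.zeros_like(g)

    def objective(u: np.ndarray) -> float:
        gx, gy = _grad(u)
        return float(np.sum((u - g) ** 2) + w * np.sum(np.hypot(gx, gy)))

    best = f.copy()
    best_obj = objective(f)
    prev_obj = best_obj
    for _ in range(int(n_iter)):
        gx, gy = _grad(fbar)
        px += sigma * gx
        py += sigma * gy
        norm = np.maximum(np.hypot(px, py) / w, 1.0)
        px /= norm
        py /= norm
        f_new = np.clip((f + tau * _div(px, py) + 2.0 * tau * g) / (1.0 + 2.0 * tau), 0.0, None)
        fbar = 2.0 * f_new - f
        f = f_new
        obj = objective(f)
        if obj < best_obj:
            best_obj = obj
            best = f.copy()
        if prev_obj > 0 and abs(prev_obj - obj) <= tol * abs(prev_obj):
            break
        prev_obj = obj
    return f_in.with_values(best)
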