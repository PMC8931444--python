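"""Model-based image reconstruction.

Solves the Tikhonov-regularized non-negative least-squares problem

    p0 = argmin_{p >= 0}  ||M p - s||_2^2 + alpha ||p||_2^2

with a projected, restarted Krylov scheme: each outer restart runs LSQR on the
augmented system [M; sqrt(alpha) I] for the unconstrained correction, projects
the iterate onto the non-negative orthant, and restarts; the loop stops when
the active set is stable and the objective has converged.  The regularization
weight alpha can be selected from a candidate grid by the L-curve criterion
(maximum curvature of the log residual-norm vs log solution-norm curve).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse.linalg as spla

from .forward import ForwardModel

__all__ = ["ReconConfig", "ReconImage", "reconstruct", "select_alpha_lcurve"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReconConfig:
    alpha: float = 1e-2
    max_iterations: int = 50        # outer restarts
    inner_iterations: int = 200     # LSQR iterations per restart
    tolerance: float = 1e-8         # relative objective change to stop
    inner_tolerance: float = 1e-10  # LSQR atol/btol
    nonneg: bool = True

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class ReconImage:
    """A reconstructed single-wavelength initial-pressure map.

    Intensities are in arbitrary initial-pressure units.  ``provenance``
    records the solver configuration and convergence diagnostics so a result
    can be traced back to its inputs.
    """

    pixels: np.ndarray
    wavelength: float | None = None
    provenance: dict = field(default_factory=dict)

    @property
    def converged(self) -> bool:
        return bool(self.provenance.get("converged", True))


def _augmented_operator(model: ForwardModel, sqrt_alpha: float):
    M = model.matrix
    m, n = M.shape

    def matvec(x):
        return np.concatenate([M @ x, sqrt_alpha * x])

    def rmatvec(y):
        return M.T @ y[:m] + sqrt_alpha * y[m:]

    return spla.LinearOperator((m + n, n), matvec=matvec, rmatvec=rmatvec)


def _objective(M, s, p, alpha):
    r = M @ p - s
    return float(r @ r + alpha * (p @ p))


def reconstruct(signals: np.ndarray, model: ForwardModel,
                config: ReconConfig, wavelength: float | None = None
                ) -> ReconImage:
    """Invert one signal frame through the forward model.

    Deterministic given inputs and config.  If the outer loop exhausts
    ``max_iterations`` without meeting the tolerance the best iterate is
    returned with ``provenance["converged"] = False``.
    """
    s = np.asarray(signals, dtype=float).ravel()
    if not np.all(np.isfinite(s)):
        raise ValueError("signals must be finite")
    M = model.matrix
    if s.size != M.shape[0]:
        raise ValueError("signals do not conform to the model geometry")

    sqrt_alpha = np.sqrt(config.alpha)
    n = M.shape[1]
    prov = {
        "alpha": config.alpha, "nonneg": config.nonneg,
        "sos_mode": model.sos_mode, "converged": True,
        "outer_iterations": 0, "objective": [],
    }

    if not np.any(s):
        return ReconImage(np.zeros(model.grid_shape), wavelength, prov)

    if not config.nonneg:
        sol = spla.lsqr(M, s, damp=sqrt_alpha,
                        atol=config.inner_tolerance,
                        btol=config.inner_tolerance,
                        iter_lim=config.inner_iterations * config.max_iterations)
        p = sol[0]
        prov["objective"] = [_objective(M, s, p, config.alpha)]
        prov["outer_iterations"] = int(sol[2])
        return ReconImage(p.reshape(model.grid_shape), wavelength, prov)

    A = _augmented_operator(model, sqrt_alpha)
    p = np.zeros(n)
    obj = _objective(M, s, p, config.alpha)
    objs = [obj]
    active = p <= 0
    converged = False
    for outer in range(config.max_iterations):
        # residual of the augmented system at the current iterate
        rhs = np.concatenate([s - M @ p, -sqrt_alpha * p])
        dp = spla.lsqr(A, rhs, atol=config.inner_tolerance,
                       btol=config.inner_tolerance,
                       iter_lim=config.inner_iterations)[0]
        # projected line search: keep the objective non-increasing
        step = 1.0
        p_new, obj_new = p, obj
        for _ in range(20):
            cand = np.maximum(p + step * dp, 0.0)
            cand_obj = _objective(M, s, cand, config.alpha)
            if cand_obj <= obj:
                p_new, obj_new = cand, cand_obj
                break
            step *= 0.5
        active_new = p_new <= 0
        rel_change = (obj - obj_new) / max(obj, np.finfo(float).tiny)
        p, obj = p_new, obj_new
        objs.append(obj)
        if np.array_equal(active_new, active) and rel_change < config.tolerance:
            converged = True
            prov["outer_iterations"] = outer + 1
            break
        active = active_new
    else:
        prov["outer_iterations"] = config.max_iterations

    if not converged:
        prov["converged"] = False
        log.warning("reconstruction did not converge in %d restarts",
                    config.max_iterations)
    prov["objective"] = objs
    return ReconImage(p.reshape(model.grid_shape), wavelength, prov)


def lcurve_points(signals: np.ndarray, model: ForwardModel, alphas,
                  config: ReconConfig | None = None):
    """(log residual norm, log solution norm) for each candidate alpha."""
    base = config or ReconConfig()
    s = np.asarray(signals, dtype=float).ravel()
    pts = []
    for a in alphas:
        cfg = ReconConfig(alpha=float(a), max_iterations=base.max_iterations,
                          inner_iterations=base.inner_iterations,
                          tolerance=base.tolerance,
                          inner_tolerance=base.inner_tolerance,
                          nonneg=base.nonneg)
        img = reconstruct(s, model, cfg)
        p = img.pixels.ravel()
        res = np.linalg.norm(model.matrix @ p - s)
        pts.append((np.log(max(res, np.finfo(float).tiny)),
                    np.log(max(np.linalg.norm(p), np.finfo(float).tiny))))
    return np.asarray(pts)


def select_alpha_lcurve(signals: np.ndarray, model: ForwardModel, alphas,
                        config: ReconConfig | None = None) -> float:
    """Pick alpha at the corner (maximum curvature) of the L-curve.

    Candidates must be strictly increasing.  Curvature of the parametric
    (log-residual, log-norm) curve is estimated by central finite differences
    in log(alpha); ties break toward the larger alpha (smoother image).  A
    single candidate is returned as-is.
    """
    alphas = np.asarray(list(alphas), dtype=float)
    if alphas.size == 1:
        return float(alphas[0])
    if alphas.size < 3:
        raise ValueError("need >= 3 candidate alphas (or exactly 1)")
    if np.any(np.diff(alphas) <= 0):
        raise ValueError("alphas must be strictly increasing")

    pts = lcurve_points(signals, model, alphas, config)
    x, y = pts[:, 0], pts[:, 1]
    if np.allclose(x, x[0]) and np.allclose(y, y[0]):
        raise ValueError("degenerate L-curve: all points identical")

    t = np.log(alphas)
    dx, dy = np.gradient(x, t), np.gradient(y, t)
    ddx, ddy = np.gradient(dx, t), np.gradient(dy, t)
    # floor the speed so numerically flat segments (where both derivatives are
    # dominated by solver noise) get ~zero curvature instead of noise blow-up
    speed_floor = 5e-2 * max(np.max(np.hypot(dx, dy)), np.finfo(float).tiny)
    denom = (dx**2 + dy**2 + speed_floor**2) ** 1.5
    kappa = (dx * ddy - dy * ddx) / denom
    # corner = maximum curvature; ties toward larger alpha
    best = np.flatnonzero(kappa == np.nanmax(kappa))[-1]
    return float(alphas[best])
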