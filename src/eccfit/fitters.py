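"""Classical least-squares ellipse fitters behind a single ``fit`` contract.

Five families are implemented, spanning the standard spectrum from purely
algebraic to approximately geometric objectives:

``algebraic``
    Plain conic least squares with Bookstein's quadratic normalization
    ``A² + B²/2 + C² = 1`` (rotation invariant), solved as a reduced
    generalized symmetric eigenproblem.
``direct``
    Ellipse-specific direct least squares: minimize the algebraic residual
    subject to ``4AC − B² = 1``, a generalized eigenproblem whose unique
    positive eigenvalue guarantees an ellipse.
``stable_direct``
    The numerically stable block decomposition of the same objective, which
    avoids the near-singular 6×6 scatter matrix.
``gradient_weighted``
    Gradient-weighted algebraic fitting: residuals normalized by the mean
    squared gradient of the conic (first-order geometric approximation),
    again a generalized eigenproblem.
``sampson_mle``
    Iterative minimization of the summed Sampson distances (pointwise
    gradient weighting) by Levenberg–Marquardt, initialized from the direct
    fit; non-ellipse iterates are rejected by increasing the damping.

All fitters center the data on its centroid and scale it to RMS radius √2
before solving, and map the conic back afterwards, so results are equivariant
under translation, rotation and scaling of the input.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.linalg

from .errors import DegenerateInputError, NotAnEllipseError, TooFewPointsError
from .geometry import (ConicCoefficients, ParametricEllipse, PointSet, _as_xy,
                       parametric_from_conic)

__all__ = ["FitResult", "fit", "is_ellipse", "METHODS"]

METHODS = ("algebraic", "direct", "stable_direct", "gradient_weighted",
           "sampson_mle")

_MIN_POINTS = 6


@dataclass
class FitResult:
    """Outcome of one ellipse fit.

    ``ellipse`` and ``conic`` are mutually consistent when ``converged`` is
    True; a failed fit carries ``ellipse=None`` and a diagnostic ``message``.
    """

    method: str
    converged: bool
    conic: Optional[ConicCoefficients] = None
    ellipse: Optional[ParametricEllipse] = None
    iterations: int = 0
    message: str = ""


def is_ellipse(c: ConicCoefficients, tol: float = 1e-12) -> bool:
    """Discriminant test: ``B² − 4AC`` negative beyond a scale-aware tolerance."""
    return c.is_ellipse(tol=tol)


def _design_matrix(xy: np.ndarray) -> np.ndarray:
    x, y = xy[:, 0], xy[:, 1]
    return np.column_stack([x * x, x * y, y * y, x, y, np.ones_like(x)])


def _normalize(xy: np.ndarray):
    """Centroid shift + isotropic scaling to RMS radius √2."""
    m = xy.mean(axis=0)
    centered = xy - m
    r = np.sqrt(np.mean(np.sum(centered**2, axis=1)))
    if r == 0:
        raise DegenerateInputError("all points coincide")
    s = np.sqrt(2.0) / r
    return centered * s, m, s


def _denormalize_conic(theta: np.ndarray, m: np.ndarray, s: float) -> np.ndarray:
    """Map a conic fitted in ``u = s (p − m)`` coordinates back to data coordinates."""
    A, B, C, D, E, F = theta
    mx, my = m
    A2 = A * s * s
    B2 = B * s * s
    C2 = C * s * s
    D2 = -2.0 * A2 * mx - B2 * my + D * s
    E2 = -B2 * mx - 2.0 * C2 * my + E * s
    F2 = (A2 * mx * mx + B2 * mx * my + C2 * my * my
          - (D * s) * mx - (E * s) * my + F)
    out = np.array([A2, B2, C2, D2, E2, F2])
    return out / np.linalg.norm(out)


def _fit_algebraic(D: np.ndarray):
    S = D.T @ D
    S11, S12, S22 = S[:3, :3], S[:3, 3:], S[3:, 3:]
    T = -np.linalg.solve(S22, S12.T)
    M = S11 + S12 @ T
    K = np.diag([1.0, 0.5, 1.0])
    w, V = scipy.linalg.eigh(M, K)
    t1 = V[:, np.argmin(w)]
    return np.concatenate([t1, T @ t1]), 0

def _fit_direct(D: np.ndarray):
    S = D.T @ D
    C = np.zeros((6, 6))
    C[0, 2] = C[2, 0] = 2.0
    C[1, 1] = -1.0
    w, V = scipy.linalg.eig(S, C)
    w = np.real(w)
    finite = np.isfinite(w)
    # the ellipse solution is the eigenvector of the single positive
    # eigenvalue; on exact data that eigenvalue degenerates to ±0, so select
    # by the equivalent ellipse condition 4AC − B² > 0 instead
    disc = 4.0 * np.real(V[0]) * np.real(V[2]) - np.real(V[1]) ** 2
    candidates = np.where(finite & (disc > 0))[0]
    if len(candidates) == 0:
        raise NotAnEllipseError("no generalized eigenvector satisfies the "
                                "ellipse constraint")
    if len(candidates) > 1:
        res = [float(np.sum((D @ (np.real(V[:, i])
                                  / np.linalg.norm(np.real(V[:, i])))) ** 2))
               for i in candidates]
        i = candidates[int(np.argmin(res))]
    else:
        i = candidates[0]
    theta = np.real(V[:, i])
    return theta, 0

def _fit_stable_direct(D: np.ndarray):
    D1, D2 = D[:, :3], D[:, 3:]
    S1 = D1.T @ D1
    S2 = D1.T @ D2
    S3 = D2.T @ D2
    T = -np.linalg.solve(S3, S2.T)
    M = S1 + S2 @ T
    # premultiply by the inverse of the constraint block diag-counteridentity
    M = np.array([M[2] / 2.0, -M[1], M[0] / 2.0])
    w, V = np.linalg.eig(M)
    # ellipse condition 4ac − b² > 0 selects the valid eigenvector
    cond = 4.0 * V[0] * V[2] - V[1] ** 2
    valid = np.where(np.real(cond) > 0)[0]
    if len(valid) == 0:
        raise NotAnEllipseError("no eigenvector satisfies 4AC − B² > 0")
    t1 = np.real(V[:, valid[0]])
    return np.concatenate([t1, T @ t1]), 0

def _fit_gradient_weighted(D: np.ndarray, xy: np.ndarray):
    x, y = xy[:, 0], xy[:, 1]
    zero = np.zeros_like(x)
    one = np.ones_like(x)
    Jx = np.column_stack([2 * x, y, zero, one, zero, zero])
    Jy = np.column_stack([zero, x, 2 * y, zero, one, zero])
    S = D.T @ D
    N = Jx.T @ Jx + Jy.T @ Jy
    w, V = scipy.linalg.eig(S, N)
    w = np.real(w)
    finite = np.isfinite(w)
    candidates = np.where(finite & (w >= -1e-12))[0]
    if len(candidates) == 0:
        raise DegenerateInputError("gradient-weighted eigenproblem has no "
                                   "non-negative finite eigenvalue")
    order = candidates[np.argsort(w[candidates])]
    # smallest non-negative eigenvalue; near-ties broken by algebraic residual
    best = order[0]
    ties = [i for i in order if w[i] <= w[best] * (1 + 1e-9) + 1e-15]
    if len(ties) > 1:
        res = [float(np.sum((D @ np.real(V[:, i]) /
                             np.linalg.norm(np.real(V[:, i]))) ** 2)) for i in ties]
        best = ties[int(np.argmin(res))]
    return np.real(V[:, best]), 0


def _sampson_residuals(theta: np.ndarray, D: np.ndarray, Jx: np.ndarray,
                       Jy: np.ndarray):
    f = D @ theta
    gx = Jx @ theta
    gy = Jy @ theta
    g = np.sqrt(gx * gx + gy * gy)
    g = np.where(g > 0, g, 1e-300)
    return f / g, f, gx, gy, g


def _fit_sampson(D: np.ndarray, xy: np.ndarray, max_iter: int = 200,
                 tol: float = 1e-12):
    x, y = xy[:, 0], xy[:, 1]
    zero = np.zeros_like(x)
    one = np.ones_like(x)
    Jx = np.column_stack([2 * x, y, zero, one, zero, zero])
    Jy = np.column_stack([zero, x, 2 * y, zero, one, zero])

    theta, _ = _fit_stable_direct(D)
    theta = theta / np.linalg.norm(theta)

    # scale-invariant barrier ‖θ‖²/(4AC − B²): diverges as the iterate
    # approaches the parabola boundary of the ellipse set, which is also the
    # route by which partial-arc fits escape to infinitely large ellipses
    def barrier(th):
        return float(th @ th / (4 * th[0] * th[2] - th[1] ** 2))

    r0, *_ = _sampson_residuals(theta, D, Jx, Jy)
    alpha = 1e-6 * max(float(r0 @ r0), 1e-12) / barrier(theta) ** 2

    def cost(th):
        r, *_ = _sampson_residuals(th, D, Jx, Jy)
        return float(r @ r) + alpha * barrier(th) ** 2

    lam = 1e-6
    current = cost(theta)
    iters = 0
    for iters in range(1, max_iter + 1):
        r, f, gx, gy, g = _sampson_residuals(theta, D, Jx, Jy)
        # dr/dθ = D/g − (f/g³)(gx·Jx + gy·Jy)
        J = D / g[:, None] - (f / g**3)[:, None] * (gx[:, None] * Jx
                                                   + gy[:, None] * Jy)
        # barrier as one extra least-squares residual √α·‖θ‖²/Δ, Δ = 4AC − B²
        delta = 4 * theta[0] * theta[2] - theta[1] ** 2
        nsq = float(theta @ theta)
        d_delta = np.array([4 * theta[2], -2 * theta[1], 4 * theta[0],
                            0.0, 0.0, 0.0])
        rb = np.sqrt(alpha) * nsq / delta
        Jb = np.sqrt(alpha) * (2 * theta * delta - nsq * d_delta) / delta ** 2
        J = np.vstack([J, Jb])
        r = np.concatenate([r, [rb]])
        JtJ = J.T @ J
        Jtr = J.T @ r
        accepted = False
        for _ in range(50):
            try:
                delta = np.linalg.solve(JtJ + lam * np.diag(np.diag(JtJ)
                                                            + 1e-12), -Jtr)
            except np.linalg.LinAlgError:
                lam *= 10
                continue
            trial = theta + delta
            trial = trial / np.linalg.norm(trial)
            # reject steps that leave the ellipse manifold or raise the cost
            if trial[1]**2 - 4 * trial[0] * trial[2] >= 0:
                lam *= 10
                continue
            new = cost(trial)
            if new <= current:
                theta = trial
                lam = max(lam / 10, 1e-12)
                accepted = True
                break
            lam *= 10
        if not accepted:
            break
        if current - new <= tol * max(current, 1e-300):
            current = new
            break
        current = new
    return theta, iters


def fit(ps: "PointSet | np.ndarray", method: str = "stable_direct") -> FitResult:
    """Fit an ellipse to 2D points with the requested method.

    Parameters
    ----------
    ps : PointSet or (n, 2) array
        At least 6 non-collinear points.
    method : str
        One of ``algebraic``, ``direct``, ``stable_direct``,
        ``gradient_weighted``, ``sampson_mle``.

    Returns
    -------
    FitResult
        ``converged=True`` with a mutually consistent conic/ellipse pair, or
        ``converged=False`` with a diagnostic when an unconstrained method
        returns a non-ellipse conic on the data.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    xy = _as_xy(ps)
    if len(xy) < _MIN_POINTS:
        raise TooFewPointsError(
            f"ellipse fitting needs ≥ {_MIN_POINTS} points, got {len(xy)}")
    centered = xy - xy.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-10 * max(1.0, np.abs(xy).max())) < 2:
        raise DegenerateInputError("points are collinear")

    nxy, m, s = _normalize(xy)
    D = _design_matrix(nxy)
    iters = 0
    try:
        if method == "algebraic":
            theta, iters = _fit_algebraic(D)
        elif method == "direct":
            theta, iters = _fit_direct(D)
        elif method == "stable_direct":
            theta, iters = _fit_stable_direct(D)
        elif method == "gradient_weighted":
            theta, iters = _fit_gradient_weighted(D, nxy)
        else:
            theta, iters = _fit_sampson(D, nxy)
    except (NotAnEllipseError, DegenerateInputError, np.linalg.LinAlgError) as exc:
        return FitResult(method=method, converged=False, message=str(exc))

    coeffs = _denormalize_conic(theta, m, s)
    conic = ConicCoefficients(*coeffs)
    if not conic.is_ellipse():
        return FitResult(method=method, converged=False, conic=conic,
                         iterations=iters,
                         message="fit returned a non-ellipse conic")
    try:
        ellipse = parametric_from_conic(conic)
    except NotAnEllipseError as exc:
        return FitResult(method=method, converged=False, conic=conic,
                         iterations=iters, message=str(exc))
    return FitResult(method=method, converged=True, conic=conic,
                     ellipse=ellipse, iterations=iters)
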