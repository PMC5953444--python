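"""Ellipse representations, conversions and distance measures.

The module provides the two standard representations of an ellipse — the
geometric (center, semi-axes, orientation) form and the general conic
coefficient form ``A x² + B x y + C y² + D x + E y + F = 0`` — together with
conversions between them, the classical eccentricity ``ε = √(a²−b²)/a``, a
per-point *eccentricity* measure ``ξ`` used to weight data points for
augmentation, and orthogonal-distance error evaluation (nearest point on the
ellipse boundary).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, NotAnEllipseError

__all__ = [
    "ParametricEllipse",
    "ConicCoefficients",
    "PointSet",
    "ellipse_eccentricity",
    "conic_from_parametric",
    "parametric_from_conic",
    "eccentricity_from_conic",
    "point_eccentricity",
    "mean_point_eccentricity",
    "orthogonal_distance",
    "orthogonal_distances",
    "rmse",
]


@dataclass(frozen=True)
class ParametricEllipse:
    """Geometric ellipse: center ``(cx, cy)``, semi-axes ``a ≥ b > 0``,
    orientation ``theta`` of the major axis in radians, stored in ``[0, π)``.

    The constructor normalizes its input: if ``b > a`` the axes are swapped
    and ``theta`` rotated by π/2; ``theta`` is reduced modulo π.
    """

    cx: float
    cy: float
    a: float
    b: float
    theta: float = 0.0

    def __post_init__(self) -> None:
        cx, cy, a, b, theta = (float(v) for v in
                               (self.cx, self.cy, self.a, self.b, self.theta))
        if not all(np.isfinite([cx, cy, a, b, theta])):
            raise ValueError("ellipse parameters must be finite")
        if a <= 0 or b <= 0:
            raise ValueError(f"semi-axes must be positive, got a={a}, b={b}")
        if b > a:
            a, b = b, a
            theta += np.pi / 2.0
        theta = float(np.mod(theta, np.pi))
        for name, val in zip(("cx", "cy", "a", "b", "theta"),
                             (cx, cy, a, b, theta)):
            object.__setattr__(self, name, val)

    @property
    def eccentricity(self) -> float:
        """ε = √(a² − b²)/a, in [0, 1)."""
        return ellipse_eccentricity(self.a, self.b)

    def boundary(self, t: np.ndarray | float) -> np.ndarray:
        """Boundary points at parametric angle(s) ``t``; shape ``t.shape + (2,)``."""
        t = np.asarray(t, dtype=float)
        c, s = np.cos(self.theta), np.sin(self.theta)
        u = self.a * np.cos(t)
        v = self.b * np.sin(t)
        x = self.cx + c * u - s * v
        y = self.cy + s * u + c * v
        return np.stack([x, y], axis=-1)

    def to_frame(self, points: np.ndarray) -> np.ndarray:
        """Map points into the ellipse's own (center, theta) frame."""
        p = np.asarray(points, dtype=float)
        c, s = np.cos(self.theta), np.sin(self.theta)
        dx = p[..., 0] - self.cx
        dy = p[..., 1] - self.cy
        return np.stack([c * dx + s * dy, -s * dx + c * dy], axis=-1)

    def to_dict(self) -> dict:
        return {"cx": self.cx, "cy": self.cy, "a": self.a, "b": self.b,
                "theta_rad": self.theta}

    @classmethod
    def from_dict(cls, d: dict) -> "ParametricEllipse":
        return cls(cx=d["cx"], cy=d["cy"], a=d["a"], b=d["b"],
                   theta=d.get("theta_rad", d.get("theta", 0.0)))


@dataclass(frozen=True)
class ConicCoefficients:
    """Coefficients ``(A, B, C, D, E, F)`` of a general conic.

    The representation is projective: rescaling all six coefficients by any
    nonzero factor describes the same curve. A conic is an ellipse iff the
    discriminant ``B² − 4AC`` is negative.
    """

    A: float
    B: float
    C: float
    D: float
    E: float
    F: float

    def __post_init__(self) -> None:
        vals = self.as_array()
        if not np.all(np.isfinite(vals)):
            raise ValueError("conic coefficients must be finite")
        if np.allclose(vals[:3], 0.0):
            raise ValueError("A, B, C must not all vanish")

    def as_array(self) -> np.ndarray:
        return np.array([self.A, self.B, self.C, self.D, self.E, self.F],
                        dtype=float)

    def matrix(self) -> np.ndarray:
        """Symmetric 3×3 matrix of the conic in homogeneous coordinates."""
        A, B, C, D, E, F = self.as_array()
        return np.array([[A, B / 2, D / 2],
                         [B / 2, C, E / 2],
                         [D / 2, E / 2, F]])

    @property
    def discriminant(self) -> float:
        return self.B * self.B - 4.0 * self.A * self.C

    def is_ellipse(self, tol: float = 1e-12) -> bool:
        """True iff ``B² − 4AC < −tol·scale²`` with scale the quadratic-part norm."""
        scale = abs(self.A) + abs(self.B) + abs(self.C)
        return self.discriminant < -tol * scale * scale

    def scaled(self, k: float) -> "ConicCoefficients":
        return ConicCoefficients(*(k * self.as_array()))

    def evaluate(self, points: np.ndarray) -> np.ndarray:
        """Algebraic residual ``Ax² + Bxy + Cy² + Dx + Ey + F`` at points."""
        p = np.asarray(points, dtype=float)
        x, y = p[..., 0], p[..., 1]
        return (self.A * x * x + self.B * x * y + self.C * y * y
                + self.D * x + self.E * y + self.F)

    def to_dict(self) -> dict:
        return dict(zip("ABCDEF", self.as_array().tolist()))

    @classmethod
    def from_dict(cls, d: dict) -> "ConicCoefficients":
        return cls(*(d[k] for k in "ABCDEF"))


@dataclass
class PointSet:
    """Ordered 2D point set with optional per-point angle annotations.

    ``points`` is an ``(n, 2)`` float array; ``angles`` (parametric or polar,
    radians) aligns with ``points`` when present. Order is meaningful: the
    augmentation resampler interpolates between adjacent points.
    """

    points: np.ndarray
    angles: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must have shape (n, 2)")
        if len(self.points) < 1:
            raise DegenerateInputError("a point set needs at least one point")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("points must be finite")
        if self.angles is not None:
            self.angles = np.asarray(self.angles, dtype=float).ravel()
            if len(self.angles) != len(self.points):
                raise ValueError("angles must align with points")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def x(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.points[:, 1]

    def to_csv(self, path) -> None:
        df = pd.DataFrame({"x": self.x, "y": self.y})
        if self.angles is not None:
            df["angle_rad"] = self.angles
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PointSet":
        df = pd.read_csv(path)
        angles = df["angle_rad"].to_numpy() if "angle_rad" in df else None
        return cls(points=df[["x", "y"]].to_numpy(), angles=angles)


def _as_xy(ps: "PointSet | np.ndarray | Sequence") -> np.ndarray:
    if isinstance(ps, PointSet):
        return ps.points
    return np.atleast_2d(np.asarray(ps, dtype=float))


def ellipse_eccentricity(a: float, b: float) -> float:
    """Eccentricity ``√(a² − b²)/a`` of an ellipse with semi-axes ``a, b``.

    The axes may be given in either order; the result is scale invariant and
    lies in ``[0, 1)``. Non-positive axes raise ``ValueError``.
    """
    a, b = float(a), float(b)
    if a <= 0 or b <= 0:
        raise ValueError("semi-axes must be positive")
    if b > a:
        a, b = b, a
    return float(np.sqrt((a - b) * (a + b)) / a)


def conic_from_parametric(e: ParametricEllipse) -> ConicCoefficients:
    """Conic coefficients of a geometric ellipse, normalized to ``B²−4AC = −1``."""
    c, s = np.cos(e.theta), np.sin(e.theta)
    ia2, ib2 = 1.0 / e.a**2, 1.0 / e.b**2
    A = c * c * ia2 + s * s * ib2
    B = 2.0 * c * s * (ia2 - ib2)
    C = s * s * ia2 + c * c * ib2
    D = -2.0 * A * e.cx - B * e.cy
    E = -B * e.cx - 2.0 * C * e.cy
    F = A * e.cx**2 + B * e.cx * e.cy + C * e.cy**2 - 1.0
    disc = B * B - 4.0 * A * C
    k = 1.0 / np.sqrt(-disc)
    return ConicCoefficients(A * k, B * k, C * k, D * k, E * k, F * k)


def parametric_from_conic(c: ConicCoefficients) -> ParametricEllipse:
    """Geometric parameters of an ellipse given in conic form.

    Raises ``NotAnEllipseError`` if the discriminant is non-negative or the
    conic is imaginary/degenerate.
    """
    if not c.is_ellipse():
        raise NotAnEllipseError(
            f"discriminant B²−4AC = {c.discriminant:g} is not negative")
    M = np.array([[c.A, c.B / 2.0], [c.B / 2.0, c.C]])
    try:
        center = np.linalg.solve(2.0 * M, [-c.D, -c.E])
    except np.linalg.LinAlgError as exc:  # pragma: no cover - disc<0 implies invertible
        raise NotAnEllipseError("degenerate quadratic part") from exc
    # constant term after translating the center to the origin
    fc = c.F + 0.5 * (c.D * center[0] + c.E * center[1])
    w, v = np.linalg.eigh(M)
    axes_sq = np.array([-fc / w[0], -fc / w[1]])
    if not np.all(axes_sq > 0):
        raise NotAnEllipseError("conic is imaginary or degenerate")
    # eigh returns ascending eigenvalues: w[0] gives the larger semi-axis
    a, b = np.sqrt(axes_sq)
    theta = np.arctan2(v[1, 0], v[0, 0])
    return ParametricEllipse(cx=center[0], cy=center[1], a=a, b=b, theta=theta)


def eccentricity_from_conic(c: ConicCoefficients) -> float:
    """Eccentricity straight from conic coefficients.

    Uses ``ε² = 2√((A−C)² + B²) / (η(A+C) + √((A−C)² + B²))`` where the sign
    ``η = +1`` when the 3×3 conic determinant is negative and ``−1``
    otherwise, which makes the value invariant under rescaling of the
    coefficients (including by negative factors).
    """
    if not c.is_ellipse():
        raise NotAnEllipseError("eccentricity is defined for ellipses only")
    root = np.hypot(c.A - c.C, c.B)
    eta = 1.0 if np.linalg.det(c.matrix()) < 0 else -1.0
    denom = eta * (c.A + c.C) + root
    if denom <= 0:
        raise NotAnEllipseError("conic is imaginary or degenerate")
    return float(np.sqrt(2.0 * root / denom))


def point_eccentricity(p, e: ParametricEllipse):
    """Eccentricity ``ξ`` of data point(s) relative to an ellipse.

    ``ξ = ε · d_a / (d_a + d_b)`` where ``d_a`` is the orthogonal distance of
    the point to the *minor*-axis line and ``d_b`` the distance to the
    *major*-axis line, both measured in the ellipse's own frame. ``ξ`` lies in
    ``[0, ε]``, is largest for points far along the major axis, and depends
    only on the direction of the point's offset from the center. A point at
    the exact center is assigned ``ξ = 0`` by convention.

    Accepts a single ``(2,)`` point or an ``(..., 2)`` array; returns a float
    or an array of matching leading shape.
    """
    p = np.asarray(p, dtype=float)
    scalar = p.ndim == 1
    uv = e.to_frame(p)
    d_a = np.abs(uv[..., 0])
    d_b = np.abs(uv[..., 1])
    total = d_a + d_b
    with np.errstate(invalid="ignore", divide="ignore"):
        xi = np.where(total > 0, e.eccentricity * d_a / np.where(total > 0, total, 1.0), 0.0)
    return float(xi) if scalar else xi


def mean_point_eccentricity(ps, e: ParametricEllipse) -> float:
    """Arithmetic mean ``ξ̄`` of the per-point eccentricities of a set."""
    xy = _as_xy(ps)
    if len(xy) == 0:
        raise DegenerateInputError("cannot average over an empty point set")
    return float(np.mean(point_eccentricity(xy, e)))


def _first_quadrant_nearest_t(x: np.ndarray, y: np.ndarray,
                              a: float, b: float, iters: int = 60) -> np.ndarray:
    """Parametric angle of the nearest boundary point for ``x, y ≥ 0``.

    The stationarity condition ``f(t) = (b²−a²) sin t cos t + a x sin t −
    b y cos t = 0`` has exactly one root in ``[0, π/2]`` for a first-quadrant
    query point; ``f(0) = −b y ≤ 0`` and ``f(π/2) = a x ≥ 0`` bracket it, so a
    fixed-iteration bisection is robust to the two-local-minima geometry of
    eccentric ellipses and vectorizes cleanly.
    """
    lo = np.zeros_like(x)
    hi = np.full_like(x, np.pi / 2.0)
    coef = b * b - a * a
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        sin_m, cos_m = np.sin(mid), np.cos(mid)
        f = coef * sin_m * cos_m + a * x * sin_m - b * y * cos_m
        take_hi = f > 0
        hi = np.where(take_hi, mid, hi)
        lo = np.where(take_hi, lo, mid)
    return 0.5 * (lo + hi)


def orthogonal_distances(ps, e: ParametricEllipse) -> np.ndarray:
    """Shortest Euclidean distance of each point to the ellipse boundary."""
    xy = _as_xy(ps)
    uv = e.to_frame(xy)
    x = np.abs(uv[:, 0])
    y = np.abs(uv[:, 1])
    t = _first_quadrant_nearest_t(x, y, e.a, e.b)
    return np.hypot(e.a * np.cos(t) - x, e.b * np.sin(t) - y)


def orthogonal_distance(p, e: ParametricEllipse) -> float:
    """Orthogonal distance of a single point to the ellipse boundary.

    Interior points (including the center, whose nearest boundary point is a
    minor vertex) return the positive distance to the boundary.
    """
    return float(orthogonal_distances(np.atleast_2d(np.asarray(p, float)), e)[0])


def rmse(ps, e: ParametricEllipse) -> float:
    """Root mean square orthogonal distance of a point set to an ellipse."""
    xy = _as_xy(ps)
    if len(xy) == 0:
        raise DegenerateInputError("cannot compute RMSE of an empty point set")
    d = orthogonal_distances(xy, e)
    return float(np.sqrt(np.mean(d * d)))
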