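"""Least-squares circle and ellipse fits to border point sets.

The high-density-area borders extracted from density maps are summarised
by algebraic least-squares shapes: the Kasa circle fit (a linear least
squares problem) and the Halir-Flusser numerically stable formulation of
the Fitzgibbon direct ellipse fit (a constrained conic fit guaranteed to
return an ellipse).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["CircleFit", "EllipseFit", "fit_circle", "fit_ellipse", "FitError"]


class FitError(ValueError):
    """Degenerate or insufficient points for a shape fit."""


@dataclass(frozen=True)
class CircleFit:
    cx: float
    cy: float
    r: float

    def contains(self, x, y):
        return (np.asarray(x) - self.cx) ** 2 + (np.asarray(y) - self.cy) ** 2 <= self.r**2


@dataclass(frozen=True)
class EllipseFit:
    cx: float
    cy: float
    a: float  # semi-major
    b: float  # semi-minor
    theta: float  # orientation of the major axis, radians CCW from +x

    def contains(self, x, y):
        dx = np.asarray(x) - self.cx
        dy = np.asarray(y) - self.cy
        c, s = math.cos(self.theta), math.sin(self.theta)
        u = c * dx + s * dy
        v = -s * dx + c * dy
        return (u / self.a) ** 2 + (v / self.b) ** 2 <= 1.0


def fit_circle(points: np.ndarray) -> CircleFit:
    """Kasa algebraic least-squares circle.

    Minimises sum (x^2 + y^2 + D x + E y + F)^2 over (D, E, F), a linear
    problem whose solution gives centre (-D/2, -E/2) and radius
    sqrt(cx^2 + cy^2 - F).  Requires >= 3 non-collinear points.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise FitError("need at least 3 points to fit a circle")
    x, y = pts[:, 0], pts[:, 1]
    A = np.column_stack([x, y, np.ones_like(x)])
    b = -(x**2 + y**2)
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 3:
        raise FitError("points are collinear or otherwise degenerate")
    D, E, F = sol
    cx, cy = -D / 2.0, -E / 2.0
    r2 = cx * cx + cy * cy - F
    if r2 <= 0:
        raise FitError("degenerate circle fit (non-positive radius)")
    return CircleFit(float(cx), float(cy), float(math.sqrt(r2)))


def _conic_to_geometric(coef: np.ndarray) -> EllipseFit:
    """Convert conic coefficients (A, B, C, D, E, F) to geometric form."""
    A, B, C, D, E, F = (float(c) for c in coef)
    M = np.array([[A, B / 2.0], [B / 2.0, C]])
    det = np.linalg.det(M)
    if det <= 0:
        raise FitError("fitted conic is not an ellipse")
    centre = np.linalg.solve(2.0 * M, [-D, -E])
    cx, cy = centre
    # conic value at the centre; semi-axes follow from the eigen-structure
    G = A * cx * cx + B * cx * cy + C * cy * cy + D * cx + E * cy + F
    evals, evecs = np.linalg.eigh(M)
    if G >= 0 or np.any(evals <= 0):
        # eigh may return the matrix negated depending on overall conic sign
        if G <= 0 or np.any(evals >= 0):
            raise FitError("degenerate conic")
        evals, G = -evals, -G
        evecs = evecs
    axes = np.sqrt(-G / evals)
    order = np.argsort(axes)[::-1]  # semi-major first
    a, b = axes[order]
    major = evecs[:, order[0]]
    theta = math.atan2(major[1], major[0]) % math.pi
    return EllipseFit(float(cx), float(cy), float(a), float(b), float(theta))


def fit_ellipse(points: np.ndarray) -> EllipseFit:
    """Direct least-squares ellipse fit (Halir-Flusser formulation).

    Minimises the algebraic conic residual subject to the ellipse
    constraint 4AC - B^2 = 1, solved through the stable 3x3 reduced
    eigenproblem.  Requires >= 6 points in general position.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 6:
        raise FitError("need at least 6 points to fit an ellipse")
    # centre the data for conditioning
    mx, my = pts.mean(axis=0)
    x = pts[:, 0] - mx
    y = pts[:, 1] - my
    D1 = np.column_stack([x * x, x * y, y * y])
    D2 = np.column_stack([x, y, np.ones_like(x)])
    S1 = D1.T @ D1
    S2 = D1.T @ D2
    S3 = D2.T @ D2
    try:
        T = -np.linalg.solve(S3, S2.T)
    except np.linalg.LinAlgError as exc:
        raise FitError("degenerate point configuration") from exc
    M = S1 + S2 @ T
    # premultiply by inv(C1) for the constraint matrix C1 = [[0,0,2],[0,-1,0],[2,0,0]]
    M = np.array([M[2] / 2.0, -M[1], M[0] / 2.0])
    evals, evecs = np.linalg.eig(M)
    cond = 4.0 * evecs[0] * evecs[2] - evecs[1] ** 2
    idx = np.flatnonzero((cond > 0) & np.isfinite(evals))
    if idx.size == 0:
        raise FitError("no ellipse solution (degenerate conic)")
    a1 = np.real(evecs[:, idx[0]])
    coef = np.concatenate([a1, T @ a1])
    A, B, C, D, E, F = coef
    # undo the centering shift
    D0 = D - 2 * A * mx - B * my
    E0 = E - 2 * C * my - B * mx
    F0 = F + A * mx * mx + B * mx * my + C * my * my - D * mx - E * my
    return _conic_to_geometric(np.array([A, B, C, D0, E0, F0]))
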