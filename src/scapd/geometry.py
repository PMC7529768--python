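"""Micropattern geometry: confinement shapes and border queries.

Micropatterns are adhesive islands (a disc or an ellipse) that confine a
stem-cell colony.  All coordinates are in micrometres with the pattern
centred at the origin.  Headings are degrees counter-clockwise from the
+x axis, stored modulo 360.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Micropattern",
    "disc",
    "ellipse",
    "contains",
    "select_interior",
    "exit_check",
    "nearest_exterior_heading",
]

# Defaults are the culture geometry: 97.5 um disc radius, 195.5 x 49 um
# ellipse semi-axes, and a 2 um interior-selection margin that gives a
# clean cut at the pattern border.
DISC_RADIUS = 97.5
ELLIPSE_SEMI_MAJOR = 195.5
ELLIPSE_SEMI_MINOR = 49.0
INTERIOR_MARGIN = 2.0


@dataclass(frozen=True)
class Micropattern:
    """A disc or ellipse confinement region centred at the origin.

    Parameters
    ----------
    kind : {"disc", "ellipse"}
    disc_radius : float
        Disc radius in um (used when ``kind == "disc"``).
    semi_major, semi_minor : float
        Ellipse semi-axes in um (used when ``kind == "ellipse"``),
        with ``semi_major >= semi_minor``.
    interior_margin : float
        Margin in um used by :func:`select_interior`.
    """

    kind: str
    disc_radius: float = DISC_RADIUS
    semi_major: float = ELLIPSE_SEMI_MAJOR
    semi_minor: float = ELLIPSE_SEMI_MINOR
    interior_margin: float = INTERIOR_MARGIN

    def __post_init__(self) -> None:
        if self.kind not in ("disc", "ellipse"):
            raise ValueError(f"unknown micropattern kind {self.kind!r}")
        if min(self.disc_radius, self.semi_major, self.semi_minor) <= 0:
            raise ValueError("all micropattern dimensions must be positive")
        if self.semi_major < self.semi_minor:
            raise ValueError("semi_major must be >= semi_minor")
        if self.interior_margin < 0:
            raise ValueError("interior_margin must be non-negative")
        if self.interior_margin >= self.min_half_dimension:
            raise ValueError("interior_margin leaves an empty interior")

    @property
    def min_half_dimension(self) -> float:
        """Smallest half-dimension of the shape (disc radius or semi-minor)."""
        return self.disc_radius if self.kind == "disc" else self.semi_minor

    @property
    def bounding_half_extents(self) -> tuple[float, float]:
        """(half-width, half-height) of the axis-aligned bounding box."""
        if self.kind == "disc":
            return (self.disc_radius, self.disc_radius)
        return (self.semi_major, self.semi_minor)


def disc(radius: float = DISC_RADIUS, interior_margin: float = INTERIOR_MARGIN) -> Micropattern:
    return Micropattern("disc", disc_radius=radius, interior_margin=interior_margin)


def ellipse(
    semi_major: float = ELLIPSE_SEMI_MAJOR,
    semi_minor: float = ELLIPSE_SEMI_MINOR,
    interior_margin: float = INTERIOR_MARGIN,
) -> Micropattern:
    return Micropattern(
        "ellipse", semi_major=semi_major, semi_minor=semi_minor, interior_margin=interior_margin
    )


def contains(pattern: Micropattern, x: float, y: float, margin: float = 0.0) -> bool:
    """True iff (x, y) lies inside the pattern shrunk by ``margin``.

    The boundary is inclusive.  The ellipse margin shrinks each semi-axis
    by ``margin`` (e.g. 195.5 x 49 with margin 2 becomes 193.5 x 47),
    not a true offset curve.
    """
    if margin < 0:
        raise ValueError("margin must be non-negative")
    if margin >= pattern.min_half_dimension:
        raise ValueError("margin must be smaller than every half-dimension")
    if pattern.kind == "disc":
        r = pattern.disc_radius - margin
        return x * x + y * y <= r * r
    a = pattern.semi_major - margin
    b = pattern.semi_minor - margin
    return (x / a) ** 2 + (y / b) ** 2 <= 1.0


def contains_many(
    pattern: Micropattern, xy: np.ndarray, margin: float = 0.0
) -> np.ndarray:
    """Vectorised :func:`contains` for an (n, 2) coordinate array."""
    if margin < 0 or margin >= pattern.min_half_dimension:
        raise ValueError("invalid margin")
    xy = np.asarray(xy, dtype=float)
    x, y = xy[..., 0], xy[..., 1]
    if pattern.kind == "disc":
        r = pattern.disc_radius - margin
        return x * x + y * y <= r * r
    a = pattern.semi_major - margin
    b = pattern.semi_minor - margin
    return (x / a) ** 2 + (y / b) ** 2 <= 1.0


def select_interior(cells, pattern: Micropattern):
    """Keep only cells more than the interior margin inside the border.

    ``cells`` is a sequence of objects whose first two indexable elements
    are x and y (labels or other fields may follow); order is preserved
    and the input is not modified.
    """
    m = pattern.interior_margin
    return [c for c in cells if contains(pattern, c[0], c[1], m)]


def exit_check(
    pattern: Micropattern, x: float, y: float, heading_deg: float, step_length: float
) -> bool:
    """True iff moving ``step_length`` um along ``heading_deg`` exits the pattern."""
    if step_length < 0:
        raise ValueError("step_length must be non-negative")
    h = math.radians(heading_deg)
    nx = x + step_length * math.cos(h)
    ny = y + step_length * math.sin(h)
    return not contains(pattern, nx, ny, 0.0)


def _ellipse_nearest_boundary_point(
    a: float, b: float, x: float, y: float
) -> tuple[float, float]:
    """Boundary point of the ellipse (a, b) nearest to the interior point (x, y).

    Works in the first quadrant on (|x|, |y|) and restores signs.  The
    stationarity condition for theta in [0, pi/2],

        (a^2 - b^2) sin t cos t - a|x| sin t + b|y| cos t = 0,

    brackets a sign change between its endpoints and is solved by bisection;
    the degenerate axis cases have closed forms.
    """
    px, py = abs(x), abs(y)
    sx = 1.0 if x >= 0 else -1.0
    sy = 1.0 if y >= 0 else -1.0
    c2 = a * a - b * b
    if px == 0.0 and py == 0.0:
        return (0.0, sy * b)  # co-vertex; caller handles the circular case
    if py == 0.0:
        # on the major axis the nearest point is interior unless px is large
        ct = a * px / c2 if c2 > 0 else 2.0
        if ct >= 1.0:
            return (sx * a, 0.0)
        st = math.sqrt(1.0 - ct * ct)
        return (sx * a * ct, sy * b * st)
    if px == 0.0:
        return (0.0, sy * b)

    def h(t: float) -> float:
        st, ct = math.sin(t), math.cos(t)
        return c2 * st * ct - a * px * st + b * py * ct

    lo, hi = 0.0, 0.5 * math.pi  # h(lo) = b*py > 0, h(hi) = -a*px < 0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if h(mid) > 0.0:
            lo = mid
        else:
            hi = mid
    t = 0.5 * (lo + hi)
    return (sx * a * math.cos(t), sy * b * math.sin(t))


def nearest_exterior_heading(
    pattern: Micropattern, x: float, y: float, rng: np.random.Generator | None = None
) -> float:
    """Heading (degrees) from an interior point toward the nearest exterior point.

    For a disc this is the radially outward direction.  At the exact disc
    centre every direction is equivalent; a uniform random heading is drawn
    from ``rng`` (required there).  For an ellipse the nearest boundary
    point is found numerically.
    """
    if not contains(pattern, x, y, 0.0):
        raise ValueError("point must lie inside the micropattern")
    if pattern.kind == "disc":
        if x == 0.0 and y == 0.0:
            if rng is None:
                raise ValueError("rng required at the degenerate disc centre")
            return float(rng.uniform(0.0, 360.0))
        return math.degrees(math.atan2(y, x)) % 360.0
    if x == 0.0 and y == 0.0 and pattern.semi_major == pattern.semi_minor:
        if rng is None:
            raise ValueError("rng required at the degenerate centre")
        return float(rng.uniform(0.0, 360.0))
    bx, by = _ellipse_nearest_boundary_point(pattern.semi_major, pattern.semi_minor, x, y)
    return math.degrees(math.atan2(by - y, bx - x)) % 360.0
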