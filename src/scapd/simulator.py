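"""Agent-based simulation of motile stem cells confined on micropatterns.

Each colony holds two cell types: T+ (brachyury-expressing, primed) and
T- (naive).  Cells move in continuous 2-D coordinates on top of the
micropattern, advanced in 15-minute timesteps for 48 hours (192 steps).
Four elementary motility rules can be switched on independently:

i.   differential speed          (T+ 100 um/h, T- 40 um/h; otherwise both
                                  move at the T- speed)
ii.  differential persistence    (T+ re-polls its heading every 105 min,
                                  T- every 15 min; otherwise every step)
iii. neighbour-directed movement (inverse-square forces within a sensing
                                  radius R: T+ is pushed away from
                                  neighbours, T- pulled toward them, with
                                  Gaussian angular noise of SD sigma)
iv.  border turning              (a cell about to exit turns by a fixed
                                  angle alpha away from the nearest exit
                                  direction; without this rule a blocked
                                  cell re-polls a random heading, bouncing
                                  off the border)

The 16 models enumerate every combination of the four rules.  An improved
variant additionally scales the speed by the velocity ratio
|sum F| / sum |F| of the sensed forces, so cells in balanced-force
configurations slow down.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import Micropattern, _ellipse_nearest_boundary_point, contains

__all__ = [
    "CellTypeParams",
    "SimParams",
    "ModelSpec",
    "Colony",
    "MODEL_RULES",
    "init_colony",
    "compute_force",
    "sample_direction",
    "velocity_ratio",
    "border_turn",
    "step",
    "run_model",
    "neighbor_fraction",
    "PlacementError",
]

TPLUS = "Tplus"
TMINUS = "Tminus"


class PlacementError(RuntimeError):
    """Raised when rejection sampling cannot place cells at the minimum separation."""


@dataclass(frozen=True)
class CellTypeParams:
    """Motility parameters for one cell type.

    v : mean speed, um/h.  persistence_time : minutes a cell keeps its
    heading before re-polling.  sensing_radius : um within which neighbours
    exert inverse-square forces.  sigma : SD (degrees) of the Gaussian noise
    on the force-derived heading.  force_sign : "push" (T+) or "pull" (T-).
    """

    v: float
    persistence_time: float
    sensing_radius: float = 50.0
    sigma: float = 3.0
    force_sign: str = "push"

    def __post_init__(self) -> None:
        if self.v < 0 or self.sensing_radius <= 0 or self.sigma < 0:
            raise ValueError("invalid cell-type parameters")
        if self.persistence_time <= 0:
            raise ValueError("persistence_time must be positive")
        if self.force_sign not in ("push", "pull"):
            raise ValueError("force_sign must be 'push' or 'pull'")


def default_tplus() -> CellTypeParams:
    return CellTypeParams(v=100.0, persistence_time=105.0, force_sign="push")


def default_tminus() -> CellTypeParams:
    return CellTypeParams(v=40.0, persistence_time=15.0, force_sign="pull")


@dataclass(frozen=True)
class SimParams:
    """Global simulation parameters (48 h in 15-min steps at defaults)."""

    timestep: float = 15.0  # minutes
    n_steps: int = 192
    min_separation: float = 2.0  # um, centre-to-centre
    alpha: float = 20.0  # border-turn angle, degrees
    tplus: CellTypeParams = field(default_factory=default_tplus)
    tminus: CellTypeParams = field(default_factory=default_tminus)
    use_velocity_ratio: bool = False

    def __post_init__(self) -> None:
        if self.timestep <= 0 or self.n_steps < 1:
            raise ValueError("invalid timing parameters")
        if self.min_separation <= 0:
            raise ValueError("min_separation must be positive")
        if not 0 < self.alpha < 180:
            raise ValueError("alpha must lie in (0, 180) degrees")

    def persistence_steps(self, cell_type: str) -> int:
        p = self.tplus if cell_type == TPLUS else self.tminus
        steps = p.persistence_time / self.timestep
        if abs(steps - round(steps)) > 1e-9 or round(steps) < 1:
            raise ValueError("persistence_time must be a positive multiple of the timestep")
        return int(round(steps))


# model number -> (rule i, rule ii, rule iii, rule iv)
MODEL_RULES: dict[int, tuple[bool, bool, bool, bool]] = {
    1: (False, False, False, False),
    2: (True, False, False, False),
    3: (False, True, False, False),
    4: (False, False, True, False),
    5: (False, False, False, True),
    6: (True, True, False, False),
    7: (True, False, True, False),
    8: (True, False, False, True),
    9: (False, True, True, False),
    10: (False, True, False, True),
    11: (False, False, True, True),
    12: (True, True, True, False),
    13: (True, True, False, True),
    14: (True, False, True, True),
    15: (False, True, True, True),
    16: (True, True, True, True),
}


@dataclass(frozen=True)
class ModelSpec:
    """One of the 16 rule combinations."""

    rule_velocity: bool
    rule_persistence: bool
    rule_directional: bool
    rule_border: bool

    @classmethod
    def from_number(cls, n: int) -> "ModelSpec":
        if n not in MODEL_RULES:
            raise ValueError(f"model number must be in 1..16, got {n}")
        return cls(*MODEL_RULES[n])

    @property
    def model_number(self) -> int:
        flags = (
            self.rule_velocity,
            self.rule_persistence,
            self.rule_directional,
            self.rule_border,
        )
        for n, f in MODEL_RULES.items():
            if f == flags:
                return n
        raise AssertionError("unreachable")


@dataclass
class Colony:
    """Mutable snapshot of one colony: parallel per-cell arrays."""

    pattern: Micropattern
    ids: list[int]
    types: list[str]
    xs: list[float]
    ys: list[float]
    headings: list[float]
    repoll: list[int]
    timestamp: int = 0

    @property
    def n_cells(self) -> int:
        return len(self.ids)

    def positions(self) -> np.ndarray:
        return np.column_stack([self.xs, self.ys])

    def copy(self) -> "Colony":
        return Colony(
            self.pattern,
            list(self.ids),
            list(self.types),
            list(self.xs),
            list(self.ys),
            list(self.headings),
            list(self.repoll),
            self.timestamp,
        )


def _sample_uniform_in_pattern(pattern: Micropattern, rng: np.random.Generator,
                               margin: float = 0.0) -> tuple[float, float]:
    hx, hy = pattern.bounding_half_extents
    for _ in range(10_000):
        x = rng.uniform(-hx, hx)
        y = rng.uniform(-hy, hy)
        if contains(pattern, x, y, margin):
            return x, y
    raise PlacementError("could not sample a point inside the micropattern")


def init_colony(
    pattern: Micropattern,
    n_cells: int,
    fraction_tplus: float,
    params: SimParams,
    rng: np.random.Generator,
    max_attempts: int = 10_000,
) -> Colony:
    """Seed a colony uniformly at random inside the pattern.

    Placement is rejection-sampled so every pairwise centre distance is at
    least ``params.min_separation``.  The T+ count is
    ``round(n_cells * fraction_tplus)``; headings are uniform.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if not 0 <= fraction_tplus <= 1:
        raise ValueError("fraction_tplus must lie in [0, 1]")
    n_plus = int(round(n_cells * fraction_tplus))
    types = [TPLUS] * n_plus + [TMINUS] * (n_cells - n_plus)
    minsep2 = params.min_separation**2
    xs: list[float] = []
    ys: list[float] = []
    for _ in range(n_cells):
        for attempt in range(max_attempts):
            x, y = _sample_uniform_in_pattern(pattern, rng)
            if all((x - xo) ** 2 + (y - yo) ** 2 >= minsep2 for xo, yo in zip(xs, ys)):
                xs.append(x)
                ys.append(y)
                break
        else:
            raise PlacementError(
                f"could not place {n_cells} cells at separation {params.min_separation} um"
            )
    headings = [float(rng.uniform(0.0, 360.0)) for _ in range(n_cells)]
    repoll = [params.persistence_steps(t) for t in types]
    return Colony(pattern, list(range(n_cells)), types, xs, ys, headings, repoll)


def compute_force(
    focal_xy: tuple[float, float],
    others_xy,
    R: float,
    sign: str,
) -> tuple[float, float]:
    """Net inverse-square force on a focal cell from neighbours within R.

    Each neighbour at Euclidean distance D <= R contributes a unit vector
    along the focal-neighbour axis scaled by 1/D^2 — away from the
    neighbour for ``sign="push"`` (T+), toward it for ``"pull"`` (T-).
    """
    if R <= 0:
        raise ValueError("sensing radius must be positive")
    fx = fy = 0.0
    x0, y0 = focal_xy
    s = 1.0 if sign == "push" else -1.0
    for xo, yo in others_xy:
        dx = x0 - xo
        dy = y0 - yo
        d2 = dx * dx + dy * dy
        if d2 == 0.0:
            raise ValueError("coincident cells: force undefined at D = 0")
        if d2 <= R * R:
            w = s / (d2 * math.sqrt(d2))  # (unit vector) * 1/D^2
            fx += w * dx
            fy += w * dy
    return fx, fy


def _force_and_magnitude_sum(
    i: int, colony: Colony, R: float, sign: str
) -> tuple[float, float, float]:
    """Net force on cell i plus the sum of individual force magnitudes."""
    fx = fy = msum = 0.0
    x0, y0 = colony.xs[i], colony.ys[i]
    s = 1.0 if sign == "push" else -1.0
    for j in range(colony.n_cells):
        if j == i:
            continue
        dx = x0 - colony.xs[j]
        dy = y0 - colony.ys[j]
        d2 = dx * dx + dy * dy
        if d2 <= R * R and d2 > 0.0:
            inv = 1.0 / d2
            msum += inv
            w = s * inv / math.sqrt(d2)
            fx += w * dx
            fy += w * dy
    return fx, fy, msum


def sample_direction(
    force: tuple[float, float], sigma: float, rng: np.random.Generator
) -> float:
    """Heading (degrees) drawn from the force direction with Gaussian noise.

    A zero net force carries no directional information: a uniform heading
    is returned.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    fx, fy = force
    if fx == 0.0 and fy == 0.0:
        return float(rng.uniform(0.0, 360.0))
    angle = math.degrees(math.atan2(fy, fx))
    if sigma > 0:
        angle += float(rng.normal(0.0, sigma))
    return angle % 360.0


def velocity_ratio(forces) -> float:
    """|sum F| / sum |F| over a collection of force vectors, in [0, 1].

    Defined as 1 on an empty collection (no neighbours leave the speed
    unmodulated).
    """
    fx = fy = msum = 0.0
    for gx, gy in forces:
        fx += gx
        fy += gy
        msum += math.hypot(gx, gy)
    if msum == 0.0:
        return 1.0
    return min(math.hypot(fx, fy) / msum, 1.0)


def _wrap_signed(angle: float) -> float:
    """Wrap an angle difference to (-180, 180]."""
    a = (angle + 180.0) % 360.0 - 180.0
    if a == -180.0:
        a = 180.0
    return a


def border_turn(current: float, escape: float, alpha: float) -> float:
    """Rotate ``current`` by alpha away from the ``escape`` heading.

    If the signed difference escape - current is positive the turn is
    clockwise (-alpha), otherwise counter-clockwise (+alpha); an exact tie
    turns counter-clockwise.
    """
    if not 0 < alpha < 180:
        raise ValueError("alpha must lie in (0, 180)")
    diff = _wrap_signed(escape - current)
    if diff > 0:
        return (current - alpha) % 360.0
    return (current + alpha) % 360.0


def _escape_heading(pattern: Micropattern, x: float, y: float,
                    rng: np.random.Generator) -> float:
    # fast in-loop version of geometry.nearest_exterior_heading
    if pattern.kind == "disc":
        if x == 0.0 and y == 0.0:
            return float(rng.uniform(0.0, 360.0))
        return math.degrees(math.atan2(y, x)) % 360.0
    bx, by = _ellipse_nearest_boundary_point(pattern.semi_major, pattern.semi_minor, x, y)
    return math.degrees(math.atan2(by - y, bx - x)) % 360.0


def step(
    colony: Colony,
    model: ModelSpec,
    params: SimParams,
    rng: np.random.Generator,
) -> Colony:
    """Advance every cell by one timestep under the model's active rules.

    Cells are updated in randomised order.  Movement is executed in 1-um
    sub-steps so that border exits and minimum-separation violations
    truncate the move at the last admissible position.  The colony is
    mutated in place and returned.
    """
    pattern = colony.pattern
    n = colony.n_cells
    minsep2 = params.min_separation**2
    dt_h = params.timestep / 60.0
    max_turns = int(360.0 / params.alpha) + 2
    order = rng.permutation(n)
    for i in order:
        i = int(i)
        ctype = colony.types[i]
        ctp = params.tplus if ctype == TPLUS else params.tminus

        # --- heading -----------------------------------------------------
        pers = params.persistence_steps(ctype) if model.rule_persistence else 1
        if colony.repoll[i] > pers:
            colony.repoll[i] = pers  # counters seeded for rule ii; cap when it is off
        forces_cached = None
        if colony.repoll[i] <= 0:
            if model.rule_directional:
                fx, fy, msum = _force_and_magnitude_sum(
                    i, colony, ctp.sensing_radius, ctp.force_sign
                )
                forces_cached = (fx, fy, msum)
                colony.headings[i] = sample_direction((fx, fy), ctp.sigma, rng)
            else:
                colony.headings[i] = float(rng.uniform(0.0, 360.0))
            colony.repoll[i] = pers

        # --- speed -------------------------------------------------------
        v = ctp.v if model.rule_velocity else params.tminus.v
        if params.use_velocity_ratio:
            if forces_cached is None:
                forces_cached = _force_and_magnitude_sum(
                    i, colony, ctp.sensing_radius, ctp.force_sign
                )
            fx, fy, msum = forces_cached
            ratio = 1.0 if msum == 0.0 else min(math.hypot(fx, fy) / msum, 1.0)
            v *= ratio
        step_len = v * dt_h  # um this timestep

        # --- movement in 1-um sub-steps ----------------------------------
        remaining = step_len
        blocked = False
        while remaining > 1e-9 and not blocked:
            d = remaining if remaining < 1.0 else 1.0
            nx = ny = 0.0
            placed = False
            for _ in range(max_turns):
                h = math.radians(colony.headings[i])
                nx = colony.xs[i] + d * math.cos(h)
                ny = colony.ys[i] + d * math.sin(h)
                if contains(pattern, nx, ny, 0.0):
                    placed = True
                    break
                if model.rule_border:
                    esc = _escape_heading(pattern, colony.xs[i], colony.ys[i], rng)
                    colony.headings[i] = border_turn(colony.headings[i], esc, params.alpha)
                else:
                    # without the border rule a blocked cell re-polls its
                    # heading; cells bounce off the border instead of
                    # accumulating against it
                    colony.headings[i] = float(rng.uniform(0.0, 360.0))
            if not placed:
                blocked = True
                break
            ok = True
            for j in range(n):
                if j == i:
                    continue
                ddx = nx - colony.xs[j]
                ddy = ny - colony.ys[j]
                if ddx * ddx + ddy * ddy < minsep2:
                    ok = False
                    break
            if not ok:
                break  # stop at the last admissible sub-step
            colony.xs[i] = nx
            colony.ys[i] = ny
            remaining -= d

        colony.repoll[i] -= 1

    colony.timestamp += 1
    return colony


def run_model(
    model: ModelSpec,
    params: SimParams,
    pattern: Micropattern,
    n_colonies: int,
    rng: np.random.Generator,
    n_cells: int = 6,
    fraction_tplus: float = 0.5,
    step_callback=None,
) -> list[Colony]:
    """Simulate independent colonies to their final snapshot.

    Each colony is freshly seeded and advanced ``params.n_steps`` steps.
    ``step_callback(colony)``, if given, is invoked after every step (used
    for trajectory checks).  Fully reproducible from ``rng``.
    """
    if n_colonies < 1:
        raise ValueError("n_colonies must be >= 1")
    finals: list[Colony] = []
    for _ in range(n_colonies):
        colony = init_colony(pattern, n_cells, fraction_tplus, params, rng)
        for _ in range(params.n_steps):
            step(colony, model, params, rng)
            if step_callback is not None:
                step_callback(colony)
        finals.append(colony)
    return finals


def neighbor_fraction(points: np.ndarray, radius: float) -> float:
    """Fraction of cells with at least one other cell within ``radius`` um."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        return 0.0
    from scipy.spatial import cKDTree

    tree = cKDTree(pts)
    counts = tree.query_ball_point(pts, r=radius, return_length=True)
    return float(np.mean(counts > 1))  # each point counts itself once
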