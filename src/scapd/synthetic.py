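"""Synthetic reference colonies emulating patterned micropattern cultures.

The imaging dataset behind the reference patterns (186 disc and 152
ellipse colonies) is not publicly deposited, so this module draws
pseudo-empirical colonies whose pooled spatial statistics reproduce the
*qualitative* organisation reported for 48-h cultures: naive T- cells
concentrated at the pattern centre, primed T+ cells preferring the disc
rim or the ellipse tips.  These are labelled stand-ins for testing the
evaluation pipeline, not reconstructions of the data.

Spatial laws (defaults):

* T- (both patterns): per colony, a compact cluster — the cluster centre
  is uniform over the pattern scaled to half its dimensions, and cells
  scatter around it with an isotropic 10 um SD.  Pooled over colonies this
  yields the flat-topped central density that real aggregated colonies
  show (a single pooled Gaussian cannot: the mass of a Gaussian inside
  its half-maximum contour is ~0.5 regardless of its SD, far below the
  ~0.82-0.85 central total densities that patterned cultures produce).
* T+ on the disc: radius drawn as (R - margin) x Beta(6, 2) (rim-shifted),
  angle uniform.
* T+ on the ellipse: equal mixture of two isotropic Gaussians (SD 20 um)
  centred at the tips (+-(a - 30) um, 0), truncated to the pattern.

Every colony respects the 2 um minimum centre separation via rejection
sampling, mirroring the simulator's packing rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import Micropattern, contains
from .simulator import PlacementError

__all__ = ["PatternSpec", "generate_reference", "generate_null_reference"]

TPLUS = "Tplus"
TMINUS = "Tminus"


@dataclass(frozen=True)
class PatternSpec:
    """Sampling law of the synthetic reference colonies."""

    cells_per_colony: int = 6
    fraction_tplus: float = 0.5
    n_colonies: int | None = None  # default: 186 disc / 152 ellipse
    cluster_center_scale: float = 0.7  # T- cluster centres: pattern scaled by this
    cluster_sd: float = 15.0  # um within-colony T- scatter
    tplus_beta: tuple[float, float] = (6.0, 2.0)  # disc radial preference
    tip_offset: float = 30.0  # um inward from the semi-major vertex
    tip_sd: float = 20.0  # um
    min_separation: float = 2.0  # um
    margin: float = 2.0  # um interior-selection margin

    def __post_init__(self) -> None:
        if self.cells_per_colony < 1:
            raise ValueError("cells_per_colony must be >= 1")
        if not 0 <= self.fraction_tplus <= 1:
            raise ValueError("fraction_tplus must lie in [0, 1]")
        if not 0 < self.cluster_center_scale <= 1:
            raise ValueError("cluster_center_scale must lie in (0, 1]")
        if min(self.cluster_sd, self.tip_sd, self.min_separation) <= 0:
            raise ValueError("spatial-law parameters must be positive")

    def resolved_n_colonies(self, pattern: Micropattern) -> int:
        if self.n_colonies is not None:
            return self.n_colonies
        return 186 if pattern.kind == "disc" else 152


def _draw_cluster_center(
    pattern: Micropattern, spec: PatternSpec, rng: np.random.Generator
) -> tuple[float, float]:
    """Uniform point inside the pattern scaled by ``cluster_center_scale``."""
    s = spec.cluster_center_scale
    hx, hy = pattern.bounding_half_extents
    for _ in range(10_000):
        x = rng.uniform(-hx * s, hx * s)
        y = rng.uniform(-hy * s, hy * s)
        if pattern.kind == "disc":
            if x * x + y * y <= (pattern.disc_radius * s) ** 2:
                return x, y
        elif (x / (pattern.semi_major * s)) ** 2 + (y / (pattern.semi_minor * s)) ** 2 <= 1.0:
            return x, y
    raise PlacementError("cluster-centre sampling failed")


def _draw_tminus(
    pattern: Micropattern,
    spec: PatternSpec,
    rng: np.random.Generator,
    center: tuple[float, float],
):
    for _ in range(10_000):
        x, y = rng.normal(center, spec.cluster_sd)
        if contains(pattern, x, y, spec.margin):
            return x, y
    raise PlacementError("T- sampling failed")


def _draw_tplus(pattern: Micropattern, spec: PatternSpec, rng: np.random.Generator):
    if pattern.kind == "disc":
        rmax = pattern.disc_radius - spec.margin
        r = rmax * rng.beta(*spec.tplus_beta)
        th = rng.uniform(0.0, 2.0 * np.pi)
        return r * np.cos(th), r * np.sin(th)
    cx = pattern.semi_major - spec.tip_offset
    for _ in range(10_000):
        side = 1.0 if rng.random() < 0.5 else -1.0
        x = rng.normal(side * cx, spec.tip_sd)
        y = rng.normal(0.0, spec.tip_sd)
        if contains(pattern, x, y, spec.margin):
            return x, y
    raise PlacementError("T+ tip sampling failed")


def _draw_uniform(pattern: Micropattern, spec: PatternSpec, rng: np.random.Generator):
    hx, hy = pattern.bounding_half_extents
    for _ in range(10_000):
        x = rng.uniform(-hx, hx)
        y = rng.uniform(-hy, hy)
        if contains(pattern, x, y, spec.margin):
            return x, y
    raise PlacementError("uniform sampling failed")


def _generate(
    pattern: Micropattern,
    spec: PatternSpec,
    rng: np.random.Generator,
    make_draws,
) -> pd.DataFrame:
    n_colonies = spec.resolved_n_colonies(pattern)
    n_plus = int(round(spec.cells_per_colony * spec.fraction_tplus))
    minsep2 = spec.min_separation**2
    rows = []
    for colony_id in range(n_colonies):
        draw_plus, draw_minus = make_draws(rng)
        placed: list[tuple[float, float]] = []
        types = [TPLUS] * n_plus + [TMINUS] * (spec.cells_per_colony - n_plus)
        for cell_id, ct in enumerate(types):
            draw = draw_plus if ct == TPLUS else draw_minus
            for _ in range(10_000):
                x, y = draw(pattern, spec, rng)
                if all((x - xo) ** 2 + (y - yo) ** 2 >= minsep2 for xo, yo in placed):
                    placed.append((x, y))
                    rows.append((colony_id, cell_id, ct, x, y))
                    break
            else:
                raise PlacementError("could not satisfy the minimum separation")
    return pd.DataFrame(
        rows, columns=["colony_id", "cell_id", "cell_type", "x_um", "y_um"]
    )


def generate_reference(
    pattern: Micropattern, spec: PatternSpec, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw patterned pseudo-empirical colonies (centre T-, rim/tip T+)."""

    def make_draws(r: np.random.Generator):
        center = _draw_cluster_center(pattern, spec, r)

        def draw_minus(pat, sp, rr):
            return _draw_tminus(pat, sp, rr, center)

        return _draw_tplus, draw_minus

    return _generate(pattern, spec, rng, make_draws)


def generate_null_reference(
    pattern: Micropattern, spec: PatternSpec, rng: np.random.Generator
) -> pd.DataFrame:
    """Control draw with both cell types uniform over the pattern interior."""
    return _generate(pattern, spec, rng, lambda r: (_draw_uniform, _draw_uniform))
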