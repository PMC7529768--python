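"""The stem-cell aggregate pattern distance (SCAPD).

SCAPD compares the spatial organisation of a simulated cell population
against reference (empirical) colonies, separately for the two cell
types, through four steps applied to each type's pooled positions:

1. a normalised kernel density map on the pattern's fixed 256 x 256 grid;
2. a threshold at the midpoint of the map's extreme values,
   T = (max g_i + min g_i) / 2, whose iso-level contours mark the borders
   of the high-density areas (HDAs);
3. a least-squares circle (disc patterns) or ellipse (ellipse patterns)
   fitted to each border;
4. symmetrisation: because seeding is random there is no preferred
   direction, so disc borders are re-centred on the pattern centre and
   ellipse tip pairs are mirrored across both axes with shared axes.

The reference total density T_e of each type is the sum of that type's
grid values falling within its symmetrised border region.  A model run is
scored by pooling its cells per type, mapping them with the reference
map's estimator settings, integrating over the *reference* borders, and

    SCAPD = |T_e(T+) - T_m(T+)| + |T_e(T-) - T_m(T-)|

which is 0 when the model reproduces the reference pattern exactly and at
most 2.

HDA topology per pattern and type: the T- HDA is a single central shape
(mass counted inside); the disc T+ HDA is the annulus between a fitted
inner circle and the pattern border (mass counted inside the pattern but
outside the circle), reflecting the rim preference of T+ cells; the
ellipse T+ HDA is a mirrored pair of tip ellipses.  The chosen side is
auto-checked against the threshold and flipped with a warning if the mean
density on that side does not exceed it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import measure

from .geometry import Micropattern
from .kde import DensityMap, estimate_density
from .shapes import CircleFit, EllipseFit, FitError, fit_circle, fit_ellipse

__all__ = [
    "FittedBorder",
    "GroundTruth",
    "SCAPDResult",
    "threshold",
    "extract_border_points",
    "symmetrize",
    "total_density",
    "build_ground_truth",
    "scapd",
    "TPLUS",
    "TMINUS",
]

TPLUS = "Tplus"
TMINUS = "Tminus"


def threshold(dmap: DensityMap) -> float:
    """HDA threshold: midpoint of the map's extreme grid values."""
    v = dmap.values
    return float((v.max() + v.min()) / 2.0)


def extract_border_points(dmap: DensityMap, level: float) -> list[np.ndarray]:
    """Iso-level contours of the density surface at ``level``, in um.

    Marching squares with linear interpolation on the grid-cell centres;
    contours with fewer than 6 points are discarded as noise.  Returned
    arrays are (k, 2) with columns (x, y), sorted by descending enclosed
    area.
    """
    v = dmap.values
    if not (v.min() < level < v.max()):
        raise ValueError("threshold must lie strictly between the map extremes")
    dx = float(dmap.x_centers[1] - dmap.x_centers[0])
    dy = float(dmap.y_centers[1] - dmap.y_centers[0])
    x0 = float(dmap.x_centers[0])
    y0 = float(dmap.y_centers[0])
    contours = []
    for c in measure.find_contours(v, level):
        if np.array_equal(c[0], c[-1]):
            c = c[:-1]  # drop the duplicated closing vertex (unbiased fits)
        if len(c) < 6:
            continue
        xy = np.column_stack([x0 + c[:, 1] * dx, y0 + c[:, 0] * dy])
        contours.append(xy)
    if not contours:
        raise ValueError("no contour found at the given threshold")
    contours.sort(key=_enclosed_area, reverse=True)
    return contours


def _enclosed_area(contour: np.ndarray) -> float:
    """Absolute shoelace area of a (possibly open) contour."""
    x, y = contour[:, 0], contour[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


@dataclass
class FittedBorder:
    """Symmetrised HDA border: one shape or a mirrored tip pair.

    ``hda_side`` says on which side of the shape(s) the high-density mass
    lies: "inside" the shape(s), or "outside" them but inside the
    micropattern (the annulus case).
    """

    shape: str  # "circle" | "ellipse"
    components: list = field(default_factory=list)  # CircleFit | EllipseFit
    hda_side: str = "inside"
    symmetrized: bool = False

    def region_mask(self, xg: np.ndarray, yg: np.ndarray, pattern_mask: np.ndarray) -> np.ndarray:
        """Boolean HDA mask over broadcastable grid coordinates."""
        inside = np.zeros(np.broadcast(xg, yg).shape, dtype=bool)
        for comp in self.components:
            inside |= comp.contains(xg, yg)
        if self.hda_side == "inside":
            return inside
        return pattern_mask & ~inside


def symmetrize(fits: list, pattern: Micropattern) -> FittedBorder:
    """Remove the arbitrary orientation of fitted HDA borders.

    Disc: the circle keeps its radius, centre moved to (0, 0).  Ellipse,
    central HDA: centre moved to (0, 0), axes kept, axis-aligned.  Ellipse,
    tip pair: shared semi-axes set to the maxima over the two fits, centres
    at (+-mean(|x1|, |x2|), 0), axis-aligned.
    """
    if pattern.kind == "disc":
        if len(fits) != 1 or not isinstance(fits[0], CircleFit):
            raise ValueError("disc patterns take exactly one fitted circle")
        c = fits[0]
        return FittedBorder("circle", [CircleFit(0.0, 0.0, c.r)], symmetrized=True)
    if not all(isinstance(f, EllipseFit) for f in fits):
        raise ValueError("ellipse patterns take fitted ellipses")
    if len(fits) == 1:
        e = fits[0]
        return FittedBorder(
            "ellipse", [EllipseFit(0.0, 0.0, e.a, e.b, 0.0)], symmetrized=True
        )
    if len(fits) == 2:
        e1, e2 = fits
        a = max(e1.a, e2.a)
        b = max(e1.b, e2.b)
        xc = (abs(e1.cx) + abs(e2.cx)) / 2.0
        return FittedBorder(
            "ellipse",
            [EllipseFit(xc, 0.0, a, b, 0.0), EllipseFit(-xc, 0.0, a, b, 0.0)],
            symmetrized=True,
        )
    raise ValueError("expected one central fit or a tip pair")


def _grid_mesh(dmap: DensityMap) -> tuple[np.ndarray, np.ndarray]:
    return np.meshgrid(dmap.x_centers, dmap.y_centers)


def _pattern_mask(dmap: DensityMap, pattern: Micropattern) -> np.ndarray:
    xg, yg = _grid_mesh(dmap)
    if pattern.kind == "disc":
        return xg**2 + yg**2 <= pattern.disc_radius**2
    return (xg / pattern.semi_major) ** 2 + (yg / pattern.semi_minor) ** 2 <= 1.0


def total_density(dmap: DensityMap, border: FittedBorder, pattern: Micropattern) -> float:
    """Sum of grid values whose cell centres fall in the HDA region."""
    xg, yg = _grid_mesh(dmap)
    mask = border.region_mask(xg, yg, _pattern_mask(dmap, pattern))
    return float(dmap.values[mask].sum())


def _fit_hda_border(
    dmap: DensityMap, pattern: Micropattern, cell_type: str
) -> FittedBorder:
    """Steps 2-4 for one cell type: threshold, contours, fit, symmetrise."""
    level = threshold(dmap)
    contours = extract_border_points(dmap, level)
    if pattern.kind == "disc":
        if cell_type == TMINUS:
            fits = [fit_circle(contours[0])]  # largest contour: central HDA
            border = symmetrize(fits, pattern)
            border.hda_side = "inside"
        else:
            # the rim annulus is bounded below by its hole: the innermost
            # contour that winds around the pattern centre (small noise
            # islands elsewhere do not qualify)
            fits = [fit_circle(_innermost_enclosing(contours))]
            border = symmetrize(fits, pattern)
            border.hda_side = "outside"
    else:
        if cell_type == TMINUS:
            fits = [_fit_ellipse_robust(contours[0])]
            border = symmetrize(fits, pattern)
            border.hda_side = "inside"
        else:
            if len(contours) >= 2:
                fits = [_fit_ellipse_robust(c) for c in contours[:2]]
            else:
                warnings.warn(
                    "expected a tip pair for ellipse T+ cells but found one "
                    "contour; fitting a single central ellipse",
                    stacklevel=2,
                )
                fits = [_fit_ellipse_robust(contours[0])]
            border = symmetrize(fits, pattern)
            border.hda_side = "inside"
    return _auto_check_side(border, dmap, pattern, level)


def _innermost_enclosing(contours: list[np.ndarray]) -> np.ndarray:
    """Smallest-area contour winding around the origin (else the largest one)."""
    enclosing = [c for c in contours if _winds_around_origin(c)]
    if enclosing:
        return min(enclosing, key=_enclosed_area)
    return contours[0]


def _winds_around_origin(contour: np.ndarray) -> bool:
    angles = np.arctan2(contour[:, 1], contour[:, 0])
    dwind = np.diff(np.unwrap(np.concatenate([angles, angles[:1]])))
    return abs(float(dwind.sum())) > np.pi  # ~2*pi for an enclosing loop


def _fit_ellipse_robust(contour: np.ndarray) -> EllipseFit:
    """Ellipse fit with a circumscribed-circle fallback for arc-like contours."""
    try:
        return fit_ellipse(contour)
    except FitError:
        c = fit_circle(contour)
        return EllipseFit(c.cx, c.cy, c.r, c.r, 0.0)


def _auto_check_side(
    border: FittedBorder, dmap: DensityMap, pattern: Micropattern, level: float
) -> FittedBorder:
    """Flip hda_side if the mean density on the chosen side is not above T."""
    xg, yg = _grid_mesh(dmap)
    pmask = _pattern_mask(dmap, pattern)
    mask = border.region_mask(xg, yg, pmask)
    if mask.sum() == 0 or float(dmap.values[mask].mean()) <= level:
        flipped = "outside" if border.hda_side == "inside" else "inside"
        other = FittedBorder(border.shape, border.components, flipped, border.symmetrized)
        omask = other.region_mask(xg, yg, pmask)
        if omask.sum() > 0 and float(dmap.values[omask].mean()) > level:
            warnings.warn(
                f"mean HDA density did not exceed the threshold; flipping "
                f"hda_side to {flipped!r}",
                stacklevel=3,
            )
            return other
    return border


@dataclass
class GroundTruth:
    """Reference borders and total densities built from empirical-style data."""

    pattern: Micropattern
    borders: dict[str, FittedBorder]
    te: dict[str, float]
    bandwidths: dict[str, tuple[float, float]]
    thresholds: dict[str, float]


@dataclass
class SCAPDResult:
    tm: dict[str, float]
    te: dict[str, float]
    scapd: float


def _pooled_points(tables: pd.DataFrame, cell_type: str) -> np.ndarray:
    sub = tables[tables["cell_type"] == cell_type]
    return sub[["x_um", "y_um"]].to_numpy(dtype=float)


def build_ground_truth(tables: pd.DataFrame, pattern: Micropattern) -> GroundTruth:
    """Run the full border pipeline per cell type on pooled reference colonies.

    ``tables`` is a cell table with columns colony_id, cell_id, cell_type
    (Tplus/Tminus), x_um, y_um.
    """
    borders: dict[str, FittedBorder] = {}
    te: dict[str, float] = {}
    bandwidths: dict[str, tuple[float, float]] = {}
    thresholds: dict[str, float] = {}
    for ct in (TPLUS, TMINUS):
        pts = _pooled_points(tables, ct)
        if len(pts) < 10:
            raise ValueError(f"need at least 10 pooled {ct} points, got {len(pts)}")
        dmap = estimate_density(pts, pattern)
        border = _fit_hda_border(dmap, pattern, ct)
        borders[ct] = border
        te[ct] = total_density(dmap, border, pattern)
        bandwidths[ct] = dmap.bandwidths
        thresholds[ct] = threshold(dmap)
    return GroundTruth(pattern, borders, te, bandwidths, thresholds)


def model_density_maps(
    gt: GroundTruth, tables: pd.DataFrame
) -> dict[str, DensityMap]:
    """Density maps of model output using the ground truth's estimator settings."""
    maps = {}
    for ct in (TPLUS, TMINUS):
        pts = _pooled_points(tables, ct)
        if len(pts) < 2:
            raise ValueError(f"model output contains too few {ct} cells")
        maps[ct] = estimate_density(pts, gt.pattern, bandwidths=gt.bandwidths[ct])
    return maps


def scapd(gt: GroundTruth, model_tables: pd.DataFrame) -> SCAPDResult:
    """SCAPD between a ground truth and pooled model colonies (Eq. above)."""
    maps = model_density_maps(gt, model_tables)
    tm = {
        ct: total_density(maps[ct], gt.borders[ct], gt.pattern) for ct in (TPLUS, TMINUS)
    }
    dist = abs(gt.te[TPLUS] - tm[TPLUS]) + abs(gt.te[TMINUS] - tm[TMINUS])
    return SCAPDResult(tm=tm, te=dict(gt.te), scapd=float(dist))
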