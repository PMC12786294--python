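"""Nuclear positioning of labeled loci.

A locus's radial position is scored by the ratio L/D, where L is the
shortest distance from the spot to the nuclear boundary and D is the
distance from the nuclear centroid to the boundary measured along the ray
through the spot. The ratio is 0 at the periphery and 1 at the centroid;
for a circular nucleus it equals 1 - r/R exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from shapely.geometry import LineString, Point, Polygon

__all__ = ["NuclearGeometry", "PositionRatio", "nuclear_position_ratio", "position_cohort_summary", "boundary_from_mask"]


@dataclass
class NuclearGeometry:
    """Closed nuclear boundary polygon with its area centroid.

    Boundary and spots must share units (px or µm, consistently); the
    ratio is unit-free.
    """

    boundary: list[tuple[float, float]]
    _polygon: Polygon = field(init=False, repr=False)

    def __post_init__(self) -> None:
        poly = Polygon(self.boundary)
        if not poly.is_valid or poly.area <= 0:
            raise ValueError("boundary must be a simple (non-self-intersecting) polygon")
        self._polygon = poly
        if not poly.contains(poly.centroid):
            raise ValueError(
                "polygon centroid lies outside the boundary; a star-shaped or "
                "convex nucleus outline is required"
            )

    @property
    def polygon(self) -> Polygon:
        return self._polygon

    @property
    def centroid(self) -> tuple[float, float]:
        c = self._polygon.centroid
        return (c.x, c.y)


@dataclass
class PositionRatio:
    l: float
    d: float
    ratio: float
    multi_crossing: bool = False


def nuclear_position_ratio(
    geometry: NuclearGeometry, spot: tuple[float, float]
) -> PositionRatio:
    """Compute (L, D, L/D) for one spot.

    L is the minimum distance from the spot to the boundary; D is measured
    from the centroid to the boundary intersection of the ray through the
    spot (the first intersection beyond the spot for non-convex outlines,
    flagged when the ray crosses the boundary more than once). A spot at
    the centroid returns ratio 1 by continuity; a spot on the boundary
    returns 0.
    """
    poly = geometry.polygon
    p = Point(spot)
    if not (poly.contains(p) or poly.touches(p)):
        raise ValueError(f"spot {spot} lies outside the nuclear boundary")

    ring = poly.exterior
    l_dist = float(ring.distance(p))

    cx, cy = geometry.centroid
    dx, dy = spot[0] - cx, spot[1] - cy
    norm = float(np.hypot(dx, dy))
    if norm == 0:
        return PositionRatio(l=l_dist, d=l_dist, ratio=1.0)
    ux, uy = dx / norm, dy / norm

    # extend the centroid->spot ray well past any boundary point
    minx, miny, maxx, maxy = poly.bounds
    reach = 2.0 * float(np.hypot(maxx - minx, maxy - miny)) + norm
    ray = LineString([(cx, cy), (cx + ux * reach, cy + uy * reach)])
    inter = ray.intersection(ring)
    if inter.is_empty:
        raise ValueError("centroid ray does not intersect the boundary")
    pts = []
    if inter.geom_type == "Point":
        pts = [inter]
    elif inter.geom_type == "MultiPoint":
        pts = list(inter.geoms)
    else:  # collinear overlap segments: take their endpoints
        for g in getattr(inter, "geoms", [inter]):
            pts.extend(Point(c) for c in g.coords)
    dists = sorted(float(np.hypot(q.x - cx, q.y - cy)) for q in pts)
    beyond = [d for d in dists if d >= norm - 1e-12]
    d_dist = beyond[0] if beyond else dists[-1]
    return PositionRatio(
        l=l_dist, d=float(d_dist), ratio=l_dist / d_dist, multi_crossing=len(dists) > 1
    )


def boundary_from_mask(mask: np.ndarray, decimation_tol: float = 0.5) -> NuclearGeometry:
    """Polygonize a binary nucleus mask at pixel resolution.

    The marching-squares contour is decimated (Douglas–Peucker, tolerance
    in px) to stabilize ray intersections against pixel-level jaggedness.
    """
    from skimage import measure

    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        raise ValueError("mask contains no boundary")
    contour = max(contours, key=len)  # (row, col) = (y, x)
    poly = Polygon([(c, r) for r, c in contour]).simplify(decimation_tol)
    return NuclearGeometry(list(poly.exterior.coords))


@dataclass
class CohortComparison:
    """Group means ± SEM and two-sample tests for two position-ratio cohorts."""

    mean_a: float
    sem_a: float
    n_a: int
    mean_b: float
    sem_b: float
    n_b: int
    t_statistic: float
    t_pvalue: float
    rank_statistic: float
    rank_pvalue: float

    def summary(self) -> str:
        return (
            f"group A: {self.mean_a:.3f} ± {self.sem_a:.3f} (n={self.n_a})\n"
            f"group B: {self.mean_b:.3f} ± {self.sem_b:.3f} (n={self.n_b})\n"
            f"t test: t={self.t_statistic:.3f}, p={self.t_pvalue:.3g}\n"
            f"rank-sum: U={self.rank_statistic:.3f}, p={self.rank_pvalue:.3g}"
        )


def position_cohort_summary(
    ratios_a: np.ndarray, ratios_b: np.ndarray
) -> CohortComparison:
    """Compare two groups of L/D ratios.

    Both a two-sided two-sample t test and a Mann–Whitney rank-sum test
    are reported; radial-position data are bounded in [0, 1] and often
    skewed, so the rank test is the safer default while the t test eases
    comparison with normal-theory summaries.
    """
    a = np.asarray(ratios_a, float)
    b = np.asarray(ratios_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 spots for a SEM")
    t_stat, t_p = stats.ttest_ind(a, b)
    try:
        u_stat, u_p = stats.mannwhitneyu(a, b, alternative="two-sided")
    except ValueError:  # identical constant groups
        u_stat, u_p = float(len(a) * len(b) / 2), 1.0
    return CohortComparison(
        mean_a=float(a.mean()),
        sem_a=float(a.std(ddof=1) / np.sqrt(len(a))),
        n_a=len(a),
        mean_b=float(b.mean()),
        sem_b=float(b.std(ddof=1) / np.sqrt(len(b))),
        n_b=len(b),
        t_statistic=float(t_stat),
        t_pvalue=float(t_p),
        rank_statistic=float(u_stat),
        rank_pvalue=float(u_p),
    )
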