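"""Domain types and geometric primitives for digitized tooth sections.

All geometry lives in a 2-D longitudinal section plane with coordinates in
micrometres (µm).  By convention the dentine-horn (cusp) tip sits at the
origin and the cervical direction is +u; enamel lies on the +v side of the
enamel-dentine junction (EDJ) for the synthetic sections produced by
:mod:`enamelgrowth.simulate`.

The two geometric operations the measurement algorithms rest on are
:func:`arc_position` (arc length of a point along the EDJ measured from the
cusp tip) and :func:`intersect_with_edj` (where an incremental line meets
the EDJ).  Both are thin, validated layers over shapely.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from shapely.geometry import LineString, MultiPoint, Point

__all__ = [
    "GeometryError",
    "Point2D",
    "Polyline",
    "EDJCurve",
    "IncrementLine",
    "EnamelSection",
    "DSRSample",
    "CERSegment",
    "CrownGrowthSummary",
    "arc_position",
    "intersect_with_edj",
]

#: Default snapping / intersection tolerance (µm).  Geometry at this layer is
#: synthetic or pre-digitized; there is no pixel noise to absorb.
SNAP_TOL = 1e-6

LineKind = Literal["long_period", "short_period", "von_ebner"]


class GeometryError(ValueError):
    """A geometric precondition was violated (point off-curve, no crossing...)."""


@dataclass(frozen=True)
class Point2D:
    """A point in the section plane (µm)."""

    u: float
    v: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.u) and np.isfinite(self.v)):
            raise GeometryError(f"non-finite coordinates ({self.u}, {self.v})")

    def as_array(self) -> np.ndarray:
        return np.array([self.u, self.v], dtype=float)


class Polyline:
    """An open, ordered polyline in the section plane.

    Parameters
    ----------
    points
        ``(n, 2)`` array-like of vertex coordinates in µm, ``n >= 2``.
        Zero-length segments are rejected.
    """

    def __init__(self, points: Sequence) -> None:
        arr = np.asarray(points, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
            raise GeometryError("a polyline needs an (n, 2) array with n >= 2")
        if not np.all(np.isfinite(arr)):
            raise GeometryError("polyline contains non-finite coordinates")
        seg = np.linalg.norm(np.diff(arr, axis=0), axis=1)
        if np.any(seg == 0.0):
            raise GeometryError("polyline contains a zero-length segment")
        self.points = arr
        self._seg_lengths = seg
        self._cum = np.concatenate([[0.0], np.cumsum(seg)])
        self._ls = LineString(arr)

    @property
    def arc_length(self) -> float:
        """Total length (µm); equals the sum of segment lengths by construction."""
        return float(self._cum[-1])

    @property
    def shapely(self) -> LineString:
        return self._ls

    def point_at(self, s: float) -> Point2D:
        """Point at arc-length position ``s`` (clamped to the curve)."""
        p = self._ls.interpolate(float(np.clip(s, 0.0, self.arc_length)))
        return Point2D(p.x, p.y)

    def tangent_at(self, s: float) -> np.ndarray:
        """Unit tangent of the segment containing arc position ``s``."""
        s = float(np.clip(s, 0.0, self.arc_length))
        i = int(np.clip(np.searchsorted(self._cum, s, side="right") - 1,
                        0, len(self._seg_lengths) - 1))
        d = self.points[i + 1] - self.points[i]
        return d / np.linalg.norm(d)

    def normal_at(self, s: float) -> np.ndarray:
        """Unit left normal (tangent rotated +90°) at arc position ``s``."""
        t = self.tangent_at(s)
        return np.array([-t[1], t[0]])

    def __len__(self) -> int:
        return len(self.points)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Polyline({len(self.points)} pts, {self.arc_length:.1f} um)"


class EDJCurve(Polyline):
    """The enamel-dentine junction, oriented cusp tip (index 0) → cervix.

    Arc-length position along this curve is the common coordinate every
    estimator is expressed in: crown extension is the advance of the enamel
    forming front along this curve.
    """


@dataclass
class IncrementLine:
    """One digitized incremental line.

    ``kind`` decides which estimators may consume the line: daily
    short-period laminations and supra-daily long-period lines (striae of
    Retzius) live in enamel; daily von Ebner lines live in dentine.
    ``day_index`` is ground truth carried by synthetic sections only, and
    ``accentuated`` flags the lines used as anchors by the cumulative-length
    extension-rate method (by default every long-period line).
    """

    path: Polyline
    kind: LineKind
    day_index: Optional[int] = None
    accentuated: bool = False


@dataclass
class EnamelSection:
    """A digitized longitudinal section: geometry plus provenance."""

    edj: EDJCurve
    outer_surface: Polyline
    enamel_lines: list[IncrementLine] = field(default_factory=list)
    dentine_lines: list[IncrementLine] = field(default_factory=list)
    specimen_id: str = ""
    cusp_id: str = ""
    species: str = ""
    truth: Optional[object] = None  # SectionConfig for synthetic sections

    def lines_of_kind(self, *kinds: str) -> list[IncrementLine]:
        return [ln for ln in self.enamel_lines + self.dentine_lines
                if ln.kind in kinds]


@dataclass(frozen=True)
class DSRSample:
    """A local daily secretion rate sample.

    ``spacing`` is the mean µm between consecutive daily lines over
    ``n_gaps`` increments, measured at ``edj_arc_position`` µm from the cusp.
    """

    edj_arc_position: float
    spacing: float
    n_gaps: int

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.n_gaps < 1:
            raise ValueError("n_gaps must be >= 1")


@dataclass(frozen=True)
class CERSegment:
    """One segment of the cumulative-length extension-rate ledger.

    ``trajectory_length_A`` is the path A from the EDJ out to the anchor
    line, ``days_x = A / daily spacing`` the days needed to secrete it, and
    ``edj_advance_y`` the EDJ arc gained over those days; the segment's
    extension rate is exactly ``y / x``.
    """

    trajectory_length_A: float
    local_mean_dsr: float
    days_x: float
    edj_advance_y: float

    @property
    def extension_rate(self) -> float:
        return self.edj_advance_y / self.days_x


@dataclass
class CrownGrowthSummary:
    """Per-cusp summary of the cumulative-length method.

    ``average_cer = sum_y / sum_x`` where Σx is the crown formation time over
    the measured EDJ and Σy the EDJ length measured.  Under a 1-day
    long-period assumption Σx halves relative to the 2-day assumption, so
    ``average_cer`` exactly doubles on the same section.
    """

    segments: list[CERSegment]
    periodicity_assumption: int
    average_dsr: float = float("nan")

    @property
    def sum_x(self) -> float:
        return float(sum(s.days_x for s in self.segments))

    @property
    def sum_y(self) -> float:
        return float(sum(s.edj_advance_y for s in self.segments))

    @property
    def average_cer(self) -> float:
        return self.sum_y / self.sum_x


def arc_position(curve: EDJCurve, pt: Point2D, tol: float = SNAP_TOL) -> float:
    """Arc length (µm) from the cusp tip to the point of *curve* nearest *pt*.

    Raises :class:`GeometryError` if *pt* lies farther than *tol* from the
    curve (the error names the offending distance).
    """
    p = Point(pt.u, pt.v)
    d = curve.shapely.distance(p)
    if d > tol:
        raise GeometryError(
            f"point ({pt.u:g}, {pt.v:g}) is {d:g} um from the curve "
            f"(tolerance {tol:g} um)")
    return float(curve.shapely.project(p))


def intersect_with_edj(line: IncrementLine | Polyline, edj: EDJCurve,
                       tol: float = SNAP_TOL) -> Optional[Point2D]:
    """Intersection of an incremental line with the EDJ, or ``None``.

    Returns the crossing nearest the cervix (largest arc position) when the
    polylines cross; if they merely approach within *tol* the nearest EDJ
    point is returned (digitized tracings often stop just short of the EDJ).
    Multiple crossings trigger a warning and the most cervical one wins.
    """
    path = line.path if isinstance(line, IncrementLine) else line
    inter = path.shapely.intersection(edj.shapely)
    pts: list[Point] = []
    if not inter.is_empty:
        if inter.geom_type == "Point":
            pts = [inter]
        elif isinstance(inter, MultiPoint):
            pts = list(inter.geoms)
        else:  # collinear overlap or mixed collection: use boundary points
            pts = [Point(c) for geom in getattr(inter, "geoms", [inter])
                   for c in getattr(geom, "coords", [])]
    if not pts:
        # tolerance snap: nearest approach
        d = path.shapely.distance(edj.shapely)
        if d <= tol:
            # project the nearest line vertex onto the EDJ
            dists = [edj.shapely.distance(Point(q)) for q in path.points]
            q = path.points[int(np.argmin(dists))]
            near = edj.shapely.interpolate(edj.shapely.project(Point(q)))
            return Point2D(near.x, near.y)
        return None
    if len(pts) > 1:
        warnings.warn("incremental line crosses the EDJ more than once; "
                      "keeping the most cervical crossing", stacklevel=2)
    arcs = [edj.shapely.project(p) for p in pts]
    best = pts[int(np.argmax(arcs))]
    return Point2D(best.x, best.y)
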