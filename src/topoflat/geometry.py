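"""Flattening of 3D injection coordinates onto a curved cortical surface.

The source region's pial surface is represented as a strip between a dorsal
and a ventral border polyline (reference-space coordinates, mm), triangulated
so that an injection's 3D coordinate can be transposed onto the surface and
expressed as normalized 2D coordinates:

* ``rc`` — rostrocaudal fraction ``d_r / (d_r + d_c)`` where ``d_r`` / ``d_c``
  are cumulative arc distances from the foot of the shortest vector to the
  midline, to the rostral / caudal end of the midline (0 = rostral).
* ``dv`` — dorsoventral fraction ``d_v / (d_v + d_d)`` where ``d_v`` / ``d_d``
  are shortest Euclidean distances to the ventral / dorsal border polyline
  (0 = ventral).

Border polylines are smoothed with a tricube-weighted local linear regression
of each coordinate against cumulative arc length before triangulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.nonparametric.smoothers_lowess import lowess


class GeometryError(ValueError):
    """Degenerate or inconsistent surface geometry."""


class BorderRole(str, Enum):
    DORSAL_A30 = "dorsal_A30"
    A29_A30_BOUNDARY = "A29_A30_boundary"
    VENTRAL_A29 = "ventral_A29"
    DORSAL_OF_AREA = "dorsal_of_area"
    VENTRAL_OF_AREA = "ventral_of_area"


@dataclass
class BorderPolyline:
    """Ordered 3D polyline along a border, rostral to caudal."""

    role: BorderRole | str
    points: np.ndarray  # (n, 3), mm

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be an (n, 3) array")
        if len(self.points) < 2:
            raise ValueError("a border polyline needs at least 2 points")
        if np.any(np.linalg.norm(np.diff(self.points, axis=0), axis=1) == 0):
            raise ValueError("consecutive polyline points must be distinct")

    @property
    def arc_length(self) -> np.ndarray:
        """Cumulative arc length per vertex, starting at 0."""
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def length(self) -> float:
        return float(self.arc_length[-1])

    def resample(self, n: int) -> "BorderPolyline":
        """Resample to ``n`` vertices at equal arc-length fractions."""
        s = self.arc_length
        target = np.linspace(0.0, s[-1], n)
        pts = np.column_stack(
            [np.interp(target, s, self.points[:, k]) for k in range(3)]
        )
        return BorderPolyline(self.role, pts)


@dataclass
class SurfaceModel:
    """Triangulated strip between a dorsal and a ventral border."""

    triangles: np.ndarray  # (m, 3, 3)
    area_label: str
    midline: np.ndarray  # (n, 3)
    dorsal: BorderPolyline = field(repr=False)
    ventral: BorderPolyline = field(repr=False)

    @property
    def midline_arc_length(self) -> np.ndarray:
        seg = np.linalg.norm(np.diff(self.midline, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])


def smooth_borders(raw_border: BorderPolyline, span: float = 0.5) -> BorderPolyline:
    """Smooth a border polyline by local regression against arc length.

    Each coordinate is fit by a tricube-weighted local linear regression
    (LOWESS) against cumulative arc length, using a window covering ``span``
    of the points. Point count is preserved.
    """
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    if len(raw_border.points) < 4:
        raise ValueError("border smoothing requires at least 4 points")
    s = raw_border.arc_length
    smoothed = np.column_stack(
        [
            lowess(raw_border.points[:, k], s, frac=span, it=0, xvals=s)
            for k in range(3)
        ]
    )
    # degenerate collapses (all points smoothed onto one) are geometry errors
    if np.all(np.linalg.norm(np.diff(smoothed, axis=0), axis=1) < 1e-12):
        raise GeometryError("smoothing collapsed the border polyline")
    # drop exactly coincident consecutive vertices introduced by smoothing
    keep = np.concatenate(
        [[True], np.linalg.norm(np.diff(smoothed, axis=0), axis=1) > 0]
    )
    return BorderPolyline(raw_border.role, smoothed[keep])


def _triangle_areas(tri: np.ndarray) -> np.ndarray:
    a = tri[:, 1] - tri[:, 0]
    b = tri[:, 2] - tri[:, 0]
    return 0.5 * np.linalg.norm(np.cross(a, b), axis=1)


def triangulate_strip(
    dorsal: BorderPolyline,
    ventral: BorderPolyline,
    area_label: str = "combined",
    n_vertices: int | None = None,
) -> SurfaceModel:
    """Triangulate the strip between two border polylines.

    Both borders are resampled to the same vertex count at equal arc-length
    fractions, and each quad between matched vertices is split into two
    triangles. The midline is the pointwise midpoint of matched vertices.
    """
    n = n_vertices or max(len(dorsal.points), len(ventral.points))
    if n < 2:
        raise ValueError("need at least 2 vertices per border")
    d = dorsal.resample(n).points
    v = ventral.resample(n).points

    tris = []
    for i in range(n - 1):
        tris.append([d[i], v[i], v[i + 1]])
        tris.append([d[i], v[i + 1], d[i + 1]])
    triangles = np.asarray(tris)

    areas = _triangle_areas(triangles)
    if np.any(areas <= 1e-12):
        raise GeometryError(
            "degenerate strip: borders coincide or triangles have zero area"
        )
    # orientation flips between adjacent triangles signal crossing borders
    a = triangles[:, 1] - triangles[:, 0]
    b = triangles[:, 2] - triangles[:, 0]
    normals = np.cross(a, b)
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    if np.any(np.einsum("ij,ij->i", normals[:-1], normals[1:]) < -1e-9):
        raise GeometryError("borders cross: triangle orientation flips")

    midline = 0.5 * (d + v)
    return SurfaceModel(
        triangles=triangles,
        area_label=area_label,
        midline=midline,
        dorsal=BorderPolyline(dorsal.role, d),
        ventral=BorderPolyline(ventral.role, v),
    )


def _closest_point_on_triangles(p: np.ndarray, tri: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Closest point to ``p`` on each triangle of ``tri`` (vectorized).

    Standard region-based point/triangle projection in barycentric form.
    Returns (closest points (m,3), squared distances (m,)).
    """
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab = b - a
    ac = c - a
    ap = p - a

    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2

    out = np.empty_like(tri[:, 0])

    # vertex regions
    m_a = (d1 <= 0) & (d2 <= 0)
    m_b = (d3 >= 0) & (d4 <= d3)
    m_c = (d6 >= 0) & (d5 <= d6)
    # edge regions
    with np.errstate(divide="ignore", invalid="ignore"):
        v_ab = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)
        w_ac = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)
        denom_bc = (d4 - d3) + (d5 - d6)
        w_bc = np.where(denom_bc != 0, (d4 - d3) / denom_bc, 0.0)
    m_ab = (~m_a) & (~m_b) & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    m_ac = (~m_a) & (~m_c) & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    m_bc = (~m_b) & (~m_c) & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)

    inner = ~(m_a | m_b | m_c | m_ab | m_ac | m_bc)
    denom = np.where(va + vb + vc != 0, va + vb + vc, 1.0)
    v = vb / denom
    w = vc / denom

    out[m_a] = a[m_a]
    out[m_b] = b[m_b]
    out[m_c] = c[m_c]
    out[m_ab] = a[m_ab] + v_ab[m_ab, None] * ab[m_ab]
    out[m_ac] = a[m_ac] + w_ac[m_ac, None] * ac[m_ac]
    out[m_bc] = b[m_bc] + w_bc[m_bc, None] * (c[m_bc] - b[m_bc])
    out[inner] = a[inner] + v[inner, None] * ab[inner] + w[inner, None] * ac[inner]

    d2_all = np.einsum("ij,ij->i", out - p, out - p)
    return out, d2_all


def transpose_to_surface(p: np.ndarray, s: SurfaceModel) -> tuple[np.ndarray, int]:
    """Transpose a 3D point onto the surface.

    Returns the closest point on the triangulated surface and the index of the
    triangle attaining it (lowest index on ties).
    """
    p = np.asarray(p, dtype=float)
    if len(s.triangles) == 0:
        raise GeometryError("empty surface")
    pts, d2 = _closest_point_on_triangles(p, s.triangles)
    idx = int(np.argmin(d2))  # argmin takes the lowest index on ties
    return pts[idx], idx


def _point_to_polyline(p: np.ndarray, poly: np.ndarray) -> tuple[float, int, float]:
    """Distance from ``p`` to a polyline.

    Returns (distance, segment index, parameter t in [0,1] on that segment).
    """
    a = poly[:-1]
    b = poly[1:]
    ab = b - a
    denom = np.einsum("ij,ij->i", ab, ab)
    t = np.clip(np.einsum("ij,ij->i", p - a, ab) / np.where(denom > 0, denom, 1.0), 0, 1)
    foot = a + t[:, None] * ab
    d = np.linalg.norm(foot - p, axis=1)
    i = int(np.argmin(d))
    return float(d[i]), i, float(t[i])


def normalize_injection(tp: np.ndarray, s: SurfaceModel) -> dict[str, float]:
    """Normalized (rc, dv) coordinates of a surface point.

    ``d_d`` / ``d_v`` are the shortest Euclidean distances to the dorsal /
    ventral border; the foot of the shortest vector to the midline splits its
    arc length into ``d_r`` (to the rostral end) and ``d_c`` (to the caudal
    end).
    """
    tp = np.asarray(tp, dtype=float)
    d_d, _, _ = _point_to_polyline(tp, s.dorsal.points)
    d_v, _, _ = _point_to_polyline(tp, s.ventral.points)
    if d_d + d_v == 0:
        raise GeometryError("point lies on both borders simultaneously")

    _, seg, t = _point_to_polyline(tp, s.midline)
    arc = s.midline_arc_length
    d_r = arc[seg] + t * (arc[seg + 1] - arc[seg])
    d_c = arc[-1] - d_r
    return {
        "rc": float(d_r / (d_r + d_c)),
        "dv": float(d_v / (d_v + d_d)),
        "d_d": d_d,
        "d_v": d_v,
        "d_r": float(d_r),
        "d_c": float(d_c),
    }


class SurfaceFlattener(BaseEstimator, TransformerMixin):
    """Flatten 3D injection coordinates to normalized (rc, dv).

    Fits a triangulated surface model from dorsal/ventral border polylines
    (after local-regression smoothing) and transforms 3D points into
    normalized rostrocaudal / dorsoventral coordinates.

    Parameters
    ----------
    span : float
        LOWESS span for border smoothing (fraction of points per window).
    smooth : bool
        Whether to smooth borders before triangulation.
    n_vertices : int or None
        Vertex count per border after resampling; defaults to the larger of
        the two input borders.

    Attributes
    ----------
    surface_ : SurfaceModel
        Triangulated strip between the smoothed borders.
    boundary_ : BorderPolyline or None
        Optional area boundary (A29/A30) used for area assignment.
    """

    def __init__(self, span: float = 0.5, smooth: bool = True, n_vertices: int | None = None):
        self.span = span
        self.smooth = smooth
        self.n_vertices = n_vertices

    def fit(self, borders, y=None):
        """Fit the surface from border polylines.

        Parameters
        ----------
        borders : dict
            Mapping with keys ``"dorsal"`` and ``"ventral"`` (BorderPolyline)
            and optionally ``"boundary"`` (the A29/A30 boundary polyline).
        """
        dorsal = borders["dorsal"]
        ventral = borders["ventral"]
        if self.smooth and len(dorsal.points) >= 4:
            dorsal = smooth_borders(dorsal, self.span)
        if self.smooth and len(ventral.points) >= 4:
            ventral = smooth_borders(ventral, self.span)
        self.surface_ = triangulate_strip(dorsal, ventral, n_vertices=self.n_vertices)
        self.boundary_ = borders.get("boundary")
        return self

    def transform(self, X) -> pd.DataFrame:
        """Transpose points onto the surface and normalize.

        Parameters
        ----------
        X : (n, 3) array or DataFrame with columns x, y, z

        Returns
        -------
        DataFrame with columns rc, dv, d_d, d_v, d_r, d_c, tx, ty, tz,
        triangle, and (if an area boundary was fitted) area.
        """
        if not hasattr(self, "surface_"):
            raise RuntimeError("SurfaceFlattener is not fitted")
        if isinstance(X, pd.DataFrame):
            pts = X[["x", "y", "z"]].to_numpy(dtype=float)
        else:
            pts = np.asarray(X, dtype=float).reshape(-1, 3)
        rows = []
        for p in pts:
            tp, tri = transpose_to_surface(p, self.surface_)
            rec = normalize_injection(tp, self.surface_)
            rec.update(tx=tp[0], ty=tp[1], tz=tp[2], triangle=tri)
            if self.boundary_ is not None:
                rec["area"] = self._assign_area(tp)
            rows.append(rec)
        out = pd.DataFrame(rows)
        if isinstance(X, pd.DataFrame):
            out.index = X.index
        return out

    def _assign_area(self, tp: np.ndarray) -> str:
        """Area of a surface point: side relative to the A29/A30 boundary.

        The point is dorsal to the boundary (A30) when it sits closer to the
        dorsal border than the nearest boundary point does, in the normalized
        dorsoventral coordinate of the full strip.
        """
        dv_p = normalize_injection(tp, self.surface_)["dv"]
        d, seg, t = _point_to_polyline(tp, self.boundary_.points)
        bpt = self.boundary_.points[seg] + t * (
            self.boundary_.points[seg + 1] - self.boundary_.points[seg]
        )
        dv_b = normalize_injection(bpt, self.surface_)["dv"]
        return "A30" if dv_p >= dv_b else "A29"
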