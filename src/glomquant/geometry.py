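"""Polyline geometry helpers shared by the scene generator and the analysis side.

All coordinates are physical micrometres in (x, y, z) order unless noted.
"""

from __future__ import annotations

import numpy as np

from .errors import DegenerateGeometryError


def segment_lengths(polyline: np.ndarray) -> np.ndarray:
    """Euclidean length of each segment of an (N, 3) polyline."""
    pts = np.asarray(polyline, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 3:
        raise ValueError("polyline must be an (N>=2, 3) array")
    return np.linalg.norm(np.diff(pts, axis=0), axis=1)


def polyline_length(polyline: np.ndarray) -> float:
    return float(segment_lengths(polyline).sum())


def total_length(polylines: list[np.ndarray]) -> float:
    return float(sum(polyline_length(p) for p in polylines))


def point_at_arclength(polyline: np.ndarray, s: float) -> np.ndarray:
    """Point at arclength ``s`` (clamped) along a polyline."""
    pts = np.asarray(polyline, dtype=float)
    seg = segment_lengths(pts)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    s = float(np.clip(s, 0.0, cum[-1]))
    i = int(np.searchsorted(cum, s, side="right") - 1)
    i = min(i, len(seg) - 1)
    frac = 0.0 if seg[i] == 0 else (s - cum[i]) / seg[i]
    return pts[i] + frac * (pts[i + 1] - pts[i])


def resample_polyline(polyline: np.ndarray, spacing: float) -> np.ndarray:
    """Dense points along a polyline at approximately uniform ``spacing`` (µm)."""
    L = polyline_length(polyline)
    if L == 0:
        return np.asarray(polyline[:1], dtype=float)
    n = max(2, int(np.ceil(L / spacing)) + 1)
    ss = np.linspace(0.0, L, n)
    return np.vstack([point_at_arclength(polyline, s) for s in ss])


def _dist_point_to_segments(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Distances from point ``p`` to each segment (a[i], b[i]); vectorised."""
    ab = b - a
    ap = p[None, :] - a
    denom = np.einsum("ij,ij->i", ab, ab)
    t = np.zeros(len(a))
    nz = denom > 0
    t[nz] = np.clip(np.einsum("ij,ij->i", ap[nz], ab[nz]) / denom[nz], 0.0, 1.0)
    closest = a + t[:, None] * ab
    return np.linalg.norm(p[None, :] - closest, axis=1)


def min_distance_to_polylines(point_xyz: np.ndarray, polylines: list[np.ndarray]) -> float:
    """Minimum Euclidean distance from a point to any polyline segment."""
    if not polylines:
        raise DegenerateGeometryError("no polylines given")
    p = np.asarray(point_xyz, dtype=float)
    best = np.inf
    for poly in polylines:
        pts = np.asarray(poly, dtype=float)
        d = _dist_point_to_segments(p, pts[:-1], pts[1:])
        best = min(best, float(d.min()))
    return best


def shoelace_area(vertices: np.ndarray) -> float:
    """Absolute area of a simple 2D polygon by the shoelace formula."""
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[0] < 3 or v.shape[1] != 2:
        raise ValueError("polygon needs at least 3 (x, y) vertices")
    x, y = v[:, 0], v[:, 1]
    return float(0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y)))
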