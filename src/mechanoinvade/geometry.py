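"""Exact convex-polytope volume clipping against a horizontal plane.

The clipped part of a convex body below a plane is itself convex, and its
vertex set is exactly {hull vertices below the plane} union {intersections
of hull edges with the plane}; the clipped volume is therefore the convex
hull volume of that vertex set, with no case analysis. Used by the Q-Pi
percent-invasion computation and validated against a Monte-Carlo
point-in-hull oracle in the test suite.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull, QhullError

__all__ = ["hull_edges", "volume_below_plane", "fraction_below_plane"]


def hull_edges(hull: ConvexHull) -> np.ndarray:
    """Unique vertex-index pairs forming the edges of a 3D convex hull."""
    s = hull.simplices
    e = np.vstack([s[:, [0, 1]], s[:, [1, 2]], s[:, [2, 0]]])
    e.sort(axis=1)
    return np.unique(e, axis=0)


def volume_below_plane(points: np.ndarray, z_plane: float) -> float:
    """Volume of the part of conv(points) with z < z_plane (z is column 2).

    Exact up to floating point: vertices strictly below the plane are kept,
    every crossing edge contributes its interpolated intersection point, and
    the volume of the convex hull of those points is returned. Degenerate
    clips (empty or flat) have volume 0.
    """
    pts = np.asarray(points, dtype=float)
    hull = ConvexHull(pts)
    verts = pts[hull.vertices]
    z = verts[:, 2]
    if (z >= z_plane).all():
        return 0.0
    if (z <= z_plane).all():
        return float(hull.volume)

    # vertices on the plane belong to the closed lower half-space (their
    # inclusion changes topology, not volume)
    clipped = [verts[z <= z_plane]]
    for i, j in hull_edges(hull):
        zi, zj = pts[i, 2], pts[j, 2]
        if (zi - z_plane) * (zj - z_plane) < 0:
            t = (z_plane - zi) / (zj - zi)
            clipped.append((pts[i] + t * (pts[j] - pts[i]))[None, :])
    cloud = np.vstack(clipped)
    if len(cloud) < 4:
        return 0.0
    try:
        return float(ConvexHull(cloud).volume)
    except QhullError:
        return 0.0  # coplanar clip: zero volume


def fraction_below_plane(points: np.ndarray, z_plane: float) -> float:
    """Fraction (0..1) of the convex hull volume below the plane."""
    pts = np.asarray(points, dtype=float)
    total = ConvexHull(pts).volume
    if total <= 0:
        raise ValueError("degenerate hull: zero volume")
    return volume_below_plane(pts, z_plane) / total
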