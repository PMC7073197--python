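"""Dominant-point contour approximation and ellipse fitting.

Dominant points are the high-curvature points of a closed digital contour,
selected with the Teh & Chin (1989) adaptive region-of-support method: each
point first determines its own region of support from the local chord-length
and arc-to-chord behaviour (no global curvature scale parameter), then a
k-cosine significance measure is computed over that support, and non-maxima
are suppressed. A final deviation-bounded refinement pass guarantees that
the polygon through the dominant points stays within a stated Hausdorff
distance of the input chain, so downstream convex-hull volumes cannot be
degraded by an over-aggressive approximation on smooth arcs.

Point arrays are (n, 2) in (row, col) image coordinates unless noted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.measure import EllipseModel

__all__ = ["dominant_points", "fit_ellipse", "EllipseParams", "hausdorff_to_chain"]


@dataclass(frozen=True)
class EllipseParams:
    """A fitted ellipse: centre (row, col), semi-axes a >= b, rotation in
    radians (angle of the a-axis from the col axis, in [0, pi))."""

    center: tuple[float, float]
    a: float
    b: float
    theta: float
    degenerate: bool = False


def _chord_and_deviation(pts: np.ndarray, i: int, k: int) -> tuple[float, float]:
    """Chord length d_ik = |p_{i-k} p_{i+k}| and signed perpendicular
    distance l_ik of p_i from that chord (closed chain, wrapped indices)."""
    n = len(pts)
    a = pts[(i - k) % n]
    b = pts[(i + k) % n]
    chord = b - a
    d = float(np.hypot(*chord))
    if d == 0.0:
        return 0.0, 0.0
    # 2D cross product gives signed area -> perpendicular distance
    rel = pts[i] - a
    l = float(chord[0] * rel[1] - chord[1] * rel[0]) / d
    return d, l


def _region_of_support(pts: np.ndarray, i: int, k_max: int) -> int:
    """Adaptive region of support of point i.

    k grows while the chord keeps lengthening and the arc-to-chord ratio
    |l|/d keeps rising with a consistent bending direction; both conditions
    break as soon as the support starts to straddle a neighbouring feature.
    """
    d_prev, l_prev = _chord_and_deviation(pts, i, 1)
    k = 1
    eps = 1e-12
    if abs(l_prev) <= eps:
        # locally straight: the point sits on the chord of its neighbours,
        # so its support must not grow across an adjacent corner
        return 1
    for k_next in range(2, k_max + 1):
        d, l = _chord_and_deviation(pts, i, k_next)
        if d < d_prev - eps:
            break
        r_prev = abs(l_prev) / d_prev if d_prev > eps else 0.0
        r = abs(l) / d if d > eps else 0.0
        if abs(l_prev) > eps and np.sign(l) != np.sign(l_prev):
            break
        # the arc-to-chord ratio must strictly rise; on straight runs l = 0
        # and the support stops immediately, so collinear interior points
        # never acquire a region crossing a neighbouring corner
        if r <= r_prev + eps:
            break
        k, d_prev, l_prev = k_next, d, l
    return k


def _k_cosine(pts: np.ndarray, i: int, k: int) -> float:
    """Cosine of the angle at p_i subtended by p_{i-k} and p_{i+k}.

    +1 is a cusp, 0 a right-angle corner, -1 exactly straight — larger means
    more significant.
    """
    n = len(pts)
    u = pts[(i - k) % n] - pts[i]
    v = pts[(i + k) % n] - pts[i]
    nu, nv = np.hypot(*u), np.hypot(*v)
    if nu == 0 or nv == 0:
        return -1.0
    return float(np.dot(u, v) / (nu * nv))


def dominant_points(
    points: np.ndarray,
    max_deviation: float = 1.0,
    closed: bool = True,
) -> np.ndarray:
    """Indices of the dominant points of a closed contour chain.

    Parameters
    ----------
    points:
        Ordered boundary points of a closed chain, shape (n, 2), n >= 3.
        The chain must not repeat its first point at the end.
    max_deviation:
        Upper bound (in pixel units) on the deviation of any chain point
        from the dominant-point polygon; arcs violating it are refined by
        inserting their farthest point, which bounds the Hausdorff distance
        of the approximation.

    Returns
    -------
    Sorted integer indices into ``points``.
    """
    if not closed:
        raise ValueError("dominant-point detection requires a closed chain")
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise ValueError("need a closed chain of >= 3 (row, col) points")
    if np.allclose(pts[0], pts[-1]) and len(pts) > 3:
        pts = pts[:-1]
    n = len(pts)
    k_max = max(n // 2 - 1, 1)

    support = np.array([_region_of_support(pts, i, k_max) for i in range(n)])
    sig = np.array([_k_cosine(pts, i, support[i]) for i in range(n)])

    # pass 1: non-maxima suppression — p_i survives iff its significance is a
    # maximum over its half region of support on both sides
    survive = np.ones(n, dtype=bool)
    for i in range(n):
        w = max(support[i] // 2, 1)
        for off in range(1, w + 1):
            for j in ((i - off) % n, (i + off) % n):
                if sig[j] > sig[i]:
                    survive[i] = False
                    break
            if not survive[i]:
                break

    # pass 2: drop exactly-straight survivors (collinear with their support)
    straight = sig <= -1.0 + 1e-9
    survive &= ~straight

    # pass 3: collapse runs of adjacent survivors to their best member
    idx = np.flatnonzero(survive)
    if len(idx) > 1:
        keep = []
        groups = _adjacent_groups(idx, n)
        for g in groups:
            keep.append(g[int(np.argmax(sig[g]))])
        idx = np.array(sorted(keep))

    if len(idx) == 0:
        # featureless chain (e.g. perfectly smooth by the measures above):
        # seed with the extremal points so refinement has a polygon to grow
        idx = np.array(sorted({int(pts[:, 0].argmin()), int(pts[:, 0].argmax()),
                               int(pts[:, 1].argmin()), int(pts[:, 1].argmax())}))

    idx = _refine_to_deviation(pts, idx, max_deviation)
    return idx


def _adjacent_groups(idx: np.ndarray, n: int) -> list[np.ndarray]:
    """Group circularly adjacent indices."""
    groups = [[idx[0]]]
    for i in idx[1:]:
        if i == groups[-1][-1] + 1:
            groups[-1].append(i)
        else:
            groups.append([i])
    # wrap-around adjacency
    if len(groups) > 1 and groups[0][0] == 0 and groups[-1][-1] == n - 1:
        groups[0] = groups.pop() + groups[0]
    return [np.array(g) for g in groups]


def _point_segment_dist(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Distances of points p (m, 2) from segment ab."""
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        return np.hypot(*(p - a).T)
    t = np.clip((p - a) @ ab / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.hypot(*(p - proj).T)


def _refine_to_deviation(pts: np.ndarray, idx: np.ndarray, tol: float) -> np.ndarray:
    """Insert chain points until every arc lies within `tol` of its chord."""
    n = len(pts)
    sel = sorted(idx.tolist())
    changed = True
    while changed:
        changed = False
        new_sel = []
        m = len(sel)
        for s in range(m):
            i, j = sel[s], sel[(s + 1) % m]
            new_sel.append(i)
            arc = np.arange(i + 1, (j if j > i else j + n))
            if arc.size == 0:
                continue
            d = _point_segment_dist(pts[arc % n], pts[i], pts[j % n])
            worst = int(np.argmax(d))
            if d[worst] > tol:
                new_sel.append(int(arc[worst] % n))
                changed = True
        sel = sorted(set(new_sel))
    return np.array(sel, dtype=int)


def hausdorff_to_chain(pts: np.ndarray, idx: np.ndarray) -> float:
    """Max distance of any chain point from the dominant-point polygon."""
    pts = np.asarray(pts, dtype=float)
    n = len(pts)
    sel = sorted(idx.tolist())
    worst = 0.0
    m = len(sel)
    for s in range(m):
        i, j = sel[s], sel[(s + 1) % m]
        arc = np.arange(i, (j if j > i else j + n) + 1)
        d = _point_segment_dist(pts[arc % n], pts[i], pts[j % n])
        worst = max(worst, float(d.max()))
    return worst


def fit_ellipse(points: np.ndarray) -> EllipseParams:
    """Least-squares ellipse through boundary points (direct conic fit).

    Requires at least 5 points; collinear or otherwise degenerate
    configurations return an :class:`EllipseParams` with the degenerate flag
    set rather than raising, since degenerate contours are expected on tiny
    end-cap slices.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (n, 2)")
    if len(pts) < 5:
        raise ValueError(f"ellipse fitting needs >= 5 points; got {len(pts)}")
    # collinearity check via the smaller singular value of the centred cloud
    centred = pts - pts.mean(axis=0)
    sv = np.linalg.svd(centred, compute_uv=False)
    if sv[-1] < 1e-9 * max(sv[0], 1.0):
        return EllipseParams(tuple(pts.mean(axis=0)), 0.0, 0.0, 0.0, degenerate=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        model = EllipseModel.from_estimate(pts[:, ::-1])  # wants (x, y) = (col, row)
    if not model:
        return EllipseParams(tuple(pts.mean(axis=0)), 0.0, 0.0, 0.0, degenerate=True)
    xc, yc = model.center
    a, b = model.axis_lengths
    theta = model.theta
    if not np.all(np.isfinite([xc, yc, a, b, theta])):
        return EllipseParams(tuple(pts.mean(axis=0)), 0.0, 0.0, 0.0, degenerate=True)
    if a < b:  # canonicalise: a is the major semi-axis
        a, b = b, a
        theta += np.pi / 2
    theta = float(np.mod(theta, np.pi))
    if a <= 0 or b <= 0:
        return EllipseParams((float(yc), float(xc)), 0.0, 0.0, 0.0, degenerate=True)
    return EllipseParams((float(yc), float(xc)), float(a), float(b), theta)
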