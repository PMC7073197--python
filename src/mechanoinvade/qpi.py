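"""Q-Pi: quantification of percentage volume invasion through a basement
membrane, from two-channel confocal z-stacks.

A cell seeded on a laminin bilayer (a decellularised mesentery mimicking the
basement membrane) is imaged as a z-stack with a cell (actin) channel and a
membrane (laminin) channel. The pipeline:

1. segment the cell channel slice by slice (smoothing, Otsu threshold,
   morphological closing) with 3D connected components defining cell
   identity across slices;
2. trace each slice boundary and reduce it to dominant points
   (Teh–Chin adaptive region-of-support approximation); regression ellipses
   are fitted per slice for QC;
3. lift the dominant points of all slices of one cell to physical
   coordinates and take their 3D convex hull — the cell's volumetric model;
4. locate the upper laminin layer as the highest-z qualifying peak of the
   per-slice mean membrane intensity;
5. report, per cell, the percentage of hull volume lying below that plane
   (cells invade toward decreasing z; z index 0 is the substrate side).

The invaded-cell counting assay is summarised by
:func:`cumulative_invaded_count` (cumulative cells per mesentery per ROI).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import ConvexHull
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import find_contours, label
from skimage.morphology import closing, disk

from .contours import EllipseParams, dominant_points, fit_ellipse
from .geometry import fraction_below_plane
from .stacks import ImageStack

__all__ = [
    "QpiParams",
    "CellContour",
    "CellReconstruction",
    "MembranePlane",
    "InvasionResult",
    "CumulativeCount",
    "segment_slice",
    "approximate_contour",
    "fit_ellipse",
    "locate_membrane",
    "reconstruct_cell",
    "percent_invasion",
    "run_qpi",
    "cumulative_invaded_count",
]


@dataclass(frozen=True)
class QpiParams:
    """Tunable segmentation/reconstruction parameters.

    ``min_contrast`` guards against segmenting pure noise: the Otsu split is
    only accepted when foreground and background separate by that many
    background standard deviations.
    """

    smoothing_sigma_px: float = 1.0
    min_area_px: int = 50
    closing_radius_px: int = 3
    min_contrast: float = 4.0
    max_deviation_px: float = 1.0
    hull_source: str = "contour"  # or "ellipse"
    exclude_border: bool = True
    min_slices: int = 2


@dataclass
class CellContour:
    """One cell's boundary on one slice."""

    slice_index: int
    points: np.ndarray  # (n, 2) ordered (row, col), counter-clockwise
    dominant_idx: np.ndarray
    ellipse: EllipseParams | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if len(self.points) < 3:
            raise ValueError("a contour needs at least 3 boundary points")

    @property
    def dominant(self) -> np.ndarray:
        return self.points[self.dominant_idx]


@dataclass
class CellReconstruction:
    """A cell's 3D convex-hull model in physical coordinates (µm, xyz)."""

    cell_id: int
    vertices_um: np.ndarray  # (m, 3) hull vertices
    facets: np.ndarray  # (f, 3) indices into vertices_um
    volume_um3: float
    slice_range: tuple[int, int]
    points_um: np.ndarray = field(repr=False, default=None)  # all source points

    def to_trimesh(self):
        """Export as a trimesh.Trimesh (for OBJ mesh output)."""
        import trimesh

        return trimesh.Trimesh(vertices=self.vertices_um, faces=self.facets)


@dataclass(frozen=True)
class MembranePlane:
    """The z-position of the upper laminin layer."""

    z_um: float
    score: float
    method: str = "zprofile_peak"


@dataclass(frozen=True)
class InvasionResult:
    cell_id: int
    percent_below: float
    volume_um3: float
    membrane_z_um: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_below <= 100.0:
            raise ValueError("percent invasion must be within [0, 100]")


@dataclass
class CumulativeCount:
    """Cumulative invaded cells per mesentery per ROI, with errors.

    Daily means are per-ROI averages divided by the number of mesenteries in
    the well; the cumulative value is the running sum of daily means and the
    cumulative error the running sum of the daily standard errors.
    """

    daily_mean: np.ndarray
    daily_sem: np.ndarray
    cumulative_mean: np.ndarray
    cumulative_sem: np.ndarray


def segment_slice(image: np.ndarray, params: QpiParams = QpiParams()) -> list[CellContour]:
    """Contours of the cells in a single-channel 2D slice.

    Gaussian smoothing, Otsu threshold (with the contrast guard), closing,
    connected components with a minimum area, then boundary tracing; each
    boundary is ordered counter-clockwise and reduced to dominant points.
    Returns an empty list on blank or pure-noise input.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("segment_slice expects a 2D single-channel image")
    mask = _threshold(image, params)
    if mask is None:
        return []
    labels = label(mask)
    return _contours_from_labels(labels, 0, params)


def _threshold(image: np.ndarray, params: QpiParams) -> np.ndarray | None:
    sm = gaussian(image, sigma=params.smoothing_sigma_px, preserve_range=True)
    if np.ptp(sm) == 0:
        return None
    t = threshold_otsu(sm)
    fg = sm > t
    if not fg.any() or fg.all():
        return None
    bg_sd = sm[~fg].std()
    if sm[fg].mean() - sm[~fg].mean() < params.min_contrast * max(bg_sd, 1e-12):
        return None
    if params.closing_radius_px > 0:
        fg = closing(fg, disk(params.closing_radius_px))
    return fg


def _contours_from_labels(labels: np.ndarray, slice_index: int, params: QpiParams) -> list[CellContour]:
    out = []
    for lab in range(1, labels.max() + 1):
        mask = labels == lab
        if mask.sum() < params.min_area_px:
            continue
        traced = find_contours(mask.astype(float), 0.5)
        if not traced:
            continue
        pts = max(traced, key=len)
        if np.allclose(pts[0], pts[-1]):
            pts = pts[:-1]
        if len(pts) < 3:
            continue
        pts = _ensure_ccw(pts)
        dom = dominant_points(pts, max_deviation=params.max_deviation_px)
        ell = fit_ellipse(pts) if len(pts) >= 5 else None
        out.append(CellContour(slice_index, pts, dom, ell))
    return out


def _ensure_ccw(pts: np.ndarray) -> np.ndarray:
    """Counter-clockwise in (x, y) = (col, row) axes."""
    x, y = pts[:, 1], pts[:, 0]
    area2 = np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    return pts if area2 >= 0 else pts[::-1]


def approximate_contour(points: np.ndarray, max_deviation: float = 1.0) -> np.ndarray:
    """Dominant points of a closed boundary chain (Teh–Chin); see
    :func:`mechanoinvade.contours.dominant_points`."""
    idx = dominant_points(points, max_deviation=max_deviation)
    return np.asarray(points, dtype=float)[idx]


def locate_membrane(
    stack: ImageStack, membrane_channel: str, n_sd: float = 3.0
) -> MembranePlane:
    """z of the upper laminin layer, from the membrane channel's z-profile.

    The per-slice mean intensity along z shows one peak per laminin layer;
    the membrane plane is the highest-z local maximum exceeding the profile
    background (median) by ``n_sd`` robust standard deviations. Exact ties
    resolve to the higher z (the "upper" layer).
    """
    vol = stack.channel(membrane_channel)
    profile = vol.mean(axis=(1, 2))
    bg = float(np.median(profile))
    sd = float(1.4826 * np.median(np.abs(profile - bg)))
    thresh = bg + n_sd * max(sd, 1e-12)
    peaks = [
        k
        for k in range(len(profile))
        if profile[k] > thresh
        and (k == 0 or profile[k] >= profile[k - 1])
        and (k == len(profile) - 1 or profile[k] >= profile[k + 1])
    ]
    if not peaks:
        raise ValueError("membrane not detected: no z-profile peak above background + "
                         f"{n_sd}*SD")
    k = max(peaks)
    return MembranePlane(z_um=k * stack.voxel_size_um[0], score=float(profile[k]))


def _contour_points_um(
    contour: CellContour, voxel_size_um: tuple[float, float, float], source: str
) -> np.ndarray:
    dz, dy, dx = voxel_size_um
    if source == "ellipse" and contour.ellipse is not None and not contour.ellipse.degenerate:
        t = np.linspace(0, 2 * np.pi, 32, endpoint=False)
        e = contour.ellipse
        row = e.center[0] + e.a * np.sin(e.theta) * np.cos(t) + e.b * np.cos(e.theta) * np.sin(t)
        col = e.center[1] + e.a * np.cos(e.theta) * np.cos(t) - e.b * np.sin(e.theta) * np.sin(t)
        pts = np.column_stack([row, col])
    else:
        pts = contour.dominant
    x = pts[:, 1] * dx
    y = pts[:, 0] * dy
    z = np.full(len(pts), contour.slice_index * dz)
    return np.column_stack([x, y, z])


def reconstruct_cell(
    contours: list[CellContour],
    voxel_size_um: tuple[float, float, float],
    cell_id: int = 0,
    hull_source: str = "contour",
) -> CellReconstruction:
    """Convex hull of one cell's contour points across slices, in µm.

    Physical coordinates are x = col*dx, y = row*dy, z = slice*dz. Requires
    contours from at least two distinct slices — a single slice has no
    z-extent and no volume.
    """
    slices = sorted({c.slice_index for c in contours})
    if len(slices) < 2:
        raise ValueError("insufficient z-extent: contours span fewer than 2 slices")
    pts = np.vstack([_contour_points_um(c, voxel_size_um, hull_source) for c in contours])
    hull = ConvexHull(pts)
    return CellReconstruction(
        cell_id=cell_id,
        vertices_um=pts[hull.vertices],
        facets=_reindex_facets(hull),
        volume_um3=float(hull.volume),
        slice_range=(slices[0], slices[-1]),
        points_um=pts,
    )


def _reindex_facets(hull: ConvexHull) -> np.ndarray:
    remap = {v: i for i, v in enumerate(hull.vertices)}
    return np.vectorize(remap.get)(hull.simplices)


def percent_invasion(
    cell: CellReconstruction, plane: MembranePlane
) -> InvasionResult:
    """Percentage of a cell's hull volume below the membrane plane.

    Exact half-space clipping of the convex hull (see
    :mod:`mechanoinvade.geometry`), so percent-below and percent-above sum
    to 100 and the result is monotone in the plane position.
    """
    frac = fraction_below_plane(cell.points_um if cell.points_um is not None else cell.vertices_um,
                                plane.z_um)
    return InvasionResult(
        cell_id=cell.cell_id,
        percent_below=float(np.clip(100.0 * frac, 0.0, 100.0)),
        volume_um3=cell.volume_um3,
        membrane_z_um=plane.z_um,
    )


def run_qpi(
    stack: ImageStack,
    cell_channel: str = "cell",
    membrane_channel: str = "membrane",
    params: QpiParams = QpiParams(),
) -> tuple[list[InvasionResult], list[dict], dict[int, CellReconstruction]]:
    """Full Q-Pi pipeline on a two-channel stack.

    Returns ``(results, skipped, reconstructions)``: one
    :class:`InvasionResult` per reconstructed cell, a skip record (cell id +
    reason) for cells that could not be reconstructed, and the per-cell hulls
    keyed by cell id (for mesh export).
    """
    vol = stack.channel(cell_channel).astype(float)
    plane = locate_membrane(stack, membrane_channel)

    sigma_px = params.smoothing_sigma_px
    sm = ndimage.gaussian_filter(vol, sigma=(0, sigma_px, sigma_px))
    flat = _threshold_volume(sm, params)
    if flat is None:
        return [], [], {}
    labels3d, n_cells = ndimage.label(flat)

    results: list[InvasionResult] = []
    skipped: list[dict] = []
    hulls: dict[int, CellReconstruction] = {}
    for cid in range(1, n_cells + 1):
        mask3d = labels3d == cid
        if mask3d.sum() < params.min_area_px:
            continue
        if params.exclude_border and _touches_lateral_border(mask3d):
            skipped.append({"cell_id": cid, "reason": "touches lateral border"})
            continue
        contours: list[CellContour] = []
        for k in np.flatnonzero(mask3d.any(axis=(1, 2))):
            sl = mask3d[k]
            if sl.sum() < params.min_area_px:
                continue
            contours.extend(_contours_from_labels(sl.astype(int), int(k), params))
        try:
            cell = reconstruct_cell(contours, stack.voxel_size_um, cid, params.hull_source)
        except ValueError as exc:
            skipped.append({"cell_id": cid, "reason": str(exc)})
            continue
        hulls[cid] = cell
        results.append(percent_invasion(cell, plane))
    return results, skipped, hulls


def _threshold_volume(sm: np.ndarray, params: QpiParams) -> np.ndarray | None:
    if np.ptp(sm) == 0:
        return None
    t = threshold_otsu(sm)
    fg = sm > t
    if not fg.any() or fg.all():
        return None
    bg_sd = sm[~fg].std()
    if sm[fg].mean() - sm[~fg].mean() < params.min_contrast * max(bg_sd, 1e-12):
        return None
    if params.closing_radius_px > 0:
        selem = disk(params.closing_radius_px)
        # slice-wise, border-safe closing (the filters act in-plane)
        fg = np.stack([closing(sl, selem) for sl in fg])
    return fg


def _touches_lateral_border(mask3d: np.ndarray) -> bool:
    return bool(
        mask3d[:, 0, :].any()
        or mask3d[:, -1, :].any()
        or mask3d[:, :, 0].any()
        or mask3d[:, :, -1].any()
    )


def results_to_frame(results: list[InvasionResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cell_id": r.cell_id,
                "volume_um3": r.volume_um3,
                "membrane_z_um": r.membrane_z_um,
                "percent_invasion": r.percent_below,
            }
            for r in results
        ]
    )


def cumulative_invaded_count(
    daily_roi_counts: list[np.ndarray],
    mesenteries_per_day: np.ndarray,
) -> CumulativeCount:
    """Cumulative cells per mesentery per ROI over the time course.

    Each day contributes the mean cell count over its ROIs divided by the
    number of mesenteries in the well that day; means and their standard
    errors are then cumulated by running summation (errors summed, as the
    assay protocol states, not added in quadrature).
    """
    mes = np.asarray(mesenteries_per_day, dtype=float)
    if len(daily_roi_counts) != len(mes):
        raise ValueError("need one mesentery count per day")
    if (mes < 1).any():
        raise ValueError("mesentery counts must be >= 1")
    means, sems = [], []
    for counts in daily_roi_counts:
        c = np.asarray(counts, dtype=float)
        if c.size == 0:
            raise ValueError("each day needs at least one ROI count")
        means.append(c.mean())
        sems.append(c.std(ddof=1) / np.sqrt(c.size) if c.size > 1 else 0.0)
    daily_mean = np.array(means) / mes
    daily_sem = np.array(sems) / mes
    return CumulativeCount(
        daily_mean=daily_mean,
        daily_sem=daily_sem,
        cumulative_mean=np.cumsum(daily_mean),
        cumulative_sem=np.cumsum(daily_sem),
    )
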