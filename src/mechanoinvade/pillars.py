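"""Micropillar traction-force analysis.

Cells seeded on an array of elastic PDMS micropillars bend the pillars they
grip. Each pillar behaves as a cantilevered beam, so its tip is a linear
spring of stiffness k = 3EI/L^3 (I = pi d^4/64); the traction force on a
pillar is its tip displacement times k. The pipeline is:

1. detect the rest lattice in the first frame,
2. track each pillar's subpixel centre through the time-lapse (2D Gaussian
   fit of the spot's point-spread-function-like intensity profile),
3. estimate stage drift from cell-free reference pillars and subtract it,
4. convert displacements to forces and reduce to per-pillar peak forces.

Positions are (x, y) in µm; forces in nN.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from skimage.feature import peak_local_max

__all__ = [
    "PillarSpec",
    "PillarTrackSet",
    "ForceSummary",
    "compute_spring_constant",
    "detect_pillars",
    "track_pillars",
    "correct_drift",
    "forces_and_summary",
]


def compute_spring_constant(
    youngs_modulus_Pa: float, height_um: float, diameter_um: float
) -> float:
    """Lateral tip stiffness of a cylindrical micropillar, in nN/µm.

    Euler–Bernoulli cantilever under a lateral tip load:
    ``k = 3 E I / L^3`` with second moment of area ``I = pi d^4 / 64``.
    For 2 MPa PDMS pillars of 5 µm height and 1 µm diameter this evaluates
    to 2.356 nN/µm (~2.36e-3 N/m).
    """
    if youngs_modulus_Pa <= 0 or height_um <= 0 or diameter_um <= 0:
        raise ValueError("E, height and diameter must all be positive")
    i_m4 = np.pi * (diameter_um * 1e-6) ** 4 / 64.0
    k_N_per_m = 3.0 * youngs_modulus_Pa * i_m4 / (height_um * 1e-6) ** 3
    return k_N_per_m * 1e3  # N/m -> nN/µm


@dataclass(frozen=True)
class PillarSpec:
    """Pillar material and geometry; the spring constant is derived on
    construction and checked against the beam formula if supplied."""

    youngs_modulus_Pa: float = 2e6
    height_um: float = 5.0
    diameter_um: float = 1.0
    spring_constant_nN_per_um: float | None = None

    def __post_init__(self) -> None:
        k = compute_spring_constant(self.youngs_modulus_Pa, self.height_um, self.diameter_um)
        if self.spring_constant_nN_per_um is None:
            object.__setattr__(self, "spring_constant_nN_per_um", k)
        elif not np.isclose(self.spring_constant_nN_per_um, k, rtol=0.01):
            raise ValueError(
                f"supplied k={self.spring_constant_nN_per_um:.4g} nN/µm disagrees with "
                f"the beam formula ({k:.4g} nN/µm)"
            )


@dataclass
class PillarTrackSet:
    """Per-pillar, per-frame tracking results.

    ``centers_um`` has shape (n_pillars, n_frames, 2) in (x, y);
    ``displacements_um = centers - rest - drift`` where drift is the applied
    per-frame correction (zeros before :func:`correct_drift`).
    """

    pillar_ids: np.ndarray
    rest_positions_um: np.ndarray  # (n_pillars, 2)
    centers_um: np.ndarray  # (n_pillars, n_frames, 2)
    drift_um: np.ndarray  # (n_frames, 2)
    frame_interval_s: float = 1.0
    lost: np.ndarray = field(default=None)  # bool per pillar

    def __post_init__(self) -> None:
        self.pillar_ids = np.asarray(self.pillar_ids)
        self.rest_positions_um = np.asarray(self.rest_positions_um, dtype=float)
        self.centers_um = np.asarray(self.centers_um, dtype=float)
        self.drift_um = np.asarray(self.drift_um, dtype=float)
        n, t = self.centers_um.shape[:2]
        if self.rest_positions_um.shape != (n, 2) or self.drift_um.shape != (t, 2):
            raise ValueError("inconsistent track-set array shapes")
        if self.lost is None:
            self.lost = np.zeros(n, dtype=bool)

    @property
    def displacements_um(self) -> np.ndarray:
        """(n_pillars, n_frames, 2) displacement vectors, drift removed."""
        return self.centers_um - self.rest_positions_um[:, None, :] - self.drift_um[None, :, :]


@dataclass
class ForceSummary:
    """Per-pillar peak forces and the per-cell aggregate."""

    pillar_ids: np.ndarray
    positions_um: np.ndarray
    peak_force_nN: np.ndarray
    cell_aggregate_nN: float
    aggregate_mode: str
    force_nN: np.ndarray  # (n_pillars, n_frames) magnitudes

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pillar_id": self.pillar_ids,
                "x_um": self.positions_um[:, 0],
                "y_um": self.positions_um[:, 1],
                "peak_force_nN": self.peak_force_nN,
            }
        )


def detect_pillars(
    frame: np.ndarray, pitch_um: float, pixel_size_um: float
) -> np.ndarray:
    """Rest positions (x, y, µm) of the pillar lattice in the first frame.

    Local intensity maxima separated by at least half the lattice pitch are
    taken as pillar tops and refined to subpixel precision with an intensity
    centroid over a pitch-sized window. Warns when the detected count does
    not fill the lattice bounding box (missing pillars).
    """
    frame = np.asarray(frame, dtype=float)
    min_dist = max(int(0.5 * pitch_um / pixel_size_um), 1)
    thresh = frame.min() + 0.3 * (frame.max() - frame.min())
    peaks = peak_local_max(frame, min_distance=min_dist, threshold_abs=thresh)
    if len(peaks) < 4:
        raise ValueError(f"only {len(peaks)} pillars detected; need at least 4")
    half = max(int(0.4 * pitch_um / pixel_size_um), 2)
    positions = np.array(
        [_centroid(frame, r, c, half) for r, c in peaks]
    )  # (row, col) subpixel
    xy = positions[:, ::-1] * pixel_size_um
    order = np.lexsort((xy[:, 0], np.round(xy[:, 1] / pitch_um)))
    xy = xy[order]
    # lattice completeness: detected count vs bounding-box capacity
    span = xy.max(axis=0) - xy.min(axis=0)
    expected = np.prod(np.round(span / pitch_um).astype(int) + 1)
    if expected > len(xy):
        warnings.warn(
            f"lattice incomplete: {len(xy)} pillars detected, bounding box "
            f"holds {expected}",
            stacklevel=2,
        )
    return xy


def _centroid(frame: np.ndarray, row: int, col: int, half: int) -> tuple[float, float]:
    r0, r1 = max(row - half, 0), min(row + half + 1, frame.shape[0])
    c0, c1 = max(col - half, 0), min(col + half + 1, frame.shape[1])
    win = frame[r0:r1, c0:c1]
    win = win - win.min()
    total = win.sum()
    if total <= 0:
        return float(row), float(col)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    return float((rr * win).sum() / total), float((cc * win).sum() / total)


def _gauss2d(coords, amp, x0, y0, sigma, offset):
    x, y = coords
    return (amp * np.exp(-((x - x0) ** 2 + (y - y0) ** 2) / (2 * sigma**2)) + offset).ravel()


def _fit_spot(
    frame: np.ndarray, guess_xy_px: np.ndarray, half: int
) -> tuple[np.ndarray, bool]:
    """Subpixel spot centre by 2D Gaussian fit; centroid fallback.

    Returns ((x, y) in px, ok). ok is False when both the fit and the
    centroid leave the window (lost pillar).
    """
    gx, gy = guess_xy_px
    c0, r0 = int(round(gx)) - half, int(round(gy)) - half
    c1, r1 = c0 + 2 * half + 1, r0 + 2 * half + 1
    if r0 < 0 or c0 < 0 or r1 > frame.shape[0] or c1 > frame.shape[1]:
        return guess_xy_px, False
    win = frame[r0:r1, c0:c1].astype(float)
    yy, xx = np.mgrid[r0:r1, c0:c1]
    p0 = (win.max() - win.min(), gx, gy, half / 2.0, win.min())
    try:
        popt, _ = curve_fit(
            _gauss2d, (xx, yy), win.ravel(), p0=p0, maxfev=200,
        )
        x0, y0 = popt[1], popt[2]
        if abs(x0 - gx) <= half and abs(y0 - gy) <= half and popt[0] > 0:
            return np.array([x0, y0]), True
    except RuntimeError:
        pass
    row, col = _centroid(frame, int(round(gy)), int(round(gx)), half)
    ok = abs(col - gx) <= half and abs(row - gy) <= half
    return np.array([col, row]), ok


def track_pillars(
    frames: np.ndarray,
    rest_positions_um: np.ndarray,
    pixel_size_um: float,
    pitch_um: float,
    frame_interval_s: float = 1.0,
) -> PillarTrackSet:
    """Track every pillar's subpixel centre through all frames.

    Each pillar is fitted with a 2D Gaussian over a window (side 2/3 of the
    lattice pitch) centred on its position in the previous frame, so slowly
    drifting pillars stay locked. A pillar whose fit diverges or whose centre
    leaves the window is flagged as lost, not fatal. Displacements are
    relative to the frame-1 position (taken as the zero-force rest).
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3:
        raise ValueError("frames must be (n_frames, ny, nx)")
    rest = np.asarray(rest_positions_um, dtype=float)
    n, t = len(rest), len(frames)
    half = max(int(round(pitch_um / 3.0 / pixel_size_um)), 3)
    centers = np.empty((n, t, 2))
    lost = np.zeros(n, dtype=bool)
    guess = rest / pixel_size_um
    for j in range(t):
        for i in range(n):
            if lost[i]:
                centers[i, j] = centers[i, j - 1]
                continue
            pos_px, ok = _fit_spot(frames[j], guess[i], half)
            if not ok:
                lost[i] = True
                pos_px = guess[i]
            centers[i, j] = pos_px * pixel_size_um
            guess[i] = pos_px
    # rest position := frame-1 fitted position (zero-force reference)
    return PillarTrackSet(
        pillar_ids=np.arange(n),
        rest_positions_um=centers[:, 0, :].copy(),
        centers_um=centers,
        drift_um=np.zeros((t, 2)),
        frame_interval_s=frame_interval_s,
        lost=lost,
    )


def correct_drift(
    tracks: PillarTrackSet,
    reference_ids: np.ndarray,
    estimator: str = "mean",
    loaded_warning_um: float = 0.05,
) -> PillarTrackSet:
    """Subtract stage drift estimated from cell-free reference pillars.

    Per-frame drift is the mean (or median) raw displacement of the
    reference pillars. With fewer than 3 references, or references that move
    coherently like loaded pillars (net displacement above
    ``loaded_warning_um``), a warning flags possible contamination.
    """
    ref = np.asarray(reference_ids)
    if ref.size == 0:
        raise ValueError("reference pillar set is empty")
    if ref.size < 3:
        warnings.warn("fewer than 3 reference pillars; drift estimate will be noisy", stacklevel=2)
    idx = np.searchsorted(tracks.pillar_ids, ref)
    raw = tracks.centers_um[idx] - tracks.rest_positions_um[idx, None, :]
    reducer = np.median if estimator == "median" else np.mean
    drift = reducer(raw, axis=0)  # (n_frames, 2)
    resid = raw - drift[None, :, :]
    if np.linalg.norm(resid, axis=-1).max() > loaded_warning_um:
        warnings.warn(
            "a reference pillar moves relative to the common drift; the "
            "reference set may include loaded pillars",
            stacklevel=2,
        )
    return PillarTrackSet(
        pillar_ids=tracks.pillar_ids,
        rest_positions_um=tracks.rest_positions_um,
        centers_um=tracks.centers_um,
        drift_um=drift,
        frame_interval_s=tracks.frame_interval_s,
        lost=tracks.lost,
    )


def forces_and_summary(
    tracks: PillarTrackSet,
    spring_constant_nN_per_um: float,
    cell_mask: np.ndarray | None = None,
    aggregate: str = "mean_of_peaks",
) -> ForceSummary:
    """Traction forces and per-pillar peaks.

    Force magnitude is ``k * |displacement|`` per frame; the per-pillar peak
    is the max over frames. The per-cell aggregate over the masked pillars is
    the mean of per-pillar peaks by default; ``aggregate='peak_of_means'``
    instead takes the max over frames of the mean force (the two readings of
    "mean maximum force").
    """
    if spring_constant_nN_per_um <= 0:
        raise ValueError("spring constant must be positive")
    disp = tracks.displacements_um
    force = spring_constant_nN_per_um * np.linalg.norm(disp, axis=-1)  # (n, t)
    peaks = force.max(axis=1)
    sel = np.ones(len(peaks), dtype=bool) if cell_mask is None else np.asarray(cell_mask, dtype=bool)
    if aggregate == "mean_of_peaks":
        agg = float(peaks[sel].mean()) if sel.any() else np.nan
    elif aggregate == "peak_of_means":
        agg = float(force[sel].mean(axis=0).max()) if sel.any() else np.nan
    else:
        raise ValueError(f"unknown aggregate mode {aggregate!r}")
    return ForceSummary(
        pillar_ids=tracks.pillar_ids,
        positions_um=tracks.rest_positions_um,
        peak_force_nN=peaks,
        cell_aggregate_nN=agg,
        aggregate_mode=aggregate,
        force_nN=force,
    )


def peak_force_heatmap(summary: ForceSummary, pitch_um: float) -> np.ndarray:
    """Grid of per-pillar peak forces at lattice resolution (rows = y)."""
    pos = summary.positions_um
    ij = np.round((pos - pos.min(axis=0)) / pitch_um).astype(int)
    grid = np.full((ij[:, 1].max() + 1, ij[:, 0].max() + 1), np.nan)
    grid[ij[:, 1], ij[:, 0]] = summary.peak_force_nN
    return grid
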