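"""Synthetic phantoms with analytic ground truth for all four assays.

Every generator is a pure function of its spec (including the seed): the
same spec yields bit-identical output. The phantoms emulate the *geometry
and statistics* of the real data — ellipsoidal cells on a laminin bilayer,
a lattice of Gaussian pillar spots, creep-and-recover bead traces, Hertzian
approach curves — not the optics of the instruments; see docs/methods.md
for what that does and does not validate.

Conventions: z index 0 is the lowest z (substrate side, below the
membrane); voxel centres sit at ``index * voxel_size``; cells seeded above
the membrane invade toward decreasing z.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .afm import ForceCurve, HertzFit, hertz_force
from .stacks import ImageStack
from .tweezers import BeadTrace

__all__ = [
    "EllipsoidCell",
    "InvasionPhantomSpec",
    "InvasionGroundTruth",
    "PillarPhantomSpec",
    "TracePhantomSpec",
    "CurvePhantomSpec",
    "ellipsoid_fraction_below",
    "generate_invasion_stack",
    "generate_pillar_sequence",
    "generate_bead_trace",
    "generate_force_curve",
]


# --------------------------------------------------------------------------
# invasion stacks
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class EllipsoidCell:
    """One ellipsoidal cell: centre (x, y, z) µm, semi-axes (a, b, c) µm
    along (x, y, z), and its fluorescence intensity."""

    center_um: tuple[float, float, float]
    semi_axes_um: tuple[float, float, float]
    intensity: float = 1000.0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.semi_axes_um):
            raise ValueError("semi-axes must be positive")
        if self.intensity <= 0:
            raise ValueError("intensity must be positive")

    @property
    def volume_um3(self) -> float:
        a, b, c = self.semi_axes_um
        return 4.0 / 3.0 * np.pi * a * b * c


@dataclass(frozen=True)
class InvasionPhantomSpec:
    """A two-channel invasion z-stack phantom.

    The membrane channel renders the laminin bilayer as two Gaussian-profile
    horizontal planes at ``membrane_z_lower`` / ``membrane_z_upper`` µm
    (default separation 0.8 µm); the upper layer is the invasion reference
    plane. The default z-step is the 0.2 µm of the imaging protocol.
    """

    cells: tuple[EllipsoidCell, ...]
    membrane_z_upper_um: float
    membrane_z_lower_um: float
    shape_zyx: tuple[int, int, int]
    voxel_size_um: tuple[float, float, float] = (0.2, 0.15, 0.15)
    noise_sd: float = 20.0
    psf_sigma_um: float = 0.2
    membrane_sigma_um: float = 0.15
    membrane_intensity: float = 800.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.membrane_z_lower_um >= self.membrane_z_upper_um:
            raise ValueError("membrane_z_lower must be below membrane_z_upper")
        if any(v <= 0 for v in self.voxel_size_um):
            raise ValueError("voxel sizes must be positive")
        if self.noise_sd < 0 or self.psf_sigma_um < 0:
            raise ValueError("noise_sd and psf_sigma must be >= 0")


@dataclass
class InvasionGroundTruth:
    """Analytic truth per cell: percent of ellipsoid volume below the upper
    laminin layer, and the true ellipsoid volume."""

    percent_below: np.ndarray
    volume_um3: np.ndarray
    membrane_z_um: float


def ellipsoid_fraction_below(center_z_um: float, c_semi_axis_um: float, z_plane_um: float) -> float:
    """Fraction of an ellipsoid's volume with z < z_plane (closed form).

    Affine scaling along z maps any ellipsoid onto the unit sphere, so the
    fraction depends only on the normalised cap height
    u = (z_plane - (cz - c)) / c: fraction = u^2 (3 - u) / 4, clipped to
    [0, 1]. For a sphere this is the spherical-cap volume ratio
    h^2 (3r - h) / (4 r^3).
    """
    u = (z_plane_um - (center_z_um - c_semi_axis_um)) / c_semi_axis_um
    u = float(np.clip(u, 0.0, 2.0))
    return u * u * (3.0 - u) / 4.0


def generate_invasion_stack(spec: InvasionPhantomSpec) -> tuple[ImageStack, InvasionGroundTruth]:
    """Render the two-channel stack and return it with its analytic truth.

    Cells are rendered as filled ellipsoids at their voxel-centre grid, the
    bilayer as two Gaussian z-profiles, then both channels are blurred with
    an isotropic Gaussian PSF and corrupted with additive Gaussian noise
    clipped at zero.
    """
    nz, ny, nx = spec.shape_zyx
    dz, dy, dx = spec.voxel_size_um
    z = np.arange(nz) * dz
    y = np.arange(ny) * dy
    x = np.arange(nx) * dx

    cell_vol = np.zeros((nz, ny, nx), dtype=float)
    for i, cell in enumerate(spec.cells):
        cx, cy, cz = cell.center_um
        a, b, c = cell.semi_axes_um
        lo = (cx - a, cy - b, cz - c)
        hi = (cx + a, cy + b, cz + c)
        if lo[0] < 0 or lo[1] < 0 or lo[2] < 0 or hi[0] > x[-1] or hi[1] > y[-1] or hi[2] > z[-1]:
            raise ValueError(f"cell {i} extends outside the stack bounds")
        inside = (
            ((x[None, None, :] - cx) / a) ** 2
            + ((y[None, :, None] - cy) / b) ** 2
            + ((z[:, None, None] - cz) / c) ** 2
        ) <= 1.0
        cell_vol[inside] = np.maximum(cell_vol[inside], cell.intensity)

    prof = spec.membrane_intensity * (
        np.exp(-((z - spec.membrane_z_upper_um) ** 2) / (2 * spec.membrane_sigma_um**2))
        + np.exp(-((z - spec.membrane_z_lower_um) ** 2) / (2 * spec.membrane_sigma_um**2))
    )
    mem_vol = np.broadcast_to(prof[:, None, None], (nz, ny, nx)).copy()

    if spec.psf_sigma_um > 0:
        sigma_vox = tuple(spec.psf_sigma_um / d for d in (dz, dy, dx))
        cell_vol = ndimage.gaussian_filter(cell_vol, sigma_vox)
        mem_vol = ndimage.gaussian_filter(mem_vol, sigma_vox)

    rng = np.random.default_rng(spec.seed)
    data = np.stack([cell_vol, mem_vol])
    if spec.noise_sd > 0:
        data = data + rng.normal(0.0, spec.noise_sd, size=data.shape)
    data = np.clip(data, 0.0, None)

    stack = ImageStack(data, spec.voxel_size_um, ("cell", "membrane"))
    truth = InvasionGroundTruth(
        percent_below=np.array(
            [
                100.0
                * ellipsoid_fraction_below(
                    c.center_um[2], c.semi_axes_um[2], spec.membrane_z_upper_um
                )
                for c in spec.cells
            ]
        ),
        volume_um3=np.array([c.volume_um3 for c in spec.cells]),
        membrane_z_um=spec.membrane_z_upper_um,
    )
    return stack, truth


# --------------------------------------------------------------------------
# pillar time-lapse sequences
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PillarPhantomSpec:
    """A bright-field-like micropillar time-lapse phantom.

    A ``n_rows x n_cols`` lattice of Gaussian spots (sigma ``spot_sigma_um``)
    at pitch ``pitch_um`` is rendered for ``n_frames`` frames at 1 frame/s
    (the imaging protocol). ``displacements_um`` (n_pillars, n_frames, 2) in
    (x, y) adds per-pillar motion; ``drift_um`` (n_frames, 2) a common stage
    drift. Displacements beyond half the pitch would make pillar identity
    ambiguous and are rejected.
    """

    n_rows: int = 8
    n_cols: int = 8
    pitch_um: float = 2.0
    spot_sigma_um: float = 0.35
    n_frames: int = 60
    frame_interval_s: float = 1.0
    pixel_size_um: float = 0.16
    amplitude: float = 1000.0
    noise_sd: float = 10.0
    margin_um: float = 2.0
    displacements_um: np.ndarray | None = None
    drift_um: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_rows, self.n_cols) < 2 or self.n_frames < 1:
            raise ValueError("need at least a 2x2 lattice and 1 frame")
        for name in ("pitch_um", "spot_sigma_um", "frame_interval_s", "pixel_size_um", "amplitude"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        n = self.n_rows * self.n_cols
        disp = self.displacements_um
        if disp is not None:
            disp = np.asarray(disp, dtype=float)
            if disp.shape != (n, self.n_frames, 2):
                raise ValueError(
                    f"displacements must be ({n}, {self.n_frames}, 2); got {disp.shape}"
                )
            if np.abs(disp).max() > self.pitch_um / 2:
                raise ValueError(
                    "displacement exceeds half the lattice pitch (pillar identity ambiguous)"
                )
            object.__setattr__(self, "displacements_um", disp)
        if self.drift_um is not None:
            d = np.asarray(self.drift_um, dtype=float)
            if d.shape != (self.n_frames, 2):
                raise ValueError(f"drift must be ({self.n_frames}, 2); got {d.shape}")
            object.__setattr__(self, "drift_um", d)

    @property
    def n_pillars(self) -> int:
        return self.n_rows * self.n_cols

    def rest_positions_um(self) -> np.ndarray:
        """(n_pillars, 2) lattice rest positions in (x, y) µm, row-major."""
        xs = self.margin_um + np.arange(self.n_cols) * self.pitch_um
        ys = self.margin_um + np.arange(self.n_rows) * self.pitch_um
        gx, gy = np.meshgrid(xs, ys)
        return np.column_stack([gx.ravel(), gy.ravel()])


def generate_pillar_sequence(spec: PillarPhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render the frames and return ``(frames, truth_displacements)``.

    ``frames`` is (n_frames, ny, nx) float; ``truth_displacements`` is the
    (n_pillars, n_frames, 2) per-pillar displacement (drift excluded — drift
    is what tracking must remove, not a pillar property).
    """
    rest = spec.rest_positions_um()
    n = spec.n_pillars
    disp = (
        np.zeros((n, spec.n_frames, 2))
        if spec.displacements_um is None
        else spec.displacements_um
    )
    drift = np.zeros((spec.n_frames, 2)) if spec.drift_um is None else spec.drift_um

    nx = int(round((2 * spec.margin_um + (spec.n_cols - 1) * spec.pitch_um) / spec.pixel_size_um)) + 1
    ny = int(round((2 * spec.margin_um + (spec.n_rows - 1) * spec.pitch_um) / spec.pixel_size_um)) + 1
    sigma_px = spec.spot_sigma_um / spec.pixel_size_um
    half = int(np.ceil(4 * sigma_px))

    rng = np.random.default_rng(spec.seed)
    frames = np.zeros((spec.n_frames, ny, nx), dtype=float)
    for t in range(spec.n_frames):
        frame = frames[t]
        centers_px = (rest + disp[:, t, :] + drift[t]) / spec.pixel_size_um
        for cx, cy in centers_px:
            c0, r0 = int(round(cx)) - half, int(round(cy)) - half
            c1, r1 = c0 + 2 * half + 1, r0 + 2 * half + 1
            rr, cc = np.mgrid[max(r0, 0) : min(r1, ny), max(c0, 0) : min(c1, nx)]
            frame[rr, cc] += spec.amplitude * np.exp(
                -((cc - cx) ** 2 + (rr - cy) ** 2) / (2 * sigma_px**2)
            )
        if spec.noise_sd > 0:
            frame += rng.normal(0.0, spec.noise_sd, size=frame.shape)
    return np.clip(frames, 0.0, None), disp


# --------------------------------------------------------------------------
# bead traces
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TracePhantomSpec:
    """A magnetic-tweezers bead-displacement phantom.

    Default regime: 12 pulses, 3 s on, 4 s rest (the tweezer protocol).
    ``amplitudes_nm`` programmes the per-pulse response amplitude; the trace
    is baseline drift + a rise-and-relax response per pulse + noise.
    """

    amplitudes_nm: tuple[float, ...] = (100.0,) * 12
    on_s: float = 3.0
    rest_s: float = 4.0
    sample_rate_hz: float = 50.0
    drift_nm_per_s: float = 0.5
    noise_sd_nm: float = 2.0
    onset_s: float = 5.0
    tail_s: float = 3.0
    rise_tau_s: float = 0.25
    fall_tau_s: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "amplitudes_nm", tuple(float(a) for a in self.amplitudes_nm))
        if len(self.amplitudes_nm) < 2:
            raise ValueError("need at least 2 pulses")
        if any(a <= 0 for a in self.amplitudes_nm):
            raise ValueError("pulse amplitudes must be positive")
        if self.on_s <= 0 or self.rest_s <= 0 or self.sample_rate_hz <= 0:
            raise ValueError("durations and sample rate must be positive")
        if self.sample_rate_hz * self.on_s < 2:
            raise ValueError(
                f"sample rate {self.sample_rate_hz} Hz cannot resolve a "
                f"{self.on_s} s pulse (< 2 samples per on-phase)"
            )

    @property
    def n_pulses(self) -> int:
        return len(self.amplitudes_nm)

    @property
    def duration_s(self) -> float:
        return self.onset_s + self.n_pulses * (self.on_s + self.rest_s) + self.tail_s


def generate_bead_trace(spec: TracePhantomSpec) -> tuple[BeadTrace, np.ndarray]:
    """Synthesise one bead trace; returns ``(trace, truth_amplitudes_nm)``.

    During each on-phase the displacement rises toward the programmed
    amplitude with time constant ``rise_tau_s`` (reaching it to within
    exp(-on/tau), < 1e-5 of A at the defaults) and relaxes back during rest,
    on top of a linear baseline drift.
    """
    n = int(round(spec.duration_s * spec.sample_rate_hz))
    t = np.arange(n) / spec.sample_rate_hz
    d = spec.drift_nm_per_s * t
    period = spec.on_s + spec.rest_s
    for i, amp in enumerate(spec.amplitudes_nm):
        t_on = spec.onset_s + i * period
        t_off = t_on + spec.on_s
        rising = (t >= t_on) & (t < t_off)
        d[rising] += amp * (1.0 - np.exp(-(t[rising] - t_on) / spec.rise_tau_s))
        peak = amp * (1.0 - np.exp(-spec.on_s / spec.rise_tau_s))
        falling = t >= t_off
        d[falling] += peak * np.exp(-(t[falling] - t_off) / spec.fall_tau_s)
    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd_nm > 0:
        d = d + rng.normal(0.0, spec.noise_sd_nm, size=n)
    return BeadTrace(t, d), np.asarray(spec.amplitudes_nm, dtype=float)


# --------------------------------------------------------------------------
# AFM approach curves
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CurvePhantomSpec:
    """A Hertzian AFM approach-curve phantom.

    Defaults follow the instrument configuration: 15 µm bead (R = 7.5 µm),
    0.03 N/m cantilever, 1 nN set force, 5 µm/s approach. The pre-contact
    region is flat (plus noise); past contact the force follows the
    spherical-indenter Hertz law with the cantilever-deflection-corrected
    indentation delta = travel - F/k.
    """

    youngs_modulus_Pa: float = 300.0
    poisson_ratio: float = 0.5
    indenter_radius_um: float = 7.5
    spring_constant_N_per_m: float = 0.03
    contact_point_um: float = 2.0
    approach_speed_um_per_s: float = 5.0
    max_force_nN: float = 1.0
    noise_sd_pN: float = 20.0
    sample_rate_hz: float = 2000.0
    max_travel_um: float = 8.0
    baseline_nN: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.youngs_modulus_Pa <= 0:
            raise ValueError("Young's modulus must be positive")
        if not 0 <= self.poisson_ratio <= 0.5:
            raise ValueError("Poisson ratio must lie in [0, 0.5]")
        for name in (
            "indenter_radius_um",
            "spring_constant_N_per_m",
            "approach_speed_um_per_s",
            "max_force_nN",
            "sample_rate_hz",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def generate_force_curve(spec: CurvePhantomSpec) -> tuple[ForceCurve, HertzFit]:
    """Synthesise an approach curve; returns ``(curve, truth_fit)``.

    The force past contact solves F = pref * (s - F/k)^(3/2) for piezo travel
    s past the contact point (Newton iteration on the monotone inverse). The
    sweep stops at the set force; if that force is not reachable within
    ``max_travel_um`` past contact the spec is rejected.
    """
    pref1 = hertz_force(1.0, spec.youngs_modulus_Pa, spec.indenter_radius_um, spec.poisson_ratio)
    k_um = spec.spring_constant_N_per_m * 1e3  # nN/µm
    delta_max = (spec.max_force_nN / pref1) ** (2.0 / 3.0)
    travel_needed = delta_max + spec.max_force_nN / k_um
    if travel_needed > spec.max_travel_um:
        raise ValueError(
            f"set force {spec.max_force_nN} nN needs {travel_needed:.2f} µm past "
            f"contact, beyond the {spec.max_travel_um} µm sampled range"
        )
    dz = spec.approach_speed_um_per_s / spec.sample_rate_hz
    z = np.arange(0.0, spec.contact_point_um + travel_needed * 1.05, dz)
    s = np.clip(z - spec.contact_point_um, 0.0, None)

    # invert s = delta + pref*delta^1.5/k by Newton (g is convex, g' >= 1)
    delta = s.copy()
    for _ in range(60):
        g = delta + pref1 * delta**1.5 / k_um - s
        gp = 1.0 + 1.5 * pref1 * np.sqrt(delta) / k_um
        step = g / gp
        delta = np.clip(delta - step, 0.0, None)
        if np.abs(step).max() < 1e-14:
            break
    force = pref1 * delta**1.5 + spec.baseline_nN

    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd_pN > 0:
        force = force + rng.normal(0.0, spec.noise_sd_pN * 1e-3, size=force.shape)

    curve = ForceCurve(
        z,
        force,
        spring_constant_N_per_m=spec.spring_constant_N_per_m,
        indenter_radius_um=spec.indenter_radius_um,
        approach_speed_um_per_s=spec.approach_speed_um_per_s,
    )
    truth = HertzFit(
        youngs_modulus_Pa=spec.youngs_modulus_Pa,
        contact_point_um=spec.contact_point_um,
        poisson_ratio=spec.poisson_ratio,
        residual_rms_pN=0.0,
        fitted_range_um=(spec.contact_point_um, float(z[-1])),
    )
    return curve, truth
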