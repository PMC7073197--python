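"""AFM compliance: Hertz spherical-indenter fits of approach curves.

A soft cantilever (spring constant ~0.03 N/m) carrying a glass bead
(radius R ~ 7.5 µm) is driven into the cell until a set force (~1 nN) is
reached. Past the contact point the force follows the Hertz law for a rigid
sphere on an elastic half-space,

    F = (4/3) * E / (1 - nu^2) * sqrt(R) * delta^(3/2),

where delta is the indentation depth and E the Young's modulus. The
indentation is the piezo travel past contact minus the cantilever's own
deflection F/k. Fitting the post-contact region of the approach curve for
(contact point, E) yields the cell's compliance; only approach curves are
analysed.

Units: positions/indentations in µm, forces in nN, E in Pa, k in N/m.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

__all__ = [
    "ForceCurve",
    "HertzFit",
    "hertz_force",
    "estimate_contact_point",
    "fit_hertz",
    "fit_batch",
]

# k [N/m] -> [nN/µm]: 1 N/m = 1e9 nN / 1e6 µm
_N_PER_M_TO_NN_PER_UM = 1e3
# Hertz prefactor unit bridge: E[Pa]*sqrt(R[µm])*delta[µm]^1.5 -> nN
# (4/3)*E*sqrt(R*1e-6)*(d*1e-6)^1.5 N = (4/3)*E*sqrt(R)*d^1.5 * 1e-12 N = ... * 1e-3 nN
_HERTZ_UNIT = 1e-3


@dataclass
class ForceCurve:
    """An approach force curve: piezo position (µm, increasing toward the
    cell) versus calibrated force (nN)."""

    position_um: np.ndarray
    force_nN: np.ndarray
    spring_constant_N_per_m: float = 0.03
    indenter_radius_um: float = 7.5
    approach_speed_um_per_s: float = 5.0

    def __post_init__(self) -> None:
        self.position_um = np.asarray(self.position_um, dtype=float)
        self.force_nN = np.asarray(self.force_nN, dtype=float)
        if self.position_um.shape != self.force_nN.shape or self.position_um.ndim != 1:
            raise ValueError("position and force must be 1D arrays of equal length")
        if (np.diff(self.position_um) <= 0).any():
            raise ValueError("approach coordinate must be strictly increasing")
        if self.spring_constant_N_per_m <= 0 or self.indenter_radius_um <= 0:
            raise ValueError("spring constant and indenter radius must be positive")

    @classmethod
    def from_csv(cls, path, **kwargs) -> "ForceCurve":
        df = pd.read_csv(path)
        return cls(df["position_um"].to_numpy(), df["force_nN"].to_numpy(), **kwargs)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"position_um": self.position_um, "force_nN": self.force_nN}
        ).to_csv(path, index=False)


@dataclass
class HertzFit:
    """Result of a Hertz fit: modulus, contact point and fit quality."""

    youngs_modulus_Pa: float
    contact_point_um: float
    poisson_ratio: float
    residual_rms_pN: float
    fitted_range_um: tuple[float, float]

    def __post_init__(self) -> None:
        if self.youngs_modulus_Pa <= 0:
            raise ValueError("Young's modulus must be positive")


def hertz_force(
    indentation_um: np.ndarray | float,
    youngs_modulus_Pa: float,
    radius_um: float,
    poisson_ratio: float = 0.5,
) -> np.ndarray | float:
    """Hertz force (nN) of a rigid sphere indenting an elastic half-space.

    ``F = (4/3) E/(1-nu^2) sqrt(R) delta^(3/2)``; nu = 0.5 is the
    incompressible limit commonly assumed for cells.
    """
    delta = np.asarray(indentation_um, dtype=float)
    if (delta < 0).any():
        raise ValueError("indentation must be >= 0")
    if youngs_modulus_Pa <= 0 or radius_um <= 0:
        raise ValueError("E and R must be positive")
    if not 0 <= poisson_ratio <= 0.5:
        raise ValueError("Poisson ratio must lie in [0, 0.5]")
    pref = (4.0 / 3.0) * youngs_modulus_Pa / (1.0 - poisson_ratio**2) * np.sqrt(radius_um)
    out = pref * delta**1.5 * _HERTZ_UNIT
    return float(out) if np.isscalar(indentation_um) else out


def _joint_residual(
    curve: ForceCurve,
    zc: float,
    poisson_ratio: float,
    max_force_nN: float | None,
) -> tuple[float, float, float]:
    """(SSR, fitted prefactor, baseline) for a candidate contact point.

    Pre-contact samples are fitted with a flat baseline, post-contact samples
    with the Hertz law in deflection-corrected indentation
    ``delta = (z - zc) - F/k``. The prefactor is the closed-form linear
    least-squares solution given the candidate zc.
    """
    z, f = curve.position_um, curve.force_nN
    pre = z < zc
    post = ~pre
    if pre.sum() < 2 or post.sum() < 2:
        return np.inf, np.nan, np.nan
    baseline = float(f[pre].mean())
    k_um = curve.spring_constant_N_per_m * _N_PER_M_TO_NN_PER_UM
    fnet = f[post] - baseline
    delta = np.clip(z[post] - zc - fnet / k_um, 0.0, None)
    if max_force_nN is not None:
        keep = fnet <= max_force_nN
        fnet, delta = fnet[keep], delta[keep]
        if len(fnet) < 2:
            return np.inf, np.nan, np.nan
    x = delta**1.5
    denom = float(x @ x)
    pref = float(x @ fnet) / denom if denom > 0 else 0.0
    pref = max(pref, 0.0)
    ssr = float(((f[pre] - baseline) ** 2).sum() + ((fnet - pref * x) ** 2).sum())
    return ssr, pref, baseline


def estimate_contact_point(
    curve: ForceCurve,
    poisson_ratio: float = 0.5,
    max_force_nN: float | None = None,
) -> float:
    """Contact point (µm) minimising the joint baseline + Hertz residual.

    A coarse scan over candidate positions brackets the optimum, then a
    golden-section refinement (bounded scalar minimisation) localises it to
    sub-sample precision. The curve must include a pre-contact baseline and a
    rising post-contact region.
    """
    z, f = curve.position_um, curve.force_nN
    if len(z) < 20:
        raise ValueError("curve too short to estimate a contact point")
    # Require a detectable contact: the top of the curve must rise well above
    # baseline scatter, else the curve never touched the cell.
    head = f[: max(10, len(f) // 10)]
    noise = max(float(head.std()), 1e-12)
    if f[-5:].mean() - head.mean() < 5 * noise:
        raise ValueError("no contact detected: curve has no rising region above baseline")

    candidates = z[5:-10]
    ssrs = np.array([_joint_residual(curve, zc, poisson_ratio, max_force_nN)[0] for zc in candidates])
    i = int(np.argmin(ssrs))
    lo = candidates[max(i - 2, 0)]
    hi = candidates[min(i + 2, len(candidates) - 1)]
    if hi <= lo:
        return float(candidates[i])
    res = minimize_scalar(
        lambda zc: _joint_residual(curve, zc, poisson_ratio, max_force_nN)[0],
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-6},
    )
    return float(res.x)


def fit_hertz(
    curve: ForceCurve,
    poisson_ratio: float = 0.5,
    max_force_nN: float | None = 1.0,
    contact_point_um: float | None = None,
) -> HertzFit:
    """Fit Young's modulus over the post-contact region up to the set force.

    ``max_force_nN`` limits the fitted range to the region the instrument
    was configured for (default 1 nN, the usual set force); pass None to use
    the whole post-contact region.
    """
    if contact_point_um is None:
        contact_point_um = estimate_contact_point(curve, poisson_ratio, max_force_nN)
    ssr, pref, baseline = _joint_residual(curve, contact_point_um, poisson_ratio, max_force_nN)
    if not np.isfinite(ssr):
        raise ValueError("Hertz fit failed: no usable pre/post-contact split")
    post = curve.position_um >= contact_point_um
    n_post = int(post.sum())
    if n_post < 10:
        raise ValueError(f"only {n_post} post-contact samples; need >= 10")
    e_fit = pref / ((4.0 / 3.0) / (1.0 - poisson_ratio**2) * np.sqrt(curve.indenter_radius_um) * _HERTZ_UNIT)
    if e_fit <= 0:
        raise ValueError("Hertz fit produced a non-positive modulus")
    # RMS over the fitted post-contact region, in pN
    k_um = curve.spring_constant_N_per_m * _N_PER_M_TO_NN_PER_UM
    fnet = curve.force_nN[post] - baseline
    delta = np.clip(curve.position_um[post] - contact_point_um - fnet / k_um, 0.0, None)
    if max_force_nN is not None:
        keep = fnet <= max_force_nN
        fnet, delta = fnet[keep], delta[keep]
    resid = fnet - pref * delta**1.5
    return HertzFit(
        youngs_modulus_Pa=float(e_fit),
        contact_point_um=float(contact_point_um),
        poisson_ratio=poisson_ratio,
        residual_rms_pN=float(np.sqrt((resid**2).mean()) * 1e3),
        fitted_range_um=(float(contact_point_um), float(curve.position_um[post][-1])),
    )


def fit_batch(
    paths: list[str | Path],
    poisson_ratio: float = 0.5,
    max_force_nN: float | None = 1.0,
    **curve_kwargs,
) -> pd.DataFrame:
    """Fit every curve in a batch; the summary row carries both the mean and
    the median modulus (cohort moduli are conventionally reported either
    way, so both are provided)."""
    rows = []
    for p in paths:
        curve = ForceCurve.from_csv(p, **curve_kwargs)
        fit = fit_hertz(curve, poisson_ratio, max_force_nN)
        rows.append(
            {
                "curve": str(p),
                "E_Pa": fit.youngs_modulus_Pa,
                "contact_point_um": fit.contact_point_um,
                "residual_rms_pN": fit.residual_rms_pN,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["E_mean_Pa"] = float(df["E_Pa"].mean()) if len(df) else np.nan
    df.attrs["E_median_Pa"] = float(df["E_Pa"].median()) if len(df) else np.nan
    return df
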