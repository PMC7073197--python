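"""Magnetic-tweezers mechanosensing analysis.

A fibronectin-coated paramagnetic bead bound to the cell surface is pulled
with a pulsatile force regime — by default 12 pulses of 1 nN, 3 s on and 4 s
rest between pulses. A cell that mechanosenses stiffens under the repeated
load, so the bead displacement amplitude shrinks from pulse to pulse. The
headline statistic is the relative decrease from the first to the last
pulse: r12 = A12 / A1 and decrease = 1 - r12, computed on amplitudes
(per-pulse maximum minus per-pulse start, which cancels slow bead drift).
Traces whose 12th-pulse amplitude is not smaller than the 1st are excluded
from the stiffening statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PulseRegime",
    "BeadTrace",
    "PulseMetrics",
    "segment_pulses",
    "pulse_amplitudes",
    "mechanosensing_metric",
    "analyze_trace",
    "analyze_cohort",
]


@dataclass(frozen=True)
class PulseRegime:
    """The pulsatile force protocol applied by the tweezers."""

    n_pulses: int = 12
    force_nN: float = 1.0
    on_s: float = 3.0
    rest_s: float = 4.0

    def __post_init__(self) -> None:
        if self.n_pulses < 2:
            raise ValueError("a pulse regime needs at least 2 pulses")
        for name in ("force_nN", "on_s", "rest_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def period_s(self) -> float:
        return self.on_s + self.rest_s

    @property
    def duration_s(self) -> float:
        """Time from first pulse onset to the end of the last on-phase."""
        return (self.n_pulses - 1) * self.period_s + self.on_s


@dataclass
class BeadTrace:
    """A bead displacement time series (uniformly sampled)."""

    time_s: np.ndarray
    displacement_nm: np.ndarray

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.displacement_nm = np.asarray(self.displacement_nm, dtype=float)
        if self.time_s.ndim != 1 or self.time_s.shape != self.displacement_nm.shape:
            raise ValueError("time and displacement must be 1D arrays of equal length")
        dt = np.diff(self.time_s)
        if len(dt) == 0 or (dt <= 0).any():
            raise ValueError("time must be strictly increasing")
        if np.ptp(dt) > 0.01 * dt.mean():
            raise ValueError("sampling must be uniform (jitter above 1%)")

    @property
    def sample_rate_hz(self) -> float:
        return 1.0 / float(np.diff(self.time_s).mean())

    @classmethod
    def from_csv(cls, path) -> "BeadTrace":
        df = pd.read_csv(path)
        return cls(df["time_s"].to_numpy(), df["displacement_nm"].to_numpy())

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"time_s": self.time_s, "displacement_nm": self.displacement_nm}
        ).to_csv(path, index=False)


@dataclass
class PulseMetrics:
    """Per-pulse amplitude summary of one bead trace.

    ``amplitude_nm[i] = max(displacement in pulse i) - displacement at pulse-i
    start``; ``relative[i] = A_i / A_1`` so ``relative[0] == 1`` exactly.
    """

    start_nm: np.ndarray
    max_nm: np.ndarray
    amplitude_nm: np.ndarray
    onset_s: float
    relative: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        for name in ("start_nm", "max_nm", "amplitude_nm"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (len(self.start_nm) == len(self.max_nm) == len(self.amplitude_nm)):
            raise ValueError("per-pulse arrays must have equal length")
        a1 = self.amplitude_nm[0]
        with np.errstate(divide="ignore", invalid="ignore"):
            self.relative = self.amplitude_nm / a1 if a1 != 0 else np.full_like(self.amplitude_nm, np.nan)


def segment_pulses(
    trace: BeadTrace,
    regime: PulseRegime = PulseRegime(),
    onset_s: float | None = None,
) -> list[tuple[int, int]]:
    """Half-open sample windows ``[start, end)`` covering each on-phase.

    Pulse ``i`` (0-based) spans ``[onset + i*period, onset + i*period + on)``
    seconds. When ``onset_s`` is not given it is estimated by sliding the
    regime's on/off template over the trace derivative and maximising the
    correlation — the response rises during on-phases and relaxes during
    rest, so the derivative is template-like even for creeping beads.
    """
    fs = trace.sample_rate_hz
    if fs * regime.on_s < 2:
        raise ValueError(
            f"sample rate {fs:.3g} Hz gives fewer than 2 samples per "
            f"{regime.on_s} s on-phase"
        )
    t0, t1 = trace.time_s[0], trace.time_s[-1]
    if onset_s is None:
        onset_s = _estimate_onset(trace, regime)
    if onset_s + regime.duration_s > t1 + 0.5 / fs:
        raise ValueError(
            f"trace ends at {t1:.3g} s but the regime needs "
            f"{onset_s + regime.duration_s:.3g} s"
        )
    windows = []
    for i in range(regime.n_pulses):
        ws = onset_s + i * regime.period_s
        start = int(np.searchsorted(trace.time_s, ws - 0.5 / fs))
        end = int(np.searchsorted(trace.time_s, ws + regime.on_s - 0.5 / fs))
        windows.append((start, end))
    if windows[0][0] < 0 or trace.time_s[windows[0][0]] < t0 - 0.5 / fs:
        raise ValueError("onset lies before the start of the trace")
    return windows


def _estimate_onset(trace: BeadTrace, regime: PulseRegime) -> float:
    """Onset time maximising correlation of d(trace)/dt with the on/off template."""
    fs = trace.sample_rate_hz
    deriv = np.diff(trace.displacement_nm)
    n_tpl = int(round(regime.duration_s * fs))
    if n_tpl >= len(deriv):
        raise ValueError("trace too short to estimate the pulse onset")
    t_rel = np.arange(n_tpl) / fs
    phase = np.mod(t_rel, regime.period_s)
    template = np.where(phase < regime.on_s, 1.0, -regime.on_s / regime.rest_s)
    corr = np.correlate(deriv, template, mode="valid")
    return float(trace.time_s[int(np.argmax(corr))])


def pulse_amplitudes(trace: BeadTrace, windows: list[tuple[int, int]]) -> PulseMetrics:
    """Per-pulse start, max and amplitude (max - start).

    The per-pulse start subtraction is the drift handling: slow bead drift
    raises starts and maxima together, so amplitudes are unaffected. No
    detrending is applied.
    """
    starts, maxima = [], []
    for i, (s, e) in enumerate(windows):
        if e - s < 2:
            raise ValueError(f"pulse window {i} has fewer than 2 samples")
        seg = trace.displacement_nm[s:e]
        starts.append(seg[0])
        maxima.append(seg.max())
    starts = np.array(starts)
    maxima = np.array(maxima)
    return PulseMetrics(
        start_nm=starts,
        max_nm=maxima,
        amplitude_nm=maxima - starts,
        onset_s=float(trace.time_s[windows[0][0]]),
    )


def baseline_noise_sd(trace: BeadTrace, onset_s: float) -> float:
    """Robust (MAD-based) SD of the pre-onset baseline, in nm."""
    pre = trace.displacement_nm[trace.time_s < onset_s]
    if len(pre) < 4:
        return 0.0
    detrended = pre - np.polyval(np.polyfit(trace.time_s[: len(pre)], pre, 1), trace.time_s[: len(pre)])
    return float(1.4826 * np.median(np.abs(detrended - np.median(detrended))))


def mechanosensing_metric(
    metrics: PulseMetrics, noise_threshold_nm: float = 0.0
) -> tuple[float, float, bool]:
    """Stiffening statistic of one trace: ``(r12, percent decrease, included)``.

    ``r12 = A_last / A_first`` and ``decrease = 100 * (1 - r12)``. The trace
    is included in the cohort statistic iff the last-pulse amplitude is
    strictly smaller than the first (stiffening response). A first-pulse
    amplitude at or below ``noise_threshold_nm`` means the bead never
    responded and is an error, not a zero.
    """
    a1 = float(metrics.amplitude_nm[0])
    a_last = float(metrics.amplitude_nm[-1])
    if a1 <= noise_threshold_nm:
        raise ValueError(
            f"no initial response: A1 = {a1:.3g} nm <= threshold {noise_threshold_nm:.3g} nm"
        )
    r = a_last / a1
    return r, 100.0 * (1.0 - r), a_last < a1


def analyze_trace(
    trace: BeadTrace,
    regime: PulseRegime = PulseRegime(),
    onset_s: float | None = None,
) -> dict:
    """Full single-trace analysis; one row of the cohort table.

    The no-response threshold is 3x the robust SD of the pre-onset baseline
    (beads whose first-pulse amplitude is indistinguishable from noise carry
    no mechanosensing information). Beads with negative first amplitude
    (moving against the force) are excluded with a reason code.
    """
    windows = segment_pulses(trace, regime, onset_s)
    metrics = pulse_amplitudes(trace, windows)
    threshold = 3.0 * baseline_noise_sd(trace, metrics.onset_s)
    row = {
        "A1_nm": float(metrics.amplitude_nm[0]),
        "A12_nm": float(metrics.amplitude_nm[-1]),
        "r12": np.nan,
        "decrease_pct": np.nan,
        "included": False,
        "exclusion_reason": "",
    }
    if metrics.amplitude_nm[0] <= 0:
        row["exclusion_reason"] = "negative_or_zero_A1"
        return row
    try:
        r, dec, included = mechanosensing_metric(metrics, threshold)
    except ValueError:
        row["exclusion_reason"] = "no_initial_response"
        return row
    row.update(r12=r, decrease_pct=dec, included=included)
    if not included:
        row["exclusion_reason"] = "A12_not_below_A1"
    return row


def analyze_cohort(
    traces: list[BeadTrace],
    regime: PulseRegime = PulseRegime(),
    onset_s: float | None = None,
) -> pd.DataFrame:
    """Per-trace rows for a cohort; the cohort statistic is the mean of
    ``decrease_pct`` over included traces (ratios averaged per bead)."""
    rows = [analyze_trace(t, regime, onset_s) for t in traces]
    return pd.DataFrame(rows)
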