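"""Time-course conditioning and quality control.

Conditioning follows a fixed order — linear detrend, robust-z despike,
zero-phase low-pass at 0.15 Hz — applied per component.  Subject-level QC
excludes high-motion subjects (mean frame-wise displacement > 0.2 mm, or any
translation > 3 mm / rotation > 3 degrees).  Component-level selection keeps
components whose low-frequency to high-frequency spectral power ratio
exceeds 4.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .containers import TimecourseSet

__all__ = [
    "n_volumes",
    "discard_initial",
    "detrend",
    "despike",
    "lowpass",
    "condition",
    "power_ratio",
    "component_power_ratios",
    "select_components",
    "QCResult",
    "qc_subject",
]

#: Conditioning order applied by :func:`condition`, recorded in provenance.
CONDITIONING_ORDER = ("detrend", "despike", "lowpass")


def n_volumes(duration_seconds: float, tr_seconds: float) -> int:
    """Number of volumes collected in ``duration_seconds`` at the given TR."""
    if tr_seconds <= 0:
        raise ValueError("tr_seconds must be positive")
    return int(round(duration_seconds / tr_seconds))


def discard_initial(ts: TimecourseSet, n_discard: int = 10) -> TimecourseSet:
    """Drop the first ``n_discard`` volumes (signal-stabilization discard)."""
    if n_discard < 0 or n_discard >= ts.n_timepoints:
        raise ValueError("n_discard must be in [0, T)")
    return ts.with_data(ts.data[n_discard:])


def detrend(ts: TimecourseSet) -> TimecourseSet:
    """Remove the per-component least-squares linear trend (and mean).

    Constant columns come back as all zeros.
    """
    if ts.n_timepoints < 3:
        raise ValueError("detrend requires T >= 3")
    return ts.with_data(signal.detrend(ts.data, axis=0, type="linear"))


def despike(ts: TimecourseSet, robust_z: float = 4.0) -> TimecourseSet:
    """Replace outlier samples by interpolation between non-spike neighbors.

    A sample is a spike when |x - median| / (1.4826 * MAD) > ``robust_z``.
    Spikes are replaced by linear interpolation between the nearest non-spike
    samples (edge spikes take the nearest valid value).  Components with
    MAD = 0 are passed through untouched.
    """
    if ts.n_timepoints < 5:
        raise ValueError("despike requires T >= 5")
    if robust_z <= 0:
        raise ValueError("robust_z must be positive")
    data = ts.data.copy()
    t = data.shape[0]
    idx = np.arange(t)
    for c in range(data.shape[1]):
        x = data[:, c]
        med = np.median(x)
        mad = np.median(np.abs(x - med))
        if mad == 0:
            continue
        z = np.abs(x - med) / (1.4826 * mad)
        spikes = z > robust_z
        if not spikes.any() or spikes.all():
            continue
        good = ~spikes
        # np.interp holds edge values constant outside the valid range
        data[spikes, c] = np.interp(idx[spikes], idx[good], x[good])
    return ts.with_data(data)


def lowpass(ts: TimecourseSet, cutoff_hz: float = 0.15, order: int = 5) -> TimecourseSet:
    """Zero-phase Butterworth low-pass (applied forward and backward)."""
    fs = 1.0 / ts.tr_seconds
    nyquist = fs / 2.0
    if not 0 < cutoff_hz < nyquist:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={nyquist:.3g}) Hz"
        )
    sos = signal.butter(order, cutoff_hz, btype="low", fs=fs, output="sos")
    return ts.with_data(signal.sosfiltfilt(sos, ts.data, axis=0))


def condition(
    ts: TimecourseSet,
    robust_z: float = 4.0,
    cutoff_hz: float = 0.15,
) -> tuple[TimecourseSet, list[str]]:
    """Apply the full conditioning chain; returns (result, steps applied)."""
    out = lowpass(despike(detrend(ts), robust_z=robust_z), cutoff_hz=cutoff_hz)
    return out, list(CONDITIONING_ORDER)


def power_ratio(
    x: np.ndarray,
    tr_seconds: float,
    low_band: tuple[float, float] = (0.0, 0.10),
    high_band: tuple[float, float] = (0.15, 0.25),
) -> float:
    """Low-band to high-band integrated spectral power ratio of one series.

    Uses a Welch periodogram (segment length min(T, 64), 50% overlap) and
    trapezoidal band integration.  Zero high-band power returns ``inf``.
    """
    x = np.asarray(x, dtype=float)
    fs = 1.0 / tr_seconds
    nyq = fs / 2.0
    for lo, hi in (low_band, high_band):
        if not (0.0 <= lo < hi <= nyq + 1e-12):
            raise ValueError("bands must satisfy 0 <= lo < hi <= Nyquist")
    nperseg = min(x.size, 64)
    freqs, pxx = signal.welch(x, fs=fs, nperseg=nperseg, noverlap=nperseg // 2)

    def band_power(lo, hi):
        mask = (freqs >= lo) & (freqs <= hi)
        if mask.sum() < 2:
            return float(pxx[mask].sum())
        return float(np.trapezoid(pxx[mask], freqs[mask]))

    low = band_power(*low_band)
    high = band_power(*high_band)
    if high == 0.0:
        return float("inf")
    return low / high


def component_power_ratios(ts: TimecourseSet, **kwargs) -> np.ndarray:
    """:func:`power_ratio` for every component column."""
    return np.array(
        [power_ratio(ts.data[:, c], ts.tr_seconds, **kwargs)
         for c in range(ts.n_components)]
    )


def select_components(
    ts: TimecourseSet, min_ratio: float = 4.0, **kwargs
) -> np.ndarray:
    """Boolean mask of components passing the spectral power-ratio criterion."""
    return component_power_ratios(ts, **kwargs) > min_ratio


@dataclass
class QCResult:
    subject_id: str
    passed: bool
    reasons: list[str] = field(default_factory=list)
    mean_fd: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "passed": self.passed,
            "reasons": list(self.reasons),
            "mean_fd": self.mean_fd,
        }


def qc_subject(
    fd_trace: np.ndarray,
    translations_mm: np.ndarray | None = None,
    rotations_deg: np.ndarray | None = None,
    mean_fd_max: float = 0.2,
    max_disp_mm: float = 3.0,
    max_rot_deg: float = 3.0,
    subject_id: str = "",
) -> QCResult:
    """Motion QC: fail on mean FD, peak translation, or peak rotation.

    ``translations_mm`` / ``rotations_deg`` are optional per-volume realignment
    parameter arrays; when omitted only the mean-FD rule applies.
    """
    fd = np.asarray(fd_trace, dtype=float)
    if fd.size == 0:
        raise ValueError("fd_trace must be non-empty")
    if np.any(fd < 0):
        raise ValueError("frame-wise displacement cannot be negative")
    reasons = []
    mean_fd = float(fd.mean())
    if mean_fd > mean_fd_max:
        reasons.append(f"mean FD {mean_fd:.3f} mm > {mean_fd_max} mm")
    if translations_mm is not None:
        peak = float(np.max(np.abs(translations_mm)))
        if peak > max_disp_mm:
            reasons.append(f"max displacement {peak:.2f} mm > {max_disp_mm} mm")
    if rotations_deg is not None:
        peak = float(np.max(np.abs(rotations_deg)))
        if peak > max_rot_deg:
            reasons.append(f"max rotation {peak:.2f} deg > {max_rot_deg} deg")
    return QCResult(
        subject_id=subject_id,
        passed=not reasons,
        reasons=reasons,
        mean_fd=mean_fd,
    )
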