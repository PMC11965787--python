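"""Pulse detection and RR-interval feature extraction.

The classifier consumes a fixed 13-dimensional vector of RR irregularity
statistics per recording: standard heart-rate-variability measures that
discriminate the irregularly irregular AF response from sinus rhythm, plus
a comb residual that detects the integer-multiple RR structure of atrial
flutter with variable AV conduction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .ppg_sim import PpgRecording, RrSeries, RR_MIN, RR_MAX
from .signal_quality import QualityAssessment, find_pulse_peaks

FEATURE_NAMES = [
    "mean_rr",
    "sdnn",
    "cv",
    "rmssd",
    "nrmssd",
    "prr50",
    "rr_entropy",
    "sample_entropy",
    "poincare_ratio",
    "lag1_autocorr",
    "turning_point_ratio",
    "mad_rr",
    "comb_residual",
]

MIN_INTERVALS = 10


class UndiagnosableRecording(Exception):
    """Too few usable beat-to-beat intervals to attempt a rhythm diagnosis."""


@dataclass
class FeatureVector:
    values: dict[str, float]

    def __post_init__(self) -> None:
        missing = set(FEATURE_NAMES) - set(self.values)
        if missing:
            raise ValueError(f"missing features: {sorted(missing)}")
        arr = self.as_array()
        if not np.all(np.isfinite(arr)):
            raise ValueError("features must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.values[k] for k in FEATURE_NAMES], dtype=float)


def _refine_peak_times(x: np.ndarray, peaks: np.ndarray, fs: float) -> np.ndarray:
    """Sub-sample peak times via parabolic interpolation of the apex."""
    times = []
    for p in peaks:
        if 0 < p < len(x) - 1:
            denom = x[p - 1] - 2 * x[p] + x[p + 1]
            delta = 0.5 * (x[p - 1] - x[p + 1]) / denom if denom != 0 else 0.0
            delta = float(np.clip(delta, -0.5, 0.5))
        else:
            delta = 0.0
        times.append((p + delta) / fs)
    return np.array(times)


def detect_pulses(rec: PpgRecording, qa: QualityAssessment) -> RrSeries:
    """Beat-to-beat intervals from pulse peaks inside good-quality spans.

    Peaks are detected separately within each maximal run of consecutive
    good windows, so no interval ever bridges a bad window.  Intervals
    outside the physiological range are discarded as detection errors.
    """
    if not qa.sufficient:
        raise ValueError("recording did not pass the signal-quality gate")
    intervals: list[float] = []
    for lo, hi in qa.good_spans(rec.fs):
        seg = rec.samples[lo:hi]
        peaks = find_pulse_peaks(seg, rec.fs)
        if len(peaks) < 2:
            continue
        t = _refine_peak_times(seg, peaks, rec.fs)
        rr = np.diff(t)
        rr = rr[(rr >= RR_MIN) & (rr <= RR_MAX)]
        intervals.extend(rr.tolist())
    if len(intervals) < MIN_INTERVALS:
        raise UndiagnosableRecording(
            f"only {len(intervals)} usable intervals (< {MIN_INTERVALS})"
        )
    return RrSeries(np.array(intervals), rhythm=rec.truth)


# ---------------------------------------------------------------------------
# Feature definitions
# ---------------------------------------------------------------------------


def _shannon_entropy_bits(rr: np.ndarray, n_bins: int = 16,
                          lo: float = 0.25, hi: float = 2.0) -> float:
    counts, _ = np.histogram(rr, bins=n_bins, range=(lo, hi))
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-np.sum(p * np.log2(p)))


def _sample_entropy(rr: np.ndarray, m: int = 2, r_frac: float = 0.2) -> float:
    """SampEn(m, r = r_frac * SD) with the Chebyshev norm; 0 on degenerate input."""
    n = len(rr)
    sd = np.std(rr)
    if sd == 0 or n <= m + 1:
        return 0.0
    r = r_frac * sd

    def _count(mm: int) -> int:
        templ = np.lib.stride_tricks.sliding_window_view(rr, mm)
        d = cdist(templ, templ, metric="chebyshev")
        # self-matches excluded
        return int(np.sum(d <= r) - len(templ))

    b = _count(m)
    a = _count(m + 1)
    if a == 0 or b == 0:
        # no template matches at tolerance r: entropy is undefined upward;
        # cap with the largest resolvable value for this series length
        return float(np.log(n - m) + np.log(n - m - 1))
    return float(-np.log(a / b))


def _comb_residual(rr: np.ndarray, c_lo: float = 0.15, c_hi: float = 0.30,
                   c_step: float = 0.001, k_max: int = 6) -> float:
    """Minimal normalized deviation of intervals from integer multiples of a
    candidate atrial cycle c: min_c mean_i min_k |rr_i - k c| / mean_rr."""
    cycles = np.arange(c_lo, c_hi + c_step / 2, c_step)
    k = np.arange(1, k_max + 1)
    grid = cycles[:, None] * k[None, :]  # (n_c, k_max)
    dev = np.abs(rr[None, None, :] - grid[:, :, None])  # (n_c, k_max, n)
    best = dev.min(axis=1).mean(axis=1)  # (n_c,)
    return float(best.min() / np.mean(rr))


def extract_features(rr: RrSeries) -> FeatureVector:
    """Compute the 13 RR irregularity statistics for one recording."""
    x = np.asarray(rr.intervals, dtype=float)
    if len(x) < MIN_INTERVALS:
        raise UndiagnosableRecording(
            f"need >= {MIN_INTERVALS} intervals, got {len(x)}"
        )
    mean_rr = float(np.mean(x))
    sdnn = float(np.std(x))
    diffs = np.diff(x)
    rmssd = float(np.sqrt(np.mean(diffs**2)))

    if sdnn == 0:
        samp_en = 0.0
        poincare = 0.0
        lag1 = 0.0
    else:
        samp_en = _sample_entropy(x)
        sd1 = float(np.std(diffs) / np.sqrt(2))
        sd2sq = max(2 * sdnn**2 - sd1**2, 0.0)
        poincare = float(sd1 / np.sqrt(sd2sq)) if sd2sq > 0 else 0.0
        lag1 = float(np.corrcoef(x[:-1], x[1:])[0, 1])
        if not np.isfinite(lag1):
            lag1 = 0.0

    interior = x[1:-1]
    turning = (
        float(np.mean((interior > x[:-2]) & (interior > x[2:])
                      | (interior < x[:-2]) & (interior < x[2:])))
        if len(x) >= 3
        else 0.0
    )

    values = {
        "mean_rr": mean_rr,
        "sdnn": sdnn,
        "cv": sdnn / mean_rr,
        "rmssd": rmssd,
        "nrmssd": rmssd / mean_rr,
        "prr50": float(np.mean(np.abs(diffs) > 0.050)) if len(diffs) else 0.0,
        "rr_entropy": _shannon_entropy_bits(x),
        "sample_entropy": samp_en,
        "poincare_ratio": poincare,
        "lag1_autocorr": lag1,
        "turning_point_ratio": turning,
        "mad_rr": float(np.median(np.abs(x - np.median(x)))),
        "comb_residual": _comb_residual(x),
    }
    return FeatureVector(values)


def features_from_recording(
    rec: PpgRecording, qa: QualityAssessment
) -> FeatureVector:
    """Convenience: detect pulses in good spans, then extract features."""
    return extract_features(detect_pulses(rec, qa))
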