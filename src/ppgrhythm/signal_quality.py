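"""Automatic per-recording PPG signal-quality assessment.

The recording is split into consecutive half-open windows (default 5 s).
A window is usable iff

  (a) at least `min_pulses` pulse peaks are detected in it,
  (b) the mean Pearson correlation between adjacent fixed-length-resampled
      pulse epochs reaches `corr_threshold` (template-consistency SQI), and
  (c) every sample stays inside the amplitude saturation bounds.

A recording is *sufficient* for rhythm diagnosis iff at least 30 usable
seconds remain — the same minimum the reference-ECG reading protocol uses
for its 1-min recordings; no separate PPG rule is published, so the ECG
rule is adopted here deliberately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import detrend, find_peaks

from .ppg_sim import PpgRecording

REFRACTORY_S = 0.25  # minimum peak spacing; caps detectable rate at 240 bpm


@dataclass
class QualityConfig:
    window_s: float = 5.0
    min_pulses: int = 3
    corr_threshold: float = 0.8
    amp_bounds: tuple[float, float] = (-6.0, 6.0)
    sufficiency_s: float = 30.0  # inclusive boundary
    epoch_pre_s: float = 0.20  # epoch extent around each peak
    epoch_post_s: float = 0.30
    epoch_len: int = 30  # resampled epoch length
    fs: float | None = None  # if set, recordings must match


@dataclass
class QualityAssessment:
    window_flags: list[bool]
    window_sqi: list[float]
    usable_seconds: float
    sufficient: bool
    window_s: float = 5.0

    def good_spans(self, fs: float) -> list[tuple[int, int]]:
        """Maximal runs of consecutive good windows as sample index ranges."""
        spans = []
        start = None
        w = self.window_s
        for i, ok in enumerate(self.window_flags + [False]):
            if ok and start is None:
                start = i
            elif not ok and start is not None:
                spans.append((int(round(start * w * fs)), int(round(i * w * fs))))
                start = None
        return spans


def find_pulse_peaks(x: np.ndarray, fs: float) -> np.ndarray:
    """Adaptive-threshold peak detection on a (detrended) PPG segment.

    Returns integer sample indices.  Threshold adapts to the robust signal
    amplitude; the refractory distance suppresses dicrotic-wave doubles.
    """
    if len(x) < 3:
        return np.array([], dtype=int)
    xd = detrend(x)
    scale = np.percentile(np.abs(xd), 95)
    if scale <= 0:
        return np.array([], dtype=int)
    peaks, _ = find_peaks(
        xd,
        distance=max(1, int(REFRACTORY_S * fs)),
        prominence=0.45 * scale,
        height=0.2 * scale,
    )
    return peaks


def _epoch_matrix(
    x: np.ndarray, peaks: np.ndarray, fs: float, cfg: QualityConfig
) -> np.ndarray:
    """Fixed-length-resampled pulse epochs around each peak (rows)."""
    pre = int(round(cfg.epoch_pre_s * fs))
    post = int(round(cfg.epoch_post_s * fs))
    rows = []
    for p in peaks:
        if p - pre < 0 or p + post > len(x):
            continue
        epoch = x[p - pre : p + post]
        grid = np.linspace(0, len(epoch) - 1, cfg.epoch_len)
        rows.append(np.interp(grid, np.arange(len(epoch)), epoch))
    return np.array(rows)


def _adjacent_epoch_correlation(epochs: np.ndarray) -> float:
    if len(epochs) < 2:
        return 0.0
    corrs = []
    for a, b in zip(epochs[:-1], epochs[1:]):
        sa, sb = np.std(a), np.std(b)
        if sa == 0 or sb == 0:
            corrs.append(0.0)
        else:
            corrs.append(float(np.corrcoef(a, b)[0, 1]))
    return float(np.mean(corrs))


def assess_quality(
    rec: PpgRecording, cfg: QualityConfig | None = None
) -> QualityAssessment:
    """Windowed quality flags, per-window SQI, and the sufficiency verdict."""
    cfg = cfg or QualityConfig()
    if len(rec.samples) == 0:
        raise ValueError("empty recording")
    if cfg.fs is not None and cfg.fs != rec.fs:
        raise ValueError(f"config expects fs={cfg.fs}, recording has fs={rec.fs}")

    wlen = int(round(cfg.window_s * rec.fs))
    n_windows = int(len(rec.samples) // wlen)
    flags: list[bool] = []
    sqis: list[float] = []
    for w in range(n_windows):
        xw = rec.samples[w * wlen : (w + 1) * wlen]  # half-open [t, t+window)
        in_bounds = bool(
            np.all((xw >= cfg.amp_bounds[0]) & (xw <= cfg.amp_bounds[1]))
        )
        xd = detrend(xw)
        peaks = find_pulse_peaks(xw, rec.fs)
        corr = _adjacent_epoch_correlation(_epoch_matrix(xd, peaks, rec.fs, cfg))
        sqi = float(np.clip(corr, 0.0, 1.0))
        good = (
            in_bounds and len(peaks) >= cfg.min_pulses and corr >= cfg.corr_threshold
        )
        flags.append(bool(good))
        sqis.append(sqi if in_bounds else 0.0)

    usable = cfg.window_s * sum(flags)
    return QualityAssessment(
        window_flags=flags,
        window_sqi=sqis,
        usable_seconds=usable,
        sufficient=usable >= cfg.sufficiency_s,
        window_s=cfg.window_s,
    )
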