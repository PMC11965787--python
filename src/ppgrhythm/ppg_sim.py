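"""Synthetic smartphone-camera PPG: rhythm models, waveform rendering, cohorts.

Three layers, each independently seedable:

1. RR-interval generators for sinus rhythm (SR), atrial fibrillation (AF) and
   atrial flutter with regular / variable AV conduction (AFL).
2. A waveform renderer that places a two-Gaussian pulse template (systolic
   peak + dicrotic wave) at every beat onset, modulates pulse amplitude after
   short preceding intervals, and adds baseline wander, white noise and
   Poisson-arriving motion-artifact bursts.
3. A pericardioversion cohort simulator: each subject records an arrhythmic
   rhythm before electrical cardioversion, converts to SR at day 0, and may
   relapse with a constant per-day hazard; recordings are made roughly twice
   daily for a configurable number of days, each paired with a simulated
   reference ("ECG-read") rhythm label.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# Labels and core containers
# ---------------------------------------------------------------------------


class RhythmLabel(str, Enum):
    SR = "SR"
    AF = "AF"
    AFL_REG = "AFL_REG"  # atrial flutter, regular AV conduction
    AFL_VAR = "AFL_VAR"  # atrial flutter, variable AV conduction
    INSUFFICIENT = "INSUFFICIENT"
    OTHER = "OTHER"

    @property
    def is_afl(self) -> bool:
        return self in (RhythmLabel.AFL_REG, RhythmLabel.AFL_VAR)

    def reporting(self) -> str:
        """Collapse the two AFL conduction patterns into one AFL category."""
        if self.is_afl:
            return "AFL"
        return self.value


GENERATABLE = (RhythmLabel.SR, RhythmLabel.AF, RhythmLabel.AFL_REG, RhythmLabel.AFL_VAR)


def to_reporting(value: str) -> str:
    """Collapse a raw or already-collapsed rhythm string to reporting level."""
    if value == "AFL":
        return "AFL"
    return RhythmLabel(value).reporting()

# physiological bounds on a beat-to-beat interval, seconds
RR_MIN = 0.25
RR_MAX = 2.5


@dataclass
class RrSeries:
    """A sequence of beat-to-beat intervals (seconds) with its rhythm."""

    intervals: np.ndarray
    rhythm: RhythmLabel
    atrial_cycle: float | None = None  # AFL only

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=float)
        if self.intervals.size == 0:
            raise ValueError("RrSeries requires at least one interval")
        if np.any(self.intervals < RR_MIN) or np.any(self.intervals > RR_MAX):
            raise ValueError(
                f"intervals must lie in [{RR_MIN}, {RR_MAX}] s"
            )

    @property
    def beat_onsets(self) -> np.ndarray:
        """Beat onset times: first beat at t=0, then cumulative intervals."""
        return np.concatenate([[0.0], np.cumsum(self.intervals)])


@dataclass
class PpgRecording:
    """One 60-s (by default) single-channel PPG measurement."""

    samples: np.ndarray
    fs: float
    duration: float
    subject_id: str = ""
    t_record: float = 0.0  # days since cardioversion
    truth: RhythmLabel = RhythmLabel.OTHER
    ecg_label: RhythmLabel = RhythmLabel.OTHER
    seed: int | None = None
    beat_onsets: np.ndarray | None = None  # ground-truth beat times (simulator only)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if len(self.samples) != round(self.fs * self.duration):
            raise ValueError("len(samples) must equal round(fs * duration)")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")


# ---------------------------------------------------------------------------
# RR-interval models
# ---------------------------------------------------------------------------


@dataclass
class SrParams:
    """Near-regular sinus rhythm with respiratory modulation.

    hr_bpm       mean heart rate
    resp_depth   fractional amplitude of respiratory sinus arrhythmia
    resp_freq    respiration frequency, Hz (~15 breaths/min)
    jitter_sd    additive white RR jitter, seconds
    """

    hr_bpm: float = 65.0
    resp_depth: float = 0.04
    resp_freq: float = 0.25
    jitter_sd: float = 0.02


@dataclass
class AfParams:
    """Irregularly irregular ventricular response: shifted-Gamma RR model.

    Beat-to-beat intervals are serially independent draws
    ``shift + Gamma(k, theta)`` with k, theta solved from the requested
    mean and coefficient of variation.
    """

    mean_rr: float = 0.55
    cv: float = 0.22
    shift: float = 0.25


@dataclass
class AflParams:
    """Atrial flutter: ventricular intervals are integer multiples of the
    atrial cycle length (AV conduction ratio 2:1, 3:1 or 4:1).

    atrial_cycle     fixed cycle, seconds; None draws U(cycle_range)
    conduction_ratio fixed ratio for AFL_REG; None draws from ratio_probs
    ratio_probs      stationary probabilities over ratios {2, 3, 4}
    stay_prob        Markov probability of keeping the current ratio (AFL_VAR)
    jitter_frac      uniform relative jitter, ±fraction of the interval
    """

    atrial_cycle: float | None = None
    cycle_range: tuple[float, float] = (0.18, 0.25)
    conduction_ratio: int | None = None
    ratio_probs: dict[int, float] = field(
        default_factory=lambda: {2: 0.6, 3: 0.3, 4: 0.1}
    )
    stay_prob: float = 0.7
    jitter_frac: float = 0.01


def generate_rr_series(
    rhythm: RhythmLabel,
    duration: float,
    params: SrParams | AfParams | AflParams | None = None,
    rng: np.random.Generator | None = None,
) -> RrSeries:
    """Generate beat-to-beat intervals whose cumulative sum covers `duration`."""
    if rhythm not in GENERATABLE:
        raise ValueError(f"cannot generate RR series for rhythm {rhythm!r}")
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng() if rng is None else rng

    if rhythm is RhythmLabel.SR:
        p = params if params is not None else SrParams()
        base = 60.0 / p.hr_bpm
        intervals = []
        t = 0.0
        while t < duration:
            rr = base * (1.0 + p.resp_depth * np.sin(2 * np.pi * p.resp_freq * t))
            if p.jitter_sd > 0:
                rr += rng.normal(0.0, p.jitter_sd)
            rr = float(np.clip(rr, RR_MIN, RR_MAX))
            intervals.append(rr)
            t += rr
        return RrSeries(np.array(intervals), rhythm)

    if rhythm is RhythmLabel.AF:
        p = params if params is not None else AfParams()
        mean_excess = p.mean_rr - p.shift
        sd = p.cv * p.mean_rr
        if mean_excess <= 0:
            raise ValueError("AF mean_rr must exceed the shift")
        k = (mean_excess / sd) ** 2
        theta = sd**2 / mean_excess
        # draw in blocks until the recording is covered
        intervals = np.empty(0)
        while intervals.sum() < duration:
            n = max(16, int(1.5 * duration / p.mean_rr))
            block = p.shift + rng.gamma(k, theta, size=n)
            intervals = np.concatenate([intervals, np.clip(block, RR_MIN, RR_MAX)])
        cum = np.cumsum(intervals)
        n_keep = int(np.searchsorted(cum, duration) + 1)
        return RrSeries(intervals[:n_keep], rhythm)

    # atrial flutter
    p = params if params is not None else AflParams()
    cycle = (
        p.atrial_cycle
        if p.atrial_cycle is not None
        else float(rng.uniform(*p.cycle_range))
    )
    ratios = np.array(sorted(p.ratio_probs))
    probs = np.array([p.ratio_probs[r] for r in ratios], dtype=float)
    probs = probs / probs.sum()

    intervals = []
    if rhythm is RhythmLabel.AFL_REG:
        ratio = (
            p.conduction_ratio
            if p.conduction_ratio is not None
            else int(rng.choice(ratios, p=probs))
        )
        t = 0.0
        while t < duration:
            rr = ratio * cycle
            if p.jitter_frac > 0:
                rr *= 1.0 + rng.uniform(-p.jitter_frac, p.jitter_frac)
            rr = float(np.clip(rr, RR_MIN, RR_MAX))
            intervals.append(rr)
            t += rr
    else:  # AFL_VAR: Markov-switched conduction ratio
        ratio = int(rng.choice(ratios, p=probs))
        t = 0.0
        while t < duration:
            rr = ratio * cycle
            if p.jitter_frac > 0:
                rr *= 1.0 + rng.uniform(-p.jitter_frac, p.jitter_frac)
            rr = float(np.clip(rr, RR_MIN, RR_MAX))
            intervals.append(rr)
            t += rr
            if rng.random() > p.stay_prob:
                others = ratios[ratios != ratio]
                w = probs[ratios != ratio]
                ratio = int(rng.choice(others, p=w / w.sum()))
    return RrSeries(np.array(intervals), rhythm, atrial_cycle=cycle)


# ---------------------------------------------------------------------------
# Waveform rendering
# ---------------------------------------------------------------------------


@dataclass
class PulseParams:
    """Two-Gaussian pulse template: systolic peak plus dicrotic wave.

    Times are seconds from the beat onset; amplitudes in arbitrary units.
    ``amp_mod_beta`` scales pulse amplitude down in proportion to the deficit
    of the preceding interval relative to the series mean — the shortened
    diastolic filling after a premature beat reduces stroke volume, which is
    the known source of pulse-amplitude variability in AF.
    """

    sys_amp: float = 1.0
    sys_mu: float = 0.15
    sys_sigma: float = 0.045
    dic_amp: float = 0.3
    dic_mu: float = 0.42
    dic_sigma: float = 0.12
    amp_mod_beta: float = 0.5
    amp_floor: float = 0.2


@dataclass
class NoiseParams:
    """Additive disturbances of the rendered waveform.

    Motion-artifact bursts arrive as a Poisson process at ``burst_rate_per_min``
    with uniform duration in ``burst_dur_s`` and uniform amplitude ±burst_amp;
    the post-revision user-feedback regime sets the burst rate to zero.
    """

    baseline_amp: float = 0.3
    baseline_freq: float = 0.2
    white_sd: float = 0.05
    burst_rate_per_min: float = 0.0
    burst_dur_s: tuple[float, float] = (1.0, 3.5)
    burst_amp: float = 8.0

    @classmethod
    def off(cls) -> "NoiseParams":
        return cls(baseline_amp=0.0, white_sd=0.0, burst_rate_per_min=0.0)

    @classmethod
    def pre_revision(cls) -> "NoiseParams":
        return cls(burst_rate_per_min=2.0)

    @classmethod
    def post_revision(cls) -> "NoiseParams":
        return cls(burst_rate_per_min=0.0)


def pulse_template(t: np.ndarray, p: PulseParams) -> np.ndarray:
    """Template amplitude at times `t` (seconds from beat onset)."""
    return p.sys_amp * np.exp(-0.5 * ((t - p.sys_mu) / p.sys_sigma) ** 2) + (
        p.dic_amp * np.exp(-0.5 * ((t - p.dic_mu) / p.dic_sigma) ** 2)
    )


def render_ppg(
    rr: RrSeries,
    fs: float = 30.0,
    pulse_params: PulseParams | None = None,
    noise_params: NoiseParams | None = None,
    rng: np.random.Generator | None = None,
    duration: float | None = None,
    **metadata,
) -> PpgRecording:
    """Render an RR series to a sampled PPG waveform.

    One pulse template per beat, placed at the beat onset.  Beats whose onset
    falls at or beyond `duration` are dropped.
    """
    if fs < 20:
        raise ValueError("sampling rate too low to resolve pulses (fs >= 20 Hz)")
    pp = pulse_params or PulseParams()
    npar = noise_params or NoiseParams.off()
    rng = np.random.default_rng() if rng is None else rng

    onsets = rr.beat_onsets
    if duration is None:
        duration = float(np.floor(onsets[-1]))
        duration = max(duration, 1.0)
    n = int(round(fs * duration))
    t = np.arange(n) / fs
    x = np.zeros(n)

    mean_rr = float(np.mean(rr.intervals))
    support = pp.dic_mu + 5 * pp.dic_sigma  # template support, seconds
    for i, onset in enumerate(onsets):
        if onset >= duration:
            break
        amp = 1.0
        if i > 0:
            deficit = max(0.0, (mean_rr - rr.intervals[i - 1]) / mean_rr)
            amp = max(pp.amp_floor, 1.0 - pp.amp_mod_beta * deficit)
        lo = int(np.ceil(onset * fs))
        hi = min(n, int(np.ceil((onset + support) * fs)))
        x[lo:hi] += amp * pulse_template(t[lo:hi] - onset, pp)

    if npar.baseline_amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        x += npar.baseline_amp * np.sin(2 * np.pi * npar.baseline_freq * t + phase)
    if npar.white_sd > 0:
        x += rng.normal(0.0, npar.white_sd, size=n)
    if npar.burst_rate_per_min > 0:
        n_bursts = rng.poisson(npar.burst_rate_per_min * duration / 60.0)
        for _ in range(n_bursts):
            start = rng.uniform(0, duration)
            dur = rng.uniform(*npar.burst_dur_s)
            lo = int(start * fs)
            hi = min(n, int((start + dur) * fs))
            x[lo:hi] += rng.uniform(-npar.burst_amp, npar.burst_amp, size=hi - lo)

    return PpgRecording(
        samples=x,
        fs=fs,
        duration=duration,
        beat_onsets=onsets[onsets < duration],
        **metadata,
    )


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------


@dataclass
class CohortSpec:
    """A pericardioversion cohort: arrhythmia before cardioversion, SR after,
    constant per-day relapse hazard, ~twice-daily recordings.

    pre_dccv_mix          probabilities over {"AF", "AFL"} for the rhythm at
                          inclusion (AFL split evenly into regular/variable
                          conduction); defaults renormalized from the observed
                          82.1% AF / 14.3% AFL baseline split
    relapse_hazard        per-day probability of relapse back to the
                          pre-cardioversion rhythm
    artifact_regime       "pre_revision" (motion-artifact bursts at 2/min) or
                          "post_revision" (no bursts)
    ecg_insufficient_rate probability that the simulated reference reading is
                          uninterpretable (label INSUFFICIENT)
    adherence             "exact": recs_per_day recordings every day;
                          "poisson": daily count ~ Poisson(recs_per_day)
    """

    n_subjects: int = 30
    days: int = 30
    recs_per_day: float = 2.0
    pre_dccv_mix: dict[str, float] = field(
        default_factory=lambda: {"AF": 0.821 / 0.964, "AFL": 0.143 / 0.964}
    )
    relapse_hazard: float = 0.05
    artifact_regime: str = "post_revision"
    ecg_insufficient_rate: float = 0.036
    adherence: str = "exact"
    fs: float = 30.0
    duration: float = 60.0
    seed: int = 0
    subject_prefix: str = "S"
    subject_offset: int = 0  # numbering offset for split/mixed-regime cohorts

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.days < 1:
            raise ValueError("days must be >= 1")
        total = sum(self.pre_dccv_mix.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"pre_dccv_mix must sum to 1 (got {total:.4f})")
        for key, v in self.pre_dccv_mix.items():
            if key not in ("AF", "AFL"):
                raise ValueError(f"pre_dccv_mix keys must be AF/AFL, got {key!r}")
            if not 0 <= v <= 1:
                raise ValueError("pre_dccv_mix probabilities must lie in [0, 1]")
        if not 0 <= self.relapse_hazard <= 1:
            raise ValueError("relapse_hazard must lie in [0, 1]")
        if not 0 <= self.ecg_insufficient_rate <= 1:
            raise ValueError("ecg_insufficient_rate must lie in [0, 1]")
        if self.artifact_regime not in ("pre_revision", "post_revision"):
            raise ValueError(
                "artifact_regime must be 'pre_revision' or 'post_revision'"
            )
        if self.adherence not in ("exact", "poisson"):
            raise ValueError("adherence must be 'exact' or 'poisson'")


def _subject_rhythm_params(
    truth: RhythmLabel, rng: np.random.Generator, base: dict | None = None
):
    """Draw per-subject physiological parameters for one rhythm."""
    if truth is RhythmLabel.SR:
        return SrParams(hr_bpm=float(np.clip(rng.normal(65, 7), 48, 90)))
    if truth is RhythmLabel.AF:
        return AfParams(
            mean_rr=float(np.clip(rng.normal(0.55, 0.05), 0.42, 0.75)),
            cv=float(np.clip(rng.normal(0.22, 0.03), 0.12, 0.35)),
        )
    # atrial flutter: one atrial cycle per subject
    return AflParams(atrial_cycle=float(rng.uniform(0.18, 0.25)))


def simulate_cohort(spec: CohortSpec) -> tuple[list[PpgRecording], pd.DataFrame]:
    """Simulate a cohort; returns recordings and a manifest (one row each).

    Every subject contributes one pre-cardioversion recording on day 0 with
    the rhythm drawn from ``pre_dccv_mix``, then SR recordings from day 1
    until a relapse (if any), after which all recordings carry the relapse
    rhythm (= the pre-cardioversion rhythm).
    """
    root = np.random.SeedSequence(spec.seed)
    subject_seqs = root.spawn(spec.n_subjects)
    noise = (
        NoiseParams.pre_revision()
        if spec.artifact_regime == "pre_revision"
        else NoiseParams.post_revision()
    )

    recordings: list[PpgRecording] = []
    rows = []
    for s_idx, sseq in enumerate(subject_seqs):
        srng = np.random.default_rng(sseq)
        subject_id = f"{spec.subject_prefix}{s_idx + spec.subject_offset:04d}"

        pre_cat = "AF" if srng.random() < spec.pre_dccv_mix["AF"] else "AFL"
        if pre_cat == "AF":
            pre_rhythm = RhythmLabel.AF
        else:
            pre_rhythm = (
                RhythmLabel.AFL_REG if srng.random() < 0.5 else RhythmLabel.AFL_VAR
            )
        arr_params = _subject_rhythm_params(pre_rhythm, srng)
        sr_params = _subject_rhythm_params(RhythmLabel.SR, srng)

        # day of relapse (recordings on that day and later carry the relapse
        # rhythm); None = no relapse within the observation window
        relapse_day: int | None = None
        for d in range(1, spec.days + 1):
            if srng.random() < spec.relapse_hazard:
                relapse_day = d
                break

        # (day, rhythm) schedule: day 0 = single pre-cardioversion recording
        schedule: list[tuple[int, RhythmLabel]] = [(0, pre_rhythm)]
        for d in range(1, spec.days + 1):
            if spec.adherence == "poisson":
                n_today = int(srng.poisson(spec.recs_per_day))
            else:
                n_today = int(round(spec.recs_per_day))
            rhythm = (
                pre_rhythm if relapse_day is not None and d >= relapse_day
                else RhythmLabel.SR
            )
            schedule.extend([(d, rhythm)] * n_today)

        for r_idx, (day, truth) in enumerate(schedule):
            # per-recording seed recorded in the manifest so any single
            # recording can be regenerated in isolation
            rec_seed = int(srng.integers(2**31))
            rec_rng = np.random.default_rng(rec_seed)
            params = sr_params if truth is RhythmLabel.SR else arr_params
            rr = generate_rr_series(truth, spec.duration, params, rec_rng)
            ecg = truth
            if srng.random() < spec.ecg_insufficient_rate:
                ecg = RhythmLabel.INSUFFICIENT
            rec = render_ppg(
                rr,
                fs=spec.fs,
                noise_params=noise,
                rng=rec_rng,
                duration=spec.duration,
                subject_id=subject_id,
                t_record=float(day),
                truth=truth,
                ecg_label=ecg,
                seed=rec_seed,
            )
            recordings.append(rec)
            rows.append(
                {
                    "subject_id": subject_id,
                    "day": day,
                    "rec_idx": r_idx,
                    "truth": truth.value,
                    "ecg_label": ecg.value,
                    "artifact_regime": spec.artifact_regime,
                    "seed": rec_seed,
                }
            )

    manifest = pd.DataFrame(rows)
    return recordings, manifest


# ---------------------------------------------------------------------------
# Disk formats: recording = CSV + JSON sidecar; manifest = CSV
# ---------------------------------------------------------------------------


def save_recording(rec: PpgRecording, directory: str | Path, stem: str) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    t = np.arange(len(rec.samples)) / rec.fs
    pd.DataFrame({"time_s": t, "amplitude": rec.samples}).to_csv(
        directory / f"{stem}.csv", index=False
    )
    sidecar = {
        "fs": rec.fs,
        "duration": rec.duration,
        "subject_id": rec.subject_id,
        "day": rec.t_record,
        "truth": rec.truth.value,
        "ecg_label": rec.ecg_label.value,
        "seed": rec.seed,
    }
    (directory / f"{stem}.json").write_text(json.dumps(sidecar, indent=1))


def load_recording(directory: str | Path, stem: str) -> PpgRecording:
    directory = Path(directory)
    df = pd.read_csv(directory / f"{stem}.csv")
    meta = json.loads((directory / f"{stem}.json").read_text())
    return PpgRecording(
        samples=df["amplitude"].to_numpy(),
        fs=meta["fs"],
        duration=meta["duration"],
        subject_id=meta["subject_id"],
        t_record=meta["day"],
        truth=RhythmLabel(meta["truth"]),
        ecg_label=RhythmLabel(meta["ecg_label"]),
        seed=meta["seed"],
    )
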