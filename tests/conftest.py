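import numpy as np
import pandas as pd
import pytest

from ppgrhythm import (
    AfParams,
    AflParams,
    FEATURE_NAMES,
    NoiseParams,
    RhythmLabel,
    SrParams,
    extract_features,
    generate_rr_series,
    render_ppg,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def clean_sr_recording():
    """Noise-free 60-bpm sinus recording, 60 s at 30 Hz."""
    rr = generate_rr_series(
        RhythmLabel.SR, 60.0, SrParams(hr_bpm=60, resp_depth=0.0, jitter_sd=0.0)
    )
    return render_ppg(
        rr, fs=30.0, duration=60.0,
        truth=RhythmLabel.SR, ecg_label=RhythmLabel.SR,
    )


def rhythm_feature_frame(n_subjects, recs_per_subject, labels, seed,
                         prefix="S", offset=0):
    """Feature rows straight from RR generators (no waveform rendering).

    ``labels`` maps each subject index to "SR"/"AF"/"AFL"; fast path for
    classifier tests that do not exercise the waveform pipeline.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        lab = labels[s % len(labels)]
        if lab == "SR":
            params = SrParams(hr_bpm=float(rng.uniform(55, 80)))
            rhythm = RhythmLabel.SR
        elif lab == "AF":
            params = AfParams(mean_rr=float(rng.uniform(0.45, 0.65)))
            rhythm = RhythmLabel.AF
        else:
            params = AflParams(atrial_cycle=float(rng.uniform(0.18, 0.25)))
            rhythm = RhythmLabel.AFL_VAR if s % 2 else RhythmLabel.AFL_REG
        for r in range(recs_per_subject):
            rr = generate_rr_series(rhythm, 60.0, params, rng)
            fv = extract_features(rr)
            rows.append(
                {
                    "subject_id": f"{prefix}{s + offset:03d}",
                    "day": r // 2,
                    "rec_idx": r,
                    "label": lab,
                    **fv.values,
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def small_binary_cohort():
    """12-subject SR/AF cohort at the feature level (6 SR, 6 AF subjects)."""
    return rhythm_feature_frame(
        12, 16, ["SR", "AF"] * 6, seed=42
    )
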