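"""Shared fixtures: small synthetic recordings and extracted strips."""

from __future__ import annotations

import numpy as np
import pytest

from ecgcomplexity.io import resample
from ecgcomplexity.segmentation import detect_r_peaks, find_segments, remove_baseline
from ecgcomplexity.synthetic import SubjectSimParams, generate_ecg


@pytest.fixture(scope="session")
def clean_recording():
    """A noiseless, jitter-free 150-s recording with its ground truth."""
    params = SubjectSimParams(
        subject_id="CLEAN", duration=150.0, heart_rate=65.0, rr_jitter_sd=0.03,
        noise_sd=0.0, baseline_wander_amp=0.0, fiducial_jitter_sd=0.0, seed=5,
    )
    return generate_ecg(params)


@pytest.fixture(scope="session")
def realistic_recording():
    """A 180-s recording with noise, wander and physiological jitter."""
    params = SubjectSimParams(
        subject_id="REAL", duration=180.0, heart_rate=70.0, rr_jitter_sd=0.04,
        noise_sd=0.02, baseline_wander_amp=0.15, fiducial_jitter_sd=0.012,
        amplitude_jitter_frac=0.05, seed=3,
    )
    return generate_ecg(params)


def extract_first_strip(signal, detrend=True):
    sig = resample(signal, 125.0)
    peaks = detect_r_peaks(sig)
    strips = find_segments(sig, peaks, 30.0, 120.0)
    assert strips, "fixture recording yielded no strips"
    return remove_baseline(strips[0]) if detrend else strips[0]


@pytest.fixture(scope="session")
def clean_strip(clean_recording):
    """A baseline-removed 60-s strip from the noiseless recording."""
    signal, _truth = clean_recording
    return extract_first_strip(signal)


@pytest.fixture(scope="session")
def realistic_strip(realistic_recording):
    signal, _truth = realistic_recording
    return extract_first_strip(signal)
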