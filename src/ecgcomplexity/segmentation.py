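"""R-peak detection, 60-s strip selection and baseline-wander removal.

Strip selection implements the automated, bias-free segment finder: a 60-s
window anchored at a beat is accepted only if every RR interval inside it
stays within 30% of the window's own mean RR and the mean heart rate falls in
the configured band.  The 30% rule excludes premature (ectopic) beats, blocks
and disconnect artefacts while tolerating respiratory sinus arrhythmia.
Accepted windows never overlap; the scan is greedy from the recording start
and advances one beat after each rejection, which makes the selection
deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import butter, find_peaks, sosfiltfilt

from ._exceptions import ParameterError, UndefinedMetricError
from .io import EcgSignal

__all__ = ["Strip", "detect_r_peaks", "find_segments", "remove_baseline", "strip_heart_rate"]

logger = logging.getLogger(__name__)

DEFAULT_HR_BAND = (30.0, 120.0)  # bpm, the extraction band
RR_DEVIATION = 0.30  # maximal relative RR deviation inside a strip
STRIP_DURATION = 60.0  # s


@dataclass
class Strip:
    """A fixed-duration artefact-free segment with its local R peaks."""

    samples: np.ndarray
    sampling_rate: float
    start: int  # index into the source signal
    r_peaks: np.ndarray  # strip-local sample indices
    subject_id: str = ""
    label: str | None = None
    strip_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.r_peaks = np.asarray(self.r_peaks, dtype=np.int64)
        if not self.strip_id:
            self.strip_id = f"{self.subject_id}:{self.start}"

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sampling_rate

    @property
    def rr_seconds(self) -> np.ndarray:
        return np.diff(self.r_peaks) / self.sampling_rate

    @property
    def mean_hr(self) -> float:
        return strip_heart_rate(self)


def strip_heart_rate(strip: Strip) -> float:
    """Mean heart rate of a strip in bpm: 60 / mean RR."""
    if len(strip.r_peaks) < 2:
        raise UndefinedMetricError("heart rate undefined with fewer than 2 R peaks")
    return 60.0 / float(np.mean(strip.rr_seconds))


def detect_r_peaks(
    signal: EcgSignal,
    *,
    band: tuple[float, float] = (5.0, 40.0),
    refractory: float = 0.3,
    integration_window: float = 0.15,
    threshold_fraction: float = 0.25,
) -> np.ndarray:
    """QRS detection: band-pass, differentiate, square, integrate, threshold.

    The refractory interval of 0.3 s caps detectable rates at 200 bpm.  Peak
    positions are refined to the dominant-polarity extremum of the raw signal
    within +/-100 ms.  An empty array is returned when nothing is found.
    """
    x = signal.samples
    fs = signal.sampling_rate
    if len(x) < 2 * fs:
        return np.array([], dtype=np.int64)
    hi = min(band[1], 0.45 * fs)
    sos = butter(2, (band[0], hi), btype="bandpass", fs=fs, output="sos")
    filtered = sosfiltfilt(sos, x)
    energy = np.gradient(filtered) ** 2
    w = max(1, int(round(integration_window * fs)))
    integ = np.convolve(energy, np.ones(w) / w, mode="same")
    height = threshold_fraction * np.percentile(integ, 99)
    if height <= 0:
        return np.array([], dtype=np.int64)
    raw_peaks, _ = find_peaks(integ, height=height, distance=max(1, int(round(refractory * fs))))
    if len(raw_peaks) == 0:
        return raw_peaks.astype(np.int64)
    # dominant QRS polarity over the detected complexes
    half = int(round(0.1 * fs))
    maxima, minima = [], []
    for p in raw_peaks:
        seg = x[max(0, p - half) : p + half + 1]
        maxima.append(seg.max())
        minima.append(seg.min())
    sign = 1.0 if np.median(maxima) >= -np.median(minima) else -1.0
    refined = []
    for p in raw_peaks:
        i0 = max(0, p - half)
        seg = sign * x[i0 : p + half + 1]
        refined.append(i0 + int(np.argmax(seg)))
    peaks = np.unique(np.asarray(refined, dtype=np.int64))
    # deduplicate refinements that collapsed within the refractory interval
    if len(peaks) > 1:
        keep = [0]
        for i in range(1, len(peaks)):
            if peaks[i] - peaks[keep[-1]] >= refractory * fs:
                keep.append(i)
            elif sign * x[peaks[i]] > sign * x[peaks[keep[-1]]]:
                keep[-1] = i
        peaks = peaks[keep]
    return peaks


def find_segments(
    signal: EcgSignal,
    r_peaks: np.ndarray,
    hr_lo: float = DEFAULT_HR_BAND[0],
    hr_hi: float = DEFAULT_HR_BAND[1],
    rr_dev: float = RR_DEVIATION,
    duration: float = STRIP_DURATION,
) -> list[Strip]:
    """Greedy non-overlapping scan for acceptable fixed-duration strips."""
    if hr_lo >= hr_hi:
        raise ParameterError(f"hr_lo must be < hr_hi, got ({hr_lo}, {hr_hi})")
    fs = signal.sampling_rate
    n_win = int(round(duration * fs))
    peaks = np.asarray(r_peaks, dtype=np.int64)
    strips: list[Strip] = []
    i = 0
    while i < len(peaks):
        s0 = int(peaks[i])
        e0 = s0 + n_win
        if e0 > len(signal.samples):
            break
        inside = peaks[(peaks >= s0) & (peaks < e0)]
        if len(inside) >= 2:
            rr = np.diff(inside) / fs
            mean_rr = float(np.mean(rr))
            hr = 60.0 / mean_rr
            if np.all(np.abs(rr - mean_rr) < rr_dev * mean_rr) and hr_lo <= hr <= hr_hi:
                strips.append(
                    Strip(signal.samples[s0:e0].copy(), fs, s0, inside - s0,
                          signal.subject_id, signal.label)
                )
                i = int(np.searchsorted(peaks, e0))
                continue
        i += 1
    logger.debug("find_segments(%s): %d strips in band [%g, %g]",
                 signal.subject_id, len(strips), hr_lo, hr_hi)
    return strips


def remove_baseline(strip: Strip, *, knot_window: float = 0.04) -> Strip:
    """Subtract a cubic spline through mid-RR baseline knots.

    Each knot sits at the midpoint of an RR interval and takes the local
    median voltage in a +/-``knot_window`` s neighbourhood (the mid-diastolic
    segment, where the trace should be isoelectric).  With fewer than two
    knots the strip median is subtracted instead (logged).
    """
    x = strip.samples
    fs = strip.sampling_rate
    r = strip.r_peaks
    mids = (r[:-1] + r[1:]) // 2
    if len(mids) < 2:
        logger.warning("strip %s: <2 baseline knots, subtracting median", strip.strip_id)
        return replace(strip, samples=x - np.median(x))
    w = max(1, int(round(knot_window * fs)))
    values = [float(np.median(x[max(0, m - w) : m + w + 1])) for m in mids]
    spline = CubicSpline(mids, values, bc_type="natural")
    baseline = spline(np.arange(len(x)))
    return replace(strip, samples=x - baseline)
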