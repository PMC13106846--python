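"""Reading, writing and resampling of single-lead ECG CSV exports.

Holter software exports vary in column naming, time units and headers, so the
reader is driven by a small dialect configuration rather than guessing.  The
sampling rate is inferred from the median time step; files whose time axis is
non-monotonic or non-uniform beyond a 1% tolerance are rejected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import resample_poly

from ._exceptions import FormatError, ParameterError, UnsupportedOperationError

__all__ = ["EcgSignal", "CsvDialect", "read_ecg_csv", "write_ecg_csv", "resample"]

logger = logging.getLogger(__name__)

ANALYSIS_RATE = 125.0  # Hz; the rate at which all downstream analysis runs


@dataclass
class EcgSignal:
    """A uniformly sampled single-lead voltage series in millivolts."""

    samples: np.ndarray
    sampling_rate: float
    subject_id: str = ""
    label: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise ParameterError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        if self.samples.ndim != 1 or len(self.samples) < 2:
            raise ParameterError("an ECG signal needs at least 2 samples")

    @property
    def duration(self) -> float:
        """Signal duration in seconds."""
        return len(self.samples) / self.sampling_rate

    @property
    def time(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.sampling_rate


@dataclass(frozen=True)
class CsvDialect:
    """Column mapping and units for an ECG CSV export.

    ``time_column`` / ``voltage_column`` may be integer positions or header
    names.  ``time_unit`` is ``"s"`` or ``"ms"``; ``voltage_scale`` converts
    the stored voltage column to millivolts.
    """

    time_column: int | str = 0
    voltage_column: int | str = 1
    time_unit: str = "s"
    voltage_scale: float = 1.0
    delimiter: str = ","
    header: str | bool = "auto"

    def __post_init__(self) -> None:
        if self.time_unit not in ("s", "ms"):
            raise ParameterError(f"time_unit must be 's' or 'ms', got {self.time_unit!r}")


def _has_header(path: Path, dialect: CsvDialect) -> bool:
    if dialect.header != "auto":
        return bool(dialect.header)
    with open(path) as fh:
        first = fh.readline()
    for tok in first.strip().split(dialect.delimiter):
        try:
            float(tok)
        except ValueError:
            return True
    return False


def _pick(frame: pd.DataFrame, column: int | str, role: str) -> np.ndarray:
    if isinstance(column, int):
        if column >= frame.shape[1]:
            raise FormatError(f"{role} column index {column} out of range ({frame.shape[1]} columns)")
        series = frame.iloc[:, column]
    else:
        if column not in frame.columns:
            raise FormatError(f"{role} column {column!r} not found in {list(frame.columns)}")
        series = frame[column]
    values = pd.to_numeric(series, errors="coerce").to_numpy(dtype=float)
    if np.isnan(values).any():
        raise FormatError(f"{role} column contains non-numeric values")
    return values


def read_ecg_csv(
    path: str | Path,
    dialect: CsvDialect = CsvDialect(),
    *,
    subject_id: str | None = None,
    label: str | None = None,
    uniformity_tol: float = 0.01,
) -> EcgSignal:
    """Read a time/voltage CSV export and infer its sampling rate.

    Raises :class:`FormatError` for missing columns, fewer than two rows, a
    non-monotonic time axis, or time steps deviating more than
    ``uniformity_tol`` (relative) from the median step.
    """
    path = Path(path)
    header = 0 if _has_header(path, dialect) else None
    frame = pd.read_csv(path, sep=dialect.delimiter, header=header)
    if len(frame) < 2:
        raise FormatError(f"{path}: need at least 2 rows, got {len(frame)}")
    t = _pick(frame, dialect.time_column, "time")
    v = _pick(frame, dialect.voltage_column, "voltage")
    if dialect.time_unit == "ms":
        t = t / 1000.0
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise FormatError(f"{path}: time column is not strictly increasing")
    step = float(np.median(dt))
    if np.max(np.abs(dt - step)) > uniformity_tol * step:
        raise FormatError(f"{path}: non-uniform sampling (> {uniformity_tol:.0%} deviation)")
    rate = 1.0 / step
    logger.info("read %s: %d samples, inferred %.6g Hz", path.name, len(v), rate)
    return EcgSignal(v * dialect.voltage_scale, rate, subject_id or path.stem, label)


def write_ecg_csv(
    signal: EcgSignal,
    path: str | Path,
    *,
    float_format: str = "%.6f",
    header: bool = True,
) -> Path:
    """Write a signal in the same dialect the reader consumes (time in s, mV)."""
    path = Path(path)
    frame = pd.DataFrame({"time": signal.time, "voltage": signal.samples})
    frame.to_csv(path, index=False, float_format=float_format, header=header)
    return path


def resample(signal: EcgSignal, target_rate: float = ANALYSIS_RATE) -> EcgSignal:
    """Anti-aliased polyphase down-sampling to ``target_rate``.

    Upsampling is refused: the analysis chain only ever reduces the rate.
    """
    if target_rate <= 0:
        raise ParameterError("target_rate must be positive")
    if target_rate > signal.sampling_rate * (1 + 1e-9):
        raise UnsupportedOperationError(
            f"upsampling {signal.sampling_rate} -> {target_rate} Hz is not supported"
        )
    if abs(target_rate - signal.sampling_rate) <= 1e-9 * signal.sampling_rate:
        return replace(signal, samples=signal.samples.copy())
    ratio = Fraction(target_rate / signal.sampling_rate).limit_denominator(10_000)
    out = resample_poly(signal.samples, ratio.numerator, ratio.denominator)
    n_out = int(round(len(signal.samples) * target_rate / signal.sampling_rate))
    out = out[:n_out]
    if len(out) < n_out:  # resample_poly may round down by one sample
        out = np.pad(out, (0, n_out - len(out)), mode="edge")
    return EcgSignal(out, target_rate, signal.subject_id, signal.label)
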