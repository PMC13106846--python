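"""Heart-rate correction of complexity values and per-subject scoring.

Normalised complexity depends non-linearly on heart rate (faster rates pack
more beats, hence more symbol transitions, into a fixed-length strip).  The
correction fits a polynomial trend of complexity versus heart rate -- degree
2, 3 or 4, selected by AIC -- to heart-rate-binned mean values and subtracts
it from the individual strip values, leaving residual "corrected complexity"
in bit/sample.  The per-subject mean of corrected values is the diagnostic
score.

The trend is fitted on the full data set (cases and controls pooled), which
mirrors how the method was developed as a pilot: this leaks group information
into the correction and is a documented bias, not an accident.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from ._exceptions import FitError, LabellingError, ParameterError

__all__ = [
    "HrComplexityPoint",
    "HrPolynomial",
    "SubjectScore",
    "fit_hr_polynomial",
    "correct",
    "subject_score",
]

logger = logging.getLogger(__name__)

DEGREES = (2, 3, 4)
BIN_WIDTH = 5.0  # bpm


@dataclass(frozen=True)
class HrComplexityPoint:
    """One strip's normalised complexity at its mean heart rate."""

    strip_id: str
    subject_id: str
    mean_hr: float
    value: float
    estimator: str = ""
    mask: int = 0


@dataclass(frozen=True)
class HrPolynomial:
    """An AIC-selected polynomial trend of complexity versus heart rate."""

    degree: int
    coefficients: tuple  # numpy.polyval order (highest degree first)
    aic: float
    candidate_aic: dict
    hr_range: tuple

    def __call__(self, hr):
        return np.polyval(self.coefficients, hr)


@dataclass(frozen=True)
class SubjectScore:
    """Per-subject mean corrected complexity with the case/control label."""

    subject_id: str
    label: str
    score: float
    n_strips: int


def _as_arrays(points) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(points, pd.DataFrame):
        return points["mean_hr"].to_numpy(float), points["value"].to_numpy(float)
    hr = np.asarray([p.mean_hr for p in points], dtype=float)
    val = np.asarray([p.value for p in points], dtype=float)
    return hr, val


def fit_hr_polynomial(
    points,
    *,
    degrees: Sequence[int] = DEGREES,
    bin_width: float = BIN_WIDTH,
    small_sample_correction: bool = False,
) -> HrPolynomial:
    """Fit the heart-rate trend to binned mean complexity and select by AIC.

    Values are averaged in ``bin_width``-bpm heart-rate bins first; candidate
    polynomials are least-squares fits to the bin means, scored with
    ``AIC = n ln(RSS/n) + 2k`` (k = number of coefficients; ``AICc`` adds the
    small-sample term when requested).  Ties go to the lower degree.
    """
    hr, val = _as_arrays(points)
    if len(hr) < 6 or len(np.unique(hr)) < 3:
        raise FitError(
            f"need >= 6 points spanning >= 3 distinct heart rates, got {len(hr)} "
            f"points / {len(np.unique(hr))} rates"
        )
    bins = np.floor(hr / bin_width).astype(int)
    frame = pd.DataFrame({"bin": bins, "hr": hr, "value": val})
    grouped = frame.groupby("bin").mean()
    bin_hr = grouped["hr"].to_numpy()
    bin_val = grouped["value"].to_numpy()
    n = len(bin_hr)
    # RSS floor: below numerical noise all candidates are "exact" and the
    # penalty term alone (hence the lower degree) should decide
    rss_floor = n * (1e-10 * max(1.0, float(np.ptp(bin_val)) or 1.0)) ** 2
    candidates: dict[int, tuple[float, np.ndarray]] = {}
    for d in sorted(degrees):
        if n < d + 2:  # need at least one residual degree of freedom
            continue
        coef = np.polyfit(bin_hr, bin_val, d)
        rss = float(np.sum((np.polyval(coef, bin_hr) - bin_val) ** 2))
        k = d + 1
        aic = n * np.log(max(rss, rss_floor) / n) + 2 * k
        if small_sample_correction and n - k - 1 > 0:
            aic += 2 * k * (k + 1) / (n - k - 1)
        candidates[d] = (float(aic), coef)
    if not candidates:
        raise FitError(f"too few heart-rate bins ({n}) for any candidate degree {tuple(degrees)}")
    best = min(candidates, key=lambda d: (candidates[d][0], d))
    aics = {d: a for d, (a, _) in candidates.items()}
    logger.debug("HR polynomial: degree %d selected, AIC per degree %s", best, aics)
    return HrPolynomial(
        degree=best,
        coefficients=tuple(candidates[best][1]),
        aic=aics[best],
        candidate_aic=aics,
        hr_range=(float(hr.min()), float(hr.max())),
    )


def correct(points, poly: HrPolynomial) -> np.ndarray:
    """Subtract the fitted trend: corrected value = value - poly(mean HR)."""
    hr, val = _as_arrays(points)
    lo, hi = poly.hr_range
    if np.any(hr < lo) or np.any(hr > hi):
        logger.warning("correcting %d points outside the fitted HR range [%g, %g]",
                       int(np.sum((hr < lo) | (hr > hi))), lo, hi)
    return val - poly(hr)


def subject_score(frame: pd.DataFrame) -> list[SubjectScore]:
    """Average corrected complexity per subject, label attached.

    ``frame`` needs columns ``subject_id``, ``label`` and ``corrected``.
    """
    if not isinstance(frame, pd.DataFrame):
        frame = pd.DataFrame(
            [{"subject_id": p[0], "label": p[1], "corrected": p[2]} for p in frame],
        )
    required = {"subject_id", "label", "corrected"}
    if not required <= set(frame.columns):
        raise ParameterError(f"subject_score needs columns {sorted(required)}")
    bad = frame["label"].isna() | ~frame["label"].isin(["case", "control"])
    if bad.any():
        raise LabellingError(
            f"subjects without a valid case/control label: "
            f"{sorted(frame.loc[bad, 'subject_id'].unique())}"
        )
    out = []
    for subject, grp in frame.groupby("subject_id", sort=True):
        labels = grp["label"].unique()
        if len(labels) != 1:
            raise LabellingError(f"subject {subject} carries conflicting labels {labels}")
        out.append(SubjectScore(str(subject), str(labels[0]),
                                float(grp["corrected"].mean()), int(len(grp))))
    return out
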