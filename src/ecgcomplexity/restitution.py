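"""Per-beat restitution intervals and the interval-triplet k-NN classifier.

Restitution analysis compares how the action-potential duration (QT), the
diastolic interval (TQ) and the QRS width depend on the basic cycle length
(RR).  Intervals are measured between the same fiducials the coarse-graining
uses: QT from Q onset to T end of one beat, TQ from that T end to the next
beat's Q onset, so that QT + TQ equals the Q-onset-to-Q-onset interval by
construction.

The classifier operates on (TQ, QT, RR) triplets standardised by the training
set, with a shrinking-k majority vote on ties.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import spearmanr

from ._exceptions import InsufficientDataError, ParameterError
from .annotation import BeatAnnotation

__all__ = ["RestitutionBeat", "beat_intervals", "restitution_curves", "knn_classify"]

logger = logging.getLogger(__name__)

CURVE_PAIRS = (("rr", "qt"), ("rr", "tq"), ("tq", "qt"), ("rr", "qrs_width"))


@dataclass(frozen=True)
class RestitutionBeat:
    """Intervals of one beat pair, in milliseconds."""

    rr: float  # R peak to next R peak
    qt: float  # Q onset to T end
    tq: float  # T end to next Q onset
    qrs_width: float  # Q onset to QRS end

    def __post_init__(self) -> None:
        if min(self.rr, self.qt, self.tq, self.qrs_width) <= 0:
            raise ParameterError(f"restitution intervals must be positive: {self}")


def beat_intervals(annotations: list[BeatAnnotation], rate: float) -> list[RestitutionBeat]:
    """One interval record per consecutive beat pair; the last beat emits none."""
    if len(annotations) < 2:
        raise InsufficientDataError("restitution needs at least 2 annotated beats")
    ms = 1000.0 / rate
    out = []
    for a, b in zip(annotations, annotations[1:]):
        out.append(
            RestitutionBeat(
                rr=(b.r_peak - a.r_peak) * ms,
                qt=(a.t_end - a.q_onset) * ms,
                tq=(b.q_onset - a.t_end) * ms,
                qrs_width=(a.qrs_end - a.q_onset) * ms,
            )
        )
    return out


def restitution_curves(beats: list[RestitutionBeat]) -> dict:
    """Paired interval series with Spearman correlations, ready for export.

    Returns ``{"frame": DataFrame, "correlations": {pair: rho_or_nan}}``;
    a correlation is reported as NaN when either axis is constant.
    """
    if len(beats) < 10:
        raise InsufficientDataError(f"restitution curves need >= 10 beats, got {len(beats)}")
    frame = pd.DataFrame([vars(b) for b in beats])
    correlations: dict[str, float] = {}
    for x, y in CURVE_PAIRS:
        if frame[x].nunique() < 2 or frame[y].nunique() < 2:
            rho = float("nan")  # undefined on constant input, reported as such
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rho = float(spearmanr(frame[x], frame[y]).statistic)
        correlations[f"{y}_vs_{x}"] = rho
    return {"frame": frame, "correlations": correlations}


def knn_classify(train_x, train_y, test_x, k: int):
    """k-nearest-neighbour vote in z-scored (TQ, QT, RR) space.

    Features are standardised with the training mean/SD; ties in the majority
    vote fall back to k-2, k-4, ... and finally the single nearest neighbour.
    """
    train_x = np.atleast_2d(np.asarray(train_x, dtype=float))
    test_x = np.atleast_2d(np.asarray(test_x, dtype=float))
    train_y = np.asarray(train_y)
    if len(train_x) == 0:
        raise ParameterError("empty training set")
    if not 1 <= k <= len(train_x):
        raise ParameterError(f"k must be in 1..{len(train_x)}, got {k}")
    mean = train_x.mean(axis=0)
    sd = train_x.std(axis=0)
    sd[sd == 0] = 1.0
    dist = cdist((test_x - mean) / sd, (train_x - mean) / sd)
    labels = []
    for row in dist:
        order = np.argsort(row, kind="stable")
        kk = k
        while True:
            votes = pd.Series(train_y[order[:kk]]).value_counts()
            if kk == 1 or (len(votes) == 1 or votes.iloc[0] > votes.iloc[1]):
                labels.append(votes.index[0])
                break
            kk = max(1, kk - 2)
    return np.asarray(labels)
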