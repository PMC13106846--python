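"""Parameterised synthetic single-lead ECGs with exact ground-truth fiducials.

The generator emulates a base-apex-style equine lead: each heartbeat is a sum
of five Gaussian bumps (P, Q, R, S, T) placed on an RR grid derived from a
heart-rate trajectory with beat-to-beat jitter.  Because every wave is an
analytic bump, the six fiducial markers (Q onset, Q peak, R peak, QRS end,
T peak, T end) are known exactly for every beat, which is what makes the whole
downstream pipeline testable without clinical recordings.

Ground-truth fiducial definitions (shared with the annotation module's search
targets; the 5% constants are documented here once):

* Q onset   -- first sample where the QRS-only waveform exceeds 5% of its
               peak-to-peak range;
* Q peak    -- minimum of the QRS-only waveform left of R;
* R peak    -- maximum-magnitude sample of the beat;
* QRS end   -- first sample after S back within 5% of the QRS peak-to-peak;
* T peak    -- maximum-magnitude sample of the T bump;
* T end     -- first sample after T peak at/below 5% of the T amplitude.

Case/control cohorts differ by a single "complexity effect" knob: the standard
deviation of beat-to-beat jitter applied to intra-beat fiducial timings (and,
proportionally, wave amplitudes).  Cases in the study population show *lower*
corrected complexity, so the default cohort effect reduces this jitter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._exceptions import ParameterError
from .io import EcgSignal

__all__ = [
    "WAVES",
    "BeatTemplateParams",
    "SubjectSimParams",
    "GroundTruth",
    "Cohort",
    "generate_beat_template",
    "generate_ecg",
    "generate_cohort",
]

logger = logging.getLogger(__name__)

WAVES = ("p", "q", "r", "s", "t")

# Threshold constants used by the ground-truth fiducial definitions.
QRS_ONSET_FRACTION = 0.05  # of QRS peak-to-peak
T_END_FRACTION = 0.05  # of T amplitude
# first sub-threshold sample of a Gaussian of width s lies ~sqrt(2 ln 20) s
# past its centre; used to place the T bump so that T end lands on a target QT
_T_END_SIGMA = float(np.sqrt(2.0 * np.log(1.0 / T_END_FRACTION)))

# Baseline "physiological" beat-to-beat variability of intra-beat timings for
# a control subject, and the default case-vs-control reduction ("strong"
# effect).  Chosen once as generator design (see the methods note): control
# fiducial jitter 12 ms SD; a strong effect removes two thirds of it.
BASE_FIDUCIAL_JITTER_SD = 0.012
STRONG_EFFECT = -0.008


@dataclass(frozen=True)
class BeatTemplateParams:
    """Per-wave amplitude (mV), centre offset from R (s) and width (s).

    Offsets are expressed at a reference RR of 1 s; the P wave offset scales
    with the local RR and the T wave is re-placed per beat from the QT model
    (see :class:`SubjectSimParams`).  R is fixed at offset 0.
    """

    amplitudes: tuple[float, float, float, float, float] = (0.20, -0.18, 1.00, -0.30, 0.35)
    offsets: tuple[float, float, float, float, float] = (-0.22, -0.040, 0.0, 0.040, 0.27)
    widths: tuple[float, float, float, float, float] = (0.045, 0.012, 0.014, 0.015, 0.050)

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.widths):
            raise ParameterError(f"wave widths must be > 0, got {self.widths}")
        amps = dict(zip(WAVES, self.amplitudes))
        if any(abs(amps[w]) > abs(amps["r"]) for w in ("q", "s")):
            raise ParameterError("R amplitude must dominate Q and S in magnitude")
        widths = dict(zip(WAVES, self.widths))
        if not all(widths["t"] > widths[w] for w in ("q", "r", "s")):
            raise ParameterError("T width must exceed the QRS wave widths")

    def wave(self, name: str) -> tuple[float, float, float]:
        i = WAVES.index(name)
        return self.amplitudes[i], self.offsets[i], self.widths[i]


@dataclass(frozen=True)
class SubjectSimParams:
    """Everything needed to synthesise one labelled recording.

    ``heart_rate`` is either a constant (bpm) or a piecewise-linear trajectory
    ``(times_s, bpm)``.  ``fiducial_jitter_sd`` is the complexity knob: the SD
    (seconds) of beat-to-beat jitter of P/Q/S/T centre offsets; amplitudes are
    jittered proportionally (``amplitude_jitter_frac``).  If
    ``fiducial_jitter_sd_above_gate`` is set, beats whose local heart rate
    exceeds ``jitter_gate_bpm`` use that SD instead, which lets an effect be
    confined to one heart-rate range.
    """

    subject_id: str = "S000"
    label: str | None = None
    duration: float = 120.0
    heart_rate: float | tuple = 60.0
    rr_jitter_sd: float = 0.04
    ectopic_rate: float = 0.0  # beats per minute
    ectopic_prematurity: float = 0.40  # fraction of mean RR, >= 0.35 by design
    fiducial_jitter_sd: float = 0.0
    fiducial_jitter_sd_above_gate: float | None = None
    jitter_gate_bpm: float = 60.0
    amplitude_jitter_frac: float = 0.0
    baseline_wander_amp: float = 0.10
    baseline_wander_freq: float = 0.15
    noise_sd: float = 0.01
    sampling_rate: float = 500.0
    qt_intercept: float = 0.26  # s; QT(RR) = intercept + slope * RR
    qt_slope: float = 0.20
    template: BeatTemplateParams = field(default_factory=BeatTemplateParams)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("rr_jitter_sd", "ectopic_rate", "fiducial_jitter_sd",
                     "amplitude_jitter_frac", "baseline_wander_amp", "noise_sd"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.sampling_rate < 250:
            raise ParameterError("native sampling rate must be >= 250 Hz")
        hr = np.atleast_1d(np.asarray(self.heart_rate[1] if isinstance(self.heart_rate, tuple)
                                      else self.heart_rate, dtype=float))
        if np.any(hr < 25) or np.any(hr > 200):
            raise ParameterError(f"heart rate trajectory must stay within 25-200 bpm, got {hr}")
        if self.duration < 60.0 / float(np.max(hr)):
            raise ParameterError("duration must cover at least one beat")

    def hr_at(self, t: np.ndarray | float) -> np.ndarray | float:
        if isinstance(self.heart_rate, tuple):
            times, bpm = self.heart_rate
            return np.interp(t, np.asarray(times, float), np.asarray(bpm, float))
        return np.broadcast_to(float(self.heart_rate), np.shape(t)) if np.ndim(t) else float(self.heart_rate)


@dataclass
class GroundTruth:
    """Exact per-beat fiducial sample indices plus an ectopic flag."""

    q_onset: np.ndarray
    q_peak: np.ndarray
    r_peak: np.ndarray
    qrs_end: np.ndarray
    t_peak: np.ndarray
    t_end: np.ndarray
    ectopic: np.ndarray

    FIELDS = ("q_onset", "q_peak", "r_peak", "qrs_end", "t_peak", "t_end")

    def __post_init__(self) -> None:
        for name in self.FIELDS:
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.int64))
        self.ectopic = np.asarray(self.ectopic, dtype=bool)
        stack = np.stack([getattr(self, f) for f in self.FIELDS])
        if stack.shape[1] and not (np.diff(stack, axis=0) > 0).all():
            raise ParameterError("ground-truth fiducials must be strictly increasing within a beat")
        if stack.shape[1] > 1 and not (self.t_end[:-1] < self.q_onset[1:]).all():
            raise ParameterError("ground-truth beats must not overlap")

    def __len__(self) -> int:
        return len(self.r_peak)

    def rescaled(self, source_rate: float, target_rate: float) -> "GroundTruth":
        """Map indices onto a grid at a different sampling rate (rounded).

        Down-sampling can collapse fiducials that sit less than one target
        sample apart, so the result is a reference mapping and is exempt from
        the strict-ordering validation of native-rate ground truth.
        """
        f = target_rate / source_rate
        out = object.__new__(GroundTruth)
        for name in self.FIELDS:
            setattr(out, name, np.round(getattr(self, name) * f).astype(np.int64))
        out.ectopic = self.ectopic.copy()
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({n: getattr(self, n) for n in (*self.FIELDS, "ectopic")})


def _gauss(tt: np.ndarray, amp: float, centre: float, width: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((tt - centre) / width) ** 2)


def _beat_fiducials_seconds(
    amps: dict[str, float], offs: dict[str, float], widths: dict[str, float], rate: float
) -> dict[str, float] | None:
    """Fiducial times (s, relative to the beat's R offset 0) from the analytic
    bumps, evaluated on a dense grid at ``rate``.  Returns None for a beat with
    no QRS deflection ("no beat")."""
    dt = 1.0 / rate
    lo = min(offs[w] - 6 * widths[w] for w in WAVES)
    hi = max(offs[w] + 6 * widths[w] for w in WAVES)
    tt = np.arange(np.floor(lo / dt), np.ceil(hi / dt) + 1) * dt
    qrs = sum(_gauss(tt, amps[w], offs[w], widths[w]) for w in ("q", "r", "s"))
    pp = float(np.ptp(qrs))
    if pp <= 0:
        return None
    thr = QRS_ONSET_FRACTION * pp
    exceed = np.flatnonzero(np.abs(qrs) > thr)
    q_on = tt[exceed[0]]
    qrs_end = tt[exceed[-1] + 1] if exceed[-1] + 1 < len(tt) else tt[-1]
    r_idx = int(np.argmax(np.abs(qrs)))
    r_t = tt[r_idx]
    left = qrs[:r_idx]
    if len(left) == 0:
        return None
    # Q peak: the local minimum before R; with a flat Q this resolves to the
    # deepest point left of R (the R upstroke foot)
    q_pk = tt[int(np.argmin(left))]
    tw = _gauss(tt, amps["t"], offs["t"], widths["t"])
    t_amp = float(np.max(np.abs(tw)))
    if t_amp <= 0:
        return None
    t_idx = int(np.argmax(np.abs(tw)))
    t_pk = tt[t_idx]
    below = np.flatnonzero(np.abs(tw[t_idx:]) <= T_END_FRACTION * t_amp)
    t_end = tt[t_idx + below[0]] if len(below) else tt[-1]
    out = {"q_onset": q_on, "q_peak": q_pk, "r_peak": r_t, "qrs_end": qrs_end,
           "t_peak": t_pk, "t_end": t_end}
    keys = list(out)
    if any(out[keys[i]] >= out[keys[i + 1]] for i in range(len(keys) - 1)):
        return None
    return out


def generate_beat_template(
    params: BeatTemplateParams, rate: float
) -> tuple[np.ndarray, dict[str, int] | None]:
    """Sample one isolated beat at ``rate`` and return its fiducial indices.

    The waveform spans six widths either side of the outermost bumps; returned
    indices are positions within that window.  ``None`` fiducials signal "no
    beat" (e.g. an all-zero template).
    """
    if rate <= 0:
        raise ParameterError("rate must be > 0")
    amps = dict(zip(WAVES, params.amplitudes))
    offs = dict(zip(WAVES, params.offsets))
    widths = dict(zip(WAVES, params.widths))
    dt = 1.0 / rate
    lo = min(offs[w] - 6 * widths[w] for w in WAVES)
    hi = max(offs[w] + 6 * widths[w] for w in WAVES)
    grid = np.arange(np.floor(lo / dt), np.ceil(hi / dt) + 1)
    tt = grid * dt
    wave = sum(_gauss(tt, amps[w], offs[w], widths[w]) for w in WAVES)
    fid = _beat_fiducials_seconds(amps, offs, widths, rate)
    if fid is None:
        return wave, None
    idx0 = int(grid[0])
    indices = {k: int(round(v / dt)) - idx0 for k, v in fid.items()}
    return wave, indices


# The premature RR interval must stay above the R-detector's refractory
# interval (0.3 s) to remain detectable; a small margin is added.
_MIN_PREMATURE_RR = 0.32
_MIN_PREMATURITY = 0.35  # below this the 30% exclusion rule is not provable


def _beat_times(sim: SubjectSimParams, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Sinus beat schedule plus ectopic flags.

    An ectopic replaces a sinus beat with an exactly premature one: the
    interval into it is ``(1 - p) * RR_nominal`` and the compensatory pause
    out of it is ``(1 + p) * RR_nominal``, after which the sinus clock
    resets.  Pinning both intervals to the *nominal* RR (not the jittered
    neighbours) guarantees that each deviates from any surrounding 60-s
    window's mean RR by at least ~p, so the 30% exclusion rule provably
    removes every window containing the ectopic.  The prematurity is capped
    so the premature interval stays detectable (>= 0.32 s); beats where even
    the minimum prematurity of 35% cannot satisfy that are left sinus.
    RR jitter is clipped at 3 SD so window means stay close to nominal.
    """
    times = []
    hr0 = float(np.max(np.atleast_1d(sim.hr_at(0.0))))
    t = 0.5 * 60.0 / hr0
    sd = sim.rr_jitter_sd
    while t < sim.duration - 0.05:
        hr = float(sim.hr_at(t))
        rr_mean = 60.0 / hr
        rr = rr_mean * (1.0 + (float(np.clip(rng.normal(0.0, sd), -3 * sd, 3 * sd)) if sd > 0 else 0.0))
        times.append(t)
        t += rr
    times = np.asarray(times)
    ectopic = np.zeros(len(times), dtype=bool)
    if sim.ectopic_rate > 0 and len(times) > 3:
        prob = min(1.0, sim.ectopic_rate * sim.duration / 60.0 / max(1, len(times) - 2))
        candidates = np.arange(1, len(times) - 1)
        chosen = candidates[rng.random(len(candidates)) < prob]
        keep = []
        last = -10
        for i in chosen:  # avoid adjacent ectopics, which would collide
            if i - last >= 2:
                keep.append(i)
                last = i
        for i in keep:
            rr_nom = 60.0 / float(sim.hr_at(times[i]))
            p = min(sim.ectopic_prematurity, 1.0 - _MIN_PREMATURE_RR / rr_nom)
            if p < _MIN_PREMATURITY:
                continue  # too fast a rhythm for a detectable premature beat
            new_t = times[i - 1] + (1.0 - p) * rr_nom
            post_target = new_t + (1.0 + p) * rr_nom
            shift = post_target - times[i + 1]
            times[i] = new_t
            times[i + 1 :] += shift
            ectopic[i] = True
        inside = times < sim.duration - 0.05
        times, ectopic = times[inside], ectopic[inside]
    return times, ectopic


def generate_ecg(sim: SubjectSimParams) -> tuple[EcgSignal, GroundTruth]:
    """Synthesise one recording; deterministic for fixed parameters and seed."""
    rng = np.random.default_rng(sim.seed)
    fs = sim.sampling_rate
    n = int(round(sim.duration * fs))
    samples = np.zeros(n)
    times, ectopic = _beat_times(sim, rng)

    amps0 = dict(zip(WAVES, sim.template.amplitudes))
    offs0 = dict(zip(WAVES, sim.template.offsets))
    widths0 = dict(zip(WAVES, sim.template.widths))
    # Q-onset offset of the noiseless template, used to anchor the QT model.
    base_fid = _beat_fiducials_seconds(amps0, offs0, widths0, fs)
    if base_fid is None:
        raise ParameterError("template produces no annotatable beat")
    q_on_off = base_fid["q_onset"]

    truth_rows: list[dict[str, float]] = []
    kept_ectopic: list[bool] = []
    tgrid = np.arange(n) / fs
    for i, t0 in enumerate(times):
        rr_prev = times[i] - times[i - 1] if i > 0 else (times[1] - times[0] if len(times) > 1 else 1.0)
        rr_next = times[i + 1] - times[i] if i + 1 < len(times) else rr_prev
        hr_local = float(sim.hr_at(t0))
        jit_sd = sim.fiducial_jitter_sd
        if sim.fiducial_jitter_sd_above_gate is not None and hr_local > sim.jitter_gate_bpm:
            jit_sd = sim.fiducial_jitter_sd_above_gate
        # Draw jitter and validate the beat's fiducials before rendering so
        # that every beat in the signal has complete ground truth; a draw
        # that degenerates the marker ordering (rare) is redrawn.
        fid = None
        amps = offs = widths = None
        for _attempt in range(20):
            jitter = {w: float(np.clip(rng.normal(0.0, jit_sd), -3 * jit_sd, 3 * jit_sd))
                      if jit_sd > 0 else 0.0 for w in WAVES}
            jitter["r"] = 0.0  # R stays on the RR grid
            # keep Q/S jitter from sliding those waves under the R bump
            for w in ("q", "s"):
                lim = 0.5 * abs(offs0[w])
                jitter[w] = float(np.clip(jitter[w], -lim, lim))
            ascale = {w: 1.0 + (float(np.clip(rng.normal(0.0, sim.amplitude_jitter_frac),
                                              -0.5, 0.5)) if sim.amplitude_jitter_frac > 0 else 0.0)
                      for w in WAVES}
            amps = {w: amps0[w] * ascale[w] for w in WAVES}
            offs = dict(offs0)
            widths = dict(widths0)
            offs["p"] = float(np.clip(offs0["p"] * rr_prev, -0.45, -0.12))
            qt = sim.qt_intercept + sim.qt_slope * rr_next
            offs["t"] = q_on_off + qt - _T_END_SIGMA * widths0["t"]
            if ectopic[i]:
                amps["p"] = 0.0
                amps["q"] *= 1.2
                amps["r"] *= 1.25
                amps["s"] *= 1.2
                for w in ("q", "r", "s"):
                    widths[w] = widths0[w] * 1.6
                amps["t"] = -amps0["t"]
            for w in WAVES:
                offs[w] += jitter[w]
            fid = _beat_fiducials_seconds(amps, offs, widths, fs)
            if fid is not None:
                break
        if fid is None:
            continue  # pathological template (e.g. zero T); beat not rendered
        row = {k: int(round((t0 + v) * fs)) for k, v in fid.items()}
        if min(row.values()) < 0 or max(row.values()) >= n:
            continue  # beat would be truncated by the recording edge
        if truth_rows and row["q_onset"] <= truth_rows[-1]["t_end"]:
            continue  # would overlap the previous beat (extreme prematurity)

        for w in WAVES:
            if amps[w] == 0.0:
                continue
            c = t0 + offs[w]
            i0 = max(0, int((c - 6 * widths[w]) * fs))
            i1 = min(n, int((c + 6 * widths[w]) * fs) + 1)
            if i1 > i0:
                samples[i0:i1] += _gauss(tgrid[i0:i1], amps[w], c, widths[w])
        truth_rows.append(row)
        kept_ectopic.append(bool(ectopic[i]))
    rows, flags = truth_rows, kept_ectopic

    phase = rng.uniform(0.0, 2 * np.pi)
    if sim.baseline_wander_amp > 0:
        samples += sim.baseline_wander_amp * np.sin(2 * np.pi * sim.baseline_wander_freq * tgrid + phase)
    if sim.noise_sd > 0:
        samples += rng.normal(0.0, sim.noise_sd, n)

    truth = GroundTruth(
        *(np.array([r[f] for r in rows], dtype=np.int64) for f in GroundTruth.FIELDS),
        ectopic=np.array(flags, dtype=bool),
    )
    signal = EcgSignal(samples, fs, sim.subject_id, sim.label)
    return signal, truth


@dataclass
class Cohort:
    """A labelled set of synthetic recordings with their ground truths."""

    recordings: list[EcgSignal]
    truths: list[GroundTruth]
    params: list[SubjectSimParams]

    @property
    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"subject_id": [r.subject_id for r in self.recordings],
             "label": [r.label for r in self.recordings]}
        )


def generate_cohort(
    n_cases: int,
    n_controls: int,
    effect: float = STRONG_EFFECT,
    seed: int = 0,
    *,
    duration: float = 200.0,
    hr_range: tuple[float, float] = (48.0, 105.0),
    base_jitter_sd: float = BASE_FIDUCIAL_JITTER_SD,
    amplitude_jitter_frac: float = 0.05,
    gate_bpm: float | None = None,
    two_level_hr: bool = False,
    **overrides,
) -> Cohort:
    """Generate a labelled case/control cohort.

    ``effect`` (seconds, signed) is added to the case fiducial-jitter SD;
    the study population's direction is negative (cases less variable, hence
    lower complexity).  With ``gate_bpm`` set, the effect applies only to
    beats above that heart rate; combined with ``two_level_hr`` each subject
    is recorded half at a low and half at a high heart rate so both bands are
    populated.
    """
    if n_cases < 0 or n_controls < 0:
        raise ParameterError("cohort sizes must be >= 0")
    rng = np.random.default_rng(seed)
    recordings, truths, params_list = [], [], []
    labels = ["case"] * n_cases + ["control"] * n_controls
    for i, label in enumerate(labels):
        case = label == "case"
        case_sd = max(base_jitter_sd + effect, 0.0)
        if two_level_hr:
            lo = float(rng.uniform(40.0, 55.0))
            hi = float(rng.uniform(70.0, 95.0))
            half = duration / 2.0
            hr: float | tuple = ([0.0, half - 1e-3, half, duration], [lo, lo, hi, hi])
        else:
            hr = float(rng.uniform(*hr_range))
        if case and gate_bpm is not None:
            jitter_sd, above = base_jitter_sd, case_sd
        elif case:
            jitter_sd, above = case_sd, None
        else:
            jitter_sd, above = base_jitter_sd, None
        p = SubjectSimParams(
            subject_id=f"{'CASE' if case else 'CTRL'}{i:03d}",
            label=label,
            duration=duration,
            heart_rate=hr,
            fiducial_jitter_sd=jitter_sd,
            fiducial_jitter_sd_above_gate=above,
            jitter_gate_bpm=gate_bpm if gate_bpm is not None else 60.0,
            amplitude_jitter_frac=amplitude_jitter_frac,
            seed=int(rng.integers(0, 2**31 - 1)),
            **overrides,
        )
        sig, truth = generate_ecg(p)
        recordings.append(sig)
        truths.append(truth)
        params_list.append(p)
    logger.info("generated cohort: %d cases, %d controls, effect %+.4f s", n_cases, n_controls, effect)
    return Cohort(recordings, truths, params_list)
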