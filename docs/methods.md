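# Methods

This note documents the models, algorithmic conventions, parameter defaults
and design decisions of `ecgcomplexity`, and what the synthetic-data tests do
and do not establish about real recordings.

## Signal model and segmentation

Input is a uniformly sampled single-lead voltage series in millivolts. The
sampling rate is inferred from the median time step of the CSV; steps
deviating more than 1% from the median are treated as a corrupt export.
All analysis runs at 125 Hz; higher-rate inputs are down-sampled by polyphase
filtering (`scipy.signal.resample_poly`), which protects QRS energy better
than naive decimation. Upsampling is refused: a 60-s strip at 125 Hz is
7500 samples, and all length normalisations assume that scale.

QRS detection is a band-pass (5–40 Hz, 2nd-order Butterworth, zero-phase) /
differentiate / square / moving-window-integrate (150 ms) chain with an
adaptive threshold (25% of the 99th percentile of the integrated energy) and
a 0.3 s refractory interval, which caps detectable rates at 200 bpm. Peak
positions are refined to the dominant-polarity raw-signal extremum within
±100 ms; lead polarity is chosen automatically from the detected complexes.

Strip selection is a greedy left-to-right scan over candidate 60-s windows
anchored at R peaks. A window is accepted iff (a) every RR interval inside it
deviates less than 30% from the window's own mean RR, and (b) the mean heart
rate lies in the extraction band (default 30–120 bpm). Accepted windows do
not overlap; the scan resumes after an accepted window and advances one beat
after a rejection. Interpreting "average RR" per-window (not per-recording)
makes the rule deterministic and local; the 30% threshold excludes premature
beats, blocks, pauses and disconnections while tolerating respiratory sinus
arrhythmia. Baseline wander is removed by subtracting a natural cubic spline
through knots at RR midpoints, each knot holding the local median voltage in
a ±40 ms window (mid-diastole is the most reliably isoelectric moment);
with fewer than two knots the strip median is subtracted instead.

## Fiducial annotation and coarse-graining

Six markers are located per beat, searching windows scaled to the local RR:

* Q peak: minimum in (R − 0.12·RR, R); S analogously after R.
* Q onset / QRS end: the first sample beyond which the waveform magnitude
  stays within 5% of the QRS peak-to-peak range (walking outwards from the
  Q/S extrema).
* T peak: maximum |deflection| in (QRS end + 0.05 s, QRS end + 0.45·RR).
* T end: first sample at/below 5% of the T amplitude after T peak
  (default); a slope-tangent method (steepest post-peak tangent extrapolated
  to baseline) is available via `AnnotationConfig(t_end_method="tangent")`.
  The amplitude-threshold default was chosen because it is the same
  definition the synthetic generator's ground truth uses, making
  annotation-accuracy statements exact rather than convention-dependent;
  on clean synthetic beats the two methods agree to within ~64 ms.

Beats whose search fails (missing T wave, edge truncation, out-of-order
markers, T running into the next beat) are dropped and logged; a strip with
no annotatable beat raises an error and is excluded upstream.

The 'J'/'L' symbols of the XD scheme mark the **T wave's** peak and
termination; the six-marker set is Q onset, Q peak, R peak, QRS end, T peak,
T end throughout. FD mask codes use the fixed bit order Qon=1, Qpk=2, R=4,
QRSend=8, Tpk=16, Tend=32, so "mask 44" always means R + QRS end + T end.

## Disorderliness estimators

Parsing conventions (they matter at small n and are frozen here):

* **LZ'76**: exhaustive-history component count; a component extends the
  longest prefix of the remainder copyable from the extended past
  (self-referential copies allowed) by one fresh symbol; a trailing fully
  reproducible chunk counts as one component. Normalised by `n / log2 n`.
* **LZ'78**: incremental-dictionary phrase count; a trailing partial phrase
  counts as one. Normalised by `n`.
* **Titchener T-complexity**: greedy maximal T-decomposition
  `x = p_m^{k_m} ... p_1^{k_1} a` (a = last symbol; each T-prefix p_i is a
  level-(i−1) codeword read innermost-first off the string tail);
  T-complexity = Σ log2(k_i + 1) taugs. The per-sample value divides by n;
  the linearised T-entropy rate (inverse logarithmic integral of T·ln 2) is
  available as `t_entropy_rate` for users who prefer that reading. Note
  that the decomposition value is *not* pointwise monotone under appending
  a symbol (appending can merge steps into a larger copy exponent — e.g.
  "01010" → "010100" drops from 3.0 to ≈2.585 taugs); it grows
  monotonically in trend, which is what matters at n = 7500.
* **Shannon entropy**: order-1 (single-symbol) in bits/symbol; no block
  length is used.
* **ApEn / SampEn**: Pincus and Richman–Moorman definitions on the raw
  voltage strip, Chebyshev distance, defaults m = 2, r = 0.2·SD (the
  field-standard values). SampEn excludes self-matches and is reported as
  undefined when no template pair matches. A zero-variance series gets an
  absolute tolerance floor so constants return 0 rather than NaN.

String estimators run on the TC string and the 63 FD strings; series
estimators run on the raw strip. All are deterministic.

## Heart-rate correction

Normalised complexity versus heart rate is non-linear (faster rates pack
more beats — hence more marker transitions — into the fixed 7500 samples).
Per estimator × mask, values are averaged in 5-bpm heart-rate bins, and
polynomials of degree 2, 3 and 4 are fitted to the bin means by least
squares; `AIC = n ln(RSS/n) + 2k` (n = bins, k = coefficients) selects the
degree, ties going to the lower degree. An RSS floor at the numerical-noise
scale prevents machine-epsilon differences from promoting a higher degree
when all candidates fit exactly; AICc is available by flag. Bin-averaging
before fitting is one of two defensible readings of "fit to averaged
values"; it was chosen because it equalises the leverage of densely and
sparsely populated heart-rate regions.

The corrected value is `value − poly(mean HR)`; the per-subject mean of
corrected values is the diagnostic score. The polynomial is fitted on the
full pooled cohort — cases included — which leaks group information into the
correction. This mirrors how such a pilot correction is derived in practice
and is a **known bias**; leave-one-subject-out correction is deliberately
out of scope.

## Evaluation

Welch's unequal-variance t-test (two-sided, Satterthwaite df) compares
per-subject scores; the AUC is rank-based and oriented as
`P(control > case) + ½·P(tie)`, so AUC > 0.5 means cases score lower (the
clinically observed direction). Band sweeps re-extract strips per
(hr_lo, hr_hi) cell and summarise the 63 masks by median/min p and
median/max AUC; cells whose pipeline leaves a class empty are reported
missing, never fabricated. No multiple-testing correction is applied across
masks — the sweep is exploratory and the min-p is a selection statistic, not
an inferential one. Ranking uses ascending p, then descending AUC, then
ascending mask code. Diagnostic metrics use Wald (normal-approximation)
95% CIs clipped to [0, 100]% — the only interval family consistent with the
worked example the test suite pins — and clinical utility indices
CUI+ = Se·PPV, CUI− = Sp·NPV as fractions.

## Restitution

QT is measured from Q onset to T end (the conventional QT definition), TQ
from T end to the next Q onset, so QT + TQ equals the Q-onset-to-Q-onset
interval exactly by construction. The last beat of a strip emits no record.
The k-NN classifier standardises (TQ, QT, RR) triplets by the training mean
and SD, votes among the k nearest Euclidean neighbours, and resolves vote
ties by shrinking k by 2 (finally the single nearest neighbour). Restitution
is demonstrated on synthetic data only; on the clinical question it is an
exploratory negative control, not a validated discriminator.

## Synthetic data: what it emulates and what it does not

Each beat is a sum of five Gaussian bumps (P, Q, R, S, T) on an RR grid
derived from a heart-rate trajectory (constant or piecewise-linear,
25–200 bpm) with multiplicative Gaussian RR jitter (clipped at 3 SD).
Defaults approximate a resting equine base-apex lead with positive polarity:
R = 1.0 mV / 14 ms width, Q = −0.18 mV, S = −0.30 mV, P = 0.20 mV,
T = 0.35 mV / 50 ms width; QT follows the programmable linear restitution
`QT = 0.26 + 0.20·RR` seconds, and the T bump is placed so its 5% amplitude
point lands on that QT. Baseline wander is a 0.15 Hz sinusoid (0.10 mV
default) and measurement noise is white Gaussian (0.01 mV default). Native
simulation rate is 500 Hz so the 125 Hz down-sampling path is always
exercised; ground-truth fiducial indices are exact by construction.

Ectopic beats replace a sinus beat with an exactly premature one: the
interval into the ectopic is (1−p)·RR_nominal and the compensatory pause out
of it is (1+p)·RR_nominal, after which the sinus clock resets. Pinning both
intervals to the nominal RR guarantees that each deviates from any 60-s
window's mean RR by ≈ p, so with p ≥ 0.35 the 30% exclusion rule provably
removes every window containing an ectopic. The prematurity is capped so the
premature interval stays above 0.32 s (the detector's refractory plus
margin); on rhythms too fast for that, the beat is left sinus. Ectopic
morphology: absent P, 20–25% larger and 60% wider QRS, inverted T.

The case/control "complexity effect" is a single knob: the SD of
beat-to-beat jitter applied to P/Q/S/T centre offsets (R stays on the RR
grid), with proportional amplitude jitter. Controls default to 12 ms SD — a
visible but sub-sample-dominated variability at 125 Hz — and the strong-
effect preset subtracts 8 ms for cases (4 ms SD), i.e. cases are *less*
variable and score lower in corrected complexity, matching the clinical
direction. The knob is signed and continuous; an HR gate restricts the
effect to beats above a threshold for band-localisation experiments. These
magnitudes were fixed once as the definition of the simulated conditions.

What passing tests therefore show: the pipeline detects a known reduction of
beat-to-beat waveform variability at realistic SNR, heart rates and strip
counts, with correct null behaviour and correct band localisation. What they
do not show: that real ectopy-prone myocardium produces this particular
generative change, or how large the clinical effect is — the generator is a
stand-in, not a mechanistic model, and no claim about clinical sensitivity
or specificity transfers from it.

## Problem sizes used by the test suite and acceptance script

Effect-recovery cohorts use 20+20 subjects with 200-s recordings (~3 strips
per subject) analysed with the LZ'76 estimator over all 63 masks; the
band-localisation cohort uses 12+12 subjects with 320-s two-level recordings
(half below, half above 60 bpm); the segmentation guarantee is checked on
1000 (tests) / 200 (script) random 75-s recordings with ectopy at 0.5–4
beats/min and prematurity 0.35–0.5; estimator/oracle equivalence runs on
10⁴ random strings of up to 64 symbols. These sizes were chosen so the whole
suite completes in a few minutes while keeping every statistical margin
wide (the key contrasts pass by several orders of magnitude).

## Known limitations

* The heart-rate correction is fitted on the pooled cohort (leakage; see
  above) and only spans the heart rates present in the data — extrapolation
  beyond the fitted range is logged, not refused.
* Annotation constants are tuned for smooth, single-lead, positive-or-
  negative monophasic complexes; heavily notched QRS or biphasic T waves
  will fail beat-wise (and be dropped) rather than be mis-measured.
* The TC/FD schemes assume the 7500-sample strip length; complexity values
  at other durations are normalised but not calibrated against each other.
* Respiratory sinus arrhythmia is modelled as white RR jitter, not as a
  periodic modulation; baseline wander is a single sinusoid, not broadband
  motion artefact.
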