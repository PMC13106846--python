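"""Disorderliness estimators for coarse-grained ECG strings and raw voltage series.

Six estimators are provided.  Three parse a symbol string into the sub-strings
needed to rebuild it (Lempel--Ziv '76 exhaustive-history components, Lempel--Ziv
'78 incremental-dictionary phrases, Titchener T-complexity), one measures the
first-order symbol distribution (Shannon entropy), and two operate on the raw
voltage series without coarse-graining (approximate and sample entropy).

Parsing conventions, which matter at small ``n``:

* LZ'76 -- a component is the shortest prefix of the unparsed remainder that is
  not reproducible from the extended past (self-referential copies allowed); a
  trailing fully-reproducible remainder counts as one component.
* LZ'78 -- a phrase is the shortest prefix of the remainder not yet in the
  dictionary; a trailing partial phrase counts as one.
* T-complexity -- greedy maximal T-decomposition
  ``x = p_m^{k_m} ... p_1^{k_1} a`` (``a`` the final symbol, each ``p_i`` a
  level-(i-1) T-prefix); the complexity is ``sum(log2(k_i + 1))`` in taugs.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.optimize import brentq
from scipy.special import expi

from ._exceptions import InsufficientDataError, ParameterError, UndefinedMetricError

__all__ = [
    "ESTIMATORS",
    "SYMBOLIC_ESTIMATORS",
    "SERIES_ESTIMATORS",
    "EntropyParams",
    "ComplexityValue",
    "lz76",
    "lz78",
    "t_decomposition",
    "t_complexity",
    "t_entropy_rate",
    "shannon_entropy",
    "approx_entropy",
    "sample_entropy",
    "normalize",
    "symbolic_complexity",
]

SYMBOLIC_ESTIMATORS = ("LZ76", "LZ78", "Titchener", "Shannon")
SERIES_ESTIMATORS = ("ApEn", "SampEn")
ESTIMATORS = SYMBOLIC_ESTIMATORS + SERIES_ESTIMATORS


@dataclass(frozen=True)
class EntropyParams:
    """Embedding parameters for approximate / sample entropy.

    ``m`` is the template length in samples; ``r`` the matching tolerance as a
    fraction of the series standard deviation.  The defaults (m=2, r=0.2) are
    the values conventionally used for physiological series.
    """

    m: int = 2
    r: float = 0.2

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ParameterError(f"embedding length m must be >= 1, got {self.m}")
        if self.r <= 0:
            raise ParameterError(f"tolerance r must be > 0, got {self.r}")


@dataclass(frozen=True)
class ComplexityValue:
    """A raw estimator output together with its length-normalised value."""

    estimator: str
    raw: float
    normalised: float
    n: int


def _text(s) -> str:
    """Accept either a plain string or an object with a ``text`` attribute."""
    return s.text if hasattr(s, "text") else s


def lz76(s) -> int:
    """Number of components in the Lempel--Ziv '76 exhaustive history of ``s``.

    A component extends the longest prefix of the remainder that can be copied
    from anywhere in the already-seen string (the copy window extends into the
    component itself) by one fresh symbol.
    """
    t = _text(s)
    n = len(t)
    if n == 0:
        raise ParameterError("LZ76 complexity of the empty string is undefined")
    c = 0
    p = 0
    while p < n:
        # Binary search for the longest reproducible extension at p.
        # Reproducibility is monotone in length, so bisection is valid.
        lo, hi = 0, n - p
        while lo < hi:
            mid = (lo + hi + 1) // 2
            if t.find(t[p : p + mid], 0, p + mid - 1) != -1:
                lo = mid
            else:
                hi = mid - 1
        c += 1
        if lo == n - p:  # trailing reproducible chunk: one (incomplete) component
            p = n
        else:
            p += lo + 1
    return c


def lz78(s) -> int:
    """Number of phrases in the Lempel--Ziv '78 incremental-dictionary parse."""
    t = _text(s)
    if not t:
        raise ParameterError("LZ78 complexity of the empty string is undefined")
    seen: set[str] = set()
    c = 0
    cur = ""
    for ch in t:
        cur += ch
        if cur not in seen:
            seen.add(cur)
            c += 1
            cur = ""
    if cur:
        c += 1
    return c


def t_decomposition(s) -> list[tuple[str, int]]:
    """Greedy maximal T-decomposition of ``s``, innermost prefix first.

    Returns ``[(p_1, k_1), ..., (p_m, k_m)]`` such that
    ``s == p_m * k_m + ... + p_1 * k_1 + s[-1]`` and each ``p_i`` has the
    T-prefix form ``p_{i-1}^{j_{i-1}} ... p_1^{j_1} b`` with ``j_l <= k_l``.
    """
    t = _text(s)
    if len(t) < 2:
        raise ParameterError("T-decomposition needs at least two symbols")
    rest = t[:-1]
    steps: list[tuple[str, int]] = []
    pos = len(rest)
    while pos > 0:
        # Read the next T-prefix off the end: a literal symbol preceded by up
        # to k_l copies of each earlier prefix, innermost level first.
        start = pos - 1
        for p_l, k_l in steps:
            length = len(p_l)
            j = 0
            while j < k_l and start >= length and rest.startswith(p_l, start - length):
                start -= length
                j += 1
        p = rest[start:pos]
        length = len(p)
        k = 1
        while start >= length and rest.startswith(p, start - length):
            start -= length
            k += 1
        steps.append((p, k))
        pos = start
    return steps


def t_complexity(s) -> float:
    """Titchener T-complexity of ``s`` in taugs: sum of log2(k_i + 1)."""
    return float(sum(math.log2(k + 1) for _, k in t_decomposition(s)))


def _log_integral(y: float) -> float:
    # li(y) = Ei(ln y) for y > 1
    return float(expi(math.log(y)))


def t_entropy_rate(s) -> float:
    """Linearised T-entropy rate in bits per symbol.

    Inverts the logarithmic integral: with ``T`` the T-complexity in taugs,
    the T-information is ``li^{-1}(T ln 2)`` nats; dividing by ``n ln 2``
    gives a per-symbol rate in bits.  Available as the alternative reading of
    a "per-sample" Titchener value (the default is T-complexity / n).
    """
    t = _text(s)
    n = len(t)
    target = t_complexity(t) * math.log(2.0)
    # li is increasing on (1, inf) with li(e) ~ 1.895; bracket the root.
    hi = 2.0
    while _log_integral(hi) < target:
        hi *= 2.0
    y = brentq(lambda v: _log_integral(v) - target, 1.0 + 1e-12, hi)
    return math.log(y) / (n * math.log(2.0))


def shannon_entropy(s) -> float:
    """First-order Shannon entropy in bits per symbol."""
    t = _text(s)
    if not t:
        raise ParameterError("Shannon entropy of the empty string is undefined")
    n = len(t)
    counts = Counter(t)
    return float(-sum((c / n) * math.log2(c / n) for c in counts.values()))


def _chebyshev_match_counts(templates: np.ndarray, r: float, block: int = 256) -> np.ndarray:
    """For each template row, the number of rows within Chebyshev distance r
    (self-matches included).  Block-wise to bound memory at n ~ 10^4."""
    n, m = templates.shape
    counts = np.empty(n, dtype=np.int64)
    for i0 in range(0, n, block):
        a = templates[i0 : i0 + block]
        d = np.abs(a[:, 0][:, None] - templates[:, 0][None, :])
        for j in range(1, m):
            np.maximum(d, np.abs(a[:, j][:, None] - templates[:, j][None, :]), out=d)
        counts[i0 : i0 + block] = (d <= r).sum(axis=1)
    return counts


def _tolerance(x: np.ndarray, params: EntropyParams) -> float:
    sd = float(np.std(x))
    r = params.r * sd
    if r <= 0:
        # Zero-variance series: relative tolerance degenerates; apply an
        # absolute floor so constant series return 0 rather than NaN.
        r = 1e-12
    return r


def approx_entropy(x, params: EntropyParams = EntropyParams()) -> float:
    """Pincus approximate entropy ApEn(m, r*sd, n) of a real-valued series."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n <= params.m + 1:
        raise InsufficientDataError(f"ApEn needs more than m+1={params.m + 1} samples, got {n}")
    r = _tolerance(x, params)

    def phi(m: int) -> float:
        templates = sliding_window_view(x, m)
        counts = _chebyshev_match_counts(np.ascontiguousarray(templates), r)
        return float(np.mean(np.log(counts / templates.shape[0])))

    return phi(params.m) - phi(params.m + 1)


def sample_entropy(x, params: EntropyParams = EntropyParams()) -> float:
    """Richman--Moorman sample entropy: -ln(A/B) with self-matches excluded."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n <= params.m + 1:
        raise InsufficientDataError(f"SampEn needs more than m+1={params.m + 1} samples, got {n}")
    r = _tolerance(x, params)
    m = params.m
    n_templates = n - m  # both lengths use the first n-m starting points

    def pair_count(length: int) -> int:
        templates = np.ascontiguousarray(sliding_window_view(x, length)[:n_templates])
        counts = _chebyshev_match_counts(templates, r)
        return int((counts.sum() - n_templates) // 2)  # remove self, halve symmetric pairs

    b = pair_count(m)
    if b == 0:
        raise UndefinedMetricError("SampEn undefined: no template matches at length m")
    a = pair_count(m + 1)
    if a == 0:
        raise UndefinedMetricError("SampEn undefined: no template matches at length m+1")
    return float(-math.log(a / b))


def normalize(estimator: str, raw: float, n: int) -> float:
    """Length normalisation mapping a raw estimator output to bit/sample scale.

    LZ'76 counts are divided by the asymptotic random-string rate n/log2(n);
    LZ'78 counts and T-complexity by the sequence length; Shannon, approximate
    and sample entropy pass through unchanged.
    """
    if n < 2:
        raise ParameterError(f"normalisation needs n >= 2, got {n}")
    if estimator == "LZ76":
        return raw * math.log2(n) / n
    if estimator == "LZ78":
        return raw / n
    if estimator == "Titchener":
        return raw / n
    if estimator in ("Shannon", "ApEn", "SampEn"):
        return raw
    raise ParameterError(f"unknown estimator {estimator!r}")


def symbolic_complexity(s, estimator: str) -> ComplexityValue:
    """Compute one symbolic estimator on a string and bundle raw + normalised."""
    t = _text(s)
    if estimator == "LZ76":
        raw: float = lz76(t)
    elif estimator == "LZ78":
        raw = lz78(t)
    elif estimator == "Titchener":
        raw = t_complexity(t)
    elif estimator == "Shannon":
        raw = shannon_entropy(t)
    else:
        raise ParameterError(f"not a symbolic estimator: {estimator!r}")
    return ComplexityValue(estimator, float(raw), normalize(estimator, raw, len(t)), len(t))
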