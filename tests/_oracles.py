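"""Independent brute-force reference implementations used only by the tests.

Each oracle is deliberately naive (explicit loops, quadratic or worse) and
shares no code with the package, so agreement between the two routes is
evidence of correctness rather than repetition.
"""

from __future__ import annotations

import math

import numpy as np


def lz76_oracle(s: str) -> int:
    """Exhaustive-history component count straight from the definition.

    At position p the component is the shortest prefix of the remainder that
    cannot be copied from any earlier starting point (copies may run into the
    component itself); a trailing fully-reproducible remainder is one
    component.
    """
    n = len(s)
    c = 0
    p = 0
    while p < n:
        length = 1
        while p + length <= n:
            sub = s[p : p + length]
            reproducible = False
            for start in range(0, p):
                if s[start : start + length] == sub and start + length <= p + length - 1:
                    reproducible = True
                    break
            if not reproducible:
                break
            length += 1
        c += 1
        if p + length > n:  # ran off the end while still reproducible
            break
        p += length
    return c


def lz78_oracle(s: str) -> int:
    """Incremental-dictionary phrase count with a plain list as dictionary."""
    dictionary: list[str] = []
    c = 0
    i = 0
    n = len(s)
    while i < n:
        j = i + 1
        while j <= n and s[i:j] in dictionary:
            j += 1
        c += 1
        if j > n:  # trailing phrase already in the dictionary
            break
        dictionary.append(s[i:j])
        i = j
    return c


def check_t_decomposition(s: str, steps: list[tuple[str, int]]) -> bool:
    """Validate a T-decomposition ``[(p_1, k_1), ..., (p_m, k_m)]`` of ``s``.

    Checks, from the definition of greedy maximal T-decomposition:
    (a) reconstruction: ``s == p_m^{k_m} ... p_1^{k_1} + s[-1]``;
    (b) well-formedness: each p_i is a level-(i-1) T-prefix, i.e. it strips
        greedily from the left as ``p_{i-1}^{j} ... p_1^{j} b`` with every
        exponent bounded by the earlier k's and a single symbol left;
    (c) maximality: the text preceding each ``p_i^{k_i}`` block does not end
        with a further copy of ``p_i``.
    """
    recon = "".join(p * k for p, k in reversed(steps)) + s[-1]
    if recon != s:
        return False

    def well_formed(prefix: str, level: int) -> bool:
        # prefix must be p_level^{j} ... p_1^{j} b with j's bounded; search
        # all exponent assignments (backtracking; strings here are short)
        if level < 0:
            return len(prefix) == 1
        pl, kl = steps[level]
        for j in range(kl + 1):
            if not prefix.startswith(pl * j):
                break
            if well_formed(prefix[len(pl) * j :], level - 1):
                return True
        return False

    for i, (p, _k) in enumerate(steps):
        if not well_formed(p, i - 1):
            return False
    end = 0
    for p, k in steps[::-1]:
        end += len(p) * k
        block_start = end - len(p) * k
        if block_start >= len(p) and s[block_start - len(p) : block_start] == p:
            return False
    return True


def t_complexity_value(steps: list[tuple[str, int]]) -> float:
    return sum(math.log2(k + 1) for _, k in steps)


def apen_oracle(x, m: int, r: float) -> float:
    """Double-loop ApEn with self-matches, straight from the definition."""
    x = np.asarray(x, dtype=float)
    n = len(x)

    def phi(mm: int) -> float:
        count = n - mm + 1
        logs = []
        for i in range(count):
            matches = 0
            for j in range(count):
                if max(abs(x[i + k] - x[j + k]) for k in range(mm)) <= r:
                    matches += 1
            logs.append(math.log(matches / count))
        return sum(logs) / count

    return phi(m) - phi(m + 1)


def sampen_oracle(x, m: int, r: float) -> float:
    """Double-loop SampEn (first n-m templates, self-matches excluded)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    count = n - m

    def pairs(mm: int) -> int:
        total = 0
        for i in range(count):
            for j in range(i + 1, count):
                if max(abs(x[i + k] - x[j + k]) for k in range(mm)) <= r:
                    total += 1
        return total

    b = pairs(m)
    a = pairs(m + 1)
    return -math.log(a / b)


def auc_oracle(scores, labels) -> float:
    """Pairwise P(control > case) + half ties, by explicit enumeration."""
    scores = list(scores)
    labels = list(labels)
    cases = [s for s, l in zip(scores, labels) if l == "case"]
    controls = [s for s, l in zip(scores, labels) if l == "control"]
    total = 0.0
    for c in controls:
        for a in cases:
            if c > a:
                total += 1.0
            elif c == a:
                total += 0.5
    return total / (len(cases) * len(controls))


def welch_oracle(a, b) -> tuple[float, float]:
    """Closed-form Welch t and Satterthwaite df (p left to scipy in tests)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1) / na, b.var(ddof=1) / nb
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (na - 1) + vb**2 / (nb - 1))
    return t, df


def template_fiducials_oracle(qrs: np.ndarray, t_bump: np.ndarray) -> dict[str, int]:
    """Plain-loop scan for the six fiducials of an isolated beat, given the
    QRS-only and T-only waveforms sampled on the same grid."""
    pp = max(qrs) - min(qrs)
    thr = 0.05 * pp
    q_onset = None
    for i, v in enumerate(qrs):
        if abs(v) > thr:
            q_onset = i
            break
    last_exceed = None
    for i, v in enumerate(qrs):
        if abs(v) > thr:
            last_exceed = i
    qrs_end = last_exceed + 1
    r_peak, best = 0, 0.0
    for i, v in enumerate(qrs):
        if abs(v) > best:
            r_peak, best = i, abs(v)
    q_peak, low = 0, float("inf")
    for i in range(r_peak):
        if qrs[i] < low:
            q_peak, low = i, qrs[i]
    t_peak, best = 0, 0.0
    for i, v in enumerate(t_bump):
        if abs(v) > best:
            t_peak, best = i, abs(v)
    t_end = None
    for i in range(t_peak, len(t_bump)):
        if abs(t_bump[i]) <= 0.05 * best:
            t_end = i
            break
    return {"q_onset": q_onset, "q_peak": q_peak, "r_peak": r_peak,
            "qrs_end": qrs_end, "t_peak": t_peak, "t_end": t_end}
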