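"""Independent reference implementations used as test oracles.

Each function here deliberately takes a different algorithmic route from
the package implementation it checks: the Lempel-Ziv oracle is the
classic pointer-scanning counter, the permutation-entropy oracle
enumerates ordinal patterns window by window, the PLI oracle is an
explicit loop with explicit angle wrapping, and the rank-test oracles
enumerate the full permutation / sign-flip null distributions.
"""

from __future__ import annotations

import math
from collections import Counter
from itertools import combinations, product

import numpy as np


def lzc_pointer(seq) -> int:
    """Lempel-Ziv production complexity via the classic pointer-scanning
    counting loop (match-length bookkeeping, no substring search)."""
    s = list(seq)
    n = len(s)
    if n == 0:
        raise ValueError("empty sequence")
    if n == 1:
        return 1
    c, l, i, k, k_max = 1, 1, 0, 1, 1
    while True:
        if s[i + k - 1] == s[l + k - 1]:
            k += 1
            if l + k > n:
                c += 1
                break
        else:
            k_max = max(k_max, k)
            i += 1
            if i == l:
                c += 1
                l += k_max
                if l + 1 > n:
                    break
                i, k, k_max = 0, 1, 1
            else:
                k = 1
    return c


def pe_direct(x, d: int, tau: int, normalized: bool = True) -> float:
    """Permutation entropy by explicit window-by-window pattern listing.

    The ordinal pattern of a window is the index ordering under a sort by
    (value, position) — ties broken by order of occurrence.
    """
    x = list(map(float, x))
    n_windows = len(x) - (d - 1) * tau
    if n_windows < 1:
        raise ValueError("series too short")
    patterns = []
    for start in range(n_windows):
        w = [x[start + m * tau] for m in range(d)]
        patterns.append(tuple(sorted(range(d), key=lambda i: (w[i], i))))
    counts = Counter(patterns)
    total = sum(counts.values())
    h = -sum((c / total) * math.log2(c / total) for c in counts.values())
    if normalized:
        h /= math.log2(math.factorial(d))
    return h


def pli_loop(phase_x, phase_y) -> float:
    """PLI by explicit looping and explicit wrapping into (-pi, pi]."""
    total = 0.0
    count = 0
    for px, py in zip(phase_x, phase_y, strict=True):
        diff = float(px) - float(py)
        while diff <= -math.pi:
            diff += 2.0 * math.pi
        while diff > math.pi:
            diff -= 2.0 * math.pi
        total += (diff > 0) - (diff < 0)
        count += 1
    return abs(total / count)


def _avg_ranks(values) -> list[float]:
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and \
                values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def wilcoxon_exact(x, y) -> float:
    """Two-sided signed-rank p-value by exhaustive sign-flip enumeration
    (zero differences dropped; average ranks for tied magnitudes)."""
    d = [float(a) - float(b) for a, b in zip(x, y, strict=True)]
    d = [v for v in d if v != 0]
    n = len(d)
    ranks = _avg_ranks([abs(v) for v in d])
    w_obs = sum(r for r, v in zip(ranks, d) if v > 0)
    dist = [sum(r for r, s in zip(ranks, signs) if s)
            for signs in product((False, True), repeat=n)]
    # two-sided: mass at least as far from the null mean as observed
    mu = sum(ranks) / 2.0
    crit = abs(w_obs - mu)
    return sum(abs(w - mu) >= crit - 1e-12 for w in dist) / len(dist)


def mannwhitney_exact(x, y) -> float:
    """Two-sided Mann-Whitney p-value by enumerating all group
    assignments of the pooled sample (ties contribute 1/2 to U)."""
    pooled = [float(v) for v in x] + [float(v) for v in y]
    nx = len(x)

    def u_of(idx_x):
        xs = [pooled[i] for i in idx_x]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx_x]
        return sum((a > b) + 0.5 * (a == b) for a in xs for b in ys)

    u_obs = u_of(tuple(range(nx)))
    dist = [u_of(c) for c in combinations(range(len(pooled)), nx)]
    mu = nx * (len(pooled) - nx) / 2.0
    crit = abs(u_obs - mu)
    return sum(abs(u - mu) >= crit - 1e-12 for u in dist) / len(dist)


def fit_sine_amplitude(x: np.ndarray, fs: float, freq: float) -> float:
    """Least-squares amplitude of a sinusoid at a known frequency."""
    t = np.arange(x.size) / fs
    design = np.column_stack([np.sin(2 * np.pi * freq * t),
                              np.cos(2 * np.pi * freq * t)])
    coef, *_ = np.linalg.lstsq(design, x, rcond=None)
    return float(np.hypot(*coef))
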