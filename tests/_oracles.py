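"""Independent brute-force oracles used to check the package's fast paths.

These deliberately avoid the library code paths they verify: the motif
oracle enumerates windows and string-matches; the agglomeration oracle
re-derives every inter-cluster distance from the Lance-Williams recurrence
at each step; the binomial oracle sums pmf terms directly in extended
precision.
"""

from __future__ import annotations

import math

import numpy as np

IUPAC = {
    "A": {"A"},
    "C": {"C"},
    "G": {"G"},
    "T": {"T"},
    "R": {"A", "G"},
    "Y": {"C", "T"},
    "S": {"C", "G"},
    "W": {"A", "T"},
    "K": {"G", "T"},
    "M": {"A", "C"},
    "N": {"A", "C", "G", "T"},
}

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def window_matches(window: str, consensus: str) -> bool:
    return len(window) == len(consensus) and all(
        base in IUPAC[letter] for base, letter in zip(window, consensus)
    )


def scan_oracle(seq: str, consensus: str, both_strands: bool = True):
    """Enumerate every window; match forward and (optionally) its revcomp."""
    m = len(consensus)
    hits = []
    for i in range(len(seq) - m + 1):
        window = seq[i : i + m]
        if window_matches(window, consensus):
            hits.append((i, i + m, "+", window))
        if both_strands and window_matches(revcomp(window), consensus):
            hits.append((i, i + m, "-", window))
    hits.sort(key=lambda h: (h[0], 0 if h[2] == "+" else 1))
    return hits


def ward_oracle(X: np.ndarray, method: str):
    """Naive O(n^3) Lance-Williams Ward agglomeration.

    method "ward_d": update applied to unsquared Euclidean distances,
    heights as-is. method "ward_d2": update applied to squared distances,
    heights square-rooted. Returns [(set_a, set_b, height)] per merge with
    set_a holding the smaller minimum element.
    """
    n = X.shape[0]
    dist = {}
    for i in range(n):
        for j in range(i + 1, n):
            d = float(np.linalg.norm(X[i] - X[j]))
            dist[(i, j)] = d if method == "ward_d" else d * d
    clusters = {i: frozenset([i]) for i in range(n)}
    next_id = n
    merges = []
    while len(clusters) > 1:
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if a >= b:
                    continue
                d = dist[(a, b)]
                if best is None or d < best[0] or (d == best[0] and (a, b) < best[1:]):
                    best = (d, a, b)
        d_ab, a, b = best
        height = d_ab if method == "ward_d" else math.sqrt(d_ab)
        sa, sb = clusters[a], clusters[b]
        if min(sb) < min(sa):
            sa, sb = sb, sa
        merges.append((sa, sb, height))
        na, nb = len(clusters[a]), len(clusters[b])
        new = {}
        for v in clusters:
            if v in (a, b):
                continue
            nv = len(clusters[v])
            dav = dist[tuple(sorted((a, v)))]
            dbv = dist[tuple(sorted((b, v)))]
            new[v] = ((na + nv) * dav + (nb + nv) * dbv - nv * d_ab) / (na + nb + nv)
        merged = clusters[a] | clusters[b]
        del clusters[a], clusters[b]
        clusters[next_id] = merged
        for v, d in new.items():
            dist[tuple(sorted((v, next_id)))] = d
        next_id += 1
    return merges


def binomial_tail_oracle(k: int, n: int, p0: float) -> float:
    """P(X >= k) by direct pmf summation in extended precision.

    Terms are generated by the pmf recurrence outward from the mode (where
    the term is large enough to evaluate without underflow), so deep tails
    stay accurate down to longdouble range.
    """
    if k <= 0:
        return 1.0
    if k > n:
        return 0.0
    p = np.longdouble(p0)
    q = np.longdouble(1.0) - p
    mode = min(max(int(n * p0), 0), n)
    log_t = (
        math.lgamma(n + 1)
        - math.lgamma(mode + 1)
        - math.lgamma(n - mode + 1)
        + mode * math.log(p0)
        + (n - mode) * math.log1p(-p0)
    )
    t_mode = np.exp(np.longdouble(log_t))
    terms = {mode: t_mode}
    t = t_mode
    for j in range(mode, n):  # upward
        t = t * (n - j) / (j + 1) * p / q
        terms[j + 1] = t
    t = t_mode
    for j in range(mode, 0, -1):  # downward
        t = t * j / (n - j + 1) * q / p
        terms[j - 1] = t
    total = sum(terms[j] for j in sorted(terms) if j >= k)
    return float(min(total, np.longdouble(1.0)))


def separation_oracle(points: np.ndarray, labels) -> float:
    """Direct pairwise enumeration of between minus within mean distance."""
    labels = list(labels)
    n = len(labels)
    within, between = [], []
    for i in range(n):
        for j in range(i + 1, n):
            d = float(np.linalg.norm(np.atleast_1d(points[i]) - np.atleast_1d(points[j])))
            (within if labels[i] == labels[j] else between).append(d)
    return sum(between) / len(between) - sum(within) / len(within)
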