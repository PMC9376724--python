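"""Independent oracles used by the tests.

These deliberately avoid the package's estimation path: exact MI by
enumeration of discrete joint distributions, a histogram (binned) MI
estimator for continuous data, a brute-force best-subset search, and a
direct DFT periodogram.  They are slow and simple on purpose.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def exact_discrete_mi(x, y) -> float:
    """Exact plug-in MI (bits) between two discrete sample columns.

    ``x`` and ``y`` may be 1-D or 2-D (rows = samples); multi-column inputs
    are treated as joint symbols.  Exact for the empirical distribution.
    """
    x = np.atleast_2d(np.asarray(x))
    y = np.atleast_2d(np.asarray(y))
    if x.shape[0] == 1:
        x = x.T
    if y.shape[0] == 1:
        y = y.T
    xs = [tuple(r) for r in x]
    ys = [tuple(r) for r in y]
    n = len(xs)
    from collections import Counter

    pxy = Counter(zip(xs, ys))
    px = Counter(xs)
    py = Counter(ys)
    mi = 0.0
    for (a, b), c in pxy.items():
        p = c / n
        mi += p * np.log2(p * n * n / (px[a] * py[b]))
    return float(mi)


def binned_mi(x, y, bins: int = 8) -> float:
    """Histogram MI estimate (bits) between two continuous 1-D variables."""
    x = np.ravel(np.asarray(x, dtype=float))
    y = np.ravel(np.asarray(y, dtype=float))
    joint, _, _ = np.histogram2d(x, y, bins=bins)
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log2(p[nz] / (px @ py)[nz])))


def brute_force_best_subsets(columns: np.ndarray, target: np.ndarray):
    """Exact best subset per size by exhaustive enumeration of discrete MI.

    Returns ``{size: (best_mi_bits, best_subset_indices)}``.  Feasible only
    for a handful of columns.
    """
    n = columns.shape[1]
    out = {}
    for k in range(1, n + 1):
        best = (-np.inf, None)
        for subset in combinations(range(n), k):
            mi = exact_discrete_mi(columns[:, list(subset)], target)
            if mi > best[0]:
                best = (mi, subset)
        out[k] = best
    return out


def dft_periodogram(traces: np.ndarray):
    """Direct-DFT one-sided ensemble periodogram over positive frequencies.

    One-sided convention: every bin except DC and (for even length) Nyquist
    carries the power of its negative-frequency twin.  DC is dropped and the
    result normalized to sum to one.
    """
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    n = traces.shape[1]
    spec = np.abs(np.fft.rfft(traces, axis=1)) ** 2
    spec[:, 1:] *= 2.0
    if n % 2 == 0:
        spec[:, -1] /= 2.0
    power = spec.mean(axis=0)[1:]  # drop DC
    return power / power.sum()


def shannon_entropy_bits(p) -> float:
    p = np.asarray(p, dtype=float)
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())
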