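"""Change-point segmentation and autocorrelation-time estimation.

PELT (pruned exact linear time) with an L2 segment cost, the standard
mean-shift model for decorrelating scalar trajectory observables: the
series is cut where its local mean shifts, and frames are then thinned
within each (locally stationary) segment at the integrated
autocorrelation time.
"""

from __future__ import annotations

import numpy as np

__all__ = ["pelt_l2", "default_penalty", "integrated_autocorr_time"]


def default_penalty(x: np.ndarray) -> float:
    """2 log(n) Var(x) — a BIC-like penalty on the series' own scale."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2:
        return 1.0
    return 2.0 * np.log(n) * float(np.var(x))


def pelt_l2(x: np.ndarray, penalty: float | None = None,
            min_size: int = 1) -> list[int]:
    """Exact penalized segmentation of ``x`` under the L2 cost.

    Returns the sorted list of segment end indices (exclusive), always
    ending with ``len(x)``. The cost of segment [i, j) is
    ``sum((x[i:j] - mean)^2)``; each additional change point pays
    ``penalty``.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n == 0:
        return []
    if penalty is None:
        penalty = default_penalty(x)
    s1 = np.concatenate([[0.0], np.cumsum(x)])
    s2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def cost(i: int, j: int) -> float:
        return s2[j] - s2[i] - (s1[j] - s1[i]) ** 2 / (j - i)

    F = np.full(n + 1, np.inf)
    F[0] = -penalty
    prev = np.zeros(n + 1, dtype=int)
    cand = [0]
    for t in range(min_size, n + 1):
        vals = [F[s] + cost(s, t) + penalty for s in cand if t - s >= min_size]
        ok = [s for s in cand if t - s >= min_size]
        if not vals:
            continue
        k = int(np.argmin(vals))
        F[t] = vals[k]
        prev[t] = ok[k]
        # PELT pruning: s can never be optimal again if even without the
        # penalty it already exceeds the best score at t
        cand = [s for s, v in zip(ok, vals) if v - penalty <= F[t]]
        cand.append(t)
    ends = []
    t = n
    while t > 0:
        ends.append(t)
        t = prev[t]
    return sorted(ends)


def integrated_autocorr_time(x: np.ndarray, significance: float = 2.58) -> float:
    """Integrated autocorrelation time via truncated positive-sequence sum.

    tau = 1 + 2 * sum_k rho_k, summed while rho_k stays above the
    white-noise significance floor ``significance / sqrt(n)`` (and above
    zero). A zero-variance series counts as a single effective sample:
    tau = len(x).
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2:
        return 1.0
    xc = x - x.mean()
    c0 = float(np.dot(xc, xc) / n)
    if c0 < 1e-30:
        return float(n)
    floor = max(0.0, significance / np.sqrt(n))
    tau = 1.0
    for k in range(1, n):
        rho = float(np.dot(xc[:-k], xc[k:]) / n) / c0
        if rho <= floor:
            break
        tau += 2.0 * rho
    return tau
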