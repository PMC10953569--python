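"""Shared fixtures and independent oracle implementations.

The oracles here are deliberately written as plain, slow loops so they stay
independent of the vectorized library code they check.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def oracle_detect(trace, threshold, dead_samples, pre, post, polarity="negative"):
    """Brute-force threshold-crossing + extremum scan, one sample at a time."""
    n = len(trace)
    extrema = []
    i = 0
    while i < n:
        if polarity == "negative":
            crossed = trace[i] < -threshold
        elif polarity == "positive":
            crossed = trace[i] > threshold
        else:
            crossed = abs(trace[i]) > threshold
        if crossed:
            j = i
            best = i
            while j < n:
                if polarity == "negative":
                    if trace[j] >= -threshold:
                        break
                    if trace[j] < trace[best]:
                        best = j
                elif polarity == "positive":
                    if trace[j] <= threshold:
                        break
                    if trace[j] > trace[best]:
                        best = j
                else:
                    if abs(trace[j]) <= threshold:
                        break
                    if abs(trace[j]) > abs(trace[best]):
                        best = j
                j += 1
            extrema.append(best)
            i = j
        else:
            i += 1
    kept = []
    for idx in extrema:
        if not kept or idx - kept[-1] >= dead_samples:
            kept.append(idx)
    return [idx for idx in kept if idx >= pre and idx + post < n]


def oracle_bursts(times, max_isi, min_spikes):
    """Run scan over consecutive inter-spike intervals."""
    out = []
    run = [times[0]] if len(times) else []
    for prev, cur in zip(times, times[1:]):
        if cur - prev <= max_isi:
            run.append(cur)
        else:
            if len(run) >= min_spikes:
                out.append((run[0], run[-1], len(run)))
            run = [cur]
    if len(run) >= min_spikes:
        out.append((run[0], run[-1], len(run)))
    return out


def oracle_correlation(X):
    """Two-pass covariance correlation, elementwise loops."""
    X = np.asarray(X, dtype=float)
    n, m = X.shape
    means = [sum(row) / m for row in X]
    out = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(n):
            ci = [x - means[i] for x in X[i]]
            cj = [x - means[j] for x in X[j]]
            num = sum(a * b for a, b in zip(ci, cj))
            di = sum(a * a for a in ci) ** 0.5
            dj = sum(b * b for b in cj) ** 0.5
            if di > 0 and dj > 0:
                out[i, j] = num / (di * dj)
    return out


def oracle_quantile(values, p):
    """Linear interpolation between order statistics."""
    v = sorted(values)
    h = (len(v) - 1) * p
    lo = int(np.floor(h))
    hi = min(lo + 1, len(v) - 1)
    return v[lo] + (h - lo) * (v[hi] - v[lo])


def oracle_circle_residual(points, cx, cy, r):
    """Max distance of points from a fitted circle."""
    return max(abs(np.hypot(x - cx, y - cy) - r) for x, y in points)
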