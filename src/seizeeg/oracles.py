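"""Naive reference implementations of the entropy statistics.

Plain double loops over template pairs, kept deliberately independent of
the vectorised fast paths in :mod:`seizeeg.features` so they can serve as
the arbiter in tests.  O(N^2) time with scalar inner loops — use on short
sequences only.
"""

from __future__ import annotations

import math

import numpy as np

from .features import EntropyParams, SampEnUndefined


def _cheb(a, b) -> float:
    return max(abs(ai - bi) for ai, bi in zip(a, b))


def apen_naive(x, p: EntropyParams = EntropyParams()) -> float:
    x = [float(v) for v in np.asarray(x).ravel()]
    N, m = len(x), p.m
    r = p.r * float(np.std(x)) if p.relative else p.r

    def phi(m: int) -> float:
        templates = [x[i : i + m] for i in range(N - m + 1)]
        total = 0.0
        for ti in templates:
            count = sum(1 for tj in templates if _cheb(ti, tj) <= r)
            total += math.log(count / len(templates))
        return total / len(templates)

    return phi(m) - phi(m + 1)


def sampen_naive(x, p: EntropyParams = EntropyParams()) -> float:
    x = [float(v) for v in np.asarray(x).ravel()]
    N, m = len(x), p.m
    r = p.r * float(np.std(x)) if p.relative else p.r
    T = N - m  # templates at both dimensions

    def pairs(m: int) -> int:
        templates = [x[i : i + m] for i in range(T)]
        count = 0
        for i in range(T):
            for j in range(i + 1, T):
                if _cheb(templates[i], templates[j]) <= r:
                    count += 1
        return count

    B, A = pairs(m), pairs(m + 1)
    if A == 0 or B == 0:
        raise SampEnUndefined(f"A={A}, B={B}")
    return -math.log(A / B)


def fuzzyen_naive(x, p: EntropyParams = EntropyParams()) -> float:
    x = [float(v) for v in np.asarray(x).ravel()]
    N, m, n = len(x), p.m, p.n
    r = p.r * float(np.std(x)) if p.relative else p.r
    if r == 0 and max(x) == min(x):
        return 0.0
    T = N - m

    def phi(m: int) -> float:
        templates = []
        for i in range(T):
            t = x[i : i + m]
            mean = sum(t) / m
            templates.append([v - mean for v in t])
        total = 0.0
        for i in range(T):
            for j in range(T):
                if i != j:
                    total += math.exp(-((_cheb(templates[i], templates[j]) / r) ** n))
        return total / (T * (T - 1))

    return math.log(phi(m)) - math.log(phi(m + 1))
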