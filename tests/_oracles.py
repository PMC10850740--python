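"""Independent brute-force oracles used to pin expected values in tests.

These stay deliberately separate from the library code paths they check:
factorial-table hypergeometric enumeration for the exact test, direct
summation for the diversity/overlap statistics, and trapezoid integration of
the t density for paired-t p-values.
"""

from __future__ import annotations

import math

import numpy as np

_FACT: list[int] = [1]


def _factorial(n: int) -> int:
    while len(_FACT) <= n:
        _FACT.append(_FACT[-1] * len(_FACT))
    return _FACT[n]


def _choose(n: int, k: int) -> int:
    if n <= 500:  # factorial-table route for the enumeration sweeps
        return _factorial(n) // (_factorial(k) * _factorial(n - k))
    return math.comb(n, k)  # repertoire-scale margins: no factorial cache


def hypergeom_weights(n1: int, n2: int, K: int) -> list[int]:
    """Integer weights w(x) proportional to P(X=x) for all tables with
    margins (n1, n2) and K total successes; support max(0, K-n2)..min(K, n1)."""
    N = n1 + n2
    lo, hi = max(0, K - n2), min(K, n1)
    return [_choose(K, x) * _choose(N - K, n1 - x) for x in range(lo, hi + 1)]


def fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive enumeration with exact integer
    probability comparisons (ties decided in integer arithmetic)."""
    n1, n2, K = a + b, c + d, a + c
    lo = max(0, K - n2)
    weights = hypergeom_weights(n1, n2, K)
    w_obs = weights[a - lo]
    return sum(w for w in weights if w <= w_obs) / sum(weights)


def simpson_oracle(freqs) -> float:
    """Direct summation of squared frequencies."""
    total = sum(freqs)
    return sum((f / total) ** 2 for f in freqs)


def morisita_oracle(fa: dict, fb: dict) -> float:
    """Direct evaluation of 2*sum(x*y)/(sum x^2 + sum y^2) over the union."""
    union = set(fa) | set(fb)
    cross = sum(fa.get(k, 0.0) * fb.get(k, 0.0) for k in union)
    return 2.0 * cross / (sum(v * v for v in fa.values()) + sum(v * v for v in fb.values()))


def t_sf_oracle(t: float, df: int, grid: int = 400_001, span: float = 400.0) -> float:
    """P(T > t) for Student's t by trapezoid integration of the density."""
    x = np.linspace(t, t + span, grid)
    log_norm = (
        math.lgamma((df + 1) / 2) - math.lgamma(df / 2) - 0.5 * math.log(df * math.pi)
    )
    dens = np.exp(log_norm - ((df + 1) / 2) * np.log1p(x * x / df))
    return float(np.trapezoid(dens, x))
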