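"""Closed-form approximation of median isoform frequencies.

The median frequency of the k-th dominant isoform of a gene with M
isoforms is well approximated by

    mf(k, M) = exp(-(1 + k/M)^2) / (k * H_M),

where H_M is the generalized harmonic number

    H_M = sum_{m=1..M} (1/m) * exp(-(1 + m/M)^2).

The unnormalized term ``(1/k) exp(-(1 + k/M)^2)`` is the *frequency
index* of rank k; normalizing the indices over k = 1..M gives mf
exactly, so each column sums to one by construction.  The formula is an
empirical approximation to the Monte-Carlo median (no derivation from
the Weibull model exists — sums of Weibull variates have no closed-form
distribution); its agreement with simulation is checked in tests, not
assumed here.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from splicestat.frequency_stats import (
    DEFAULT_K_MAX,
    DEFAULT_M_MAX,
    FrequencyMatrix,
)


def frequency_index(k: int, M: int) -> float:
    """Unnormalized dominance index ``(1/k) * exp(-(1 + k/M)^2)``."""
    if M < 1:
        raise ValueError("isoform count M must be >= 1")
    if not (1 <= k <= M):
        raise ValueError(f"rank k={k} must satisfy 1 <= k <= M={M}")
    return float(np.exp(-((1.0 + k / M) ** 2)) / k)


@lru_cache(maxsize=None)
def harmonic_number(M: int) -> float:
    """Generalized harmonic number ``H_M`` — the finite sum above."""
    if M < 1:
        raise ValueError("isoform count M must be >= 1")
    m = np.arange(1, M + 1)
    return float(np.sum(np.exp(-((1.0 + m / M) ** 2)) / m))


def median_frequency_formula(k: int, M: int) -> float:
    """Approximate median frequency ``mf(k, M)``; columns sum to 1 exactly."""
    return frequency_index(k, M) / harmonic_number(M)


def formula_matrix(
    k_max: int = DEFAULT_K_MAX, M_max: int = DEFAULT_M_MAX
) -> FrequencyMatrix:
    """The formula's median-frequency matrix over the standard 9x30 mask."""
    if k_max > M_max:
        raise ValueError("k_max must not exceed M_max")
    out = np.full((k_max, M_max), np.nan)
    for M in range(1, M_max + 1):
        H = harmonic_number(M)
        for k in range(1, min(k_max, M) + 1):
            out[k - 1, M - 1] = frequency_index(k, M) / H
    return FrequencyMatrix(out)
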