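"""Monte-Carlo engine for the Weibull splicing model.

A gene with M isoforms is simulated by drawing M expression levels from
``W(a, 1)`` (the scale cancels in frequencies) and converting them to a
descending frequency vector.  Repeating this per M yields the simulated
median frequency matrix, the pooled frequency quantiles behind the
dominance thresholds, tail probabilities of ranked frequencies, and the
expected number of expressed isoforms at a frequency cutoff.

The shape parameter is estimated by grid search: the simulated median
matrix is built for each candidate ``a`` and compared with an observed
matrix by Euclidean distance; the argmin is the estimate.  For two
isoforms the dominant-frequency tail has the closed form
``P(f(1,2) >= t) = 2 / (1 + (t/(1-t))^a)``, used as an independent check.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from splicestat.frequency_stats import (
    DEFAULT_K_MAX,
    DEFAULT_M_MAX,
    FrequencyMatrix,
    matrix_distance,
    median_frequency_matrix,
)
from splicestat.weibull_model import WeibullParams, sample as weibull_sample

DEFAULT_GRID = np.round(np.arange(0.01, 1.00, 0.01), 2)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the frequency simulation.

    ``reps`` is the number of simulated genes per isoform count M; the
    default 10,000 suits median matrices, while quantile thresholds and
    tail probabilities should use >= 100,000 (see the dedicated
    defaults below).  The scale ``b`` has no effect on frequencies and is
    kept at 1.
    """

    a: float = 0.39
    b: float = 1.0
    reps: int = 10_000
    M_max: int = DEFAULT_M_MAX
    k_max: int = DEFAULT_K_MAX
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.a <= 1):
            raise ValueError("shape a must lie in (0, 1] for this regime")
        if self.b <= 0:
            raise ValueError("scale b must be positive")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")


def _sub_rng(config: SimulationConfig, M: int) -> np.random.Generator:
    # deterministic sub-stream per (seed, shape, M)
    return np.random.default_rng((config.seed, int(round(config.a * 100)), M))


def simulate_gene_frequencies(config: SimulationConfig, M: int) -> np.ndarray:
    """``(reps, M)`` array of descending frequency vectors under W(a, b).

    Rows whose draws all underflow to zero (possible at very small shapes)
    are dropped — a zero-expression gene has no frequencies.
    """
    rng = _sub_rng(config, M)
    x = weibull_sample(WeibullParams(config.a, config.b), (config.reps, M), rng=rng)
    x = np.sort(x, axis=1)[:, ::-1]
    totals = x.sum(axis=1)
    ok = totals > 0
    return x[ok] / totals[ok, None]


def simulate_frequency_groups(
    config: SimulationConfig, M_values: Sequence[int] | None = None
) -> dict[int, np.ndarray]:
    """Mapping M -> simulated frequency vectors for M = 1..M_max."""
    if M_values is None:
        M_values = range(1, config.M_max + 1)
    return {int(M): simulate_gene_frequencies(config, int(M)) for M in M_values}


def simulated_median_matrix(config: SimulationConfig) -> FrequencyMatrix:
    """The simulated median frequency matrix mf(k, M) under W(a, 1)."""
    groups = simulate_frequency_groups(config)
    return median_frequency_matrix(groups, k_max=config.k_max, M_max=config.M_max)


def estimate_shape(
    observed: FrequencyMatrix,
    grid: Sequence[float] | None = None,
    config: SimulationConfig | None = None,
) -> tuple[float, pd.DataFrame]:
    """Grid-search shape estimate against an observed median matrix.

    For each candidate shape the simulated median matrix is built (from a
    deterministic sub-seed per shape, so the profile is reproducible) and
    its Euclidean distance to ``observed`` recorded.  Returns the argmin
    and the full distance-vs-shape profile; ties break toward smaller a.
    """
    if config is None:
        config = SimulationConfig()
    if grid is None:
        grid = DEFAULT_GRID
    grid = np.sort(np.asarray(grid, dtype=float))
    if grid.size == 0:
        raise ValueError("shape grid must be nonempty")
    if np.any((grid <= 0) | (grid >= 1)):
        raise ValueError("shape grid must lie inside (0, 1)")
    distances = []
    for a in grid:
        cfg = replace(config, a=float(a))
        sim = simulated_median_matrix(cfg)
        distances.append(matrix_distance(observed, sim))
    profile = pd.DataFrame({"a": grid, "distance": distances})
    a_hat = float(grid[int(np.argmin(distances))])  # first minimum = smallest a
    return a_hat, profile


def dominance_threshold(
    M: int, alpha: float = 0.05, config: SimulationConfig | None = None
) -> float:
    """Frequency above which an isoform is significantly dominant.

    The ``(1 - alpha)`` quantile of the *pooled* isoform frequencies (all
    ranks) over simulated genes with M isoforms: a randomly selected
    isoform exceeds the returned frequency with probability alpha.
    Quantiles interpolate linearly between order statistics.
    """
    if M < 2:
        raise ValueError("threshold is degenerate for M < 2 (frequency is always 1)")
    if not (0 < alpha < 0.5):
        raise ValueError("alpha must be in (0, 0.5)")
    if config is None:
        config = SimulationConfig(reps=100_000)
    freqs = simulate_gene_frequencies(config, M)
    return float(np.quantile(freqs.ravel(), 1.0 - alpha))


def dominance_threshold_table(
    M_values: Sequence[int],
    alpha: float = 0.05,
    config: SimulationConfig | None = None,
) -> pd.DataFrame:
    """Threshold table (columns M, alpha, threshold) over several M."""
    rows = [
        {"M": int(M), "alpha": alpha, "threshold": dominance_threshold(M, alpha, config)}
        for M in M_values
    ]
    return pd.DataFrame(rows)


def probability_rank_exceeds(
    k: int, M: int, t: float, config: SimulationConfig | None = None
) -> tuple[float, float]:
    """Monte-Carlo ``P(f(k, M) >= t)`` with its standard error."""
    if not (1 <= k <= M):
        raise ValueError(f"rank k={k} must satisfy 1 <= k <= M={M}")
    if not (0 < t < 1):
        raise ValueError("threshold t must lie in (0, 1)")
    if config is None:
        config = SimulationConfig(reps=100_000)
    freqs = simulate_gene_frequencies(config, M)
    hits = freqs[:, k - 1] >= t
    p = float(hits.mean())
    se = float(np.sqrt(p * (1.0 - p) / hits.size))
    return p, se


def dominant_two_isoform_tail(t: float, a: float) -> float:
    """Closed form ``P(f(1,2) >= t) = 2 / (1 + (t/(1-t))^a)`` for t in (0,1).

    The ratio of two independent W(a, 1) variates raised to the a-th power
    is a ratio of exponentials, whose odds are logistic; for t <= 1/2 the
    probability is 1 (the larger of two always holds at least half).
    """
    if not (0 < t < 1):
        raise ValueError("t must lie in (0, 1)")
    if t <= 0.5:
        return 1.0
    return 2.0 / (1.0 + (t / (1.0 - t)) ** a)


def genome_weighted_percent(
    weights: Mapping[int, float],
    k: int,
    t: float,
    config: SimulationConfig | None = None,
) -> float:
    """Percentage of genes with ``f(k, M) >= t``, weighted by the number of
    genes per isoform-count group (e.g. from an annotation's per-M census).

    Groups with M < k contribute probability 0 (rank k does not exist).
    """
    w_total = float(sum(weights.values()))
    if w_total <= 0 or any(w < 0 for w in weights.values()):
        raise ValueError("weights must be nonnegative and not all zero")
    acc = 0.0
    for M, w in weights.items():
        if w == 0:
            continue
        p = probability_rank_exceeds(k, M, t, config)[0] if M >= k else 0.0
        acc += w * p
    return 100.0 * acc / w_total


def expected_expressed_isoforms(
    M: int, cutoff: float = 0.001, config: SimulationConfig | None = None
) -> float:
    """Median number of isoforms with frequency >= cutoff for a gene with M
    isoforms under the model — the expected detected-isoform count."""
    if not (0 < cutoff < 1):
        raise ValueError("cutoff must lie in (0, 1)")
    if config is None:
        config = SimulationConfig()
    freqs = simulate_gene_frequencies(config, M)
    counts = (freqs >= cutoff).sum(axis=1)
    return float(np.median(counts))


def expected_expressed_isoform_curve(
    cutoff: float = 0.001, config: SimulationConfig | None = None
) -> pd.DataFrame:
    """The expected-expressed-count curve over M = 1..M_max."""
    if config is None:
        config = SimulationConfig()
    rows = [
        {"M": M, "median_expressed": expected_expressed_isoforms(M, cutoff, config)}
        for M in range(1, config.M_max + 1)
    ]
    return pd.DataFrame(rows)
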