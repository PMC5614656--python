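"""Empirical statistics of isoform usage frequencies.

A gene with ``M`` annotated isoforms yields a descending frequency vector
``f(1..M)``; genes are grouped by ``M`` and summarized in a median
frequency matrix ``mf(k, M)`` (ranks k = 1..9 by isoform counts
M = 1..30 by default, cells with k > M masked).  Matrices from
experiment, simulation and the closed-form approximation are compared by
Euclidean distance; binned frequency distributions are compared by
Kullback-Leibler divergence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

DEFAULT_K_MAX = 9
DEFAULT_M_MAX = 30


@dataclass(frozen=True)
class FrequencyMatrix:
    """The k x M table of median frequencies, NaN where undefined.

    Rows are ranks k = 1..k_max, columns isoform counts M = 1..M_max.
    Cells with k > M are structurally masked; cells whose group was empty
    are masked too.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2:
            raise ValueError("frequency matrix must be 2-D (k x M)")
        k_max, M_max = v.shape
        for k in range(1, k_max + 1):
            for M in range(1, min(k, M_max + 1)):
                if np.isfinite(v[k - 1, M - 1]):
                    raise ValueError(f"cell (k={k}, M={M}) with k > M must be masked")

    @property
    def k_max(self) -> int:
        return self.values.shape[0]

    @property
    def M_max(self) -> int:
        return self.values.shape[1]

    def cell(self, k: int, M: int) -> float:
        return float(self.values[k - 1, M - 1])

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            self.values,
            index=[f"k{k}" for k in range(1, self.k_max + 1)],
            columns=[f"M{M}" for M in range(1, self.M_max + 1)],
        )
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "FrequencyMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(dtype=float))


def median_frequency_matrix(
    groups: Mapping[int, Sequence],
    k_max: int = DEFAULT_K_MAX,
    M_max: int = DEFAULT_M_MAX,
) -> FrequencyMatrix:
    """Median of the k-th ranked frequency over all vectors in each group.

    ``groups`` maps isoform count M to a list (or 2-D array) of descending
    frequency vectors of length M.  Empty or absent groups leave their
    column masked.
    """
    out = np.full((k_max, M_max), np.nan)
    for M, vectors in groups.items():
        if M < 1 or M > M_max:
            continue
        arr = np.asarray(vectors, dtype=float)
        if arr.size == 0:
            continue
        arr = arr.reshape(-1, M)
        med = np.median(arr, axis=0)
        depth = min(k_max, M)
        out[:depth, M - 1] = med[:depth]
    return FrequencyMatrix(out)


def matrix_distance(f1: FrequencyMatrix, f2: FrequencyMatrix) -> float:
    """Euclidean distance over unmasked cells:
    ``sqrt(sum_k sum_{M>=k} (f1(k,M) - f2(k,M))^2)``.

    Cells masked in either matrix contribute zero.
    """
    if f1.values.shape != f2.values.shape:
        raise ValueError(
            f"matrix shapes differ: {f1.values.shape} vs {f2.values.shape}"
        )
    both = np.isfinite(f1.values) & np.isfinite(f2.values)
    diff = f1.values[both] - f2.values[both]
    return float(np.sqrt(np.sum(diff**2)))


@dataclass(frozen=True)
class BinnedDistribution:
    """A normalized histogram on [0, 1] — the operand of KLd and entropy."""

    edges: np.ndarray
    probs: np.ndarray

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges, dtype=float)
        probs = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "edges", edges)
        object.__setattr__(self, "probs", probs)
        if edges.size != probs.size + 1:
            raise ValueError("need len(edges) == len(probs) + 1")
        if np.any(probs < 0):
            raise ValueError("probabilities must be nonnegative")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError(f"probabilities sum to {probs.sum()}, not 1")

    @classmethod
    def from_samples(
        cls, values, n_bins: int = 40, value_range: tuple[float, float] = (0.0, 1.0)
    ) -> "BinnedDistribution":
        values = np.asarray(values, dtype=float)
        counts, edges = np.histogram(values, bins=n_bins, range=value_range)
        total = counts.sum()
        if total == 0:
            raise ValueError("no samples fall inside the binning range")
        return cls(edges, counts / total)


def _check_same_bins(P: BinnedDistribution, Q: BinnedDistribution) -> None:
    if P.edges.size != Q.edges.size or not np.allclose(P.edges, Q.edges):
        raise ValueError("distributions must share identical bin edges")


def kl_divergence(
    P: BinnedDistribution, Q: BinnedDistribution, pseudo: float = 1e-9
) -> float:
    """Kullback-Leibler divergence ``sum_i P(i) ln(P(i)/Q(i))`` in nats.

    The information lost when Q (typically the model) approximates P
    (typically data).  Empty Q bins are handled by adding pseudo-mass
    ``pseudo`` to every Q bin and renormalizing.
    """
    _check_same_bins(P, Q)
    q = Q.probs + pseudo
    q = q / q.sum()
    mask = P.probs > 0
    return float(np.sum(P.probs[mask] * np.log(P.probs[mask] / q[mask])))


def entropy(P: BinnedDistribution) -> float:
    """Shannon entropy ``-sum_i P(i) ln P(i)`` in nats (nonnegative form)."""
    p = P.probs[P.probs > 0]
    return float(-np.sum(p * np.log(p)))


def expressed_isoform_counts(profiles: Iterable, cutoff: float = 0.001):
    """Per-gene count of isoforms with frequency >= cutoff, summarized per M.

    Returns ``(per_gene, summary)``: a DataFrame of per-profile counts and
    a per-M DataFrame with the median and quartiles of the expressed-
    isoform count.  The cutoff is inclusive.
    """
    if not (0 <= cutoff < 1):
        raise ValueError("cutoff must be in [0, 1)")
    rows = []
    for p in profiles:
        n_expr = int(np.sum(np.asarray(p.frequencies) >= cutoff))
        rows.append(
            {
                "gene_id": p.gene_id,
                "sample_id": p.sample_id,
                "M": p.M,
                "n_expressed": n_expr,
            }
        )
    per_gene = pd.DataFrame(rows)
    if per_gene.empty:
        return per_gene, per_gene
    summary = (
        per_gene.groupby("M")["n_expressed"]
        .agg(
            n_genes="size",
            median="median",
            q25=lambda s: s.quantile(0.25),
            q75=lambda s: s.quantile(0.75),
        )
        .reset_index()
    )
    return per_gene, summary


@dataclass
class SwitchReport:
    """Genes whose top-ranked (dominant) isoform differs between conditions."""

    condition_pair: tuple[str, str]
    n_subsets: int
    genes: dict = field(default_factory=dict)

    def switching_in(self, n: int) -> list[str]:
        """Genes whose dominant isoform switched in exactly n subsets and
        that agreed (switched) in every subset where they were evaluable."""
        return sorted(
            g
            for g, rec in self.genes.items()
            if rec["switched"] == n and rec["switched"] == rec["evaluated"]
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "condition_pair": list(self.condition_pair),
                    "n_subsets": self.n_subsets,
                    "genes": self.genes,
                    "all_subset_switches": self.switching_in(self.n_subsets),
                    "n_minus_one_switches": self.switching_in(self.n_subsets - 1),
                },
                fh,
                indent=2,
            )


def detect_dominance_switches(
    profiles: Iterable, condition_pair: tuple[str, str]
) -> SwitchReport:
    """Detect dominant-isoform switches between two conditions.

    Profiles carry ``sample_id`` (the cell subset) and ``condition``.  A
    subset votes for a gene only when the gene passes the expression
    filter (i.e. has a profile) under *both* conditions in that subset; it
    is a switch vote when the identity of the rank-1 isoform differs.
    Genes evaluable in fewer subsets than exist overall are flagged
    partial.
    """
    cond_a, cond_b = condition_pair
    seen_conditions: set[str] = set()
    subsets: set[str] = set()
    # (gene, subset, condition) -> top isoform id
    top: dict[tuple[str, str, str], str] = {}
    for p in profiles:
        seen_conditions.add(p.condition)
        if p.condition not in condition_pair:
            continue
        subsets.add(p.sample_id)
        top[(p.gene_id, p.sample_id, p.condition)] = p.isoform_ids[0]
    for cond in condition_pair:
        if cond not in seen_conditions:
            raise ValueError(f"unknown condition label {cond!r}")

    report = SwitchReport(condition_pair=(cond_a, cond_b), n_subsets=len(subsets))
    genes = {g for g, _, _ in top}
    for gene in sorted(genes):
        evaluated = 0
        switched = 0
        for subset in subsets:
            ta = top.get((gene, subset, cond_a))
            tb = top.get((gene, subset, cond_b))
            if ta is None or tb is None:
                continue
            evaluated += 1
            if ta != tb:
                switched += 1
        if evaluated == 0 or switched == 0:
            continue
        report.genes[gene] = {
            "evaluated": evaluated,
            "switched": switched,
            "partial": evaluated < len(subsets),
        }
    return report
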