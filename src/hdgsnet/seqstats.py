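"""Sequence-dependence analyses of nucleosome occupancy.

Sites are grouped by occupancy level (quartile split, 1-D k-means with
k = 3, or deciles after a descending sort) and each group's sequences are
summarized by mono-/dinucleotide composition tables and by a positional
16 x 146 dinucleotide frequency matrix (the heatmap representation: one
row per dinucleotide type, one column per window position, columns summing
to 1).  The canonical finding these tools reproduce is that GG/CC/GC/CG
("GC-type") dinucleotides are enriched in high-occupancy groups and
AA/TT/AT/TA ("AT-type") dinucleotides in low-occupancy groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from statsmodels.stats.proportion import proportions_ztest

from .encoding import BASES, DINUCLEOTIDES, dinucleotide_onehot
from .stratify import boxplot_stats

__all__ = [
    "GC_TYPE", "AT_TYPE", "OccupancyGroups",
    "group_by_quartile", "group_by_kmeans3", "group_by_decile",
    "composition", "positional_matrix", "gc_at_frequencies",
    "enrichment_test",
]

GC_TYPE = ("GG", "CC", "GC", "CG")
AT_TYPE = ("AA", "TT", "AT", "TA")


@dataclass
class OccupancyGroups:
    """Group assignment per site; ``order`` lists labels high -> low.

    ``assignments[i]`` is the group label of site i, or None for sites left
    out of the contrast (the middle band of the quartile split).
    """

    method: str
    assignments: list[str | None]
    order: list[str]

    def members(self, label: str) -> np.ndarray:
        return np.array([i for i, g in enumerate(self.assignments)
                         if g == label], dtype=np.int64)


def group_by_quartile(values: np.ndarray) -> OccupancyGroups:
    """High = strictly above Q3, low = strictly below Q1; the middle band is
    unassigned and excluded from composition contrasts."""
    values = np.asarray(values, dtype=np.float64)
    if values.size < 8:
        raise ValueError("need at least 8 values for a quartile split")
    bs = boxplot_stats(values)
    if bs.q1 == bs.q3:
        raise ValueError("degenerate distribution: Q1 == Q3")
    assignments: list[str | None] = []
    for v in values:
        if v > bs.q3:
            assignments.append("high")
        elif v < bs.q1:
            assignments.append("low")
        else:
            assignments.append(None)
    return OccupancyGroups("quartile", assignments, ["high", "low"])


def group_by_kmeans3(values: np.ndarray, seed: int = 0) -> OccupancyGroups:
    """1-D k-means with k=3; clusters relabeled high/medium/low by
    descending centroid."""
    values = np.asarray(values, dtype=np.float64)
    if np.unique(values).size < 3:
        raise ValueError("need at least 3 distinct values for k-means (k=3)")
    km = KMeans(n_clusters=3, n_init=10, random_state=seed)
    raw = km.fit_predict(values[:, None])
    order = np.argsort(-km.cluster_centers_[:, 0])
    names = ["high", "medium", "low"]
    relabel = {int(cluster): names[rank] for rank, cluster in enumerate(order)}
    return OccupancyGroups("kmeans3", [relabel[int(c)] for c in raw], names)


def group_by_decile(values: np.ndarray) -> OccupancyGroups:
    """Sort descending and split into ten contiguous groups G1 (highest)
    ... G10 (lowest), sizes differing by at most 1.  Ties are broken
    stably by (value descending, index ascending)."""
    values = np.asarray(values, dtype=np.float64)
    n = values.size
    if n < 10:
        raise ValueError("need at least 10 values for deciles")
    order = np.argsort(-values, kind="stable")
    sizes = np.full(10, n // 10)
    sizes[:n % 10] += 1
    labels = [f"G{i + 1}" for i in range(10)]
    assignments: list[str | None] = [None] * n
    start = 0
    for lbl, size in zip(labels, sizes):
        for idx in order[start:start + size]:
            assignments[idx] = lbl
        start += size
    return OccupancyGroups("decile", assignments, labels)


def composition(sequences: list[str]) -> tuple[dict[str, float], dict[str, float]]:
    """Pooled mononucleotide (4 bases) and dinucleotide (16 types)
    frequency tables over a group of equal-length ACGT sequences; each
    table sums to 1."""
    if not sequences:
        raise ValueError("empty sequence group")
    length = len(sequences[0])
    if any(len(s) != length for s in sequences):
        raise ValueError("sequences in a group must have equal length")
    mono = dict.fromkeys(BASES, 0)
    di = dict.fromkeys(DINUCLEOTIDES, 0)
    for seq in sequences:
        for b in seq:
            if b not in mono:
                raise ValueError(f"non-ACGT symbol {b!r}")
            mono[b] += 1
        for j in range(length - 1):
            di[seq[j:j + 2]] += 1
    n_mono = sum(mono.values())
    n_di = sum(di.values())
    return ({b: c / n_mono for b, c in mono.items()},
            {d: c / n_di for d, c in di.items()})


def positional_matrix(sequences: list[str], window: int = 147) -> np.ndarray:
    """16 x (window-1) positional dinucleotide frequency matrix.

    Entry (d, j) is the fraction of group sequences whose dinucleotide at
    position j is type d; every column sums to 1.
    """
    if not sequences:
        raise ValueError("empty sequence group")
    if any(len(s) != window for s in sequences):
        raise ValueError(f"all sequences must have length {window}")
    acc = np.zeros((16, window - 1), dtype=np.float64)
    for seq in sequences:
        acc += dinucleotide_onehot(seq)
    return acc / len(sequences)


def gc_at_frequencies(di_table: dict[str, float]) -> tuple[float, float]:
    """Summed GC-type and AT-type dinucleotide frequencies of a table."""
    return (sum(di_table[d] for d in GC_TYPE),
            sum(di_table[d] for d in AT_TYPE))


def enrichment_test(count_a: int, n_a: int, count_b: int, n_b: int) -> float:
    """Two-sided two-proportion z-test p-value for a dinucleotide enrichment
    contrast between two groups (continuity-uncorrected)."""
    if n_a <= 0 or n_b <= 0:
        raise ValueError("group totals must be positive")
    if not (0 <= count_a <= n_a and 0 <= count_b <= n_b):
        raise ValueError("counts must lie within their totals")
    if count_a / n_a == count_b / n_b:
        return 1.0  # identical proportions, including the all-zero case
    _, p = proportions_ztest([count_a, count_b], [n_a, n_b],
                             alternative="two-sided")
    return float(p)
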