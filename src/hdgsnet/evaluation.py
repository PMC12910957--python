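"""Regression metrics and per-chromosome correlation reports.

Model quality on genome tracks is summarized the way occupancy papers
report it: a Pearson correlation between predicted and experimental dMean
values per chromosome, the unweighted mean r over non-excluded
chromosomes, and MAE / R-squared pooled over all non-excluded sites.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import mean_absolute_error, r2_score

from .genome_io import DatasetContainer, OccupancyTrack

__all__ = ["EvalReport", "pearson", "evaluate_by_chromosome"]


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation coefficient.

    Raises on length mismatch, n < 2 or a constant argument (the
    correlation is undefined there, not zero).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 2:
        raise ValueError("need at least 2 points")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(np.sum(xc ** 2))
    sy = np.sqrt(np.sum(yc ** 2))
    if sx == 0.0 or sy == 0.0:
        raise ValueError("correlation undefined for a constant vector")
    return float(np.sum(xc * yc) / (sx * sy))


@dataclass
class EvalReport:
    per_chromosome: dict[str, float]
    mean_r: float
    mae: float
    r2: float
    excluded: list[str] = field(default_factory=list)

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("chrom\tpearson_r\texcluded\n")
            for chrom, r in self.per_chromosome.items():
                fh.write(f"{chrom}\t{r:.4f}\t{int(chrom in self.excluded)}\n")
            fh.write(f"#mean_r\t{self.mean_r:.4f}\n")
            fh.write(f"#mae\t{self.mae:.4f}\n")
            fh.write(f"#r2\t{self.r2:.4f}\n")


def evaluate_by_chromosome(predictions: np.ndarray,
                           container: DatasetContainer,
                           tracks: list[OccupancyTrack] | None = None,
                           excluded: list[str] | None = None,
                           site_weighted_mean: bool = False) -> EvalReport:
    """Per-chromosome Pearson r plus pooled MAE and R-squared.

    Truth is the container's labels, or the (normalized) tracks' values at
    the container's coordinates when ``tracks`` is given.  Chromosomes in
    ``excluded`` still appear in the per-chromosome map but are left out of
    the mean and the pooled metrics.  Chromosomes with fewer than 2 sites
    are skipped with a warning.
    """
    predictions = np.asarray(predictions, dtype=np.float64)
    if predictions.shape[0] != len(container):
        raise ValueError("predictions and container differ in length")
    excluded = list(excluded or [])
    if tracks is not None:
        tmap = {t.chrom: t for t in tracks}
        for t in tracks:
            if not t.normalized:
                raise ValueError(f"track {t.chrom} is not dMean-normalized")
        truth = np.array([tmap[c].values[p] for c, p in
                          zip(container.chroms, container.positions)])
    else:
        truth = container.labels.astype(np.float64)

    per_chrom: dict[str, float] = {}
    counts: dict[str, int] = {}
    for chrom in dict.fromkeys(container.chroms):
        mask = container.chroms == chrom
        if mask.sum() < 2:
            warnings.warn(f"chromosome {chrom} has < 2 sites; skipped")
            continue
        per_chrom[chrom] = pearson(predictions[mask], truth[mask])
        counts[chrom] = int(mask.sum())

    kept = [c for c in per_chrom if c not in excluded]
    if not kept:
        raise ValueError("no non-excluded chromosome with >= 2 sites")
    if site_weighted_mean:
        w = np.array([counts[c] for c in kept], dtype=np.float64)
        mean_r = float(np.average([per_chrom[c] for c in kept], weights=w))
    else:
        mean_r = float(np.mean([per_chrom[c] for c in kept]))
    pooled = np.isin(container.chroms.astype(str), kept)
    mae = float(mean_absolute_error(truth[pooled], predictions[pooled]))
    r2 = float(r2_score(truth[pooled], predictions[pooled]))
    return EvalReport(per_chrom, mean_r, mae, r2, excluded)
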