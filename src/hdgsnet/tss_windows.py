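"""TSS-centered, strand-aware sample construction.

For each transcription start site, prediction targets are laid on a grid
of centers at 10-bp steps across the +/-1000 bp flanking region (201
centers for an interior TSS, endpoints included).  Grid offsets are
strand-oriented: for a '-' TSS, strand-oriented offset +d lies at genomic
coordinate TSS - d.  Each center contributes a 147-bp window read on the
TSS strand (reverse complement for '-') labelled with the occupancy at
the center.  Centers whose window leaves the chromosome or contains N are
skipped and reported.
"""

from __future__ import annotations

import numpy as np

from .encoding import FLANK, build_samples
from .genome_io import (DatasetContainer, GenomeSequence, OccupancyTrack,
                        SiteAnnotation)

__all__ = ["tss_grid", "build_tss_windows"]


def tss_grid(tss: SiteAnnotation, span: int = 1000, step: int = 10,
             ) -> list[SiteAnnotation]:
    """Grid of window centers for one TSS, in strand-oriented order from
    -span to +span inclusive (negative genomic offsets may be clipped by
    downstream bounds checks, not here)."""
    offsets = np.arange(-span, span + 1, step)
    sign = 1 if tss.strand == "+" else -1
    return [SiteAnnotation(tss.chrom, int(tss.position + sign * off), tss.strand)
            for off in offsets if tss.position + sign * off >= 0]


def build_tss_windows(genomes: list[GenomeSequence] | GenomeSequence,
                      tracks: list[OccupancyTrack] | OccupancyTrack,
                      tss_list: list[SiteAnnotation],
                      span: int = 1000, step: int = 10,
                      ) -> tuple[DatasetContainer, list]:
    """Encode the 10-bp-step window grids of all TSS into one container.

    Returns the container (one 16 x 146 sample per admissible center, in
    grid order TSS by TSS) and the skip report; a TSS whose centers are all
    skipped is additionally reported as ('all centers skipped', tss).
    """
    centers: list[SiteAnnotation] = []
    owners: list[int] = []
    for i, tss in enumerate(tss_list):
        grid = tss_grid(tss, span=span, step=step)
        centers.extend(grid)
        owners.extend([i] * len(grid))
    container, skipped = build_samples(genomes, tracks, centers, flank=FLANK)
    report: list = list(skipped)
    kept_keys = {(c, int(p), s) for c, p, s in
                 zip(container.chroms, container.positions, container.strands)}
    for i, tss in enumerate(tss_list):
        n_kept = sum(1 for c, o in zip(centers, owners)
                     if o == i and (c.chrom, c.position, c.strand) in kept_keys)
        if n_kept == 0:
            report.append(("all centers skipped", tss))
    return container, report
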