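"""Dinucleotide one-hot encoding of 147-bp nucleosome windows.

A 147-bp window centered on a genomic site is represented by its 146
overlapping dinucleotides; each dinucleotide maps to one of 16 rows
(lexicographic order AA=0, AC=1, ..., TT=15), giving a binary 16 x 146
matrix with exactly one 1 per column.  The regression label of a window
is the dMean occupancy at its central base.

Minus-strand sites are encoded from the reverse complement of the
genomic span, i.e. the 5'->3' reading of the annotated strand.
"""

from __future__ import annotations

import numpy as np

from .genome_io import (DatasetContainer, GenomeSequence, OccupancyTrack,
                        SiteAnnotation)

__all__ = [
    "DINUCLEOTIDES",
    "DINUC_INDEX",
    "FLANK",
    "WINDOW",
    "reverse_complement",
    "dinucleotide_onehot",
    "decode_onehot",
    "extract_window",
    "build_samples",
]

BASES = "ACGT"
DINUCLEOTIDES = tuple(a + b for a in BASES for b in BASES)
DINUC_INDEX = {d: i for i, d in enumerate(DINUCLEOTIDES)}
FLANK = 73
WINDOW = 2 * FLANK + 1  # 147 bp, the canonical nucleosome core length

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
# base -> integer code; 255 marks N / invalid
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i


def reverse_complement(seq: str) -> str:
    """5'->3' sequence of the opposite strand."""
    return seq.translate(_COMPLEMENT)[::-1]


def _codes(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def dinucleotide_onehot(seq: str) -> np.ndarray:
    """Encode an ACGT string as a binary 16 x (len-1) dinucleotide matrix.

    Column j is the one-hot vector of the dinucleotide seq[j:j+2] under the
    lexicographic row order AA=0 ... TT=15.  Any non-ACGT symbol raises a
    ValueError naming the first offending offset.
    """
    if len(seq) < 2:
        raise ValueError("sequence must have length >= 2")
    codes = _codes(seq)
    bad = np.nonzero(codes == 255)[0]
    if bad.size:
        raise ValueError(
            f"non-ACGT symbol {seq[bad[0]]!r} at offset {int(bad[0])}")
    idx = 4 * codes[:-1].astype(np.int64) + codes[1:]
    mat = np.zeros((16, len(seq) - 1), dtype=np.uint8)
    mat[idx, np.arange(len(seq) - 1)] = 1
    return mat


def decode_onehot(matrix: np.ndarray) -> str:
    """Invert :func:`dinucleotide_onehot` (the dinucleotide overlap makes the
    encoding uniquely decodable)."""
    matrix = np.asarray(matrix)
    if matrix.ndim != 2 or matrix.shape[0] != 16:
        raise ValueError("expected a 16 x L matrix")
    if not np.isin(matrix, (0, 1)).all() or np.any(matrix.sum(axis=0) != 1):
        raise ValueError("matrix columns must be one-hot")
    rows = matrix.argmax(axis=0)
    first = BASES[rows[0] // 4]
    rest = [BASES[r % 4] for r in rows]
    seq = first + "".join(rest)
    # consistency: overlapping bases must agree
    for j in range(1, len(rows)):
        if rows[j] // 4 != rows[j - 1] % 4:
            raise ValueError(f"inconsistent overlap between columns {j-1},{j}")
    return seq


def extract_window(genome: GenomeSequence | str, center: int, strand: str = "+",
                   flank: int = FLANK) -> str:
    """Return the (2*flank+1)-bp window centered on ``center`` (0-based,
    inclusive span [center-flank, center+flank]); reverse complement for '-'.
    """
    seq = genome.seq if isinstance(genome, GenomeSequence) else genome
    if center - flank < 0 or center + flank >= len(seq):
        raise IndexError(
            f"window [{center - flank}, {center + flank}] out of bounds "
            f"for chromosome of length {len(seq)}")
    window = seq[center - flank:center + flank + 1]
    if strand == "-":
        window = reverse_complement(window)
    elif strand != "+":
        raise ValueError(f"invalid strand {strand!r}")
    return window


def _bulk_encode(codes: np.ndarray, centers: np.ndarray,
                 strands: np.ndarray, flank: int = FLANK) -> np.ndarray:
    """Vectorized window encoding; all windows must be in-bounds and N-free."""
    offsets = np.arange(-flank, flank + 1)
    win = codes[centers[:, None] + offsets[None, :]].astype(np.int64)
    neg = strands == "-"
    if neg.any():
        win[neg] = 3 - win[neg, ::-1]  # reverse complement in code space
    idx = 4 * win[:, :-1] + win[:, 1:]
    n, w = idx.shape
    mats = np.zeros((n, 16, w), dtype=np.uint8)
    mats[np.arange(n)[:, None], idx, np.arange(w)[None, :]] = 1
    return mats


def build_samples(genomes: list[GenomeSequence] | GenomeSequence,
                  tracks: list[OccupancyTrack] | OccupancyTrack,
                  sites: list[SiteAnnotation],
                  flank: int = FLANK) -> tuple[DatasetContainer, list[tuple[SiteAnnotation, str]]]:
    """Encode one sample per admissible site; label = track value at center.

    Inadmissible sites (window out of bounds, window containing N, unknown
    chromosome) are skipped, not fatal; the skip report lists each with its
    reason.  Input site order is preserved.
    """
    if isinstance(genomes, GenomeSequence):
        genomes = [genomes]
    if isinstance(tracks, OccupancyTrack):
        tracks = [tracks]
    gmap = {g.chrom: g for g in genomes}
    tmap = {t.chrom: t for t in tracks}
    for t in tracks:
        if not t.normalized:
            raise ValueError(f"track {t.chrom} is not dMean-normalized")

    code_cache = {c: _codes(g.seq) for c, g in gmap.items()}
    keep: list[int] = []
    skipped: list[tuple[SiteAnnotation, str]] = []
    for i, s in enumerate(sites):
        if s.chrom not in gmap or s.chrom not in tmap:
            skipped.append((s, "unknown chromosome"))
            continue
        codes = code_cache[s.chrom]
        if s.position - flank < 0 or s.position + flank >= codes.size:
            skipped.append((s, "window out of bounds"))
            continue
        if s.position >= len(tmap[s.chrom]):
            skipped.append((s, "no track value at site"))
            continue
        if (codes[s.position - flank:s.position + flank + 1] == 255).any():
            skipped.append((s, "window contains N"))
            continue
        keep.append(i)

    if not keep:
        empty = DatasetContainer(np.zeros((0, 16, 2 * flank), dtype=np.uint8),
                                 np.zeros(0, dtype=np.float32),
                                 np.array([], dtype=object),
                                 np.zeros(0, dtype=np.int64),
                                 np.array([], dtype="U1"))
        return empty, skipped

    kept = [sites[i] for i in keep]
    chroms = np.array([s.chrom for s in kept], dtype=object)
    positions = np.array([s.position for s in kept], dtype=np.int64)
    strands = np.array([s.strand for s in kept], dtype="U1")
    feats = np.empty((len(kept), 16, 2 * flank), dtype=np.uint8)
    labels = np.empty(len(kept), dtype=np.float32)
    for chrom in dict.fromkeys(chroms):
        mask = chroms == chrom
        feats[mask] = _bulk_encode(code_cache[chrom], positions[mask],
                                   strands[mask], flank)
        labels[mask] = tmap[chrom].values[positions[mask]]
    return DatasetContainer(feats, labels, chroms, positions, strands), skipped
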