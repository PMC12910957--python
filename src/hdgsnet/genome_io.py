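"""Genome, occupancy-track and dataset I/O.

Carriers for the three inputs of the occupancy-prediction pipeline:

* genome sequences (FASTA),
* per-base nucleosome occupancy tracks (bedGraph or fixedStep WIG), and
* site annotations (BED6),

plus the HDF5 container that holds encoded samples (16x146 dinucleotide
one-hot matrices, labels, coordinates).

All internal coordinates are 0-based, half-open (BED convention); the
1-based fixedStep WIG dialect is converted at the parser boundary.

dMean normalization — the occupancy unit used throughout — divides every
per-base value by the mean read count over all covered bases of all
supplied chromosomes, so the genome-wide average is exactly 1.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import h5py
import numpy as np
from Bio import SeqIO

__all__ = [
    "GenomeSequence",
    "OccupancyTrack",
    "SiteAnnotation",
    "DatasetContainer",
    "ParseError",
    "read_fasta",
    "write_fasta",
    "read_occupancy",
    "write_occupancy",
    "coverage_report",
    "dmean_normalize",
    "read_bed_sites",
    "write_bed_sites",
    "write_dataset",
    "read_dataset",
]

_VALID_BASES = set("ACGTN")


class ParseError(ValueError):
    """Malformed input file (message names the offending line)."""


def _normalize_seq(seq: str) -> str:
    """Uppercase and map every symbol outside {A,C,G,T} to N."""
    seq = seq.upper()
    if set(seq) <= _VALID_BASES:
        return seq
    return "".join(c if c in _VALID_BASES else "N" for c in seq)


@dataclass
class GenomeSequence:
    """One chromosome: identifier plus uppercase {A,C,G,T,N} sequence."""

    chrom: str
    seq: str

    def __post_init__(self) -> None:
        if len(self.seq) == 0:
            raise ValueError(f"empty sequence for chromosome {self.chrom!r}")
        self.seq = _normalize_seq(self.seq)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class OccupancyTrack:
    """Per-base non-negative occupancy values for one chromosome.

    ``covered`` marks bases that were present in the source file; gap bases
    are zero-filled and excluded from the dMean denominator.
    """

    chrom: str
    values: np.ndarray
    normalized: bool = False
    covered: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("track values must be a nonempty 1-D array")
        if np.any(self.values < 0):
            raise ValueError(f"negative occupancy value on {self.chrom}")
        if self.covered is None:
            self.covered = np.ones(self.values.size, dtype=bool)
        else:
            self.covered = np.asarray(self.covered, dtype=bool)
            if self.covered.shape != self.values.shape:
                raise ValueError("coverage mask length mismatch")

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class SiteAnnotation:
    """A single genomic site (0-based position) with strand."""

    chrom: str
    position: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.position < 0:
            raise ValueError("position must be >= 0")


@dataclass
class DatasetContainer:
    """Parallel arrays of encoded samples: features N x 16 x 146 (uint8),
    labels N (float32), coords N triples (chrom, position, strand)."""

    features: np.ndarray
    labels: np.ndarray
    chroms: np.ndarray
    positions: np.ndarray
    strands: np.ndarray

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.uint8)
        self.labels = np.asarray(self.labels, dtype=np.float32)
        self.chroms = np.asarray(self.chroms, dtype=object)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.strands = np.asarray(self.strands, dtype="U1")
        n = len(self.labels)
        if self.features.shape[0] != n or len(self.chroms) != n \
                or len(self.positions) != n or len(self.strands) != n:
            raise ValueError("parallel arrays of the container differ in length")
        if self.features.ndim != 3 or self.features.shape[1:] != (16, 146):
            if n > 0:
                raise ValueError(
                    f"features must be N x 16 x 146, got {self.features.shape}")
            self.features = self.features.reshape(0, 16, 146)
        if n and np.any(self.labels < 0):
            raise ValueError("labels must be non-negative")

    def __len__(self) -> int:
        return len(self.labels)

    def subset(self, idx: np.ndarray) -> "DatasetContainer":
        return DatasetContainer(self.features[idx], self.labels[idx],
                                self.chroms[idx], self.positions[idx],
                                self.strands[idx])

    @property
    def sites(self) -> list[SiteAnnotation]:
        return [SiteAnnotation(c, int(p), s)
                for c, p, s in zip(self.chroms, self.positions, self.strands)]


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str) -> list[GenomeSequence]:
    """Read a (multi-record) FASTA file into uppercase genome sequences."""
    if os.path.getsize(path) == 0:
        raise ParseError(f"{path}: empty file")
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip() == "":
                continue
            if not line.startswith(">"):
                raise ParseError(
                    f"{path}:{lineno}: expected FASTA header line starting "
                    f"with '>', got {line.strip()[:30]!r}")
            break
    records = [GenomeSequence(rec.id, str(rec.seq))
               for rec in SeqIO.parse(path, "fasta")]
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    return records


def write_fasta(genomes: list[GenomeSequence], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for g in genomes:
            fh.write(f">{g.chrom}\n")
            for i in range(0, len(g.seq), width):
                fh.write(g.seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Occupancy tracks

def _parse_bedgraph(path: str) -> dict[str, list[tuple[int, int, float]]]:
    per_chrom: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith(("#", "track", "browser")):
                continue
            parts = s.split()
            if len(parts) < 4:
                raise ParseError(f"{path}:{lineno}: bedGraph needs 4 columns")
            chrom = parts[0]
            try:
                start, end, value = int(parts[1]), int(parts[2]), float(parts[3])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            if end <= start:
                raise ParseError(
                    f"{path}:{lineno}: interval end {end} <= start {start}")
            if value < 0:
                raise ParseError(f"{path}:{lineno}: negative value {value}")
            per_chrom.setdefault(chrom, []).append((start, end, value))
    return per_chrom


def _parse_wig_fixedstep(path: str) -> dict[str, list[tuple[int, int, float]]]:
    """Parse fixedStep WIG into 0-based half-open intervals."""
    per_chrom: dict[str, list[tuple[int, int, float]]] = {}
    chrom = None
    pos = step = span = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith(("#", "track", "browser")):
                continue
            if s.startswith("fixedStep"):
                fields = dict(kv.split("=", 1) for kv in s.split()[1:])
                try:
                    chrom = fields["chrom"]
                    start1 = int(fields["start"])  # 1-based
                except KeyError as exc:
                    raise ParseError(
                        f"{path}:{lineno}: fixedStep missing {exc}") from None
                step = int(fields.get("step", 1))
                span = int(fields.get("span", 1))
                if start1 < 1 or step < 1 or span < 1:
                    raise ParseError(f"{path}:{lineno}: bad fixedStep header")
                pos = start1 - 1  # to 0-based
                continue
            if s.startswith("variableStep"):
                raise ParseError(f"{path}:{lineno}: variableStep not supported")
            if chrom is None:
                raise ParseError(f"{path}:{lineno}: value before fixedStep header")
            try:
                value = float(s)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: bad value {s!r}") from None
            if value < 0:
                raise ParseError(f"{path}:{lineno}: negative value {value}")
            per_chrom.setdefault(chrom, []).append((pos, pos + span, value))
            pos += step
    return per_chrom


def read_occupancy(path: str, format: str = "bedgraph") -> list[OccupancyTrack]:
    """Read a per-base occupancy track, expanding intervals to base resolution.

    Bases not covered by any interval are zero-filled and flagged uncovered
    (see :func:`coverage_report`).  Overlapping intervals are an error.
    """
    if format == "bedgraph":
        per_chrom = _parse_bedgraph(path)
    elif format == "wig_fixedstep":
        per_chrom = _parse_wig_fixedstep(path)
    else:
        raise ValueError(f"unknown track format {format!r}")
    tracks = []
    for chrom, ivals in per_chrom.items():
        ivals.sort(key=lambda t: t[0])
        length = max(end for _, end, _ in ivals)
        values = np.zeros(length, dtype=np.float64)
        covered = np.zeros(length, dtype=bool)
        for start, end, value in ivals:
            if covered[start:end].any():
                raise ParseError(
                    f"{path}: overlapping intervals on {chrom} near {start}")
            values[start:end] = value
            covered[start:end] = True
        tracks.append(OccupancyTrack(chrom, values, normalized=False,
                                     covered=covered))
    return tracks


def write_occupancy(tracks: list[OccupancyTrack], path: str,
                    format: str = "bedgraph") -> None:
    """Write tracks back out (run-length merged for bedGraph)."""
    with open(path, "w") as fh:
        for t in tracks:
            if format == "bedgraph":
                vals, cov = t.values, t.covered
                i, n = 0, len(vals)
                while i < n:
                    if not cov[i]:
                        i += 1
                        continue
                    j = i + 1
                    while j < n and cov[j] and vals[j] == vals[i]:
                        j += 1
                    fh.write(f"{t.chrom}\t{i}\t{j}\t{vals[i]:.17g}\n")
                    i = j
            elif format == "wig_fixedstep":
                fh.write(f"fixedStep chrom={t.chrom} start=1 step=1\n")
                for v in t.values:
                    fh.write(f"{v:.17g}\n")
            else:
                raise ValueError(f"unknown track format {format!r}")


def coverage_report(tracks: list[OccupancyTrack]) -> dict[str, dict[str, int]]:
    """Per-chromosome counts of covered and zero-filled (uncovered) bases."""
    return {t.chrom: {"length": len(t),
                      "covered": int(t.covered.sum()),
                      "uncovered": int((~t.covered).sum())}
            for t in tracks}


def dmean_normalize(tracks: list[OccupancyTrack]) -> list[OccupancyTrack]:
    """dMean-normalize tracks jointly: divide by the global mean over all
    covered bases of all chromosomes, so the output mean is exactly 1.
    """
    if any(t.normalized for t in tracks):
        raise ValueError("tracks are already dMean-normalized")
    total = sum(float(t.values[t.covered].sum()) for t in tracks)
    nbases = sum(int(t.covered.sum()) for t in tracks)
    if nbases == 0 or total == 0.0:
        raise ValueError("dMean undefined: all occupancy values are zero")
    mean = total / nbases
    return [OccupancyTrack(t.chrom, t.values / mean, normalized=True,
                           covered=t.covered.copy()) for t in tracks]


# ---------------------------------------------------------------------------
# BED6 sites

def read_bed_sites(path: str) -> list[SiteAnnotation]:
    """Read site annotations from BED6 (position = interval start; strand
    from column 6, defaulting to '+')."""
    sites = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith(("#", "track", "browser")):
                continue
            parts = s.split()
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: BED needs >= 3 columns")
            strand = parts[5] if len(parts) >= 6 else "+"
            try:
                sites.append(SiteAnnotation(parts[0], int(parts[1]), strand))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
    return sites


def write_bed_sites(sites: list[SiteAnnotation], path: str) -> None:
    with open(path, "w") as fh:
        for s in sites:
            fh.write(f"{s.chrom}\t{s.position}\t{s.position + 1}\t.\t0\t{s.strand}\n")


# ---------------------------------------------------------------------------
# HDF5 dataset container

def write_dataset(container: DatasetContainer, path: str) -> None:
    """Write the encoded dataset to HDF5 (/features, /labels, /coords/*)."""
    with h5py.File(path, "w") as h5:
        h5.create_dataset("features", data=container.features, dtype="uint8")
        h5.create_dataset("labels", data=container.labels, dtype="float32")
        grp = h5.create_group("coords")
        grp.create_dataset("chrom",
                           data=np.array([c.encode() for c in container.chroms]))
        grp.create_dataset("position", data=container.positions, dtype="int64")
        grp.create_dataset("strand",
                           data=np.array([s.encode() for s in container.strands]))


def read_dataset(path: str) -> DatasetContainer:
    with h5py.File(path, "r") as h5:
        for key in ("features", "labels", "coords"):
            if key not in h5:
                raise ParseError(f"{path}: missing dataset {key!r}")
        for key in ("chrom", "position", "strand"):
            if key not in h5["coords"]:
                raise ParseError(f"{path}: missing dataset coords/{key!r}")
        features = h5["features"][...]
        labels = h5["labels"][...]
        chroms = np.array([c.decode() for c in h5["coords/chrom"][...]],
                          dtype=object)
        positions = h5["coords/position"][...]
        strands = np.array([s.decode() for s in h5["coords/strand"][...]])
    return DatasetContainer(features, labels, chroms, positions, strands)
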