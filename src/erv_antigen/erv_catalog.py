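"""ERV interval catalog: BED I/O, sequence extraction, and binding-peak proximity.

All intervals are BED-style 0-based half-open.  Two intervals overlap iff
``max(starts) < min(ends)``.  The distance between two disjoint intervals is
the gap in bases plus one, so touching intervals (``a.end == b.start``) are at
distance 1 and do not overlap.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

from Bio.Seq import reverse_complement

__all__ = [
    "ErvRecord",
    "PeakRecord",
    "ProximityAnnotation",
    "BedParseError",
    "read_interval_file",
    "load_genome",
    "extract_erv_sequences",
    "extend_intervals",
    "interval_distance",
    "annotate_peak_proximity",
    "write_proximity_tsv",
]


class BedParseError(ValueError):
    """Raised for malformed interval lines; message names the line number."""


@dataclass(frozen=True)
class ErvRecord:
    """One catalog ERV as a stranded genomic interval."""

    erv_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    alias: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval for {self.erv_id}: [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r} for {self.erv_id}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class PeakRecord:
    """One binding-site peak interval."""

    peak_id: str
    chrom: str
    start: int
    end: int
    score: float | None = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval for {self.peak_id}: [{self.start}, {self.end})"
            )


@dataclass(frozen=True)
class ProximityAnnotation:
    """Smallest window (kb) at which an ERV meets an extended peak."""

    erv_id: str
    relation: str  # {"superimposed", "within_window", "none"}
    window_kb: int | None
    distance_bp: int
    nearest_peak_id: str | None = None

    def __post_init__(self) -> None:
        if self.relation == "superimposed" and self.distance_bp != 0:
            raise ValueError("superimposed annotation must have distance 0")
        if self.relation == "none" and self.nearest_peak_id is not None:
            raise ValueError("relation 'none' cannot carry a nearest peak")


def read_interval_file(path: str | Path, kind: str) -> list:
    """Parse a 3-6 column BED file into ERV or peak records.

    ``kind`` is ``"erv"`` or ``"peak"``.  Column order: chrom, start, end,
    then optional name, score, strand.  Missing names are synthesised from
    the line number; strand ``.`` is read as ``+``.
    """
    if kind not in ("erv", "peak"):
        raise ValueError(f"unknown kind {kind!r}")
    records = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise BedParseError(f"line {lineno}: expected >=3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise BedParseError(
                    f"line {lineno}: non-integer coordinate in {fields[1:3]}"
                ) from None
            if start < 0 or start >= end:
                raise BedParseError(f"line {lineno}: invalid interval [{start}, {end})")
            name = fields[3] if len(fields) > 3 else f"{kind}_{lineno}"
            score = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                try:
                    score = float(fields[4])
                except ValueError:
                    raise BedParseError(f"line {lineno}: bad score {fields[4]!r}") from None
            strand = fields[5] if len(fields) > 5 else "+"
            if strand == ".":
                strand = "+"
            if strand not in ("+", "-"):
                raise BedParseError(f"line {lineno}: unknown strand {strand!r}")
            if kind == "erv":
                records.append(ErvRecord(name, chrom, start, end, strand))
            else:
                records.append(PeakRecord(name, chrom, start, end, score))
    return records


def load_genome(path: str | Path):
    """Open a FASTA genome for random access (pyfaidx)."""
    from pyfaidx import Fasta

    return Fasta(str(path), sequence_always_upper=True)


def extract_erv_sequences(
    genome: Mapping[str, Union[str, Sequence]], ervs: Iterable[ErvRecord]
) -> dict[str, str]:
    """Extract the nucleotide sequence of each ERV; minus-strand records are
    reverse-complemented so the sense orientation comes first."""
    out: dict[str, str] = {}
    for rec in ervs:
        try:
            chrom_seq = genome[rec.chrom]
        except KeyError:
            raise KeyError(f"chromosome {rec.chrom!r} not in genome") from None
        if rec.end > len(chrom_seq):
            raise ValueError(
                f"{rec.erv_id}: interval end {rec.end} exceeds "
                f"{rec.chrom} length {len(chrom_seq)}"
            )
        seq = str(chrom_seq[rec.start : rec.end]).upper()
        if rec.strand == "-":
            seq = reverse_complement(seq)
        out[rec.erv_id] = seq
    return out


def extend_intervals(peaks: Sequence[PeakRecord], flank_bp: int) -> list[PeakRecord]:
    """Extend each peak by ``flank_bp`` on both sides, clipping at 0."""
    if flank_bp < 0:
        raise ValueError(f"flank_bp must be >= 0, got {flank_bp}")
    return [
        replace(p, start=max(0, p.start - flank_bp), end=p.end + flank_bp)
        for p in peaks
    ]


def interval_distance(start1: int, end1: int, start2: int, end2: int) -> int:
    """0 if the half-open intervals overlap, else gap-in-bases + 1."""
    if max(start1, start2) < min(end1, end2):
        return 0
    return max(start2 - end1, start1 - end2) + 1


def annotate_peak_proximity(
    ervs: Sequence[ErvRecord],
    peaks: Sequence[PeakRecord],
    windows_kb: Sequence[int] = (0, 1, 5, 10),
) -> list[ProximityAnnotation]:
    """For each ERV report the smallest window at which any peak, extended by
    that many kb on each side, overlaps it.

    Window 0 means the peak is superimposed on the ERV.  A peak extended by
    ``f`` bases overlaps an ERV iff their unextended distance is <= ``f``, so
    the scan reduces to a nearest-distance computation.  Ties on distance are
    broken by lexicographically smallest peak id.
    """
    if not windows_kb:
        raise ValueError("windows_kb must be non-empty")
    windows = sorted(set(int(w) for w in windows_kb))
    if windows[0] < 0:
        raise ValueError("windows must be >= 0 kb")
    by_chrom: dict[str, list[PeakRecord]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append(p)

    annotations = []
    for erv in ervs:
        nearest_dist: int | None = None
        nearest_id: str | None = None
        for p in by_chrom.get(erv.chrom, ()):
            d = interval_distance(erv.start, erv.end, p.start, p.end)
            if (
                nearest_dist is None
                or d < nearest_dist
                or (d == nearest_dist and p.peak_id < nearest_id)
            ):
                nearest_dist, nearest_id = d, p.peak_id
        chosen = None
        if nearest_dist is not None:
            for w in windows:
                if nearest_dist <= w * 1000:
                    chosen = w
                    break
        if chosen is None:
            annotations.append(
                ProximityAnnotation(erv.erv_id, "none", None, nearest_dist or 0)
            )
        elif chosen == 0:
            annotations.append(
                ProximityAnnotation(erv.erv_id, "superimposed", 0, 0, nearest_id)
            )
        else:
            annotations.append(
                ProximityAnnotation(
                    erv.erv_id, "within_window", chosen, nearest_dist, nearest_id
                )
            )
    return annotations


def write_proximity_tsv(annotations: Iterable[ProximityAnnotation], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["erv_id", "peak_id", "relation", "window_kb", "distance_bp"])
        for a in annotations:
            w.writerow(
                [
                    a.erv_id,
                    a.nearest_peak_id or ".",
                    a.relation,
                    "." if a.window_kb is None else a.window_kb,
                    a.distance_bp,
                ]
            )
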