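"""ERV expression quantification from alignment evidence.

Counting model: reads failing the transcriptome are aligned to the ERV
reference.  Paired-end fragments are kept when both mates perfectly match a
common ERV (PM) or when at most one mismatch is present across both mates
against a common ERV (1MM).  Single ends are kept when they (i) perfectly
match an ERV, (ii) are not part of any retained PM/1MM pair, and (iii) do not
match the transcriptome.  After fragment deduplication, raw expression is

    2 * (n_pe_pm + n_pe_1mm) + n_se

normalized per million library reads and per kilobase of ERV length.
"""

from __future__ import annotations

import csv
import math
from collections import OrderedDict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "ReadAlignment",
    "FragmentEvidence",
    "ErvCount",
    "ComparisonResult",
    "CandidateSet",
    "partition_reads",
    "classify_pair",
    "retain_single_end",
    "deduplicate_fragments",
    "compute_erv_expression",
    "normalize_expression",
    "quantify_sample",
    "call_responsive",
    "tier_and_union",
    "read_alignment_tsv",
    "write_counts_tsv",
]


@dataclass(frozen=True)
class ReadAlignment:
    """One read's alignment evidence: transcriptome status plus ERV hits."""

    read_id: str
    mate: str  # "1", "2", or "single"
    transcriptome_mapped: bool
    erv_hits: tuple[tuple[str, int], ...]  # (erv_id, n_mismatch)
    frag_pos: int = 0
    orient: str = "+"

    def __post_init__(self) -> None:
        if self.mate not in ("1", "2", "single"):
            raise ValueError(f"invalid mate {self.mate!r}")
        for erv_id, nm in self.erv_hits:
            if nm < 0:
                raise ValueError(f"negative mismatch count for {erv_id}")

    def best_hits(self) -> dict[str, int]:
        """erv_id -> minimum mismatch count among this read's hits."""
        best: dict[str, int] = {}
        for erv_id, nm in self.erv_hits:
            if erv_id not in best or nm < best[erv_id]:
                best[erv_id] = nm
        return best


@dataclass(frozen=True)
class FragmentEvidence:
    """One retained fragment-to-ERV assignment (pre- or post-dedup)."""

    kind: str  # "PE" or "SE"
    category: str  # "PM", "MM1", or "SE"
    erv_id: str
    frag_pos: int
    orient: str
    read_id: str

    @property
    def fragment_key(self) -> tuple[str, str, int, str]:
        return (self.kind, self.erv_id, self.frag_pos, self.orient)


@dataclass
class ErvCount:
    """Per-ERV retained evidence counts and expression."""

    erv_id: str
    n_pe_pm: int
    n_pe_1mm: int
    n_se: int
    library_size: int
    erv_length: int

    @property
    def expression_raw(self) -> int:
        return 2 * (self.n_pe_pm + self.n_pe_1mm) + self.n_se

    @property
    def expression_norm(self) -> float:
        return normalize_expression(self)


@dataclass(frozen=True)
class ComparisonResult:
    erv_id: str
    comparison: str
    log2fc: float
    responsive: bool


@dataclass
class CandidateSet:
    """Non-redundant candidate union with per-cell-line provenance."""

    erv_ids: list[str]
    provenance: dict[str, dict[str, dict]] = field(default_factory=dict)
    # provenance[erv_id][cell_line] = {"tier": ..., "polysome": bool}


def partition_reads(
    alignments: Iterable[ReadAlignment],
) -> tuple[list[ReadAlignment], list[ReadAlignment]]:
    """Split reads into (transcriptome-mapped, ERV candidates)."""
    mapped, candidates = [], []
    for r in alignments:
        (mapped if r.transcriptome_mapped else candidates).append(r)
    return mapped, candidates


def classify_pair(
    r1: ReadAlignment, r2: ReadAlignment
) -> tuple[str, tuple[str, ...]]:
    """Classify a mate pair as PM, MM1, or none against common ERVs.

    PM: some common ERV hit by both mates with 0 mismatches each.
    MM1: some common ERV with total mismatches across both mates <= 1.
    The winning ERV ids are all ERVs meeting the achieved category, so a
    multi-mapping fragment counts toward every such ERV.
    """
    if r1.read_id != r2.read_id:
        raise ValueError(f"mates from different reads: {r1.read_id} vs {r2.read_id}")
    if {r1.mate, r2.mate} != {"1", "2"}:
        raise ValueError("classify_pair requires mates 1 and 2")
    h1, h2 = r1.best_hits(), r2.best_hits()
    common = h1.keys() & h2.keys()
    pm = sorted(e for e in common if h1[e] == 0 and h2[e] == 0)
    if pm:
        return "PM", tuple(pm)
    mm1 = sorted(e for e in common if h1[e] + h2[e] <= 1)
    if mm1:
        return "MM1", tuple(mm1)
    return "none", ()


def retain_single_end(
    read: ReadAlignment, paired_read_ids: frozenset[str] | set[str]
) -> tuple[bool, tuple[str, ...]]:
    """Apply the three single-end retention criteria.

    Returns (retained, perfect-match erv ids).  ``paired_read_ids`` holds the
    ids of reads already retained as part of a PM/1MM pair.
    """
    if read.transcriptome_mapped:  # criterion (iii)
        return False, ()
    if read.read_id in paired_read_ids:  # criterion (ii)
        return False, ()
    perfect = tuple(sorted(e for e, nm in read.best_hits().items() if nm == 0))
    if not perfect:  # criterion (i)
        return False, ()
    return True, perfect


def deduplicate_fragments(
    evidence: Sequence[FragmentEvidence],
) -> list[FragmentEvidence]:
    """Keep the first record per fragment key; idempotent."""
    seen: set[tuple] = set()
    kept = []
    for ev in evidence:
        if ev.fragment_key not in seen:
            seen.add(ev.fragment_key)
            kept.append(ev)
    return kept


def compute_erv_expression(
    erv_id: str,
    evidence: Sequence[FragmentEvidence],
    library_size: int,
    erv_length: int,
) -> ErvCount:
    """Tally deduplicated evidence for one ERV into an ErvCount."""
    n_pm = sum(1 for e in evidence if e.erv_id == erv_id and e.category == "PM")
    n_mm1 = sum(1 for e in evidence if e.erv_id == erv_id and e.category == "MM1")
    n_se = sum(1 for e in evidence if e.erv_id == erv_id and e.category == "SE")
    return ErvCount(erv_id, n_pm, n_mm1, n_se, library_size, erv_length)


def normalize_expression(count: ErvCount) -> float:
    """Raw expression per million library reads per kilobase of ERV."""
    if count.library_size <= 0:
        raise ValueError("library_size must be > 0")
    if count.erv_length <= 0:
        raise ValueError("erv_length must be > 0")
    return count.expression_raw / (count.library_size / 1e6) / (count.erv_length / 1e3)


def collect_evidence(alignments: Sequence[ReadAlignment]) -> list[FragmentEvidence]:
    """Run partition -> pair classification -> single-end retention and
    return the raw (pre-dedup) fragment evidence list."""
    _, candidates = partition_reads(alignments)
    by_read: dict[str, dict[str, ReadAlignment]] = OrderedDict()
    singles: list[ReadAlignment] = []
    for r in candidates:
        if r.mate == "single":
            singles.append(r)
        else:
            by_read.setdefault(r.read_id, {})[r.mate] = r

    evidence: list[FragmentEvidence] = []
    paired_ids: set[str] = set()
    leftover: list[ReadAlignment] = []
    for read_id, mates in by_read.items():
        if len(mates) == 2:
            category, winners = classify_pair(mates["1"], mates["2"])
            if category in ("PM", "MM1"):
                paired_ids.add(read_id)
                pos = min(mates["1"].frag_pos, mates["2"].frag_pos)
                for erv_id in winners:
                    evidence.append(
                        FragmentEvidence("PE", category, erv_id, pos,
                                         mates["1"].orient, read_id)
                    )
                continue
        leftover.extend(mates.values())

    for r in leftover + singles:
        retained, winners = retain_single_end(r, paired_ids)
        if retained:
            for erv_id in winners:
                evidence.append(
                    FragmentEvidence("SE", "SE", erv_id, r.frag_pos, r.orient, r.read_id)
                )
    return evidence


def quantify_sample(
    alignments: Sequence[ReadAlignment],
    erv_lengths: Mapping[str, int],
    library_size: int | None = None,
) -> dict[str, ErvCount]:
    """Full per-sample quantification: retention, dedup, counting, per ERV.

    ``library_size`` defaults to the number of input read records (all mates,
    including transcriptome-mapped reads).
    """
    if library_size is None:
        library_size = len(alignments)
    evidence = deduplicate_fragments(collect_evidence(alignments))
    counts = {}
    for erv_id, length in erv_lengths.items():
        counts[erv_id] = compute_erv_expression(erv_id, evidence, library_size, length)
    return counts


def call_responsive(
    high: Sequence[float],
    low: Sequence[float],
    comparison: str = "",
    erv_id: str = "",
    pseudocount: float = 1.0,
    log2fc_min: float = 1.0,
    min_expr: float = 1.0,
) -> ComparisonResult:
    """Default responsiveness rule: log2((mean_high+c)/(mean_low+c)) >=
    ``log2fc_min`` and mean_high >= ``min_expr``.  The per-comparison scoring
    criterion is configurable; these defaults are a declared stand-in."""
    if not len(high) or not len(low):
        raise ValueError("both arms need >= 1 replicate")
    mean_high = sum(high) / len(high)
    mean_low = sum(low) / len(low)
    log2fc = math.log2((mean_high + pseudocount) / (mean_low + pseudocount))
    responsive = log2fc >= log2fc_min and mean_high >= min_expr
    return ComparisonResult(erv_id, comparison, log2fc, responsive)


_TIER_ORDER = {"all_three": 3, "two_of_three": 2, "fewer": 0}


def _tier(flags: Sequence[bool]) -> str:
    n = sum(bool(f) for f in flags)
    if n == 3:
        return "all_three"
    if n == 2:
        return "two_of_three"
    return "fewer"


def tier_and_union(
    flags_by_cell_line: Mapping[str, Mapping[str, Sequence[bool]]],
    polysome_by_cell_line: Mapping[str, Mapping[str, bool]] | None = None,
) -> CandidateSet:
    """Tier each ERV per cell line and take the non-redundant candidate union.

    An ERV is a candidate when it scored in >= 2 of the 3 pairwise
    comparisons of some cell line, or was polysome-responsive there, or both.
    """
    polysome_by_cell_line = polysome_by_cell_line or {}
    provenance: dict[str, dict[str, dict]] = {}
    candidates: set[str] = set()
    cell_lines = set(flags_by_cell_line) | set(polysome_by_cell_line)
    for cell in sorted(cell_lines):
        flags = flags_by_cell_line.get(cell, {})
        poly = polysome_by_cell_line.get(cell, {})
        for erv_id in set(flags) | set(poly):
            tier = _tier(flags.get(erv_id, ()))
            is_poly = bool(poly.get(erv_id, False))
            provenance.setdefault(erv_id, {})[cell] = {
                "tier": tier,
                "polysome": is_poly,
            }
            if _TIER_ORDER[tier] >= 2 or is_poly:
                candidates.add(erv_id)
    return CandidateSet(
        sorted(candidates),
        {e: provenance[e] for e in sorted(provenance)},
    )


# -- plain-text I/O -----------------------------------------------------------

_ALIGN_HEADER = ["read_id", "mate", "txome_mapped", "erv_id", "nm", "frag_pos", "orient"]


def read_alignment_tsv(path: str | Path) -> list[ReadAlignment]:
    """Read the simplified alignment TSV; rows sharing (read_id, mate) merge
    into one record with several ERV hits.  erv_id '.' means no ERV hit."""
    grouped: "OrderedDict[tuple[str, str], dict]" = OrderedDict()
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None:
            return []
        if [h.strip() for h in header] != _ALIGN_HEADER:
            raise ValueError(f"unexpected alignment header: {header}")
        for row in reader:
            if not row or not row[0]:
                continue
            read_id, mate, txome, erv_id, nm, frag_pos, orient = row
            key = (read_id, mate)
            rec = grouped.setdefault(
                key,
                {
                    "txome": txome == "1",
                    "hits": [],
                    "frag_pos": int(frag_pos),
                    "orient": orient,
                },
            )
            if erv_id != ".":
                rec["hits"].append((erv_id, int(nm)))
    return [
        ReadAlignment(read_id, mate, rec["txome"], tuple(rec["hits"]),
                      rec["frag_pos"], rec["orient"])
        for (read_id, mate), rec in grouped.items()
    ]


def write_alignment_tsv(alignments: Iterable[ReadAlignment], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_ALIGN_HEADER)
        for r in alignments:
            hits = r.erv_hits or ((".", 0),)
            for erv_id, nm in hits:
                w.writerow(
                    [r.read_id, r.mate, int(r.transcriptome_mapped), erv_id, nm,
                     r.frag_pos, r.orient]
                )


def write_counts_tsv(counts: Mapping[str, ErvCount], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["erv_id", "n_pe_pm", "n_pe_1mm", "n_se",
                    "expression_raw", "expression_norm"])
        for erv_id in sorted(counts):
            c = counts[erv_id]
            w.writerow([c.erv_id, c.n_pe_pm, c.n_pe_1mm, c.n_se,
                        c.expression_raw, f"{c.expression_norm:.6g}"])
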