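"""Six-frame proteogenomic search-space construction and peptide source mapping.

ORFs are maximal stop-free stretches of the translation of each of the six
reading frames, with no start-codon requirement by default.  Peptide matching
treats isoleucine and leucine as one symbol because they are isobaric.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import reverse_complement

__all__ = [
    "OrfProtein",
    "DbEntry",
    "SearchDatabase",
    "SourceMatch",
    "PeptideSourceMap",
    "six_frame_orfs",
    "build_search_db",
    "read_fasta_entries",
    "unique_kmer_contribution",
    "map_peptide_sources",
    "collapse_il",
]

_NT_ALPHABET = frozenset("ACGTN")

# 64-codon lookup from the standard genetic code; stops are '*'.
_CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON_TABLE[_stop] = "*"

SOURCE_CLASSES = ("reference", "contaminant", "erv")


@dataclass(frozen=True)
class OrfProtein:
    """One stop-free translation stretch from a single reading frame.

    ``frame`` is +1/+2/+3 for the forward strand and -1/-2/-3 for the
    reverse complement; ``aa_offset`` is the 0-based position of the stretch
    within that frame's full translation.
    """

    source_id: str
    frame: int
    aa_offset: int
    sequence: str

    def __post_init__(self) -> None:
        if "*" in self.sequence:
            raise ValueError("ORF sequence may not contain a stop symbol")
        if self.frame not in (1, 2, 3, -1, -2, -3):
            raise ValueError(f"invalid frame {self.frame}")


@dataclass(frozen=True)
class DbEntry:
    accession: str
    sequence: str
    source_class: str
    description: str = ""


@dataclass
class SearchDatabase:
    """Merged target database: reference proteome + ERV ORFs (+ contaminants)."""

    entries: list[DbEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for e in self.entries:
            if e.accession in seen:
                raise ValueError(f"duplicate accession {e.accession!r}")
            if not e.sequence:
                raise ValueError(f"empty sequence for {e.accession!r}")
            seen.add(e.accession)

    def __len__(self) -> int:
        return len(self.entries)

    def by_class(self, source_class: str) -> list[DbEntry]:
        return [e for e in self.entries if e.source_class == source_class]

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for e in self.entries:
                desc = f" {e.description}" if e.description else ""
                fh.write(f">{e.accession} |class={e.source_class}|{desc}\n")
                for i in range(0, len(e.sequence), 60):
                    fh.write(e.sequence[i : i + 60] + "\n")


def _translate_frame(nt: str) -> str:
    """Translate a frame-aligned nucleotide string, dropping the trailing
    partial codon.  Codons containing N translate to 'X'; X never terminates
    an ORF but also never matches a peptide query downstream."""
    aas = []
    for i in range(0, len(nt) - len(nt) % 3, 3):
        codon = nt[i : i + 3]
        aas.append(_CODON_TABLE.get(codon, "X"))
    return "".join(aas)


def six_frame_orfs(
    seq: str,
    min_protein_length: int = 7,
    require_met: bool = False,
    source_id: str = "",
) -> list[OrfProtein]:
    """Enumerate ORFs (maximal stop-free stretches) in all six frames.

    With ``require_met`` each stretch is trimmed to begin at its first
    methionine before the length check.
    """
    if min_protein_length < 1:
        raise ValueError("min_protein_length must be >= 1")
    seq = seq.upper()
    bad = set(seq) - _NT_ALPHABET
    if bad:
        raise ValueError(f"invalid nucleotide characters: {sorted(bad)}")
    orfs: list[OrfProtein] = []
    for strand_sign, strand_seq in ((1, seq), (-1, reverse_complement(seq))):
        for offset in range(3):
            frame = strand_sign * (offset + 1)
            protein = _translate_frame(strand_seq[offset:])
            pos = 0
            for stretch in protein.split("*"):
                if stretch:
                    aa_offset, candidate = pos, stretch
                    if require_met:
                        m = candidate.find("M")
                        if m == -1:
                            candidate = ""
                        else:
                            candidate = candidate[m:]
                            aa_offset += m
                    if len(candidate) >= min_protein_length:
                        orfs.append(OrfProtein(source_id, frame, aa_offset, candidate))
                pos += len(stretch) + 1
    return orfs


def read_fasta_entries(path: str | Path) -> list[tuple[str, str]]:
    """Read (accession, sequence) pairs; accession is the first header token."""
    from Bio import SeqIO

    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def build_search_db(
    reference: Sequence[tuple[str, str]],
    erv_orfs: Sequence[OrfProtein],
    contaminants: Sequence[tuple[str, str]] = (),
) -> SearchDatabase:
    """Merge reference proteome, contaminants, and ERV ORF proteins.

    ERV ORFs receive accessions ``ERV|<source_id>|<frame>|<aa_offset>``.
    Exact duplicate sequences within one source class collapse to a single
    entry; the first accession wins and the description lists every source.
    """
    if not reference:
        raise ValueError("reference proteome must be non-empty")
    entries: list[DbEntry] = []
    seen_acc: set[str] = set()

    def _add_class(pairs: Iterable[tuple[str, str, str]], source_class: str) -> None:
        by_seq: dict[str, int] = {}
        for acc, seq, src in pairs:
            if not seq:
                raise ValueError(f"empty sequence for {acc!r}")
            if seq in by_seq:
                idx = by_seq[seq]
                prev = entries[idx]
                entries[idx] = DbEntry(
                    prev.accession,
                    prev.sequence,
                    prev.source_class,
                    prev.description + f" sources={src}" if src else prev.description,
                )
                continue
            if acc in seen_acc:
                raise ValueError(f"duplicate accession {acc!r} across inputs")
            seen_acc.add(acc)
            by_seq[seq] = len(entries)
            entries.append(DbEntry(acc, seq, source_class, f"sources={src}" if src else ""))

    _add_class(((a, s, "") for a, s in reference), "reference")
    _add_class(((a, s, "") for a, s in contaminants), "contaminant")
    _add_class(
        (
            (f"ERV|{o.source_id}|{o.frame:+d}|{o.aa_offset}", o.sequence, o.source_id)
            for o in erv_orfs
        ),
        "erv",
    )
    return SearchDatabase(entries)


def collapse_il(seq: str) -> str:
    """Collapse the isobaric residues I and L to one symbol (J)."""
    return seq.replace("I", "J").replace("L", "J")


def unique_kmer_contribution(
    db: SearchDatabase, k: int = 9
) -> dict[str, tuple[int, float]]:
    """Count distinct I/L-collapsed k-mers attributable to each source class.

    A k-mer occurring in several classes is attributed once, by priority
    reference > contaminant > erv.  Fractions are over all distinct k-mers
    and sum to 1 when any exist.  k-mers containing X are skipped (they can
    never match a peptide).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    kmers_by_class: dict[str, set[str]] = {}
    for e in db.entries:
        s = collapse_il(e.sequence)
        bucket = kmers_by_class.setdefault(e.source_class, set())
        for i in range(len(s) - k + 1):
            kmer = s[i : i + k]
            if "X" not in kmer:
                bucket.add(kmer)
    claimed: set[str] = set()
    counts: dict[str, int] = {}
    for cls in SOURCE_CLASSES:
        if cls not in kmers_by_class:
            continue
        own = kmers_by_class[cls] - claimed
        counts[cls] = len(own)
        claimed |= kmers_by_class[cls]
    total = sum(counts.values())
    return {
        cls: (n, n / total if total else 0.0) for cls, n in counts.items()
    }


@dataclass(frozen=True)
class SourceMatch:
    accession: str
    source_class: str
    position: int


@dataclass(frozen=True)
class PeptideSourceMap:
    """Every database location a peptide could originate from."""

    peptide: str
    matches: tuple[SourceMatch, ...]
    il_collapsed: bool

    @property
    def erv_exclusive(self) -> bool:
        """True iff the peptide maps to >=1 ERV entry and no reference entry."""
        classes = {m.source_class for m in self.matches}
        return "erv" in classes and "reference" not in classes

    @property
    def source_ervs(self) -> tuple[str, ...]:
        ids = sorted(
            {m.accession.split("|")[1] for m in self.matches if m.source_class == "erv"}
        )
        return tuple(ids)


def map_peptide_sources(
    peptide: str, db: SearchDatabase, collapse_il_flag: bool = True
) -> PeptideSourceMap:
    """Locate every substring occurrence of ``peptide`` in the database,
    treating I and L as identical when ``collapse_il_flag``."""
    if not peptide:
        raise ValueError("peptide must be non-empty")
    # 'X' in database entries is an ambiguity placeholder and must never
    # match; querying with a sentinel guarantees that.
    query = peptide.upper().replace("X", "\x00")
    if collapse_il_flag:
        query = collapse_il(query)
    matches: list[SourceMatch] = []
    for e in db.entries:
        hay = collapse_il(e.sequence) if collapse_il_flag else e.sequence
        start = hay.find(query)
        while start != -1:
            matches.append(SourceMatch(e.accession, e.source_class, start))
            start = hay.find(query, start + 1)
    return PeptideSourceMap(peptide.upper(), tuple(matches), collapse_il_flag)


def write_source_map_tsv(maps: Iterable[PeptideSourceMap], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["peptide", "accession", "source_class", "position", "erv_exclusive"])
        for m in maps:
            if not m.matches:
                w.writerow([m.peptide, ".", ".", ".", str(m.erv_exclusive).lower()])
            for hit in m.matches:
                w.writerow(
                    [m.peptide, hit.accession, hit.source_class, hit.position,
                     str(m.erv_exclusive).lower()]
                )
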