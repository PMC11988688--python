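"""PSM-level filtering: target-decoy FDR, fixed thresholds, strike
classification, and the final peptide call chain.

Boundary semantics follow the printed rules: "minimum" thresholds are
inclusive; the spectral-similarity check passes strictly above 0.6; the
retention-time check passes within +/- 10 min inclusive; the binding check
passes strictly below percentile rank 2.0.  A PSM accumulating 0 strikes
passes, 1 is a maybe, and 2 or 3 fail.
"""

from __future__ import annotations

import csv
import math
import warnings
from collections import OrderedDict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "PsmRecord",
    "StrikeResult",
    "FdrResult",
    "PeptideCall",
    "PeptideCallSet",
    "estimate_fdr_threshold",
    "apply_fixed_thresholds",
    "spectral_angle",
    "select_rt_calibration",
    "strike_classify",
    "binder_category",
    "sequence_tag_length",
    "peptide_monoisotopic_mass",
    "label_shift",
    "hamming_distance",
    "finalize_peptide_calls",
    "read_psm_tsv",
    "write_psm_tsv",
    "MONOISOTOPIC_RESIDUE_MASSES",
    "WATER_MONOISOTOPIC",
]

# Monoisotopic residue (in-chain) masses, Da.
MONOISOTOPIC_RESIDUE_MASSES: dict[str, float] = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}
WATER_MONOISOTOPIC = 18.0105646863

# Isotope monoisotopic masses for heavy-label arithmetic.
_M_12C, _M_13C = 12.0, 13.00335483507
_M_14N, _M_15N = 14.00307400443, 15.00010889888


@dataclass(frozen=True)
class PsmRecord:
    """One peptide-spectrum match with engine and rescoring metrics."""

    psm_id: str
    peptide: str
    charge: int
    sm_score: float
    spi_pct: float
    bcs: float
    rt_obs_min: float
    rt_pred_min: float
    hla_rank: float
    is_decoy: bool = False
    sample_id: str = ""
    run_id: str = ""
    tissue: str = "tumor"
    source_class: str = ""
    by_obs: Mapping[str, float] = field(default_factory=dict)
    by_pred: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.spi_pct <= 100.0:
            raise ValueError(f"{self.psm_id}: spi_pct must be in [0, 100]")
        if self.hla_rank < 0:
            raise ValueError(f"{self.psm_id}: hla_rank must be >= 0")

    @property
    def delta_rt_min(self) -> float:
        return self.rt_obs_min - self.rt_pred_min


@dataclass(frozen=True)
class StrikeResult:
    psm_id: str
    sa_dp: float
    delta_rt_min: float
    binder_category: str
    strikes: int
    verdict: str


@dataclass
class FdrResult:
    """Score cutoffs, per-PSM q-values, and the accepted target PSMs."""

    cutoffs: dict[str, float]
    qvalues: dict[str, float]
    accepted: list[PsmRecord]


def _fdr_curve(
    psms: Sequence[PsmRecord],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Scores sorted descending with FDR and q-value at each position.

    FDR(s) = #decoys(score >= s) / max(1, #targets(score >= s)); the q-value
    is the running minimum of FDR over descending score.
    """
    order = sorted(psms, key=lambda p: -p.sm_score)
    scores = np.array([p.sm_score for p in order])
    decoy = np.cumsum([p.is_decoy for p in order])
    target = np.cumsum([not p.is_decoy for p in order])
    fdr = decoy / np.maximum(1, target)
    # ties: every PSM at a tied score shares the worst (last) FDR of the tie
    for i in range(len(order) - 2, -1, -1):
        if scores[i] == scores[i + 1]:
            fdr[i] = fdr[i + 1]
    q = np.minimum.accumulate(fdr[::-1])[::-1]
    return scores, fdr, np.array([p.psm_id for p in order]), q


def _threshold_one(
    psms: Sequence[PsmRecord], level: float
) -> tuple[float, dict[str, float]]:
    targets = [p for p in psms if not p.is_decoy]
    if not targets:
        raise ValueError("no target PSMs supplied")
    if not any(p.is_decoy for p in psms):
        warnings.warn("no decoy PSMs: FDR estimate is 0, accepting all targets")
        return min(p.sm_score for p in targets), {p.psm_id: 0.0 for p in psms}
    scores, fdr, ids, q = _fdr_curve(psms)
    qvalues = dict(zip(ids, q))
    passing = scores[q <= level]
    if len(passing) == 0:
        cutoff = math.inf  # nothing reaches the level
    else:
        cutoff = float(passing.min())
    return cutoff, qvalues


def estimate_fdr_threshold(
    psms: Sequence[PsmRecord], level: float = 0.01, scope: str = "aggregate"
) -> FdrResult:
    """Choose the smallest score cutoff achieving FDR <= ``level``.

    ``scope="aggregate"`` thresholds the whole set at once.  ``scope="run"``
    thresholds each ``run_id`` first, then re-checks the pooled survivors in
    aggregate and tightens globally if needed, so both the per-run and the
    aggregate guarantees hold.
    """
    if scope not in ("aggregate", "run"):
        raise ValueError(f"unknown scope {scope!r}")
    if scope == "aggregate":
        cutoff, qvalues = _threshold_one(psms, level)
        accepted = [p for p in psms if not p.is_decoy and p.sm_score >= cutoff]
        return FdrResult({"aggregate": cutoff}, qvalues, accepted)

    cutoffs: dict[str, float] = {}
    qvalues: dict[str, float] = {}
    survivors: list[PsmRecord] = []
    runs: "OrderedDict[str, list[PsmRecord]]" = OrderedDict()
    for p in psms:
        runs.setdefault(p.run_id, []).append(p)
    for run_id, run_psms in runs.items():
        cutoff, run_q = _threshold_one(run_psms, level)
        cutoffs[run_id] = cutoff
        qvalues.update(run_q)
        survivors.extend(p for p in run_psms if p.sm_score >= cutoff)
    agg_cutoff, _ = _threshold_one(survivors, level) if survivors else (math.inf, {})
    cutoffs["aggregate"] = agg_cutoff
    accepted = [
        p for p in survivors if not p.is_decoy and p.sm_score >= agg_cutoff
    ]
    return FdrResult(cutoffs, qvalues, accepted)


def apply_fixed_thresholds(
    psms: Iterable[PsmRecord],
    min_score: float = 7.0,
    min_spi_pct: float = 50.0,
    min_bcs: float = 5.0,
    charge_range: tuple[int, int] = (1, 4),
    length_range: tuple[int, int] = (8, 11),
) -> list[PsmRecord]:
    """Tightened fixed thresholds; all minima and both ranges are inclusive."""
    lo_z, hi_z = charge_range
    lo_l, hi_l = length_range
    return [
        p
        for p in psms
        if p.sm_score >= min_score
        and p.spi_pct >= min_spi_pct
        and p.bcs >= min_bcs
        and lo_z <= p.charge <= hi_z
        and lo_l <= len(p.peptide) <= hi_l
    ]


def spectral_angle(
    by_obs: Mapping[str, float], by_pred: Mapping[str, float]
) -> float:
    """Normalized spectral contrast angle between two b/y intensity vectors.

    Vectors are aligned on the union of ion labels (missing = 0) and
    L2-normalized; the similarity is 1 - 2*arccos(cos theta)/pi, clipped to
    [0, 1].  If either aligned vector is all-zero the similarity is 0.
    """
    labels = sorted(set(by_obs) | set(by_pred))
    a = np.array([by_obs.get(l, 0.0) for l in labels], dtype=float)
    b = np.array([by_pred.get(l, 0.0) for l in labels], dtype=float)
    if (a < 0).any() or (b < 0).any():
        raise ValueError("ion intensities must be non-negative")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        return 0.0
    cos = float(np.clip(a @ b / (na * nb), -1.0, 1.0))
    return float(np.clip(1.0 - 2.0 * math.acos(cos) / math.pi, 0.0, 1.0))


def select_rt_calibration(
    psms: Sequence[PsmRecord], n_segments: int = 50, top_k: int = 15
) -> list[PsmRecord]:
    """Pick the retention-time calibration subset: split the observed RT
    range into ``n_segments`` equal-width bins and keep the ``top_k``
    highest-scoring reference-proteome PSMs per bin."""
    if n_segments < 1 or top_k < 1:
        raise ValueError("n_segments and top_k must be >= 1")
    if not psms:
        return []
    rts = [p.rt_obs_min for p in psms]
    lo, hi = min(rts), max(rts)
    width = (hi - lo) / n_segments if hi > lo else 1.0
    bins: dict[int, list[PsmRecord]] = {}
    for p in psms:
        if p.source_class != "reference":
            continue
        idx = min(n_segments - 1, int((p.rt_obs_min - lo) / width))
        bins.setdefault(idx, []).append(p)
    subset: list[PsmRecord] = []
    for idx in sorted(bins):
        ranked = sorted(bins[idx], key=lambda p: -p.sm_score)
        subset.extend(ranked[:top_k])
    return subset


def binder_category(hla_rank: float) -> str:
    """<0.5 strong; 0.5-2 weak (inclusive); >2 non-binder."""
    if hla_rank < 0:
        raise ValueError("hla_rank must be >= 0")
    if hla_rank < 0.5:
        return "strong"
    if hla_rank <= 2.0:
        return "weak"
    return "non"


def strike_classify(
    sa_dp: float,
    delta_rt_min: float,
    hla_rank: float,
    psm_id: str = "",
    sa_min: float = 0.6,
    rt_tol_min: float = 10.0,
    rank_max: float = 2.0,
) -> StrikeResult:
    """Count strikes against the three rescoring checks and render a verdict.

    Pass conditions: sa_dp > 0.6; |delta RT| <= 10 min; rank < 2.0.
    Verdict: 0 strikes pass, 1 maybe, 2 or 3 fail.
    """
    strikes = 0
    if not sa_dp > sa_min:
        strikes += 1
    if not abs(delta_rt_min) <= rt_tol_min:
        strikes += 1
    if not hla_rank < rank_max:
        strikes += 1
    verdict = "pass" if strikes == 0 else ("maybe" if strikes == 1 else "fail")
    return StrikeResult(
        psm_id, sa_dp, delta_rt_min, binder_category(hla_rank), strikes, verdict
    )


def sequence_tag_length(
    peaks: Sequence[float],
    residue_masses: Mapping[str, float] | None = None,
    tol: float = 0.01,
) -> int:
    """Longest run of peaks consecutively separated by residue masses.

    Builds a DAG on the sorted peak list with an edge u -> v whenever the m/z
    difference matches some residue mass within +/- tol, and returns the
    longest path length in edges.  A spectrum passes the quality filter when
    the result exceeds 1 (three peaks spanning two residues).
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    masses = list((residue_masses or MONOISOTOPIC_RESIDUE_MASSES).values())
    pk = sorted(peaks)
    n = len(pk)
    best = [0] * n  # longest tag ending at peak i, in edges
    for i in range(n):
        for j in range(i):
            diff = pk[i] - pk[j]
            if any(abs(diff - m) <= tol for m in masses):
                best[i] = max(best[i], best[j] + 1)
    return max(best, default=0)


def peptide_monoisotopic_mass(
    peptide: str, modifications: Mapping[str, float] | None = None
) -> float:
    """Monoisotopic peptide mass: sum of residue masses plus water, with an
    optional per-residue modification mass map (e.g. {"C": +57.02146})."""
    if not peptide:
        raise ValueError("peptide must be non-empty")
    modifications = modifications or {}
    mass = WATER_MONOISOTOPIC
    for aa in peptide.upper():
        try:
            mass += MONOISOTOPIC_RESIDUE_MASSES[aa]
        except KeyError:
            raise ValueError(f"unknown residue {aa!r}") from None
        mass += modifications.get(aa, 0.0)
    return mass


def label_shift(label: str = "lys8") -> float:
    """Mass shift of a heavy-isotope label.  lys8 = 6x(13C-12C) + 2x(15N-14N)."""
    if label != "lys8":
        raise ValueError(f"unknown label {label!r}")
    return 6 * (_M_13C - _M_12C) + 2 * (_M_15N - _M_14N)


def hamming_distance(a: str, b: str) -> int:
    """Number of differing positions between two equal-length sequences."""
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class PeptideCall:
    peptide: str
    psm_id: str
    sample_id: str
    verdict: str
    source_ervs: tuple[str, ...]


@dataclass
class PeptideCallSet:
    """Final peptide list plus a per-stage audit of surviving counts."""

    audit: "OrderedDict[str, int]"
    calls: list[PeptideCall]


def _il_key(peptide: str) -> str:
    return peptide.replace("I", "J").replace("L", "J")


def finalize_peptide_calls(
    psms: Sequence[PsmRecord],
    source_maps: Mapping[str, object],
    strikes: Mapping[str, StrikeResult],
    normal_peptides: Iterable[str] = (),
) -> PeptideCallSet:
    """Run the terminal peptide filter chain with a stage audit.

    Stages, in order: (1) drop peptides that also map to the reference
    proteome (I/L-aware, via their source maps); (2) drop peptides detected
    in any normal-tissue sample; (3) collapse to one call per peptide,
    keeping the best-scoring PSM; (4) drop cysteine-containing peptides;
    (5) drop peptides whose verdict is fail (>= 2 strikes).

    ``source_maps`` maps peptide -> PeptideSourceMap; ``normal_peptides`` are
    additional normal-tissue detections beyond any tissue="normal" PSMs in
    the input.
    """
    audit: "OrderedDict[str, int]" = OrderedDict()
    normal_set = {_il_key(p) for p in normal_peptides}
    normal_set |= {_il_key(p.peptide) for p in psms if p.tissue == "normal"}
    pool = [p for p in psms if p.tissue != "normal" and not p.is_decoy]
    audit["input"] = len(pool)

    kept = []
    for p in pool:
        smap = source_maps.get(p.peptide)
        if smap is None:
            raise KeyError(f"no source map for peptide {p.peptide} (psm {p.psm_id})")
        if smap.erv_exclusive:
            kept.append(p)
    pool = kept
    audit["reference_collision"] = len(pool)

    pool = [p for p in pool if _il_key(p.peptide) not in normal_set]
    audit["normal_tissue"] = len(pool)

    best: "OrderedDict[str, PsmRecord]" = OrderedDict()
    for p in pool:
        cur = best.get(p.peptide)
        if cur is None or p.sm_score > cur.sm_score:
            best[p.peptide] = p
    pool = list(best.values())
    audit["redundancy"] = len(pool)

    pool = [p for p in pool if "C" not in p.peptide]
    audit["cysteine"] = len(pool)

    calls = []
    for p in pool:
        strike = strikes.get(p.psm_id)
        if strike is None:
            raise KeyError(f"no strike verdict for psm {p.psm_id}")
        if strike.verdict != "fail":
            calls.append(
                PeptideCall(
                    p.peptide,
                    p.psm_id,
                    p.sample_id,
                    strike.verdict,
                    tuple(source_maps[p.peptide].source_ervs),
                )
            )
    audit["strike_fail"] = len(calls)
    return PeptideCallSet(audit, calls)


# -- plain-text I/O -----------------------------------------------------------

_PSM_HEADER = [
    "psm_id", "peptide", "charge", "sm_score", "spi_pct", "bcs",
    "rt_obs_min", "rt_pred_min", "hla_rank", "is_decoy", "sample_id",
    "run_id", "tissue", "source_class", "by_obs", "by_pred",
]


def _ions_to_str(ions: Mapping[str, float]) -> str:
    return ";".join(f"{k}:{ions[k]:.6g}" for k in sorted(ions))


def _ions_from_str(s: str) -> dict[str, float]:
    if not s or s == ".":
        return {}
    out = {}
    for part in s.split(";"):
        label, _, val = part.rpartition(":")
        out[label] = float(val)
    return out


def write_psm_tsv(psms: Iterable[PsmRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_PSM_HEADER)
        for p in psms:
            w.writerow(
                [
                    p.psm_id, p.peptide, p.charge, f"{p.sm_score:.6g}",
                    f"{p.spi_pct:.6g}", f"{p.bcs:.6g}", f"{p.rt_obs_min:.6g}",
                    f"{p.rt_pred_min:.6g}", f"{p.hla_rank:.6g}",
                    int(p.is_decoy), p.sample_id, p.run_id, p.tissue,
                    p.source_class, _ions_to_str(p.by_obs) or ".",
                    _ions_to_str(p.by_pred) or ".",
                ]
            )


def read_psm_tsv(path: str | Path) -> list[PsmRecord]:
    psms = []
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None:
            return []
        if [h.strip() for h in header] != _PSM_HEADER:
            raise ValueError(f"unexpected PSM header: {header}")
        for row in reader:
            if not row or not row[0]:
                continue
            psms.append(
                PsmRecord(
                    psm_id=row[0], peptide=row[1], charge=int(row[2]),
                    sm_score=float(row[3]), spi_pct=float(row[4]),
                    bcs=float(row[5]), rt_obs_min=float(row[6]),
                    rt_pred_min=float(row[7]), hla_rank=float(row[8]),
                    is_decoy=row[9] == "1", sample_id=row[10], run_id=row[11],
                    tissue=row[12], source_class=row[13],
                    by_obs=_ions_from_str(row[14]), by_pred=_ions_from_str(row[15]),
                )
            )
    return psms
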