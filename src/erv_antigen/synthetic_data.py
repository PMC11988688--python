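"""Synthetic data with ground truth for every pipeline stage.

Catalogs plant a shared, stop-free nucleotide block inside each homologous
family so translated peptides map to every member; alignment simulations
plant per-ERV abundances with controllable duplicate/single-end/mismatch
composition; PSM tables mix correct and incorrect identifications with
known labels; expression matrices plant a latent-factor correlation.

All generators are deterministic functions of their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .erv_catalog import ErvRecord
from .erv_quant import ReadAlignment
from .immunopep_filter import PsmRecord

__all__ = [
    "SimulationConfig",
    "CatalogSim",
    "make_erv_catalog",
    "write_catalog",
    "simulate_alignments",
    "simulate_psm_table",
    "simulate_expression_matrix",
]

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}
_NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]
# Peptide alphabet without C (cysteine is injected separately) and without
# I to keep I/L-collapse bookkeeping simple in tests.
_PEPTIDE_AA = list("ADEFGHKLMNPQRSTVWY")


@dataclass
class SimulationConfig:
    """Defaults for all sub-generators; one global seed governs everything.

    Stage generators derive their own streams from ``seed`` via fixed
    offsets so each stage can be re-simulated independently.
    """

    seed: int = 0
    # catalog
    n_ervs: int = 20
    n_families: int = 5
    family_shared_fraction: float = 0.3
    erv_length: int = 300
    # alignments
    duplicate_rate: float = 0.1
    se_rate: float = 0.1
    mismatch_rate: float = 0.1
    n_noise_reads: int = 100
    # psm mixture
    n_target: int = 1000
    n_decoy: int = 100
    fraction_correct: float = 0.9
    score_mean_correct: float = 12.0
    score_mean_null: float = 5.0
    score_sd: float = 2.0
    # expression matrix
    n_samples: int = 100
    planted_correlation: float = 0.8

    def __post_init__(self) -> None:
        for name in ("family_shared_fraction", "duplicate_rate", "se_rate",
                     "mismatch_rate", "fraction_correct"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.score_sd <= 0:
            raise ValueError("score_sd must be > 0")
        if self.n_ervs < self.n_families or self.n_families < 1:
            raise ValueError("need n_ervs >= n_families >= 1")

    def stage_seed(self, stage: str) -> int:
        offsets = {"catalog": 11, "alignments": 23, "psms": 37, "matrix": 53}
        return self.seed * 1009 + offsets[stage]


@dataclass
class CatalogSim:
    genome: dict[str, str]
    ervs: list[ErvRecord]
    families: dict[str, str]  # erv_id -> family_id
    shared_blocks: dict[str, str] = field(default_factory=dict)  # family -> nt


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n)) if n else ""


def make_erv_catalog(
    n_ervs: int = 20,
    n_families: int = 5,
    family_shared_fraction: float = 0.3,
    erv_length: int = 300,
    seed: int = 0,
) -> CatalogSim:
    """Build a toy genome with homologous ERV families.

    Each family carries a stop-free (frame +1) shared codon block spanning
    ``family_shared_fraction`` of the ERV length, placed at nucleotide
    offset 3 inside every member, so block-derived peptides map to the whole
    family.
    """
    if not 0.0 <= family_shared_fraction <= 1.0:
        raise ValueError("family_shared_fraction must be in [0, 1]")
    if n_ervs < n_families or n_families < 1:
        raise ValueError("need n_ervs >= n_families >= 1")
    rng = np.random.default_rng(seed)
    block_nt = int(erv_length * family_shared_fraction) // 3 * 3
    if block_nt + 3 > erv_length:
        raise ValueError("family_shared_fraction too large for erv_length")
    blocks = {
        f"fam{f+1}": "".join(
            rng.choice(_NONSTOP_CODONS, size=block_nt // 3)
        )
        for f in range(n_families)
    }
    chrom = "chrS"
    pieces: list[str] = []
    ervs: list[ErvRecord] = []
    families: dict[str, str] = {}
    pos = 0
    for i in range(n_ervs):
        fam = f"fam{i % n_families + 1}"
        erv_id = f"ERV{i+1:04d}"
        body = list(_random_bases(rng, erv_length))
        if block_nt:
            body[3 : 3 + block_nt] = blocks[fam]
        seq = "".join(body)
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            from Bio.Seq import reverse_complement

            seq = reverse_complement(seq)
        spacer = _random_bases(rng, 50)
        pieces.append(spacer)
        pos += 50
        pieces.append(seq)
        ervs.append(ErvRecord(erv_id, chrom, pos, pos + erv_length, strand))
        families[erv_id] = fam
        pos += erv_length
    pieces.append(_random_bases(rng, 50))
    return CatalogSim({chrom: "".join(pieces)}, ervs, families, blocks)


def write_catalog(cat: CatalogSim, outdir: str | Path) -> dict[str, Path]:
    """Write genome.fa, ervs.bed, and families.tsv into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fa",
        "ervs": outdir / "ervs.bed",
        "families": outdir / "families.tsv",
    }
    with open(paths["genome"], "w") as fh:
        for chrom in sorted(cat.genome):
            fh.write(f">{chrom}\n")
            seq = cat.genome[chrom]
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    with open(paths["ervs"], "w") as fh:
        for e in cat.ervs:
            fh.write(f"{e.chrom}\t{e.start}\t{e.end}\t{e.erv_id}\t0\t{e.strand}\n")
    with open(paths["families"], "w") as fh:
        fh.write("erv_id\tfamily\n")
        for erv_id in sorted(cat.families):
            fh.write(f"{erv_id}\t{cat.families[erv_id]}\n")
    return paths


def simulate_alignments(
    ervs: Sequence[ErvRecord],
    abundances: Mapping[str, float],
    seed: int = 0,
    duplicate_rate: float = 0.1,
    se_rate: float = 0.1,
    mismatch_rate: float = 0.1,
    n_noise_reads: int = 0,
    read_prefix: str = "r",
    poisson: bool = True,
) -> tuple[list[ReadAlignment], dict[str, dict]]:
    """Draw alignment evidence with planted per-ERV fragment abundances.

    Returns (alignments, truth) where truth[erv_id] records the retained
    paired-end and single-end fragment counts and the implied raw
    expression.  Fragment positions are unique per ERV so that injected
    duplicates (same fragment key, new read id) are exactly removable.
    """
    rng = np.random.default_rng(seed)
    alignments: list[ReadAlignment] = []
    truth: dict[str, dict] = {}
    idx = 0
    for erv in ervs:
        lam = float(abundances.get(erv.erv_id, 0.0))
        n = int(rng.poisson(lam)) if poisson else int(round(lam))
        t = {"abundance": lam, "n_fragments": n, "n_pe": 0, "n_se": 0}
        positions = (
            rng.choice(1_000_000, size=n, replace=False) if n else np.array([], int)
        )
        for pos in positions:
            pos = int(pos)
            idx += 1
            read_id = f"{read_prefix}{idx}"
            orient = "+" if rng.random() < 0.5 else "-"
            if rng.random() < se_rate:
                nm = int(rng.random() < mismatch_rate)
                rec = ReadAlignment(read_id, "single", False,
                                    ((erv.erv_id, nm),), pos, orient)
                alignments.append(rec)
                if nm == 0:
                    t["n_se"] += 1
                if rng.random() < duplicate_rate:
                    idx += 1
                    alignments.append(
                        ReadAlignment(f"{read_prefix}{idx}", "single", False,
                                      ((erv.erv_id, nm),), pos, orient)
                    )
            else:
                nm1 = int(rng.random() < mismatch_rate)
                nm2 = int(rng.random() < mismatch_rate)
                r1 = ReadAlignment(read_id, "1", False, ((erv.erv_id, nm1),),
                                   pos, orient)
                r2 = ReadAlignment(read_id, "2", False, ((erv.erv_id, nm2),),
                                   pos + 100, orient)
                alignments.extend([r1, r2])
                if nm1 + nm2 <= 1:
                    t["n_pe"] += 1
                if rng.random() < duplicate_rate:
                    idx += 1
                    dup_id = f"{read_prefix}{idx}"
                    alignments.extend(
                        [
                            ReadAlignment(dup_id, "1", False,
                                          ((erv.erv_id, nm1),), pos, orient),
                            ReadAlignment(dup_id, "2", False,
                                          ((erv.erv_id, nm2),), pos + 100, orient),
                        ]
                    )
        t["expression_raw"] = 2 * t["n_pe"] + t["n_se"]
        truth[erv.erv_id] = t
    for _ in range(n_noise_reads):
        idx += 1
        alignments.append(
            ReadAlignment(f"{read_prefix}{idx}", "single", True, (), 0, "+")
        )
    return alignments, truth


def _random_peptide(rng: np.random.Generator, length: int, with_cys: bool) -> str:
    aas = rng.choice(_PEPTIDE_AA, size=length)
    pep = "".join(aas)
    if with_cys:
        i = int(rng.integers(length))
        pep = pep[:i] + "C" + pep[i + 1 :]
    return pep


_ION_LABELS = ["b2", "b3", "b4", "y2", "y3", "y4", "y5", "y6"]


def simulate_psm_table(
    n_target: int = 1000,
    n_decoy: int = 100,
    fraction_correct: float = 0.9,
    seed: int = 0,
    score_mean_correct: float = 12.0,
    score_mean_null: float = 5.0,
    score_sd: float = 2.0,
    n_runs: int = 1,
    cys_fraction: float = 0.0,
    normal_fraction: float = 0.0,
    reference_fraction: float = 0.5,
    erv_peptides: Sequence[str] = (),
) -> tuple[list[PsmRecord], dict[str, bool]]:
    """Mix correct and incorrect target PSMs with decoys, all labelled.

    Correct targets draw engine scores from the high Normal and rescoring
    metrics that predominantly pass all three strike checks; incorrect
    targets and decoys draw from the null distributions.  A
    ``normal_fraction`` of correct target peptides is re-emitted as a
    normal-tissue PSM.  Truth maps psm_id -> correctness (decoys False).
    """
    rng = np.random.default_rng(seed)
    psms: list[PsmRecord] = []
    truth: dict[str, bool] = {}
    normal_extras: list[PsmRecord] = []

    def _spectra(correct: bool) -> tuple[dict, dict]:
        pred = {l: float(v) for l, v in
                zip(_ION_LABELS, rng.gamma(2.0, 50.0, size=len(_ION_LABELS)))}
        if correct:
            obs = {l: max(0.0, v * (1.0 + rng.normal(0, 0.05))) for l, v in pred.items()}
        else:
            obs = {l: float(v) for l, v in
                   zip(_ION_LABELS, rng.gamma(2.0, 50.0, size=len(_ION_LABELS)))}
        return obs, pred

    for i in range(n_target + n_decoy):
        is_decoy = i >= n_target
        correct = (not is_decoy) and rng.random() < fraction_correct
        psm_id = f"psm{i+1}"
        length = int(rng.choice([8, 9, 10, 11], p=[0.15, 0.5, 0.2, 0.15]))
        with_cys = rng.random() < cys_fraction
        if correct and erv_peptides is not None and len(erv_peptides):
            peptide = str(erv_peptides[int(rng.integers(len(erv_peptides)))])
        else:
            peptide = _random_peptide(rng, length, with_cys)
        mean = score_mean_correct if correct else score_mean_null
        sm_score = float(rng.normal(mean, score_sd))
        if correct:
            spi = float(np.clip(rng.normal(75, 10), 0, 100))
            bcs = float(rng.normal(8, 1.5))
            rt_pred = float(rng.uniform(5, 115))
            rt_obs = rt_pred + float(rng.normal(0, 2))
            hla_rank = float(abs(rng.normal(0, 0.7)))
        else:
            spi = float(np.clip(rng.normal(55, 15), 0, 100))
            bcs = float(rng.normal(5, 2))
            rt_pred = float(rng.uniform(5, 115))
            rt_obs = float(rng.uniform(0, 120))
            hla_rank = float(rng.uniform(0, 10))
        by_obs, by_pred = _spectra(correct)
        source_class = (
            "reference"
            if (correct and rng.random() < reference_fraction and not erv_peptides)
            else ("" if is_decoy else "erv")
        )
        rec = PsmRecord(
            psm_id=psm_id, peptide=peptide, charge=int(rng.integers(1, 5)),
            sm_score=sm_score, spi_pct=spi, bcs=bcs, rt_obs_min=rt_obs,
            rt_pred_min=rt_pred, hla_rank=hla_rank, is_decoy=is_decoy,
            sample_id="s1", run_id=f"run{i % n_runs + 1}", tissue="tumor",
            source_class=source_class, by_obs=by_obs, by_pred=by_pred,
        )
        psms.append(rec)
        truth[psm_id] = correct
        if correct and rng.random() < normal_fraction:
            norm_id = f"{psm_id}n"
            normal_extras.append(
                PsmRecord(
                    psm_id=norm_id, peptide=peptide, charge=rec.charge,
                    sm_score=sm_score, spi_pct=spi, bcs=bcs,
                    rt_obs_min=rt_obs, rt_pred_min=rt_pred, hla_rank=hla_rank,
                    is_decoy=False, sample_id="n1", run_id=rec.run_id,
                    tissue="normal", source_class=source_class,
                    by_obs=by_obs, by_pred=by_pred,
                )
            )
            truth[norm_id] = True
    return psms + normal_extras, truth


def simulate_expression_matrix(
    n_samples: int = 100,
    n_signature_genes: int = 10,
    n_housekeeping_genes: int = 10,
    n_ervs: int = 15,
    planted_correlation: float = 0.8,
    seed: int = 0,
):
    """Latent-factor expression matrix: signature genes and responsive ERVs
    load on a per-sample activity variable with the planted correlation;
    housekeeping genes are independent.  Values are on a positive 2**x scale
    so the log/z pipeline applies directly.

    Returns (DataFrame features x samples, truth: feature -> planted rho).
    """
    import pandas as pd

    if n_samples < 3:
        raise ValueError("need n_samples >= 3")
    if not -1.0 <= planted_correlation <= 1.0:
        raise ValueError("planted_correlation must be in [-1, 1]")
    rng = np.random.default_rng(seed)
    h = rng.normal(size=n_samples)
    rho = planted_correlation
    noise_sd = float(np.sqrt(max(0.0, 1.0 - rho * rho)))

    rows, names, truth = [], [], {}

    def _loaded(name: str, r: float) -> None:
        signal = r * h + noise_sd * rng.normal(size=n_samples) if abs(r) < 1 else r * h
        rows.append(np.maximum(0.0, 2.0 ** (5.0 + signal) - 1.0))
        names.append(name)
        truth[name] = r

    for g in range(n_signature_genes):
        _loaded(f"SIG{g+1}", rho)
    for g in range(n_housekeeping_genes):
        signal = rng.normal(size=n_samples)
        rows.append(np.maximum(0.0, 2.0 ** (5.0 + signal) - 1.0))
        names.append(f"HK{g+1}")
        truth[f"HK{g+1}"] = 0.0
    for g in range(n_ervs):
        _loaded(f"ERV{g+1:04d}", rho)

    matrix = pd.DataFrame(
        rows, index=names, columns=[f"sample{j+1}" for j in range(n_samples)]
    )
    return matrix, truth
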