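"""End-to-end pipeline driver: configuration, stage ordering, audit report.

The discovery pipeline runs quantification -> responsiveness calling ->
candidate union -> search-database construction -> PSM filtering ->
signature correlation, recording stage counts and every effective parameter
in a machine-readable audit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import erv_catalog, erv_quant, immunopep_filter, signature_stats, sixframe_db

__all__ = ["PipelineConfig", "DEFAULT_PARAMS", "run_discovery"]

# Every parameter defaults to the printed value where one exists.
DEFAULT_PARAMS: dict[str, Any] = {
    "pseudocount": 1.0,
    "log2fc_min": 1.0,
    "min_expr": 1.0,
    "fdr_level": 0.01,
    "fdr_scope": "run",
    "min_protein_length": 7,
    "require_met": False,
    "windows_kb": [0, 1, 5, 10],
    "min_score": 7.0,
    "min_spi_pct": 50.0,
    "min_bcs": 5.0,
    "charge_range": [1, 4],
    "length_range": [8, 11],
    "sa_min": 0.6,
    "rt_tol_min": 10.0,
    "rank_max": 2.0,
    "kmer": 9,
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (plain key-value YAML on disk)."""

    outdir: Path
    ervs: Path | None = None
    genome: Path | None = None
    peaks: Path | None = None
    reference_proteome: Path | None = None
    contaminants: Path | None = None
    alignments: dict[str, Path] = field(default_factory=dict)
    comparisons: dict[str, dict[str, list[str]]] = field(default_factory=dict)
    polysome: dict[str, bool] = field(default_factory=dict)
    psms: Path | None = None
    normals: Path | None = None
    expression_matrix: Path | None = None
    signatures: dict[str, Path] = field(default_factory=dict)
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        merged = dict(DEFAULT_PARAMS)
        unknown = set(self.params) - set(DEFAULT_PARAMS)
        if unknown:
            raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
        merged.update(self.params)
        self.params = merged
        for name, comp in self.comparisons.items():
            if set(comp) != {"high", "low"}:
                raise ValueError(f"comparison {name!r} needs 'high' and 'low' arms")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "outdir" not in raw:
            raise ValueError("config must define 'outdir'")
        path_keys = ("ervs", "genome", "peaks", "reference_proteome",
                     "contaminants", "psms", "normals", "expression_matrix")
        kwargs: dict[str, Any] = {"outdir": Path(raw.pop("outdir"))}
        for k in path_keys:
            if k in raw:
                kwargs[k] = Path(raw.pop(k))
        if "alignments" in raw:
            kwargs["alignments"] = {s: Path(p) for s, p in raw.pop("alignments").items()}
        if "signatures" in raw:
            kwargs["signatures"] = {s: Path(p) for s, p in raw.pop("signatures").items()}
        for k in ("comparisons", "polysome", "params"):
            if k in raw:
                kwargs[k] = raw.pop(k)
        if raw:
            raise ValueError(f"unknown config key(s): {sorted(raw)}")
        return cls(**kwargs)

    def to_dict(self) -> dict[str, Any]:
        def _p(v):
            return str(v) if isinstance(v, Path) else v

        return {
            "outdir": str(self.outdir),
            "ervs": _p(self.ervs), "genome": _p(self.genome),
            "peaks": _p(self.peaks),
            "reference_proteome": _p(self.reference_proteome),
            "contaminants": _p(self.contaminants),
            "alignments": {k: str(v) for k, v in self.alignments.items()},
            "comparisons": self.comparisons,
            "polysome": self.polysome,
            "psms": _p(self.psms), "normals": _p(self.normals),
            "expression_matrix": _p(self.expression_matrix),
            "signatures": {k: str(v) for k, v in self.signatures.items()},
            "params": self.params,
        }


def _require(path: Path | None, what: str) -> Path:
    if path is None:
        raise FileNotFoundError(f"pipeline stage needs input {what!r} (not configured)")
    if not Path(path).exists():
        raise FileNotFoundError(f"{what}: no such file {path}")
    return Path(path)


def run_discovery(config: PipelineConfig) -> dict[str, Any]:
    """Execute the configured stages in order and write artifacts + audit.

    Returns the audit dictionary; also written to ``outdir/audit.json``.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    p = config.params
    audit: dict[str, Any] = {"params": dict(p), "stages": {}, "config": config.to_dict()}

    ervs = None
    if config.ervs is not None:
        ervs = erv_catalog.read_interval_file(_require(config.ervs, "ervs"), "erv")
        audit["stages"]["catalog"] = {"n_ervs": len(ervs)}
    erv_lengths = {e.erv_id: e.length for e in ervs} if ervs else {}

    # -- quantification per sample -------------------------------------------
    norm_by_sample: dict[str, dict[str, float]] = {}
    if config.alignments:
        if ervs is None:
            raise FileNotFoundError("quantification needs 'ervs'")
        for sample, path in config.alignments.items():
            alignments = erv_quant.read_alignment_tsv(_require(path, f"alignments[{sample}]"))
            counts = erv_quant.quantify_sample(alignments, erv_lengths)
            erv_quant.write_counts_tsv(counts, out / f"erv_counts.{sample}.tsv")
            norm_by_sample[sample] = {
                e: c.expression_norm for e, c in counts.items()
            }
        audit["stages"]["quant"] = {"n_samples": len(norm_by_sample)}

    # -- responsiveness + candidate union ------------------------------------
    flags: dict[str, list[bool]] = {}
    if config.comparisons:
        rows = []
        comp_names = sorted(config.comparisons)
        for erv_id in erv_lengths:
            flags[erv_id] = []
        for name in comp_names:
            arms = config.comparisons[name]
            for erv_id in sorted(erv_lengths):
                res = erv_quant.call_responsive(
                    [norm_by_sample[s][erv_id] for s in arms["high"]],
                    [norm_by_sample[s][erv_id] for s in arms["low"]],
                    comparison=name, erv_id=erv_id,
                    pseudocount=p["pseudocount"], log2fc_min=p["log2fc_min"],
                    min_expr=p["min_expr"],
                )
                flags[erv_id].append(res.responsive)
                rows.append(res)
        with open(out / "comparisons.tsv", "w") as fh:
            fh.write("erv_id\tcomparison\tlog2fc\tresponsive\n")
            for r in rows:
                fh.write(f"{r.erv_id}\t{r.comparison}\t{r.log2fc:.4f}\t{int(r.responsive)}\n")
        candidates = erv_quant.tier_and_union(
            {"all": flags}, {"all": config.polysome} if config.polysome else None
        )
        with open(out / "candidates.tsv", "w") as fh:
            fh.write("erv_id\ttier\tpolysome\n")
            for erv_id in candidates.erv_ids:
                prov = candidates.provenance[erv_id]["all"]
                fh.write(f"{erv_id}\t{prov['tier']}\t{int(prov['polysome'])}\n")
        audit["stages"]["candidates"] = {
            "n_responsive_calls": sum(any(f) for f in flags.values()),
            "n_candidates": len(candidates.erv_ids),
        }
        candidate_ids = candidates.erv_ids
    else:
        candidate_ids = sorted(erv_lengths)

    # -- peak proximity -------------------------------------------------------
    if config.peaks is not None and ervs is not None:
        peaks = erv_catalog.read_interval_file(_require(config.peaks, "peaks"), "peak")
        annotations = erv_catalog.annotate_peak_proximity(ervs, peaks, p["windows_kb"])
        erv_catalog.write_proximity_tsv(annotations, out / "proximity.tsv")
        audit["stages"]["proximity"] = {
            "n_superimposed": sum(a.relation == "superimposed" for a in annotations),
            "n_within_window": sum(a.relation == "within_window" for a in annotations),
        }

    # -- search database ------------------------------------------------------
    db = None
    if config.reference_proteome is not None:
        reference = sixframe_db.read_fasta_entries(
            _require(config.reference_proteome, "reference_proteome")
        )
        contaminants = (
            sixframe_db.read_fasta_entries(_require(config.contaminants, "contaminants"))
            if config.contaminants is not None
            else ()
        )
        orfs = []
        if ervs is not None and config.genome is not None:
            genome = erv_catalog.load_genome(_require(config.genome, "genome"))
            chosen = [e for e in ervs if e.erv_id in set(candidate_ids)]
            seqs = erv_catalog.extract_erv_sequences(genome, chosen)
            for erv_id in sorted(seqs):
                orfs.extend(
                    sixframe_db.six_frame_orfs(
                        seqs[erv_id], p["min_protein_length"], p["require_met"], erv_id
                    )
                )
        db = sixframe_db.build_search_db(reference, orfs, contaminants)
        db.write_fasta(out / "searchdb.fa")
        kmers = sixframe_db.unique_kmer_contribution(db, p["kmer"])
        with open(out / "kmer_contribution.tsv", "w") as fh:
            fh.write("source_class\tn_unique_kmers\tfraction\n")
            for cls, (n, frac) in sorted(kmers.items()):
                fh.write(f"{cls}\t{n}\t{frac:.4f}\n")
        audit["stages"]["searchdb"] = {
            "n_entries": len(db),
            "n_erv_orfs": len(orfs),
            "kmer_fractions": {c: frac for c, (n, frac) in kmers.items()},
        }

    # -- PSM filtering --------------------------------------------------------
    if config.psms is not None:
        if db is None:
            raise FileNotFoundError("PSM filtering needs 'reference_proteome'")
        psms = immunopep_filter.read_psm_tsv(_require(config.psms, "psms"))
        fdr = immunopep_filter.estimate_fdr_threshold(
            psms, level=p["fdr_level"], scope=p["fdr_scope"]
        )
        tightened = immunopep_filter.apply_fixed_thresholds(
            fdr.accepted, p["min_score"], p["min_spi_pct"], p["min_bcs"],
            tuple(p["charge_range"]), tuple(p["length_range"]),
        )
        source_maps = {
            pep: sixframe_db.map_peptide_sources(pep, db)
            for pep in sorted({x.peptide for x in tightened})
        }
        strikes = {}
        for x in tightened:
            sa = immunopep_filter.spectral_angle(x.by_obs, x.by_pred)
            strikes[x.psm_id] = immunopep_filter.strike_classify(
                sa, x.delta_rt_min, x.hla_rank, x.psm_id,
                p["sa_min"], p["rt_tol_min"], p["rank_max"],
            )
        normals: list[str] = []
        if config.normals is not None:
            normals = [
                line.strip()
                for line in open(_require(config.normals, "normals"))
                if line.strip()
            ]
        callset = immunopep_filter.finalize_peptide_calls(
            tightened, source_maps, strikes, normals
        )
        with open(out / "calls.tsv", "w") as fh:
            fh.write("peptide\tpsm_id\tsample_id\tverdict\tsource_ervs\n")
            for c in callset.calls:
                fh.write(
                    f"{c.peptide}\t{c.psm_id}\t{c.sample_id}\t{c.verdict}\t"
                    f"{','.join(c.source_ervs) or '.'}\n"
                )
        with open(out / "audit.tsv", "w") as fh:
            fh.write("stage\tsurviving\n")
            fh.write(f"fdr_accept\t{len(fdr.accepted)}\n")
            fh.write(f"fixed_thresholds\t{len(tightened)}\n")
            for stage, n in callset.audit.items():
                fh.write(f"{stage}\t{n}\n")
        audit["stages"]["psm_filter"] = {
            "n_input": len(psms),
            "fdr_accept": len(fdr.accepted),
            "fixed_thresholds": len(tightened),
            **callset.audit,
        }

    # -- signature correlation -----------------------------------------------
    if config.expression_matrix is not None and config.signatures:
        import pandas as pd

        matrix = pd.read_csv(
            _require(config.expression_matrix, "expression_matrix"),
            sep="\t", index_col=0,
        )
        z = signature_stats.log_zscore(matrix)
        targets = {}
        for name, path in sorted(config.signatures.items()):
            genes = [l.strip() for l in open(_require(path, f"signatures[{name}]")) if l.strip()]
            targets[name] = signature_stats.signature_score(z, genes)
        erv_rows = z.loc[[i for i in z.index if i.startswith("ERV")]]
        reports = signature_stats.correlate_with_bh(erv_rows, targets)
        signature_stats.reports_to_frame(reports).to_csv(
            out / "correlations.tsv", sep="\t", index=False
        )
        audit["stages"]["correlate"] = {
            "n_tests": len(reports),
            "n_significant": sum(
                1 for r in reports if r.p_adj == r.p_adj and r.p_adj < 0.05
            ),
        }

    with open(out / "audit.json", "w") as fh:
        json.dump(audit, fh, indent=2, sort_keys=True)
    return audit
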