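"""Signature scoring and ERV-signature correlation with BH adjustment."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CorrelationReport",
    "log_zscore",
    "signature_score",
    "correlate_with_bh",
]


@dataclass(frozen=True)
class CorrelationReport:
    erv_id: str
    target: str
    r: float
    p: float
    p_adj: float


def log_zscore(matrix: pd.DataFrame) -> pd.DataFrame:
    """log2(x+1) then per-feature z-score across samples (ddof=1).

    Zero-variance features become all-zero rows (with a warning) rather than
    NaN so that downstream averaging stays defined.
    """
    if (matrix.values < 0).any():
        raise ValueError("expression values must be >= 0")
    logged = np.log2(matrix.astype(float) + 1.0)
    mean = logged.mean(axis=1)
    sd = logged.std(axis=1, ddof=1)
    flat = sd == 0
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} zero-variance feature(s) set to all-zero z-rows"
        )
        sd = sd.mask(flat, 1.0)
    z = logged.sub(mean, axis=0).div(sd, axis=0)
    z.loc[flat] = 0.0
    return z


def signature_score(zmatrix: pd.DataFrame, gene_set: Iterable[str]) -> pd.Series:
    """Per-sample signature score: mean z-row over the gene-set members
    present in the matrix.  Missing members trigger a warning; an empty
    intersection is an error."""
    genes = list(dict.fromkeys(gene_set))
    present = [g for g in genes if g in zmatrix.index]
    missing = [g for g in genes if g not in zmatrix.index]
    if not present:
        raise ValueError(f"no gene of the set is present in the matrix: {genes}")
    if missing:
        warnings.warn(f"signature members missing from matrix: {missing}")
    return zmatrix.loc[present].mean(axis=0)


def correlate_with_bh(
    erv_rows: pd.DataFrame, targets: Mapping[str, pd.Series] | pd.DataFrame
) -> list[CorrelationReport]:
    """Pearson correlation of each ERV row against each target profile, with
    Benjamini-Hochberg adjustment within each target family (one family per
    target, across ERVs).  Zero-variance rows are flagged with r = NaN and
    excluded from the BH family."""
    if isinstance(targets, pd.DataFrame):
        targets = {name: targets.loc[name] for name in targets.index}
    reports: list[CorrelationReport] = []
    for target_name, target in targets.items():
        target = pd.Series(target)
        if len(target) < 3:
            raise ValueError("need >= 3 samples for correlation")
        aligned = erv_rows[target.index]
        rows: list[tuple[str, float, float]] = []
        flagged: list[str] = []
        for erv_id in aligned.index:
            x = aligned.loc[erv_id].to_numpy(dtype=float)
            y = target.to_numpy(dtype=float)
            if np.std(x) == 0 or np.std(y) == 0:
                flagged.append(erv_id)
                continue
            r, p = stats.pearsonr(x, y)
            rows.append((erv_id, float(r), float(p)))
        if rows:
            _, p_adj, _, _ = multipletests(
                [p for _, _, p in rows], method="fdr_bh"
            )
            for (erv_id, r, p), pa in zip(rows, p_adj):
                reports.append(CorrelationReport(erv_id, target_name, r, p, float(pa)))
        for erv_id in flagged:
            reports.append(
                CorrelationReport(erv_id, target_name, float("nan"), float("nan"),
                                  float("nan"))
            )
    return reports


def reports_to_frame(reports: Sequence[CorrelationReport]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.erv_id, r.target, r.r, r.p, r.p_adj) for r in reports],
        columns=["erv_id", "target", "r", "p", "p_adj"],
    )
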