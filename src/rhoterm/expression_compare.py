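"""Expression comparison between wild-type and Rho-mutant strains.

Implements the study's comparison logic for two-colour array intensities and
qRT-PCR: per-gene log2 fold changes, an affected-gene cutoff of a 5-fold
change (|log2 FC| >= log2 5), overlay classification of genes by whether the
primary-binding-site (PBS) and/or secondary-binding-site (SBS) mutants
affect them, and relative quantification by the 2^-ddCt method against an
internal control gene.  Input tables are assumed normalized; no significance
testing is applied -- the comparison is a pure fold-change cutoff, as in the
source assays.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DdctInput",
    "log2_fold_change",
    "add_log2fc",
    "mean_log2fc",
    "count_affected",
    "overlay_classify",
    "ddct_fold_change",
    "fold_cutoff_log2",
]

logger = logging.getLogger(__name__)


def fold_cutoff_log2(fold_threshold: float = 5.0,
                     scale: Literal["fold", "log2"] = "fold") -> float:
    """Cutoff on |log2 FC| implied by the threshold.

    ``scale="fold"`` (default) reads the threshold as a fold change reported
    on the log2 scale (5-fold -> cutoff log2 5 ~ 2.32).  ``scale="log2"``
    reads it as log2 units directly (5 -> 32-fold); the phrasing of
    fold-change cutoffs in array studies is ambiguous enough that both
    readings are supported.
    """
    if fold_threshold <= (1.0 if scale == "fold" else 0.0):
        raise ValueError("fold_threshold must exceed 1 (fold scale) or 0 (log2 scale)")
    return math.log2(fold_threshold) if scale == "fold" else float(fold_threshold)


def log2_fold_change(mut, wt):
    """log2(mut / wt); positive = up-regulated in the mutant."""
    mut = np.asarray(mut, dtype=float)
    wt = np.asarray(wt, dtype=float)
    if np.any(mut <= 0) or np.any(wt <= 0):
        raise ValueError("intensities must be strictly positive")
    out = np.log2(mut / wt)
    return float(out) if out.ndim == 0 else out


def add_log2fc(table: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of an intensity table with a ``log2fc`` column.

    Accepts either wt/mut intensity columns or a precomputed ``log2fc``.
    """
    df = table.copy()
    if "log2fc" not in df.columns:
        if not {"wt", "mut"} <= set(df.columns):
            raise ValueError("table needs either a log2fc column or wt and mut columns")
        df["log2fc"] = log2_fold_change(df["mut"].to_numpy(), df["wt"].to_numpy())
    return df


def mean_log2fc(tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Average log2 fold changes across replicate tables (inner join on gene_id).

    Mirrors the overlay procedure of averaging two mutants per binding-site
    class before comparison.
    """
    if not tables:
        raise ValueError("need at least one table")
    frames = [add_log2fc(t).set_index("gene_id")["log2fc"] for t in tables]
    joined = pd.concat(frames, axis=1, join="inner")
    if joined.empty:
        raise ValueError("replicate tables share no gene_ids")
    out = joined.mean(axis=1).rename("log2fc").reset_index()
    first = add_log2fc(tables[0])
    if "category" in first.columns:
        out = out.merge(first[["gene_id", "category"]], on="gene_id", how="left")
    return out


def count_affected(table: pd.DataFrame, fold_threshold: float = 5.0,
                   scale: Literal["fold", "log2"] = "fold") -> dict[str, int]:
    """Count genes whose expression changed by at least the fold cutoff.

    Returns ``{"up", "down", "total"}`` with the split by sign of log2 FC.
    """
    df = add_log2fc(table)
    if df.empty:
        raise ValueError("expression table is empty")
    cutoff = fold_cutoff_log2(fold_threshold, scale)
    lfc = df["log2fc"].to_numpy()
    up = int(np.count_nonzero(lfc >= cutoff))
    down = int(np.count_nonzero(lfc <= -cutoff))
    return {"up": up, "down": down, "total": up + down}


def overlay_classify(records_pbs: pd.DataFrame | Sequence[pd.DataFrame],
                     records_sbs: pd.DataFrame | Sequence[pd.DataFrame],
                     fold_threshold: float = 5.0,
                     scale: Literal["fold", "log2"] = "fold") -> pd.DataFrame:
    """Classify each gene by which mutant class affects it.

    PBS mutants are recruitment-defective, SBS mutants translocation-
    defective; overlaying the two profiles separates terminators that need a
    functional primary binding site from those that do not.  Classes:
    ``sbs_only`` (affected by SBS mutants but not PBS), ``pbs_and_sbs``,
    ``pbs_only``, ``neither``.  Lists of replicate tables are averaged
    first; the two profiles are inner-joined on gene_id and mismatches are
    logged.  The classes partition the joined gene set exactly.
    """
    pbs = mean_log2fc(list(records_pbs)) if not isinstance(records_pbs, pd.DataFrame) \
        else add_log2fc(records_pbs)
    sbs = mean_log2fc(list(records_sbs)) if not isinstance(records_sbs, pd.DataFrame) \
        else add_log2fc(records_sbs)
    merged = pbs[["gene_id", "log2fc"]].merge(
        sbs[["gene_id", "log2fc"]], on="gene_id", how="inner",
        suffixes=("_pbs", "_sbs"))
    if merged.empty:
        raise ValueError("PBS and SBS tables share no gene_ids")
    dropped = (len(pbs) - len(merged)) + (len(sbs) - len(merged))
    if dropped:
        logger.warning("overlay_classify: %d records outside the gene_id "
                       "intersection were dropped", dropped)
    cutoff = fold_cutoff_log2(fold_threshold, scale)
    aff_pbs = merged["log2fc_pbs"].abs() >= cutoff
    aff_sbs = merged["log2fc_sbs"].abs() >= cutoff
    cls = np.select(
        [aff_pbs & aff_sbs, aff_sbs & ~aff_pbs, aff_pbs & ~aff_sbs],
        ["pbs_and_sbs", "sbs_only", "pbs_only"], default="neither")
    out = merged.copy()
    out["overlay_class"] = cls
    return out


@dataclass(frozen=True)
class DdctInput:
    """Threshold cycles for one target gene in mutant and wild type.

    The control gene is the internal reference whose expression does not
    respond to the perturbation (rpoC in the source assays).
    """

    ct_target_mut: float
    ct_control_mut: float
    ct_target_wt: float
    ct_control_wt: float

    def __post_init__(self) -> None:
        for name in ("ct_target_mut", "ct_control_mut", "ct_target_wt",
                     "ct_control_wt"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and > 0, got {v!r}")


def ddct_fold_change(d: DdctInput) -> float:
    """Relative expression change of the mutant by the 2^-ddCt method.

    dCt = Ct(target) - Ct(control) within each strain; ddCt = dCt(mutant) -
    dCt(WT); fold = 2^-ddCt.  The internal control cancels exactly, so equal
    target Cts give 1.0 regardless of control values.
    """
    dct_mut = d.ct_target_mut - d.ct_control_mut
    dct_wt = d.ct_target_wt - d.ct_control_wt
    return float(2.0 ** -(dct_mut - dct_wt))
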