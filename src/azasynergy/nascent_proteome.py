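"""Nascent-proteome (AHA pulse / ClickIT enrichment) PSM analysis.

Newly synthesised proteins are pulse-labelled with azidohomoalanine (AHA),
click-enriched and identified by mass spectrometry; peptide-spectrum-match
(PSM) counts per protein serve as semi-quantitative abundance. The analysis
is a three-stage filter cascade on MaxQuant-style protein groups:

1. drop search artefacts flagged as potential contaminant, reverse (decoy)
   or "only identified by site";
2. drop proteins detected in the no-AHA background channel (non-specific
   binders), unless their untreated signal is at least ``background_ratio``
   (default 10) times the background signal;
3. drop proteins with PSM = 0 in one or more DMSO control replicates (not
   reliably quantified at baseline).

Retained proteins are called "affected" by treatment when their mean PSM
count drops by at least ``reduction_cut`` (default 75%, inclusive) or
disappears entirely. Overlap between affected proteins and transcripts
repressed at the nascent-RNA level is summarised as mutual percentages plus
an upper-tail hypergeometric enrichment p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FilterCascadeResult",
    "OverlapStats",
    "filter_protein_groups",
    "call_affected",
    "overlap_stats",
    "dmso_columns",
    "treated_columns",
]


def dmso_columns(records: pd.DataFrame) -> list[str]:
    return [c for c in records.columns if c.startswith("psm_dmso_")]


def treated_columns(records: pd.DataFrame) -> list[str]:
    return [c for c in records.columns if c.startswith("psm_treated_")]


@dataclass
class FilterCascadeResult:
    """Outcome of the protein-group filter cascade.

    ``stage_log`` is an ordered list of (stage name, n_removed, n_remaining);
    ``retained`` the surviving protein_ids; ``affected``/``reduction`` are
    filled by :func:`call_affected`.
    """

    stage_log: list[tuple[str, int, int]]
    retained: pd.Index
    affected: pd.Index | None = None
    reduction: pd.Series | None = None


FLAG_COLUMNS = ("potential_contaminant", "reverse", "only_identified_by_site")


def filter_protein_groups(
    records: pd.DataFrame, background_ratio: float = 10.0
) -> FilterCascadeResult:
    """Apply the QC / background / baseline-detection cascade in order.

    ``records`` is indexed by protein_id with boolean flag columns
    ``potential_contaminant, reverse, only_identified_by_site``, an integer
    ``psm_background`` column and per-replicate ``psm_dmso_*`` /
    ``psm_treated_*`` columns.
    """
    log: list[tuple[str, int, int]] = []
    if len(records) == 0:
        return FilterCascadeResult(stage_log=log, retained=records.index)
    dmso = dmso_columns(records)
    if not dmso:
        raise ValueError("need at least one psm_dmso_* replicate column")

    cur = records
    flagged = cur[list(FLAG_COLUMNS)].any(axis=1)
    cur = cur[~flagged]
    log.append(("qc_flags", int(flagged.sum()), len(cur)))

    bg = cur["psm_background"].to_numpy(dtype=float)
    mean_dmso = cur[dmso].mean(axis=1).to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        high_ratio = np.where(bg > 0, mean_dmso / np.where(bg > 0, bg, 1.0), np.inf)
    drop_bg = (bg > 0) & (high_ratio < background_ratio)
    cur = cur[~drop_bg]
    log.append(("background", int(drop_bg.sum()), len(cur)))

    any_zero = (cur[dmso] == 0).any(axis=1)
    cur = cur[~any_zero]
    log.append(("dmso_zero", int(any_zero.sum()), len(cur)))

    return FilterCascadeResult(stage_log=log, retained=cur.index)


def call_affected(
    result: FilterCascadeResult,
    records: pd.DataFrame,
    reduction_cut: float = 0.75,
    strict: bool = False,
) -> FilterCascadeResult:
    """Call proteins affected by treatment from their PSM reduction.

    ``reduction = 1 - mean(psm_treated)/mean(psm_dmso)``. A protein is
    affected when it disappears entirely (mean treated PSM = 0) or its
    reduction reaches the cutoff — inclusive (>=) by default, ``strict=True``
    demands a strict decrease (>). Proteins outside the retained set are
    skipped. Fills ``result.affected`` and ``result.reduction`` and returns
    the same object.
    """
    if not (0.0 <= reduction_cut <= 1.0):
        raise ValueError("reduction_cut must lie in [0, 1]")
    sub = records.loc[records.index.isin(result.retained)]
    mean_dmso = sub[dmso_columns(records)].mean(axis=1)
    mean_trt = sub[treated_columns(records)].mean(axis=1)
    reduction = (1.0 - mean_trt / mean_dmso).clip(lower=0.0, upper=1.0)
    if strict:
        hit = reduction > reduction_cut
    else:
        hit = reduction >= reduction_cut
    affected = hit | (mean_trt == 0)
    result.affected = sub.index[affected]
    result.reduction = reduction.rename("reduction")
    return result


@dataclass(frozen=True)
class OverlapStats:
    """Two-way overlap summary between two gene-id hit sets.

    Percentages are of each parent set; ``p_value`` is the upper-tail
    hypergeometric probability of an overlap at least this large given the
    set sizes and a shared detection universe (a supplementary statistic
    beyond the raw percentages).
    """

    n_proteomics: int
    n_slamseq: int
    n_intersection: int
    pct_of_proteomics: float
    pct_of_slamseq: float
    p_value: float


def overlap_stats(
    affected_proteins: set, down_nascent_genes: set, universe_size: int
) -> OverlapStats:
    """Overlap of affected-protein genes with nascent-RNA-down genes."""
    a = set(affected_proteins)
    b = set(down_nascent_genes)
    if universe_size < len(a | b):
        raise ValueError("universe smaller than the union of the two sets")
    inter = len(a & b)
    pct_a = 100.0 * inter / len(a) if a else 0.0
    pct_b = 100.0 * inter / len(b) if b else 0.0
    # P(X >= inter) with X ~ Hypergeom(M=universe, n=|A|, N=|B|)
    p = float(stats.hypergeom.sf(inter - 1, universe_size, len(a), len(b)))
    return OverlapStats(
        n_proteomics=len(a),
        n_slamseq=len(b),
        n_intersection=inter,
        pct_of_proteomics=pct_a,
        pct_of_slamseq=pct_b,
        p_value=p,
    )
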