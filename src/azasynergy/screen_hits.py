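"""Pooled shRNA loss-of-function screen analysis.

A pooled screen compares the abundance of integrated shRNA constructs in
drug-treated versus control cell populations by deep sequencing of the
hairpin cassettes. Constructs targeting genes required for survival under
treatment drop out (deplete); constructs whose knockdown confers resistance
rise (enrich). This module normalises raw construct counts to reads per
million (RPM), computes per-shRNA log2 fold changes, and calls gene-level
hits with a sign-consistency ("trend") rule: a gene is a candidate only if
at least ``min_consistent`` of its shRNAs change in the same direction
(default 5 of 8). Gene-level significance comes from a permutation test that
draws random same-size shRNA sets from the whole library.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LibraryDesign",
    "ShRNACountMatrix",
    "CellRequirements",
    "required_cells",
    "normalize_rpm",
    "shrna_log2fc",
    "call_gene_hits",
    "gene_permutation_pvalue",
    "permutation_pvalues",
]


# ---------------------------------------------------------------------------
# Library design and coverage arithmetic
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LibraryDesign:
    """Composition and coverage parameters of a pooled shRNA library.

    Parameters
    ----------
    n_genes : int
        Number of target genes.
    shrnas_per_gene : int
        Constructs per gene (library_size = n_genes * shrnas_per_gene).
    representation : float
        Desired fold coverage, i.e. average number of cells carrying each
        construct (e.g. 1000 for 1000x representation).
    infection_efficiency : float
        Fraction of cells transduced, in (0, 1]. Kept low (~0.1) in pooled
        screens to favour single-copy integration.
    """

    n_genes: int
    shrnas_per_gene: int
    representation: float = 1000.0
    infection_efficiency: float = 0.1

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.shrnas_per_gene <= 0:
            raise ValueError("n_genes and shrnas_per_gene must be positive")
        if not (0.0 < self.infection_efficiency <= 1.0):
            raise ValueError("infection_efficiency must be in (0, 1]")
        if self.representation <= 0:
            raise ValueError("representation must be positive")

    @property
    def library_size(self) -> int:
        return self.n_genes * self.shrnas_per_gene


def _round_sig(x: float, sig: int = 2) -> float:
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


@dataclass(frozen=True)
class CellRequirements:
    """Cell numbers needed to run a pooled screen at a given coverage."""

    cells_to_transduce: float
    minimum_maintained_cells: float
    cells_to_transduce_2sf: float
    minimum_maintained_cells_2sf: float


def required_cells(design: LibraryDesign) -> CellRequirements:
    """Cell numbers required to preserve library representation.

    ``cells_to_transduce = library_size * representation / infection_efficiency``
    (only the infected fraction contributes coverage);
    ``minimum_maintained_cells = library_size * representation`` is the floor
    below which the selected population must never drop. Both are also
    reported rounded to 2 significant figures, the precision at which such
    numbers are conventionally quoted.
    """
    transduce = design.library_size * design.representation / design.infection_efficiency
    floor = design.library_size * design.representation
    return CellRequirements(
        cells_to_transduce=transduce,
        minimum_maintained_cells=floor,
        cells_to_transduce_2sf=_round_sig(transduce),
        minimum_maintained_cells_2sf=_round_sig(floor),
    )


# ---------------------------------------------------------------------------
# Count matrix container
# ---------------------------------------------------------------------------

@dataclass
class ShRNACountMatrix:
    """Raw (and optionally RPM-normalised) shRNA counts.

    ``counts`` is indexed by shRNA identifier with one column per sample;
    ``genes`` maps each shRNA to exactly one gene; ``samples`` carries per-
    sample metadata with columns ``condition`` (``control``/``treated``) and
    ``replicate``.
    """

    counts: pd.DataFrame
    genes: pd.Series
    samples: pd.DataFrame
    rpm: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.genes.index):
            raise ValueError("counts and gene map must share the shRNA index")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples metadata missing for columns: {sorted(missing)}")

    def sample_ids(self, condition: str) -> list[str]:
        sel = self.samples.index[self.samples["condition"] == condition]
        return [s for s in self.counts.columns if s in set(sel)]


def normalize_rpm(matrix: ShRNACountMatrix) -> ShRNACountMatrix:
    """Fill the reads-per-million view: ``rpm = count * 1e6 / column_sum``.

    Raises
    ------
    ValueError
        If any sample column has zero total count (names the sample).
    """
    colsums = matrix.counts.sum(axis=0)
    zero = colsums.index[colsums == 0].tolist()
    if zero:
        raise ValueError(f"zero-depth sample column(s): {zero}")
    matrix.rpm = matrix.counts * 1e6 / colsums
    return matrix


def shrna_log2fc(matrix: ShRNACountMatrix, pseudocount: float = 0.5) -> pd.DataFrame:
    """Per-shRNA log2 fold change of treated over control mean RPM.

    ``log2fc = log2((mean treated RPM + pc) / (mean control RPM + pc))``.
    The pseudocount (default 0.5 RPM) keeps dropout shRNAs finite while
    preserving rank.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if matrix.rpm is None:
        normalize_rpm(matrix)
    ctrl = matrix.sample_ids("control")
    trt = matrix.sample_ids("treated")
    if not ctrl or not trt:
        raise ValueError("need at least one control and one treated sample")
    mean_c = matrix.rpm[ctrl].mean(axis=1)
    mean_t = matrix.rpm[trt].mean(axis=1)
    return pd.DataFrame(
        {
            "shrna_id": matrix.counts.index,
            "gene_id": matrix.genes.values,
            "mean_rpm_control": mean_c.values,
            "mean_rpm_treated": mean_t.values,
            "log2fc": np.log2((mean_t.values + pseudocount) / (mean_c.values + pseudocount)),
        }
    ).set_index("shrna_id")


# ---------------------------------------------------------------------------
# Gene-level trend rule
# ---------------------------------------------------------------------------

def call_gene_hits(
    fcs: pd.DataFrame,
    min_consistent: int = 5,
    expected_shrnas: int = 8,
) -> pd.DataFrame:
    """Call gene-level hits by sign consistency of per-shRNA fold changes.

    A gene passes the trend rule when at least ``min_consistent`` of its
    detected shRNAs share the majority sign of log2fc (default 5, tuned to
    8-shRNA libraries). Zeros count toward neither sign; an exact sign tie
    yields no direction. ``avg_log2fc`` averages over ALL detected shRNAs of
    the gene, not only the consistent ones. Genes detected with fewer than
    ``expected_shrnas`` constructs are still scored (a 5-of-6 gene can pass)
    but flagged via ``underrepresented``.

    Returns a DataFrame indexed by gene_id with columns
    ``n_shrnas_detected, n_consistent, direction, avg_log2fc,
    passes_trend_rule, underrepresented``.
    """
    rows = []
    for gene, grp in fcs.groupby("gene_id", sort=True):
        lfc = grp["log2fc"].to_numpy()
        n_det = len(lfc)
        if n_det == 0:  # pragma: no cover - groupby never yields empty groups
            continue
        n_pos = int((lfc > 0).sum())
        n_neg = int((lfc < 0).sum())
        n_consistent = max(n_pos, n_neg)
        if n_pos == n_neg:
            candidate = "none"
        else:
            candidate = "enriched" if n_pos > n_neg else "depleted"
        passes = candidate != "none" and n_consistent >= min_consistent
        rows.append(
            {
                "gene_id": gene,
                "n_shrnas_detected": n_det,
                "n_consistent": n_consistent,
                "direction": candidate if passes else "none",
                "avg_log2fc": float(lfc.mean()),
                "passes_trend_rule": passes,
                "underrepresented": n_det < expected_shrnas,
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


# ---------------------------------------------------------------------------
# Permutation significance
# ---------------------------------------------------------------------------

def _subset_means(pool: np.ndarray, size: int, n: int, rng: np.random.Generator) -> np.ndarray:
    """Means of ``n`` random size-``size`` subsets of ``pool``, drawn without
    replacement within each subset (rejection of duplicate-index rows)."""
    N = len(pool)
    idx = rng.integers(0, N, size=(n, size))
    if size > 1:
        while True:
            srt = np.sort(idx, axis=1)
            bad = (srt[:, 1:] == srt[:, :-1]).any(axis=1)
            if not bad.any():
                break
            idx[bad] = rng.integers(0, N, size=(int(bad.sum()), size))
    return pool[idx].mean(axis=1)


def gene_permutation_pvalue(
    fcs: pd.DataFrame,
    gene_id: str,
    n_permutations: int = 1000,
    seed: int = 0,
) -> float:
    """Two-sided permutation p-value for a gene's mean log2 fold change.

    The null draws random same-size shRNA sets (without replacement) from the
    full library and asks how often |mean log2fc| of a random set is at least
    the observed |mean|; p = (1 + exceedances) / (1 + n_permutations), the
    add-one estimator whose resolution floor is 1/(1+n_permutations).
    """
    if n_permutations < 100:
        warnings.warn("n_permutations < 100 gives a very coarse p-value", stacklevel=2)
    pool = fcs["log2fc"].to_numpy()
    mask = fcs["gene_id"].to_numpy() == gene_id
    g = int(mask.sum())
    if g < 2:
        raise ValueError(f"gene {gene_id!r} has fewer than 2 shRNAs")
    observed = abs(float(pool[mask].mean()))
    rng = np.random.default_rng(seed)
    null_means = _subset_means(pool, g, n_permutations, rng)
    exceed = int((np.abs(null_means) >= observed).sum())
    return (1 + exceed) / (1 + n_permutations)


def permutation_pvalues(
    fcs: pd.DataFrame,
    n_permutations: int = 1000,
    seed: int = 0,
) -> pd.Series:
    """Permutation p-values for every gene with >=2 shRNAs.

    Each gene gets an independent sub-stream spawned from ``seed`` so that
    adding or removing genes does not perturb the others' draws.
    """
    pool = fcs["log2fc"].to_numpy()
    genes = fcs["gene_id"].to_numpy()
    out: dict[str, float] = {}
    parent = np.random.SeedSequence(seed)
    for i, gene in enumerate(pd.unique(genes)):
        mask = genes == gene
        g = int(mask.sum())
        if g < 2:
            continue
        rng = np.random.default_rng(np.random.SeedSequence(entropy=parent.entropy, spawn_key=(i,)))
        observed = abs(float(pool[mask].mean()))
        null_means = _subset_means(pool, g, n_permutations, rng)
        out[gene] = (1 + int((np.abs(null_means) >= observed).sum())) / (1 + n_permutations)
    return pd.Series(out, name="p_value")
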