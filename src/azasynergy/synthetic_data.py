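"""Synthetic inputs with planted ground truth for every pipeline stage.

Four generators emulate the structure of the study's deposited datasets so
the downstream analyses can be exercised end-to-end with known answers:

* a pooled shRNA screen count table (negative-binomial counts; planted
  depleted/enriched genes shift a configurable subset of their hairpins by a
  known log2 fold change);
* single-agent dose-response viability tables drawn from the median-effect
  model, so the fitting stage can be tested as an exact inverse;
* combination viability tables constructed by inverting the combination-
  index equation, so the true CI of every dose pair is known;
* SLAM-seq conversion-stratified read counts (binomial mixture of labelled
  and unlabelled reads) with planted nascent repression;
* MaxQuant-style protein-group tables (Poisson PSM counts) with planted QC
  artefacts, background binders and affected proteins.

Count noise models (negative binomial for the screen, binomial mixture for
conversions, Poisson for PSMs) are the standard choices for each data type;
every rate is an explicit config field. Each gene/protein draws from its own
deterministic sub-stream of the seed, so enlarging a simulation leaves the
existing entities' data unchanged.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .screen_hits import ShRNACountMatrix
from .synergy import MedianEffectFit, dose_for_effect

__all__ = [
    "ScreenSimConfig",
    "SlamSimConfig",
    "ProteomeSimConfig",
    "gen_screen_counts",
    "gen_dose_response",
    "gen_combination",
    "gen_slamseq_counts",
    "gen_protein_groups",
]


def _check_fraction(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must lie in [0, 1], got {value}")


def _child_rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


# ---------------------------------------------------------------------------
# Pooled shRNA screen
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScreenSimConfig:
    """Simulation parameters for a pooled shRNA screen.

    Defaults mirror the screened library's composition (912 chromatin genes
    x 8 hairpins = 7296 constructs, three replicates per arm). The planted
    effect moves ``frac_active_shrnas`` of each planted gene's hairpins by
    ``effect_log2fc`` (down for depleted genes, up for enriched) in the
    treated arm only.
    """

    n_genes: int = 912
    shrnas_per_gene: int = 8
    n_replicates: int = 3
    baseline_mean: float = 500.0
    dispersion: float = 0.05
    frac_depleted: float = 0.05
    frac_enriched: float = 0.03
    effect_log2fc: float = 2.0
    frac_active_shrnas: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.shrnas_per_gene <= 0 or self.n_replicates <= 0:
            raise ValueError("n_genes, shrnas_per_gene and n_replicates must be positive")
        if not (math.isfinite(self.baseline_mean) and self.baseline_mean > 0):
            raise ValueError("baseline_mean must be a finite positive number")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        for name in ("frac_depleted", "frac_enriched", "frac_active_shrnas"):
            _check_fraction(name, getattr(self, name))
        if self.frac_depleted + self.frac_enriched > 1.0:
            raise ValueError("frac_depleted + frac_enriched must not exceed 1")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB2 counts with Var = mu + dispersion * mu^2."""
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


def gen_screen_counts(config: ScreenSimConfig) -> tuple[ShRNACountMatrix, pd.DataFrame]:
    """Simulate raw screen counts plus the planted-gene truth table.

    Returns the count matrix (n_genes*shrnas_per_gene rows, 2*n_replicates
    sample columns named ``control_<r>``/``treated_<r>``) and a truth table
    indexed by gene_id with ``label`` in {depleted, enriched, null} and the
    number of hairpins carrying the effect.
    """
    n_dep = round(config.frac_depleted * config.n_genes)
    n_enr = round(config.frac_enriched * config.n_genes)
    n_active = math.ceil(config.frac_active_shrnas * config.shrnas_per_gene)
    sample_names = [f"control_{r + 1}" for r in range(config.n_replicates)] + [
        f"treated_{r + 1}" for r in range(config.n_replicates)
    ]
    n_samples = len(sample_names)
    width = len(str(config.n_genes))

    blocks, shrna_ids, gene_ids, truth_rows = [], [], [], []
    for gi in range(config.n_genes):
        gene = f"gene_{gi + 1:0{width}d}"
        if gi < n_dep:
            label, sign = "depleted", -1.0
        elif gi < n_dep + n_enr:
            label, sign = "enriched", +1.0
        else:
            label, sign = "null", 0.0
        mean = np.full((config.shrnas_per_gene, n_samples), config.baseline_mean)
        if sign != 0.0 and config.effect_log2fc != 0.0:
            shift = 2.0 ** (sign * config.effect_log2fc)
            mean[:n_active, config.n_replicates:] *= shift
        rng = _child_rng(config.seed, gi)
        blocks.append(_nb_draw(rng, mean, config.dispersion))
        shrna_ids.extend(f"{gene}_sh{h + 1}" for h in range(config.shrnas_per_gene))
        gene_ids.extend([gene] * config.shrnas_per_gene)
        truth_rows.append(
            {"gene_id": gene, "label": label, "n_active_shrnas": n_active if sign else 0}
        )

    counts = pd.DataFrame(
        np.vstack(blocks), index=pd.Index(shrna_ids, name="shrna_id"), columns=sample_names
    )
    samples = pd.DataFrame(
        {
            "condition": ["control"] * config.n_replicates + ["treated"] * config.n_replicates,
            "replicate": list(range(1, config.n_replicates + 1)) * 2,
        },
        index=pd.Index(sample_names, name="sample_id"),
    )
    matrix = ShRNACountMatrix(
        counts=counts, genes=pd.Series(gene_ids, index=counts.index, name="gene_id"), samples=samples
    )
    truth = pd.DataFrame(truth_rows).set_index("gene_id")
    return matrix, truth


# ---------------------------------------------------------------------------
# Dose-response and combination viability
# ---------------------------------------------------------------------------

def median_effect_fa(dose: np.ndarray, m: float, Dm: float) -> np.ndarray:
    """Fraction affected under the median-effect model, fa = (D/Dm)^m / (1+(D/Dm)^m)."""
    ratio = (np.asarray(dose, dtype=float) / Dm) ** m
    return ratio / (1.0 + ratio)


def gen_dose_response(
    m: float,
    Dm: float,
    doses,
    n_replicates: int = 4,
    noise_sd: float = 0.0,
    seed: int = 0,
    drug_id: str = "drug",
) -> pd.DataFrame:
    """Single-agent viability table from the median-effect model.

    Per dose and replicate, ``pct_live = 100*(1 - fa)`` plus Gaussian noise
    truncated to the physical bounds [0, 100] of a viability assay.
    Columns: ``drug_id, dose_um, replicate, pct_live``.
    """
    if m <= 0 or Dm <= 0:
        raise ValueError("m and Dm must be positive")
    doses = np.asarray(doses, dtype=float)
    if (doses <= 0).any():
        raise ValueError("doses must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    fa = median_effect_fa(doses, m, Dm)
    rows = []
    for d, f in zip(doses, fa):
        for rep in range(1, n_replicates + 1):
            live = 100.0 * (1.0 - f)
            if noise_sd > 0:
                live += rng.normal(0.0, noise_sd)
            rows.append(
                {
                    "drug_id": drug_id,
                    "dose_um": d,
                    "replicate": rep,
                    "pct_live": float(np.clip(live, 0.0, 100.0)),
                }
            )
    return pd.DataFrame(rows)


def gen_combination(
    fit_a: MedianEffectFit,
    fit_b: MedianEffectFit,
    dose_pairs,
    target_ci: float,
    n_replicates: int = 1,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Combination viability table whose true CI equals ``target_ci``.

    For each (dose_a, dose_b), solves the combination-index equation
    ``dA/DxA(fa) + dB/DxB(fa) = target_ci`` for fa; the left side is
    strictly decreasing in fa so the root on (0, 1) is unique. Pairs for
    which the solver fails are skipped with a warning. The emitted table has
    ``dose_a_um, dose_b_um, replicate, pct_live`` plus the noise-free
    ``fa_true`` ground truth.
    """
    if target_ci <= 0:
        raise ValueError("target_ci must be positive")
    for fit in (fit_a, fit_b):
        if not fit.monotone:
            raise ValueError(f"degenerate fit for {fit.drug_id!r}")
    rng = np.random.default_rng(seed)
    rows = []
    for da, db in dose_pairs:
        def gap(fa: float) -> float:
            return da / dose_for_effect(fit_a, fa) + db / dose_for_effect(fit_b, fa) - target_ci

        try:
            fa = optimize.brentq(gap, 1e-12, 1.0 - 1e-12, xtol=1e-14, rtol=1e-15)
        except ValueError:
            warnings.warn(f"no fa in (0,1) solves CI={target_ci} at pair ({da}, {db}); skipped")
            continue
        for rep in range(1, n_replicates + 1):
            live = 100.0 * (1.0 - fa)
            if noise_sd > 0:
                live += rng.normal(0.0, noise_sd)
            rows.append(
                {
                    "dose_a_um": float(da),
                    "dose_b_um": float(db),
                    "replicate": rep,
                    "pct_live": float(np.clip(live, 0.0, 100.0)),
                    "fa_true": float(fa),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# SLAM-seq conversion counts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SlamSimConfig:
    """Simulation parameters for conversion-stratified SLAM-seq counts.

    Reads are a mixture: a fraction ``frac_labeled`` are nascent (4sU-
    labelled) and convert each of their ``n_t_sites`` T positions at
    ``p_conversion_labeled``; the rest convert only at the sequencing-error
    rate ``p_conversion_background``. Repressed genes lose labelled reads by
    ``repression_log2fc`` in treated samples only; unlabelled (pre-existing)
    reads are untouched, emulating a purely transcriptional effect on the
    short labelling timescale.
    """

    n_genes: int = 300
    utrs_per_gene: int = 2
    n_replicates: int = 3
    reads_per_utr_mean: float = 500.0
    n_t_sites: int = 25
    p_conversion_labeled: float = 0.025
    p_conversion_background: float = 0.001
    frac_labeled: float = 0.3
    frac_repressed: float = 0.1
    repression_log2fc: float = -2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.utrs_per_gene, self.n_replicates, self.n_t_sites) <= 0:
            raise ValueError("counts and sizes must be positive")
        if self.reads_per_utr_mean <= 0:
            raise ValueError("reads_per_utr_mean must be positive")
        for name in (
            "p_conversion_labeled",
            "p_conversion_background",
            "frac_labeled",
            "frac_repressed",
        ):
            _check_fraction(name, getattr(self, name))
        if self.p_conversion_background >= self.p_conversion_labeled:
            raise ValueError("p_conversion_background must be below p_conversion_labeled")


def _conversion_strata(
    rng: np.random.Generator, n_reads: int, n_sites: int, p: float
) -> np.ndarray:
    """Counts of reads with exactly k = 0..n_sites conversions."""
    if n_reads == 0:
        return np.zeros(n_sites + 1, dtype=int)
    pmf = stats.binom.pmf(np.arange(n_sites + 1), n_sites, p)
    pmf = pmf / pmf.sum()
    return rng.multinomial(n_reads, pmf)


def gen_slamseq_counts(config: SlamSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate conversion-stratified read counts plus the truth table.

    Returns a long table with columns ``utr_id, gene_id, sample_id,
    condition, replicate, k, n_reads`` covering both conditions (``DMSO``
    control and ``C646`` treated), and a truth table indexed by gene_id with
    ``repressed`` and ``true_log2fc`` (the planted labelled-read log2 fold
    change; 0 for unaffected genes).
    """
    n_rep_genes = round(config.frac_repressed * config.n_genes)
    width = len(str(config.n_genes))
    samples = [("DMSO", r) for r in range(1, config.n_replicates + 1)] + [
        ("C646", r) for r in range(1, config.n_replicates + 1)
    ]
    rows, truth_rows = [], []
    for gi in range(config.n_genes):
        gene = f"gene_{gi + 1:0{width}d}"
        repressed = gi < n_rep_genes
        truth_rows.append(
            {
                "gene_id": gene,
                "repressed": repressed,
                "true_log2fc": config.repression_log2fc if repressed else 0.0,
            }
        )
        rng = _child_rng(config.seed, gi)
        for u in range(config.utrs_per_gene):
            utr = f"{gene}_utr{u + 1}"
            for cond, rep in samples:
                lam_lab = config.reads_per_utr_mean * config.frac_labeled
                if repressed and cond == "C646":
                    lam_lab *= 2.0**config.repression_log2fc
                lam_old = config.reads_per_utr_mean * (1.0 - config.frac_labeled)
                n_lab = int(rng.poisson(lam_lab))
                n_old = int(rng.poisson(lam_old))
                strata = _conversion_strata(
                    rng, n_lab, config.n_t_sites, config.p_conversion_labeled
                ) + _conversion_strata(
                    rng, n_old, config.n_t_sites, config.p_conversion_background
                )
                sample_id = f"{cond}_{rep}"
                for k in np.nonzero(strata)[0]:
                    rows.append(
                        {
                            "utr_id": utr,
                            "gene_id": gene,
                            "sample_id": sample_id,
                            "condition": cond,
                            "replicate": rep,
                            "k": int(k),
                            "n_reads": int(strata[k]),
                        }
                    )
    return pd.DataFrame(rows), pd.DataFrame(truth_rows).set_index("gene_id")


# ---------------------------------------------------------------------------
# Nascent-proteome protein groups
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteomeSimConfig:
    """Simulation parameters for MaxQuant-style protein-group PSM tables.

    PSM counts are Poisson around ``psm_mean`` per replicate. QC artefacts
    (contaminant / decoy / only-by-site) and no-AHA background binders are
    assigned independently at the configured fractions; a sub-fraction of
    background proteins get a weak background signal so their untreated/
    background ratio clears the 10-fold rescue. Affected proteins have their
    treated-condition mean multiplied by ``reduction_factor``.
    """

    n_proteins: int = 2800
    frac_contaminant: float = 0.02
    frac_reverse: float = 0.02
    frac_onlysite: float = 0.02
    frac_background: float = 0.06
    frac_background_highratio: float = 0.05
    psm_mean: float = 25.0
    frac_affected: float = 0.68
    reduction_factor: float = 0.1
    n_dmso_reps: int = 3
    n_treated_reps: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins <= 0 or self.n_dmso_reps <= 0 or self.n_treated_reps <= 0:
            raise ValueError("n_proteins and replicate counts must be positive")
        if self.psm_mean <= 0:
            raise ValueError("psm_mean must be positive")
        for name in (
            "frac_contaminant",
            "frac_reverse",
            "frac_onlysite",
            "frac_background",
            "frac_background_highratio",
            "frac_affected",
            "reduction_factor",
        ):
            _check_fraction(name, getattr(self, name))


def gen_protein_groups(config: ProteomeSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate protein-group records plus the per-protein truth table.

    Returns a records table indexed by protein_id with ``gene_id``, boolean
    QC flag columns, ``psm_background`` and per-replicate ``psm_dmso_*`` /
    ``psm_treated_*`` counts, and a truth table with ``affected``,
    ``category`` ({clean, contaminant, reverse, only_by_site}),
    ``background`` and ``background_highratio``.
    """
    c1 = config.frac_contaminant
    c2 = c1 + config.frac_reverse
    c3 = c2 + config.frac_onlysite
    width = len(str(config.n_proteins))
    rows, truth_rows = [], []
    for pi in range(config.n_proteins):
        pid = f"protein_{pi + 1:0{width}d}"
        rng = _child_rng(config.seed, pi)
        u_cat, u_bg, u_hr, u_aff = rng.random(4)
        if u_cat < c1:
            category = "contaminant"
        elif u_cat < c2:
            category = "reverse"
        elif u_cat < c3:
            category = "only_by_site"
        else:
            category = "clean"
        background = u_bg < config.frac_background
        highratio = background and (u_hr < config.frac_background_highratio)
        affected = u_aff < config.frac_affected

        dmso = rng.poisson(config.psm_mean, size=config.n_dmso_reps)
        treated_mean = config.psm_mean * (config.reduction_factor if affected else 1.0)
        treated = rng.poisson(treated_mean, size=config.n_treated_reps)
        if background:
            # weak signal for rescued binders, comparable signal otherwise
            bg_mean = config.psm_mean / 50.0 if highratio else config.psm_mean
            psm_bg = max(1, int(rng.poisson(bg_mean)))
        else:
            psm_bg = 0

        row = {
            "protein_id": pid,
            "gene_id": f"gene_{pi + 1:0{width}d}",
            "potential_contaminant": category == "contaminant",
            "reverse": category == "reverse",
            "only_identified_by_site": category == "only_by_site",
            "psm_background": psm_bg,
        }
        row.update({f"psm_dmso_{r + 1}": int(v) for r, v in enumerate(dmso)})
        row.update({f"psm_treated_{r + 1}": int(v) for r, v in enumerate(treated)})
        rows.append(row)
        truth_rows.append(
            {
                "protein_id": pid,
                "affected": affected,
                "category": category,
                "background": background,
                "background_highratio": highratio,
            }
        )
    records = pd.DataFrame(rows).set_index("protein_id")
    truth = pd.DataFrame(truth_rows).set_index("protein_id")
    return records, truth
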