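"""Chou-Talalay median-effect dose-response and combination-index analysis.

The median-effect model relates the fraction of cells affected (fa) to dose:
``fa/fu = (D/Dm)^m`` with ``fu = 1 - fa``, where Dm is the dose producing a
50% effect (the IC50 surrogate) and m the sigmoidicity slope. The model is
linear in log space, ``log10(fa/fu) = m*log10(D) - m*log10(Dm)``, so single-
agent parameters are fitted by ordinary least squares. For a combination
observed at effect level fa, the combination index is

    CI = dA / DxA(fa) + dB / DxB(fa),

where Dx(fa) = Dm * (fa/(1-fa))^(1/m) is the single-agent dose that alone
would give fa. CI < 1 indicates synergy, CI = 1 additivity and CI > 1
antagonism; finer bands follow the conventional table (synergism up to 0.85,
additive 0.9-1.1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DEFAULT_BANDS",
    "FA_EPS",
    "MedianEffectFit",
    "CIResult",
    "viability_to_fa",
    "fit_median_effect",
    "dose_for_effect",
    "combination_index",
    "classify_ci",
    "ci_table",
]

#: Clipping distance keeping fa strictly inside (0,1): the log(fa/fu)
#: linearisation is undefined at the boundaries.
FA_EPS = 1e-3

#: Default CI band table as (upper_edge, inclusive, label), in increasing
#: order; any CI above the last edge gets the final label. Edges are
#: inclusive on the synergism side.
DEFAULT_BANDS: tuple[tuple[float, bool, str], ...] = (
    (0.85, True, "synergism"),
    (0.90, False, "slight_synergism"),
    (1.10, True, "additive"),
    (1.20, True, "slight_antagonism"),
    (float("inf"), True, "antagonism"),
)


@dataclass(frozen=True)
class MedianEffectFit:
    """Single-agent median-effect parameters from the linearised fit.

    ``r`` is the Pearson correlation of (log10 D, log10 fa/fu); a fit with
    ``m <= 0`` is non-monotone (viability rising with dose) and is flagged
    rather than silently used.
    """

    drug_id: str
    m: float
    Dm: float
    r: float
    n_points: int

    @property
    def monotone(self) -> bool:
        return self.m > 0


@dataclass(frozen=True)
class CIResult:
    dose_a: float
    dose_b: float
    fa_observed: float
    dx_a: float
    dx_b: float
    ci: float
    label: str


def viability_to_fa(
    pct_live_treated: float, pct_live_vehicle: float, eps: float = FA_EPS
) -> float:
    """Convert % live cells (relative to vehicle) to fraction affected.

    ``fa = 1 - treated/vehicle``, clipped to [eps, 1-eps]. Apparent
    stimulation (treated > vehicle) clips to eps with a warning.
    """
    if pct_live_vehicle <= 0:
        raise ValueError("vehicle viability must be positive")
    raw = 1.0 - pct_live_treated / pct_live_vehicle
    if raw < 0:
        warnings.warn(
            "treated viability exceeds vehicle (stimulation); fa clipped to eps",
            stacklevel=2,
        )
    return float(np.clip(raw, eps, 1.0 - eps))


def fit_median_effect(points: pd.DataFrame, drug_id: str | None = None) -> MedianEffectFit:
    """Fit (m, Dm, r) by OLS of log10(fa/fu) on log10(dose).

    ``points`` needs columns ``dose_um`` and ``fa`` with fa strictly inside
    (0, 1); at least two distinct doses are required. Replicates at the same
    dose are used as individual points.
    """
    d = points["dose_um"].to_numpy(dtype=float)
    fa = points["fa"].to_numpy(dtype=float)
    if (d <= 0).any():
        raise ValueError("doses must be positive")
    ok = (fa > 0) & (fa < 1)
    d, fa = d[ok], fa[ok]
    if len(np.unique(d)) < 2:
        raise ValueError("need >=2 distinct doses with fa strictly inside (0,1)")
    x = np.log10(d)
    y = np.log10(fa / (1.0 - fa))
    res = stats.linregress(x, y)
    m = float(res.slope)
    if m <= 0:
        warnings.warn("non-monotone median-effect fit (slope <= 0)", stacklevel=2)
        dm = float("nan")
    else:
        dm = float(10.0 ** (-res.intercept / m))
    if drug_id is None:
        drug_id = str(points["drug_id"].iloc[0]) if "drug_id" in points else "drug"
    return MedianEffectFit(drug_id=drug_id, m=m, Dm=dm, r=float(res.rvalue), n_points=len(d))


def dose_for_effect(fit: MedianEffectFit, fa: float) -> float:
    """Dx = Dm * (fa/(1-fa))^(1/m): single-agent dose producing effect fa."""
    if not (0.0 < fa < 1.0):
        raise ValueError("fa must be strictly inside (0, 1)")
    if fit.m == 0:
        raise ValueError("median-effect slope m must be non-zero")
    return float(fit.Dm * (fa / (1.0 - fa)) ** (1.0 / fit.m))


def classify_ci(
    ci: float, bands: tuple[tuple[float, bool, str], ...] = DEFAULT_BANDS
) -> str:
    """Map a combination index onto its interaction label.

    ``bands`` is an increasing sequence of (upper_edge, inclusive, label);
    the last band must have an infinite edge so the labels partition (0, inf).
    """
    if ci <= 0:
        raise ValueError("CI must be positive")
    edges = [b[0] for b in bands]
    if any(e2 <= e1 for e1, e2 in zip(edges, edges[1:])):
        raise ValueError("band edges must be strictly increasing")
    if not np.isinf(edges[-1]):
        raise ValueError("last band must cover (edge, inf)")
    for edge, inclusive, label in bands:
        if ci < edge or (inclusive and ci == edge):
            return label
    return bands[-1][2]  # pragma: no cover - inf edge always matches


def combination_index(
    fit_a: MedianEffectFit,
    fit_b: MedianEffectFit,
    dose_a: float,
    dose_b: float,
    fa_observed: float,
    bands: tuple[tuple[float, bool, str], ...] = DEFAULT_BANDS,
) -> CIResult:
    """Combination index for one observed combination dose point.

    Evaluated independently per point with its observed fa (non-constant-
    ratio design: one drug swept over doses against a fixed dose of the
    partner).
    """
    for fit in (fit_a, fit_b):
        if not fit.monotone:
            raise ValueError(f"degenerate median-effect fit for {fit.drug_id!r} (m <= 0)")
    if dose_a <= 0 or dose_b <= 0:
        raise ValueError("combination doses must be positive")
    dx_a = dose_for_effect(fit_a, fa_observed)
    dx_b = dose_for_effect(fit_b, fa_observed)
    ci = dose_a / dx_a + dose_b / dx_b
    return CIResult(
        dose_a=dose_a,
        dose_b=dose_b,
        fa_observed=fa_observed,
        dx_a=dx_a,
        dx_b=dx_b,
        ci=ci,
        label=classify_ci(ci, bands),
    )


def ci_table(
    fit_a: MedianEffectFit,
    fit_b: MedianEffectFit,
    combo: pd.DataFrame,
    vehicle_pct_live: float = 100.0,
    eps: float = FA_EPS,
    bands: tuple[tuple[float, bool, str], ...] = DEFAULT_BANDS,
) -> pd.DataFrame:
    """Per-dose-pair CI from a replicated combination viability table.

    ``combo`` needs columns ``dose_a_um, dose_b_um, replicate, pct_live``.
    fa is computed per replicate and the CI at each dose pair uses the
    replicate-mean fa; per-replicate CIs are also reported (``ci_sd``) as a
    dispersion summary.
    """
    rows = []
    for (da, db), grp in combo.groupby(["dose_a_um", "dose_b_um"], sort=True):
        fas = np.array(
            [viability_to_fa(v, vehicle_pct_live, eps) for v in grp["pct_live"]]
        )
        res = combination_index(fit_a, fit_b, float(da), float(db), float(fas.mean()), bands)
        rep_cis = [
            combination_index(fit_a, fit_b, float(da), float(db), float(f), bands).ci
            for f in fas
        ]
        rows.append(
            {
                "dose_a_um": res.dose_a,
                "dose_b_um": res.dose_b,
                "fa_observed": res.fa_observed,
                "dx_a": res.dx_a,
                "dx_b": res.dx_b,
                "ci": res.ci,
                "ci_sd": float(np.std(rep_cis, ddof=1)) if len(rep_cis) > 1 else 0.0,
                "label": res.label,
            }
        )
    return pd.DataFrame(rows)
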