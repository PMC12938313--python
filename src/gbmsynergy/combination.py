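"""Chou-Talalay combination-index scoring over dose-pair grids.

For an observed fraction affected ``fa`` at a dose pair (d1, d2), the
combination index is the two-term (mutually exclusive) form

    CI = d1 / Dx1(fa) + d2 / Dx2(fa)

where ``Dx_i(fa)`` is the single-agent dose of drug *i* producing ``fa``
under its fitted median-effect curve.  CI < 1 indicates synergy, CI near 1
an additive interaction, CI > 1 antagonism.  The grid design mirrors a
non-constant-ratio screen: drug 1 in a serial dilution crossed with a few
fixed partner doses of drug 2, with fa measured (not modeled) per cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dose_response import FA_CLIP, DoseResponseError, MedianEffectFit, dose_for_effect

__all__ = [
    "DoseMatrix",
    "CIPoint",
    "InteractionCall",
    "SensitivitySynergyCorrelation",
    "ADDITIVE_BAND",
    "DEFAULT_FA_MIN",
    "ci_point",
    "ci_grid",
    "min_ci",
    "classify_interaction",
    "isobologram",
    "fixed_dose_effect",
    "correlate_sensitivity_synergy",
]

#: "C.I. around 1" band for interaction calls (the additive zone).
ADDITIVE_BAND = (0.9, 1.1)

#: default effect floor for the lowest-CI search; CI estimates at very low
#: fractional effect are noise-dominated.
DEFAULT_FA_MIN = 0.2


@dataclass(frozen=True)
class DoseMatrix:
    """Measured fraction-affected over a drug1 x drug2 dose grid."""

    drug1_doses: np.ndarray  # µM, serial dilution of drug 1
    drug2_doses: np.ndarray  # µM, fixed partner doses of drug 2
    fa_grid: np.ndarray  # shape (len(drug1_doses), len(drug2_doses))
    model_id: str = ""

    def __post_init__(self):
        d1 = np.asarray(self.drug1_doses, dtype=float)
        d2 = np.asarray(self.drug2_doses, dtype=float)
        fa = np.asarray(self.fa_grid, dtype=float)
        if np.any(d1 <= 0) or np.any(d2 <= 0):
            raise ValueError("all grid doses must be strictly positive")
        if fa.shape != (d1.size, d2.size):
            raise ValueError("fa_grid shape must be (n_drug1, n_drug2)")
        ok = np.isnan(fa) | ((fa >= 0) & (fa <= 1))
        if not np.all(ok):
            raise ValueError("fa_grid values must be in [0, 1] or NaN (missing)")
        object.__setattr__(self, "drug1_doses", d1)
        object.__setattr__(self, "drug2_doses", d2)
        object.__setattr__(self, "fa_grid", fa)

    @property
    def n_conditions(self) -> int:
        return int(self.fa_grid.size)


@dataclass(frozen=True)
class CIPoint:
    """Combination-index evaluation at one dose pair."""

    d1: float
    d2: float
    fa: float
    Dx1: float
    Dx2: float
    ci: float
    flags: tuple[str, ...] = field(default_factory=tuple)

    @property
    def evaluable(self) -> bool:
        return not self.flags


@dataclass(frozen=True)
class InteractionCall:
    label: str  # synergistic | additive | antagonistic
    additive_band: tuple[float, float] = ADDITIVE_BAND


@dataclass(frozen=True)
class SensitivitySynergyCorrelation:
    r: float
    p: float
    n: int


def ci_point(
    d1: float,
    d2: float,
    fa: float,
    fit1: MedianEffectFit,
    fit2: MedianEffectFit,
    clip: float = FA_CLIP,
) -> CIPoint:
    """Evaluate the two-term combination index at one dose pair.

    Points whose fa lies at the clip boundary (effectively 0% or 100% kill)
    are flagged ``unreliable`` and excluded from the lowest-CI search.
    """
    fa_c = float(np.clip(fa, clip, 1.0 - clip))
    flags: list[str] = []
    if not (clip < fa_c < 1.0 - clip) or fa_c != fa:
        flags.append("unreliable")
    dx1 = dose_for_effect(fit1, fa_c)
    dx2 = dose_for_effect(fit2, fa_c)
    ci = d1 / dx1 + d2 / dx2
    return CIPoint(
        d1=float(d1), d2=float(d2), fa=fa_c, Dx1=dx1, Dx2=dx2, ci=float(ci),
        flags=tuple(flags),
    )


def ci_grid(
    matrix: DoseMatrix,
    fit1: MedianEffectFit,
    fit2: MedianEffectFit,
    clip: float = FA_CLIP,
) -> list[CIPoint]:
    """Evaluate the combination index at every grid cell.

    Returns one CIPoint per cell; cells with missing fa or fa at the clip
    boundary are flagged.  Raises if no cell is evaluable.
    """
    points: list[CIPoint] = []
    for i, d1 in enumerate(matrix.drug1_doses):
        for j, d2 in enumerate(matrix.drug2_doses):
            fa = matrix.fa_grid[i, j]
            if np.isnan(fa):
                points.append(
                    CIPoint(d1=float(d1), d2=float(d2), fa=float("nan"),
                            Dx1=float("nan"), Dx2=float("nan"), ci=float("nan"),
                            flags=("missing",))
                )
                continue
            points.append(ci_point(d1, d2, fa, fit1, fit2, clip=clip))
    if not any(p.evaluable for p in points):
        raise DoseResponseError("no-evaluable-points", "no evaluable grid cell")
    return points


def min_ci(
    grid: list[CIPoint], fa_min: float = DEFAULT_FA_MIN
) -> tuple[float, CIPoint]:
    """Lowest combination index among evaluable points with fa >= fa_min.

    Ties are broken toward higher fa, then lower total dose, so the reported
    condition is the most strongly supported one.
    """
    candidates = [p for p in grid if p.evaluable and p.fa >= fa_min]
    if not candidates:
        raise DoseResponseError(
            "no-evaluable-points", f"no unflagged point with fa >= {fa_min}"
        )
    best = min(candidates, key=lambda p: (p.ci, -p.fa, p.d1 + p.d2))
    return best.ci, best


def classify_interaction(
    ci: float, band: tuple[float, float] = ADDITIVE_BAND
) -> InteractionCall:
    """Call the interaction: synergy below the additive band, antagonism above."""
    if ci < 0:
        raise ValueError("combination index must be >= 0")
    low, high = band
    if not (low < 1.0 < high):
        raise ValueError("additive band must straddle 1")
    if ci < low:
        label = "synergistic"
    elif ci <= high:
        label = "additive"
    else:
        label = "antagonistic"
    return InteractionCall(label=label, additive_band=(low, high))


def isobologram(grid: list[CIPoint]) -> pd.DataFrame:
    """Normalized-dose isobologram coordinates for each evaluable point.

    Each point is (d1/Dx1, d2/Dx2, fa); the two coordinates sum to the CI, so
    additive points fall on the unit antidiagonal and synergistic points below.
    """
    rows = [
        {"d1_norm": p.d1 / p.Dx1, "d2_norm": p.d2 / p.Dx2, "fa": p.fa, "ci": p.ci}
        for p in grid
        if p.evaluable
    ]
    return pd.DataFrame(rows, columns=["d1_norm", "d2_norm", "fa", "ci"])


def fixed_dose_effect(
    viability_single: float, viability_combo: float
) -> dict[str, float]:
    """Viability change when a partner is added to a fixed single-agent dose.

    Returns the percentage-point drop of control-normalized viability
    (``delta_pp``) and, because "X% decrease" is also read as a relative
    change, the relative decrease (``delta_rel_pct``).
    """
    for v in (viability_single, viability_combo):
        if not (0.0 <= v <= 1.0):
            raise ValueError("viabilities must lie in [0, 1]")
    delta_pp = 100.0 * (viability_single - viability_combo)
    delta_rel = (
        100.0 * (viability_single - viability_combo) / viability_single
        if viability_single > 0
        else float("nan")
    )
    return {"delta_pp": delta_pp, "delta_rel_pct": delta_rel}


def correlate_sensitivity_synergy(
    ic50s, cis
) -> SensitivitySynergyCorrelation:
    """Pearson correlation between single-agent IC50 and combination index.

    A negative r means models more resistant to the single agent gain more
    from the combination.  Two-sided p from the t distribution with n-2 df.
    """
    x = np.asarray(ic50s, dtype=float)
    y = np.asarray(cis, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("ic50s and cis must be 1-D and the same length")
    if x.size < 3:
        raise ValueError("need at least 3 models")
    if np.any(~np.isfinite(x)) or np.any(~np.isfinite(y)):
        raise ValueError("missing values not allowed")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DoseResponseError("degenerate-input", "zero variance in a vector")
    res = stats.pearsonr(x, y)
    return SensitivitySynergyCorrelation(
        r=float(res.statistic), p=float(res.pvalue), n=x.size
    )
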