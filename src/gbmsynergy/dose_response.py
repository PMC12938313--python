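"""Single-agent dose-response analysis under the median-effect model.

Raw plate-reader luminescence is normalized against vehicle controls to a
fraction-affected curve, which is then fitted by the mass-action
median-effect model

    fa / fu = (D / Dm) ** m

whose log-linearization  log(fa/fu) = m*log(D) - m*log(Dm)  is fitted by
ordinary least squares.  ``Dm`` (the dose giving fa = 0.5) is reported as
the IC50.  A four-parameter logistic fit is available as a diagnostic
cross-check; the median-effect ``Dm`` is the canonical IC50 because the
combination-index machinery is built on the same model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "EffectVector",
    "MedianEffectFit",
    "FourPLFit",
    "DoseResponseError",
    "normalize_viability",
    "fit_median_effect",
    "dose_for_effect",
    "effect_at_dose",
    "fit_four_pl",
    "FA_CLIP",
]

#: fraction-affected clipping bound applied before the log-odds transform;
#: points at the clip boundary are excluded from the regression.
FA_CLIP = 1e-4


class DoseResponseError(ValueError):
    """Raised for unusable dose-response input; ``.code`` is machine-readable."""

    def __init__(self, code: str, message: str):
        super().__init__(message)
        self.code = code


@dataclass(frozen=True)
class EffectVector:
    """Fraction affected at each positive dose of a single agent.

    ``fa`` is 1 - viability where viability is luminescence relative to the
    mean of vehicle-control (dose 0) wells; replicates are averaged at the
    luminescence level before normalization.
    """

    doses: np.ndarray  # µM, strictly increasing
    fa: np.ndarray  # fraction affected in [0, 1]
    n_reps: np.ndarray
    model_id: str = ""
    agent: str = ""
    n_clipped_stimulation: int = 0  # wells with viability > 1 clipped to 1

    @property
    def fu(self) -> np.ndarray:
        return 1.0 - self.fa

    def __post_init__(self):
        d = np.asarray(self.doses, dtype=float)
        f = np.asarray(self.fa, dtype=float)
        if d.ndim != 1 or d.shape != f.shape:
            raise ValueError("doses and fa must be 1-D arrays of equal length")
        if np.any(d <= 0):
            raise ValueError("doses must be strictly positive")
        if np.any(np.diff(d) <= 0):
            raise ValueError("doses must be strictly increasing")
        if np.any((f < 0) | (f > 1)):
            raise ValueError("fa must lie in [0, 1]")
        object.__setattr__(self, "doses", d)
        object.__setattr__(self, "fa", f)
        object.__setattr__(self, "n_reps", np.asarray(self.n_reps, dtype=int))


@dataclass(frozen=True)
class MedianEffectFit:
    """Parameters of the median-effect linearization for one agent."""

    m: float  # sigmoidicity (slope of the linearization)
    Dm: float  # median-effect dose, µM; fa = 0.5 at D = Dm
    r_linfit: float  # Pearson correlation of the linearization
    n_points_used: int
    model_id: str = ""
    agent: str = ""
    flags: tuple[str, ...] = field(default_factory=tuple)

    @property
    def ic50(self) -> float:
        return self.Dm


@dataclass(frozen=True)
class FourPLFit:
    """Four-parameter logistic fit of viability vs dose (diagnostic only)."""

    bottom: float
    top: float
    hill: float
    ec50: float  # µM
    flags: tuple[str, ...] = field(default_factory=tuple)


def normalize_viability(
    records: pd.DataFrame, model_id: str, agent: str
) -> EffectVector:
    """Normalize raw luminescence to a fraction-affected vector.

    Parameters
    ----------
    records
        Long-format viability table with columns ``model_id``, ``agent``,
        ``dose_uM``, ``luminescence``, ``replicate``.  Vehicle controls are
        rows with ``dose_uM == 0`` for the same model (any agent).
    model_id, agent
        Which single-agent series to extract.

    Returns
    -------
    EffectVector with fa = 1 - mean(lum at dose)/mean(control lum), clipped
    to [0, 1].  Viability above 1 (apparent stimulation) is clipped with a
    counter on the result.
    """
    sub = records[records["model_id"] == model_id]
    if "dose2_uM" in sub.columns:  # combination wells are not single-agent data
        sub = sub[sub["dose2_uM"].fillna(0) == 0]
    ctrl = sub.loc[sub["dose_uM"] == 0, "luminescence"]
    if len(ctrl) == 0 or not np.isfinite(ctrl.mean()) or ctrl.mean() <= 0:
        raise DoseResponseError(
            "no-control",
            f"no vehicle control (dose 0) with positive luminescence for "
            f"model {model_id!r}",
        )
    ctrl_mean = float(ctrl.mean())

    treated = sub[(sub["agent"] == agent) & (sub["dose_uM"] > 0)]
    if treated["dose_uM"].nunique() < 3:
        raise DoseResponseError(
            "insufficient-doses",
            f"fewer than 3 nonzero doses for model {model_id!r}, agent {agent!r}",
        )
    by_dose = (
        treated.groupby("dose_uM")["luminescence"].agg(["mean", "size"]).sort_index()
    )
    viability = by_dose["mean"].to_numpy() / ctrl_mean
    n_stim = int(np.sum(viability > 1.0))
    fa = np.clip(1.0 - viability, 0.0, 1.0)
    return EffectVector(
        doses=by_dose.index.to_numpy(dtype=float),
        fa=fa,
        n_reps=by_dose["size"].to_numpy(),
        model_id=model_id,
        agent=agent,
        n_clipped_stimulation=n_stim,
    )


def fit_median_effect(
    effect: EffectVector,
    clip: float = FA_CLIP,
    fa_window: tuple[float, float] = (0.1, 1.0),
) -> MedianEffectFit:
    """Fit m and Dm by OLS on the median-effect linearization.

    Fractions affected are clipped to ``[clip, 1-clip]``; points that land on
    the clip boundary carry no usable effect information and are excluded.
    The regression is further restricted to ``fa_window`` (default
    [0.1, 1.0], i.e. a low-effect floor only): under multiplicative
    (CV-type) assay noise the error of log(fa/fu) scales as 1/fa, so doses
    with near-zero true effect turn pure noise into extreme leverage points,
    while near-complete-kill doses remain precise.  If fewer than 3 doses
    fall in the window, the unclipped points nearest fa = 0.5 are added until
    3 are available, so steep curves on sparse dilution ladders remain
    fittable (and noiseless data is still reproduced exactly).
    """
    fa = np.clip(effect.fa, clip, 1.0 - clip)
    usable = (fa > clip) & (fa < 1.0 - clip)
    in_window = usable & (fa >= fa_window[0]) & (fa <= fa_window[1])
    if in_window.sum() < 3:
        extras = np.flatnonzero(usable & ~in_window)
        # deterministic: closest to the median effect first, then lower dose
        extras = extras[np.lexsort((effect.doses[extras],
                                    np.abs(fa[extras] - 0.5)))]
        take = extras[: max(0, 3 - int(in_window.sum()))]
        in_window = in_window.copy()
        in_window[take] = True
    if in_window.sum() < 3:
        raise DoseResponseError(
            "insufficient-effect-range",
            f"only {int(in_window.sum())} dose(s) with fa strictly inside "
            f"({clip}, {1 - clip}); need >= 3",
        )
    usable = in_window
    x = np.log(effect.doses[usable])
    y = np.log(fa[usable] / (1.0 - fa[usable]))
    res = stats.linregress(x, y)
    m = float(res.slope)
    flags: list[str] = []
    if m <= 0:
        flags.append("non-monotone-fit")
        warnings.warn(
            f"median-effect slope m={m:.3g} <= 0 for "
            f"{effect.model_id}/{effect.agent}; Dm unreliable",
            stacklevel=2,
        )
        Dm = float("nan")
    else:
        Dm = float(np.exp(-res.intercept / m))
    return MedianEffectFit(
        m=m,
        Dm=Dm,
        r_linfit=float(res.rvalue),
        n_points_used=int(usable.sum()),
        model_id=effect.model_id,
        agent=effect.agent,
        flags=tuple(flags),
    )


def dose_for_effect(fit: MedianEffectFit, fa: float) -> float:
    """Invert the fitted median-effect curve: Dx = Dm*(fa/(1-fa))**(1/m)."""
    if not (0.0 < fa < 1.0):
        raise DoseResponseError("boundary-effect", f"fa={fa} must be in (0, 1)")
    if not (fit.m > 0) or not np.isfinite(fit.Dm):
        raise DoseResponseError(
            "non-monotone-fit", "dose_for_effect requires a valid fit with m > 0"
        )
    return float(fit.Dm * (fa / (1.0 - fa)) ** (1.0 / fit.m))


def effect_at_dose(fit: MedianEffectFit, dose: float | np.ndarray) -> np.ndarray:
    """Fraction affected predicted by the fit: fa = 1/(1 + (Dm/D)**m)."""
    dose = np.asarray(dose, dtype=float)
    ratio = (dose / fit.Dm) ** fit.m
    return ratio / (1.0 + ratio)


def _four_pl(d, bottom, top, hill, ec50):
    # decreasing viability curve: v(ec50) = midpoint
    return bottom + (top - bottom) / (1.0 + (d / ec50) ** hill)


def fit_four_pl(effect: EffectVector) -> FourPLFit:
    """Nonlinear least-squares 4PL fit of viability (= 1 - fa) vs dose.

    Diagnostic cross-check of the median-effect Dm; not used by the
    combination-index machinery.
    """
    if len(effect.doses) < 4:
        raise DoseResponseError("insufficient-doses", "4PL needs >= 4 doses")
    d = effect.doses
    v = 1.0 - effect.fa
    flags: list[str] = []
    # viability should fall with dose; a rising trend inverts the model
    if stats.linregress(np.log(d), v).slope > 0:
        raise DoseResponseError(
            "fit-failed", "viability increases with dose; 4PL model inverted"
        )
    ec50_guess = float(np.exp(np.interp(0.5, (v[::-1] - v.min()) / max(np.ptp(v), 1e-12),
                                        np.log(d[::-1]))))
    p0 = [max(v.min(), 0.0), min(v.max(), 1.0), 1.0, ec50_guess]
    try:
        popt, _ = optimize.curve_fit(
            _four_pl,
            d,
            v,
            p0=p0,
            bounds=([-0.5, 0.0, 0.05, d.min() / 1e3], [0.5, 2.0, 20.0, d.max() * 1e3]),
            maxfev=20000,
        )
    except RuntimeError as exc:  # pragma: no cover - scipy-specific failure path
        raise DoseResponseError("fit-failed", f"4PL did not converge: {exc}") from exc
    bottom, top, hill, ec50 = (float(p) for p in popt)
    if bottom >= top:
        raise DoseResponseError("fit-failed", "4PL fit degenerate: bottom >= top")
    if not (d.min() <= ec50 <= d.max()):
        flags.append("ec50-outside-tested-range")
    return FourPLFit(bottom=bottom, top=top, hill=hill, ec50=ec50, flags=tuple(flags))
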