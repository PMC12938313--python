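"""Limiting-dilution stem-cell frequency estimation (single-hit model).

A well seeded with ``d`` cells is positive (forms a sphere) if it received at
least one active cell.  With active-cell frequency ``f`` per cell, the
single-hit Poisson model gives

    P(negative | dose d) = exp(-f * d)

so positives are binomial with p(d) = 1 - exp(-f*d).  The frequency is
estimated by maximum likelihood on log(f) — equivalent to a binomial GLM
with complementary log-log link and offset log(d) — with 95% confidence
intervals from the profile likelihood (Wald on log f as fallback).  Group
differences are tested by a likelihood-ratio test of a common-frequency
model against group-specific frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "WellCounts",
    "FrequencyEstimate",
    "FrequencyComparison",
    "estimate_frequency",
    "compare_frequencies",
    "pairwise_comparison_table",
    "loglik",
]

_LOGF_LO, _LOGF_HI = -30.0, 0.0  # search window for log(f); f per-cell in (0, 1]


@dataclass(frozen=True)
class WellCounts:
    """Limiting-dilution outcome counts for one treatment group."""

    dose: np.ndarray  # cells/well, positive integers
    n_wells: np.ndarray
    n_positive: np.ndarray
    group: str = ""

    def __post_init__(self):
        d = np.asarray(self.dose, dtype=float)
        n = np.asarray(self.n_wells, dtype=int)
        k = np.asarray(self.n_positive, dtype=int)
        if not (d.shape == n.shape == k.shape) or d.ndim != 1:
            raise ValueError("dose, n_wells, n_positive must be 1-D, equal length")
        if np.any(d <= 0):
            raise ValueError("doses must be positive")
        if np.any(n < 1) or np.any(k < 0) or np.any(k > n):
            raise ValueError("need 0 <= n_positive <= n_wells, n_wells >= 1")
        object.__setattr__(self, "dose", d)
        object.__setattr__(self, "n_wells", n)
        object.__setattr__(self, "n_positive", k)

    @staticmethod
    def pool(groups: "list[WellCounts]", group: str = "pooled") -> "WellCounts":
        return WellCounts(
            dose=np.concatenate([g.dose for g in groups]),
            n_wells=np.concatenate([g.n_wells for g in groups]),
            n_positive=np.concatenate([g.n_positive for g in groups]),
            group=group,
        )


@dataclass(frozen=True)
class FrequencyEstimate:
    """MLE of the active-cell frequency with a CI on the 1-in-N scale."""

    f: float  # frequency per cell
    one_in: float  # 1 / f
    ci_low: float  # lower bound of one_in (from the upper bound of f)
    ci_high: float  # upper bound of one_in
    loglik: float
    group: str = ""
    flags: tuple[str, ...] = field(default_factory=tuple)


@dataclass(frozen=True)
class FrequencyComparison:
    group_a: str
    group_b: str
    chisq: float
    df: int
    p: float
    flags: tuple[str, ...] = field(default_factory=tuple)


def loglik(logf: float, wells: WellCounts) -> float:
    """Binomial log-likelihood of the single-hit model at log-frequency logf."""
    f = np.exp(logf)
    mu = f * wells.dose
    # log(1 - exp(-mu)) computed stably for small mu
    log_p_pos = np.log(-np.expm1(-mu))
    return float(np.sum(wells.n_positive * log_p_pos - (wells.n_wells - wells.n_positive) * mu))


def _score(logf: float, wells: WellCounts) -> float:
    """d loglik / d logf (analytic)."""
    f = np.exp(logf)
    mu = f * wells.dose
    with np.errstate(over="ignore"):
        ratio = mu / np.expm1(mu)  # mu * exp(-mu) / (1 - exp(-mu))
    return float(np.sum(wells.n_positive * ratio - (wells.n_wells - wells.n_positive) * mu))


def _mle_logf(wells: WellCounts) -> tuple[float, float]:
    res = optimize.minimize_scalar(
        lambda t: -loglik(t, wells),
        bounds=(_LOGF_LO, _LOGF_HI),
        method="bounded",
        options={"xatol": 1e-10},
    )
    t0 = float(res.x)
    # polish to machine precision on the analytic score
    lo, hi = t0 - 0.01, t0 + 0.01
    if _score(lo, wells) > 0 > _score(hi, wells):
        t0 = float(optimize.brentq(_score, lo, hi, args=(wells,), xtol=1e-14))
    return t0, loglik(t0, wells)


def _profile_bounds(wells: WellCounts, logf_hat: float, ll_max: float,
                    conf: float) -> tuple[float, float, list[str]]:
    """Profile-likelihood bounds on log f; Wald fallback on failure."""
    drop = stats.chi2.ppf(conf, df=1) / 2.0
    flags: list[str] = []

    def g(t):
        return loglik(t, wells) - (ll_max - drop)

    lo = hi = float("nan")
    try:
        # lower: walk left until g < 0
        a = logf_hat
        step = 0.5
        while g(a) > 0 and a > _LOGF_LO:
            a = max(a - step, _LOGF_LO)
            step *= 2
        lo = optimize.brentq(g, a, logf_hat, xtol=1e-10) if g(a) < 0 else _LOGF_LO
        # upper: walk right
        b = logf_hat
        step = 0.5
        while g(b) > 0 and b < _LOGF_HI:
            b = min(b + step, _LOGF_HI)
            step *= 2
        hi = optimize.brentq(g, logf_hat, b, xtol=1e-10) if g(b) < 0 else _LOGF_HI
        if hi >= _LOGF_HI:
            flags.append("ci-upper-at-bound")
    except (ValueError, RuntimeError):
        flags.append("wald-ci")
        h = 1e-4
        d2 = (loglik(logf_hat + h, wells) - 2 * ll_max + loglik(logf_hat - h, wells)) / h**2
        se = np.sqrt(-1.0 / d2) if d2 < 0 else np.nan
        z = stats.norm.ppf(0.5 + conf / 2.0)
        lo, hi = logf_hat - z * se, logf_hat + z * se
    return lo, hi, flags


def estimate_frequency(wells: WellCounts, conf: float = 0.95) -> FrequencyEstimate:
    """Maximum-likelihood single-hit frequency estimate for one group.

    Boundary data (all wells negative, or all positive at every dose) yield a
    flagged one-sided result rather than a point estimate: the returned
    interval is the one-sided profile bound and ``f`` sits at the boundary.
    """
    all_neg = int(wells.n_positive.sum()) == 0
    all_pos = bool(np.all(wells.n_positive == wells.n_wells))
    drop = stats.chi2.ppf(conf, df=1) / 2.0
    if all_neg:
        # loglik -> 0 as f -> 0; upper bound where sum(n*d)*f = drop
        f_up = drop / float(np.sum(wells.n_wells * wells.dose))
        return FrequencyEstimate(
            f=0.0, one_in=float("inf"), ci_low=1.0 / f_up, ci_high=float("inf"),
            loglik=0.0, group=wells.group, flags=("boundary-zero",),
        )
    if all_pos:
        # likelihood increases toward f = 1; report the lower bound only
        ll_max = loglik(0.0, wells)

        def g(t):
            return loglik(t, wells) - (ll_max - drop)

        f_lo = np.exp(optimize.brentq(g, _LOGF_LO, 0.0, xtol=1e-10))
        return FrequencyEstimate(
            f=1.0, one_in=1.0, ci_low=1.0, ci_high=1.0 / f_lo,
            loglik=ll_max, group=wells.group, flags=("boundary-saturated",),
        )
    logf_hat, ll_max = _mle_logf(wells)
    lo, hi, flags = _profile_bounds(wells, logf_hat, ll_max, conf)
    f = float(np.exp(logf_hat))
    return FrequencyEstimate(
        f=f,
        one_in=1.0 / f,
        ci_low=float(np.exp(-hi)),  # upper f bound -> lower one_in bound
        ci_high=float(np.exp(-lo)),
        loglik=ll_max,
        group=wells.group,
        flags=tuple(flags),
    )


def compare_frequencies(a: WellCounts, b: WellCounts) -> FrequencyComparison:
    """Likelihood-ratio test of equal frequencies in two groups (1 df)."""
    est_a = estimate_frequency(a)
    est_b = estimate_frequency(b)
    boundary = tuple(
        fl for e in (est_a, est_b) for fl in e.flags if fl.startswith("boundary")
    )
    if boundary:
        return FrequencyComparison(
            group_a=a.group, group_b=b.group, chisq=float("nan"), df=1,
            p=float("nan"), flags=("boundary-group",) + boundary,
        )
    pooled = WellCounts.pool([a, b])
    _, ll_pooled = _mle_logf(pooled)
    chisq = max(0.0, 2.0 * (est_a.loglik + est_b.loglik - ll_pooled))
    p = float(stats.chi2.sf(chisq, df=1))
    return FrequencyComparison(group_a=a.group, group_b=b.group, chisq=chisq, df=1, p=p)


def pairwise_comparison_table(
    groups: list[WellCounts], bonferroni: bool = True
) -> pd.DataFrame:
    """All unordered pairwise frequency comparisons, unadjusted p-values.

    An optional Bonferroni-adjusted column is appended; the unadjusted
    p-values are the primary report, matching limiting-dilution convention.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    rows = []
    for ga, gb in combinations(groups, 2):
        cmp = compare_frequencies(ga, gb)
        rows.append(
            {
                "group_a": cmp.group_a,
                "group_b": cmp.group_b,
                "chisq": cmp.chisq,
                "df": cmp.df,
                "p": cmp.p,
                "flag": ";".join(cmp.flags),
            }
        )
    table = pd.DataFrame(rows)
    if bonferroni:
        m = len(rows)
        table["p_bonferroni"] = np.minimum(table["p"] * m, 1.0)
    return table
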