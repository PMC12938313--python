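"""Seeded synthetic-data generators for every pipeline input.

The generators emulate the structure of a PDX drug-combination study with
known ground truth:

* a 14-model viability panel (9 non-mesenchymal, 5 mesenchymal-like) whose
  single-agent median-effect parameters span IC50 ~0.5-5 µM, screened on a
  12 x 4 combination grid (drug 1 in 1:3 serial dilution from 100 µM down to
  0.56 nM; drug 2 at 25/12.5/6.25/3.125 µM);
* limiting-dilution assays at 1-500 cells/well under the single-hit model;
* expression cohorts (a 14-model PDX panel, or a 20-sample clinical cohort
  with 16 resistant / 4 sensitive samples) carrying planted gene-set signals.

Synergy is injected as a potency shift: drug 2 multiplies drug 1's effective
dose by ``1 + alpha * d2/(d2 + Dm2)``, after which the combination effect is
the exact Loewe-additive response to the boosted dose.  With ``alpha = 0``
the surface satisfies Loewe additivity exactly (CI = 1 everywhere before
noise); larger ``alpha`` drives CI below 1.  The panel couples ``alpha`` to
single-agent resistance so that high-IC50 models are the most synergistic,
reproducing a negative IC50-C.I. association.  Measurement noise is
multiplicative lognormal on luminescence (default CV 5%).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .biomarkers import PanelPhenotypes
from .combination import DoseMatrix
from .dose_response import MedianEffectFit, dose_for_effect
from .elda import WellCounts
from .enrichment import GeneSetCollection

__all__ = [
    "SimulationConfig",
    "ModelTruth",
    "PanelTruth",
    "SyntheticCohort",
    "default_panel_truth",
    "ATO_DOSES_UM",
    "PARTNER_DOSES_UM",
    "ELDA_DOSES",
    "loewe_fa",
    "expected_ci",
    "simulate_viability_panel",
    "simulate_elda",
    "simulate_expression_cohort",
]

#: drug-1 serial dilution: 12 doses, 1:3 steps from 100 µM down to ~0.56 nM
ATO_DOSES_UM = 100.0 / 3.0 ** np.arange(12)

#: fixed partner doses of drug 2 (µM)
PARTNER_DOSES_UM = np.array([25.0, 12.5, 6.25, 3.125])

#: limiting-dilution seeding ladder (cells/well)
ELDA_DOSES = np.array([1, 5, 10, 25, 50, 100, 250, 500])


@dataclass(frozen=True)
class SimulationConfig:
    """Study-level simulation settings; identical config + seed is bit-reproducible."""

    seed: int = 0
    noise_cv: float = 0.05  # lognormal CV of luminescence noise
    n_replicates: int = 3
    wells_per_dose: int = 12
    control_lum: float = 10000.0
    # expression cohort
    n_genes: int = 2000
    planted_set_size: int = 50
    n_decoy_sets: int = 20
    effect_log2: float = 1.0  # planted shift in log2 units
    gene_noise_log2: float = 0.5
    n_resistant: int = 16  # clinical cohort composition
    n_sensitive: int = 4
    ci_noise_sd: float = 0.05


@dataclass(frozen=True)
class ModelTruth:
    """Ground-truth parameters for one panel model."""

    model_id: str
    subtype: str  # 'mesenchymal' | 'non-mesenchymal'
    m1: float
    Dm1: float  # µM, drug-1 median-effect dose (the true IC50)
    m2: float
    Dm2: float
    alpha: float  # Loewe-deviation potency boost; 0 = additive

    def fit1(self) -> MedianEffectFit:
        return MedianEffectFit(m=self.m1, Dm=self.Dm1, r_linfit=1.0,
                               n_points_used=0, model_id=self.model_id, agent="drug1")

    def fit2(self) -> MedianEffectFit:
        return MedianEffectFit(m=self.m2, Dm=self.Dm2, r_linfit=1.0,
                               n_points_used=0, model_id=self.model_id, agent="drug2")


@dataclass(frozen=True)
class PanelTruth:
    models: tuple[ModelTruth, ...]

    def __post_init__(self):
        if any(t.Dm1 <= 0 or t.Dm2 <= 0 or t.alpha < 0 for t in self.models):
            raise ValueError("Dm > 0 and alpha >= 0 required")

    def __iter__(self):
        return iter(self.models)

    def __len__(self):
        return len(self.models)

    def true_min_ci(self, fa_min: float = 0.2) -> pd.Series:
        """Noiseless lowest CI per model over the default grid (fa >= fa_min)."""
        out = {}
        for t in self.models:
            cis = [
                expected_ci(t, d1, d2)
                for d1 in ATO_DOSES_UM
                for d2 in PARTNER_DOSES_UM
                if loewe_fa(t, d1, d2) >= fa_min
            ]
            out[t.model_id] = min(cis) if cis else float("nan")
        return pd.Series(out, name="true_min_ci")


def default_panel_truth(
    n_models: int = 14,
    n_mesenchymal: int = 5,
    ic50_range_um: tuple[float, float] = (0.5, 5.0),
    alpha_max: float = 2.5,
) -> PanelTruth:
    """The default 14-model panel: IC50 log-spaced over 0.5-5 µM, the five
    most resistant models labelled mesenchymal-like, and the synergy
    parameter alpha rising with resistance (zero for the most sensitive
    model) so that single-agent IC50 and combination index are negatively
    associated.
    """
    dm1 = np.geomspace(ic50_range_um[0], ic50_range_um[1], n_models)
    t = (np.log(dm1) - np.log(dm1[0])) / (np.log(dm1[-1]) - np.log(dm1[0]))
    m1_cycle = np.array([1.2, 1.5, 1.8, 2.0, 1.4])
    m2_cycle = np.array([1.1, 1.4, 1.6])
    dm2_cycle = np.array([8.0, 10.0, 12.0, 15.0])
    models = []
    for i in range(n_models):
        subtype = "mesenchymal" if i >= n_models - n_mesenchymal else "non-mesenchymal"
        models.append(
            ModelTruth(
                model_id=f"PDX{i + 1:02d}",
                subtype=subtype,
                m1=float(m1_cycle[i % len(m1_cycle)]),
                Dm1=float(dm1[i]),
                m2=float(m2_cycle[i % len(m2_cycle)]),
                Dm2=float(dm2_cycle[i % len(dm2_cycle)]),
                alpha=float(alpha_max * t[i]),
            )
        )
    return PanelTruth(models=tuple(models))


def _single_agent_fa(dose: np.ndarray, m: float, Dm: float) -> np.ndarray:
    ratio = (np.asarray(dose, dtype=float) / Dm) ** m
    return ratio / (1.0 + ratio)


def loewe_fa(truth: ModelTruth, d1: float, d2: float) -> float:
    """Noiseless combination effect: Loewe-additive fa for the boosted dose.

    Solves d1_eff/Dx1(fa) + d2/Dx2(fa) = 1 for fa, where the potency boost
    d1_eff = d1 * (1 + alpha * d2/(d2 + Dm2)) injects synergy (alpha > 0).
    """
    d1_eff = d1 * (1.0 + truth.alpha * d2 / (d2 + truth.Dm2))
    f1, f2 = truth.fit1(), truth.fit2()

    def excess(logit_fa: float) -> float:
        fa = 1.0 / (1.0 + np.exp(-logit_fa))
        return d1_eff / dose_for_effect(f1, fa) + d2 / dose_for_effect(f2, fa) - 1.0

    # excess is decreasing in fa: +inf at fa->0, -1 at fa->1; bounds keep fa
    # strictly inside (0, 1) in double precision
    return float(1.0 / (1.0 + np.exp(-optimize.brentq(excess, -30.0, 30.0, xtol=1e-14))))


def expected_ci(truth: ModelTruth, d1: float, d2: float) -> float:
    """Noiseless combination index implied by the planted truth."""
    fa = loewe_fa(truth, d1, d2)
    return float(
        d1 / dose_for_effect(truth.fit1(), fa) + d2 / dose_for_effect(truth.fit2(), fa)
    )


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-(sigma**2) / 2.0, sigma=sigma, size=size)


def simulate_viability_panel(
    config: SimulationConfig, truth: PanelTruth | None = None
) -> tuple[pd.DataFrame, dict[str, DoseMatrix]]:
    """Simulate the full screening panel: single-agent plates + combination grids.

    Returns a long-format viability table (model_id, agent, dose_uM,
    luminescence, replicate; dose 0 rows are vehicle controls) and, per
    model, a DoseMatrix of measured combination fractions affected computed
    from replicate-averaged noisy luminescence normalized to the model's
    noisy control mean.
    """
    if truth is None:
        truth = default_panel_truth()
    rng = np.random.default_rng(config.seed)
    rows = []
    matrices: dict[str, DoseMatrix] = {}
    n_rep = config.n_replicates
    for t in truth:
        # vehicle controls
        ctrl = config.control_lum * _lognormal_factor(rng, config.noise_cv, n_rep)
        for r, lum in enumerate(ctrl, start=1):
            rows.append((t.model_id, "control", 0.0, lum, r))
        ctrl_mean = ctrl.mean()
        # single agents
        for agent, m, Dm in (("drug1", t.m1, t.Dm1), ("drug2", t.m2, t.Dm2)):
            fa = _single_agent_fa(ATO_DOSES_UM, m, Dm)
            for dose, f in zip(ATO_DOSES_UM, fa):
                lum = (
                    config.control_lum
                    * (1.0 - f)
                    * _lognormal_factor(rng, config.noise_cv, n_rep)
                )
                for r, v in enumerate(lum, start=1):
                    rows.append((t.model_id, agent, dose, v, r))
        # combination grid: measured fa from noisy replicate-averaged signal
        fa_grid = np.empty((ATO_DOSES_UM.size, PARTNER_DOSES_UM.size))
        for i, d1 in enumerate(ATO_DOSES_UM):
            for j, d2 in enumerate(PARTNER_DOSES_UM):
                fa_true = loewe_fa(t, d1, d2)
                lum = (
                    config.control_lum
                    * (1.0 - fa_true)
                    * _lognormal_factor(rng, config.noise_cv, n_rep)
                )
                fa_grid[i, j] = np.clip(1.0 - lum.mean() / ctrl_mean, 0.0, 1.0)
        matrices[t.model_id] = DoseMatrix(
            drug1_doses=ATO_DOSES_UM,
            drug2_doses=PARTNER_DOSES_UM,
            fa_grid=fa_grid,
            model_id=t.model_id,
        )
    records = pd.DataFrame(
        rows, columns=["model_id", "agent", "dose_uM", "luminescence", "replicate"]
    )
    return records, matrices


def simulate_elda(
    f: float,
    doses=ELDA_DOSES,
    wells_per_dose: int = 12,
    seed: int | np.random.Generator = 0,
    group: str = "",
) -> WellCounts:
    """Simulate a limiting-dilution assay under the single-hit model.

    Each well at seeding dose d is positive with probability 1 - exp(-f*d),
    independently across wells.
    """
    if not (0 < f < 1):
        raise ValueError("frequency f must be in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    doses = np.asarray(doses, dtype=float)
    p = -np.expm1(-f * doses)
    k = rng.binomial(wells_per_dose, p)
    return WellCounts(
        dose=doses,
        n_wells=np.full(doses.size, wells_per_dose),
        n_positive=k,
        group=group,
    )


@dataclass(frozen=True)
class SyntheticCohort:
    """Expression cohort with planted pathway signals and full ground truth."""

    expr: pd.DataFrame  # genes x samples, TPM
    phenotypes: pd.DataFrame  # per-sample ci, ic50_uM, subtype, status
    gene_sets: GeneSetCollection
    truth: dict = field(default_factory=dict)

    def panel_phenotypes(self) -> PanelPhenotypes:
        return PanelPhenotypes(
            ci=self.phenotypes["ci"],
            ic50=self.phenotypes["ic50_uM"],
            subtype=self.phenotypes["subtype"],
        )


TRANSLATION_SET = "TRANSLATION_INITIATION"
SYNERGY_SET = "SYNERGY_PROGRAM"


def simulate_expression_cohort(
    config: SimulationConfig,
    kind: str = "pdx",
    truth: PanelTruth | None = None,
    translation_effect_log2: float | None = None,
    synergy_effect_log2: float | None = None,
) -> SyntheticCohort:
    """Simulate a TPM expression cohort with planted gene-set signals.

    Two planted signals, each a ``planted_set_size``-gene set:

    * ``TRANSLATION_INITIATION`` — shifted up in sensitive samples
      (clinical cohort) or proportionally to -log(IC50) (PDX panel),
      emulating translation pathways activating in drug-sensitive tumors;
    * ``SYNERGY_PROGRAM`` — negatively coupled to the combination index, so
      high expression marks synergistic models.

    ``kind='pdx'`` produces the 14-model panel with continuous (ci, ic50,
    subtype) phenotypes derived from the viability ground truth;
    ``kind='clinical'`` produces the 20-sample cohort (16 resistant /
    4 sensitive by default).  Decoy sets are random draws from the
    remaining genes.  Returns the matrix, phenotypes, gene-set collection
    (planted + decoys) and a truth record.
    """
    if kind not in ("pdx", "clinical"):
        raise ValueError("kind must be 'pdx' or 'clinical'")
    te = config.effect_log2 if translation_effect_log2 is None else translation_effect_log2
    se = config.effect_log2 if synergy_effect_log2 is None else synergy_effect_log2
    rng = np.random.default_rng(config.seed)

    if kind == "pdx":
        if truth is None:
            truth = default_panel_truth()
        samples = [t.model_id for t in truth]
        ic50 = np.array([t.Dm1 for t in truth])
        subtype = [t.subtype for t in truth]
        true_ci = truth.true_min_ci().to_numpy()
        ci = np.clip(true_ci + rng.normal(0.0, config.ci_noise_sd, len(samples)),
                     0.05, None)
        status = np.where(ic50 <= np.median(ic50), "sensitive", "resistant")
    else:
        n = config.n_resistant + config.n_sensitive
        samples = [f"PT{i + 1:02d}" for i in range(n)]
        status = np.array(
            ["sensitive"] * config.n_sensitive + ["resistant"] * config.n_resistant
        )
        ic50 = np.where(
            status == "sensitive",
            rng.lognormal(np.log(0.7), 0.3, n),
            rng.lognormal(np.log(3.5), 0.3, n),
        )
        # resistant tumors gain more from the combination (lower ci)
        ci = np.clip(
            1.1 - 0.5 * (status == "resistant") + rng.normal(0, config.ci_noise_sd, n),
            0.05,
            None,
        )
        # mesenchymal enriched among resistant samples
        subtype = np.where(
            (status == "resistant") & (rng.random(n) < 0.5),
            "mesenchymal",
            "non-mesenchymal",
        ).tolist()

    n_samp = len(samples)
    genes = np.array([f"G{i + 1:05d}" for i in range(config.n_genes)], dtype=object)
    base = rng.normal(3.0, 1.5, config.n_genes)  # per-gene mean log2 TPM
    log2 = base[:, None] + rng.normal(0.0, config.gene_noise_log2,
                                      (config.n_genes, n_samp))

    k = config.planted_set_size
    idx = rng.permutation(config.n_genes)
    translation_idx, synergy_idx = idx[:k], idx[k: 2 * k]
    sens_z = -np.log(ic50)
    sens_z = (sens_z - sens_z.mean()) / sens_z.std()
    ci_z = (ci - ci.mean()) / ci.std()
    if kind == "clinical":
        log2[translation_idx] += te * (status == "sensitive")
    else:
        log2[translation_idx] += te * sens_z / 2.0
    log2[synergy_idx] += se * (-ci_z) / 2.0

    expr = pd.DataFrame(2.0 ** log2, index=genes, columns=samples)
    sets = {
        TRANSLATION_SET: tuple(genes[translation_idx]),
        SYNERGY_SET: tuple(genes[synergy_idx]),
    }
    remaining = idx[2 * k:]
    for d in range(config.n_decoy_sets):
        pick = rng.choice(remaining, size=k, replace=False)
        sets[f"DECOY_{d + 1:02d}"] = tuple(genes[pick])
    phenotypes = pd.DataFrame(
        {"ci": ci, "ic50_uM": ic50, "subtype": subtype, "status": status},
        index=pd.Index(samples, name="sample"),
    )
    return SyntheticCohort(
        expr=expr,
        phenotypes=phenotypes,
        gene_sets=GeneSetCollection(sets=sets),
        truth={
            "translation_genes": tuple(genes[translation_idx]),
            "synergy_genes": tuple(genes[synergy_idx]),
            "translation_effect_log2": te,
            "synergy_effect_log2": se,
            "kind": kind,
        },
    )
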