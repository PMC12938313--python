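"""Covariate-adjusted per-gene synergy biomarker selection.

For each gene, a linear model

    ci ~ tpm + subtype + ic50

is fitted across the panel; the expression term's partial F statistic
(full-vs-reduced residual-sum-of-squares decomposition, 1 and n-4 df) gates
significance, and the raw Spearman correlation between expression and the
combination index orients the effect.  Genes with rho <= -rho_cut pass into
the synergy list (higher expression, lower C.I.), genes with rho >= +rho_cut
into the additive list; both lists feed one-sided Fisher overrepresentation
against an annotation collection with the tested genes as the background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import GeneSetCollection, overrepresentation

__all__ = [
    "PanelPhenotypes",
    "per_gene_ancova",
    "select_synergy_genes",
    "biomarker_pipeline",
    "RHO_CUT",
    "P_CUT",
]

RHO_CUT = 0.2  # |Spearman rho| threshold for direction calls
P_CUT = 0.1  # expression-term F-test p-value gate


@dataclass(frozen=True)
class PanelPhenotypes:
    """Per-model phenotypes: combination index, single-agent IC50, subtype."""

    ci: pd.Series  # dimensionless, indexed by model id
    ic50: pd.Series  # µM
    subtype: pd.Series  # 'mesenchymal' | 'non-mesenchymal'

    def __post_init__(self):
        idx = self.ci.index
        if not (self.ic50.index.equals(idx) and self.subtype.index.equals(idx)):
            raise ValueError("ci, ic50, subtype must share the same model index")
        if idx.has_duplicates:
            raise ValueError("one row per model required")
        for s in (self.ci, self.ic50):
            if s.isna().any():
                raise ValueError("missing phenotype values not allowed")

    @property
    def models(self) -> pd.Index:
        return self.ci.index

    def mesenchymal_mask(self) -> np.ndarray:
        return (self.subtype == "mesenchymal").to_numpy()


def _spearman_vec(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    rX = stats.rankdata(X, axis=1)
    ry = stats.rankdata(y)
    rX_c = rX - rX.mean(axis=1, keepdims=True)
    ry_c = ry - ry.mean()
    denom = np.sqrt((rX_c**2).sum(axis=1) * (ry_c**2).sum())
    out = np.zeros(X.shape[0])
    np.divide(rX_c @ ry_c, denom, out=out, where=denom > 0)
    return out


def per_gene_ancova(
    expr: pd.DataFrame,
    pheno: PanelPhenotypes,
    log_transform: bool = False,
    rho_cut: float = RHO_CUT,
    p_cut: float = P_CUT,
) -> pd.DataFrame:
    """Per-gene ANCOVA of the combination index on expression + covariates.

    Parameters
    ----------
    expr
        TPM matrix, genes x models; columns must match the phenotype index.
    pheno
        Panel phenotypes; the subtype covariate is a single binary indicator
        (mesenchymal vs not).  If only one subtype is present the term is
        dropped with a warning flag in the output attrs.
    log_transform
        Enter expression as log2(TPM + 1) instead of natural-scale TPM.

    Returns
    -------
    DataFrame indexed by gene with F_expr, p_expr, rho (raw Spearman vs ci),
    rho_partial (Spearman of rank residuals after covariate adjustment),
    direction in {synergy, additive, none}, and a constant-expression flag.

    Notes
    -----
    The partial F for the expression term is computed through the equivalent
    partial-correlation identity: residualize ci and each gene on the reduced
    design (intercept + covariates), then F = (n - p_full) * r^2 / (1 - r^2)
    with 1 numerator df, identical to the RSS_reduced - RSS_full decomposition.
    """
    models = pheno.models
    if not set(models) <= set(expr.columns):
        raise ValueError("expression matrix missing phenotype models")
    X = expr[models].to_numpy(dtype=float)
    if log_transform:
        X = np.log2(X + 1.0)
    n = len(models)
    if n < 6:
        raise ValueError("need at least 6 models for the ANCOVA")
    y = pheno.ci.to_numpy(dtype=float)
    mes = pheno.mesenchymal_mask().astype(float)
    ic50 = pheno.ic50.to_numpy(dtype=float)
    cols = [np.ones(n)]
    subtype_dropped = False
    if np.ptp(mes) > 0:
        cols.append(mes)
    else:
        subtype_dropped = True
    cols.append(ic50)
    Z = np.column_stack(cols)  # reduced design (no expression term)
    p_full = Z.shape[1] + 1
    df_resid = n - p_full

    # residualize y and every gene row against Z
    ZtZ_inv_Zt = np.linalg.pinv(Z)
    ey = y - Z @ (ZtZ_inv_Zt @ y)
    EX = X - (Z @ (ZtZ_inv_Zt @ X.T)).T

    sd_gene = X.std(axis=1)
    constant = sd_gene == 0
    ex_ss = (EX**2).sum(axis=1)
    ey_ss = float(ey @ ey)
    denom = np.sqrt(ex_ss * ey_ss)
    r = np.zeros(X.shape[0])
    ok = denom > 0
    np.divide(EX @ ey, denom, out=r, where=ok)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = df_resid * r**2 / (1.0 - r**2)
    F = np.where(ok & ~constant, F, np.nan)
    p = stats.f.sf(F, 1, df_resid)

    rho = _spearman_vec(X, y)
    # partial Spearman: residualize the rank-transformed data on the covariates
    rX = stats.rankdata(X, axis=1)
    ry = stats.rankdata(y)
    ery = ry - Z @ (ZtZ_inv_Zt @ ry)
    ErX = rX - (Z @ (ZtZ_inv_Zt @ rX.T)).T
    dpart = np.sqrt((ErX**2).sum(axis=1) * float(ery @ ery))
    rho_partial = np.zeros(X.shape[0])
    np.divide(ErX @ ery, dpart, out=rho_partial, where=dpart > 0)

    direction = np.full(X.shape[0], "none", dtype=object)
    passed = (p <= p_cut) & ~constant
    direction[passed & (rho <= -rho_cut)] = "synergy"
    direction[passed & (rho >= rho_cut)] = "additive"

    table = pd.DataFrame(
        {
            "F_expr": F,
            "p_expr": p,
            "rho": np.where(constant, 0.0, rho),
            "rho_partial": rho_partial,
            "direction": direction,
            "constant_expression": constant,
        },
        index=expr.index,
    )
    table.attrs["subtype_dropped"] = subtype_dropped
    table.attrs["log_transform"] = log_transform
    table.attrs["df"] = (1, df_resid)
    return table


def select_synergy_genes(
    records: pd.DataFrame, rho_cut: float = RHO_CUT, p_cut: float = P_CUT
) -> tuple[list[str], list[str]]:
    """Partition ANCOVA records into synergy- and additive-associated lists.

    Synergy list: rho <= -rho_cut and p_expr <= p_cut (expression rises as
    C.I. falls).  Additive list: rho >= +rho_cut and p_expr <= p_cut.  The
    lists are disjoint for any positive rho_cut.
    """
    usable = records[~records["constant_expression"]]
    gate = usable["p_expr"] <= p_cut
    synergy = usable.index[gate & (usable["rho"] <= -rho_cut)].tolist()
    additive = usable.index[gate & (usable["rho"] >= rho_cut)].tolist()
    return synergy, additive


def biomarker_pipeline(
    expr: pd.DataFrame,
    pheno: PanelPhenotypes,
    annotation: GeneSetCollection,
    rho_cut: float = RHO_CUT,
    p_cut: float = P_CUT,
    log_transform: bool = False,
) -> dict:
    """ANCOVA gate -> gene selection -> overrepresentation, per direction.

    The ORA background is the full set of tested (non-constant) genes.
    Returns the ANCOVA table, both gene lists, and the two ORA tables
    (empty DataFrames when a list is empty).
    """
    records = per_gene_ancova(
        expr, pheno, log_transform=log_transform, rho_cut=rho_cut, p_cut=p_cut
    )
    synergy, additive = select_synergy_genes(records, rho_cut=rho_cut, p_cut=p_cut)
    background = records.index[~records["constant_expression"]].tolist()
    empty = pd.DataFrame(
        columns=["term", "k", "K", "n", "N", "fold_enrichment", "p", "fdr"]
    )
    ora_synergy = (
        overrepresentation(synergy, background, annotation) if synergy else empty
    )
    ora_additive = (
        overrepresentation(additive, background, annotation) if additive else empty
    )
    return {
        "ancova": records,
        "synergy_genes": synergy,
        "additive_genes": additive,
        "ora_synergy": ora_synergy,
        "ora_additive": ora_additive,
    }
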