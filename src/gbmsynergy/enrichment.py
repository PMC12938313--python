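"""Gene-set enrichment machinery: phenotype-correlation ranking, preranked
GSEA, single-sample GSEA, Fisher's-exact overrepresentation, and hierarchical
heatmap ordering.

Preranked GSEA uses the weighted Kolmogorov-Smirnov running sum: walking down
a ranked gene list, in-set genes increment the sum by |score|**weight
(normalized to total 1 over the set) and out-of-set genes decrement it by
1/(n-K).  The enrichment score (ES) is the extreme of the running sum;
significance comes from gene-label permutation, and the normalized score
(NES) divides ES by the mean permuted |ES| of the same sign.

ssGSEA scores one sample at a time as the cumulative difference between a
rank-weighted in-set ECDF and the uniform out-of-set ECDF, making the score
invariant to any monotone transform of the expression values within a sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSetCollection",
    "RankedGeneList",
    "HeatmapOrder",
    "EnrichmentError",
    "rank_genes_by_phenotype",
    "gsea_preranked",
    "ssgsea",
    "overrepresentation",
    "heatmap_order",
    "enrichment_score",
]


class EnrichmentError(ValueError):
    def __init__(self, code: str, message: str):
        super().__init__(message)
        self.code = code


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets (e.g. pathways) with optional descriptions."""

    sets: dict[str, tuple[str, ...]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for name, genes in self.sets.items():
            if len(genes) == 0:
                raise ValueError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValueError(f"gene set {name!r} has duplicate genes")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> tuple[str, ...]:
        return self.sets[name]

    def items(self):
        return self.sets.items()

    def filtered(
        self, universe, min_size: int = 5, max_size: int = 500
    ) -> "GeneSetCollection":
        """Restrict sets to genes in ``universe`` and apply size bounds."""
        uni = set(universe)
        kept = {}
        for name, genes in self.sets.items():
            g = tuple(x for x in genes if x in uni)
            if min_size <= len(g) <= max_size:
                kept[name] = g
        return GeneSetCollection(
            sets=kept,
            descriptions={k: v for k, v in self.descriptions.items() if k in kept},
        )


@dataclass(frozen=True)
class RankedGeneList:
    """Genes sorted by a ranking statistic, descending; ties stable by id."""

    genes: np.ndarray
    scores: np.ndarray
    flagged_zero_variance: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self):
        g = np.asarray(self.genes, dtype=object)
        s = np.asarray(self.scores, dtype=float)
        if g.shape != s.shape or g.ndim != 1:
            raise ValueError("genes and scores must be 1-D, equal length")
        if np.any(~np.isfinite(s)):
            raise ValueError("ranking scores must be finite")
        if np.any(np.diff(s) > 0):
            raise ValueError("scores must be sorted descending")
        object.__setattr__(self, "genes", g)
        object.__setattr__(self, "scores", s)

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class HeatmapOrder:
    row_order: np.ndarray  # indices into the (retained) gene axis
    col_order: np.ndarray
    row_labels: np.ndarray  # flat-cluster labels per retained row
    col_labels: np.ndarray
    genes: np.ndarray  # retained gene ids, original order
    samples: np.ndarray


def rank_genes_by_phenotype(
    expr: pd.DataFrame, phenotype: pd.Series | np.ndarray
) -> RankedGeneList:
    """Rank genes by Spearman correlation with a per-sample phenotype.

    ``expr`` is genes x samples; the phenotype is one value per sample in
    column order.  Ties get mid-ranks.  Genes with zero expression variance
    are assigned rho = 0 and flagged.
    """
    pheno = np.asarray(
        phenotype.loc[expr.columns] if isinstance(phenotype, pd.Series) else phenotype,
        dtype=float,
    )
    if expr.shape[1] < 4:
        raise EnrichmentError("too-few-samples", "need >= 4 samples")
    if pheno.shape[0] != expr.shape[1]:
        raise ValueError("phenotype length must match number of samples")
    if np.ptp(pheno) == 0:
        raise EnrichmentError("degenerate-phenotype", "phenotype is constant")
    X = expr.to_numpy(dtype=float)
    rp = stats.rankdata(pheno)
    rX = stats.rankdata(X, axis=1)
    rp_c = rp - rp.mean()
    rX_c = rX - rX.mean(axis=1, keepdims=True)
    denom = np.sqrt((rX_c**2).sum(axis=1) * (rp_c**2).sum())
    zero_var = denom == 0
    rho = np.zeros(X.shape[0])
    np.divide(rX_c @ rp_c, denom, out=rho, where=~zero_var)
    flagged = tuple(np.asarray(expr.index, dtype=object)[zero_var])
    order = sorted(range(len(rho)), key=lambda i: (-rho[i], str(expr.index[i])))
    return RankedGeneList(
        genes=np.asarray(expr.index, dtype=object)[order],
        scores=rho[order],
        flagged_zero_variance=flagged,
    )


def enrichment_score(
    ranked: RankedGeneList, gene_set, weight: float = 1.0
) -> tuple[float, np.ndarray, list[str]]:
    """Weighted-KS enrichment score, running sum, and leading-edge genes."""
    n = len(ranked)
    in_set = np.isin(ranked.genes, list(gene_set))
    K = int(in_set.sum())
    if K == 0 or K == n:
        raise EnrichmentError("degenerate-set", "set is empty or covers the list")
    w = np.abs(ranked.scores) ** weight
    hit_w = np.where(in_set, w, 0.0)
    total = hit_w.sum()
    if total == 0:  # all in-set scores exactly zero: fall back to unweighted
        hit_w = in_set.astype(float)
        total = hit_w.sum()
    steps = hit_w / total - (~in_set) / (n - K)
    running = np.cumsum(steps)
    i_max = int(np.argmax(running))
    i_min = int(np.argmin(running))
    es = running[i_max] if running[i_max] >= -running[i_min] else running[i_min]
    if es >= 0:
        leading = [g for g, h in zip(ranked.genes[: i_max + 1], in_set[: i_max + 1]) if h]
    else:
        leading = [g for g, h in zip(ranked.genes[i_min:], in_set[i_min:]) if h]
    return float(es), running, leading


def _permuted_es(
    scores_w: np.ndarray, K: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """ES for n_perm random K-subsets of hit positions (gene-label permutation).

    Uses the fact that the running sum between hits falls linearly, so its
    extremes occur immediately after a hit (local max candidates) or
    immediately before one (local min candidates).
    """
    n = scores_w.size
    miss = 1.0 / (n - K)
    # random K positions per permutation, sorted
    pos = np.argsort(rng.random((n_perm, n)), axis=1)[:, :K]
    pos.sort(axis=1)
    hit_w = scores_w[pos]
    cumw = np.cumsum(hit_w, axis=1)
    totals = cumw[:, -1:]
    # guard all-zero hit weights (possible when many scores are exactly 0)
    zero = totals[:, 0] == 0
    if np.any(zero):
        cumw[zero] = np.arange(1, K + 1)
        totals = np.where(totals == 0, K, totals)
    j = np.arange(K)
    after = cumw / totals - (pos - j) * miss
    before = after - hit_w / np.where(totals == 0, 1, totals)
    max_dev = after.max(axis=1)
    min_dev = np.minimum(before.min(axis=1), 0.0)
    return np.where(max_dev >= -min_dev, max_dev, min_dev)


def gsea_preranked(
    ranked: RankedGeneList,
    sets: GeneSetCollection,
    weight: float = 1.0,
    n_perm: int = 10000,
    seed: int | None = 0,
    min_size: int = 5,
    max_size: int = 500,
) -> pd.DataFrame:
    """Preranked GSEA over a collection, gene-label permutation nulls.

    Returns a table with ES, NES, nominal p, BH-adjusted p, set size and
    leading-edge genes, sorted by p.  NES normalization is sign-stratified:
    a positive ES is divided by the mean positive permuted ES and a negative
    ES by the mean |negative permuted ES|.
    """
    usable = sets.filtered(ranked.genes, min_size=min_size, max_size=max_size)
    if len(usable) == 0:
        raise EnrichmentError("no-testable-sets", "no set within size bounds")
    rng = np.random.default_rng(seed)
    w_scores = np.abs(ranked.scores) ** weight
    rows = []
    for name, genes in usable.items():
        es, _, leading = enrichment_score(ranked, genes, weight=weight)
        K = int(np.isin(ranked.genes, list(genes)).sum())
        perm = _permuted_es(w_scores, K, n_perm, rng)
        pos, neg = perm[perm >= 0], perm[perm < 0]
        if es >= 0:
            same = pos
            p = float((same >= es).sum()) / max(len(same), 1)
            nes = es / pos.mean() if len(pos) and pos.mean() > 0 else float("nan")
        else:
            same = neg
            p = float((same <= es).sum()) / max(len(same), 1)
            nes = -es / neg.mean() if len(neg) and neg.mean() < 0 else float("nan")
        rows.append(
            {
                "set": name,
                "ES": es,
                "NES": nes,
                "p": p,
                "size": K,
                "leading_edge": ",".join(map(str, leading)),
            }
        )
    table = pd.DataFrame(rows)
    table["p_adj"] = multipletests(table["p"], method="fdr_bh")[1]
    return table.sort_values("p", kind="stable").reset_index(drop=True)[
        ["set", "ES", "NES", "p", "p_adj", "size", "leading_edge"]
    ]


def _ssgsea_sample(values: np.ndarray, in_set: np.ndarray, alpha: float) -> float:
    """ssGSEA score for one sample from expression values and set mask."""
    n = values.size
    K = int(in_set.sum())
    ranks = stats.rankdata(values)  # higher expression -> larger rank
    desc = np.argsort(-values, kind="stable")  # genes by descending expression
    rw = ranks[desc] ** alpha
    hits = in_set[desc]
    num = np.where(hits, rw, 0.0)
    P_in = np.cumsum(num) / num.sum()
    P_out = np.cumsum(~hits) / (n - K)
    return float(np.sum(P_in - P_out))


def ssgsea(
    expr: pd.DataFrame,
    sets: GeneSetCollection,
    alpha: float = 0.25,
    min_size: int = 1,
    max_size: int = 10000,
    normalize: bool = False,
) -> pd.DataFrame:
    """Single-sample GSEA scores, one row per set and one column per sample.

    Being purely rank-based, scores are invariant to monotone transforms of
    the expression values within a sample.  Optional min-max normalization
    rescales the whole score matrix to [0, 1] (off by default).
    """
    if expr.shape[1] < 1:
        raise EnrichmentError("no-samples", "need at least one sample")
    usable = sets.filtered(expr.index, min_size=min_size, max_size=max_size)
    if len(usable) == 0:
        raise EnrichmentError("no-testable-sets", "no usable gene set")
    genes = np.asarray(expr.index, dtype=object)
    X = expr.to_numpy(dtype=float)
    out = {}
    for name, gset in usable.items():
        mask = np.isin(genes, list(gset))
        if mask.all():
            warnings.warn(
                f"gene set {name!r} covers every gene; ssGSEA undefined (degenerate-set)",
                stacklevel=2,
            )
            continue
        out[name] = [
            _ssgsea_sample(X[:, j], mask, alpha) for j in range(X.shape[1])
        ]
    if not out:
        raise EnrichmentError("degenerate-set", "every set covers the full gene list")
    scores = pd.DataFrame(out, index=expr.columns).T
    if normalize:
        lo, hi = scores.min().min(), scores.max().max()
        if hi > lo:
            scores = (scores - lo) / (hi - lo)
    return scores


def overrepresentation(
    genes,
    background,
    annotation: GeneSetCollection,
    filter_fold: bool = True,
) -> pd.DataFrame:
    """One-sided Fisher's-exact overrepresentation of a gene list per term.

    The 2x2 table per term is (k, n-k, K-k, N-K-n+k) for list size n,
    term size K, overlap k, universe N; p is the hypergeometric upper tail.
    BH FDR is computed across all tested terms; by convention only terms with
    fold enrichment (k/n)/(K/N) > 1 are reported.
    """
    gene_set = set(genes)
    bg = set(background)
    if not gene_set <= bg:
        raise EnrichmentError(
            "inconsistent-universe", "gene list contains ids not in the background"
        )
    if len(bg) < 2 * len(gene_set):
        raise EnrichmentError(
            "inconsistent-universe", "background must be at least 2x the list size"
        )
    N, n = len(bg), len(gene_set)
    rows = []
    for term, members in annotation.items():
        members_bg = set(members) & bg
        K = len(members_bg)
        if K == 0:
            continue
        k = len(members_bg & gene_set)
        fold = (k / n) / (K / N) if n > 0 else 0.0
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {"term": term, "k": k, "K": K, "n": n, "N": N,
             "fold_enrichment": fold, "p": p}
        )
    table = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "fold_enrichment", "p"])
    if len(table):
        table["fdr"] = multipletests(table["p"], method="fdr_bh")[1]
    else:
        table["fdr"] = pd.Series(dtype=float)
    if filter_fold:
        table = table[table["fold_enrichment"] > 1.0]
    return table.sort_values(["p", "term"], kind="stable").reset_index(drop=True)


def heatmap_order(
    expr: pd.DataFrame,
    top_genes,
    n_row_clusters: int = 2,
    n_col_clusters: int = 2,
) -> HeatmapOrder:
    """Hierarchical ordering of a gene-subset heatmap.

    Rows (genes) are z-scored, then rows and columns are clustered with
    Euclidean distance and complete linkage; leaf orders and flat cluster
    labels at the requested cut are returned.  Zero-variance rows are dropped
    with a warning.
    """
    sub = expr.loc[[g for g in top_genes if g in expr.index]]
    if sub.shape[0] < 2 or sub.shape[1] < 2:
        raise EnrichmentError("too-small", "need >= 2 genes and >= 2 samples")
    X = sub.to_numpy(dtype=float)
    sd = X.std(axis=1, ddof=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} zero-variance gene row(s)", stacklevel=2
        )
    X = (X[keep] - X[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    genes = np.asarray(sub.index, dtype=object)[keep]
    row_link = hierarchy.linkage(pdist(X), method="complete")
    col_link = hierarchy.linkage(pdist(X.T), method="complete")
    return HeatmapOrder(
        row_order=hierarchy.leaves_list(row_link),
        col_order=hierarchy.leaves_list(col_link),
        row_labels=hierarchy.fcluster(row_link, n_row_clusters, criterion="maxclust"),
        col_labels=hierarchy.fcluster(col_link, n_col_clusters, criterion="maxclust"),
        genes=genes,
        samples=np.asarray(sub.columns, dtype=object),
    )
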