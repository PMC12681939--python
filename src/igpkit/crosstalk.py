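"""Glycosylation-phosphorylation crosstalk analytics.

Intra-protein: overlap of modified protein sets and concordance of
tumor/NAT fold changes between glycoforms and phosphosites of the same
protein.  Inter-protein: for every (glycoform, phosphosite) pair, the
Pearson correlation is computed separately within tumor and within NAT
columns of paired samples; pairs with a strong NAT correlation that
collapses in tumors are the rewired pairs, and per-gene counts of lost
associations identify hub proteins.  A related analysis correlates
composition-aggregated glycan abundance against glycosylation-enzyme
protein abundance and clusters the glycans into coherent regulatory
patterns (GC.1 / GC.2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .glycans import parse_glycoform_key

logger = logging.getLogger(__name__)


def modified_protein_overlap(
    glyco_ids: set[str], phospho_ids: set[str], global_ids: set[str]
) -> dict[str, int]:
    """All seven region counts of the three-way Venn partition."""
    g, p, t = glyco_ids, phospho_ids, global_ids
    return {
        "glyco_only": len(g - p - t),
        "phospho_only": len(p - g - t),
        "global_only": len(t - g - p),
        "glyco_phospho": len((g & p) - t),
        "glyco_global": len((g & t) - p),
        "phospho_global": len((p & t) - g),
        "all_three": len(g & p & t),
    }


@dataclass
class RegressionFit:
    slope: float
    intercept: float
    r: float
    p_value: float
    n: int


def fold_change_concordance(
    glyco_de: pd.DataFrame,
    phospho_de: pd.DataFrame,
    glyco_genes: pd.Series,
    phospho_genes: pd.Series,
) -> tuple[pd.DataFrame, RegressionFit | None]:
    """Pair glyco and phospho fold changes through shared gene symbols.

    All glycoform x phosphosite combinations within a gene are paired;
    phospho log2fc is regressed on glyco log2fc by ordinary least
    squares with a two-sided Pearson correlation p-value.  Returns the
    pair table and the fit (None when undefined, e.g. a constant axis).
    """
    g = glyco_de[["log2fc"]].join(glyco_genes.rename("gene"), how="inner").dropna()
    p = phospho_de[["log2fc"]].join(phospho_genes.rename("gene"), how="inner").dropna()
    pairs = g.reset_index(names="glyco_feature").merge(
        p.reset_index(names="phospho_feature"),
        on="gene",
        suffixes=("_glyco", "_phospho"),
    )
    if len(pairs) < 3:
        return pairs, None
    x = pairs["log2fc_glyco"].to_numpy()
    y = pairs["log2fc_phospho"].to_numpy()
    if np.std(x) == 0 or np.std(y) == 0:
        return pairs, None
    res = stats.linregress(x, y)
    fit = RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        p_value=float(res.pvalue),
        n=len(pairs),
    )
    return pairs, fit


def _pairwise_correlations(
    A: np.ndarray, B: np.ndarray, min_n: int
) -> tuple[np.ndarray, np.ndarray]:
    """Pearson correlations between every row of A and every row of B
    over pairwise-complete observations; NaN below ``min_n`` pairs."""
    na, nb = A.shape[0], B.shape[0]
    corr = np.full((na, nb), np.nan)
    counts = np.zeros((na, nb), dtype=int)
    maskB = ~np.isnan(B)
    for i in range(na):
        a = A[i]
        ok_a = ~np.isnan(a)
        for j in range(nb):
            ok = ok_a & maskB[j]
            n = int(ok.sum())
            counts[i, j] = n
            if n < min_n:
                continue
            x, y = a[ok], B[j, ok]
            sx, sy = x.std(), y.std()
            if sx == 0 or sy == 0:
                continue
            corr[i, j] = np.corrcoef(x, y)[0, 1]
    return corr, counts


def paired_condition_correlations(
    glyco: pd.DataFrame,
    phospho: pd.DataFrame,
    tumor_samples: list[str],
    nat_samples: list[str],
    min_pairs: int = 10,
) -> pd.DataFrame:
    """Per (glycoform, phosphosite) pair: within-tumor and within-NAT
    Pearson correlations over shared samples.

    Pairs with fewer than ``min_pairs`` complete observations in either
    condition, or an undefined correlation (constant feature), are
    omitted.  Returns a table with corr_tumor, corr_nat and the
    NAT-minus-tumor delta.
    """
    Gt = glyco[tumor_samples].to_numpy(dtype=float)
    Gn = glyco[nat_samples].to_numpy(dtype=float)
    Pt = phospho[tumor_samples].to_numpy(dtype=float)
    Pn = phospho[nat_samples].to_numpy(dtype=float)
    corr_t, n_t = _pairwise_correlations(Gt, Pt, min_pairs)
    corr_n, n_n = _pairwise_correlations(Gn, Pn, min_pairs)
    gi, pj = np.meshgrid(np.arange(len(glyco)), np.arange(len(phospho)), indexing="ij")
    df = pd.DataFrame(
        {
            "glycoform": glyco.index.to_numpy()[gi.ravel()],
            "phosphosite": phospho.index.to_numpy()[pj.ravel()],
            "corr_tumor": corr_t.ravel(),
            "corr_nat": corr_n.ravel(),
            "n_tumor": n_t.ravel(),
            "n_nat": n_n.ravel(),
        }
    )
    df = df.dropna(subset=["corr_tumor", "corr_nat"]).reset_index(drop=True)
    df["delta"] = df["corr_nat"] - df["corr_tumor"]
    return df


def rewired_pairs(pairs: pd.DataFrame, delta_threshold: float = 0.3) -> pd.DataFrame:
    """Pairs whose NAT correlation is strong and collapses in tumors.

    Selected iff corr_nat >= ``delta_threshold`` and
    corr_nat - corr_tumor > ``delta_threshold``; sorted by delta
    descending.
    """
    sel = pairs[
        (pairs["corr_nat"] >= delta_threshold) & (pairs["delta"] > delta_threshold)
    ]
    return sel.sort_values("delta", ascending=False).reset_index(drop=True)


def _gene_of(feature_id: str) -> str:
    """Gene symbol from a glycoform key or a GENE_S123 phosphosite id."""
    try:
        return parse_glycoform_key(feature_id).gene
    except Exception:
        return feature_id.split("_")[0]


def hub_counts(selected: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Lost-association counts per glyco-side and phospho-side gene,
    descending.  Both count vectors sum to the number of selected pairs."""
    if selected.empty:
        empty = pd.Series(dtype=int)
        return empty, empty
    glyco_genes = selected["glycoform"].map(_gene_of)
    phospho_genes = selected["phosphosite"].map(_gene_of)
    return (
        glyco_genes.value_counts(),
        phospho_genes.value_counts(),
    )


def enzyme_glycan_patterns(
    glycoforms: pd.DataFrame,
    enzymes: pd.DataFrame,
    k: int = 2,
) -> tuple[pd.DataFrame, pd.Series]:
    """Correlate composition-level glycan abundance with enzyme abundance
    and cluster the glycans into ``k`` regulatory patterns.

    Each glycoform row is z-transformed across the (tumor) columns, then
    rows are aggregated to one row per glycan composition by the median.
    The composition-by-enzyme Pearson correlation matrix is clustered by
    average-linkage hierarchical clustering on the correlation distance
    between correlation profiles; pattern labels are GC.1, GC.2, ...
    """
    common = glycoforms.columns.intersection(enzymes.columns)
    G = glycoforms[common]
    E = enzymes[common]
    z = G.sub(G.mean(axis=1), axis=0).div(G.std(axis=1, ddof=1), axis=0)
    compositions = pd.Series(
        [parse_glycoform_key(i).composition.__str__() for i in z.index], index=z.index
    )
    agg = z.groupby(compositions).median()

    corr = pd.DataFrame(index=agg.index, columns=E.index, dtype=float)
    for enz in E.index:
        e = E.loc[enz].to_numpy(dtype=float)
        for comp in agg.index:
            g = agg.loc[comp].to_numpy(dtype=float)
            ok = ~(np.isnan(e) | np.isnan(g))
            if ok.sum() >= 3 and g[ok].std() > 0 and e[ok].std() > 0:
                corr.loc[comp, enz] = np.corrcoef(g[ok], e[ok])[0, 1]
    profiles = corr.fillna(0.0).to_numpy(dtype=float)
    if len(profiles) <= k:
        labels = pd.Series(
            [f"GC.{i + 1}" for i in range(len(profiles))], index=corr.index
        )
        return corr, labels
    profile_corr = np.corrcoef(profiles)
    dist = 1.0 - profile_corr
    np.fill_diagonal(dist, 0.0)
    link = linkage(squareform(dist, checks=False), method="average")
    cut = fcluster(link, t=k, criterion="maxclust")
    labels = pd.Series([f"GC.{c}" for c in cut], index=corr.index, name="pattern")
    return corr, labels
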