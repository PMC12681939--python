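"""Differential expression between two sample groups, regulation
categories, over-representation analysis and PCA.

Each feature is tested with a two-sided Wilcoxon rank-sum test (exact
for small untied groups); p-values are Benjamini-Hochberg adjusted.
Features with FDR < 0.01 and |log2 FC| >= 1 are significantly up/down
regulated (S-U / S-D); FDR < 0.01 with milder fold change gives U / D;
everything else is NS.  The fold change is the difference of group
medians on the log2 scale.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

CATEGORIES = ("S-U", "U", "D", "S-D", "NS")


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Step-up BH adjustment with cumulative minimum, clipped to 1.

    NaN entries are skipped and returned as NaN.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    m = len(pv)
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(adjusted, 1.0)
    out[ok] = adj
    return out


def categorize_regulation(log2fc: float, fdr: float) -> str:
    """Regulation category from fold change and FDR.

    Zero fold change at significant FDR falls to D (non-positive is
    down, a documented tie rule).
    """
    if fdr is None or np.isnan(fdr) or np.isnan(log2fc):
        return "NS"
    if fdr >= 0.01:
        return "NS"
    if log2fc >= 1:
        return "S-U"
    if log2fc <= -1:
        return "S-D"
    return "U" if log2fc > 0 else "D"


def _rank_sum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided rank-sum p: exact for small untied groups, otherwise a
    tie-corrected normal approximation with continuity correction."""
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    if len(a) <= 25 and len(b) <= 25 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    return float(
        stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
    )


def wilcoxon_differential(
    matrix: pd.DataFrame,
    groups: Mapping[str, str],
    group_a: str,
    group_b: str,
    min_per_group: int = 3,
) -> pd.DataFrame:
    """Per-feature rank-sum test of group A versus group B.

    ``groups`` maps sample id to group label.  Features with fewer than
    ``min_per_group`` non-missing values in either group are reported NS
    with missing p.  Returns a DataFrame indexed by feature with columns
    log2fc, p_value, fdr, category, n_a, n_b.
    """
    samples_a = [s for s in matrix.columns if groups.get(s) == group_a]
    samples_b = [s for s in matrix.columns if groups.get(s) == group_b]
    if not samples_a or not samples_b:
        raise ValueError(f"empty group: {group_a}={len(samples_a)}, {group_b}={len(samples_b)}")

    rows = []
    for feature, values in matrix.iterrows():
        a = values[samples_a].dropna().to_numpy(dtype=float)
        b = values[samples_b].dropna().to_numpy(dtype=float)
        if len(a) < min_per_group or len(b) < min_per_group:
            rows.append((feature, np.nan, np.nan, len(a), len(b)))
            continue
        log2fc = float(np.median(a) - np.median(b))
        rows.append((feature, log2fc, _rank_sum_p(a, b), len(a), len(b)))
    df = pd.DataFrame(
        rows, columns=["feature", "log2fc", "p_value", "n_a", "n_b"]
    ).set_index("feature")
    df["fdr"] = benjamini_hochberg(df["p_value"].to_numpy())
    df["category"] = [
        categorize_regulation(fc, q) for fc, q in zip(df["log2fc"], df["fdr"])
    ]
    return df[["log2fc", "p_value", "fdr", "category", "n_a", "n_b"]]


def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT gene-set file: name, description, then member genes."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            sets[fields[0]] = set(g for g in fields[2:] if g)
    return sets


def overrepresentation(
    query: set[str],
    background: set[str],
    gene_sets: Mapping[str, set[str]],
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test per gene set.

    Each set is first restricted to the background; the p-value is the
    upper tail P(X >= overlap).  BH adjustment across sets; the
    ``significant`` column applies FDR < ``fdr_threshold``.
    """
    if not query <= background:
        raise ValueError("query genes must be a subset of the background")
    n_bg = len(background)
    n_query = len(query)
    rows = []
    for name, members in gene_sets.items():
        in_bg = members & background
        overlap = len(in_bg & query)
        k_set = len(in_bg)
        if k_set == 0:
            continue
        p = float(stats.hypergeom.sf(overlap - 1, n_bg, k_set, n_query))
        rows.append((name, overlap, k_set, p))
    df = pd.DataFrame(rows, columns=["set", "overlap", "set_size", "p_value"]).set_index("set")
    df["fdr"] = benjamini_hochberg(df["p_value"].to_numpy())
    df["significant"] = df["fdr"] < fdr_threshold
    return df.sort_values("p_value")


def principal_components(
    matrix: pd.DataFrame,
    n_components: int = 2,
    min_present: float = 0.5,
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples on the feature matrix.

    Features observed in fewer than ``min_present`` of samples are
    dropped; remaining missing values are feature-mean imputed.  Returns
    (sample scores, explained-variance fractions).
    """
    from sklearn.decomposition import PCA

    present = matrix.notna().mean(axis=1) >= min_present
    sub = matrix.loc[present]
    filled = sub.T.fillna(sub.mean(axis=1))
    n_components = min(n_components, min(filled.shape) - 1) or 1
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(filled.to_numpy())
    score_df = pd.DataFrame(
        scores,
        index=filled.index,
        columns=[f"PC{i + 1}" for i in range(scores.shape[1])],
    )
    return score_df, pca.explained_variance_ratio_
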