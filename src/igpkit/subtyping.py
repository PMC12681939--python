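"""NMF consensus subtyping of tumor samples on glycoform abundances.

The log2 matrix is reduced to its more variable features, z-scored, and
made non-negative by splitting every feature into a positive-part row
and a negated-negative-part row.  Repeated NMF runs from random
initializations give per-run labels (argmax of the coefficient matrix);
their co-clustering frequencies form a consensus matrix whose
cophenetic correlation and dispersion guide rank selection (the rank
maximizing their product wins, ties to the smaller rank).
Representative features per cluster are those with relative basis
contribution >= 0.8.  Subtype concordance against external labelings
uses the Jaccard index with a permutation test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform
from sklearn.decomposition import NMF

from .diffexpr import benjamini_hochberg

logger = logging.getLogger(__name__)


def filter_variable_features(
    matrix: pd.DataFrame,
    mode: str = "percentile",
    sd_threshold: float = 0.25,
) -> pd.DataFrame:
    """Keep high-variability features and z-score them.

    ``percentile`` (default) drops features whose standard deviation is
    at or below the 25th percentile of all feature standard deviations;
    ``absolute`` keeps features with sd > ``sd_threshold``.  Surviving
    features are standardized to mean 0, sd 1.
    """
    sds = matrix.std(axis=1, ddof=1, skipna=True)
    if mode == "percentile":
        cutoff = float(np.nanpercentile(sds, 25))
        keep = sds > cutoff
    elif mode == "absolute":
        keep = sds > sd_threshold
    else:
        raise ValueError(f"unknown mode {mode!r}")
    sub = matrix.loc[keep]
    return sub.sub(sub.mean(axis=1), axis=0).div(sub.std(axis=1, ddof=1), axis=0)


def nonnegative_split(matrix: pd.DataFrame) -> pd.DataFrame:
    """Double the feature rows into positive and negated-negative parts.

    Row order: all positive-part rows (suffix ``+``) then all
    negative-magnitude rows (suffix ``-``).  Exactly invertible:
    positive part minus negative part reconstructs the input.
    """
    pos = matrix.clip(lower=0)
    neg = (-matrix).clip(lower=0)
    pos.index = [f"{i}+" for i in matrix.index]
    neg.index = [f"{i}-" for i in matrix.index]
    return pd.concat([pos, neg], axis=0)


@dataclass
class SubtypeModel:
    """Result of consensus NMF at one rank."""

    rank: int
    labels: pd.Series                 # sample -> cluster in 1..k
    basis: pd.DataFrame               # features x k
    coefficients: pd.DataFrame        # k x samples
    consensus: pd.DataFrame           # samples x samples in [0, 1]
    cophenetic: float
    dispersion: float

    @property
    def quality(self) -> float:
        return self.cophenetic * self.dispersion


def _consensus_stats(consensus: np.ndarray) -> tuple[float, float]:
    n = consensus.shape[0]
    dispersion = float(np.mean(4.0 * (consensus - 0.5) ** 2))
    dist = 1.0 - consensus
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    if np.allclose(condensed, condensed[0] if len(condensed) else 0.0):
        # perfectly uniform distances: cophenetic correlation undefined;
        # treat a perfect block structure (all 0/1) as 1
        cophenetic_c = 1.0 if set(np.round(np.unique(consensus), 9)) <= {0.0, 1.0} else 0.0
        return cophenetic_c, dispersion
    link = linkage(condensed, method="average")
    coph_corr, _ = cophenet(link, condensed)
    if np.isnan(coph_corr):
        coph_corr = 1.0 if np.allclose(condensed, np.round(condensed)) else 0.0
    return float(coph_corr), dispersion


def nmf_consensus(
    matrix: pd.DataFrame,
    k: int,
    n_runs: int = 30,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> SubtypeModel:
    """Consensus NMF at rank ``k`` over ``n_runs`` random restarts.

    The reported basis/coefficients come from the restart with the
    lowest reconstruction error; labels are the argmax of its
    coefficient columns.
    """
    if k < 2:
        raise ValueError("rank k must be >= 2")
    X = matrix.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("NMF input must not contain missing values")
    if (X < 0).any():
        raise ValueError("NMF input must be non-negative")
    n_samples = X.shape[1]
    rng = np.random.default_rng(seed)
    co = np.zeros((n_samples, n_samples))
    best = None
    best_err = np.inf
    for run in range(n_runs):
        rs = int(rng.integers(0, 2**31 - 1))
        model = NMF(
            n_components=k,
            init="random",
            solver="mu",
            beta_loss="frobenius",
            max_iter=max_iter,
            tol=tol,
            random_state=rs,
        )
        import warnings
        from sklearn.exceptions import ConvergenceWarning

        with warnings.catch_warnings():
            # the update cap is a deliberate compute bound, not a failure
            warnings.simplefilter("ignore", ConvergenceWarning)
            W = model.fit_transform(X)
        H = model.components_
        labels = np.argmax(H, axis=0)
        co += labels[:, None] == labels[None, :]
        if model.reconstruction_err_ < best_err:
            best_err = model.reconstruction_err_
            best = (W, H, labels)
    consensus = co / n_runs
    coph, disp = _consensus_stats(consensus)
    W, H, labels = best
    return SubtypeModel(
        rank=k,
        labels=pd.Series(labels + 1, index=matrix.columns, name="cluster"),
        basis=pd.DataFrame(W, index=matrix.index, columns=range(1, k + 1)),
        coefficients=pd.DataFrame(H, index=range(1, k + 1), columns=matrix.columns),
        consensus=pd.DataFrame(consensus, index=matrix.columns, columns=matrix.columns),
        cophenetic=coph,
        dispersion=disp,
    )


def select_rank(
    matrix: pd.DataFrame,
    k_range=range(2, 11),
    n_runs: int = 30,
    final_runs: int = 500,
    seed: int = 0,
) -> tuple[SubtypeModel, pd.DataFrame]:
    """Survey ranks and refit the winner.

    The winning rank maximizes cophenetic x dispersion of the consensus
    matrix (ties to the smaller rank); the final model is refit with
    ``final_runs`` restarts.  Returns (final model, rank survey table).
    """
    surveys = []
    for k in k_range:
        if k >= matrix.shape[1]:
            break
        m = nmf_consensus(matrix, k, n_runs=n_runs, seed=seed + k)
        surveys.append((k, m.cophenetic, m.dispersion, m.quality))
        logger.info("rank %d: cophenetic=%.4f dispersion=%.4f product=%.4f",
                    k, m.cophenetic, m.dispersion, m.quality)
    survey = pd.DataFrame(
        surveys, columns=["k", "cophenetic", "dispersion", "product"]
    ).set_index("k")
    k_star = int(survey["product"].idxmax())  # idxmax takes the first (smallest) max
    final = nmf_consensus(matrix, k_star, n_runs=final_runs, seed=seed + 1000)
    return final, survey


def extract_representative_features(
    model: SubtypeModel, threshold: float = 0.8
) -> dict[int, list[str]]:
    """Features whose relative basis contribution to one cluster is
    at least ``threshold`` (inclusive)."""
    basis = model.basis.to_numpy(dtype=float)
    totals = basis.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(totals > 0, basis / totals, 0.0)
    out: dict[int, list[str]] = {j: [] for j in range(1, model.rank + 1)}
    for i, feature in enumerate(model.basis.index):
        j = int(np.argmax(rel[i]))
        if rel[i, j] >= threshold:
            out[j + 1].append(feature)
    return out


def jaccard_index(a: set, b: set) -> float:
    """|A n B| / |A u B|; 0 when both sets are empty."""
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


def label_permutation_test(
    labels_1: pd.Series,
    labels_2: pd.Series,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Jaccard concordance between two labelings with a permutation test.

    For each (class of labels_1, class of labels_2) pair, the p-value is
    the add-one-smoothed fraction of permutations of labels_2 achieving
    a Jaccard index at least as large as observed; BH correction is
    applied across pairs.
    """
    common = labels_1.index.intersection(labels_2.index)
    l1 = labels_1.loc[common]
    l2 = labels_2.loc[common]
    classes_1 = sorted(l1.unique())
    classes_2 = sorted(l2.unique())
    sets_1 = {c: set(common[l1 == c]) for c in classes_1}
    observed = {
        (c1, c2): jaccard_index(sets_1[c1], set(common[l2 == c2]))
        for c1 in classes_1
        for c2 in classes_2
    }
    rng = np.random.default_rng(seed)
    exceed = {pair: 0 for pair in observed}
    values = l2.to_numpy()
    for _ in range(n_perm):
        perm = rng.permutation(values)
        perm_series = pd.Series(perm, index=common)
        for c1 in classes_1:
            for c2 in classes_2:
                j = jaccard_index(sets_1[c1], set(common[perm_series == c2]))
                if j >= observed[(c1, c2)]:
                    exceed[(c1, c2)] += 1
    rows = [
        (c1, c2, observed[(c1, c2)], (exceed[(c1, c2)] + 1) / (n_perm + 1))
        for c1 in classes_1
        for c2 in classes_2
    ]
    df = pd.DataFrame(rows, columns=["class_1", "class_2", "jaccard", "p_value"])
    df["fdr"] = benjamini_hochberg(df["p_value"].to_numpy())
    df["stars"] = np.select([df["fdr"] < 0.01, df["fdr"] < 0.05], ["**", "*"], default="")
    return df


def signed_fdr(log2fc, fdr) -> np.ndarray:
    """sign(log2fc) * -log10(fdr), elementwise."""
    return np.sign(np.asarray(log2fc, dtype=float)) * (
        -np.log10(np.asarray(fdr, dtype=float))
    )


def signed_fdr_cdf(
    de_results: pd.DataFrame, glycan_types: pd.Series
) -> dict[str, pd.DataFrame]:
    """Per-glycan-type empirical CDF of the signed FDR statistic.

    ``de_results`` needs columns log2fc and fdr; ``glycan_types`` maps
    feature id to a glycan type.  Returns per-type DataFrames with
    sorted ``value`` and non-decreasing ``cdf`` in (0, 1].
    """
    joined = de_results[["log2fc", "fdr"]].join(glycan_types.rename("glycan_type"), how="inner")
    joined = joined.dropna()
    joined["signed"] = signed_fdr(joined["log2fc"], joined["fdr"])
    out = {}
    for gtype, grp in joined.groupby("glycan_type"):
        values = np.sort(grp["signed"].to_numpy())
        cdf = np.arange(1, len(values) + 1) / len(values)
        out[str(gtype)] = pd.DataFrame({"value": values, "cdf": cdf})
    return out
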