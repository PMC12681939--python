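"""Reporter-ion quantification and glycoform aggregation.

Raw reporter intensities are extracted per channel, summed over the
glycopeptides covering the same glycoform (protein, gene, site,
composition), converted to log2 ratios against a pooled-reference
channel and median-centered per sample.  The resulting feature-by-
sample matrix (missing values allowed) is the container consumed by
all downstream cohort analytics.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .spectra import FragmentSpectrum, ReporterDesign

logger = logging.getLogger(__name__)


def extract_reporter_intensities(
    s: FragmentSpectrum, design: ReporterDesign | None = None
) -> dict[str, float]:
    """Nearest-peak intensity per reporter channel; NaN when absent."""
    design = design or ReporterDesign()
    out: dict[str, float] = {}
    for name, mz in design.channels.items():
        sel = np.abs(s.mz - mz) <= design.tolerance_da
        if sel.any():
            idx = np.nonzero(sel)[0]
            nearest = idx[np.argmin(np.abs(s.mz[idx] - mz))]
            out[name] = float(s.intensity[nearest])
        else:
            out[name] = float("nan")
    return out


def aggregate_glycoforms(psm_table: pd.DataFrame, channels: Sequence[str]) -> pd.DataFrame:
    """Sum raw PSM reporter intensities per glycoform.

    ``psm_table`` must carry columns ``protein, gene, site, glycan`` plus
    one raw-intensity column per channel.  A glycoform covered by a
    single glycopeptide keeps that glycopeptide's intensities; multiple
    contributing glycopeptides (e.g. missed-cleavage variants) are
    summed.  Aggregation happens on raw intensities, before any ratio or
    log transform.
    """
    key_cols = ["protein", "gene", "site", "glycan"]
    grouped = psm_table.groupby(key_cols, sort=True)[list(channels)].sum(min_count=1)
    grouped.index = [
        f"{p}_{g}_{s}_{c}" for p, g, s, c in grouped.index
    ]
    grouped.index.name = "glycoform"
    return grouped


def normalize_to_pool(
    raw: pd.DataFrame,
    pool_channel: str,
    sample_names: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """log2(channel / pool) per feature, then per-sample median centering.

    Rows whose pool intensity is missing or zero are dropped (counted in
    the log).  ``sample_names`` optionally renames channels to sample
    ids; the pool channel itself is excluded from the output.
    """
    if pool_channel not in raw.columns:
        raise ValueError(f"pool channel {pool_channel!r} not in table")
    pool = raw[pool_channel]
    ok = pool.notna() & (pool > 0)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("dropped %d features with missing/zero pool intensity", n_dropped)
    data = raw.loc[ok, [c for c in raw.columns if c != pool_channel]]
    with np.errstate(divide="ignore", invalid="ignore"):
        log_ratio = np.log2(data.div(pool[ok], axis=0))
    log_ratio = log_ratio.replace([np.inf, -np.inf], np.nan)
    log_ratio = log_ratio - log_ratio.median(axis=0, skipna=True)
    if sample_names:
        log_ratio = log_ratio.rename(columns=dict(sample_names))
    return log_ratio


def concat_plexes(matrices: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Concatenate per-plex normalized matrices on the feature axis
    (outer join; features absent from a plex stay missing)."""
    return pd.concat(matrices, axis=1, join="outer")


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a feature-by-sample matrix as TSV (empty cell = missing)."""
    matrix.to_csv(path, sep="\t", index_label=matrix.index.name or "feature")


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a feature-by-sample TSV matrix written by :func:`write_matrix`."""
    return pd.read_csv(path, sep="\t", index_col=0)
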