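"""Median-of-ratios normalization and intergenic expression filtering.

Size factors follow the pseudo-reference scheme standard in bulk
RNA-seq: each sample's factor is the median, over features expressed in
every sample, of the ratio of its count to that feature's geometric
mean across samples.  The expression filter pools the normalized,
log2-scale levels of the intergenic regions (a transcriptional noise
floor), takes a percentile (default 95th) per sex, and keeps the genic
features that exceed the corresponding linear cutoff in at least one
sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


def split_counts(counts: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Split a counts table with a leading ``region`` column."""
    if "region" not in counts.columns:
        raise ValueError("counts table must carry a 'region' column")
    return counts.drop(columns="region"), counts["region"]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factor per sample.

    ``counts`` is features x samples (no region column).  Only features
    with nonzero counts in every sample enter the geometric mean and the
    median, matching the reference implementation of the method.
    """
    mat = counts.to_numpy(dtype=float)
    all_nonzero = (mat > 0).all(axis=1)
    if not all_nonzero.any():
        raise ValueError("no feature has nonzero counts in all samples")
    logs = np.log(mat[all_nonzero])
    log_geomean = logs.mean(axis=1)
    log_ratios = logs - log_geomean[:, None]
    factors = np.exp(np.median(log_ratios, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize_counts(counts: pd.DataFrame, factors: pd.Series | None = None) -> pd.DataFrame:
    """Divide each sample column by its size factor."""
    if factors is None:
        factors = size_factors(counts)
    return counts / factors


@dataclass
class FilterResult:
    cutoff_log2: float
    cutoff_linear: float
    kept_feature_ids: list[str] = field(default_factory=list)


def filter_by_intergenic(
    normalized: pd.DataFrame,
    regions: pd.Series,
    percentile: float = 95.0,
    zero_handling: str = "exclude",
    pseudocount: float = 1.0,
) -> FilterResult:
    """Intergenic-percentile expression filter for one sex's samples.

    The cutoff is the ``percentile`` of log2 normalized intergenic
    levels pooled over intergenic features x samples.  Zeros are either
    excluded from that distribution (default; a zero count carries no
    noise-floor information on the log scale) or shifted by
    ``pseudocount`` when ``zero_handling='pseudocount'``.  A genic
    feature is kept iff its normalized level exceeds the linear cutoff
    in at least one sample.
    """
    regions = regions.reindex(normalized.index)
    inter = normalized[regions == "intergenic"].to_numpy(dtype=float).ravel()
    if inter.size == 0:
        raise ValueError("no intergenic features; cannot set filter cutoff")
    if zero_handling == "exclude":
        inter = inter[inter > 0]
        if inter.size == 0:
            # all-zero noise floor: every positive genic level passes
            cutoff_log2, cutoff_linear = -np.inf, 0.0
        else:
            cutoff_log2 = float(np.percentile(np.log2(inter), percentile))
            cutoff_linear = 2.0 ** cutoff_log2
    elif zero_handling == "pseudocount":
        cutoff_log2 = float(np.percentile(np.log2(inter + pseudocount), percentile))
        cutoff_linear = 2.0 ** cutoff_log2 - pseudocount
    else:
        raise ValueError(f"unknown zero_handling {zero_handling!r}")

    genic = normalized[regions == "genic"]
    keep = (genic > cutoff_linear).any(axis=1)
    return FilterResult(
        cutoff_log2=cutoff_log2,
        cutoff_linear=cutoff_linear,
        kept_feature_ids=list(genic.index[keep]),
    )
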