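"""Knockdown-vs-control expression ratios against random-set backgrounds.

For a disrupted gene's genotype pair the ratio of normalized expression
(mutant / control) is computed for each candidate interacting gene and
placed within the ratio distribution of random gene sets drawn from the
same expressed-gene universe (matched background and sex).  Under a
null generator the background ratio distribution centers on unity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def expression_ratio(mutant_expr: pd.Series, control_expr: pd.Series) -> pd.Series:
    """Elementwise mutant/control ratio of normalized expression.

    Genes with non-positive control expression are excluded (logged).
    """
    control_expr = control_expr.reindex(mutant_expr.index)
    bad = ~(control_expr > 0)
    if bad.any():
        logger.info("excluding %d genes with non-positive control expression", int(bad.sum()))
    keep = ~bad
    return mutant_expr[keep] / control_expr[keep]


@dataclass
class RatioReport:
    candidate_ratios: pd.Series
    candidate_percentiles: pd.Series
    background_median: float
    background_quantiles: dict[float, float]
    n_sets: int
    n_genes_per_set: int


def background_ratios(
    mutant_expr: pd.Series,
    control_expr: pd.Series,
    candidates,
    n_genes: int = 1000,
    n_sets: int = 100,
    seed: int = 0,
) -> RatioReport:
    """Random-set ratio background and candidate percentile placement.

    ``n_sets`` sets of ``n_genes`` genes are sampled without replacement
    from the expressed universe (positive control expression); the
    candidate percentile is the fraction of pooled background ratios
    below the candidate's ratio.
    """
    ratios = expression_ratio(mutant_expr, control_expr)
    universe = ratios.index.difference(pd.Index(candidates))
    if len(universe) < n_genes:
        raise ValueError(
            f"expressed-gene universe ({len(universe)}) smaller than set size ({n_genes})"
        )
    rng = np.random.default_rng(seed)
    pooled = []
    for _ in range(n_sets):
        chosen = rng.choice(universe.to_numpy(), size=n_genes, replace=False)
        pooled.append(ratios.loc[chosen].to_numpy())
    pooled = np.concatenate(pooled)

    cand = ratios.reindex(pd.Index(candidates)).dropna()
    percentiles = cand.map(lambda r: float(np.mean(pooled < r)))
    qs = {q: float(np.percentile(pooled, 100 * q)) for q in (0.025, 0.25, 0.5, 0.75, 0.975)}
    return RatioReport(
        candidate_ratios=cand,
        candidate_percentiles=percentiles,
        background_median=float(np.median(pooled)),
        background_quantiles=qs,
        n_sets=n_sets,
        n_genes_per_set=n_genes,
    )
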