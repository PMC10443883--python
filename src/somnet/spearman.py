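"""Rank correlations with Fisher-z intervals and control comparison.

For every unordered pair of candidate genes and every sex x scheme data
subset we compute the Spearman correlation (Pearson on mid-ranks), a
confidence interval via the normal approximation to arctanh(rho) with
variance 1/(n-3), a rho != 0 significance flag, and whether the
selected scheme's interval overlaps the same-sex control interval.
Interval non-overlap is deliberately conservative relative to the
difference-of-z test (it overestimates the total variance), which is
kept available as a simulation oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats


def spearman_rho(x, y) -> float:
    """Spearman correlation: Pearson correlation of average ranks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(stats.spearmanr(x, y).statistic)


def fisher_ci(rho: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """CI for a correlation: tanh(arctanh(rho) +/- z / sqrt(n - 3))."""
    if not abs(rho) < 1:
        raise ValueError("|rho| must be < 1 for the Fisher transform")
    if n <= 3:
        raise ValueError("need n > 3 for the Fisher-z interval")
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z / np.sqrt(n - 3)
    center = np.arctanh(rho)
    return float(np.tanh(center - half)), float(np.tanh(center + half))


def fisher_difference_test(rho1: float, n1: int, rho2: float, n2: int) -> float:
    """Two-sided p for rho1 = rho2 via the z-difference (oracle route)."""
    z = (np.arctanh(rho1) - np.arctanh(rho2)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    return float(2.0 * stats.norm.sf(abs(z)))


def intervals_overlap(a: tuple[float, float], b: tuple[float, float]) -> bool:
    return not (a[1] < b[0] or b[1] < a[0])


@dataclass
class CorrelationComparison:
    gene_i: str
    gene_j: str
    sex: str
    scheme: str
    rho: float
    n: int
    ci_low: float
    ci_high: float
    significant_nonzero: bool
    overlaps_control: bool


def compare_all_pairs(
    expr_by_scheme: dict[str, pd.DataFrame],
    gene_set,
    sex: str = "",
    level: float = 0.95,
    control_key: str = "control",
) -> list[CorrelationComparison]:
    """Correlation comparisons for all C(n,2) gene pairs, per scheme.

    ``expr_by_scheme`` maps scheme name to a genes x samples expression
    table for one sex; selected schemes are compared against
    ``control_key``.  Control rows carry ``overlaps_control=True`` by
    convention.
    """
    genes = sorted(gene_set)
    if control_key not in expr_by_scheme:
        raise ValueError(f"expression for {control_key!r} scheme is required")
    out: list[CorrelationComparison] = []
    cache: dict[tuple[str, str, str], tuple[float, int, tuple[float, float]]] = {}

    def corr(scheme: str, gi: str, gj: str):
        key = (scheme, gi, gj)
        if key not in cache:
            tab = expr_by_scheme[scheme]
            rho = spearman_rho(tab.loc[gi], tab.loc[gj])
            n = tab.shape[1]
            cache[key] = (rho, n, fisher_ci(rho, n, level))
        return cache[key]

    for gi, gj in combinations(genes, 2):
        ctrl_rho, ctrl_n, ctrl_ci = corr(control_key, gi, gj)
        for scheme in expr_by_scheme:
            rho, n, ci = corr(scheme, gi, gj)
            out.append(
                CorrelationComparison(
                    gene_i=gi, gene_j=gj, sex=sex, scheme=scheme,
                    rho=rho, n=n, ci_low=ci[0], ci_high=ci[1],
                    significant_nonzero=not (ci[0] <= 0.0 <= ci[1]),
                    overlaps_control=(
                        True if scheme == control_key else intervals_overlap(ci, ctrl_ci)
                    ),
                )
            )
    return out


def comparisons_to_frame(comparisons: list[CorrelationComparison]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in comparisons])
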