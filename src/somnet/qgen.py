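"""Selection differentials, realized heritability, and CV_E.

Per generation t the selection differential is
S_t = mean(selected parents at t) - mean(all measured at t), and the
response is R_t = mean(all measured at t+1) - mean(all measured at t).
Realized heritability is the OLS slope (with intercept) of the
cumulated response on the cumulated differential -- the breeder's
equation h^2 = sum(R)/sum(S) in regression form, reported as
slope +/- SE with a two-sided p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class HeritabilityEstimate:
    h2: float
    se: float
    p: float


@dataclass
class CveResult:
    mean: float
    sd: float
    cv_e: float


def selection_stats(
    phenotypes: pd.DataFrame, scheme: str, replicate: int
) -> pd.DataFrame:
    """Per-generation S, R and their cumulated sums for one population.

    Sexes are pooled.  The last generation contributes no S/R row (it has
    no offspring); missing intermediate generations are an error.
    """
    sub = phenotypes[
        (phenotypes["scheme"] == scheme)
        & (phenotypes["population_replicate"] == replicate)
    ]
    if sub.empty:
        raise ValueError(f"no phenotypes for scheme={scheme!r} replicate={replicate}")
    gens = np.sort(sub["generation"].unique())
    if not np.array_equal(gens, np.arange(gens[0], gens[-1] + 1)):
        raise ValueError(f"missing generations in phenotype table: have {gens}")

    pop_mean = sub.groupby("generation")["night_sleep_minutes"].mean()
    sel = sub[sub["selected_parent"]]
    sel_mean = sel.groupby("generation")["night_sleep_minutes"].mean()

    rows = []
    for t in gens[:-1]:
        if t not in sel_mean.index:
            raise ValueError(f"generation {t} has no selected parents flagged")
        s_t = sel_mean.loc[t] - pop_mean.loc[t]
        r_t = pop_mean.loc[t + 1] - pop_mean.loc[t]
        rows.append((t, s_t, r_t))
    traj = pd.DataFrame(rows, columns=["generation", "S", "R"])
    traj["cum_S"] = traj["S"].cumsum()
    traj["cum_R"] = traj["R"].cumsum()
    return traj


def realized_heritability(traj: pd.DataFrame) -> HeritabilityEstimate:
    """OLS slope of cumulated response on cumulated differential."""
    if len(traj) < 3:
        raise ValueError("need at least 3 generations to regress")
    x = traj["cum_S"].to_numpy(float)
    y = traj["cum_R"].to_numpy(float)
    if np.ptp(x) == 0:
        raise ValueError("cumulated selection differential is constant; slope undefined")
    res = stats.linregress(x, y)
    return HeritabilityEstimate(h2=res.slope, se=res.stderr, p=res.pvalue)


def cv_e(values) -> CveResult:
    """Coefficient of environmental variation, 100 * sd / mean (sample SD)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty phenotype vector")
    mu = values.mean()
    if mu == 0:
        raise ValueError("mean is zero; CV undefined")
    sd = values.std(ddof=1) if values.size > 1 else 0.0
    return CveResult(mean=mu, sd=sd, cv_e=100.0 * sd / mu)
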