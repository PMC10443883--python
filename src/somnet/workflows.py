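"""End-to-end drivers tying the pipeline stages together.

These functions are the shared machinery behind the ``analysis/``
scripts, the acceptance script, and the integration tests: simulate or
load a count matrix, normalize and filter it, screen genes with the
hierarchical GLM, and run the single-/two-channel GP interaction
analysis for a set of candidate pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .glm import (
    GlmPriors,
    bh_adjust,
    build_design,
    fit_gene,
    fits_to_frame,
    mean_log_expression_gen0,
)
from .gp import GpPriors, fit_pair, fit_single_channel, reduced_schedule
from .interactions import InteractionCall, build_network, call_pair
from .mcmc import HmcConfig
from .normalize import size_factors


def glm_screen(
    counts: pd.DataFrame,
    manifest: pd.DataFrame,
    sex: str,
    genes=None,
    n_restarts: int = 3,
    alpha: float = 0.001,
    seed: int = 0,
) -> pd.DataFrame:
    """Hierarchical NB-GLM screen of ``genes`` for one sex.

    ``counts`` is a genes x samples table (no region column); returns
    the per-gene fit table with BH-adjusted q-values.
    """
    mani = manifest[manifest["sex"] == sex]
    mat = counts[mani["sample_id"]]
    factors = size_factors(mat)
    design = build_design(mani, factors)
    genes = list(mat.index) if genes is None else list(genes)
    fits = {}
    for gene in genes:
        y = mat.loc[gene].to_numpy()
        priors = GlmPriors(y0bar=mean_log_expression_gen0(y, mani, factors))
        fits[gene] = fit_gene(y, design, priors, n_restarts=n_restarts, seed=seed)
    frame = fits_to_frame(fits)
    frame["q"], frame["significant"] = bh_adjust(frame["p"].to_numpy(), alpha=alpha)
    return frame


@dataclass
class GpSubset:
    """One sex x scheme data slice prepared for GP fitting."""

    x: np.ndarray  # generation per sample
    counts: pd.DataFrame  # genes x samples
    offsets: np.ndarray  # log size factors


def prepare_gp_subsets(
    counts: pd.DataFrame, manifest: pd.DataFrame, sex: str, schemes=("short", "control", "long")
) -> dict[str, GpSubset]:
    """Split one sex's samples by scheme, attaching offsets and generations."""
    mani = manifest[manifest["sex"] == sex]
    mat = counts[mani["sample_id"]]
    factors = size_factors(mat)
    subsets = {}
    for scheme in schemes:
        sub = mani[mani["scheme"] == scheme].sort_values(["generation", "population_replicate"])
        sids = sub["sample_id"]
        subsets[scheme] = GpSubset(
            x=sub["generation"].to_numpy(float),
            counts=mat[sids],
            offsets=np.log(factors.reindex(sids).to_numpy(float)),
        )
    return subsets


def gp_interaction_analysis(
    subsets: dict[str, GpSubset],
    pairs: list[tuple[str, str]],
    sex: str = "",
    schemes=("short", "long"),
    control_key: str = "control",
    mcmc: HmcConfig | None = None,
    gp_priors: GpPriors | None = None,
    phi_scale: float = 1.0,
    seed: int = 0,
    max_reruns: int = 1,
) -> tuple[list[InteractionCall], dict[str, object]]:
    """Single-channel fits, pairwise fits, and interaction calls.

    For each gene involved in ``pairs`` a single-channel GP is fitted
    per scheme (selected schemes and control) to propagate priors; each
    pair is then fitted in each selected scheme and in the control, and
    called significant when the signal-correlation credible intervals
    are disjoint from control.  Returns the calls and the per-scheme
    networks over the genes involved.
    """
    mcmc = mcmc or reduced_schedule(seed)
    gp_priors = gp_priors or GpPriors(phi_scale=phi_scale)
    genes = sorted({g for p in pairs for g in p})
    fit_schemes = list(schemes) + [control_key]

    singles: dict[tuple[str, str], object] = {}
    for si, scheme in enumerate(fit_schemes):
        sub = subsets[scheme]
        for gi, gene in enumerate(genes):
            cfg = HmcConfig(**{**mcmc.__dict__, "seed": mcmc.seed + 101 * si + 13 * gi})
            singles[(gene, scheme)] = fit_single_channel(
                sub.counts.loc[gene].to_numpy(float), sub.x, sub.offsets,
                priors=gp_priors, mcmc=cfg, max_reruns=max_reruns,
                interleave=False,  # moments for prior propagation only
            )

    calls: list[InteractionCall] = []
    pair_fits: dict[tuple[str, str, str], object] = {}
    for pi, (ga, gb) in enumerate(pairs):
        for si, scheme in enumerate(fit_schemes):
            sub = subsets[scheme]
            cfg = HmcConfig(**{**mcmc.__dict__, "seed": mcmc.seed + 1009 * pi + 211 * si + 7})
            pair_fits[(ga, gb, scheme)] = fit_pair(
                sub.counts.loc[ga].to_numpy(float), sub.counts.loc[gb].to_numpy(float),
                sub.x, sub.offsets, sub.offsets,
                singles[(ga, scheme)], singles[(gb, scheme)],
                mcmc=cfg, phi_scale=phi_scale, max_reruns=max_reruns,
            )
        for scheme in schemes:
            calls.append(
                call_pair(
                    pair_fits[(ga, gb, scheme)], pair_fits[(ga, gb, control_key)],
                    gene_i=ga, gene_j=gb, sex=sex, scheme=scheme,
                )
            )

    networks = {
        scheme: build_network([c for c in calls if c.scheme == scheme], genes)
        for scheme in schemes
    }
    return calls, {"networks": networks, "singles": singles, "pair_fits": pair_fits}
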