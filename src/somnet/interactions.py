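"""Interaction calls and network assembly from pairwise GP posteriors.

The signal correlation rho = sigma_ij^2 / (sigma_i sigma_j) is computed
per retained MCMC draw; a pair is called interacting in a selection
scheme when the central 95% credible interval of rho in that scheme is
disjoint from the same-sex control interval.  Significant calls become
edges of a per sex x scheme network whose node degrees summarize each
gene's connectivity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import networkx as nx
import numpy as np


def posterior_rho(
    sigma2_i: np.ndarray, sigma2_j: np.ndarray, sigma2_ij: np.ndarray
) -> dict:
    """Per-draw signal correlation with expectation and central 95% CI.

    Draws with a non-positive variance are excluded and counted; more
    than 1% exclusions triggers a warning.
    """
    sigma2_i = np.asarray(sigma2_i, float).ravel()
    sigma2_j = np.asarray(sigma2_j, float).ravel()
    sigma2_ij = np.asarray(sigma2_ij, float).ravel()
    if not (len(sigma2_i) == len(sigma2_j) == len(sigma2_ij)):
        raise ValueError("draw vectors must be aligned by MCMC iteration")
    valid = (sigma2_i > 0) & (sigma2_j > 0)
    n_excluded = int(np.sum(~valid))
    if n_excluded > 0.01 * len(valid):
        warnings.warn(
            f"{n_excluded}/{len(valid)} draws excluded for non-positive variances",
            RuntimeWarning,
        )
    rho = sigma2_ij[valid] / np.sqrt(sigma2_i[valid] * sigma2_j[valid])
    assert np.all(np.abs(rho) <= 1 + 1e-9), "rho draws must lie in [-1, 1]"
    return {
        "draws": rho,
        "expectation": float(rho.mean()),
        "ci": (float(np.percentile(rho, 2.5)), float(np.percentile(rho, 97.5))),
        "n_excluded": n_excluded,
    }


def rho_from_posterior(post) -> dict:
    """Convenience wrapper taking a pairwise :class:`~somnet.gp.GpPosterior`."""
    return posterior_rho(
        post.draws["sigma2_i"], post.draws["sigma2_j"], post.draws["sigma2_ij"]
    )


@dataclass
class InteractionCall:
    gene_i: str
    gene_j: str
    sex: str
    scheme: str
    rho_expectation: float
    rho_ci: tuple[float, float]
    control_ci: tuple[float, float]
    significant: bool


def _central_ci(draws: np.ndarray, level: float) -> tuple[float, float]:
    lo = 100 * (0.5 - level / 2)
    a, b = np.percentile(np.asarray(draws, float).ravel(), [lo, 100 - lo])
    return float(a), float(b)


def call_pair(
    sel_posterior,
    control_posterior,
    level: float = 0.95,
    gene_i: str = "i",
    gene_j: str = "j",
    sex: str = "",
    scheme: str = "",
) -> InteractionCall:
    """Compare selected vs control rho posteriors at ``level`` credibility."""
    sel = rho_from_posterior(sel_posterior) if hasattr(sel_posterior, "draws") else sel_posterior
    ctl = (
        rho_from_posterior(control_posterior)
        if hasattr(control_posterior, "draws")
        else control_posterior
    )
    sel_ci = _central_ci(sel["draws"], level)
    ctl_ci = _central_ci(ctl["draws"], level)
    disjoint = sel_ci[1] < ctl_ci[0] or ctl_ci[1] < sel_ci[0]
    return InteractionCall(
        gene_i=gene_i, gene_j=gene_j, sex=sex, scheme=scheme,
        rho_expectation=float(np.mean(sel["draws"])),
        rho_ci=sel_ci, control_ci=ctl_ci, significant=bool(disjoint),
    )


@dataclass
class InteractionNetwork:
    graph: nx.Graph
    degrees: dict[str, int]
    average_degree: float
    n_edges: int


def build_network(
    calls: Iterable[InteractionCall],
    gene_set: Iterable[str],
    connected_only: bool = True,
) -> InteractionNetwork:
    """Assemble the network of significant calls over ``gene_set``.

    ``connected_only`` (default) averages the degree over nodes with at
    least one edge, mirroring how unconnected genes are reported as
    not-applicable; switch it off to divide by the full gene set.
    """
    g = nx.Graph()
    g.add_nodes_from(gene_set)
    for call in calls:
        if not call.significant:
            continue
        if call.gene_i not in g or call.gene_j not in g:
            raise ValueError(f"call references genes outside gene_set: {call.gene_i}, {call.gene_j}")
        g.add_edge(call.gene_i, call.gene_j, rho=call.rho_expectation, sign=np.sign(call.rho_expectation))
    degrees = {node: int(d) for node, d in g.degree()}
    n_edges = g.number_of_edges()
    if connected_only:
        active = [d for d in degrees.values() if d > 0]
        avg = float(np.mean(active)) if active else 0.0
    else:
        avg = 2.0 * n_edges / max(len(degrees), 1)
    return InteractionNetwork(graph=g, degrees=degrees, average_degree=avg, n_edges=n_edges)
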