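"""Hierarchical negative-binomial GLM screen for expression trends.

Each gene (one sex at a time) is modeled as NB counts with log link

    eta = X beta + log(size factor),    var = mu + mu^2 / alpha,

where the 11-column design carries per-population-replicate intercepts,
scheme indicators for short/long sleepers, a shared generation slope,
and replicate-specific scheme-by-generation interaction slopes (the
generation value where the treatment applies, 0 elsewhere).  Replicate
pairs of coefficients are tied hierarchically: each pair is Gaussian
around a group-level mean with a half-Cauchy(0,1) scale, and the group
means get N(0,1) hyperpriors (the intercept group mean is centered on
the mean log expression at generation 0).  MAP estimates maximize the
penalized likelihood; significance of the four interaction slopes comes
from a likelihood-ratio test of the full model against the reduced
model without them (chi-square, df=4 by default), BH-corrected across
genes at the 0.001 level.  Genes whose group-level short-by-generation
and long-by-generation means have opposite signs in both sexes form the
cross-sex candidate set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

FULL_COLUMNS = [
    "b1", "b2",
    "b_short1", "b_short2", "b_long1", "b_long2",
    "b_gen",
    "b_short_gen1", "b_short_gen2", "b_long_gen1", "b_long_gen2",
]
REDUCED_COLUMNS = FULL_COLUMNS[:7]

# hierarchical groups: (hyper name, beta column indices)
FULL_GROUPS = [
    ("control", (0, 1)),
    ("short", (2, 3)),
    ("long", (4, 5)),
    ("short_gen", (7, 8)),
    ("long_gen", (9, 10)),
]
REDUCED_GROUPS = FULL_GROUPS[:3]

GEN_SLOPE_INDEX = 6  # b_gen, fixed N(0, 2) prior
ALPHA_BOUNDS = (0.0, 1e9)


@dataclass
class GlmDesign:
    X: np.ndarray  # (n_samples, 11)
    offsets: np.ndarray  # log size factors
    sample_ids: list[str]
    columns: list[str] = field(default_factory=lambda: list(FULL_COLUMNS))


@dataclass
class GlmPriors:
    """Hyperprior settings; ``y0bar`` anchors the intercept group mean."""

    y0bar: float = 0.0
    hyper_mu_sd: float = 1.0
    hyper_sigma_scale: float = 1.0  # half-Cauchy scale
    gen_slope_sd: float = 2.0


@dataclass
class GlmFit:
    params: dict[str, float]
    hyper_params: dict[str, float]
    alpha: float
    loglik_full: float
    loglik_reduced: float
    lrt_stat: float
    p: float
    q: float = np.nan
    mu_short_gen: float = np.nan
    mu_long_gen: float = np.nan
    converged: bool = True
    posterior: Optional[pd.DataFrame] = None


def build_design(manifest: pd.DataFrame, size_factors: pd.Series) -> GlmDesign:
    """Design matrix for one sex's samples, with log-size-factor offsets."""
    if manifest["sex"].nunique() > 1:
        raise ValueError("manifest must be restricted to a single sex")
    known = {"short", "control", "long"}
    unknown = set(manifest["scheme"]) - known
    if unknown:
        raise ValueError(f"unknown scheme labels: {sorted(unknown)}")

    n = len(manifest)
    X = np.zeros((n, len(FULL_COLUMNS)))
    for i, row in enumerate(manifest.itertuples(index=False)):
        rep = int(row.population_replicate)
        if rep not in (1, 2):
            raise ValueError(f"population_replicate must be 1 or 2, got {rep}")
        X[i, rep - 1] = 1.0  # intercept: exactly one of b1/b2
        gen = float(row.generation)
        X[i, GEN_SLOPE_INDEX] = gen
        if row.scheme == "short":
            X[i, 2 + (rep - 1)] = 1.0
            X[i, 7 + (rep - 1)] = gen
        elif row.scheme == "long":
            X[i, 4 + (rep - 1)] = 1.0
            X[i, 9 + (rep - 1)] = gen
    sample_ids = list(manifest["sample_id"])
    offsets = np.log(size_factors.reindex(sample_ids).to_numpy(float))
    return GlmDesign(X=X, offsets=offsets, sample_ids=sample_ids)


def mean_log_expression_gen0(
    counts_row: np.ndarray, manifest: pd.DataFrame, size_factors: pd.Series
) -> float:
    """Mean of log(normalized count + 1) over generation-0 samples."""
    mask = (manifest["generation"] == 0).to_numpy()
    sids = manifest["sample_id"].to_numpy()[mask]
    norm = np.asarray(counts_row, float)[mask] / size_factors.reindex(sids).to_numpy(float)
    return float(np.mean(np.log(norm + 1.0)))


def nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    """NB2 log-likelihood with mean mu and concentration alpha."""
    mu = np.maximum(mu, 1e-12)
    return float(
        np.sum(
            special.gammaln(y + alpha)
            - special.gammaln(alpha)
            - special.gammaln(y + 1.0)
            + alpha * np.log(alpha / (alpha + mu))
            + special.xlogy(y, mu / (alpha + mu))
        )
    )


def _unpack(theta: np.ndarray, n_groups: int, n_beta: int):
    mus = theta[:n_groups]
    log_sigmas = theta[n_groups: 2 * n_groups]
    btilde = theta[2 * n_groups: 2 * n_groups + n_beta]
    log_alpha = theta[-1]
    return mus, log_sigmas, btilde, log_alpha


def _betas_from(theta: np.ndarray, groups, n_beta: int) -> np.ndarray:
    """Recover natural coefficients beta = mu_g + sigma_g * btilde."""
    mus, log_sigmas, btilde, _ = _unpack(theta, len(groups), n_beta)
    sigmas = np.exp(log_sigmas)
    betas = btilde.copy()
    for gi, (_, idx) in enumerate(groups):
        for j in idx:
            betas[j] = mus[gi] + sigmas[gi] * btilde[j]
    return betas


def _log_posterior_and_grad(
    theta: np.ndarray,
    y: np.ndarray,
    X: np.ndarray,
    offsets: np.ndarray,
    priors: GlmPriors,
    groups,
    jacobian: bool = False,
):
    """Penalized NB log-likelihood and gradient, non-centered form.

    Replicate coefficients are expressed as beta = mu_g + sigma_g *
    btilde with btilde ~ N(0,1), which keeps the hierarchical objective
    bounded (the centered-form density diverges as a group scale
    approaches zero) and is how these models are conventionally coded.
    With ``jacobian`` the log-scale transform terms are added, turning
    the objective into the sampling density on unconstrained space.
    """
    n_groups, n_beta = len(groups), X.shape[1]
    mus, log_sigmas, btilde, log_alpha = _unpack(theta, n_groups, n_beta)
    sigmas = np.exp(log_sigmas)
    alpha = np.exp(log_alpha)
    betas = _betas_from(theta, groups, n_beta)

    eta = np.clip(X @ betas + offsets, -30.0, 30.0)
    mu = np.exp(eta)
    lp = nb_loglik(y, mu, alpha)
    grad = np.zeros_like(theta)

    # likelihood gradient through the reparameterization
    g_eta = y - (y + alpha) * mu / (alpha + mu)
    g_beta = X.T @ g_eta
    grad[2 * n_groups: 2 * n_groups + n_beta] = g_beta  # overwritten per group below
    dll_dalpha = np.sum(
        special.digamma(y + alpha)
        - special.digamma(alpha)
        + np.log(alpha / (alpha + mu))
        + 1.0
        - (alpha + y) / (alpha + mu)
    )
    grad[-1] = alpha * dll_dalpha

    for gi, (name, idx) in enumerate(groups):
        for j in idx:
            grad[gi] += g_beta[j]
            grad[n_groups + gi] += sigmas[gi] * btilde[j] * g_beta[j]
            grad[2 * n_groups + j] = sigmas[gi] * g_beta[j]
        # standard-normal prior on the non-centered coefficients
        for j in idx:
            lp += -0.5 * btilde[j] ** 2
            grad[2 * n_groups + j] += -btilde[j]
        # hyperpriors: mu ~ N(m0, hyper_mu_sd); sigma ~ half-Cauchy(0, scale)
        m0 = priors.y0bar if name == "control" else 0.0
        lp += -0.5 * (mus[gi] - m0) ** 2 / priors.hyper_mu_sd ** 2
        grad[gi] += -(mus[gi] - m0) / priors.hyper_mu_sd ** 2
        c = priors.hyper_sigma_scale
        lp += -np.log(1.0 + (sigmas[gi] / c) ** 2)
        grad[n_groups + gi] += (
            -2.0 * (sigmas[gi] / c) ** 2 / (1.0 + (sigmas[gi] / c) ** 2)
        )
        if jacobian:
            lp += log_sigmas[gi]
            grad[n_groups + gi] += 1.0

    # shared generation slope, direct parameterization with N(0, sd) prior
    bgen = btilde[GEN_SLOPE_INDEX]
    lp += -0.5 * bgen ** 2 / priors.gen_slope_sd ** 2
    grad[2 * n_groups + GEN_SLOPE_INDEX] += -bgen / priors.gen_slope_sd ** 2

    # flat prior on alpha within bounds
    if not (ALPHA_BOUNDS[0] < alpha < ALPHA_BOUNDS[1]):
        lp = -np.inf
    if jacobian:
        lp += log_alpha
        grad[-1] += 1.0
    return lp, grad


def _initial_theta(y, X, offsets, priors, groups, rng=None, scale=0.0):
    n_groups, n_beta = len(groups), X.shape[1]
    base = np.log(np.mean(y / np.exp(offsets)) + 0.1)
    theta = np.zeros(2 * n_groups + n_beta + 1)
    theta[0] = base  # intercept group mean
    theta[n_groups: 2 * n_groups] = np.log(0.5)
    theta[-1] = np.log(10.0)
    if rng is not None and scale > 0:
        theta = theta + rng.normal(0.0, scale, theta.shape)
    return theta


def _bounds(groups, n_beta):
    n_groups = len(groups)
    return (
        [(-30.0, 30.0)] * n_groups  # hyper means
        + [(-10.0, 5.0)] * n_groups  # log scales
        + [(-30.0, 30.0)] * n_beta
        + [(np.log(1e-6), np.log(ALPHA_BOUNDS[1]))]  # log alpha
    )


def _fit_model(y, X, offsets, priors, groups, n_restarts=10, seed=0, gtol=1e-8,
               extra_starts=()):
    rng = np.random.default_rng(seed)
    best = None
    starts = [
        _initial_theta(y, X, offsets, priors, groups, rng=rng, scale=0.0 if r == 0 else 0.5)
        for r in range(n_restarts)
    ] + [np.asarray(s, float) for s in extra_starts]
    for theta0 in starts:
        with np.errstate(all="ignore"):
            res = optimize.minimize(
                lambda t: tuple(
                    -v for v in _log_posterior_and_grad(t, y, X, offsets, priors, groups)
                ),
                theta0,
                jac=True,
                method="L-BFGS-B",
                bounds=_bounds(groups, X.shape[1]),
                options={"maxiter": 500, "gtol": gtol, "ftol": 1e-12},
            )
        if np.isfinite(res.fun) and (best is None or -res.fun > best[0]):
            best = (-res.fun, res.x, res.success)
    if best is None:
        raise RuntimeError("all optimizer starts failed")
    lp, theta, ok = best
    n_groups, n_beta = len(groups), X.shape[1]
    mus, log_sigmas, _, log_alpha = _unpack(theta, n_groups, n_beta)
    betas = _betas_from(theta, groups, n_beta)
    mu = np.exp(X @ betas + offsets)
    ll = nb_loglik(y, mu, np.exp(log_alpha))
    return {
        "theta": theta,
        "log_posterior": lp,
        "loglik": ll,
        "betas": betas,
        "mus": mus,
        "sigmas": np.exp(log_sigmas),
        "alpha": float(np.exp(log_alpha)),
        "converged": bool(ok),
    }


def lrt(loglik_full: float, loglik_reduced: float, df: int = 4, tol: float = 0.5) -> tuple[float, float]:
    """Likelihood-ratio statistic and upper-tail chi-square p-value.

    Because both models are fitted by penalized (MAP) optimization, the
    full model's raw likelihood may sit marginally below the reduced
    one for null genes; deficits within ``tol`` are clamped to zero and
    larger ones raise (a genuine optimizer failure).
    """
    stat = 2.0 * (loglik_full - loglik_reduced)
    if stat < -2.0 * tol:
        raise RuntimeError(
            f"reduced model log-likelihood exceeds full model by {-stat / 2:g}: optimizer failure"
        )
    stat = max(stat, 0.0)
    return stat, float(stats.chi2.sf(stat, df))


def fit_gene(
    counts_row: np.ndarray,
    design: GlmDesign,
    priors: GlmPriors,
    mode: str = "map",
    df: int = 4,
    n_restarts: int = 10,
    seed: int = 0,
    mcmc=None,
) -> GlmFit:
    """Fit full and reduced hierarchical NB-GLMs to one gene's counts.

    ``mode='posterior'`` additionally samples the full-model posterior
    with the in-package HMC sampler and attaches draw summaries.
    """
    y = np.asarray(counts_row, dtype=float)
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise ValueError("counts must be non-negative integers")
    if len(y) != design.X.shape[0]:
        raise ValueError("counts row does not align with design rows")

    X_red = design.X[:, : len(REDUCED_COLUMNS)]
    red = _fit_model(y, X_red, design.offsets, priors, REDUCED_GROUPS,
                     n_restarts=n_restarts, seed=seed + 1)
    # warm-start the full model from the reduced solution (interactions at 0)
    warm = np.zeros(2 * len(FULL_GROUPS) + len(FULL_COLUMNS) + 1)
    tr = red["theta"]
    warm[0:3] = tr[0:3]
    warm[5:8] = tr[3:6]
    warm[3:5] = 0.0
    warm[8:10] = np.log(0.1)
    warm[10:17] = tr[6:13]
    warm[-1] = tr[-1]
    full = _fit_model(y, design.X, design.offsets, priors, FULL_GROUPS,
                      n_restarts=n_restarts, seed=seed, extra_starts=[warm])
    stat, p = lrt(full["loglik"], red["loglik"], df=df)

    params = dict(zip(FULL_COLUMNS, full["betas"]))
    hyper = {}
    for gi, (name, _) in enumerate(FULL_GROUPS):
        hyper[f"mu_{name}"] = float(full["mus"][gi])
        hyper[f"sigma_{name}"] = float(full["sigmas"][gi])

    fit = GlmFit(
        params=params,
        hyper_params=hyper,
        alpha=full["alpha"],
        loglik_full=full["loglik"],
        loglik_reduced=red["loglik"],
        lrt_stat=stat,
        p=p,
        mu_short_gen=hyper["mu_short_gen"],
        mu_long_gen=hyper["mu_long_gen"],
        converged=full["converged"] and red["converged"],
    )

    if mode == "posterior":
        from .mcmc import HmcConfig, sample_hmc

        cfg = mcmc if mcmc is not None else HmcConfig(n_chains=4, n_iter=1000, seed=seed)

        def logp_grad(t):
            return _log_posterior_and_grad(
                t, y, design.X, design.offsets, priors, FULL_GROUPS, jacobian=True
            )

        draws = sample_hmc(logp_grad, full["theta"], cfg)
        flat = draws.reshape(-1, draws.shape[-1])
        natural = np.array(
            [_betas_from(t, FULL_GROUPS, len(FULL_COLUMNS)) for t in flat]
        )
        names = (
            [f"mu_{n}" for n, _ in FULL_GROUPS]
            + [f"log_sigma_{n}" for n, _ in FULL_GROUPS]
        )
        post = pd.DataFrame(flat[:, : 2 * len(FULL_GROUPS)], columns=names)
        post[FULL_COLUMNS] = natural
        post["log_alpha"] = flat[:, -1]
        fit.posterior = post
    elif mode != "map":
        raise ValueError(f"unknown mode {mode!r}")
    return fit


def bh_adjust(pvals, alpha: float = 0.001) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjusted q-values and significance mask."""
    pvals = np.asarray(pvals, dtype=float)
    if np.any((pvals < 0) | (pvals > 1) | ~np.isfinite(pvals)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, qvals, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    return qvals, reject


def fits_to_frame(fits: dict[str, GlmFit]) -> pd.DataFrame:
    """Tabulate per-gene fits (one row per gene) for reporting."""
    rows = []
    for gene, f in fits.items():
        row = {"gene": gene, **{k: v for k, v in f.params.items()}, **f.hyper_params,
               "alpha": f.alpha, "loglik_full": f.loglik_full,
               "loglik_reduced": f.loglik_reduced, "lrt_stat": f.lrt_stat,
               "p": f.p, "q": f.q, "converged": f.converged}
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene")


def classify_and_intersect(
    fits_F: pd.DataFrame, fits_M: pd.DataFrame, alpha: float = 0.001
) -> dict[str, set[str]]:
    """Opposite-trend significant genes per sex and their cross-sex overlap.

    Input frames need columns ``q``, ``mu_short_gen``, ``mu_long_gen``
    indexed by gene.  A gene qualifies in a sex when q < alpha and the
    group-level short-by-generation and long-by-generation means have
    opposite signs.
    """
    out = {}
    for sex, frame in (("F", fits_F), ("M", fits_M)):
        sig = frame["q"] < alpha
        opposite = frame["mu_short_gen"] * frame["mu_long_gen"] < 0
        out[sex] = set(frame.index[sig & opposite])
    out["both"] = out["F"] & out["M"]
    return out
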