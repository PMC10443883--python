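"""Latent Gaussian-process regression of count trajectories.

Single channel: counts y at generations x follow a negative binomial
with log-mean

    eta = mu0 + sigma_f * (L_c ftilde) + log(size factor),

where L_c is the Cholesky factor of the SE correlation matrix C(l),
ftilde are standard-normal latent variates (non-centered
parameterization), and the NB variance is mu + mu^2/phi.  The constant
mean mu0 is the mean of log(normalized counts + 1) for the data subset.

Two channels: the concatenated latent vector gets the block covariance
[[s1^2 C11, s12^2 C12], [s12^2 C12^T, s2^2 C22]] with the PSD
cross-correlation C12; the signal covariance is parameterized as
s12^2 = rho~ * s1 * s2 with rho~ = tanh(u) so the block matrix is valid
by construction, and the N(0, max(s)) prior on s12^2 is applied with
the transform's Jacobian.  Single-channel posterior summaries
(mean/variance of s_i^2 and l_i) propagate into the pairwise priors.

Posteriors are sampled by the in-package adaptive HMC over the fully
unconstrained parameterization; the log density and its analytic
gradient (via Cholesky differentiation in adjoint form) are evaluated
for all chains at once.  Runs are accepted when split R-hat of every
kernel/dispersion parameter lies in (0.95, 1.05), with up to two
reruns on fresh seeds otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import special

from .diagnostics import converged as _band_ok
from .diagnostics import diagnose
from .mcmc import HmcConfig, sample_hmc

JITTER = 1e-6


def default_schedule(seed: int = 0) -> HmcConfig:
    """Production schedule: 8 chains x 40,000, half warm-up, thin 40."""
    return HmcConfig(n_chains=8, n_iter=40_000, thin=40, seed=seed)


def reduced_schedule(seed: int = 0) -> HmcConfig:
    """Desk-scale schedule used by the test/calibration suites."""
    return HmcConfig(n_chains=4, n_iter=1600, thin=3, n_leapfrog=16, seed=seed)


@dataclass
class GpPriors:
    """Single-channel prior scales; ``None`` derives them from the data.

    sigma_scale: half-normal scale on sigma_f (default: data SD on the
    log(normalized+1) scale, floored at 0.5); ell_scale: half-normal
    scale on the bandwidth (default: the generation span); phi_scale:
    half-normal scale on the NB concentration phi.
    """

    sigma_scale: Optional[float] = None
    ell_scale: Optional[float] = None
    phi_scale: float = 1.0


@dataclass
class GpPosterior:
    draws: dict[str, np.ndarray]  # name -> (n_chains, n_kept)
    summary: pd.DataFrame  # mean, sd, ci2.5, ci97.5 per parameter
    diagnostics: dict[str, dict[str, float]]
    converged: bool
    n_reruns: int
    latent_mean: np.ndarray  # posterior mean of eta - offset per observation
    latent_sd: np.ndarray
    data_sd: float | tuple[float, float]

    @property
    def n_retained(self) -> int:
        first = next(iter(self.draws.values()))
        return int(first.shape[0] * first.shape[1])

    def ci(self, name: str, level: float = 0.95) -> tuple[float, float]:
        flat = self.draws[name].ravel()
        lo = 100 * (0.5 - level / 2)
        return tuple(np.percentile(flat, [lo, 100 - lo]))


def _summarize(named: dict[str, np.ndarray]) -> pd.DataFrame:
    rows = {}
    for name, d in named.items():
        flat = d.ravel()
        rows[name] = {
            "mean": flat.mean(),
            "sd": flat.std(ddof=1),
            "ci2.5": np.percentile(flat, 2.5),
            "ci97.5": np.percentile(flat, 97.5),
        }
    return pd.DataFrame(rows).T


def _nb_batched(y: np.ndarray, eta: np.ndarray, phi: np.ndarray):
    """Batched NB2 log-likelihood, d/d eta, and d/d log phi.

    ``y`` is (n,), ``eta`` is (B, n), ``phi`` is (B,).
    """
    ph = phi[:, None]
    mu = np.exp(eta)
    ll = np.sum(
        special.gammaln(y + ph)
        - special.gammaln(ph)
        - special.gammaln(y + 1.0)
        + ph * np.log(ph / (ph + mu))
        + special.xlogy(y, mu / (ph + mu)),
        axis=1,
    )
    g_eta = y - (y + ph) * mu / (ph + mu)
    dphi = np.sum(
        special.digamma(y + ph)
        - special.digamma(ph)
        + np.log(ph / (ph + mu))
        + 1.0
        - (ph + y) / (ph + mu),
        axis=1,
    )
    return ll, g_eta, phi * dphi


def _mu0(y: np.ndarray, offsets: np.ndarray) -> float:
    return float(np.mean(np.log(y / np.exp(offsets) + 1.0)))


def _data_sd(y: np.ndarray, offsets: np.ndarray) -> float:
    vals = np.log(y / np.exp(offsets) + 1.0)
    return float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0


def _batched_cholesky(mats: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Stacked Cholesky with a per-element fallback on failure."""
    try:
        return np.linalg.cholesky(mats), np.ones(mats.shape[0], dtype=bool)
    except np.linalg.LinAlgError:
        ok = np.ones(mats.shape[0], dtype=bool)
        out = np.zeros_like(mats)
        eye = np.eye(mats.shape[-1])
        for i, mat in enumerate(mats):
            try:
                out[i] = np.linalg.cholesky(mat)
            except np.linalg.LinAlgError:
                ok[i] = False
                out[i] = eye
        return out, ok


def _adjoint_q_batched(L: np.ndarray, a: np.ndarray, ftilde: np.ndarray) -> np.ndarray:
    """Adjoint matrices Q with d(g . dL f)/dtheta = sum(dK/dtheta * Q).

    For eta = L ftilde the directional derivative along a symmetric dK
    is sum_ij dK_ij Q_ij with Q = L^-T T L^-1 and T the lower-triangular
    (half-diagonal) mask of outer(a, ftilde), a = L^T g.
    """
    t = np.tril(a[:, :, None] * ftilde[:, None, :])
    idx = np.arange(t.shape[-1])
    t[:, idx, idx] *= 0.5
    lt = np.swapaxes(L, -1, -2)
    y = np.linalg.solve(lt, t)  # L^-T T
    q = np.swapaxes(np.linalg.solve(lt, np.swapaxes(y, -1, -2)), -1, -2)
    return q


# ---------------------------------------------------------------- single


def _single_logp_grad_factory(y, x, offsets, priors: GpPriors):
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    offsets = np.asarray(offsets, dtype=float)
    n = len(y)
    mu0 = _mu0(y, offsets)
    s_data = _data_sd(y, offsets)
    sigma_scale = priors.sigma_scale if priors.sigma_scale is not None else max(s_data, 0.5)
    span = float(np.ptp(x)) or 1.0
    ell_scale = priors.ell_scale if priors.ell_scale is not None else span
    phi_scale = priors.phi_scale
    # latent variates live on the unique inputs (replicate observations
    # share a generation's latent value); the model is the one with a
    # latent per observation up to the jitter scale, at a quarter of the
    # linear-algebra cost
    xu, inv = np.unique(x, return_inverse=True)
    nu = len(xu)
    d2 = (xu[:, None] - xu[None, :]) ** 2
    proj = np.zeros((n, nu))
    proj[np.arange(n), inv] = 1.0
    idx = np.arange(nu)

    def logp_grad(zs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        zs = np.atleast_2d(np.asarray(zs, dtype=float))
        ok = np.max(np.abs(zs[:, :3]), axis=1) <= 20.0
        zsafe = np.where(ok[:, None], zs, 0.0)
        sigma = np.exp(zsafe[:, 0])
        ell = np.exp(zsafe[:, 1])
        phi = np.exp(zsafe[:, 2])
        ok &= ell <= 100 * span
        ell = np.where(ok, ell, 1.0)
        ftilde = zsafe[:, 3:]

        c = np.exp(-d2[None, :, :] / (2.0 * ell[:, None, None] ** 2))
        c[:, idx, idx] += JITTER
        lc, chol_ok = _batched_cholesky(c)
        ok &= chol_ok
        lf = np.einsum("bij,bj->bi", lc, ftilde)
        eta = mu0 + sigma[:, None] * lf[:, inv] + offsets[None, :]
        ok &= np.max(eta, axis=1) <= 50.0
        eta = np.clip(eta, -50.0, 50.0)
        with np.errstate(all="ignore"):
            ll, g_eta, dll_dup = _nb_batched(y, eta, phi)
        g_eta = np.where(np.isfinite(g_eta), g_eta, 0.0)
        ok &= np.isfinite(ll)
        g_u = g_eta @ proj  # accumulate over replicate observations

        grad = np.zeros_like(zs)
        grad[:, 0] = sigma * np.sum(g_u * lf, axis=1)
        q = _adjoint_q_batched(lc, np.einsum("bij,bi->bj", lc, sigma[:, None] * g_u), ftilde)
        dc = c * (d2[None, :, :] / ell[:, None, None] ** 2)  # diag of d2 is 0
        grad[:, 1] = np.sum(dc * q, axis=(1, 2))
        grad[:, 2] = dll_dup
        grad[:, 3:] = sigma[:, None] * np.einsum("bij,bi->bj", lc, g_u)

        lp = ll
        # half-normal priors with log-scale Jacobians
        lp = lp - 0.5 * sigma ** 2 / sigma_scale ** 2 + zsafe[:, 0]
        grad[:, 0] += -(sigma ** 2) / sigma_scale ** 2 + 1.0
        lp = lp - 0.5 * ell ** 2 / ell_scale ** 2 + zsafe[:, 1]
        grad[:, 1] += -(ell ** 2) / ell_scale ** 2 + 1.0
        lp = lp - 0.5 * phi ** 2 / phi_scale ** 2 + zsafe[:, 2]
        grad[:, 2] += -(phi ** 2) / phi_scale ** 2 + 1.0
        lp = lp - 0.5 * np.sum(ftilde ** 2, axis=1)
        grad[:, 3:] += -ftilde

        lp = np.where(ok, lp, -np.inf)
        grad[~ok] = 0.0
        return lp, grad

    return logp_grad, nu, mu0, s_data


def _single_logp_grad_centered_factory(y, x, offsets, priors: GpPriors):
    """Centered variant: the latent function values f ~ N(0, K) are the
    sampled quantities.  Identical posterior to the non-centered form;
    mixes better when replicated observations pin the latent function.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    offsets = np.asarray(offsets, dtype=float)
    n = len(y)
    mu0 = _mu0(y, offsets)
    s_data = _data_sd(y, offsets)
    sigma_scale = priors.sigma_scale if priors.sigma_scale is not None else max(s_data, 0.5)
    span = float(np.ptp(x)) or 1.0
    ell_scale = priors.ell_scale if priors.ell_scale is not None else span
    phi_scale = priors.phi_scale
    xu, inv = np.unique(x, return_inverse=True)
    nu = len(xu)
    d2 = (xu[:, None] - xu[None, :]) ** 2
    proj = np.zeros((n, nu))
    proj[np.arange(n), inv] = 1.0
    idx = np.arange(nu)

    def logp_grad(zs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        zs = np.atleast_2d(np.asarray(zs, dtype=float))
        ok = np.max(np.abs(zs[:, :3]), axis=1) <= 20.0
        zsafe = np.where(ok[:, None], zs, 0.0)
        sigma2 = np.exp(2.0 * zsafe[:, 0])
        ell = np.exp(zsafe[:, 1])
        phi = np.exp(zsafe[:, 2])
        ok &= ell <= 100 * span
        ell = np.where(ok, ell, 1.0)
        f = zsafe[:, 3:]

        k = sigma2[:, None, None] * np.exp(-d2[None] / (2.0 * ell[:, None, None] ** 2))
        k[:, idx, idx] += JITTER * sigma2[:, None]
        lc, chol_ok = _batched_cholesky(k)
        ok &= chol_ok
        eta = mu0 + f[:, inv] + offsets[None, :]
        ok &= np.max(eta, axis=1) <= 50.0
        eta = np.clip(eta, -50.0, 50.0)
        with np.errstate(all="ignore"):
            ll, g_eta, dll_dup = _nb_batched(y, eta, phi)
        g_eta = np.where(np.isfinite(g_eta), g_eta, 0.0)
        ok &= np.isfinite(ll)
        g_u = g_eta @ proj

        # GP prior: -0.5 f^T K^-1 f - 0.5 logdet K
        ldiag = np.diagonal(lc, axis1=1, axis2=2)
        alpha = np.linalg.solve(np.swapaxes(lc, -1, -2),
                                np.linalg.solve(lc, f[:, :, None]))[:, :, 0]
        kinv = np.linalg.solve(np.swapaxes(lc, -1, -2),
                               np.linalg.solve(lc, np.broadcast_to(np.eye(nu), k.shape).copy()))
        quad = np.sum(f * alpha, axis=1)
        lp = ll - 0.5 * quad - np.sum(np.log(np.maximum(ldiag, 1e-300)), axis=1)

        grad = np.zeros_like(zs)
        grad[:, 3:] = g_u - alpha
        w = alpha[:, :, None] * alpha[:, None, :] - kinv
        # d/d log sigma: dK = 2K
        grad[:, 0] = 0.5 * np.sum(w * k, axis=(1, 2)) * 2.0
        dk_ell = k * (d2[None] / ell[:, None, None] ** 2)
        grad[:, 1] = 0.5 * np.sum(w * dk_ell, axis=(1, 2))
        grad[:, 2] = dll_dup

        sigma = np.exp(zsafe[:, 0])
        lp = lp - 0.5 * sigma ** 2 / sigma_scale ** 2 + zsafe[:, 0]
        grad[:, 0] += -(sigma ** 2) / sigma_scale ** 2 + 1.0
        lp = lp - 0.5 * ell ** 2 / ell_scale ** 2 + zsafe[:, 1]
        grad[:, 1] += -(ell ** 2) / ell_scale ** 2 + 1.0
        lp = lp - 0.5 * phi ** 2 / phi_scale ** 2 + zsafe[:, 2]
        grad[:, 2] += -(phi ** 2) / phi_scale ** 2 + 1.0

        lp = np.where(ok, lp, -np.inf)
        grad[~ok] = 0.0
        return lp, grad

    def init_latent():
        resid = np.log(y / np.exp(offsets) + 1.0) - mu0
        sums = resid @ proj
        counts = proj.sum(axis=0)
        return sums / counts

    def build_chol(theta):
        ok = np.max(np.abs(theta), axis=1) <= 20.0
        tsafe = np.where(ok[:, None], theta, 0.0)
        sigma2 = np.exp(2.0 * tsafe[:, 0])
        ell = np.minimum(np.exp(tsafe[:, 1]), 100 * span)
        k = sigma2[:, None, None] * np.exp(-d2[None] / (2.0 * ell[:, None, None] ** 2))
        k[:, idx, idx] += JITTER * sigma2[:, None]
        lc, chol_ok = _batched_cholesky(k)
        logdet = np.sum(np.log(np.maximum(np.diagonal(lc, axis1=1, axis2=2), 1e-300)), axis=1)
        return lc, logdet, ok & chol_ok

    return logp_grad, nu, mu0, s_data, init_latent, build_chol


def _pair_logp_grad_centered_factory(
    y1, y2, x, offsets1, offsets2, prior1: "PropagatedPrior", prior2: "PropagatedPrior",
    smax: float, phi_scale: float = 1.0, prefactor: bool = True,
):
    y1 = np.asarray(y1, float)
    y2 = np.asarray(y2, float)
    x = np.asarray(x, float)
    n = len(x)
    y = np.concatenate([y1, y2])
    offsets = np.concatenate([np.asarray(offsets1, float), np.asarray(offsets2, float)])
    mu_vec = np.concatenate([np.full(n, _mu0(y1, offsets1)), np.full(n, _mu0(y2, offsets2))])
    span = float(np.ptp(x)) or 1.0
    xu, inv = np.unique(x, return_inverse=True)
    nu = len(xu)
    d2 = (xu[:, None] - xu[None, :]) ** 2
    idx_full = np.concatenate([inv, nu + inv])
    proj = np.zeros((2 * n, 2 * nu))
    proj[np.arange(2 * n), idx_full] = 1.0
    eye = np.eye(2 * nu)

    def logp_grad(zs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        zs = np.atleast_2d(np.asarray(zs, dtype=float))
        ok = np.max(np.abs(zs[:, :6]), axis=1) <= 20.0
        zsafe = np.where(ok[:, None], zs, 0.0)
        s1, s2 = np.exp(zsafe[:, 0]), np.exp(zsafe[:, 1])
        rho = np.tanh(zsafe[:, 2])
        l1, l2 = np.exp(zsafe[:, 3]), np.exp(zsafe[:, 4])
        phi = np.exp(zsafe[:, 5])
        ok &= (l1 <= 100 * span) & (l2 <= 100 * span)
        l1 = np.where(ok, l1, 1.0)
        l2 = np.where(ok, l2, 1.0)
        f = zsafe[:, 6:]

        k, c11, c22, c12 = _pair_kernel(s1, s2, rho, l1, l2, d2, prefactor)
        lc, chol_ok = _batched_cholesky(k)
        ok &= chol_ok
        eta = mu_vec[None, :] + f[:, idx_full] + offsets[None, :]
        ok &= np.max(eta, axis=1) <= 50.0
        eta = np.clip(eta, -50.0, 50.0)
        with np.errstate(all="ignore"):
            ll, g_eta, dll_dup = _nb_batched(y, eta, phi)
        g_eta = np.where(np.isfinite(g_eta), g_eta, 0.0)
        ok &= np.isfinite(ll)
        g_u = g_eta @ proj

        ldiag = np.diagonal(lc, axis1=1, axis2=2)
        alpha = np.linalg.solve(np.swapaxes(lc, -1, -2),
                                np.linalg.solve(lc, f[:, :, None]))[:, :, 0]
        kinv = np.linalg.solve(np.swapaxes(lc, -1, -2),
                               np.linalg.solve(lc, np.broadcast_to(eye, k.shape).copy()))
        lp = ll - 0.5 * np.sum(f * alpha, axis=1) \
            - np.sum(np.log(np.maximum(ldiag, 1e-300)), axis=1)

        grad = np.zeros_like(zs)
        grad[:, 6:] = g_u - alpha
        w = alpha[:, :, None] * alpha[:, None, :] - kinv
        w11, w22 = w[:, :nu, :nu], w[:, nu:, nu:]
        w12 = w[:, :nu, nu:] + np.swapaxes(w[:, nu:, :nu], -1, -2)
        s12 = rho * s1 * s2
        sum11 = np.sum(c11 * w11, axis=(1, 2))
        sum22 = np.sum(c22 * w22, axis=(1, 2))
        sum12 = np.sum(c12 * w12, axis=(1, 2))
        tr_w = np.trace(w, axis1=1, axis2=2)
        grad[:, 0] = 0.5 * (2 * s1 ** 2 * sum11 + s12 * sum12 + JITTER * s1 ** 2 * tr_w)
        grad[:, 1] = 0.5 * (2 * s2 ** 2 * sum22 + s12 * sum12 + JITTER * s2 ** 2 * tr_w)
        ds12_dur = s1 * s2 * (1 - rho ** 2)
        grad[:, 2] = 0.5 * ds12_dur * sum12
        ssum = l1 ** 2 + l2 ** 2
        dc11 = c11 * (d2[None] / l1[:, None, None] ** 2)
        pref1 = (0.5 * (1 - 2 * l1 ** 2 / ssum))[:, None, None] if prefactor else 0.0
        dc12_l1 = c12 * (pref1 + d2[None] * (2 * l1 ** 2 / ssum ** 2)[:, None, None])
        grad[:, 3] = 0.5 * (s1 ** 2 * np.sum(dc11 * w11, axis=(1, 2))
                            + s12 * np.sum(dc12_l1 * w12, axis=(1, 2)))
        dc22 = c22 * (d2[None] / l2[:, None, None] ** 2)
        pref2 = (0.5 * (1 - 2 * l2 ** 2 / ssum))[:, None, None] if prefactor else 0.0
        dc12_l2 = c12 * (pref2 + d2[None] * (2 * l2 ** 2 / ssum ** 2)[:, None, None])
        grad[:, 4] = 0.5 * (s2 ** 2 * np.sum(dc22 * w22, axis=(1, 2))
                            + s12 * np.sum(dc12_l2 * w12, axis=(1, 2)))
        grad[:, 5] = dll_dup

        # priors on kernel/dispersion parameters (as in the NC variant)
        lp = lp - 0.5 * (s1 ** 2 - prior1.sigma2_hat) ** 2 / prior1.v_sigma
        grad[:, 0] += -(s1 ** 2 - prior1.sigma2_hat) / prior1.v_sigma * 2 * s1 ** 2
        lp = lp - 0.5 * (s2 ** 2 - prior2.sigma2_hat) ** 2 / prior2.v_sigma
        grad[:, 1] += -(s2 ** 2 - prior2.sigma2_hat) / prior2.v_sigma * 2 * s2 ** 2
        lp = lp - 0.5 * (l1 - prior1.ell_hat) ** 2 / prior1.v_ell
        grad[:, 3] += -(l1 - prior1.ell_hat) / prior1.v_ell * l1
        lp = lp - 0.5 * (l2 - prior2.ell_hat) ** 2 / prior2.v_ell
        grad[:, 4] += -(l2 - prior2.ell_hat) / prior2.v_ell * l2
        lp = lp - 0.5 * s12 ** 2 / smax ** 2
        grad[:, 0] += -(s12 / smax ** 2) * s12
        grad[:, 1] += -(s12 / smax ** 2) * s12
        grad[:, 2] += -(s12 / smax ** 2) * ds12_dur
        lp = lp - 0.5 * phi ** 2 / phi_scale ** 2
        grad[:, 5] += -(phi ** 2) / phi_scale ** 2
        lp = lp + np.log(2 * s1 ** 2) + np.log(2 * s2 ** 2)
        grad[:, 0] += 2.0
        grad[:, 1] += 2.0
        lp = lp + np.log(s1) + np.log(s2) + np.log1p(-rho ** 2)
        grad[:, 0] += 1.0
        grad[:, 1] += 1.0
        grad[:, 2] += -2.0 * rho
        lp = lp + zsafe[:, 3] + zsafe[:, 4] + zsafe[:, 5]
        grad[:, 3] += 1.0
        grad[:, 4] += 1.0
        grad[:, 5] += 1.0

        lp = np.where(ok, lp, -np.inf)
        grad[~ok] = 0.0
        return lp, grad

    def init_latent():
        r1 = np.log(y1 / np.exp(np.asarray(offsets1, float)) + 1.0) - mu_vec[0]
        r2 = np.log(y2 / np.exp(np.asarray(offsets2, float)) + 1.0) - mu_vec[n]
        p = proj[:n, :nu]
        counts = p.sum(axis=0)
        return np.concatenate([(r1 @ p) / counts, (r2 @ p) / counts])

    def build_chol(theta):
        ok = np.max(np.abs(theta), axis=1) <= 20.0
        tsafe = np.where(ok[:, None], theta, 0.0)
        s1, s2 = np.exp(tsafe[:, 0]), np.exp(tsafe[:, 1])
        rho = np.tanh(tsafe[:, 2])
        l1 = np.minimum(np.exp(tsafe[:, 3]), 100 * span)
        l2 = np.minimum(np.exp(tsafe[:, 4]), 100 * span)
        k, _, _, _ = _pair_kernel(s1, s2, rho, l1, l2, d2, prefactor)
        lc, chol_ok = _batched_cholesky(k)
        logdet = np.sum(np.log(np.maximum(np.diagonal(lc, axis1=1, axis2=2), 1e-300)), axis=1)
        return lc, logdet, ok & chol_ok

    return logp_grad, mu_vec, init_latent, build_chol


def _make_interleaver(logp_grad, build_chol, n_head: int):
    """Non-centered hyperparameter move interwoven with centered HMC.

    With the latent function held fixed in its whitened coordinates
    (f~ = L^-1 f), a random-walk proposal on the unconstrained
    hyperparameters drags the latents along the prior-implied
    direction — the move the centered dynamics cannot make.  The
    acceptance ratio in whitened coordinates is the centered log
    density plus log|L| (the whitening Jacobian).  The proposal scale
    adapts toward ~30% acceptance during warm-up.
    """
    state = {"step": None}

    def interleave(q, lp, grad, in_warmup, rng):
        m, dim = q.shape
        if state["step"] is None:
            state["step"] = np.full(m, 0.1)
        step = state["step"]
        theta = q[:, :n_head]
        f = q[:, n_head:]
        lc, logdet, ok0 = build_chol(theta)
        ftilde = np.linalg.solve(lc, f[:, :, None])[:, :, 0]
        theta_new = theta + step[:, None] * rng.standard_normal((m, n_head))
        lc_new, logdet_new, ok1 = build_chol(theta_new)
        f_new = np.einsum("bij,bj->bi", lc_new, ftilde)
        q_new = np.concatenate([theta_new, f_new], axis=1)
        lp_new, grad_new = logp_grad(q_new)
        with np.errstate(invalid="ignore"):
            log_alpha = (lp_new + logdet_new) - (lp + logdet)
            log_alpha = np.where(ok0 & ok1 & np.isfinite(log_alpha), log_alpha, -np.inf)
        accept = rng.random(m) < np.exp(np.minimum(0.0, log_alpha))
        q[accept] = q_new[accept]
        lp[accept] = lp_new[accept]
        grad[accept] = grad_new[accept]
        if in_warmup:
            rate = np.exp(np.minimum(0.0, log_alpha))
            state["step"] = np.clip(step * np.exp(0.1 * (rate - 0.3)), 1e-4, 2.0)
        return q, lp, grad

    return interleave


def _run_with_reruns(logp_grad, init, mcmc: HmcConfig, names_of_interest, extract,
                     max_reruns=2, interleave=None):
    n_reruns = 0
    cfg = mcmc
    while True:
        draws = sample_hmc(logp_grad, init, cfg, batched=True, interleave=interleave)
        named = extract(draws)
        diag = diagnose({k: named[k] for k in names_of_interest})
        if _band_ok(diag) or n_reruns >= max_reruns:
            return draws, named, diag, _band_ok(diag), n_reruns
        n_reruns += 1
        cfg = HmcConfig(**{**cfg.__dict__, "seed": cfg.seed + 7919 * n_reruns})


def fit_single_channel(
    y,
    x,
    offsets=None,
    priors: GpPriors | None = None,
    mcmc: HmcConfig | None = None,
    max_reruns: int = 2,
    parameterization: str = "centered",
    interleave: bool = True,
) -> GpPosterior:
    """Posterior over (sigma_f^2, ell, phi, latent f) for one gene.

    ``parameterization`` selects how the latent function is sampled:
    'centered' (function values; default, mixes well with replicated
    observations) or 'noncentered' (whitened standard-normal variates).
    Both target the same posterior.
    """
    y = np.asarray(y, dtype=float)
    if np.any(y < 0):
        raise ValueError("counts must be non-negative")
    x = np.asarray(x, dtype=float)
    offsets = np.zeros_like(x) if offsets is None else np.asarray(offsets, dtype=float)
    priors = priors or GpPriors()
    mcmc = mcmc or default_schedule()

    head = [np.log(max(np.sqrt(1.0), 0.3)), np.log(max(np.ptp(x) / 3.0, 1.0)), 0.0]
    interleaver = None
    if parameterization == "centered":
        logp_grad, nu, mu0, s_data, init_latent, build_chol = _single_logp_grad_centered_factory(
            y, x, offsets, priors
        )
        head[0] = np.log(max(s_data, 0.3))
        init = np.concatenate([head, init_latent()])
        if interleave:
            interleaver = _make_interleaver(logp_grad, build_chol, 3)
    elif parameterization == "noncentered":
        logp_grad, nu, mu0, s_data = _single_logp_grad_factory(y, x, offsets, priors)
        head[0] = np.log(max(s_data, 0.3))
        init = np.concatenate([head, np.zeros(nu)])
    else:
        raise ValueError(f"unknown parameterization {parameterization!r}")

    def extract(draws):
        return {
            "sigma2": np.exp(2.0 * draws[:, :, 0]),
            "ell": np.exp(draws[:, :, 1]),
            "phi": np.exp(draws[:, :, 2]),
        }

    draws, named, diag, ok, n_reruns = _run_with_reruns(
        logp_grad, init, mcmc, ["sigma2", "ell", "phi"], extract, max_reruns,
        interleave=interleaver,
    )

    # posterior latent trajectory (eta - offset) per observation
    flat = draws.reshape(-1, draws.shape[-1])
    sub = flat[:: max(1, len(flat) // 400)]
    xu, inv = np.unique(x, return_inverse=True)
    if parameterization == "centered":
        etas = mu0 + sub[:, 3:][:, inv]
    else:
        d2 = (xu[:, None] - xu[None, :]) ** 2
        idx = np.arange(len(xu))
        c = np.exp(-d2[None] / (2 * np.exp(sub[:, 1])[:, None, None] ** 2))
        c[:, idx, idx] += JITTER
        lc, _ = _batched_cholesky(c)
        etas = mu0 + np.exp(sub[:, 0])[:, None] * np.einsum("bij,bj->bi", lc, sub[:, 3:])[:, inv]

    return GpPosterior(
        draws=named,
        summary=_summarize(named),
        diagnostics=diag,
        converged=ok,
        n_reruns=n_reruns,
        latent_mean=etas.mean(axis=0),
        latent_sd=etas.std(axis=0, ddof=1),
        data_sd=s_data,
    )


# ------------------------------------------------------------------ pair


@dataclass
class PropagatedPrior:
    """Moments carried from a single-channel fit into the pair model."""

    sigma2_hat: float
    v_sigma: float
    ell_hat: float
    v_ell: float

    @classmethod
    def from_posterior(cls, post: GpPosterior, floor: float = 1e-3) -> "PropagatedPrior":
        s = post.summary
        return cls(
            sigma2_hat=float(s.loc["sigma2", "mean"]),
            v_sigma=max(float(s.loc["sigma2", "sd"]) ** 2, floor),
            ell_hat=float(s.loc["ell", "mean"]),
            v_ell=max(float(s.loc["ell", "sd"]) ** 2, floor),
        )


def _pair_kernel(s1, s2, rho, l1, l2, d2, prefactor):
    """Batched block covariance; returns (K, C11, C22, C12)."""
    b, n = s1.shape[0], d2.shape[0]
    ssum = l1 ** 2 + l2 ** 2
    c11 = np.exp(-d2[None] / (2 * l1[:, None, None] ** 2))
    c22 = np.exp(-d2[None] / (2 * l2[:, None, None] ** 2))
    c12 = np.exp(-d2[None] / ssum[:, None, None])
    if prefactor:
        c12 = np.sqrt(2 * l1 * l2 / ssum)[:, None, None] * c12
    s12 = rho * s1 * s2
    k = np.empty((b, 2 * n, 2 * n))
    k[:, :n, :n] = s1[:, None, None] ** 2 * c11
    k[:, n:, n:] = s2[:, None, None] ** 2 * c22
    k[:, :n, n:] = s12[:, None, None] * c12
    k[:, n:, :n] = np.swapaxes(k[:, :n, n:], -1, -2)
    idx = np.arange(2 * n)
    k[:, idx, idx] += JITTER * 0.5 * (s1 ** 2 + s2 ** 2)[:, None]
    return k, c11, c22, c12


def _pair_logp_grad_factory(
    y1, y2, x, offsets1, offsets2, prior1: PropagatedPrior, prior2: PropagatedPrior,
    smax: float, phi_scale: float = 1.0, prefactor: bool = True,
):
    y1 = np.asarray(y1, float)
    y2 = np.asarray(y2, float)
    x = np.asarray(x, float)
    n = len(x)
    y = np.concatenate([y1, y2])
    offsets = np.concatenate([np.asarray(offsets1, float), np.asarray(offsets2, float)])
    mu_vec = np.concatenate([np.full(n, _mu0(y1, offsets1)), np.full(n, _mu0(y2, offsets2))])
    span = float(np.ptp(x)) or 1.0
    # latents on unique inputs, shared by replicate observations
    xu, inv = np.unique(x, return_inverse=True)
    nu = len(xu)
    d2 = (xu[:, None] - xu[None, :]) ** 2
    idx_full = np.concatenate([inv, nu + inv])
    proj = np.zeros((2 * n, 2 * nu))
    proj[np.arange(2 * n), idx_full] = 1.0

    def logp_grad(zs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        zs = np.atleast_2d(np.asarray(zs, dtype=float))
        ok = np.max(np.abs(zs[:, :6]), axis=1) <= 20.0
        zsafe = np.where(ok[:, None], zs, 0.0)
        s1, s2 = np.exp(zsafe[:, 0]), np.exp(zsafe[:, 1])
        rho = np.tanh(zsafe[:, 2])
        l1, l2 = np.exp(zsafe[:, 3]), np.exp(zsafe[:, 4])
        phi = np.exp(zsafe[:, 5])
        ok &= (l1 <= 100 * span) & (l2 <= 100 * span)
        l1 = np.where(ok, l1, 1.0)
        l2 = np.where(ok, l2, 1.0)
        ftilde = zsafe[:, 6:]

        k, c11, c22, c12 = _pair_kernel(s1, s2, rho, l1, l2, d2, prefactor)
        lc, chol_ok = _batched_cholesky(k)
        ok &= chol_ok
        lf = np.einsum("bij,bj->bi", lc, ftilde)
        eta = mu_vec[None, :] + lf[:, idx_full] + offsets[None, :]
        ok &= np.max(eta, axis=1) <= 50.0
        eta = np.clip(eta, -50.0, 50.0)
        with np.errstate(all="ignore"):
            ll, g_eta, dll_dup = _nb_batched(y, eta, phi)
        g_eta = np.where(np.isfinite(g_eta), g_eta, 0.0)
        ok &= np.isfinite(ll)
        g_u = g_eta @ proj

        grad = np.zeros_like(zs)
        q = _adjoint_q_batched(lc, np.einsum("bij,bi->bj", lc, g_u), ftilde)
        q11, q22 = q[:, :nu, :nu], q[:, nu:, nu:]
        q12 = q[:, :nu, nu:] + np.swapaxes(q[:, nu:, :nu], -1, -2)
        s12 = rho * s1 * s2
        sum11 = np.sum(c11 * q11, axis=(1, 2))
        sum22 = np.sum(c22 * q22, axis=(1, 2))
        sum12 = np.sum(c12 * q12, axis=(1, 2))
        tr_q = np.trace(q, axis1=1, axis2=2)
        # jitter tracks the mean diagonal (s1^2 + s2^2)/2
        grad[:, 0] = 2 * s1 ** 2 * sum11 + s12 * sum12 + JITTER * s1 ** 2 * tr_q
        grad[:, 1] = 2 * s2 ** 2 * sum22 + s12 * sum12 + JITTER * s2 ** 2 * tr_q
        ds12_dur = s1 * s2 * (1 - rho ** 2)
        grad[:, 2] = ds12_dur * sum12
        ssum = l1 ** 2 + l2 ** 2
        dc11 = c11 * (d2[None] / l1[:, None, None] ** 2)
        pref1 = (0.5 * (1 - 2 * l1 ** 2 / ssum))[:, None, None] if prefactor else 0.0
        dc12_l1 = c12 * (pref1 + d2[None] * (2 * l1 ** 2 / ssum ** 2)[:, None, None])
        grad[:, 3] = s1 ** 2 * np.sum(dc11 * q11, axis=(1, 2)) + s12 * np.sum(dc12_l1 * q12, axis=(1, 2))
        dc22 = c22 * (d2[None] / l2[:, None, None] ** 2)
        pref2 = (0.5 * (1 - 2 * l2 ** 2 / ssum))[:, None, None] if prefactor else 0.0
        dc12_l2 = c12 * (pref2 + d2[None] * (2 * l2 ** 2 / ssum ** 2)[:, None, None])
        grad[:, 4] = s2 ** 2 * np.sum(dc22 * q22, axis=(1, 2)) + s12 * np.sum(dc12_l2 * q12, axis=(1, 2))
        grad[:, 5] = dll_dup
        grad[:, 6:] = np.einsum("bij,bi->bj", lc, g_u)

        lp = ll
        # propagated priors on signal variances (on sigma^2) and bandwidths
        lp = lp - 0.5 * (s1 ** 2 - prior1.sigma2_hat) ** 2 / prior1.v_sigma
        grad[:, 0] += -(s1 ** 2 - prior1.sigma2_hat) / prior1.v_sigma * 2 * s1 ** 2
        lp = lp - 0.5 * (s2 ** 2 - prior2.sigma2_hat) ** 2 / prior2.v_sigma
        grad[:, 1] += -(s2 ** 2 - prior2.sigma2_hat) / prior2.v_sigma * 2 * s2 ** 2
        lp = lp - 0.5 * (l1 - prior1.ell_hat) ** 2 / prior1.v_ell
        grad[:, 3] += -(l1 - prior1.ell_hat) / prior1.v_ell * l1
        lp = lp - 0.5 * (l2 - prior2.ell_hat) ** 2 / prior2.v_ell
        grad[:, 4] += -(l2 - prior2.ell_hat) / prior2.v_ell * l2
        # signal covariance prior N(0, max(s)) on sigma_12^2
        lp = lp - 0.5 * s12 ** 2 / smax ** 2
        grad[:, 0] += -(s12 / smax ** 2) * s12
        grad[:, 1] += -(s12 / smax ** 2) * s12
        grad[:, 2] += -(s12 / smax ** 2) * ds12_dur
        # phi half-normal
        lp = lp - 0.5 * phi ** 2 / phi_scale ** 2
        grad[:, 5] += -(phi ** 2) / phi_scale ** 2
        # Jacobian of the (u1,u2,ur,ul1,ul2,up) transform
        lp = lp + np.log(2 * s1 ** 2) + np.log(2 * s2 ** 2)
        grad[:, 0] += 2.0
        grad[:, 1] += 2.0
        lp = lp + np.log(s1) + np.log(s2) + np.log1p(-rho ** 2)
        grad[:, 0] += 1.0
        grad[:, 1] += 1.0
        grad[:, 2] += -2.0 * rho
        lp = lp + zsafe[:, 3] + zsafe[:, 4] + zsafe[:, 5]
        grad[:, 3] += 1.0
        grad[:, 4] += 1.0
        grad[:, 5] += 1.0
        lp = lp - 0.5 * np.sum(ftilde ** 2, axis=1)
        grad[:, 6:] += -ftilde

        lp = np.where(ok, lp, -np.inf)
        grad[~ok] = 0.0
        return lp, grad

    return logp_grad, mu_vec


def fit_pair(
    y_i,
    y_j,
    x,
    offsets_i=None,
    offsets_j=None,
    single_fit_i: GpPosterior | PropagatedPrior | None = None,
    single_fit_j: GpPosterior | PropagatedPrior | None = None,
    mcmc: HmcConfig | None = None,
    phi_scale: float = 1.0,
    prefactor: bool = True,
    max_reruns: int = 2,
    parameterization: str = "centered",
    interleave: bool = False,
) -> GpPosterior:
    """Joint posterior over the two-channel GP parameters of a gene pair.

    ``single_fit_i``/``single_fit_j`` supply the propagated priors on
    each channel's signal variance and bandwidth (required).
    """
    if single_fit_i is None or single_fit_j is None:
        raise ValueError("single-channel summaries are required for the pairwise priors")
    x = np.asarray(x, dtype=float)
    n = len(x)
    y_i = np.asarray(y_i, float)
    y_j = np.asarray(y_j, float)
    offsets_i = np.zeros(n) if offsets_i is None else np.asarray(offsets_i, float)
    offsets_j = np.zeros(n) if offsets_j is None else np.asarray(offsets_j, float)
    mcmc = mcmc or default_schedule()

    def as_prior(f):
        return f if isinstance(f, PropagatedPrior) else PropagatedPrior.from_posterior(f)

    p1, p2 = as_prior(single_fit_i), as_prior(single_fit_j)
    s_1, s_2 = _data_sd(y_i, offsets_i), _data_sd(y_j, offsets_j)
    smax = max(s_1, s_2, 0.25)

    head = [0.5 * np.log(max(p1.sigma2_hat, 1e-2)), 0.5 * np.log(max(p2.sigma2_hat, 1e-2)),
            0.0, np.log(max(p1.ell_hat, 0.5)), np.log(max(p2.ell_hat, 0.5)), 0.0]
    nu = len(np.unique(x))
    interleaver = None
    if parameterization == "centered":
        logp_grad, mu_vec, init_latent, build_chol = _pair_logp_grad_centered_factory(
            y_i, y_j, x, offsets_i, offsets_j, p1, p2, smax, phi_scale, prefactor
        )
        init = np.concatenate([head, init_latent()])
        if interleave:
            interleaver = _make_interleaver(logp_grad, build_chol, 6)
    elif parameterization == "noncentered":
        logp_grad, mu_vec = _pair_logp_grad_factory(
            y_i, y_j, x, offsets_i, offsets_j, p1, p2, smax, phi_scale, prefactor
        )
        init = np.concatenate([head, np.zeros(2 * nu)])
    else:
        raise ValueError(f"unknown parameterization {parameterization!r}")

    def extract(draws):
        s1 = np.exp(draws[:, :, 0])
        s2 = np.exp(draws[:, :, 1])
        rho = np.tanh(draws[:, :, 2])
        return {
            "sigma2_i": s1 ** 2,
            "sigma2_j": s2 ** 2,
            "sigma2_ij": rho * s1 * s2,
            "rho": rho,
            "ell_i": np.exp(draws[:, :, 3]),
            "ell_j": np.exp(draws[:, :, 4]),
            "phi": np.exp(draws[:, :, 5]),
        }

    check = ["sigma2_i", "sigma2_j", "sigma2_ij", "ell_i", "ell_j", "phi"]
    draws, named, diag, ok, n_reruns = _run_with_reruns(
        logp_grad, init, mcmc, check, extract, max_reruns, interleave=interleaver,
    )

    # latent trajectories from a subsample of retained draws
    flat = draws.reshape(-1, draws.shape[-1])
    sub = flat[:: max(1, len(flat) // 400)]
    xu, inv = np.unique(x, return_inverse=True)
    idx_full = np.concatenate([inv, len(xu) + inv])
    if parameterization == "centered":
        etas = mu_vec[None, :] + sub[:, 6:][:, idx_full]
    else:
        k, _, _, _ = _pair_kernel(
            np.exp(sub[:, 0]), np.exp(sub[:, 1]), np.tanh(sub[:, 2]),
            np.exp(sub[:, 3]), np.exp(sub[:, 4]), (xu[:, None] - xu[None, :]) ** 2, prefactor,
        )
        lc, _ = _batched_cholesky(k)
        etas = mu_vec[None, :] + np.einsum("bij,bj->bi", lc, sub[:, 6:])[:, idx_full]

    return GpPosterior(
        draws=named,
        summary=_summarize(named),
        diagnostics=diag,
        converged=ok,
        n_reruns=n_reruns,
        latent_mean=etas.mean(axis=0),
        latent_sd=etas.std(axis=0, ddof=1),
        data_sd=(s_1, s_2),
    )
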