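"""Adaptive Hamiltonian Monte Carlo over unconstrained parameters.

A compact gradient-based sampler used for the GP (and optionally GLM)
posteriors: leapfrog dynamics with a jittered number of steps, dual-
averaging step-size adaptation toward a target acceptance rate, and a
per-chain diagonal mass matrix re-estimated halfway through warm-up.
Chains are propagated simultaneously: the target density is supplied as
a batched callable mapping (n_chains, dim) points to (n_chains,) log
densities and (n_chains, dim) gradients, which keeps the per-iteration
numpy overhead shared across chains.  Single-point callables are
adapted with :func:`batchify`.  All parameters are assumed
unconstrained (use log / atanh transforms with Jacobians in the
caller).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

BatchedLogpGrad = Callable[[np.ndarray], tuple[np.ndarray, np.ndarray]]


@dataclass
class HmcConfig:
    n_chains: int = 4
    n_iter: int = 2000  # total iterations per chain, warm-up included
    warmup: int | None = None  # default: half of n_iter
    thin: int = 1
    n_leapfrog: int = 12  # upper bound; actual count jittered in [L/2, L]
    target_accept: float = 0.8
    init_scale: float = 0.1  # SD of the random jitter around the init point
    seed: int = 0

    @property
    def n_warmup(self) -> int:
        return self.n_iter // 2 if self.warmup is None else self.warmup

    @property
    def n_kept_per_chain(self) -> int:
        return max(0, (self.n_iter - self.n_warmup + self.thin - 1) // self.thin)


def batchify(logp_grad) -> BatchedLogpGrad:
    """Lift a single-point (dim,) -> (lp, grad) callable to batches."""

    def batched(qs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        lps = np.empty(qs.shape[0])
        grads = np.empty_like(qs)
        for i, q in enumerate(qs):
            lps[i], grads[i] = logp_grad(q)
        return lps, grads

    return batched


def sample_hmc(
    logp_grad,
    init: np.ndarray,
    config: HmcConfig,
    batched: bool | None = None,
    interleave=None,
) -> np.ndarray:
    """Run HMC chains; returns draws of shape (n_chains, n_kept, dim).

    ``logp_grad`` may be single-point or batched; pass ``batched`` to
    override the auto-detection (a trial call on a 2-D array).

    ``interleave``, if given, is called after every HMC iteration as
    ``q, lp, grad = interleave(q, lp, grad, in_warmup, rng)`` and may
    apply an extra posterior-invariant update (e.g. a reparameterized
    hyperparameter move interwoven with the HMC dynamics).
    """
    init = np.asarray(init, dtype=float)
    dim = init.size
    cfg = config
    if batched is None:
        try:
            lps, _ = logp_grad(np.tile(init, (2, 1)))
            batched = np.shape(lps) == (2,)
        except Exception:
            batched = False
    f = logp_grad if batched else batchify(logp_grad)

    m = cfg.n_chains
    warmup = cfg.n_warmup
    rng = np.random.default_rng(cfg.seed)
    draws = np.empty((m, cfg.n_kept_per_chain, dim))

    q = init[None, :] + cfg.init_scale * rng.standard_normal((m, dim))
    lp, grad = f(q)
    for _ in range(100):
        bad = ~np.isfinite(lp)
        if not bad.any():
            break
        q[bad] = init[None, :] + cfg.init_scale * rng.standard_normal((int(bad.sum()), dim))
        lp, grad = f(q)
    if not np.all(np.isfinite(lp)):
        raise RuntimeError("could not find finite-density starting points")

    inv_mass = np.ones((m, dim))
    sqrt_mass = np.ones((m, dim))
    eps = np.full(m, 0.2 * dim ** -0.25)
    # dual averaging state (per chain)
    mu_da = np.log(10.0 * eps)
    log_eps_bar = np.zeros(m)
    h_bar = np.zeros(m)
    gamma, t0, kappa = 0.05, 10.0, 0.75
    da_count = 0
    mass_updates = {warmup // 3, (2 * warmup) // 3}
    history: list[np.ndarray] = []
    kept = 0

    for it in range(cfg.n_iter):
        n_leap = int(rng.integers(max(1, cfg.n_leapfrog // 2), cfg.n_leapfrog + 1))
        p = rng.standard_normal((m, dim)) * sqrt_mass
        h0 = -lp + 0.5 * np.sum(p ** 2 * inv_mass, axis=1)
        q_new, lp_new, grad_new = q.copy(), lp.copy(), grad.copy()
        p_new = p + 0.5 * eps[:, None] * grad_new
        alive = np.isfinite(lp_new)
        for step in range(n_leap):
            q_new = q_new + eps[:, None] * inv_mass * p_new
            lp_new, grad_new = f(q_new)
            alive &= np.isfinite(lp_new)
            grad_safe = np.where(np.isfinite(grad_new), grad_new, 0.0)
            p_new = p_new + (0.5 if step == n_leap - 1 else 1.0) * eps[:, None] * grad_safe
        with np.errstate(invalid="ignore", over="ignore"):
            h1 = -lp_new + 0.5 * np.sum(p_new ** 2 * inv_mass, axis=1)
            delta = np.where(alive & np.isfinite(h1), h0 - h1, -np.inf)
            accept_prob = np.exp(np.minimum(0.0, delta))
        take = rng.random(m) < accept_prob
        q[take] = q_new[take]
        lp[take] = lp_new[take]
        grad[take] = grad_new[take]

        if interleave is not None:
            q, lp, grad = interleave(q, lp, grad, it < warmup, rng)

        if it < warmup:
            da_count += 1
            frac = 1.0 / (da_count + t0)
            h_bar = (1 - frac) * h_bar + frac * (cfg.target_accept - accept_prob)
            log_eps = mu_da - np.sqrt(da_count) / gamma * h_bar
            w = da_count ** -kappa
            log_eps_bar = w * log_eps + (1 - w) * log_eps_bar
            eps = np.exp(log_eps)
            history.append(q.copy())
            if it + 1 in mass_updates and len(history) > 10:
                window = np.asarray(history[len(history) // 2:])  # (t, m, dim)
                var = window.var(axis=0, ddof=1)
                n_w = window.shape[0]
                # shrink lightly toward a small floor (not unit scale, which
                # would swamp the typical 1e-2..1e-1 posterior variances)
                var = n_w / (n_w + 5.0) * var + 5.0 / (n_w + 5.0) * 1e-3
                inv_mass = var
                sqrt_mass = 1.0 / np.sqrt(var)
                # restart step-size adaptation around the current value
                mu_da = np.log(10.0) + np.log(eps)
                log_eps_bar = np.log(eps)
                h_bar = np.zeros(m)
                da_count = 0
                history.clear()
            if it + 1 == warmup:
                eps = np.exp(log_eps_bar)
        else:
            if (it - warmup) % cfg.thin == 0:
                draws[:, kept] = q
                kept += 1
    assert kept == cfg.n_kept_per_chain
    return draws
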