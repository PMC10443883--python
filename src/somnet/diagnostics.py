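"""Split-chain R-hat and effective sample size.

Classic formulations: chains are split in half, the potential scale
reduction factor is sqrt(((n-1)/n W + B/n) / W), and ESS uses the
FFT-based autocorrelation combined across split chains with Geyer's
initial monotone positive-pair truncation.  Runs are accepted when
0.95 < R-hat < 1.05 for every parameter.
"""

from __future__ import annotations

import numpy as np

RHAT_BAND = (0.95, 1.05)


def _split(chains: np.ndarray) -> np.ndarray:
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2:
        raise ValueError("expected array of shape (n_chains, n_draws)")
    m, n = chains.shape
    if m < 2:
        raise ValueError("R-hat requires at least 2 chains")
    half = n // 2
    return np.concatenate([chains[:, :half], chains[:, half: 2 * half]], axis=0)


def split_rhat(chains: np.ndarray) -> float:
    """Potential scale reduction factor over split chains."""
    x = _split(chains)
    m, n = x.shape
    if n < 2:
        raise ValueError("need at least 2 draws per split chain")
    chain_means = x.mean(axis=1)
    w = x.var(axis=1, ddof=1).mean()
    b = n * chain_means.var(ddof=1)
    if w == 0:
        return 1.0  # constant chains: no between- or within-chain variance
    var_hat = (n - 1) / n * w + b / n
    return float(np.sqrt(var_hat / w))


def _autocovariance(x: np.ndarray) -> np.ndarray:
    n = len(x)
    xc = x - x.mean()
    size = 2 ** int(np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(xc, size)
    acov = np.fft.irfft(f * np.conjugate(f))[:n].real / n
    return acov


def ess(chains: np.ndarray) -> float:
    """Effective sample size over split chains (Geyer truncation)."""
    x = _split(chains)
    m, n = x.shape
    acov = np.asarray([_autocovariance(row) for row in x])
    chain_var = acov[:, 0] * n / (n - 1)
    w = chain_var.mean()
    var_hat = (n - 1) / n * w + n * x.mean(axis=1).var(ddof=1) / n
    if var_hat == 0:
        return float(m * n)
    rho = 1.0 - (w - acov.mean(axis=0)) / var_hat
    # Geyer: sum pairs while they stay positive, enforce monotone decrease
    tau = 1.0
    prev_pair = np.inf
    t = 1
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair < 0:
            break
        pair = min(pair, prev_pair)
        tau += 2.0 * pair
        prev_pair = pair
        t += 2
    return float(m * n / tau)


def diagnose(chains_by_param: dict[str, np.ndarray]) -> dict[str, dict[str, float]]:
    """R-hat and ESS per parameter plus an overall acceptance verdict."""
    out = {}
    for name, chains in chains_by_param.items():
        out[name] = {"rhat": split_rhat(chains), "ess": ess(chains)}
    return out


def converged(diag: dict[str, dict[str, float]], band=RHAT_BAND) -> bool:
    return all(band[0] < v["rhat"] < band[1] for v in diag.values())
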