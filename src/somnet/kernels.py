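"""Squared-exponential and cross-channel covariance functions.

Single channel: k(x, x') = sigma_f^2 * exp(-(x - x')^2 / (2 l^2)).

Two channels with bandwidths l1, l2 are coupled through the cross-
correlation

    c12(x1, x2) = sqrt(2 l1 l2 / (l1^2 + l2^2))
                  * exp(-(x1 - x2)^2 / (l1^2 + l2^2)),

the standard multi-task SE construction; the prefactor guarantees that
the assembled two-channel matrix is positive semi-definite whenever
|sigma12^2| <= sigma1 * sigma2.  A literal prefactor-free variant is
available behind a flag for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def _check_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not value > 0:
            raise ValueError(f"{name} must be positive, got {value!r}")


def se_kernel_matrix(x: np.ndarray, sigma2: float, ell: float) -> np.ndarray:
    """SE covariance matrix K_ab = sigma2 * exp(-(x_a - x_b)^2 / (2 ell^2))."""
    _check_positive(sigma2=sigma2, ell=ell)
    x = np.asarray(x, dtype=float)
    d = x[:, None] - x[None, :]
    return sigma2 * np.exp(-(d ** 2) / (2.0 * ell ** 2))


def cross_correlation_matrix(
    x1: np.ndarray,
    x2: np.ndarray,
    ell1: float,
    ell2: float,
    prefactor: bool = True,
) -> np.ndarray:
    """Cross-channel correlation block C12 between inputs x1 and x2.

    With ``prefactor`` (default) entries are
    sqrt(2 l1 l2 / (l1^2+l2^2)) * exp(-r^2 / (l1^2+l2^2)); without it the
    leading factor is 1.
    """
    _check_positive(ell1=ell1, ell2=ell2)
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    ssum = ell1 ** 2 + ell2 ** 2
    d = x1[:, None] - x2[None, :]
    c = np.exp(-(d ** 2) / ssum)
    if prefactor:
        c = np.sqrt(2.0 * ell1 * ell2 / ssum) * c
    return c


@dataclass
class PairKernelParams:
    """Covariance parameters of a two-channel GP.

    ``sigma2_12`` is the signal covariance; it may be negative but is
    constrained by |sigma2_12| <= sqrt(sigma2_1 * sigma2_2).
    """

    sigma2_1: float
    sigma2_2: float
    sigma2_12: float
    ell1: float
    ell2: float

    def __post_init__(self) -> None:
        _check_positive(
            sigma2_1=self.sigma2_1, sigma2_2=self.sigma2_2, ell1=self.ell1, ell2=self.ell2
        )
        bound = np.sqrt(self.sigma2_1 * self.sigma2_2)
        if abs(self.sigma2_12) > bound * (1 + 1e-12):
            raise ValueError(
                f"|sigma2_12|={abs(self.sigma2_12):g} exceeds sqrt(sigma2_1*sigma2_2)={bound:g}"
            )


def assemble_pair_covariance(
    params: PairKernelParams,
    x1: np.ndarray,
    x2: np.ndarray,
    jitter: float = 1e-6,
    prefactor: bool = True,
) -> np.ndarray:
    """Assemble the (N1+N2) x (N1+N2) two-channel covariance matrix.

    Block layout [[s1^2 C11, s12^2 C12], [s12^2 C12^T, s2^2 C22]] plus
    ``jitter`` times the mean diagonal on the diagonal.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    k11 = se_kernel_matrix(x1, params.sigma2_1, params.ell1)
    k22 = se_kernel_matrix(x2, params.sigma2_2, params.ell2)
    c12 = cross_correlation_matrix(x1, x2, params.ell1, params.ell2, prefactor=prefactor)
    k12 = params.sigma2_12 * c12
    top = np.hstack([k11, k12])
    bottom = np.hstack([k12.T, k22])
    k = np.vstack([top, bottom])
    k[np.diag_indices_from(k)] += jitter * np.mean(np.diag(k))
    return k


def robust_cholesky(k: np.ndarray, jitter: float = 1e-6, max_doublings: int = 3) -> np.ndarray:
    """Cholesky factor of ``k`` with jitter doubled up to ``max_doublings`` times."""
    scale = np.mean(np.diag(k))
    eps = jitter * scale
    for _ in range(max_doublings + 1):
        try:
            return np.linalg.cholesky(k + eps * np.eye(k.shape[0]))
        except np.linalg.LinAlgError:
            eps *= 2.0
    raise np.linalg.LinAlgError(
        f"covariance matrix not positive definite even with jitter {eps / scale:g} x mean diagonal"
    )
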