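"""First-order autoregressive longitudinal covariance.

The within-individual covariance of repeated measurements is modelled as
Sigma[k,l] = sigma2 * rho**|k-l| (stationary AR(1) on the measurement
index): sigma2 is the marginal variance at each time point and rho the
lag-1 correlation. The inverse is tridiagonal, so quadratic forms and the
log-determinant are available in closed form at O(T) per vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = ["AR1Covariance", "ar1_quadform", "ar1_logdet", "profile_ar1_mle"]


@dataclass(frozen=True)
class AR1Covariance:
    """AR(1) covariance: Sigma[k,l] = sigma2 * rho**|k-l|."""

    sigma2: float
    rho: float

    def __post_init__(self):
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        if not -1.0 < self.rho < 1.0:
            raise ValueError("rho must lie in (-1, 1)")

    def matrix(self, T: int) -> np.ndarray:
        k = np.arange(T)
        return self.sigma2 * self.rho ** np.abs(k[:, None] - k[None, :])

    def corr_inverse(self, T: int) -> np.ndarray:
        """Inverse of the correlation matrix R (tridiagonal)."""
        rho = self.rho
        P = np.zeros((T, T))
        idx = np.arange(T)
        P[idx, idx] = 1.0 + rho**2
        P[0, 0] = P[-1, -1] = 1.0
        P[idx[:-1], idx[1:]] = -rho
        P[idx[1:], idx[:-1]] = -rho
        return P / (1.0 - rho**2)

    def logdet(self, T: int) -> float:
        return ar1_logdet(self.sigma2, self.rho, T)


def ar1_logdet(sigma2: float, rho: float, T: int) -> float:
    return T * np.log(sigma2) + (T - 1) * np.log1p(-(rho**2))


def ar1_quadform(E: np.ndarray, rho: float) -> np.ndarray:
    """e' R(rho)^{-1} e for each row e of E, with R the AR(1) correlation."""
    E = np.atleast_2d(E)
    sq = E**2
    cross = (E[:, :-1] * E[:, 1:]).sum(axis=1)
    inner = sq[:, 1:-1].sum(axis=1) if E.shape[1] > 2 else 0.0
    return (sq[:, 0] + sq[:, -1] + (1 + rho**2) * inner - 2 * rho * cross) / (
        1.0 - rho**2
    )


def profile_ar1_mle(E: np.ndarray, rho_bound: float = 0.99) -> AR1Covariance:
    """Maximum-likelihood AR(1) parameters for zero-mean residual rows E.

    sigma2 is profiled out analytically for each rho; the remaining 1-D
    likelihood in rho is maximized numerically.
    """
    E = np.atleast_2d(np.asarray(E, dtype=float))
    n, T = E.shape

    def neg2ll(rho: float) -> float:
        q = ar1_quadform(E, rho).sum()
        sigma2 = max(q / (n * T), 1e-300)
        return n * T * np.log(sigma2) + n * (T - 1) * np.log1p(-(rho**2)) + n * T

    res = minimize_scalar(neg2ll, bounds=(-rho_bound, rho_bound), method="bounded",
                          options={"xatol": 1e-8})
    rho = float(res.x)
    sigma2 = float(max(ar1_quadform(E, rho).sum() / (n * T), 1e-300))
    return AR1Covariance(sigma2=sigma2, rho=rho)
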