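"""Random-effects covariance Sigma = T P T and correlation transforms.

T is the diagonal matrix of random-effect standard deviations tau (ordered
mu-blocks first, then sigma-blocks) and P is an unstructured correlation
matrix.  For sampling, P is parameterised through the canonical partial
correlations of its Cholesky factor (tanh of an unconstrained vector), the
standard unbounded parameterisation used with the LKJ prior.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class RandomEffectsCovariance:
    """Scales tau and correlation matrix P of the random effects."""

    tau: np.ndarray
    corr: np.ndarray

    def __post_init__(self) -> None:
        self.tau = np.atleast_1d(np.asarray(self.tau, dtype=float))
        self.corr = np.asarray(self.corr, dtype=float)
        d = self.tau.size
        if np.any(self.tau <= 0) or not np.all(np.isfinite(self.tau)):
            raise ValueError("tau must be strictly positive and finite")
        if self.corr.shape != (d, d):
            raise ValueError(f"corr must be {d}x{d}")
        if not np.allclose(self.corr, self.corr.T):
            raise ValueError("corr must be symmetric")
        if not np.allclose(np.diag(self.corr), 1.0):
            raise ValueError("corr must have unit diagonal")
        # positive definiteness via Cholesky
        try:
            np.linalg.cholesky(self.corr)
        except np.linalg.LinAlgError as exc:
            raise ValueError("corr is not positive definite") from exc

    @property
    def dim(self) -> int:
        return self.tau.size

    def assemble(self) -> np.ndarray:
        """Sigma = T P T, with Sigma[a, b] = tau_a tau_b rho_ab."""
        return self.corr * np.outer(self.tau, self.tau)

    @classmethod
    def from_sigma(cls, sigma: np.ndarray) -> "RandomEffectsCovariance":
        """Recover (tau, P) from an assembled covariance matrix."""
        sigma = np.asarray(sigma, dtype=float)
        tau = np.sqrt(np.diag(sigma))
        corr = sigma / np.outer(tau, tau)
        # enforce exact unit diagonal against rounding
        np.fill_diagonal(corr, 1.0)
        return cls(tau=tau, corr=corr)


def assemble_covariance(cov: RandomEffectsCovariance) -> np.ndarray:
    return cov.assemble()


def n_corr_params(dim: int) -> int:
    return dim * (dim - 1) // 2


def corr_cholesky_from_unconstrained(x: np.ndarray, dim: int) -> np.ndarray:
    """Lower-triangular Cholesky factor of a correlation matrix.

    ``x`` holds one unconstrained value per strictly-lower-triangular
    element (row-major).  Works with complex input so derivatives can be
    taken by complex step.
    """
    x = np.asarray(x)
    if x.size != n_corr_params(dim):
        raise ValueError(f"expected {n_corr_params(dim)} parameters for dim {dim}")
    L = np.zeros((dim, dim), dtype=x.dtype)
    L[0, 0] = 1.0
    pos = 0
    for i in range(1, dim):
        rem = 1.0 + 0.0 * x[0] if np.iscomplexobj(x) else 1.0
        for j in range(i):
            z = np.tanh(x[pos])
            pos += 1
            L[i, j] = z * np.sqrt(rem)
            rem = rem - L[i, j] ** 2
            # rem > 0 holds exactly; guard against rounding at tanh saturation
            if not np.iscomplexobj(x) and rem < 1e-16:
                rem = 1e-16
        L[i, i] = np.sqrt(rem)
    return L


def corr_transform_logdet_and_lkj(x: np.ndarray, dim: int, eta: float = 1.0):
    """Log density of the LKJ(eta) prior on the Cholesky factor implied by x,
    including the log Jacobian of the unconstrained-to-Cholesky transform.

    Returns (log_density, L).  Complex-safe for complex-step derivatives.
    """
    x = np.asarray(x)
    L = corr_cholesky_from_unconstrained(x, dim)
    logdet = 0.0 * L[0, 0]
    pos = 0
    cplx = np.iscomplexobj(x)
    for i in range(1, dim):
        rem = 1.0 + 0.0 * x[0] if cplx else 1.0
        for j in range(i):
            z = np.tanh(x[pos])
            pos += 1
            # d tanh / dx plus the sqrt(rem) stretch of the transform
            one_minus_z2 = 1.0 - z**2
            if not cplx and one_minus_z2 < 1e-300:  # tanh saturation guard
                one_minus_z2 = 1e-300
            logdet = logdet + np.log(one_minus_z2) + 0.5 * np.log(rem)
            rem = rem - (z * np.sqrt(rem)) ** 2
            if not cplx and rem < 1e-16:
                rem = 1e-16
    lkj = 0.0
    for i in range(1, dim):
        lkj = lkj + (dim - i - 1 + 2.0 * eta - 2.0) * np.log(L[i, i])
    return lkj + logdet, L


def corr_prior_value_grad_and_chol(
    x: np.ndarray, dim: int, eta: float = 1.0
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Value/gradient of the correlation prior plus the Cholesky Jacobian.

    Returns (logp, dlogp/dx, L, dL/dx) with dL/dx of shape (m, dim, dim).
    Derivatives are computed by complex step on the (cheap) transform; the
    expensive likelihood terms chain through dL/dx analytically elsewhere.
    """
    m = x.size
    h = 1e-20
    # batch: row 0 is the unperturbed point, row k+1 perturbs coordinate k
    xb = np.tile(x.astype(complex), (m + 1, 1))
    xb[1:][np.diag_indices(m)] += 1j * h
    # vectorised transform over the batch
    L = np.zeros((m + 1, dim, dim), dtype=complex)
    L[:, 0, 0] = 1.0
    logdet = np.zeros(m + 1, dtype=complex)
    lkj = np.zeros(m + 1, dtype=complex)
    pos = 0
    for i in range(1, dim):
        rem = np.ones(m + 1, dtype=complex)
        for j in range(i):
            z = np.tanh(xb[:, pos])
            pos += 1
            one_minus_z2 = 1.0 - z**2
            one_minus_z2[one_minus_z2.real < 1e-300] = 1e-300
            logdet += np.log(one_minus_z2) + 0.5 * np.log(rem)
            L[:, i, j] = z * np.sqrt(rem)
            rem = rem - L[:, i, j] ** 2
            rem[rem.real < 1e-16] = 1e-16
        L[:, i, i] = np.sqrt(rem)
        lkj += (dim - i - 1 + 2.0 * eta - 2.0) * np.log(L[:, i, i])
    total = lkj + logdet
    grad = total[1:].imag / h
    dL = L[1:].imag / h
    return float(total[0].real), grad, L[0].real.copy(), dL


def unconstrained_from_corr(corr: np.ndarray) -> np.ndarray:
    """Inverse transform: unconstrained vector from a correlation matrix."""
    corr = np.asarray(corr, dtype=float)
    dim = corr.shape[0]
    L = np.linalg.cholesky(corr)
    x = np.zeros(n_corr_params(dim))
    pos = 0
    for i in range(1, dim):
        rem = 1.0
        for j in range(i):
            z = L[i, j] / np.sqrt(rem)
            x[pos] = np.arctanh(np.clip(z, -1 + 1e-12, 1 - 1e-12))
            pos += 1
            rem -= L[i, j] ** 2
    return x
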