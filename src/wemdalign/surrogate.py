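"""Gaussian-process surrogate over rotation matrices.

The alignment loss is modeled as a zero-mean Gaussian process on SO(3) with
a squared-exponential covariance in the Frobenius embedding of the rotation
matrices into R⁹:

    k(R1, R2) = σ² exp(−‖R1 − R2‖²_F / (2 ℓ²))

which is positive definite because it is the Euclidean squared-exponential
restricted to the embedded manifold.  Conditioning on the evaluated
candidates (Rᵢ, yᵢ) gives the kriging mean

    m(R) = k(R)ᵀ (K + ε I)⁻¹ y

used as the acquisition function (pure exploitation; the early-stopped inner
optimization supplies the exploration).  The nugget ε guards the Cholesky
factorization when candidates nearly coincide.  The mean has a closed-form
Euclidean gradient, enabling fast Riemannian descent on the manifold.

The kriging mean is scale-free in σ²: it cancels between k(R) and K⁻¹, so σ²
is kept in the formulas for documentation fidelity but fixed to 1 and not
exposed as a tuning knob.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "SurrogateState",
    "se_kernel",
    "kernel_matrix",
    "fit_interpolant",
    "surrogate_mean",
    "surrogate_grad",
]


def _check_hyper(sigma2: float, lengthscale: float) -> None:
    if lengthscale <= 0 or sigma2 <= 0:
        raise ValueError("kernel hyperparameters must be positive")


def se_kernel(r1: np.ndarray, r2: np.ndarray, sigma2: float = 1.0, lengthscale: float = 0.75) -> float:
    """Squared-exponential covariance between two rotations (Frobenius embedding)."""
    _check_hyper(sigma2, lengthscale)
    d2 = float(np.sum((np.asarray(r1, float) - np.asarray(r2, float)) ** 2))
    return sigma2 * np.exp(-d2 / (2.0 * lengthscale**2))


def _stack(candidates) -> np.ndarray:
    return np.asarray([np.asarray(c, float).ravel() for c in candidates])


def kernel_matrix(candidates, sigma2: float = 1.0, lengthscale: float = 0.75) -> np.ndarray:
    """Gram matrix of :func:`se_kernel`; symmetric with diagonal σ²."""
    _check_hyper(sigma2, lengthscale)
    flat = _stack(candidates)
    if flat.shape[0] == 0:
        raise ValueError("need at least one candidate")
    sq = np.sum(flat**2, axis=1)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2.0 * flat @ flat.T, 0.0)
    k = sigma2 * np.exp(-d2 / (2.0 * lengthscale**2))
    return (k + k.T) / 2.0


@dataclass
class SurrogateState:
    """Fitted GP interpolant: hyperparameters, history and solved weights."""

    lengthscale: float
    sigma2: float
    nugget: float
    candidates: np.ndarray  # (m, 3, 3)
    values: np.ndarray  # (m,)
    factor: tuple  # Cholesky factor of K + nugget*I, as returned by cho_factor
    weights: np.ndarray  # solution of (K + nugget*I) w = y

    def __len__(self) -> int:
        return len(self.values)


def fit_interpolant(
    candidates,
    values,
    lengthscale: float = 0.75,
    nugget: float = 1e-4,
    sigma2: float = 1.0,
) -> SurrogateState:
    """Factorize (K + εI) and solve for the interpolation weights.

    Raises ``numpy.linalg.LinAlgError`` when the regularized kernel matrix is
    not positive definite — e.g. duplicated candidates with ε = 0.
    """
    cands = np.asarray([np.asarray(c, float) for c in candidates])
    y = np.asarray(values, dtype=float)
    if cands.shape[0] != y.shape[0]:
        raise ValueError("candidates and values must have equal length")
    if nugget < 0:
        raise ValueError("nugget must be nonnegative")
    k = kernel_matrix(cands, sigma2, lengthscale)
    try:
        factor = cho_factor(k + nugget * np.eye(len(y)), lower=True)
    except np.linalg.LinAlgError:
        raise
    except Exception as exc:  # scipy may raise its own LinAlgError subclass
        raise np.linalg.LinAlgError(str(exc))
    weights = cho_solve(factor, y)
    return SurrogateState(float(lengthscale), float(sigma2), float(nugget), cands, y, factor, weights)


def _cross_kernel(state: SurrogateState, r: np.ndarray) -> np.ndarray:
    diffs = state.candidates - np.asarray(r, float)[None, :, :]
    d2 = np.sum(diffs**2, axis=(1, 2))
    return state.sigma2 * np.exp(-d2 / (2.0 * state.lengthscale**2))


def surrogate_mean(state: SurrogateState, r: np.ndarray) -> float:
    """Kriging mean m(R) = k(R)ᵀ w; interpolates the observations when ε = 0."""
    return float(_cross_kernel(state, r) @ state.weights)


def surrogate_grad(state: SurrogateState, r: np.ndarray) -> np.ndarray:
    """Euclidean gradient of the kriging mean with respect to the 9 matrix entries.

    d/dR [k(R, Rᵢ)] = k(R, Rᵢ) (Rᵢ − R) / ℓ², summed with the weights:
    ∇m(R) = Σᵢ wᵢ k(R, Rᵢ) (Rᵢ − R) / ℓ².
    """
    r = np.asarray(r, float)
    kvec = _cross_kernel(state, r)
    coeff = state.weights * kvec / state.lengthscale**2
    return np.tensordot(coeff, state.candidates - r[None, :, :], axes=1)
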