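"""Time-lagged independent component analysis of a finite trajectory.

tICA finds linear combinations v_k of the input coordinates whose projections
y_k(t) = v_k . x(t) have maximal lag-tau autocorrelation.  For a finite
trajectory the time-lagged covariance is not symmetric, and two
symmetrization conventions are in use:

* ``main`` — both the lagged and the instantaneous matrix are estimated from
  averages over all ordered pairs (x_t, x_{t+tau}) and (x_{t+tau}, x_t):

      C_sym(tau) = 1/(2(n-tau)) sum_t (x_t x_{t+tau}^T + x_{t+tau} x_t^T)
      Sigma      = 1/(2(n-tau)) sum_t (x_t x_t^T + x_{t+tau} x_{t+tau}^T)

  so each eigenvalue is a genuine normalized autocorrelation in [-1, 1].

* ``alternative`` — the left-hand side is symmetrized the same way but the
  right-hand side keeps the plain full-trajectory covariance C(0) with its
  1/n prefactor.

The generalized symmetric eigenproblem C_sym v = lambda R v is solved by the
AMUSE construction: diagonalize R = Q Lambda Q^T, form the whitening map
W = Q Lambda^{-1/2} on the retained subspace, solve the ordinary symmetric
problem for u_k, and map back v_k = W u_k.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._linalg import DegenerateInputError, sign_for, whiten
from .trajectory import Trajectory

__all__ = ["CovariancePair", "TicaResult", "covariances", "tica", "METHODS"]

METHODS = ("main", "alternative")


def _validate(traj: Trajectory, tau: int) -> None:
    if not traj.centered:
        raise ValueError("trajectory must be centered first (see trajectory.center)")
    if not (1 <= tau <= traj.n - 2):
        raise ValueError(f"lag tau={tau} outside valid range [1, n-2] for n={traj.n}")


def _check_method(method: str) -> None:
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}, got {method!r}")


@dataclass(frozen=True)
class CovariancePair:
    """Symmetrized lagged covariance and the method's right-hand-side matrix."""

    lagged: np.ndarray
    instantaneous: np.ndarray
    method: str
    tau: int


@dataclass(frozen=True)
class TicaResult:
    """Eigenvalues (descending), eigenvectors v_k (d x m) and unit-norm
    projections y_k (n x m) of one tICA solve."""

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    projections: np.ndarray
    method: str
    tau: int
    norm: str = "unit"

    @property
    def n_components(self) -> int:
        return self.eigenvalues.size


def covariances(traj: Trajectory, tau: int, method: str = "main") -> CovariancePair:
    """Pair-symmetrized covariance estimators at lag ``tau``."""
    _validate(traj, tau)
    _check_method(method)
    x = traj.coords
    n = traj.n
    x0 = x[: n - tau]
    x1 = x[tau:]
    norm = 2.0 * (n - tau)
    lagged = (x0.T @ x1 + x1.T @ x0) / norm
    if method == "main":
        instantaneous = (x0.T @ x0 + x1.T @ x1) / norm
    else:
        instantaneous = x.T @ x / n
    return CovariancePair(lagged=lagged, instantaneous=instantaneous, method=method, tau=tau)


def tica(
    traj: Trajectory,
    tau: int,
    method: str = "main",
    n_components: int | None = None,
    norm: str = "unit",
    rel_cutoff: float = 1e-10,
) -> TicaResult:
    """Solve the symmetrized tICA generalized eigenproblem.

    Directions with right-hand-side eigenvalue below ``rel_cutoff`` times the
    largest are discarded (rank-deficient input is fine as long as one
    direction survives).  Projections are returned with unit norm
    (``norm="unit"``) or unit standard deviation (``norm="std"``), each with
    a deterministic sign convention.
    """
    if norm not in ("unit", "std"):
        raise ValueError("norm must be 'unit' or 'std'")
    pair = covariances(traj, tau, method)
    try:
        W = whiten(pair.instantaneous, rel_cutoff)
    except DegenerateInputError as exc:
        raise DegenerateInputError(
            "trajectory covariance has no retained direction"
        ) from exc
    small = W.T @ pair.lagged @ W
    small = (small + small.T) / 2.0
    evals, U = np.linalg.eigh(small)
    order = np.argsort(evals)[::-1]
    evals, U = evals[order], U[:, order]
    if n_components is not None:
        evals, U = evals[:n_components], U[:, :n_components]
    V = W @ U
    Y = traj.coords @ V
    for k in range(Y.shape[1]):
        col = Y[:, k]
        scale = np.linalg.norm(col) if norm == "unit" else np.std(col)
        if scale == 0.0:
            continue
        s = sign_for(col)
        Y[:, k] = s * col / scale
        V[:, k] = s * V[:, k] / scale
    return TicaResult(
        eigenvalues=evals, eigenvectors=V, projections=Y, method=method, tau=tau, norm=norm
    )
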