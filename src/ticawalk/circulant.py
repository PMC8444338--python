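"""The d = n special case: B^{-1}A and its circulant asymptotics.

When the dimension equals the number of frames (and X is treated as
invertible), the swapped tICA eigenproblem becomes independent of the data:
its eigenpairs are those of B^{-1}A, except that the constant vector
(1, ..., 1)^T — a null vector of a centered X — is an eigenvector of B^{-1}A
with eigenvalue exactly 1.

For large n, B^{-1}A differs from a circulant matrix (entries 1/2 at cyclic
offsets +-tau) only at tau-sized corners, and the two are asymptotically
equivalent: the sorted spectra converge to the Fourier eigenvalues

    lambda_k = cos(2 pi tau k / n),  k = 0..n-1.

The eigenVECTORS do not converge individually wherever eigenvalues cluster
(|cos| near 1): numerical eigenvectors are arbitrary within the
near-degenerate eigenspace, so comparisons must be made between subspaces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mmatrix import build_weights
from .tica import _check_method

__all__ = [
    "CirculantSpectrum",
    "binv_a",
    "circulant_matrix",
    "circulant_eigenvalues",
    "spectral_gap_to_circulant",
]


@dataclass(frozen=True)
class CirculantSpectrum:
    """Analytic Fourier spectrum of the circulant limit matrix."""

    n: int
    tau: int
    eigenvalues: np.ndarray  # lambda_k = cos(2 pi tau k / n), k = 0..n-1
    frequencies: np.ndarray  # the indices k
    degeneracy_map: dict  # group key -> list of k with equal lambda_k


def binv_a(n: int, tau: int, method: str = "main") -> np.ndarray:
    """Dense B^{-1}A.  For the alternative method this is simply A/2.

    The main method requires tau <= (n-1)/2 so that every frame enters at
    least one of the two instantaneous sums (B has no zero diagonal entry).
    """
    _check_method(method)
    weights = build_weights(n, tau, method)
    if np.any(weights.b_diag == 0.0):
        raise ValueError(
            f"main-method B is singular for tau={tau}, n={n} (need tau <= (n-1)/2)"
        )
    return np.asarray(weights.A.todense()) / weights.b_diag[:, None]


def circulant_matrix(n: int, tau: int) -> np.ndarray:
    """n-periodic extension of the bulk rows of B^{-1}A: 1/2 at offsets +-tau."""
    C = np.zeros((n, n))
    idx = np.arange(n)
    C[idx, (idx + tau) % n] += 0.5
    C[idx, (idx - tau) % n] += 0.5
    return C


def circulant_eigenvalues(n: int, tau: int) -> CirculantSpectrum:
    """Fourier eigenvalues cos(2 pi tau k / n) with their degeneracy grouping.

    lambda_k depends only on tau*k mod n up to reflection, so frequencies k
    with min(tau*k mod n, n - tau*k mod n) equal share an eigenvalue exactly.
    """
    if not (1 <= tau <= n - 2):
        raise ValueError(f"lag tau={tau} outside valid range [1, n-2] for n={n}")
    k = np.arange(n)
    evals = np.cos(2.0 * np.pi * tau * k / n)
    keys = np.minimum((tau * k) % n, (n - (tau * k) % n) % n)
    groups: dict[int, list[int]] = {}
    for ki, key in zip(k, keys):
        groups.setdefault(int(key), []).append(int(ki))
    return CirculantSpectrum(
        n=n, tau=tau, eigenvalues=evals, frequencies=k, degeneracy_map=groups
    )


def spectral_gap_to_circulant(n: int, tau: int, method: str = "main") -> dict:
    """Discrepancy between the exact B^{-1}A spectrum and the circulant one.

    Both spectra are sorted and compared element-wise; asymptotic equal
    distribution of the eigenvalues makes the gap shrink with n at fixed tau.
    """
    exact = np.linalg.eigvals(binv_a(n, tau, method))
    if np.max(np.abs(exact.imag)) > 1e-8 * np.max(np.abs(exact)):
        raise ValueError("unexpected complex eigenvalues of B^{-1}A")
    exact = np.sort(exact.real)
    limit = np.sort(circulant_eigenvalues(n, tau).eigenvalues)
    diff = np.abs(exact - limit)
    return {
        "n": n,
        "tau": tau,
        "method": method,
        "max_abs_diff": float(np.max(diff)),
        "mean_abs_diff": float(np.mean(diff)),
    }
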