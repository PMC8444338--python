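"""Shared numerical helpers: whitening, sign conventions, correlations."""

from __future__ import annotations

import numpy as np


class DegenerateInputError(ValueError):
    """Raised when a whitening / eigendecomposition step has no usable rank."""


class TrackingWarning(UserWarning):
    """Raised when eigenvector continuity tracking across a lag grid fails."""


def whiten(R: np.ndarray, rel_cutoff: float = 1e-10) -> np.ndarray:
    """Whitening map W = Q Lambda^{-1/2} of a symmetric PSD matrix R.

    Eigenvalues below ``rel_cutoff`` times the largest are discarded, so the
    returned W has shape (d, m) with m <= d and W^T R W = I_m.
    """
    R = np.asarray(R, dtype=float)
    evals, Q = np.linalg.eigh((R + R.T) / 2.0)
    top = evals[-1]
    if top <= 0.0:
        raise DegenerateInputError("matrix has no positive eigenvalue; cannot whiten")
    keep = evals > rel_cutoff * top
    if not np.any(keep):
        raise DegenerateInputError("no eigenvalue above the whitening cutoff")
    return Q[:, keep] / np.sqrt(evals[keep])


def cosine_inner_products(y: np.ndarray) -> np.ndarray:
    """Inner products c_k = sum_{t=1..n} y_t cos(k*pi*t/n) for k = 0..n.

    Computed with one length-2n FFT; the phase factor accounts for the t=1..n
    sampling convention.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    F = np.fft.rfft(y, 2 * n)
    k = np.arange(F.size)
    return (F * np.exp(-1j * np.pi * k / n)).real


def sign_for(y: np.ndarray) -> float:
    """Deterministic sign convention for an eigenvector / projection.

    The sign is chosen so that the inner product with the sampled cosine
    cos(k*pi*t/n) at the dominant frequency k >= 1 is non-negative; if that
    inner product vanishes, the first nonzero component is made positive.
    """
    c = cosine_inner_products(y)
    c[0] = 0.0
    k_star = int(np.argmax(np.abs(c)))
    if c[k_star] > 0:
        return 1.0
    if c[k_star] < 0:
        return -1.0
    nz = np.flatnonzero(y)
    if nz.size == 0 or y[nz[0]] > 0:
        return 1.0
    return -1.0


def unit(y: np.ndarray) -> np.ndarray:
    nrm = np.linalg.norm(y)
    if nrm == 0.0:
        raise DegenerateInputError("zero-norm vector cannot be normalized")
    return y / nrm


def abs_corr(a: np.ndarray, b: np.ndarray) -> float:
    """Absolute Pearson correlation of two sequences (sign- and scale-free)."""
    a = np.asarray(a, dtype=float) - np.mean(a)
    b = np.asarray(b, dtype=float) - np.mean(b)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(abs(a @ b) / (na * nb))


def frequency_content(y: np.ndarray, omega: float) -> float:
    """Fraction of |y| captured by span{cos(omega*t), sin(omega*t)}, t=1..n.

    Phase-free analogue of a correlation with a single sinusoid; returns a
    value in [0, 1].
    """
    y = np.asarray(y, dtype=float)
    t = np.arange(1, y.size + 1)
    basis = np.column_stack([np.cos(omega * t), np.sin(omega * t)])
    qb, _ = np.linalg.qr(basis)
    proj = qb.T @ y
    nrm = np.linalg.norm(y)
    if nrm == 0.0:
        return 0.0
    return float(np.linalg.norm(proj) / nrm)
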