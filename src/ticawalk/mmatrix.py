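"""The M-matrix reformulation of tICA and its ensemble average.

Writing the trajectory as the d x n matrix X (columns are frames), the
symmetrized tICA problem can be expressed with two structured n x n weight
matrices:

* A — symmetric, with entries 1 at (t, t+tau) and (t+tau, t), so that
  X A X^T equals the pair-symmetrized lagged sum (no prefactor);
* B — diagonal; for the main method the entry at t counts how often frame t
  enters the instantaneous estimator ([t <= n-tau] + [t >= tau+1], i.e. 1 at
  the tau first/last frames and 2 in the bulk); for the alternative method
  every diagonal entry is 2, so X B X^T = 2 X X^T.

With W the whitening map of X B X^T, the tICA projections y_k are exactly
the eigenvectors with nonzero eigenvalue of the n x n matrix

    M = X^T W W^T X A.

Because M depends on the walk only through X, its ensemble average <M> over
many random walks gives "expected" tICA projections of the random-walk null
model — the semianalytical solution for arbitrary n and d.  Note
M = P A with P = X^T W W^T X, so the average is accumulated over P (one
n x n matrix of memory regardless of the sample count) and A is applied
once.  For the alternative method B does not depend on tau, hence neither
does P: a single pass over the walk sample serves every lag.

The nonzero eigenpairs of M are computed without forming M: they coincide
with those of the small symmetric m x m matrix W^T (X A X^T) W, whose
eigenvectors u_k map to y_k = X^T W u_k.  For <M> = <P> A the reduction is
through the symmetric matrix <P>^{1/2} A <P>^{1/2}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from ._linalg import DegenerateInputError, sign_for, unit, whiten
from .tica import METHODS, _check_method
from .trajectory import Trajectory, generate_random_walk

__all__ = [
    "StructuredWeights",
    "MDecomposition",
    "ExpectedProjections",
    "build_weights",
    "build_M",
    "expected_M",
]


@dataclass(frozen=True)
class StructuredWeights:
    """Sparse A (lagged pair weights) and diagonal B (frame multiplicities)."""

    A: sp.csr_matrix
    B: sp.csr_matrix
    b_diag: np.ndarray
    tau: int
    n: int
    method: str


def build_weights(n: int, tau: int, method: str = "main") -> StructuredWeights:
    """Construct the n x n weight matrices A and B for lag ``tau``."""
    _check_method(method)
    if not (1 <= tau <= n - 2):
        raise ValueError(f"lag tau={tau} outside valid range [1, n-2] for n={n}")
    t = np.arange(n - tau)
    rows = np.concatenate([t, t + tau])
    cols = np.concatenate([t + tau, t])
    data = np.ones(2 * (n - tau))
    A = sp.csr_matrix((data, (rows, cols)), shape=(n, n))
    if method == "main":
        idx = np.arange(n)
        b_diag = (idx < n - tau).astype(float) + (idx >= tau).astype(float)
    else:
        b_diag = np.full(n, 2.0)
    B = sp.diags(b_diag, format="csr")
    return StructuredWeights(A=A, B=B, b_diag=b_diag, tau=tau, n=n, method=method)


@dataclass(frozen=True)
class MDecomposition:
    """Whitening map plus the retained eigenpairs of M for one trajectory.

    ``eigenvalues`` are the raw eigenvalues of M = X^T W W^T X A (no
    estimator prefactors).  For the main method these equal the generalized
    tICA eigenvalues; for the alternative method the tICA convention carries
    an extra n/(n-tau) factor, exposed as ``generalized_eigenvalues``.
    The n x n matrix M itself is only materialized on demand.
    """

    W: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # n x m, the projections y_k, unit norm
    tau: int
    n: int
    d: int
    method: str
    _coords: np.ndarray = field(repr=False, default=None)

    @property
    def generalized_eigenvalues(self) -> np.ndarray:
        if self.method == "alternative":
            return self.eigenvalues * (self.n / (self.n - self.tau))
        return self.eigenvalues

    def materialize(self) -> np.ndarray:
        """Dense n x n matrix M = X^T W W^T X A (memory: n^2 floats)."""
        T = self._coords @ self.W  # n x m
        A = build_weights(self.n, self.tau, self.method).A
        return T @ (A.T @ T).T  # (T T^T) A with A symmetric


def _raw_rhs(x: np.ndarray, tau: int, method: str) -> np.ndarray:
    """X B X^T without prefactor, from the (n, d) coordinate array."""
    n = x.shape[0]
    if method == "main":
        x0, x1 = x[: n - tau], x[tau:]
        return x0.T @ x0 + x1.T @ x1
    return 2.0 * (x.T @ x)


def _raw_lagged(x: np.ndarray, tau: int) -> np.ndarray:
    """X A X^T without prefactor."""
    n = x.shape[0]
    x0, x1 = x[: n - tau], x[tau:]
    return x0.T @ x1 + x1.T @ x0


def build_M(
    traj: Trajectory,
    tau: int,
    method: str = "main",
    rel_cutoff: float = 1e-10,
) -> MDecomposition:
    """Eigenpairs of M for a single centered trajectory.

    Computed via the equivalent m x m symmetric problem (m = retained rank of
    X B X^T), never forming the n x n matrix.  Eigenpairs with |lambda| below
    ``rel_cutoff`` times the spectral radius are discarded; the rest are
    sorted descending with the package sign convention applied.
    """
    if not traj.centered:
        raise ValueError("trajectory must be centered first (see trajectory.center)")
    _check_method(method)
    if not (1 <= tau <= traj.n - 2):
        raise ValueError(f"lag tau={tau} outside valid range [1, n-2] for n={traj.n}")
    x = traj.coords
    try:
        W = whiten(_raw_rhs(x, tau, method), rel_cutoff)
    except DegenerateInputError as exc:
        raise DegenerateInputError("rank-0 whitening: trajectory has no variance") from exc
    small = W.T @ _raw_lagged(x, tau) @ W
    small = (small + small.T) / 2.0
    evals, U = np.linalg.eigh(small)
    order = np.argsort(evals)[::-1]
    evals, U = evals[order], U[:, order]
    radius = np.max(np.abs(evals)) if evals.size else 0.0
    keep = np.abs(evals) > rel_cutoff * radius
    evals, U = evals[keep], U[:, keep]
    Y = x @ (W @ U)
    cols = []
    for k in range(Y.shape[1]):
        col = Y[:, k]
        nrm = np.linalg.norm(col)
        if nrm == 0.0:
            cols.append(col)
            continue
        cols.append(sign_for(col) * col / nrm)
    Y = np.column_stack(cols) if cols else Y
    return MDecomposition(
        W=W, eigenvalues=evals, eigenvectors=Y, tau=tau, n=traj.n, d=traj.d,
        method=method, _coords=x,
    )


@dataclass(frozen=True)
class ExpectedProjections:
    """Eigenpairs of the sample-averaged matrix <M> = <P> A.

    ``projections`` (n x m) are the expected tICA projections of the
    random-walk ensemble, unit norm, descending eigenvalue order, with the
    package sign convention.  ``mean_P`` is kept so that <M> for other lags
    (alternative method) or diagnostics can be derived without re-sampling.
    """

    projections: np.ndarray
    eigenvalues: np.ndarray
    n: int
    d: int
    tau: int
    method: str
    n_samples: int
    seed: object
    mean_P: np.ndarray | None = field(repr=False, default=None)

    @property
    def mean_M(self) -> np.ndarray:
        if self.mean_P is None:
            raise ValueError("mean_P was not stored (keep_mean=False)")
        A = build_weights(self.n, self.tau, self.method).A
        return (A.T @ self.mean_P.T).T  # <P> A, exploiting symmetry of both


def _walk_seeds(seed, n_samples: int) -> list:
    """Per-walk seeds: either an explicit sequence or spawned from one seed."""
    if np.iterable(seed) and not isinstance(seed, np.random.SeedSequence):
        seeds = list(seed)
        if len(seeds) != n_samples:
            raise ValueError("explicit seed sequence must have length n_samples")
        return seeds
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    return ss.spawn(n_samples)


def mean_P(
    n: int,
    d: int,
    tau: int,
    method: str,
    walk_seeds: list,
    step_distribution: str = "gaussian",
    rel_cutoff: float = 1e-10,
    chunk_floats: int = 5_000_000,
) -> np.ndarray:
    """Average of P = X^T W W^T X over random walks with the given seeds.

    Walks are regenerated from their seeds, so a fixed seed list gives common
    random numbers across different lags (smooth eigenvalue curves).  The
    rank-m factors T = X^T W are stacked into chunks and accumulated with one
    symmetric rank-k update per chunk.
    """
    Pm = np.zeros((n, n))
    stack: list[np.ndarray] = []
    width = 0
    max_width = max(1, chunk_floats // n)
    for s in walk_seeds:
        x = generate_random_walk(n, d, s, step_distribution).coords
        W = whiten(_raw_rhs(x, tau, method), rel_cutoff)
        T = x @ W
        stack.append(T)
        width += T.shape[1]
        if width >= max_width:
            Tc = np.concatenate(stack, axis=1)
            Pm += Tc @ Tc.T
            stack, width = [], 0
    if stack:
        Tc = np.concatenate(stack, axis=1)
        Pm += Tc @ Tc.T
    Pm /= len(walk_seeds)
    return Pm


def eig_PA(
    Pm: np.ndarray,
    A: sp.spmatrix,
    k: int | None = None,
    rel_cutoff: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray]:
    """Real eigenpairs of the product <P> A through a symmetric reduction.

    <P> is symmetric PSD, so the nonzero spectrum of <P> A equals that of
    S = <P>^{1/2} A <P>^{1/2}, which is symmetric — the retained eigenvalues
    are real by construction rather than by truncating imaginary parts.
    Eigenvectors are recovered as y = <P>^{1/2} z.
    """
    w, U = np.linalg.eigh((Pm + Pm.T) / 2.0)
    w = np.clip(w, 0.0, None)
    P_half = (U * np.sqrt(w)) @ U.T
    S = P_half @ (A @ P_half)
    S = (S + S.T) / 2.0
    s, Z = np.linalg.eigh(S)
    order = np.argsort(s)[::-1]
    s, Z = s[order], Z[:, order]
    radius = np.max(np.abs(s)) if s.size else 0.0
    keep = np.abs(s) > rel_cutoff * radius
    s, Z = s[keep], Z[:, keep]
    if k is not None:
        s, Z = s[:k], Z[:, :k]
    Y = P_half @ Z
    cols = []
    kept_vals = []
    for j in range(Y.shape[1]):
        col = Y[:, j]
        nrm = np.linalg.norm(col)
        if nrm <= 1e-12:
            continue
        cols.append(sign_for(col) * col / nrm)
        kept_vals.append(s[j])
    if not cols:
        raise DegenerateInputError("averaged matrix has no retained eigenpair")
    return np.asarray(kept_vals), np.column_stack(cols)


def expected_M(
    n: int,
    d: int,
    tau: int,
    method: str = "main",
    n_samples: int = 20000,
    seed: object = 0,
    step_distribution: str = "gaussian",
    k: int | None = None,
    keep_mean: bool = True,
    rel_cutoff: float = 1e-10,
) -> ExpectedProjections:
    """Expected tICA projections of the (n, d) random-walk ensemble at one lag.

    <M> is the arithmetic mean of M over ``n_samples`` independent walks whose
    seeds are spawned deterministically from ``seed`` (or taken verbatim if
    ``seed`` is a sequence of length n_samples).  The default sample size of
    20000 matches the regime where the average is effectively converged;
    smaller samples are appropriate for exploratory work.
    """
    _check_method(method)
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    seeds = _walk_seeds(seed, n_samples)
    Pm = mean_P(n, d, tau, method, seeds, step_distribution, rel_cutoff)
    A = build_weights(n, tau, method).A
    evals, Y = eig_PA(Pm, A, k=k, rel_cutoff=rel_cutoff)
    return ExpectedProjections(
        projections=Y, eigenvalues=evals, n=n, d=d, tau=tau, method=method,
        n_samples=n_samples, seed=seed, mean_P=Pm if keep_mean else None,
    )
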