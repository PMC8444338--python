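"""Convergence and effective-dimensionality diagnostics.

A trajectory whose tICA projections look like those of a random walk has not
sampled any feature of its underlying landscape: at the small lags typically
used, random-walk projections are near-perfect half-period cosines, so the
cosine content of the leading projections quantifies random-walk likeness.
Going further, the expected projections depend on the walk dimension d
through the critical-lag structure, so the d that maximizes the similarity
between a trajectory's projections and the random-walk expectation acts as
an operational "effective dimensionality" of the dynamics.

The similarity score used here is our own construction (the comparison is
usually made by eye): the mean, over a set of lags and over the first two
projections, of the absolute Pearson correlation between the trajectory
projection and the expected random-walk projection of the same rank.  It is
bounded in [0, 1], sign-free and scale-free.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._linalg import DegenerateInputError, abs_corr
from .mmatrix import expected_M
from .tica import tica
from .trajectory import Trajectory, center

__all__ = [
    "CosineContent",
    "SimilarityReport",
    "cosine_content",
    "randomwalk_similarity",
    "effective_dimensionality",
    "two_state_trajectory",
    "default_tau_set",
]


@dataclass(frozen=True)
class CosineContent:
    order: int
    value: float


@dataclass(frozen=True)
class SimilarityReport:
    """Similarity of a trajectory's projections to random-walk expectations,
    per candidate dimension."""

    scores: list  # [(candidate d, score)]
    best_d: int
    best_score: float
    tau_set: tuple
    method: str


def cosine_content(projection, order: int = 1) -> CosineContent:
    """Squared normalized inner product with cos(order * pi * t / n), t=1..n.

    Bounded in [0, 1] by Cauchy-Schwarz; 1 means the projection is exactly
    the sampled half-period cosine of that order (random-walk-like for the
    leading orders), 0 means orthogonal to it.
    """
    y = np.asarray(projection, dtype=float).ravel()
    n = y.size
    if n < 2:
        raise ValueError("projection must have at least 2 samples")
    if order < 1:
        raise ValueError("order must be >= 1")
    yy = float(y @ y)
    if yy == 0.0:
        raise DegenerateInputError("zero-norm projection has no cosine content")
    t = np.arange(1, n + 1)
    c = np.cos(order * np.pi * t / n)
    value = float((y @ c) ** 2 / (yy * (c @ c)))
    return CosineContent(order=order, value=value)


def default_tau_set(n: int) -> tuple:
    """Lags spanning up to n/5, straddling typical critical-lag locations."""
    return tuple(sorted({max(2, n // 20), max(3, n // 10), max(4, n // 5)}))


def randomwalk_similarity(
    projections,
    n: int,
    candidate_d: int,
    tau_set,
    method: str = "main",
    n_samples: int = 200,
    seed: object = 0,
    n_components: int = 2,
    _expected_cache: dict | None = None,
) -> float:
    """Mean absolute rank-matched correlation with expected projections.

    ``projections`` is a sequence aligned with ``tau_set``: one n x m array
    (m >= n_components) of the trajectory's tICA projections per lag.  The
    expected projections of the (n, candidate_d) random-walk ensemble are
    computed at the same lags; the score averages |corr| over lags and over
    the first ``n_components`` ranks.  Deterministic given ``seed``.
    """
    tau_set = tuple(int(t) for t in tau_set)
    projections = [np.atleast_2d(np.asarray(p, dtype=float)) for p in projections]
    if len(projections) != len(tau_set):
        raise ValueError("one projection matrix per lag in tau_set is required")
    cache = _expected_cache if _expected_cache is not None else {}
    scores = []
    for tau, proj in zip(tau_set, projections):
        if proj.shape[0] != n:
            raise ValueError(
                f"projection length {proj.shape[0]} does not match n={n}"
            )
        key = (n, candidate_d, tau, method, n_components)
        if key not in cache:
            cache[key] = expected_M(
                n, candidate_d, tau, method, n_samples=n_samples, seed=seed,
                k=n_components, keep_mean=False,
            ).projections
        exp = cache[key]
        m = min(n_components, proj.shape[1], exp.shape[1])
        for k in range(m):
            scores.append(abs_corr(proj[:, k], exp[:, k]))
    return float(np.mean(scores))


def effective_dimensionality(
    trajectory: Trajectory,
    d_candidates,
    tau_set=None,
    method: str = "main",
    n_samples: int = 200,
    seed: object = 0,
    n_components: int = 2,
    _expected_cache: dict | None = None,
) -> SimilarityReport:
    """Random-walk dimension whose expected projections best match a trajectory.

    The trajectory's own tICA projections are computed once per lag; each
    candidate d is scored with :func:`randomwalk_similarity` and the argmax
    is reported.  Ties break toward the smaller d.  A shared cache dict may
    be passed to reuse expected projections across trajectories.
    """
    d_candidates = [int(d) for d in d_candidates]
    if not d_candidates:
        raise ValueError("need at least one candidate dimension")
    traj = center(trajectory)
    if tau_set is None:
        tau_set = default_tau_set(traj.n)
    tau_set = tuple(int(t) for t in tau_set)
    proj_per_tau = [
        tica(traj, tau, method, n_components=n_components).projections
        for tau in tau_set
    ]
    cache = _expected_cache if _expected_cache is not None else {}
    scores = []
    for d in sorted(set(d_candidates)):
        s = randomwalk_similarity(
            proj_per_tau, traj.n, d, tau_set, method,
            n_samples=n_samples, seed=seed, n_components=n_components,
            _expected_cache=cache,
        )
        scores.append((d, s))
    best_d, best_score = max(scores, key=lambda p: (p[1], -p[0]))
    return SimilarityReport(
        scores=scores, best_d=int(best_d), best_score=float(best_score),
        tau_set=tau_set, method=method,
    )


def two_state_trajectory(
    n: int,
    d: int,
    seed: int | np.random.SeedSequence,
    jump_prob: float = 1e-3,
    separation: float = 5.0,
    noise_sigma: float = 1.0,
) -> Trajectory:
    """Synthetic metastable trajectory: a negative control for the diagnostics.

    A symmetric two-state jump process (flip probability ``jump_prob`` per
    frame) displaced by ``separation`` times the noise scale along a random
    direction in d dimensions, plus i.i.d. Gaussian intra-state noise.  Its
    projections are step-like rather than cosine-like, mimicking a
    trajectory that genuinely hops between free-energy minima.
    """
    if n < 2 or d < 1:
        raise ValueError("need n >= 2 and d >= 1")
    rng = np.random.default_rng(seed)
    flips = rng.random(n) < jump_prob
    state = np.where(np.cumsum(flips) % 2 == 0, 1.0, -1.0)
    direction = rng.standard_normal(d)
    direction /= np.linalg.norm(direction)
    coords = (
        np.outer(state, direction) * (separation * noise_sigma / 2.0)
        + rng.standard_normal((n, d)) * noise_sigma
    )
    return center(Trajectory(coords))
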