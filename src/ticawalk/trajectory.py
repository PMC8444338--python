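"""Random-walk trajectories: the null model for tICA convergence analysis.

A trajectory is an n x d coordinate matrix, one frame per row, time steps
t = 1..n (stored 0-based internally).  Random walks in a flat landscape are
the reference against which MD-style trajectories are compared: a walk that
has not yet explored any feature of its energy landscape produces tICA
projections with a characteristic cosine structure.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["Trajectory", "generate_random_walk", "center"]

_STEP_DISTRIBUTIONS = ("gaussian", "uniform", "rademacher")


@dataclass(frozen=True)
class Trajectory:
    """An n-frame, d-coordinate trajectory.

    ``centered`` records whether column means have been subtracted; every
    tICA entry point requires a centered trajectory.
    """

    coords: np.ndarray
    centered: bool = False

    def __post_init__(self) -> None:
        coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        if coords.ndim != 2:
            raise ValueError("coords must be a 2-d (n x d) array")
        object.__setattr__(self, "coords", coords)

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    @property
    def d(self) -> int:
        return self.coords.shape[1]


def generate_random_walk(
    n: int,
    d: int,
    seed: int | np.random.SeedSequence,
    step_distribution: str = "gaussian",
) -> Trajectory:
    """Generate a centered d-dimensional random walk of n time steps.

    Increments are i.i.d. with mean 0 and unit variance per coordinate;
    non-Gaussian step distributions are rescaled to unit variance so that all
    choices share the same diffusion scale.  The walk starts at the origin,
    which is irrelevant after centering.  Fully reproducible from ``seed``.
    """
    if n < 1 or d < 1:
        raise ValueError(f"n and d must be >= 1, got n={n}, d={d}")
    if step_distribution not in _STEP_DISTRIBUTIONS:
        raise ValueError(
            f"step_distribution must be one of {_STEP_DISTRIBUTIONS}, "
            f"got {step_distribution!r}"
        )
    rng = np.random.default_rng(seed)
    if step_distribution == "gaussian":
        steps = rng.standard_normal((n, d))
    elif step_distribution == "uniform":
        # U(-sqrt(3), sqrt(3)) has unit variance
        steps = rng.uniform(-np.sqrt(3.0), np.sqrt(3.0), size=(n, d))
    else:  # rademacher: +/-1 with equal probability, unit variance already
        steps = rng.integers(0, 2, size=(n, d)).astype(float) * 2.0 - 1.0
    coords = np.cumsum(steps, axis=0)
    return center(Trajectory(coords))


def center(traj: Trajectory) -> Trajectory:
    """Subtract column means.  Idempotent; returns a new Trajectory."""
    if traj.centered:
        return traj
    coords = traj.coords - traj.coords.mean(axis=0, keepdims=True)
    return replace(traj, coords=coords, centered=True)
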