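"""Critical lag times: eigenvalue crossings of <M> and their scaling with d.

The spectrum of <M> as a function of the lag tau splits into two families:

* a decreasing family, whose eigenvectors are low-frequency cosines of
  period 2n, 2n/2, 2n/3, ... and whose eigenvalues follow the sampled
  autocorrelation of those cosines (hence decrease with tau);
* an increasing family, starting near zero at small tau, whose eigenvectors
  are cosine/sine pairs of period tau, 2 tau, 3 tau, ... and whose average
  autocorrelation grows as the period lengthens.

Where an increasing curve overtakes a decreasing one the eigenvalues are
degenerate, their order switches, and the top-ranked eigenVECTORS — and with
them the tICA projections — change abruptly.  The first such crossing
affects the rank-2 projection, the next one the rank-1 projection.  The lag
of the first abrupt change empirically scales as tau* ~ n / sqrt(d).

Detection operates on eigenvector continuity rather than eigenvalue
proximity (which degenerates exactly at the crossing): a rank-r projection
"jumps" at the first lag where its absolute overlap with the same rank at
the previous lag drops below 1/sqrt(2) — halfway between identical and
orthogonal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linear_sum_assignment
from scipy.stats import linregress

from ._linalg import TrackingWarning
from .mmatrix import _walk_seeds, build_M, build_weights, eig_PA, mean_P
from .tica import _check_method
from .trajectory import Trajectory

__all__ = [
    "EigenvalueCurves",
    "CriticalLags",
    "PowerLawFit",
    "eigenvalue_curves",
    "detect_critical_lags_expected",
    "locate_critical_lags",
    "detect_critical_lags_single",
    "fit_power_law",
    "OVERLAP_THRESHOLD",
]

OVERLAP_THRESHOLD = 1.0 / np.sqrt(2.0)


@dataclass(frozen=True)
class EigenvalueCurves:
    """Top-K eigenpairs of <M> (or one walk's M) over a lag grid.

    ``eigenvalues[i, r]`` is the rank-r (descending) eigenvalue at
    ``tau_grid[i]``; ``projections[i]`` the matching n x K eigenvectors.
    ``tracks[i, r]`` assigns a continuity label: the curve id followed from
    the first grid point by maximal successive eigenvector overlap.
    """

    tau_grid: np.ndarray
    eigenvalues: np.ndarray  # (G, K)
    projections: np.ndarray  # (G, n, K)
    tracks: np.ndarray  # (G, K) int curve ids
    labels: dict  # curve id -> annotation string
    n: int
    d: int
    method: str
    n_samples: int
    seed: object
    tracked: bool = True


@dataclass(frozen=True)
class CriticalLags:
    """Lags of the abrupt projection changes.  ``first`` affects the rank-2
    projection, ``second`` the rank-1 projection (expected-curve detector);
    the single-walk detector reports them ordered by lag.  None = not found
    inside the scanned grid."""

    first: float | None
    second: float | None
    n: int
    d: int
    method: str
    metadata: dict = field(default_factory=dict)


@dataclass(frozen=True)
class PowerLawFit:
    """Least-squares power law tau* = a * n * d^b on log-log axes.

    The empirical square-root scaling of the first critical lag corresponds
    to b = -1/2 (tau* ~ n / sqrt(d)) with a of order 1."""

    a: float
    b: float
    d_range: tuple
    points: list
    n: int
    residuals: np.ndarray
    stderr_b: float


def _track(projections: np.ndarray) -> tuple[np.ndarray, bool]:
    """Assign curve ids across the grid by maximal |eigenvector overlap|."""
    G, _, K = projections.shape
    tracks = np.zeros((G, K), dtype=int)
    tracks[0] = np.arange(K)
    ok = True
    for i in range(1, G):
        O = np.abs(projections[i - 1].T @ projections[i])  # (K, K)
        if np.max(O) < 0.5:
            ok = False
        rows, cols = linear_sum_assignment(-O)
        for r, c in zip(rows, cols):
            tracks[i, c] = tracks[i - 1, r]
    if not ok:
        warnings.warn(
            "eigenvector overlap < 0.5 between neighbouring grid points; "
            "grid too coarse for continuity tracking",
            TrackingWarning,
        )
    return tracks, ok


def _label_curves(curves_vals: dict, tau_grid: np.ndarray, projections, tracks) -> dict:
    """Annotate each tracked curve as decreasing (period-2n/j cosines) or
    increasing (period tau*j cosine/sine pairs) from its eigenvalue trend."""
    labels = {}
    for cid, vals in curves_vals.items():
        vals = np.asarray(vals)
        if vals.size < 2:
            labels[cid] = "unclassified"
            continue
        rising = vals[-1] > vals[0]
        start_low = vals[0] < 0.5 * np.max(np.abs(vals))
        if rising and start_low:
            labels[cid] = "increasing (period ~ tau*j cosine/sine pair)"
        else:
            labels[cid] = "decreasing (period 2n/j cosine)"
    return labels


def eigenvalue_curves(
    n: int,
    d: int,
    tau_grid,
    method: str = "main",
    n_samples: int = 1000,
    seed: object = 0,
    K: int = 6,
    step_distribution: str = "gaussian",
) -> EigenvalueCurves:
    """Top-K eigenpairs of <M> on a lag grid, with continuity tracking.

    The same walk seeds are reused at every lag (common random numbers), so
    curves are smooth in tau up to the genuine crossings.  For the
    alternative method the whitening does not depend on tau and the walk
    sample is traversed only once.
    """
    _check_method(method)
    tau_grid = np.asarray(sorted(set(int(t) for t in np.asarray(tau_grid).ravel())))
    if tau_grid.size < 2:
        raise ValueError("tau_grid needs at least two points")
    if tau_grid[0] < 1 or tau_grid[-1] > n - 2:
        raise ValueError("tau_grid outside valid range [1, n-2]")
    seeds = _walk_seeds(seed, n_samples)
    evals_g = np.zeros((tau_grid.size, K))
    projs_g = np.zeros((tau_grid.size, n, K))
    Pm_shared = None
    if method == "alternative":
        Pm_shared = mean_P(n, d, tau_grid[0], method, seeds, step_distribution)
    for i, tau in enumerate(tau_grid):
        Pm = Pm_shared if Pm_shared is not None else mean_P(
            n, d, int(tau), method, seeds, step_distribution
        )
        A = build_weights(n, int(tau), method).A
        vals, Y = eig_PA(Pm, A, k=K)
        m = min(K, vals.size)
        evals_g[i, :m] = vals[:m]
        projs_g[i, :, :m] = Y[:, :m]
    tracks, ok = _track(projs_g)
    curves_vals: dict[int, list] = {}
    for i in range(tau_grid.size):
        for r in range(K):
            curves_vals.setdefault(int(tracks[i, r]), []).append(evals_g[i, r])
    labels = _label_curves(curves_vals, tau_grid, projs_g, tracks)
    return EigenvalueCurves(
        tau_grid=tau_grid, eigenvalues=evals_g, projections=projs_g,
        tracks=tracks, labels=labels, n=n, d=d, method=method,
        n_samples=n_samples, seed=seed, tracked=ok,
    )


def _rank_jumps(
    projections: np.ndarray, tau_grid: np.ndarray, ranks, threshold: float
) -> dict:
    """First grid lag at which each rank's eigenvector overlap with its
    predecessor drops below the threshold."""
    jumps = {}
    for r in ranks:
        jumps[r] = (None, None)
        for i in range(1, tau_grid.size):
            o = float(abs(projections[i - 1][:, r] @ projections[i][:, r]))
            if o < threshold:
                jumps[r] = (float(tau_grid[i]), o)
                break
    return jumps


def detect_critical_lags_expected(
    curves: EigenvalueCurves, threshold: float = OVERLAP_THRESHOLD
) -> CriticalLags:
    """Critical lags from precomputed expected curves (grid resolution).

    ``first`` is the jump of the rank-2 eigenvector (the earlier crossing),
    ``second`` that of the rank-1 eigenvector.  A crossing estimate from the
    tracked eigenvalue curves (linear interpolation at the order switch) is
    attached as metadata when available.
    """
    jumps = _rank_jumps(curves.projections, curves.tau_grid, (0, 1), threshold)
    second, o1 = jumps[0]
    first, o2 = jumps[1]
    meta = {
        "rank1_jump_overlap": o1,
        "rank2_jump_overlap": o2,
        "threshold": threshold,
        "tau_grid": curves.tau_grid.tolist(),
    }
    # eigenvalue-interpolated crossing for each detected order switch
    for name, rank in (("first", 1), ("second", 0)):
        tau_jump = first if name == "first" else second
        if tau_jump is None or not curves.tracked:
            continue
        i = int(np.searchsorted(curves.tau_grid, tau_jump))
        if i < 1:
            continue
        # curves occupying this rank before and after the switch
        cid_before = curves.tracks[i - 1, rank]
        cid_after = curves.tracks[i, rank]
        if cid_before == cid_after:
            continue
        r_before_after = np.flatnonzero(curves.tracks[i] == cid_before)
        r_after_before = np.flatnonzero(curves.tracks[i - 1] == cid_after)
        if r_before_after.size == 0 or r_after_before.size == 0:
            continue
        g1 = curves.eigenvalues[i - 1, rank] - curves.eigenvalues[i - 1, r_after_before[0]]
        g2 = curves.eigenvalues[i, r_before_after[0]] - curves.eigenvalues[i, rank]
        if g1 + g2 > 0:
            frac = g1 / (g1 + g2)
            meta[f"{name}_interpolated"] = float(
                curves.tau_grid[i - 1] + frac * (curves.tau_grid[i] - curves.tau_grid[i - 1])
            )
    return CriticalLags(
        first=first, second=second, n=curves.n, d=curves.d,
        method=curves.method, metadata=meta,
    )


def locate_critical_lags(
    n: int,
    d: int,
    method: str = "main",
    tau_min: int = 10,
    tau_max: int = 300,
    step: int = 10,
    n_samples: int = 1000,
    seed: object = 0,
    K: int = 6,
    refine: bool = True,
    step_distribution: str = "gaussian",
) -> CriticalLags:
    """Coarse expected-curve scan plus bisection refinement to lag step 1.

    Refinement recomputes the rank-r eigenvector of <M> (same walk seeds) at
    midpoint lags and bisects on the overlap-with-pre-jump-vector criterion,
    reporting the first integer lag past the crossing.
    """
    grid = np.arange(tau_min, tau_max + 1, step)
    curves = eigenvalue_curves(
        n, d, grid, method, n_samples=n_samples, seed=seed, K=K,
        step_distribution=step_distribution,
    )
    detected = detect_critical_lags_expected(curves)
    if not refine:
        return detected
    seeds = _walk_seeds(seed, n_samples)
    Pm_shared = None
    if method == "alternative":
        Pm_shared = mean_P(n, d, tau_min, method, seeds, step_distribution)

    def rank_vec(tau: int, rank: int) -> np.ndarray:
        Pm = Pm_shared if Pm_shared is not None else mean_P(
            n, d, tau, method, seeds, step_distribution
        )
        _, Y = eig_PA(Pm, build_weights(n, tau, method).A, k=rank + 1)
        return Y[:, rank]

    refined = {}
    for name, rank in (("first", 1), ("second", 0)):
        tau_jump = getattr(detected, name)
        if tau_jump is None:
            refined[name] = None
            continue
        hi = int(tau_jump)
        lo = hi - step
        i_lo = int(np.searchsorted(curves.tau_grid, lo))
        ref = curves.projections[i_lo][:, rank]
        while hi - lo > 1:
            mid = (hi + lo) // 2
            y_mid = rank_vec(mid, rank)
            if abs(float(ref @ y_mid)) >= detected.metadata["threshold"]:
                lo = mid
                ref = y_mid
            else:
                hi = mid
        refined[name] = float(hi)
    meta = dict(detected.metadata)
    meta["coarse_first"] = detected.first
    meta["coarse_second"] = detected.second
    return CriticalLags(
        first=refined["first"], second=refined["second"], n=n, d=d,
        method=method, metadata=meta,
    )


def detect_critical_lags_single(
    traj: Trajectory,
    tau_grid,
    method: str = "main",
    threshold: float = OVERLAP_THRESHOLD,
    stop_after: str = "second",
) -> CriticalLags:
    """Per-walk critical lags from one trajectory's own M eigenvectors.

    For each of the top-2 projections the jump lag is the first grid point
    where the absolute overlap with the previous grid point drops below the
    threshold; ``first``/``second`` are the earlier/later of the two.  With
    ``stop_after="first"`` the scan stops at the earliest jump (cheaper, used
    for the power-law experiments).
    """
    if stop_after not in ("first", "second"):
        raise ValueError("stop_after must be 'first' or 'second'")
    tau_grid = np.asarray(sorted(set(int(t) for t in np.asarray(tau_grid).ravel())))
    prev = None
    jumps: dict[int, float | None] = {0: None, 1: None}
    overlaps: dict[int, float] = {}
    for tau in tau_grid:
        md = build_M(traj, int(tau), method)
        Y = md.eigenvectors[:, :2]
        if Y.shape[1] < 2:
            raise ValueError("trajectory must support at least two projections")
        if prev is not None:
            for r in (0, 1):
                if jumps[r] is not None:
                    continue
                o = float(abs(prev[:, r] @ Y[:, r]))
                if o < threshold:
                    jumps[r] = float(tau)
                    overlaps[r] = o
        prev = Y
        found = [j for j in jumps.values() if j is not None]
        if stop_after == "first" and found:
            break
        if len(found) == 2:
            break
    found = sorted(j for j in jumps.values() if j is not None)
    first = found[0] if found else None
    second = found[1] if len(found) > 1 else None
    return CriticalLags(
        first=first, second=second, n=traj.n, d=traj.d, method=method,
        metadata={"jump_overlaps": overlaps, "threshold": threshold,
                  "rank_jumps": {r: jumps[r] for r in jumps}},
    )


def fit_power_law(points, n: int, d_range: tuple | None = None) -> PowerLawFit:
    """Least-squares fit of the n-normalized critical lag, tau/n = a * d^b.

    ``points`` is a sequence of (d, tau*) pairs; only d inside ``d_range``
    (inclusive) enter the fit.  At least 3 points are required.
    """
    pts = [(float(dd), float(tt)) for dd, tt in points]
    if d_range is not None:
        lo, hi = d_range
        pts = [(dd, tt) for dd, tt in pts if lo <= dd <= hi]
    else:
        d_range = (min(p[0] for p in pts), max(p[0] for p in pts)) if pts else (0, 0)
    if len(pts) < 3:
        raise ValueError("need at least 3 points inside d_range for a power-law fit")
    logd = np.log([p[0] for p in pts])
    logy = np.log([p[1] / n for p in pts])
    fit = linregress(logd, logy)
    residuals = logy - (fit.intercept + fit.slope * logd)
    return PowerLawFit(
        a=float(np.exp(fit.intercept)), b=float(fit.slope),
        d_range=tuple(d_range), points=pts, n=n,
        residuals=residuals, stderr_b=float(fit.stderr),
    )
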