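# ticawalk

**tICA projections of high-dimensional random walks — convergence and
effective-dimensionality diagnostics for MD-style trajectories.**

Time-lagged independent component analysis (tICA) is the standard dimension
reduction for building Markov state models from molecular dynamics: it
finds collective coordinates `v_k` whose projections
`y_k(t) = v_k · x(t)` have maximal autocorrelation at a chosen lag `tau`.
But a finite trajectory is partly noise, and noise alone produces richly
structured tICA projections.  `ticawalk` implements the null model — the
`d`-dimensional random walk of `n` steps in a flat energy landscape — and
the machinery to compute what tICA *of pure noise* looks like, so that real
trajectories can be compared against it:

* both finite-trajectory symmetrizations of the tICA generalized
  eigenproblem (`main`, whose eigenvalues are autocorrelations, and the
  `alternative` right-hand-side convention), solved by AMUSE whitening;
* the reformulation `M = X^T W W^T X A`, whose nonzero-eigenvalue
  eigenvectors *are* the tICA projections, and its ensemble average `<M>`
  over random walks — the "expected" projections for given `(n, d, tau)`.
  At small lags these are half-period cosines `cos(k pi t/n)` (main) or
  doubled-frequency sines (alternative);
* the `d = n` special case where the problem reduces to `B^-1 A`, with its
  circulant limit and analytic Fourier spectrum
  `lambda_k = cos(2 pi tau k/n)`;
* **critical lag times**: eigenvalue curves of `<M>` over a lag grid cross,
  the eigenvector order switches, and the projections change abruptly; the
  first critical lag scales as `tau* ~ n / sqrt(d)` (power-law fit
  `tau*/n = a d^b` included);
* diagnostics: cosine content of projections, similarity of a trajectory's
  projections to the random-walk expectation, and an operational
  "effective dimensionality" (the `d` maximizing that similarity).

A trajectory whose projections match the random-walk expectation is
unconverged — it carries no information about its free-energy landscape,
and apparent "clusters" in its projections are likely stochastic artifacts
rather than conformational substates.

## Worked example

```python
import numpy as np
import ticawalk as tw

# tICA of a random walk: the first projection is a half-period cosine
walk = tw.generate_random_walk(n=1000, d=50, seed=1)
res = tw.tica(walk, tau=10, method="main")
print(round(res.eigenvalues[0], 4))
print(round(tw.cosine_content(res.projections[:, 0], order=1).value, 3))

# expected projections of the random-walk ensemble (1000-walk average)
exp = tw.expected_M(1000, 50, tau=10, method="main", n_samples=1000, seed=1, k=2)
t = np.arange(1, 1001)
r = np.corrcoef(exp.projections[:, 0], np.cos(np.pi * t / 1000))[0, 1]
print(round(abs(r), 4))

# the abrupt change of the expected projections near tau ~ 110
lags = tw.locate_critical_lags(1000, 50, "main", tau_min=10, tau_max=200,
                               step=10, n_samples=1000, seed=101)
print(lags.first, lags.second)
```

prints

```
0.999
0.998
1.0
110.0 152.0
```

The first tICA eigenvalue of a single random walk at `tau=10` is an
autocorrelation close to 1; its first projection already has cosine content
0.998 — the signature of unconverged sampling.  The ensemble-averaged first
projection correlates with `cos(pi t/n)` to 4 digits.  The expected
projections change abruptly at the critical lags: the second projection at
`tau = 110`, the first at `tau ~ 152` (for `n=1000, d=50`).

The same operations are available from the shell:

```bash
ticawalk simulate --n 1000 --dim 50 --seed 1 --out walk.txt
ticawalk tica --input walk.txt --tau 10 --out out/walk
ticawalk expected --n 1000 --dim 50 --tau 10 --samples 1000 --seed 1 --out out/exp
ticawalk diagnose --input walk.txt --tau 100 --tau 200 \
    --d-candidates 20 --d-candidates 50 --d-candidates 100 --out report.json
```

User trajectories are plain delimited-text matrices, one frame per row
(`ticawalk.read_trajectory`); center before analysis.

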