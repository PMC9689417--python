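# wcusum — weighted CUSUM change-point tests

`wcusum` detects a single change in the mean of a time-ordered sample —
a univariate series or an n × q matrix whose rows are time points and
whose columns are replicates, spatial locations or pixels.  It is aimed
at settings where *prior knowledge about the change location* exists:
surveillance and epidemiological series where an emerging shift sits in
the recent past, video/imaging streams where an object arrives near the
start and departs near the end, and high-dimensional designs (many
replicates per time point) where the test operates on row means.

## The statistic

The weighted CUSUM statistic aggregates all candidate splits instead of
maximizing over them:

    S_n(Y; τ, γ) = Σ_{k=1}^{n-1} w_k(τ)^{-1} | Σ_{i≤k} (Y_i − Ȳ) |^γ,

with quadratic weights encoding the prior change location τ:

| weight            | formula        | favours changes |
|-------------------|----------------|-----------------|
| `left`   (τ = 0)  | (n + k)(n − k) | late (right tail of the series) |
| `center` (τ = n/2)| k(n − k)       | central (likelihood-ratio weighting) |
| `right`  (τ = n)  | k(2n − k)      | early (left tail of the series) |

For γ = 2 the statistic is a Gaussian quadratic form Y'QY and its exact
null distribution is a weighted sum of independent χ²(1) variables,

    S_n / σ² =d Σ_{k=1}^{n-1} λ_k(τ) Z_k²,
    λ_k = 1/(k(k+1))  (center),   λ_k = 1/(2k(2k+1))  (left, right),

the center case being the Anderson–Darling spectrum.  CDFs, p-values
and critical values are computed by Imhof's method (exact numerical
inversion of the characteristic function) with an asymptotic
integration-by-parts treatment of the oscillatory tail; the n = ∞
limits use the truncated Karhunen–Loève series.  The change point is
estimated by k̂ = argmax_k w_k^{-1/2} |Σ_{i≤k}(Y_i − Ȳ)|.

Variants: a **Poisson mixed-model** test (the saddle-point
approximation to the marginal likelihood reduces it to the weighted
CUSUM of log row means), a **graph-based** test (edge counts along a
heuristic shortest Hamiltonian path, calibrated exactly by
permutation), and a **self-normalized** test for weakly dependent
series (Shao–Zhang random norming, calibrated against Monte-Carlo
Brownian-bridge limits).  A simulation harness generates the standard
synthetic designs and estimates power.

## Worked example

```python
import numpy as np
from wcusum import WeightedCUSUM, SimConfig, generate

data = generate(SimConfig(n=40, q=50, k_star=20, delta=0.5, seed=7))
res = WeightedCUSUM(data, tau_kind="center").fit(level=0.05)
print(res.summary())
```

```
Weighted CUSUM change-point test
==============================================
variant                wc
n (time points)        40
q (replicates)         50
tau_kind               center
gamma                  2
statistic              12.1055
variance estimate      0.0872449
critical value (0.95)  2.46736
p-value                1.4954e-06
reject H0              True
changepoint estimate   20
==============================================
```

The simulated 40 × 50 matrix shifts its mean by 0.5 after row 20.  The
studentized statistic 12.1 far exceeds the exact n = 40 critical value
2.467 (p ≈ 1.5e-6), and the weighted partial-sum profile peaks at
k̂ = 20, recovering the true change point.  `res.plot()` draws that
profile.

The same functionality is exposed on the command line:

```bash
$ wcusum critval --tau center --n 20 --p 0.95
2.442
$ wcusum critval --tau left --n inf --p 0.95
0.798
$ wcusum test --input data.csv --tau left --level 0.05
$ wcusum graph-test --input data.csv --metric pseudo --gamma 2
$ wcusum power-sim --config sim.json --out report.csv
```

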