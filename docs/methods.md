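# Methods

## Model and hypotheses

The observations form an n × q matrix Y with rows indexed by time.  In
the baseline model the entries are independent with E(Y_ij) = μ_i and
common variance; the null hypothesis is μ_i ≡ μ and the alternative is
a single break, μ_i = μ− for i ≤ k* and μ+ for i > k*.  All tests act
on the row means Ȳ_i (q = 1 gives a plain series).  A mixed-model
reading — a shared latent effect per row inducing within-row
dependence — leads to the same row-mean statistic, which is why the
row-mean reduction is the canonical form here.

## The weighted CUSUM family

S_n(Y; τ, γ) = Σ_{k=1}^{n-1} w_k(τ)^{-1} |S_k|^γ with S_k the k-th
partial sum of the centred series.  The three quadratic weights are the
cases of w_k(τ) = −(k − τ)² + max{τ², (n − τ)²} at τ ∈ {0, n/2, n};
they also equal expected absorption times of a simple random walk.
The reciprocal weight acts like an inverse prior on the change
location: `left` (τ = 0) concentrates sensitivity on late changes,
`right` (τ = n) on early ones, `center` is the likelihood-ratio
weighting.  τ is stored categorically, so odd n needs no n/2
convention; the center formula k(n − k) is used verbatim for any n.

For γ = 2, S_n = Y'QY with n²Q = AA', column A_k having first k
entries p_k^{1/2}(n − k) and the rest −p_k^{1/2}k (p_k = 1/w_k).  Q is
PSD of rank n − 1 and annihilates constants; its nonzero eigenvalues
have the closed forms λ_k = 1/(k(k+1)) (center) and 1/(2k(2k+1))
(left/right), verified numerically to 1e−10 in the tests.  Growing n
appends one eigenvalue and keeps the rest, and the even-indexed center
eigenvalues coincide with the left spectrum.

## Null distribution numerics (Imhof inversion)

The null CDF of Σ λ_k Z_k² is computed as

F(x) = 1/2 − (1/π) ∫₀^∞ sin θ(u) / (u ρ(u)) du,
θ(u) = ½ Σ arctan(λ_k u) − xu/2,  log ρ(u) = ¼ Σ log(1 + λ_k²u²).

Numerical choices:

* **Adaptive quadrature** on (0, U] (`scipy.integrate.quad`,
  absolute tolerance 0.1·tol with tol = 1e−8 by default).
* **Oscillatory tail.**  The integrand envelope 1/(uρ(u)) decays like
  u^{−1−m/2} for m eigenvalues, which is too slow to truncate when m is
  small.  The tail ∫_U^∞ is therefore evaluated analytically by two
  integration-by-parts terms in the phase θ (boundary terms in
  cos θ·g/θ′ and sin θ·(g/θ′)′/θ′), and U is doubled until the
  remainder bound is below the tolerance.  This keeps a single
  eigenvalue accurate to ~1e−8 against the χ²(1) closed form while
  large spectra terminate at small U.
* **Large spectra.**  Eigenvalues with λ_k·u below 1e−4 enter θ and
  log ρ through their first-order expansions using precomputed suffix
  sums; the neglected cubic remainders are orders of magnitude below
  the quadrature tolerance.  This makes CDF evaluation on ~2·10⁵
  eigenvalues take milliseconds per integrand call.
* **Quantiles** by bracketing root-finding (`brentq`, |F(x) − p|
  driven to ~1e−8), with an optional bracket hint (used when walking
  the critical-value table across n).  The CLI prints critical values
  to 3 decimals.

**Infinite-sample limit.**  The limit spectrum is represented by its
first K terms plus a deterministic shift equal to the exactly known
tail mass (telescoping: 1/(K+1) for the center series; 1 − log 2 minus
the partial sum for left/right).  Replacing the tail by its expectation
neglects a centred fluctuation of standard deviation
√(2 Σ_{k>K} λ_k²); the truncation point is the smallest K driving that
below a user-visible `epsilon` (default 1e−8, K ≈ 1.9·10⁵ for the
center series), so the total distributional error of the
representation is O(epsilon).  A plain truncation with comparable
accuracy would need ~10⁸ terms.  The historical tabulation of the
limiting 0.975/0.99 quantiles (3.070, 3.850) disagrees with this
computation (3.077, 3.878), which continues the finite-n trend; the
package reports the computed values.

## Testing and estimation

The studentized test statistic is S_n(Ȳ; τ, 2)/σ̂² with
σ̂² = (n−1)^{−1} Σ (Ȳ_i − μ̂)², calibrated against the **exact
finite-n spectrum** rather than the series limit — the exact
calibration costs the same and converges to it.  A known-variance mode
(`sigma2=`) bypasses the plug-in.  Type-I error at n = 40 is within
±0.01 of the 5% level over 5000 replicates for all three weights, and
the known-variance statistic matches the Imhof CDF to KS < 0.025.

The change-point estimator maximizes w_k^{−1/2}|S_k|.  The absolute
value makes k̂ invariant to the direction of the shift (an argmax of
the signed sum would only track upward shifts); ties break to the
smallest k, so a constant series returns k = 1 and is flagged.  On a
noiseless step the criterion peaks exactly at k* for all three weights.

Degenerate inputs raise typed errors rather than returning NaN: a
constant series (σ̂² = 0), a Poisson series with zero row means, a
self-normalizer that vanishes against a nonzero numerator.

## Poisson mixed model

Counts with conditional mean exp(ρ_i + U_i), U_i ~ N(0, ν²).  The
marginal likelihood integral I(ρ; a, b, ν²) = ∫ exp(−be^u + au −
(u−ρ)²/2ν²) du has no closed form; a saddle-point (Laplace) expansion
around c = log(a/b) gives I ≈ (a/(be))^a √(2π/a) exp(−(c−ρ)²/2ν²),
accurate to <1% relative error already at a = 50 and improving with a
(verified against adaptive quadrature on the log scale).  Applied to
the likelihood ratio, the approximation reduces the test to the
weighted CUSUM of **log row means** with the same null spectrum.  The
implementation applies the transform directly; the saddle-point
integral is exposed for verification.  Zero row means are rejected
with the offending rows named — no silent continuity correction.

## Self-normalized variant (weak dependence)

For dependent series the long-run variance is replaced by the
Shao–Zhang random norming w_k: the within-segment CUSUM sums of
squares of the two candidate segments (forward term
Σ_{i≤k}{S_i − (i/k)S_k}², backward analogue on i > k; a displayed
version of this weight with (i/k) multiplying the *partial* sum to i is
an evident typo and the standard construction is used).  Both the
summed statistic Σ_k w_k^{−1}S_k'² and the max statistic
max_k (n/w_k)S_k'² are exactly location- and scale-invariant.  Their
pivotal limits — ∫ {B−tB(1)}²/(D₁+D₂) dt and its max analogue, with
D₁, D₂ the within-segment squared-bridge integrals — have no closed
form and are calibrated by Monte Carlo: a Brownian bridge discretized
on a 2000-point grid, 10⁵ replicates, seed 20221652, computed once per
process and cached (regenerating from code keeps results reproducible
without shipping tables).  Under AR(1) dependence (φ = 0.3, n = 200)
the empirical size is within ±0.02 of the 5% level.

## Graph-based variant

Rows become nodes with pairwise distances — `euclidean` on full rows
(sensitive to mean and variance changes) or the `pseudo` distance
|Ȳ_{i} − Ȳ_{j}| (mean changes only).  A short Hamiltonian path is
built by a deterministic heuristic: greedy edge insertion (edges sorted
by length with lexicographic tie-breaks, rejecting cycles and degree-3
nodes) followed by best-improvement 2-opt; exhaustive search is
NP-hard, and the heuristic is exact on collinear points and n = 3 and
never worse than the identity ordering in tests.  For each split k the
statistic uses the centred cross-edge count 2k(n−k)/n − C_P, whose
permutation-null mean and variance are the classical closed forms.

**Norming.**  Writing k = tn, the permutation variance of the centred
count grows like 2n·2t²(1−t)², which fixes the finite-sample norming
constants of the two statistics: √(n/2)·S_n for γ = 1 and S_n/2 for
γ = 2 put them on the scale of the Brownian-bridge functionals
∫{B−tB(1)}²ψ(t)dt + const (γ = 1; the constant −1 or log 2 − 1 makes
the mean zero) and ∫({B−tB(1)}² − t(1−t))²ψ(t)dt (γ = 2), with
ψ = 1/{t(1−t)}, 1/(1−t²), 1/{t(2−t)} for center/left/right.  These
constants were confirmed by simulation at n ∈ {100, 200, 400}.

**Calibration.**  Under the null the time labels are exchangeable
conditional on the path, so the *exact* null law of the statistic is
its permutation distribution — and by the combinatorial CLT the
centred count at each split is asymptotically normal.  The γ = 1
statistic is linear in the counts, so the bridge functional's first
two moments match the permutation null and the asymptotic calibration
is accurate (empirical size 2.6–3.3% at the 5% level).  The γ = 2
statistic depends on fourth moments, where the bridge-squared
functional is markedly heavier-tailed than the permutation null
(sd 0.72 vs 0.23 at the center weight); its asymptotic calibration is
therefore conservative (size ≈ 1%), and an affine location/scale
correction was evaluated and rejected because it overshoots the upper
tail (size ≈ 10%).  The default calibration is consequently the
**permutation null**, sampled exactly in O(n) per draw (2000 draws per
fit, or a cached 5000-draw universal sample in the power harness); the
asymptotic option remains available and is documented as conservative
for γ = 2.

## Synthetic data and the power harness

The generators emulate the standard simulation designs, and their
defaults are the study conditions: n = 40, q = 50, change at k* = n/2,
magnitude Δ = 0.2, 200 replicates at level 0.05.

* `normal_shift`: i.i.d. N(0,1), post-change mean Δ.
* `normal_mixture`: post-change two-component normal mixture with unit
  variances; the two canonical settings (weights (0.5, 0.5), means
  (0, 0.2)) and ((0.8, 0.2), (0, 1)) imply mean shifts 0.1 and 0.2
  with inflated variance.
* `poisson_mixed`: per-row latent U_i ~ N(0, ν²), counts conditionally
  Poisson(exp(ρ_i + U_i)); ρ steps at k*.
* `ar1_weakdep`: columns follow a stationary AR(1) in time (a linear
  process, hence weakly dependent), optional mean shift.
* `image_sequence`: n noise frames (h × w, flattened to q pixels) with
  a bright Gaussian blob present on frames (k1, k2], k1 ≈ 0.1n and
  k2 ≈ 0.9n by default — an object arriving early and departing late.
  The right weight applied to a prefix of the frames locates the
  arrival; the left weight on the full sequence locates the departure.

The harness derives replicate r's generator from
`SeedSequence(seed, spawn_key=(r,))`, so serial and parallel runs
agree, and evaluates every requested method on the same data within a
replicate (common random numbers), which makes method comparisons
low-variance.  Weighted CUSUM tests use exact critical values computed
once per (n, τ); graph tests use the cached permutation null.

What the generators deliberately do **not** emulate: real video
(codecs, illumination drift, moving small distractors), heavy-tailed
or serially dependent replicate noise within rows, and multiple
changes beyond the two-change image fixture.  Passing tests show
correct calibration and power under these idealized designs, not
performance on arbitrary real data.

## Known limitations

* Weights are restricted to τ ∈ {0, n/2, n}; intermediate τ (n/4,
  3n/4) have no recursive eigenvalue structure and are out of scope.
* One change point per test invocation (the image fixture is analysed
  by windowing); no segmentation wrapper is provided.
* The exact null calibration assumes (approximately) normal row means
  with independent rows; under strong dependence use the
  self-normalized variant.
* The γ = 2 graph test's asymptotic calibration is conservative (see
  above); the default permutation calibration avoids this.
* Q is built densely (O(n²) memory): fine for series lengths in the
  thousands, not for n ≫ 10⁴ — while critical values themselves are
  computed from the closed-form spectrum and remain cheap up to
  n = 10⁴ and beyond.
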