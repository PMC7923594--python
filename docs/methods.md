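# Methods

## The estimator

Given forecast–outcome pairs (xᵢ, yᵢ), i = 1..n, with xᵢ ∈ [0, 1] and
yᵢ ∈ {0, 1}, the package first aggregates by unique forecast value:
z₁ < … < z_k, issued n_j times with o_j events.  The CEP estimate is
the weighted isotonic least-squares fit of the frequencies o_j/n_j with
weights n_j, computed by a single left-to-right pool-adjacent-violators
pass: each value starts as its own block, and a block is merged with
its left neighbour while the neighbour's mean is not strictly below
(within 1e-12, which also canonicalises exact ties).  Each pooled value
is the block's event frequency, so the fit is also the isotonic
Bernoulli maximum-likelihood estimate.  The pass is O(k) after the
O(n log n) aggregation sort.

Ties in the forecast values are merged *before* the PAV pass, which
makes the fit order-independent.  Per-case recalibrated probabilities
x̂ᵢ are obtained by exact lookup of the fitted value at xᵢ; linear
interpolation between unique values is purely a display convention of
the diagram and never feeds back into scores or bands.

## Score decompositions

For a scoring rule S, the mean scores of the original forecasts (S̄ₓ),
of the PAV-recalibrated forecasts (S̄_C), and of the constant marginal
event frequency ȳ (S̄_R) give MCB = S̄ₓ − S̄_C, DSC = S̄_R − S̄_C,
UNC = S̄_R, and the identity S̄ₓ = MCB − DSC + UNC holds by
construction.  Nonnegativity of MCB and DSC follows from the PAV fit's
optimality among isotonic recalibrations (both the identity map on the
forecast values and the constant ȳ are feasible candidates).  Shipped
rules: Brier (x − y)²; logarithmic −y log x − (1 − y) log(1 − x) with
the 0·log 0 = 0 convention, so a wrong certain forecast scores +inf and
the infinity propagates through means and components rather than being
clipped; misclassification error with penalty ½ at x = ½ exactly.
Strict propriety is carried as metadata only.

The classical Murphy decomposition (REL, RES, UNC = ȳ(1 − ȳ)) is
computed from the raw value-wise frequencies.  When those frequencies
are nondecreasing the PAV fit leaves them untouched and MCB = REL,
DSC = RES under the Brier score; the test suite asserts this on
constructed instances, and the toy example in the tests shows the
inequality in the violating case.

## Diagram conventions

Discrete versus continuous display is decided by the smallest gap
between distinct forecast values: gaps of 0.01 or larger (plus a 1e-12
float tolerance so a nominal gap of exactly 0.01 is not misclassified
by binary rounding) mean discrete.  The discrete marginal is a
per-value bar chart; the continuous marginal is a histogram with the
Freedman–Diaconis width h = 2·IQR·n^(−1/3) (linear-interpolation
quantiles), bins anchored at 0 with a final right-closed bin ending at
1; a zero IQR falls back to a single bin spanning the data range.
Diagrams are plain serialisable objects (JSON round-trip asserted);
matplotlib rendering is optional and cannot affect numerical content.
Inset components are displayed at 3 decimals, stored at full precision.

## Uncertainty bands

Resampling (default B = 1000): outcomes are redrawn as independent
Bernoulli draws with success probability xᵢ (consistency) or x̂ᵢ
(confidence).  Because outcomes within one unique value are
exchangeable, the redraw reduces to one binomial per unique value,
and the refitted PAV curves are computed with a vectorised row-wise
PAV kernel (numba-accelerated when available, with an equivalent pure
Python fallback).  The band is the pointwise (1 ± γ)/2 empirical
quantile envelope (linear interpolation, no recentering) at the unique
forecast values, reproducible by seed.  Pointwise quantiles of isotonic
curves are themselves isotonic, and bands at nested levels computed
from the same seed nest.

Discrete asymptotics: under calibration the frequency at z_j is a
scaled Binomial(n_j, z_j), and the band is z_j ± Φ⁻¹((1+γ)/2)·
sqrt(z_j(1−z_j)/n_j), clipped to [0, 1].  This is a deliberate
simplification of the exact normal-mixture limit of the isotonic
estimator; since isotonic pooling can only reduce variance below the
unpooled binomial standard error, the approximation errs on the wide
side, and the coverage simulations below confirm accurate-to-slightly-
conservative behaviour.

Continuous asymptotics: the isotonic estimation error at x, magnified
by n^(1/3), converges to (4·x(1−x)·c′/q(x))^(1/3) · Z with c′ the CEP
slope, q the marginal forecast density and Z Chernoff's distribution
(argmax over t of W(t) − t², W two-sided standard Brownian motion).
The consistency band plugs in c′ = 1 (the calibration hypothesis) and
the Freedman–Diaconis histogram estimate q̂; points with q̂ = 0 are
reported as gaps (NaN).  Chernoff quantiles are computed once by Monte
Carlo — 10⁵ paths on a |t| ≤ 2 grid with step 0.01, fixed internal
seed, sample symmetrised about 0 — and cached; the 97.5% point matches
the published value 0.998 to two decimals, and a finer-grid run agrees
to 0.01.  Both asymptotic constructions are consistency-only: the
confidence default is resampling throughout, since the asymptotic
route would require a strictly increasing true CEP.

Method selection (defaults): consistency bands use resampling when
n ≤ 1000, or when n ≤ 5000 and n ≤ 50k; otherwise discrete asymptotics
when n ≥ 8k², else continuous asymptotics.  Bands are evaluated at the
unique forecast values and interpolated only for display.

Coverage semantics: a consistency band is checked against the fitted
curve (under calibration, the estimated diagram should leave the band
around the diagonal with probability 1 − γ), a confidence band against
the true CEP.  Checking the diagonal against a consistency band would
be vacuous — the discrete-asymptotic band is centred on the diagonal by
construction.

## Synthetic scenarios

The generators emulate calibrated forecasts with three marginals on
[0, 1]: uniform; linear with density 0.4 + 1.2x (sampled by inverse
CDF); and a 3/4 Beta(1, 10) + 1/4 uniform mixture that piles forecasts
near zero as rare-event predictions do.  Discrete variants place mass
p_j ∝ q(x_j) on x_j = (2j−1)/(2k).  Outcomes are Bernoulli(cep(x)) with
cep the identity by default; an arbitrary cep function can be supplied
to study miscalibrated regimes, but no specific miscalibrated shape is
built in.  Everything is reproducible from a single seed via spawned
child seeds.

What the generators do *not* emulate: serial dependence (forecast
archives are time series; all theory here assumes exchangeable cases),
covariate-driven heterogeneity, and estimated-versus-issued forecast
distinctions.  Passing coverage/efficiency tests therefore certify the
method under independent sampling only.

## Experiment design and problem sizes

Band coverage: 200 replicates per cell at level 0.9, with cells chosen
so every default construction is exercised — resampling (uniform k=10
n=500; beta-mix k=20 n=900; uniform k=10 n=1024 and linear continuous
n=1024 for confidence), discrete asymptotics (linear k=10 n=2000), and
continuous asymptotics (uniform and linear continuous n=10000).
Acceptance window 0.85–0.98 around the nominal 0.9, reflecting Monte
Carlo noise plus the deliberately conservative approximations.

Estimation efficiency: three families × supports {k=10, k=50,
continuous} × n ∈ {128, 256, 512, 1024}, 200 replicates; competitors
are fixed equidistant bins (m = 5, 10, 50) and quantile bins with
m(n) = ⌊n^α⌋, α ∈ {1/6, 1/3, 1/2} (⌊·⌋ with a 1e-9 guard against float
dust, so e.g. n = 1000, α = 1/3 gives 10 bins).  Errors are squared
differences between estimated and true CEP, averaged over the sampled
forecast values — which weights accuracy by the forecast's own
marginal — then over replicates; bins are half-open with the last bin
right-closed, bin estimates use bin-averaged forecast abscissae, and
empty bins contribute no evaluation points.

Decay rates: the continuous-case slope of log MSE versus log n is
measured on the n ∈ {128..1024} grid (expected −2/3, the cube-root-
regression rate).  The discrete k = 10 slope is measured on
n ∈ {2048..16384}: the parametric n^(−1) rate applies once per-value
standard errors are small against the 0.1 support gap so that isotonic
pooling no longer merges distinct values, and at n ≤ 1024 the estimator
is still visibly in the pooled regime (measured slope ≈ −0.75 there).
Rates are measured under the uniform family, the canonical setting for
the rate analysis.

## Numerical choices and edge cases

Block means are merged within 1e-12; calibration checks use the same
tolerance.  Degenerate inputs: a constant forecast yields one block at
ȳ (DSC = 0); x ≡ 0 or 1 yields zero-width resampling bands; samples
must be nonempty with x ∈ [0, 1] and y ∈ {0, 1}, violations reported
with the offending index (or file row for CSV input).  Quantile-bin
breaks use half-open intervals so ties fall upward.  All display
rounding is 3 decimals; stored artifacts keep full precision.

## Known limitations

The asymptotic band constructions are documented approximations (plain
binomial-normal in place of the exact mixture limit; plug-in slope and
histogram density in the Chernoff band), validated empirically by the
coverage experiments rather than derived exactly.  The logarithmic
score can produce infinite components on degenerate recalibrations,
which is faithful to the rule's definition but means log-score
decompositions of perfectly separated samples are not finite.
Dependent data, real-valued outcomes (mean/quantile/expectile
recalibration), Murphy diagrams and ROC analysis are out of scope.
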