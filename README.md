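# corpcal

Calibration assessment for probabilistic classifiers: reliability
diagrams with automatically chosen, provably optimal bins, exact
proper-score decompositions, and uncertainty bands.

## The problem

A probabilistic classifier assigns a predictive probability x ∈ [0, 1]
to a binary event y ∈ {0, 1} — rain tomorrow, disease onset, loan
default.  It is *calibrated* (reliable) when, among all cases with a
given forecast value, the observed event frequency matches that value.
The classical diagnostic is the reliability diagram: bin the forecast
values, plot the bin-wise event frequency against the bin-average
forecast, and compare to the diagonal.  That approach is notoriously
unstable — moving from 9 to 11 equidistant bins can change the picture
drastically — and the instability propagates into the numeric
reliability measures built on it.

`corpcal` replaces ad-hoc binning with nonparametric isotonic
regression.  The pool-adjacent-violators (PAV) algorithm estimates the
conditional event probability (CEP)

    ĉ = argmin_{c nondecreasing} Σ_j n_j (c_j − o_j/n_j)²

over the k unique forecast values z₁ < … < z_k issued n₁, …, n_k times
with o₁, …, o_k events.  The level sets of ĉ are the bins: their number
and position are determined by the data, with no tuning parameters, and
the fit is simultaneously the isotonic least-squares and the isotonic
maximum-likelihood estimate, optimal in finite samples under every
proper scoring rule subject to monotonicity.

Any mean proper score S̄ₓ = (1/n) Σᵢ S(xᵢ, yᵢ) then decomposes exactly as

    S̄ₓ = MCB − DSC + UNC

with MCB = S̄ₓ − S̄_C (miscalibration: excess penalty of the original
forecasts over their PAV-recalibrated versions x̂ᵢ), DSC = S̄_R − S̄_C
(discrimination: improvement of x̂ over the constant marginal event
frequency ȳ), and UNC = S̄_R (the difficulty of the prediction problem).
Because x̂ and ȳ are both calibrated, MCB ≥ 0 and DSC ≥ 0 for every
proper rule — no counterintuitive negative components.  Under the Brier
score S(x, y) = (x − y)², when the value-wise frequencies o_j/n_j are
already nondecreasing, MCB and DSC coincide with the classical Murphy
reliability (REL) and resolution (RES) terms.

Uncertainty is quantified by *consistency bands* (how much would the
curve wiggle around the diagonal if the forecast were calibrated?) and
*confidence bands* (frequentist coverage of the true CEP around the
estimate), via outcome resampling in small samples and via n^(1/2)
(discrete) or n^(1/3) Chernoff-limit (continuous) asymptotics in large
ones.

## Worked example

```python
from corpcal import ReliabilityModel, Scenario, sample_scenario

# 400 calibrated forecasts on the 10-point grid 0.05, 0.15, ..., 0.95,
# drawn with a linearly increasing marginal density
s = sample_scenario(Scenario(family="linear", n=400, k=10), seed=7)

res = ReliabilityModel(s.x, s.y, name="simulated").fit(
    bands="consistency", level=0.9, seed=7
)
print(res.summary())
```

```
CORP Reliability Analysis
==============================================
forecast:                 simulated
observations:             400
unique forecast values:   10
setting:                  discrete
bins (isotonic blocks):   9
event frequency:          0.640
----------------------------------------------
score decomposition (brier)
  mean score              0.162
  MCB (miscalibration)    0.005
  DSC (discrimination)    0.073
  UNC (uncertainty)       0.230
----------------------------------------------
band:                     consistency (resampling), level 0.9
==============================================
```

The forecasts are calibrated by construction, and the decomposition
says so: of the mean Brier score 0.162, essentially nothing (MCB =
0.005) is attributable to miscalibration; the forecast earns a
discrimination credit DSC = 0.073 against the base-rate score UNC =
0.230, and 0.162 = 0.005 − 0.073 + 0.230 exactly.  The ten forecast
values were pooled into nine bins; e.g. the values 0.35 and 0.45 were
merged into one bin with pooled event frequency 0.394 (71 cases), the
diagram's way of flagging that the sample cannot tell those two values
apart:

```python
res.plot()                          # reliability diagram + 90% band
res.diagram().to_json()             # the same content, serialisable
res.decomposition("log")            # any proper rule: brier, log, misclassification
res.murphy_decomposition()          # classical REL / RES / UNC
```

The same analysis runs from the shell on a CSV with an outcome column
and one or more forecast columns:

```sh
corpcal decompose forecasts.csv --outcome obs --score brier
corpcal diagram forecasts.csv --bands consistency --level 0.9 --seed 7 --out diagram.json
corpcal simulate --experiment mse --family uniform --k 10 --seed 1
```

The worked meteorological example used throughout the documentation
(92 probability-of-precipitation forecasts at Niamey, Niger, 2016,
four forecasting systems) is publicly deposited; run
`python scripts/fetch_niamey.py` (network required) to place it under
`data/`, after which the corresponding golden tests run and
`corpcal decompose data/precip_Niamey_2016.csv --outcome obs`
reproduces the published decomposition table.

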