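"""Uncertainty quantification for the CORP reliability curve.

Two kinds of bands are offered.  Consistency bands are computed under
the hypothesis that the forecasts are calibrated and are positioned
around the diagonal: they answer "how much would the diagram wiggle if
the forecast were perfect?".  Confidence bands cluster around the
estimated curve and carry the usual frequentist coverage
interpretation for the true CEP.

Three constructions are available, with the default selected from the
sample size n and the number k of unique forecast values:

* resampling — redraw the outcomes from Bernoulli(x_i) (consistency)
  or Bernoulli(x_hat_i) (confidence), refit the PAV curve each time,
  and take pointwise percentiles;
* discrete asymptotics — in the discrete setting the estimation error
  at a unique value shrinks at the n^(1/2) rate; we use the plain
  binomial-normal approximation z_j +/- q * sqrt(z_j(1-z_j)/n_j),
  an approximation to the exact normal-mixture limit that the coverage
  simulations show to be accurate to slightly conservative;
* continuous asymptotics — with continuously distributed forecasts the
  error shrinks at the n^(1/3) rate and, suitably scaled, follows
  Chernoff's distribution (the argmax of two-sided Brownian motion
  minus a parabola); the band plugs a Freedman-Diaconis density
  estimate and unit CEP slope (the calibration hypothesis) into that
  limit.  Chernoff quantiles are obtained once by Monte Carlo path
  maximisation and cached.

Defaults: consistency bands use resampling when n <= 1000, or when
n <= 5000 and n <= 50 k; otherwise discrete asymptotics when
n >= 8 k^2, else continuous asymptotics.  Confidence bands use
resampling throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.stats import norm

from .diagram import fd_histogram
from .pav import PairedSample, AggregatedSample, aggregate, pav_fit, _pav_means

__all__ = [
    "Band",
    "select_method",
    "compute_band",
    "resample_band",
    "discrete_asymptotic_band",
    "continuous_asymptotic_band",
    "chernoff_quantile",
]

CONSISTENCY = "consistency"
CONFIDENCE = "confidence"

RESAMPLING = "resampling"
DISCRETE_ASYMPTOTIC = "discrete_asymptotic"
CONTINUOUS_ASYMPTOTIC = "continuous_asymptotic"

DEFAULT_RESAMPLES = 1000


# ---------------------------------------------------------------------------
# fast row-wise PAV for resampling


def _pav_rows_py(freqs: np.ndarray, weights: np.ndarray) -> np.ndarray:
    out = np.empty_like(freqs)
    for b in range(freqs.shape[0]):
        means, _, sizes = _pav_means(freqs[b], weights)
        out[b] = np.repeat(means, sizes)
    return out


def _pav_rows_impl(freqs, weights):  # pragma: no cover - numba-compiled twin
    nrow, k = freqs.shape
    out = np.empty((nrow, k))
    means = np.empty(k)
    wts = np.empty(k)
    sizes = np.empty(k, dtype=np.int64)
    for b in range(nrow):
        top = -1
        for j in range(k):
            top += 1
            means[top] = freqs[b, j]
            wts[top] = weights[j]
            sizes[top] = 1
            while top > 0 and means[top - 1] >= means[top] - 1e-12:
                w = wts[top - 1] + wts[top]
                means[top - 1] = (
                    wts[top - 1] * means[top - 1] + wts[top] * means[top]
                ) / w
                wts[top - 1] = w
                sizes[top - 1] += sizes[top]
                top -= 1
        pos = 0
        for t in range(top + 1):
            for _ in range(sizes[t]):
                out[b, pos] = means[t]
                pos += 1
    return out


try:  # optional acceleration; the pure-python path is equivalent
    from numba import njit

    _pav_rows = njit(cache=False)(_pav_rows_impl)
except Exception:  # pragma: no cover
    _pav_rows = _pav_rows_py


@dataclass(frozen=True)
class Band:
    """Pointwise lower/upper envelope at the unique forecast values."""

    band_type: str
    method: str
    level: float
    z: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    n_resamples: Optional[int] = None
    seed: Optional[int] = None

    def to_dict(self) -> dict:
        return {
            "band_type": self.band_type,
            "method": self.method,
            "level": self.level,
            "z": np.asarray(self.z).tolist(),
            "lower": np.asarray(self.lower).tolist(),
            "upper": np.asarray(self.upper).tolist(),
            "n_resamples": self.n_resamples,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Band":
        return cls(
            band_type=d["band_type"],
            method=d["method"],
            level=d["level"],
            z=np.asarray(d["z"], dtype=float),
            lower=np.asarray(d["lower"], dtype=float),
            upper=np.asarray(d["upper"], dtype=float),
            n_resamples=d.get("n_resamples"),
            seed=d.get("seed"),
        )


def select_method(n: int, k: int, band_type: str) -> str:
    """Default band construction for a sample with n cases, k unique values."""
    if band_type == CONFIDENCE:
        return RESAMPLING
    if band_type != CONSISTENCY:
        raise ValueError(f"unknown band type {band_type!r}")
    if n <= 1000 or (n <= 5000 and n <= 50 * k):
        return RESAMPLING
    if n >= 8 * k * k:
        return DISCRETE_ASYMPTOTIC
    return CONTINUOUS_ASYMPTOTIC


def resample_band(
    sample: PairedSample,
    band_type: str,
    level: float = 0.9,
    n_resamples: int = DEFAULT_RESAMPLES,
    seed: Optional[int] = None,
) -> Band:
    """Pointwise percentile band from resampled PAV curves.

    Outcomes are redrawn as independent Bernoulli variables with
    success probability x_i (consistency: the calibration hypothesis)
    or the PAV-recalibrated x_hat_i (confidence); the PAV curve is
    refitted on each replicate and the band is the pointwise empirical
    (1-level)/2 and (1+level)/2 quantile envelope at the unique
    forecast values.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    if band_type not in (CONSISTENCY, CONFIDENCE):
        raise ValueError(f"unknown band type {band_type!r}")
    agg = aggregate(sample)
    if band_type == CONSISTENCY:
        p = agg.z
    else:
        p = pav_fit(agg).cep_hat
    rng = np.random.default_rng(seed)
    counts = agg.counts
    # outcomes within one unique value are exchangeable, so the y* draw
    # reduces to a binomial per unique value
    events = rng.binomial(counts[None, :], p[None, :], size=(n_resamples, agg.k))
    freqs = events / counts
    curves = _pav_rows(np.ascontiguousarray(freqs, dtype=float), counts.astype(float))
    alpha = (1.0 - level) / 2.0
    lower, upper = np.quantile(curves, [alpha, 1.0 - alpha], axis=0)
    return Band(
        band_type=band_type,
        method=RESAMPLING,
        level=level,
        z=agg.z,
        lower=np.clip(lower, 0.0, 1.0),
        upper=np.clip(upper, 0.0, 1.0),
        n_resamples=n_resamples,
        seed=seed,
    )


def discrete_asymptotic_band(
    agg: AggregatedSample, band_type: str = CONSISTENCY, level: float = 0.9
) -> Band:
    """Normal-approximation consistency band for discrete forecasts.

    Under calibration the event frequency at value z_j is a scaled
    Binomial(n_j, z_j), so the band is z_j +/- Phi^{-1}((1+level)/2)
    times the binomial standard error, clipped to [0, 1].  Deterministic.
    """
    if band_type != CONSISTENCY:
        raise ValueError("asymptotic bands are implemented for consistency bands only")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    q = norm.ppf((1.0 + level) / 2.0)
    hw = q * np.sqrt(agg.z * (1.0 - agg.z) / agg.counts)
    return Band(
        band_type=band_type,
        method=DISCRETE_ASYMPTOTIC,
        level=level,
        z=agg.z,
        lower=np.clip(agg.z - hw, 0.0, 1.0),
        upper=np.clip(agg.z + hw, 0.0, 1.0),
    )


def continuous_asymptotic_band(
    sample: PairedSample, band_type: str = CONSISTENCY, level: float = 0.9
) -> Band:
    """Chernoff-limit consistency band for continuous forecasts.

    At forecast value x the isotonic estimation error, magnified by
    n^(1/3), converges to (4 x (1-x) c' / q(x))^(1/3) times a Chernoff
    variate, where c' is the CEP slope (1 under the calibration
    hypothesis) and q the marginal forecast density, estimated here by
    the Freedman-Diaconis histogram.  Points where the density estimate
    vanishes get NaN bounds (a gap in the band).
    """
    if band_type != CONSISTENCY:
        raise ValueError("asymptotic bands are implemented for consistency bands only")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    agg = aggregate(sample)
    hist = fd_histogram(sample.x)
    qhat = hist.density_at(agg.z)
    qc = chernoff_quantile((1.0 + level) / 2.0)
    n = sample.n
    with np.errstate(divide="ignore", invalid="ignore"):
        hw = n ** (-1.0 / 3.0) * (4.0 * agg.z * (1.0 - agg.z) / qhat) ** (1.0 / 3.0) * qc
    hw = np.where(qhat > 0.0, hw, np.nan)
    return Band(
        band_type=band_type,
        method=CONTINUOUS_ASYMPTOTIC,
        level=level,
        z=agg.z,
        lower=np.clip(agg.z - hw, 0.0, 1.0),
        upper=np.clip(agg.z + hw, 0.0, 1.0),
    )


# ---------------------------------------------------------------------------
# Chernoff's distribution: argmax_t { W(t) - t^2 }

_CHERNOFF_SEED = 20210217
_chernoff_cache: dict = {}


def _chernoff_samples(
    n_paths: int = 100_000, t_max: float = 2.0, dt: float = 0.01, seed: int = _CHERNOFF_SEED
) -> np.ndarray:
    """Monte Carlo draws of the Chernoff argmax location.

    Two-sided Brownian motion is simulated on a grid of step ``dt`` up
    to ``|t| <= t_max`` and the argmax of W(t) - t^2 is located per
    path.  The sample is symmetrised (the law is symmetric about 0)
    and cached per parameter set.
    """
    key = (n_paths, t_max, dt, seed)
    if key in _chernoff_cache:
        return _chernoff_cache[key]
    rng = np.random.default_rng(seed)
    steps = int(round(t_max / dt))
    t = np.arange(steps + 1) * dt
    drift = t**2
    out = np.empty(n_paths)
    chunk = 10_000
    sqdt = np.sqrt(dt)
    for start in range(0, n_paths, chunk):
        m = min(chunk, n_paths - start)
        best_val = np.zeros(m)  # t = 0 gives W - t^2 = 0
        best_t = np.zeros(m)
        for sign in (1.0, -1.0):
            w = np.cumsum(rng.standard_normal((m, steps)) * sqdt, axis=1)
            proc = w - drift[1:]
            idx = np.argmax(proc, axis=1)
            val = proc[np.arange(m), idx]
            better = val > best_val
            best_val = np.where(better, val, best_val)
            best_t = np.where(better, sign * t[1:][idx], best_t)
        out[start : start + m] = best_t
    out = np.concatenate([out, -out])
    _chernoff_cache[key] = out
    return out


def chernoff_quantile(p: float, **mc_kwargs) -> float:
    """Quantile of Chernoff's distribution, symmetric about zero."""
    if not 0.0 < p < 1.0:
        raise ValueError("p must be in (0, 1)")
    samples = _chernoff_samples(**mc_kwargs)
    return float(np.quantile(samples, p))


# ---------------------------------------------------------------------------


def compute_band(
    sample: PairedSample,
    band_type: str = CONSISTENCY,
    level: float = 0.9,
    method: str = "auto",
    n_resamples: int = DEFAULT_RESAMPLES,
    seed: Optional[int] = None,
) -> Band:
    """Compute a band using the default method-selection rules.

    ``method`` may be "auto", "resampling", "discrete" or "continuous".
    """
    agg = aggregate(sample)
    aliases = {
        "discrete": DISCRETE_ASYMPTOTIC,
        "continuous": CONTINUOUS_ASYMPTOTIC,
        RESAMPLING: RESAMPLING,
        DISCRETE_ASYMPTOTIC: DISCRETE_ASYMPTOTIC,
        CONTINUOUS_ASYMPTOTIC: CONTINUOUS_ASYMPTOTIC,
    }
    if method == "auto":
        method = select_method(sample.n, agg.k, band_type)
    elif method in aliases:
        method = aliases[method]
    else:
        raise ValueError(f"unknown band method {method!r}")
    if method == RESAMPLING:
        return resample_band(sample, band_type, level, n_resamples, seed)
    if method == DISCRETE_ASYMPTOTIC:
        return discrete_asymptotic_band(agg, band_type, level)
    return continuous_asymptotic_band(sample, band_type, level)
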