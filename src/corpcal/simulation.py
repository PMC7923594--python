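"""Synthetic forecast-outcome scenarios and experiment harnesses.

The generators produce calibrated probability forecasts with one of
three marginal distributions on [0, 1]:

* uniform — density q(x) = 1;
* linear — linearly increasing density q(x) = 0.4 + 1.2 x (ordinates
  0.4 at x=0 and 1.6 at x=1);
* beta_mix — a mixture of Beta(1, 10) and Uniform components with
  weights 3/4 and 1/4, concentrating forecasts near zero the way rare
  events do.

Each family comes in a continuous version and discretised versions
with k unique values x_j = (2j-1)/(2k) attained with probability
p_j proportional to q(x_j).  Outcomes are drawn under calibration,
y_i ~ Bernoulli(cep(x_i)) with cep the identity by default, so the
true CEP curve is the diagonal.

Two experiment harnesses reproduce the package's headline claims on
synthetic data: `coverage_experiment` measures empirical pointwise
coverage of the uncertainty bands under calibration, and
`mse_experiment` compares the estimation accuracy of the PAV-based CEP
estimate against classical binning and counting with fixed or
quantile-based bins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .bands import compute_band
from .pav import PairedSample, aggregate, pav_fit

__all__ = [
    "Scenario",
    "FAMILIES",
    "density",
    "sample_scenario",
    "FixedBins",
    "QuantileBins",
    "BinnedCEP",
    "binning_counting_cep",
    "corp_cep",
    "coverage_experiment",
    "mse_experiment",
]

FAMILIES = ("uniform", "linear", "beta_mix")

_BETA_A, _BETA_B = 1.0, 10.0
_BETA_WEIGHT = 0.75


def density(family: str, x) -> np.ndarray:
    """Marginal forecast density q(x) of a scenario family on [0, 1]."""
    x = np.asarray(x, dtype=float)
    if family == "uniform":
        return np.ones_like(x)
    if family == "linear":
        return 0.4 + 1.2 * x
    if family == "beta_mix":
        return _BETA_WEIGHT * stats.beta.pdf(x, _BETA_A, _BETA_B) + (1.0 - _BETA_WEIGHT)
    raise ValueError(f"unknown family {family!r}; choose from {FAMILIES}")


@dataclass(frozen=True)
class Scenario:
    """A forecast-generating scenario.

    ``k=None`` means continuously distributed forecasts; a positive
    integer k discretises the family onto (2j-1)/(2k), j=1..k.  ``cep``
    maps forecast values to true conditional event probabilities; the
    default identity yields calibrated forecasts.
    """

    family: str
    n: int
    k: Optional[int] = None
    cep: Optional[Callable[[np.ndarray], np.ndarray]] = None

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {FAMILIES}")
        if self.k is not None and self.k < 1:
            raise ValueError("k must be a positive integer or None")
        if self.n < 1:
            raise ValueError("n must be >= 1")

    @property
    def support(self) -> str:
        return "continuous" if self.k is None else f"k={self.k}"

    def true_cep(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return x if self.cep is None else np.asarray(self.cep(x), dtype=float)


def _draw_continuous(family: str, n: int, rng: np.random.Generator) -> np.ndarray:
    u = rng.random(n)
    if family == "uniform":
        return u
    if family == "linear":
        # CDF F(x) = 0.4 x + 0.6 x^2 inverted in closed form
        return (-0.4 + np.sqrt(0.16 + 2.4 * u)) / 1.2
    beta = rng.beta(_BETA_A, _BETA_B, size=n)
    unif = rng.random(n)
    return np.where(rng.random(n) < _BETA_WEIGHT, beta, unif)


def discrete_support(family: str, k: int):
    """Support points x_j = (2j-1)/(2k) and probabilities p_j ~ q(x_j)."""
    j = np.arange(1, k + 1)
    xj = (2 * j - 1) / (2 * k)
    q = density(family, xj)
    return xj, q / q.sum()


def sample_scenario(scenario: Scenario, seed=None) -> PairedSample:
    """Draw a forecast-outcome sample from a scenario, reproducibly."""
    rng = np.random.default_rng(seed)
    if scenario.k is None:
        x = _draw_continuous(scenario.family, scenario.n, rng)
    else:
        xj, pj = discrete_support(scenario.family, scenario.k)
        x = rng.choice(xj, size=scenario.n, p=pj)
    y = (rng.random(scenario.n) < scenario.true_cep(x)).astype(float)
    return PairedSample(x=x, y=y)


# ---------------------------------------------------------------------------
# binning-and-counting CEP estimators


@dataclass(frozen=True)
class FixedBins:
    """m equidistant bins partitioning [0, 1]."""

    m: int

    def edges(self, x: np.ndarray) -> np.ndarray:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        return np.linspace(0.0, 1.0, self.m + 1)

    @property
    def label(self) -> str:
        return f"fixed_m{self.m}"


@dataclass(frozen=True)
class QuantileBins:
    """m(n) = floor(n^alpha) bins bracketed by empirical quantiles."""

    alpha: float

    @staticmethod
    def n_bins(n: int, alpha: float) -> int:
        # guard against floating-point dust, e.g. 1000**(1/3) = 9.99...
        return max(1, int(np.floor(n**alpha + 1e-9)))

    def edges(self, x: np.ndarray) -> np.ndarray:
        m = self.n_bins(x.size, self.alpha)
        inner = np.quantile(x, np.arange(1, m) / m)
        return np.concatenate([[0.0], inner, [1.0]])

    @property
    def label(self) -> str:
        return f"quantile_a{self.alpha:g}"


@dataclass(frozen=True)
class BinnedCEP:
    """Step-function CEP estimate from binning and counting.

    ``freqs[j]`` is the event frequency in bin j (NaN when empty) and
    ``abscissae[j]`` the bin-averaged forecast value, the natural
    plotting position of the step.
    """

    edges: np.ndarray
    freqs: np.ndarray
    abscissae: np.ndarray

    def predict(self, x) -> np.ndarray:
        """Estimate at points ``x``: the frequency of the containing bin."""
        x = np.asarray(x, dtype=float)
        idx = np.clip(np.searchsorted(self.edges, x, side="right") - 1, 0, len(self.freqs) - 1)
        return self.freqs[idx]


def binning_counting_cep(sample: PairedSample, scheme) -> BinnedCEP:
    """Classical reliability-diagram estimate with a prespecified binning.

    Bins are half-open [e_{j-1}, e_j) with the last bin right-closed;
    ties at quantile bin breaks therefore fall into the upper bin, and
    bins left empty by ties simply contribute no estimate.
    """
    edges = scheme.edges(sample.x)
    idx = np.clip(np.searchsorted(edges, sample.x, side="right") - 1, 0, len(edges) - 2)
    m = len(edges) - 1
    counts = np.bincount(idx, minlength=m).astype(float)
    events = np.bincount(idx, weights=sample.y, minlength=m)
    xsums = np.bincount(idx, weights=sample.x, minlength=m)
    with np.errstate(invalid="ignore"):
        freqs = np.where(counts > 0, events / np.maximum(counts, 1), np.nan)
        absc = np.where(counts > 0, xsums / np.maximum(counts, 1), np.nan)
    return BinnedCEP(edges=edges, freqs=freqs, abscissae=absc)


def corp_cep(sample: PairedSample) -> np.ndarray:
    """PAV-based CEP estimate evaluated at the sampled forecast values."""
    from .pav import calibrate

    return calibrate(sample)


# ---------------------------------------------------------------------------
# experiment harnesses


def _child_seeds(seed, count: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=count)


def coverage_experiment(
    cells: Sequence[dict],
    replicates: int = 200,
    level: float = 0.9,
    n_resamples: int = 1000,
    seed=None,
) -> pd.DataFrame:
    """Empirical pointwise band coverage under calibrated scenarios.

    Each cell is a dict with keys ``family``, ``k`` (None for
    continuous), ``n`` and ``band_type``.  Per replicate a calibrated
    sample is drawn and a band computed with the default method
    selection.  Consistency bands are checked against the fitted PAV
    curve (under calibration, the curve should stay inside a band
    positioned around the diagonal), confidence bands against the true
    CEP.  Coverage is the fraction of covered (replicate, unique
    forecast value) pairs, averaged equally over the forecast values;
    band gaps (undefined density points) are excluded from the average.
    """
    rows = []
    cell_seeds = _child_seeds(seed, len(cells))
    for cell, cell_seed in zip(cells, cell_seeds):
        scen = Scenario(family=cell["family"], n=cell["n"], k=cell.get("k"))
        band_type = cell["band_type"]
        rep_seeds = _child_seeds(cell_seed, 2 * replicates).reshape(replicates, 2)
        total = 0.0
        methods = set()
        for draw_seed, band_seed in rep_seeds:
            sample = sample_scenario(scen, seed=int(draw_seed))
            band = compute_band(
                sample,
                band_type=band_type,
                level=level,
                method="auto",
                n_resamples=n_resamples,
                seed=int(band_seed),
            )
            methods.add(band.method)
            if band_type == "consistency":
                target = pav_fit(aggregate(sample)).cep_hat
            else:
                target = scen.true_cep(band.z)
            ok = ~(np.isnan(band.lower) | np.isnan(band.upper))
            tol = 1e-12
            covered = (band.lower[ok] - tol <= target[ok]) & (
                target[ok] <= band.upper[ok] + tol
            )
            total += covered.mean()
        rows.append(
            {
                "family": scen.family,
                "support": scen.support,
                "n": scen.n,
                "band_type": band_type,
                "level": level,
                "replicates": replicates,
                "method": "+".join(sorted(methods)),
                "coverage": total / replicates,
            }
        )
    return pd.DataFrame(rows)


def _estimators(estimator_specs):
    ests = []
    for spec in estimator_specs:
        if spec == "corp":
            ests.append(("corp", None))
        elif spec[0] == "fixed":
            ests.append((f"fixed_m{spec[1]}", FixedBins(spec[1])))
        elif spec[0] == "quantile":
            ests.append((f"quantile_a{spec[1]:g}", QuantileBins(spec[1])))
        else:
            raise ValueError(f"unknown estimator spec {spec!r}")
    return ests


DEFAULT_ESTIMATORS = (
    "corp",
    ("fixed", 5),
    ("fixed", 10),
    ("fixed", 50),
    ("quantile", 1 / 6),
    ("quantile", 1 / 3),
    ("quantile", 1 / 2),
)


def mse_experiment(
    scenarios: Sequence[Scenario],
    n_grid: Sequence[int],
    estimators=DEFAULT_ESTIMATORS,
    replicates: int = 200,
    seed=None,
) -> pd.DataFrame:
    """Mean squared CEP-estimation error of competing estimators.

    For each (scenario, n, estimator) the squared difference between
    the estimated and the true CEP is averaged over the sampled
    forecast values of the replicate, then over replicates.  The
    sampled-value evaluation weights accuracy by the forecast's own
    marginal distribution.
    """
    ests = _estimators(estimators)
    rows = []
    cell_seeds = _child_seeds(seed, len(scenarios) * len(n_grid))
    i = 0
    for scen in scenarios:
        for n in n_grid:
            s = Scenario(family=scen.family, n=int(n), k=scen.k, cep=scen.cep)
            rep_seeds = _child_seeds(cell_seeds[i], replicates)
            i += 1
            sums = {name: 0.0 for name, _ in ests}
            for rs in rep_seeds:
                sample = sample_scenario(s, seed=int(rs))
                truth = s.true_cep(sample.x)
                for name, scheme in ests:
                    if scheme is None:
                        est = corp_cep(sample)
                    else:
                        est = binning_counting_cep(sample, scheme).predict(sample.x)
                    sums[name] += float(np.mean((est - truth) ** 2))
            for name, _ in ests:
                rows.append(
                    {
                        "family": s.family,
                        "support": s.support,
                        "n": int(n),
                        "estimator": name,
                        "replicates": replicates,
                        "mse": sums[name] / replicates,
                    }
                )
    return pd.DataFrame(rows)


def loglog_slope(df: pd.DataFrame, estimator: str = "corp") -> float:
    """OLS slope of log MSE against log n for one estimator."""
    sub = df[df["estimator"] == estimator]
    if sub["n"].nunique() < 2:
        raise ValueError("need at least two sample sizes for a slope")
    return float(np.polyfit(np.log(sub["n"]), np.log(sub["mse"]), 1)[0])
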