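"""Nonparametric isotonic estimation of conditional event probabilities.

The estimator at the heart of the CORP approach: aggregate probability
forecasts by unique value, then run the pool-adjacent-violators (PAV)
algorithm on the per-value event frequencies, weighted by the number of
times each value was issued.  The result is simultaneously the isotonic
weighted least-squares fit and the isotonic maximum-likelihood estimate
of the conditional event probability (CEP) as a nondecreasing function
of the forecast value.  Its level sets ("blocks") are the automatically
chosen bins of the CORP reliability diagram.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PairedSample",
    "AggregatedSample",
    "Block",
    "IsotonicFit",
    "aggregate",
    "pav_fit",
    "calibrate",
]

#: blocks whose means differ by less than this are merged, keeping the
#: block structure canonical in the presence of floating-point ties
_MERGE_TOL = 1e-12


@dataclass(frozen=True)
class PairedSample:
    """A sample of probability forecasts paired with binary outcomes.

    Parameters
    ----------
    x : ndarray
        Predictive probabilities, all in [0, 1].
    y : ndarray
        Binary outcomes, all in {0, 1}.
    """

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if x.ndim != 1 or y.ndim != 1:
            raise ValueError("x and y must be one-dimensional")
        if x.size != y.size:
            raise ValueError(
                f"length mismatch: {x.size} forecasts vs {y.size} outcomes"
            )
        if x.size == 0:
            raise ValueError("empty sample")
        bad = np.flatnonzero(~((x >= 0.0) & (x <= 1.0)))
        if bad.size:
            raise ValueError(
                f"forecast out of [0, 1] at index {bad[0]}: x[{bad[0]}] = {x[bad[0]]}"
            )
        bad = np.flatnonzero(~((y == 0.0) | (y == 1.0)))
        if bad.size:
            raise ValueError(
                f"outcome not in {{0, 1}} at index {bad[0]}: y[{bad[0]}] = {y[bad[0]]}"
            )

    @property
    def n(self) -> int:
        return self.x.size

    @property
    def event_rate(self) -> float:
        """Marginal event frequency, the reference forecast of the decomposition."""
        return float(self.y.mean())


@dataclass(frozen=True)
class AggregatedSample:
    """Forecasts aggregated by unique value.

    ``z`` holds the k strictly increasing unique forecast values, issued
    ``counts[j]`` times with ``events[j]`` observed events each.
    """

    z: np.ndarray
    counts: np.ndarray
    events: np.ndarray

    def __post_init__(self):
        z = np.asarray(self.z, dtype=float)
        counts = np.asarray(self.counts, dtype=np.int64)
        events = np.asarray(self.events, dtype=np.int64)
        object.__setattr__(self, "z", z)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "events", events)
        if not (z.size == counts.size == events.size):
            raise ValueError("z, counts and events must have equal length")
        if z.size == 0:
            raise ValueError("empty aggregation")
        if np.any(np.diff(z) <= 0):
            raise ValueError("z must be strictly increasing")
        if np.any(counts < 1):
            raise ValueError("counts must be positive")
        if np.any((events < 0) | (events > counts)):
            raise ValueError("events must satisfy 0 <= events <= counts")

    @property
    def k(self) -> int:
        return self.z.size

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def frequencies(self) -> np.ndarray:
        """Per-value empirical event frequencies o_j / n_j."""
        return self.events / self.counts


@dataclass(frozen=True)
class Block:
    """A level set of the isotonic fit: indices [start, stop) over z."""

    start: int
    stop: int
    value: float
    weight: float


@dataclass(frozen=True)
class IsotonicFit:
    """PAV-calibrated probabilities per unique forecast value."""

    z: np.ndarray
    cep_hat: np.ndarray
    blocks: tuple = field(default_factory=tuple)

    @property
    def k(self) -> int:
        return self.z.size


def aggregate(sample: PairedSample) -> AggregatedSample:
    """Group a paired sample by unique forecast value.

    Returns the strictly increasing unique values with their issue
    counts and event counts; the result does not depend on the order of
    the input pairs.
    """
    z, inverse, counts = np.unique(sample.x, return_inverse=True, return_counts=True)
    events = np.bincount(inverse, weights=sample.y, minlength=z.size)
    return AggregatedSample(z=z, counts=counts, events=events.astype(np.int64))


def _pav_means(values: np.ndarray, weights: np.ndarray):
    """Classical stack-based PAV pass.

    Left to right, push each (value, weight) as a block and merge while
    the preceding block's mean is not strictly below the new block's
    mean (within ``_MERGE_TOL``).  Returns parallel arrays of block
    means, block weights and block sizes; linear in the number of
    values.
    """
    k = values.size
    means = np.empty(k)
    wts = np.empty(k)
    sizes = np.empty(k, dtype=np.int64)
    top = -1
    for j in range(k):
        top += 1
        means[top] = values[j]
        wts[top] = weights[j]
        sizes[top] = 1
        while top > 0 and means[top - 1] >= means[top] - _MERGE_TOL:
            w = wts[top - 1] + wts[top]
            means[top - 1] = (wts[top - 1] * means[top - 1] + wts[top] * means[top]) / w
            wts[top - 1] = w
            sizes[top - 1] += sizes[top]
            top -= 1
    return means[: top + 1], wts[: top + 1], sizes[: top + 1]


def pav_fit(agg: AggregatedSample) -> IsotonicFit:
    """Weighted isotonic regression of the per-value event frequencies.

    Minimises sum_j n_j (c_j - o_j/n_j)^2 over nondecreasing c; the
    pooled value of each block is its empirical event frequency
    (sum of events) / (sum of counts), so the fit is also the isotonic
    maximum-likelihood estimate under the Bernoulli likelihood.
    """
    means, wts, sizes = _pav_means(agg.frequencies, agg.counts.astype(float))
    cep_hat = np.repeat(means, sizes)
    blocks = []
    start = 0
    for m, w, s in zip(means, wts, sizes):
        blocks.append(Block(start=start, stop=start + int(s), value=float(m), weight=float(w)))
        start += int(s)
    return IsotonicFit(z=agg.z, cep_hat=np.clip(cep_hat, 0.0, 1.0), blocks=tuple(blocks))


def calibrate(sample: PairedSample) -> np.ndarray:
    """PAV-recalibrated probability for every case in the sample.

    Each x_i is mapped to the fitted CEP at its own unique forecast
    value (exact lookup, no interpolation), so the returned vector is a
    nondecreasing function of x_i.
    """
    z, inverse = np.unique(sample.x, return_inverse=True)
    counts = np.bincount(inverse)
    events = np.bincount(inverse, weights=sample.y)
    agg = AggregatedSample(z=z, counts=counts, events=events.astype(np.int64))
    fit = pav_fit(agg)
    return fit.cep_hat[inverse]
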