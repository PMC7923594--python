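from pathlib import Path

import numpy as np
import pytest

from corpcal import PairedSample

REPO_ROOT = Path(__file__).resolve().parents[1]
NIAMEY_CSV = REPO_ROOT / "data" / "precip_Niamey_2016.csv"


@pytest.fixture
def toy_sample() -> PairedSample:
    """Four forecasts with one adjacent violator pair in the middle."""
    return PairedSample(x=np.array([0.2, 0.4, 0.6, 0.8]), y=np.array([0.0, 1.0, 0.0, 1.0]))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20210217)


def random_paired_sample(rng, n=None, discrete_prob=0.5, miscalibrate=True):
    """A random sample: mixed discrete/continuous forecasts, arbitrary CEP."""
    if n is None:
        n = int(rng.integers(2, 40))
    if rng.random() < discrete_prob:
        k = int(rng.integers(1, 9))
        support = np.sort(rng.random(k))
        x = rng.choice(support, size=n)
    else:
        x = rng.random(n)
    if miscalibrate:
        a, b = rng.random(2)
        p = np.clip(a + (b - a) * x + 0.3 * np.sin(6 * x), 0, 1)
    else:
        p = x
    y = (rng.random(n) < p).astype(float)
    return PairedSample(x=x, y=y)


def brute_force_isotonic(values, weights):
    """Exact weighted isotonic least squares by partition enumeration.

    Every isotonic fit is piecewise constant on contiguous blocks with
    the block value equal to the weighted block mean; enumerating all
    2^(k-1) contiguous partitions and keeping the feasible (nondecreasing
    pooled means) one with the smallest weighted SSE is therefore an
    exact, PAV-independent oracle for small k.
    """
    values = np.asarray(values, float)
    weights = np.asarray(weights, float)
    k = values.size
    best_sse, best_fit = np.inf, None
    for mask in range(1 << (k - 1)):
        # bit j set => cut between j and j+1
        cuts = [0] + [j + 1 for j in range(k - 1) if mask >> j & 1] + [k]
        means = []
        for a, b in zip(cuts[:-1], cuts[1:]):
            means.append(np.average(values[a:b], weights=weights[a:b]))
        if any(m2 < m1 for m1, m2 in zip(means, means[1:])):
            continue
        fit = np.concatenate(
            [np.full(b - a, m) for (a, b), m in zip(zip(cuts[:-1], cuts[1:]), means)]
        )
        sse = float(np.sum(weights * (fit - values) ** 2))
        if sse < best_sse - 1e-15:
            best_sse, best_fit = sse, fit
    return best_fit
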