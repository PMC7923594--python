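"""Proper scoring rules and the CORP score decomposition.

A proper scoring rule S(x, y) penalises a probability forecast x for a
binary outcome y such that the true event probability minimises the
expected penalty.  The mean score of a sample decomposes exactly as

    S_X = MCB - DSC + UNC

where MCB = S_X - S_C measures miscalibration (excess penalty of the
original forecasts over their PAV-recalibrated counterparts),
DSC = S_R - S_C measures discrimination (improvement of the
recalibrated forecasts over the constant marginal event frequency), and
UNC = S_R is the mean score of that constant reference forecast.  With
the PAV recalibration and the marginal event frequency as reference,
MCB and DSC are guaranteed nonnegative under every proper rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .pav import AggregatedSample, PairedSample, aggregate, calibrate

__all__ = [
    "ScoringRule",
    "BRIER",
    "LOG",
    "MISCLASSIFICATION",
    "get_rule",
    "mean_score",
    "is_calibrated",
    "Decomposition",
    "MurphyDecomposition",
    "corp_decompose",
    "murphy_decompose",
]


@dataclass(frozen=True)
class ScoringRule:
    """A penalty function S(x, y) >= 0 with propriety metadata."""

    name: str
    penalty: Callable[[np.ndarray, np.ndarray], np.ndarray]
    strictly_proper: bool

    def __call__(self, x, y):
        return self.penalty(np.asarray(x, dtype=float), np.asarray(y, dtype=float))


def _brier(x, y):
    return (x - y) ** 2


def _log(x, y):
    # 0*log 0 = 0 convention: zero penalty for a correct certain
    # forecast, +inf for a wrong one.
    with np.errstate(divide="ignore"):
        lx = np.log(x)
        l1x = np.log1p(-x)
    out = np.where(y == 1.0, -lx, -l1x)
    return out


def _misclassification(x, y):
    wrong = ((x < 0.5) & (y == 1.0)) | ((x > 0.5) & (y == 0.0))
    return np.where(x == 0.5, 0.5, wrong.astype(float))


BRIER = ScoringRule("brier", _brier, strictly_proper=True)
LOG = ScoringRule("log", _log, strictly_proper=True)
MISCLASSIFICATION = ScoringRule("misclassification", _misclassification, strictly_proper=False)

_RULES = {r.name: r for r in (BRIER, LOG, MISCLASSIFICATION)}


def get_rule(name) -> ScoringRule:
    if isinstance(name, ScoringRule):
        return name
    try:
        return _RULES[name]
    except KeyError:
        raise ValueError(
            f"unknown scoring rule {name!r}; choose from {sorted(_RULES)}"
        ) from None


def mean_score(sample: PairedSample, forecasts, rule="brier") -> float:
    """Mean penalty of ``forecasts`` against the sample's outcomes.

    +inf is propagated for the logarithmic score when a certain
    forecast is wrong.
    """
    rule = get_rule(rule)
    forecasts = np.asarray(forecasts, dtype=float)
    if forecasts.size != sample.n:
        raise ValueError(
            f"length mismatch: {forecasts.size} forecasts vs sample of size {sample.n}"
        )
    return float(np.mean(rule(forecasts, sample.y)))


def is_calibrated(agg: AggregatedSample, tol: float = 1e-12) -> bool:
    """Whether each unique forecast value equals its event frequency."""
    return bool(np.all(np.abs(agg.z - agg.frequencies) <= tol))


@dataclass(frozen=True)
class Decomposition:
    """Exact mean-score decomposition S_X = MCB - DSC + UNC."""

    score_name: str
    S_X: float
    S_C: float
    S_R: float
    mcb: float
    dsc: float
    unc: float
    reference: float

    def to_dict(self) -> dict:
        return {
            "score": self.score_name,
            "mean_score": self.S_X,
            "MCB": self.mcb,
            "DSC": self.dsc,
            "UNC": self.unc,
            "reference": self.reference,
        }

    def __str__(self):
        return (
            f"{self.score_name}: S={self.S_X:.3f}  MCB={self.mcb:.3f}  "
            f"DSC={self.dsc:.3f}  UNC={self.unc:.3f}"
        )


@dataclass(frozen=True)
class MurphyDecomposition:
    """Classical Brier-score decomposition S_X = REL - RES + UNC."""

    rel: float
    res: float
    unc: float


def corp_decompose(sample: PairedSample, rule="brier") -> Decomposition:
    """CORP decomposition of the mean score of a sample.

    The recalibrated forecasts are the PAV-transformed probabilities,
    the reference forecast is the marginal event frequency; both are
    calibrated by construction, which is what makes MCB and DSC
    nonnegative for every proper scoring rule.
    """
    rule = get_rule(rule)
    x_hat = calibrate(sample)
    r = sample.event_rate
    s_x = mean_score(sample, sample.x, rule)
    s_c = mean_score(sample, x_hat, rule)
    s_r = mean_score(sample, np.full(sample.n, r), rule)
    return Decomposition(
        score_name=rule.name,
        S_X=s_x,
        S_C=s_c,
        S_R=s_r,
        mcb=s_x - s_c,
        dsc=s_r - s_c,
        unc=s_r,
        reference=r,
    )


def murphy_decompose(sample: PairedSample) -> MurphyDecomposition:
    """Murphy's reliability/resolution/uncertainty Brier decomposition.

    REL and RES are computed from the per-unique-value event
    frequencies; when those frequencies happen to be nondecreasing the
    terms coincide with the CORP MCB and DSC under the Brier score.
    """
    agg = aggregate(sample)
    n = agg.n
    freq = agg.frequencies
    ybar = agg.events.sum() / n
    rel = float(np.sum(agg.counts * (freq - agg.z) ** 2) / n)
    res = float(np.sum(agg.counts * (freq - ybar) ** 2) / n)
    return MurphyDecomposition(rel=rel, res=res, unc=float(ybar * (1.0 - ybar)))
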