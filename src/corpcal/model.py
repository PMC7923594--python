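"""Model/results interface for CORP calibration assessment.

`ReliabilityModel` holds a sample of probability forecasts and binary
outcomes; `fit()` runs the PAV isotonic regression (and, optionally, an
uncertainty band) and returns a `ReliabilityResults` object carrying
the estimated CEP curve, the automatically chosen bins, the score
decompositions, and `summary()` / `plot()` / `to_json()` accessors.

Example
-------
>>> import numpy as np
>>> from corpcal import ReliabilityModel
>>> model = ReliabilityModel([0.2, 0.4, 0.6, 0.8], [0, 1, 0, 1])
>>> res = model.fit()
>>> res.decomposition("brier").mcb
0.075
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from . import bands as _bands
from .diagram import (
    ReliabilityDiagram,
    build_discrimination_diagram,
    build_reliability_diagram,
    detect_setting,
    plot_discrimination_diagram,
    plot_reliability_diagram,
)
from .pav import PairedSample, aggregate, calibrate, pav_fit
from .scores import (
    Decomposition,
    MurphyDecomposition,
    corp_decompose,
    get_rule,
    is_calibrated,
    murphy_decompose,
)

__all__ = ["ReliabilityModel", "ReliabilityResults"]


class ReliabilityModel:
    """Calibration model for one forecaster against binary outcomes.

    Parameters
    ----------
    forecasts : array-like
        Predictive probabilities in [0, 1].
    outcomes : array-like
        Binary outcomes in {0, 1}.
    name : str
        Label used in summaries and serialised artifacts.
    """

    def __init__(self, forecasts, outcomes, name: str = "forecast"):
        self.sample = PairedSample(x=np.asarray(forecasts, dtype=float),
                                   y=np.asarray(outcomes, dtype=float))
        self.name = name

    @classmethod
    def from_dataframe(cls, df, forecast: str, outcome: str, name: Optional[str] = None):
        """Build a model from two columns of a DataFrame."""
        return cls(df[forecast].to_numpy(), df[outcome].to_numpy(),
                   name=name or forecast)

    @property
    def nobs(self) -> int:
        return self.sample.n

    def fit(
        self,
        bands: Optional[str] = None,
        level: float = 0.9,
        band_method: str = "auto",
        n_resamples: int = _bands.DEFAULT_RESAMPLES,
        seed: Optional[int] = None,
    ) -> "ReliabilityResults":
        """Fit the PAV recalibration and optionally a band.

        Parameters
        ----------
        bands : {"consistency", "confidence", None}
            Which uncertainty band to attach, if any.
        level : float
            Nominal band coverage in (0, 1).
        band_method : {"auto", "resampling", "discrete", "continuous"}
            Band construction; "auto" applies the sample-size defaults.
        n_resamples : int
            Bootstrap replicates for resampling bands.
        seed : int, optional
            Seed for the resampling; recorded in the band.
        """
        agg = aggregate(self.sample)
        fit = pav_fit(agg)
        band = None
        if bands is not None:
            band = _bands.compute_band(
                self.sample,
                band_type=bands,
                level=level,
                method=band_method,
                n_resamples=n_resamples,
                seed=seed,
            )
        return ReliabilityResults(self, agg, fit, band)


class ReliabilityResults:
    """Fitted CORP recalibration with diagnostics.

    Attributes
    ----------
    unique_forecasts : ndarray
        The k strictly increasing unique forecast values z_j.
    cep : ndarray
        PAV-calibrated probability at each unique value.
    calibrated : ndarray
        Per-case recalibrated probabilities x_hat_i.
    blocks : tuple of Block
        Level sets of the isotonic fit (the automatic bins).
    setting : str
        "discrete" or "continuous" display setting.
    band : Band or None
    """

    def __init__(self, model: ReliabilityModel, agg, isofit, band):
        self.model = model
        self.sample = model.sample
        self.agg = agg
        self.isotonic_fit = isofit
        self.band = band
        self.unique_forecasts = isofit.z
        self.cep = isofit.cep_hat
        self.blocks = isofit.blocks
        self.setting = detect_setting(agg)

    @property
    def nobs(self) -> int:
        return self.sample.n

    @property
    def calibrated(self) -> np.ndarray:
        return calibrate(self.sample)

    @property
    def is_calibrated(self) -> bool:
        """Whether every forecast value equals its event frequency exactly."""
        return is_calibrated(self.agg)

    def decomposition(self, rule="brier") -> Decomposition:
        """CORP decomposition S_X = MCB - DSC + UNC under a scoring rule."""
        return corp_decompose(self.sample, rule)

    def murphy_decomposition(self) -> MurphyDecomposition:
        """Classical Murphy Brier-score decomposition (REL, RES, UNC)."""
        return murphy_decompose(self.sample)

    def diagram(self, rule="brier") -> ReliabilityDiagram:
        diag = build_reliability_diagram(self.sample, rule=rule)
        return ReliabilityDiagram(
            curve_x=diag.curve_x, curve_y=diag.curve_y, setting=diag.setting,
            bins=diag.bins, marginal=diag.marginal, inset=diag.inset,
            n=diag.n, band=self.band,
        )

    def discrimination_diagram(self, rule="brier") -> ReliabilityDiagram:
        diag = build_discrimination_diagram(self.sample, rule=rule)
        return ReliabilityDiagram(
            curve_x=diag.curve_x, curve_y=diag.curve_y, setting=diag.setting,
            bins=diag.bins, marginal=diag.marginal, inset=diag.inset,
            n=diag.n, band=self.band, extra_histograms=diag.extra_histograms,
        )

    def plot(self, ax=None, rule="brier"):
        return plot_reliability_diagram(self.diagram(rule), ax=ax)

    def plot_discrimination(self, rule="brier"):
        return plot_discrimination_diagram(self.discrimination_diagram(rule))

    def to_json(self, rule="brier", **kwargs) -> str:
        return self.diagram(rule).to_json(**kwargs)

    def summary(self, rule="brier") -> str:
        """Plain-text summary of the fit and its score decomposition."""
        dec = self.decomposition(rule)
        rule = get_rule(rule)
        lines = [
            "CORP Reliability Analysis",
            "=" * 46,
            f"{'forecast:':<26}{self.model.name}",
            f"{'observations:':<26}{self.nobs}",
            f"{'unique forecast values:':<26}{self.agg.k}",
            f"{'setting:':<26}{self.setting}",
            f"{'bins (isotonic blocks):':<26}{len(self.blocks)}",
            f"{'event frequency:':<26}{self.sample.event_rate:.3f}",
            "-" * 46,
            f"score decomposition ({rule.name})",
            f"{'  mean score':<26}{dec.S_X:.3f}",
            f"{'  MCB (miscalibration)':<26}{dec.mcb:.3f}",
            f"{'  DSC (discrimination)':<26}{dec.dsc:.3f}",
            f"{'  UNC (uncertainty)':<26}{dec.unc:.3f}",
        ]
        if self.band is not None:
            lines += [
                "-" * 46,
                f"{'band:':<26}{self.band.band_type} ({self.band.method}), "
                f"level {self.band.level:g}",
            ]
        lines.append("=" * 46)
        return "\n".join(lines)

    def __repr__(self):
        return (
            f"<ReliabilityResults: {self.model.name}, n={self.nobs}, "
            f"k={self.agg.k}, {len(self.blocks)} bins>"
        )
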