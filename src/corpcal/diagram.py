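"""Assembly of CORP reliability and discrimination diagrams.

A diagram is first and foremost a plain, serialisable data object: the
PAV curve (points at unique forecast values, linearly interpolated in
between), the automatically chosen bins (the level sets of the isotonic
fit), a marginal summary of the forecast distribution, and an inset
with the score decomposition.  Rendering to matplotlib is a separate,
optional step and never influences the numerical content.

Two display settings are distinguished.  If the smallest gap between
distinct forecast values is at least 0.01 the forecast is treated as
discrete and the marginal is a per-value bar chart; otherwise it is
treated as continuous and the marginal is a histogram with the
Freedman-Diaconis bin width 2*IQR*n^(-1/3).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .pav import PairedSample, AggregatedSample, IsotonicFit, aggregate, pav_fit
from .scores import Decomposition, corp_decompose, get_rule

__all__ = [
    "DISCRETE",
    "CONTINUOUS",
    "detect_setting",
    "Histogram",
    "fd_histogram",
    "ReliabilityDiagram",
    "build_reliability_diagram",
    "build_discrimination_diagram",
    "plot_reliability_diagram",
    "plot_discrimination_diagram",
]

DISCRETE = "discrete"
CONTINUOUS = "continuous"

#: smallest gap between distinct forecast values at or above which we
#: operate in the discrete setting
DISCRETENESS_GAP = 0.01


def detect_setting(agg: AggregatedSample) -> str:
    """Classify a forecast as discretely or continuously distributed."""
    if agg.k == 1:
        return DISCRETE
    gap = float(np.min(np.diff(agg.z)))
    # tolerance so that a gap of exactly 0.01 stored in binary floats
    # (e.g. 0.21 - 0.2) still counts as discrete
    return DISCRETE if gap >= DISCRETENESS_GAP - 1e-12 else CONTINUOUS


@dataclass(frozen=True)
class Histogram:
    """Histogram over [0, 1]; counts sum to the sample size."""

    edges: np.ndarray
    counts: np.ndarray

    @property
    def densities(self) -> np.ndarray:
        widths = np.diff(self.edges)
        n = self.counts.sum()
        return self.counts / (n * widths)

    def density_at(self, x) -> np.ndarray:
        """Histogram density estimate at points ``x`` (0 outside the bins)."""
        x = np.asarray(x, dtype=float)
        idx = np.searchsorted(self.edges, x, side="right") - 1
        # the last bin is right-closed
        idx = np.where(x == self.edges[-1], len(self.counts) - 1, idx)
        ok = (idx >= 0) & (idx < len(self.counts))
        out = np.zeros_like(x, dtype=float)
        out[ok] = self.densities[idx[ok]]
        return out


def fd_histogram(x) -> Histogram:
    """Freedman-Diaconis histogram of forecast values.

    Bin width h = 2*IQR(x)*n^(-1/3) (linear-interpolation quantiles),
    bins anchored at 0; the final bin ends at 1 and is right-closed.
    Degenerate samples (zero IQR) fall back to a single bin spanning
    the data range.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least two values for a histogram")
    iqr = float(np.quantile(x, 0.75) - np.quantile(x, 0.25))
    if iqr <= 0.0:
        lo, hi = float(x.min()), float(x.max())
        if lo == hi:
            lo, hi = max(0.0, lo - 0.5e-2), min(1.0, hi + 0.5e-2)
        edges = np.array([lo, hi])
    else:
        h = 2.0 * iqr * n ** (-1.0 / 3.0)
        edges = np.arange(0.0, 1.0, h)
        edges = np.append(edges, 1.0)
    counts, _ = np.histogram(x, bins=edges)
    return Histogram(edges=edges, counts=counts)


@dataclass(frozen=True)
class ReliabilityDiagram:
    """Serialisable CORP reliability-diagram content.

    ``curve_x``/``curve_y`` are the unique forecast values and their
    PAV-calibrated probabilities; consumers interpolate linearly in
    between and never extrapolate outside [min z, max z].  ``bins``
    lists the isotonic blocks as dicts with the covered forecast-value
    range, the pooled event frequency and the number of cases.
    """

    curve_x: np.ndarray
    curve_y: np.ndarray
    setting: str
    bins: tuple
    marginal: dict
    inset: Decomposition
    n: int
    band: Optional["object"] = None
    extra_histograms: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "curve": {"x": self.curve_x.tolist(), "y": self.curve_y.tolist()},
            "setting": self.setting,
            "bins": list(self.bins),
            "marginal": self.marginal,
            "inset": self.inset.to_dict(),
            "n": self.n,
            "band": self.band.to_dict() if self.band is not None else None,
        }
        if self.extra_histograms:
            d["extra_histograms"] = self.extra_histograms
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)

    @classmethod
    def from_json(cls, text: str) -> "ReliabilityDiagram":
        from .bands import Band  # local import to avoid a cycle

        d = json.loads(text)
        inset = Decomposition(
            score_name=d["inset"]["score"],
            S_X=d["inset"]["mean_score"],
            S_C=d["inset"]["UNC"] - d["inset"]["DSC"],
            S_R=d["inset"]["UNC"],
            mcb=d["inset"]["MCB"],
            dsc=d["inset"]["DSC"],
            unc=d["inset"]["UNC"],
            reference=d["inset"]["reference"],
        )
        band = Band.from_dict(d["band"]) if d.get("band") else None
        return cls(
            curve_x=np.asarray(d["curve"]["x"]),
            curve_y=np.asarray(d["curve"]["y"]),
            setting=d["setting"],
            bins=tuple(d["bins"]),
            marginal=d["marginal"],
            inset=inset,
            n=d["n"],
            band=band,
            extra_histograms=d.get("extra_histograms", {}),
        )


def _bins_from_fit(fit: IsotonicFit) -> tuple:
    out = []
    for b in fit.blocks:
        out.append(
            {
                "z_min": float(fit.z[b.start]),
                "z_max": float(fit.z[b.stop - 1]),
                "cep": b.value,
                "n": int(round(b.weight)),
            }
        )
    return tuple(out)


def _marginal(sample: PairedSample, agg: AggregatedSample, setting: str) -> dict:
    if setting == DISCRETE:
        return {
            "type": "bars",
            "values": agg.z.tolist(),
            "counts": agg.counts.tolist(),
        }
    hist = fd_histogram(sample.x)
    return {
        "type": "histogram",
        "edges": hist.edges.tolist(),
        "counts": hist.counts.tolist(),
    }


def build_reliability_diagram(
    sample: PairedSample,
    rule="brier",
    band_request: Optional[dict] = None,
) -> ReliabilityDiagram:
    """Assemble the CORP reliability diagram for a sample.

    Parameters
    ----------
    sample : PairedSample
    rule : str or ScoringRule
        Scoring rule for the inset decomposition (default Brier).
    band_request : dict, optional
        Keyword arguments for :func:`corpcal.bands.compute_band`, e.g.
        ``{"band_type": "consistency", "level": 0.9, "seed": 7}``.
    """
    rule = get_rule(rule)
    agg = aggregate(sample)
    fit = pav_fit(agg)
    setting = detect_setting(agg)
    band = None
    if band_request is not None:
        from .bands import compute_band

        band = compute_band(sample, **band_request)
    return ReliabilityDiagram(
        curve_x=fit.z,
        curve_y=fit.cep_hat,
        setting=setting,
        bins=_bins_from_fit(fit),
        marginal=_marginal(sample, agg, setting),
        inset=corp_decompose(sample, rule),
        n=sample.n,
        band=band,
    )


def build_discrimination_diagram(sample: PairedSample, rule="brier") -> ReliabilityDiagram:
    """Reliability content plus marginals of both x and the PAV x-hat.

    The recalibrated histogram concentrates its mass on the block
    values; strong dispersion of that histogram signals high
    discrimination ability, a single spike signals none.
    """
    diag = build_reliability_diagram(sample, rule=rule)
    agg = aggregate(sample)
    fit = pav_fit(agg)
    block_values = [b.value for b in fit.blocks]
    block_weights = [b.weight / sample.n for b in fit.blocks]
    if diag.setting == DISCRETE:
        original = {
            "type": "bars",
            "values": agg.z.tolist(),
            "weights": (agg.counts / sample.n).tolist(),
        }
    else:
        hist = fd_histogram(sample.x)
        original = {
            "type": "histogram",
            "edges": hist.edges.tolist(),
            "counts": hist.counts.tolist(),
        }
    return ReliabilityDiagram(
        curve_x=diag.curve_x,
        curve_y=diag.curve_y,
        setting=diag.setting,
        bins=diag.bins,
        marginal=diag.marginal,
        inset=diag.inset,
        n=diag.n,
        band=diag.band,
        extra_histograms={
            "original": original,
            "recalibrated": {
                "type": "bars",
                "values": block_values,
                "weights": block_weights,
            },
        },
    )


# ---------------------------------------------------------------------------
# rendering


def _draw_reliability(ax, diag: ReliabilityDiagram):
    ax.plot([0, 1], [0, 1], color="0.7", lw=1, ls="--", zorder=1)
    if diag.band is not None:
        bx = np.asarray(diag.band.z)
        lo = np.asarray(diag.band.lower)
        hi = np.asarray(diag.band.upper)
        ok = ~(np.isnan(lo) | np.isnan(hi))
        ax.fill_between(bx[ok], lo[ok], hi[ok], color="#9ecae1", alpha=0.6, zorder=0)
    ax.plot(diag.curve_x, diag.curve_y, color="#d62728", lw=1.8, zorder=3)
    if diag.setting == DISCRETE:
        ax.plot(diag.curve_x, diag.curve_y, "o", color="#d62728", ms=4, zorder=4)
    ins = diag.inset
    ax.text(
        0.02,
        0.98,
        f"MCB = {ins.mcb:.3f}\nDSC = {ins.dsc:.3f}\nUNC = {ins.unc:.3f}",
        transform=ax.transAxes,
        va="top",
        fontsize=9,
    )
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.set_xlabel("forecast probability")
    ax.set_ylabel("conditional event probability")


def plot_reliability_diagram(diag: ReliabilityDiagram, ax=None):
    """Render a reliability diagram; returns the matplotlib figure."""
    import matplotlib.pyplot as plt

    if ax is None:
        fig, ax = plt.subplots(figsize=(4.2, 4.6))
    else:
        fig = ax.figure
    _draw_reliability(ax, diag)
    # marginal strip at the bottom
    m = diag.marginal
    if m["type"] == "bars":
        w = np.asarray(m["counts"], dtype=float)
        ax.bar(m["values"], 0.08 * w / w.max(), width=0.015, bottom=0.0, color="0.4", zorder=2)
    else:
        edges = np.asarray(m["edges"])
        counts = np.asarray(m["counts"], dtype=float)
        ax.bar(
            edges[:-1],
            0.08 * counts / counts.max(),
            width=np.diff(edges),
            align="edge",
            bottom=0.0,
            color="0.4",
            alpha=0.8,
            zorder=2,
        )
    return fig


def plot_discrimination_diagram(diag: ReliabilityDiagram):
    """Render a discrimination diagram (marginals of x on top, x-hat at right)."""
    import matplotlib.pyplot as plt

    if not diag.extra_histograms:
        raise ValueError("diagram carries no discrimination histograms; "
                         "use build_discrimination_diagram")
    fig = plt.figure(figsize=(5.4, 5.4))
    gs = fig.add_gridspec(2, 2, width_ratios=(4, 1), height_ratios=(1, 4),
                          hspace=0.05, wspace=0.05)
    ax = fig.add_subplot(gs[1, 0])
    ax_top = fig.add_subplot(gs[0, 0], sharex=ax)
    ax_right = fig.add_subplot(gs[1, 1], sharey=ax)
    _draw_reliability(ax, diag)
    orig = diag.extra_histograms["original"]
    if orig["type"] == "bars":
        ax_top.bar(orig["values"], orig["weights"], width=0.015, color="0.4")
    else:
        edges = np.asarray(orig["edges"])
        ax_top.bar(edges[:-1], orig["counts"], width=np.diff(edges), align="edge",
                   color="0.4")
    rec = diag.extra_histograms["recalibrated"]
    ax_right.barh(rec["values"], rec["weights"], height=0.015, color="0.4")
    for a in (ax_top, ax_right):
        a.tick_params(labelbottom=False, labelleft=False)
    return fig
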