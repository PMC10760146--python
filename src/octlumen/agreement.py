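"""Bland–Altman and linear-regression agreement between paired metrics.

Differences follow the proposed-minus-reference sign convention; the
limits of agreement are bias +/- 1.96 * SD of the differences with the
n-1 SD denominator.  Regression is ordinary least squares of the
proposed values (Y) on the reference values (X), with the slope p-value
from a two-sided t-test on n-2 degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "PairedSeries",
    "AgreementReport",
    "bland_altman",
    "linear_regression",
    "agreement_report",
    "report_to_text",
    "plot_agreement",
]

LOA_MULTIPLIER = 1.96  # 95% limits of agreement


@dataclass(frozen=True)
class PairedSeries:
    """One metric measured per frame by two methods."""

    proposed: np.ndarray
    reference: np.ndarray
    metric_name: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        p = np.asarray(self.proposed, dtype=float)
        r = np.asarray(self.reference, dtype=float)
        object.__setattr__(self, "proposed", p)
        object.__setattr__(self, "reference", r)
        if p.shape != r.shape or p.ndim != 1:
            raise ValueError("proposed and reference must be equal-length 1D series")
        if len(p) < 3:
            raise ValueError("at least 3 pairs are required")
        if not (np.all(np.isfinite(p)) and np.all(np.isfinite(r))):
            raise ValueError("series must not contain missing values")

    @property
    def n(self) -> int:
        return len(self.proposed)


@dataclass(frozen=True)
class AgreementReport:
    metric_name: str
    units: str
    n: int
    bias: float  # mean(proposed - reference)
    sd_diff: float  # SD of differences, n-1 denominator
    loa_low: float  # bias - 1.96 * sd_diff
    loa_high: float  # bias + 1.96 * sd_diff
    slope: float
    intercept: float
    r: float
    r_squared: float
    p_value: float


def bland_altman(series: PairedSeries) -> tuple[float, float, float, float]:
    """Return (bias, loa_low, loa_high, sd_diff) of proposed - reference."""
    d = series.proposed - series.reference
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, bias - LOA_MULTIPLIER * sd, bias + LOA_MULTIPLIER * sd, sd


def linear_regression(series: PairedSeries) -> tuple[float, float, float, float, float]:
    """OLS of proposed on reference: (slope, intercept, r, r^2, p_value)."""
    x, y = series.reference, series.proposed
    if np.ptp(x) == 0:
        raise ValueError("reference series has zero variance")
    if np.ptp(y) == 0:
        # No association: flat fit, r = 0, slope t-statistic 0 -> p = 1.
        return 0.0, float(y.mean()), 0.0, 0.0, 1.0
    res = stats.linregress(x, y)
    return (float(res.slope), float(res.intercept), float(res.rvalue),
            float(res.rvalue**2), float(res.pvalue))


def _make_report(series: PairedSeries) -> AgreementReport:
    bias, lo, hi, sd = bland_altman(series)
    slope, intercept, r, r2, p = linear_regression(series)
    return AgreementReport(metric_name=series.metric_name, units=series.units,
                           n=series.n, bias=bias, sd_diff=sd, loa_low=lo,
                           loa_high=hi, slope=slope, intercept=intercept,
                           r=r, r_squared=r2, p_value=p)


_METRICS = (("area", "mm^2"), ("d_mean", "mm"), ("d_max", "mm"), ("d_min", "mm"))


def agreement_report(
    per_frame_proposed,
    per_frame_reference,
    exclude_flags=None,
) -> dict[str, AgreementReport]:
    """Per-metric agreement reports over aligned per-frame metric lists.

    Frames with a truthy exclude flag (e.g. unsegmentable, manually
    flagged) are dropped from both series before analysis — one report
    each for area and mean/max/min diameter.
    """
    if len(per_frame_proposed) != len(per_frame_reference):
        raise ValueError("proposed and reference frame lists must be aligned")
    n = len(per_frame_proposed)
    flags = list(exclude_flags) if exclude_flags is not None else [False] * n
    if len(flags) != n:
        raise ValueError("exclude_flags must align with the frame lists")
    keep = [i for i in range(n) if not flags[i]]
    if len(keep) < 3:
        raise ValueError(f"only {len(keep)} frames survive exclusion; need >= 3")
    reports: dict[str, AgreementReport] = {}
    for attr, units in _METRICS:
        series = PairedSeries(
            proposed=np.array([getattr(per_frame_proposed[i], attr) for i in keep]),
            reference=np.array([getattr(per_frame_reference[i], attr) for i in keep]),
            metric_name=attr, units=units)
        reports[attr] = _make_report(series)
    return reports


def report_to_text(report: AgreementReport) -> str:
    """Human-readable one-metric summary (differences are proposed - reference)."""
    return (
        f"{report.metric_name} [{report.units}] (n={report.n})\n"
        f"  bias (proposed - reference): {report.bias:.4f}\n"
        f"  SD of differences:           {report.sd_diff:.4f}\n"
        f"  95% limits of agreement:     {report.loa_low:.4f} to {report.loa_high:.4f}\n"
        f"  regression: Y = {report.slope:.4f} X + {report.intercept:+.4f}"
        f"  (r = {report.r:.4f}, R^2 = {report.r_squared:.4f}, p = {report.p_value:.3g})\n"
    )


def plot_agreement(series: PairedSeries, path) -> None:
    """Bland–Altman and scatter/regression panels for one metric (PNG)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rep = _make_report(series)
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
    mean = (series.proposed + series.reference) / 2
    diff = series.proposed - series.reference
    ax1.scatter(mean, diff, s=12)
    for y, style in ((rep.bias, "-"), (rep.loa_low, "--"), (rep.loa_high, "--")):
        ax1.axhline(y, color="k", linestyle=style, linewidth=0.8)
    ax1.set_xlabel(f"mean of methods [{series.units}]")
    ax1.set_ylabel(f"difference [{series.units}]")
    ax1.set_title(f"Bland–Altman: {series.metric_name}")
    ax2.scatter(series.reference, series.proposed, s=12)
    xs = np.linspace(series.reference.min(), series.reference.max(), 50)
    ax2.plot(xs, rep.slope * xs + rep.intercept, "k-", linewidth=0.8,
             label=f"Y={rep.slope:.2f}X{rep.intercept:+.2f}, R²={rep.r_squared:.3f}")
    ax2.plot(xs, xs, "k:", linewidth=0.6)
    ax2.set_xlabel(f"reference [{series.units}]")
    ax2.set_ylabel(f"proposed [{series.units}]")
    ax2.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
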