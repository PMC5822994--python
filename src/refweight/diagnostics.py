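"""Normal probability plots of weighted residuals.

If the model is correct and the weights describe the residual variance,
the weighted deviates sqrt(w_i) * (Fo^2_i - Fc^2_i) are standard normal.
Sorting them in ascending order and plotting them against the standard
normal order-statistic quantiles Phi^-1((i - 0.5)/n) should then give the
identity line: a gradient of 1 and an intercept of 0.  A gradient above 1
is the signature of underestimated standard uncertainties (common in
multipolar refinements); curvature flags systematic error.

Every reflection contributes one point (no binned averaging), and the
straight line summarizing the plot is fitted only to the points between the
lower and upper quartiles by rank, so large outliers in the tails cannot
bias it.  The deviates are not normalized by the overall goodness of fit:
a correctly weighted but poorly fitting refinement shows its inflated
spread as a slope above 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy import stats

from .errors import ValidationError
from .reflections import ReflectionSet
from .weights import (
    FilterSpec,
    WeightingScheme,
    apply_filters,
    refinement_stats,
    weight_array,
)

__all__ = [
    "NppResult",
    "npp_from_deviates",
    "npp_data",
    "iq_regression",
    "plot_npp",
    "npp_table",
    "weighting_report",
]

REPORT_VERSION = 1


@dataclass
class NppResult:
    """Every-point normal probability plot data.

    ``observed`` holds the weighted deviates sorted ascending, ``expected``
    the matching normal quantiles Phi^-1((i - 0.5)/n); ``slope`` and
    ``intercept`` are the interquartile regression coefficients.  ``order``
    (when built from a reflection set) maps each rank back to the original
    reflection row, and ``weights`` holds the sorted reflections' weights.
    """

    observed: np.ndarray
    expected: np.ndarray
    slope: float
    intercept: float
    n: int
    order: Optional[np.ndarray] = field(default=None, repr=False)
    weights: Optional[np.ndarray] = field(default=None, repr=False)


def _expected_quantiles(n: int) -> np.ndarray:
    return stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)


def npp_from_deviates(deviates: np.ndarray) -> NppResult:
    """Build the plot data from raw deviates (already weighted)."""
    deviates = np.asarray(deviates, dtype=float)
    n = deviates.size
    if n < 4:
        raise ValidationError(f"need at least 4 deviates for a normal probability plot, got {n}")
    order = np.argsort(deviates, kind="stable")
    npp = NppResult(
        observed=deviates[order],
        expected=_expected_quantiles(n),
        slope=np.nan,
        intercept=np.nan,
        n=n,
        order=order,
    )
    iq_regression(npp)
    return npp


def npp_data(rs: ReflectionSet, scheme: WeightingScheme, p: int) -> NppResult:
    """Normal probability plot of the weighted deviates sqrt(w) * Delta."""
    w = weight_array(rs, scheme)
    deviates = np.sqrt(w) * (rs.f_obs_sq - rs.f_calc_sq)
    npp = npp_from_deviates(deviates)
    npp.weights = w[npp.order]
    return npp


def iq_regression(npp: NppResult) -> Tuple[float, float]:
    """Least-squares line through the interquartile points, by rank.

    Ranks i with n/4 < i <= 3n/4 (the central half of the order statistics)
    enter an ordinary least-squares fit of observed on expected; the
    coefficients are stored back on ``npp`` and returned.  Membership is by
    rank, not by value, so ties are handled deterministically and anything
    placed in the tails can never influence the line.
    """
    n = npp.n
    ranks = np.arange(1, n + 1)
    central = (ranks > n / 4) & (ranks <= 3 * n / 4)
    if central.sum() < 2:
        raise ValidationError("fewer than 2 points between the quartiles")
    x = npp.expected[central]
    y = npp.observed[central]
    slope, intercept = np.polyfit(x, y, 1)
    npp.slope = float(slope)
    npp.intercept = float(intercept)
    return npp.slope, npp.intercept


def plot_npp(npp: NppResult, path, axis_range: Optional[Tuple[float, float]] = None):
    """Write the plot: one point per reflection, a dashed y = x reference
    line for normally distributed residuals, and the interquartile
    regression line.  Returns the matplotlib Figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    ax.scatter(npp.expected, npp.observed, s=6, color="#1f4e79", label="weighted deviates")
    lo = float(npp.expected[0]) if axis_range is None else axis_range[0]
    hi = float(npp.expected[-1]) if axis_range is None else axis_range[1]
    ref = np.array([lo, hi])
    ax.plot(ref, ref, "r--", label="normal (y = x)")
    ax.plot(
        ref,
        npp.slope * ref + npp.intercept,
        color="k",
        label=f"interquartile fit: y = {npp.slope:.4f}x {npp.intercept:+.5f}",
    )
    if axis_range is not None:
        ax.set_xlim(axis_range)
        ax.set_ylim(axis_range)
    ax.set_xlabel("expected normal quantile")
    ax.set_ylabel(r"observed weighted deviate $\sqrt{w}\,(F_o^2 - F_c^2)$")
    ax.legend(loc="upper left", fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return fig


def npp_table(npp: NppResult, rs: Optional[ReflectionSet] = None) -> str:
    """Tab-separated export of the plot points.

    Columns: rank, expected, observed and, when the originating reflection
    set is given, the reflection identity (h, k, l, Fo^2, Fc^2, sigma, w) of
    each point — the batch equivalent of picking a point in a plot window.
    """
    with_ids = rs is not None and npp.order is not None
    header = ["rank", "expected", "observed"]
    if with_ids:
        header += ["h", "k", "l", "f_obs_sq", "f_calc_sq", "sigma_f_obs_sq", "weight"]
    lines = ["\t".join(header)]
    for i in range(npp.n):
        row = [str(i + 1), repr(float(npp.expected[i])), repr(float(npp.observed[i]))]
        if with_ids:
            j = int(npp.order[i])
            row += [
                str(int(rs.hkl[j, 0])),
                str(int(rs.hkl[j, 1])),
                str(int(rs.hkl[j, 2])),
                repr(float(rs.f_obs_sq[j])),
                repr(float(rs.f_calc_sq[j])),
                repr(float(rs.sigma_f_obs_sq[j])),
                repr(float(npp.weights[i])) if npp.weights is not None else "",
            ]
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"


def weighting_report(
    rs: ReflectionSet,
    scheme: WeightingScheme,
    p: int,
    filters: Optional[FilterSpec] = None,
) -> dict:
    """One JSON-serializable report of a weighting evaluation.

    Aggregates the applied scheme (all six parameters), the cut-off counts,
    the refinement statistics and the normal-probability-plot coefficients.
    """
    if filters is not None:
        rs, counts = apply_filters(rs, filters, return_counts=True)
        filter_counts = counts.as_dict()
    else:
        filter_counts = None
    stats_ = refinement_stats(rs, scheme, p)
    npp = npp_data(rs, scheme, p)
    report = {
        "report_version": REPORT_VERSION,
        "scheme": scheme.as_dict(),
        "filters": filter_counts,
        "n": stats_.n,
        "p": stats_.p,
        "statistics": {
            "r1": stats_.r1,
            "wr2": stats_.wr2,
            "goof": stats_.goof,
            "wgoof": stats_.wgoof,
        },
        "npp": {"slope": npp.slope, "intercept": npp.intercept, "n": npp.n},
    }
    json.dumps(report)  # guarantee serializability at build time
    return report
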