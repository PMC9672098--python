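"""Feedback-coefficient estimation: DV binning, proportional fits, comparisons.

The feedback coefficient is the proportionality between a junction's relative
myosin rate and its strain rate.  Edges are grouped into equal-width bins
along the DV axis (optionally restricted to an orientation class), each
edge contributes its time-averaged rates over a stated developmental window,
and the coefficient is the least-squares slope through the origin of
(strain rate, myosin rate) points, with a t-based 95% confidence interval.
Coefficients from different bins/conditions are compared with a Welch
unequal-variance t-test on the slope estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .tracks import EdgeTrack, compute_rates

__all__ = [
    "RegionBin",
    "FeedbackFit",
    "FeedbackProfile",
    "classify_orientation",
    "edge_mean_rates",
    "bin_edges",
    "fit_proportionality",
    "fit_bin",
    "compare_coefficients",
    "feedback_profile",
]

OrientationClass = Literal["ap_parallel", "dv_parallel", "all"]


@dataclass(frozen=True)
class RegionBin:
    """Edges of one DV bin with their per-edge time-averaged rates."""

    dv_range: tuple[float, float]
    orientation_class: str
    edge_ids: np.ndarray
    strain_rates: np.ndarray     # per-edge time-mean strain rate (per minute)
    myosin_rates: np.ndarray     # per-edge time-mean myosin rate (per minute)
    n_edges: int
    usable: bool                 # n_edges >= the binning's minimum

    @property
    def center(self) -> float:
        return 0.5 * (self.dv_range[0] + self.dv_range[1])

    @property
    def mean_strain_rate(self) -> float:
        return float(np.mean(self.strain_rates)) if self.n_edges else math.nan

    @property
    def mean_myosin_rate(self) -> float:
        return float(np.mean(self.myosin_rates)) if self.n_edges else math.nan

    @property
    def sd_strain_rate(self) -> float:
        return float(np.std(self.strain_rates, ddof=1)) if self.n_edges > 1 else math.nan

    @property
    def sd_myosin_rate(self) -> float:
        return float(np.std(self.myosin_rates, ddof=1)) if self.n_edges > 1 else math.nan


@dataclass(frozen=True)
class FeedbackFit:
    """Best-fit proportionality coefficient with its 95% CI."""

    coefficient: float
    ci95: tuple[float, float]
    se: float
    n: int
    region: str = ""

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        if not (lo - 1e-12 <= self.coefficient <= hi + 1e-12):
            raise ValueError("ci95 must contain the coefficient")


def classify_orientation(angle: float, cone_halfwidth: float = 30.0) -> str:
    """Classify a junction angle (degrees from the AP axis, in [0, 90]).

    ``ap_parallel`` if within ``cone_halfwidth`` of 0°, ``dv_parallel`` if
    within it of 90°, else ``unclassified``.
    """
    if not 0.0 <= angle <= 90.0:
        raise ValueError(f"angle {angle} outside [0, 90]")
    if angle < cone_halfwidth:
        return "ap_parallel"
    if angle > 90.0 - cone_halfwidth:
        return "dv_parallel"
    return "unclassified"


def edge_mean_rates(track: EdgeTrack, window: tuple[float, float],
                    sigma: float = 10.0) -> tuple[float, float]:
    """Time-mean strain and myosin rate (per minute) over ``window`` minutes."""
    r = compute_rates(track, sigma=sigma)
    t_min = r.times / 60.0
    sel = (t_min >= window[0]) & (t_min <= window[1])
    if not np.any(sel):
        raise ValueError(
            f"edge {track.edge_id}: window {window} outside track support")
    return float(np.mean(r.strain_rate[sel])), float(np.mean(r.myosin_rate[sel]))


def bin_edges(tracks: Sequence[EdgeTrack], n_bins: int,
              orientation_class: OrientationClass = "all",
              window: tuple[float, float] = (10.0, 20.0),
              sigma: float = 10.0,
              cone_halfwidth: float = 30.0,
              min_edges: int = 30,
              dv_max: float | None = None) -> list[RegionBin]:
    """Equal-width DV bins of per-edge time-averaged rates.

    ``window`` is in minutes from track start (the developmental interval the
    rates are averaged over).  Bins with fewer than ``min_edges`` members are
    flagged ``usable=False`` and excluded from downstream fits.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if not tracks:
        raise ValueError("no tracks given")
    if orientation_class == "all":
        kept = list(tracks)
    else:
        kept = [t for t in tracks
                if classify_orientation(t.orientation, cone_halfwidth)
                == orientation_class]
    if dv_max is None:
        dv_max = max((t.dv_position for t in tracks), default=0.0)
    if not dv_max > 0:
        raise ValueError("tracks carry no positive dv_position")
    edges_dv = np.array([t.dv_position for t in kept])
    bounds = np.linspace(0.0, dv_max, n_bins + 1)
    idx = np.clip(np.searchsorted(bounds, edges_dv, side="right") - 1,
                  0, n_bins - 1)

    rates = np.array([edge_mean_rates(t, window, sigma) for t in kept]) \
        if kept else np.empty((0, 2))
    ids = np.array([t.edge_id for t in kept], dtype=int)

    out = []
    for b in range(n_bins):
        sel = idx == b
        n = int(np.sum(sel))
        out.append(RegionBin(
            dv_range=(float(bounds[b]), float(bounds[b + 1])),
            orientation_class=orientation_class,
            edge_ids=ids[sel],
            strain_rates=rates[sel, 0] if n else np.empty(0),
            myosin_rates=rates[sel, 1] if n else np.empty(0),
            n_edges=n,
            usable=n >= min_edges,
        ))
    return out


def fit_proportionality(strain_rates: np.ndarray, myosin_rates: np.ndarray,
                        region: str = "") -> FeedbackFit:
    """Least-squares slope through the origin with a t-based 95% CI.

    ``c = sum(x*y)/sum(x**2)``; the standard error uses the residual variance
    with n-1 degrees of freedom.  Raises if the strain rates are all
    (numerically) zero, in which case the coefficient is unidentifiable.
    """
    x = np.asarray(strain_rates, dtype=float)
    y = np.asarray(myosin_rates, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("strain and myosin rate arrays must match")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 points")
    sxx = float(x @ x)
    scale = float(np.max(np.abs(x)))
    if scale == 0.0 or sxx < (1e-12 * max(scale, 1.0)) ** 2:
        raise ValueError("unidentifiable: strain rates are all ~0")
    c = float(x @ y) / sxx
    resid = y - c * x
    s2 = float(resid @ resid) / (n - 1)
    se = math.sqrt(s2 / sxx)
    tcrit = stats.t.ppf(0.975, n - 1)
    return FeedbackFit(coefficient=c, ci95=(c - tcrit * se, c + tcrit * se),
                       se=se, n=n, region=region)


def fit_bin(region: RegionBin) -> FeedbackFit:
    label = (f"dv[{region.dv_range[0]:.0f},{region.dv_range[1]:.0f})"
             f"/{region.orientation_class}")
    return fit_proportionality(region.strain_rates, region.myosin_rates,
                               region=label)


def compare_coefficients(a: FeedbackFit, b: FeedbackFit,
                         alternative: str = "greater"
                         ) -> tuple[float, float, float]:
    """Welch t-test on two slope estimates.

    Returns ``(t, df, p)`` with Welch–Satterthwaite degrees of freedom and a
    one-sided p-value (``alternative='greater'`` tests a > b).
    """
    if not (a.se >= 0 and b.se >= 0):
        raise ValueError("fits must carry standard errors")
    var_a, var_b = a.se ** 2, b.se ** 2
    denom = math.sqrt(var_a + var_b)
    if denom == 0.0:
        raise ValueError("both fits have zero standard error")
    t = (a.coefficient - b.coefficient) / denom
    df = ((var_a + var_b) ** 2
          / (var_a ** 2 / (a.n - 1) + var_b ** 2 / (b.n - 1)))
    if alternative == "greater":
        p = float(stats.t.sf(t, df))
    elif alternative == "less":
        p = float(stats.t.cdf(t, df))
    elif alternative == "two-sided":
        p = float(2.0 * stats.t.sf(abs(t), df))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return float(t), float(df), p


@dataclass(frozen=True)
class FeedbackProfile:
    """Per-bin feedback coefficients plus a linear trend along DV."""

    table: pd.DataFrame          # columns: dv_center, coefficient, ci_lo, ci_hi, se, n
    slope: float                 # coefficient change per µm of DV distance
    slope_ci95: tuple[float, float]
    intercept: float

    def coefficient_at(self, dv: np.ndarray) -> np.ndarray:
        """Linear interpolation of the per-bin coefficients (clamped ends)."""
        t = self.table.sort_values("dv_center")
        return np.interp(np.asarray(dv, dtype=float),
                         t["dv_center"].to_numpy(),
                         t["coefficient"].to_numpy())


def feedback_profile(bins: Sequence[RegionBin]) -> FeedbackProfile:
    """Fit each usable bin and a linear trend of coefficient vs DV center."""
    rows = []
    for rb in bins:
        if not rb.usable:
            continue
        try:
            fit = fit_bin(rb)
        except ValueError:
            continue
        rows.append({"dv_center": rb.center, "coefficient": fit.coefficient,
                     "ci_lo": fit.ci95[0], "ci_hi": fit.ci95[1],
                     "se": fit.se, "n": fit.n})
    if len(rows) < 2:
        raise ValueError("need >= 2 identifiable bins for a profile")
    table = pd.DataFrame(rows)
    res = stats.linregress(table["dv_center"], table["coefficient"])
    dof = len(rows) - 2
    tcrit = stats.t.ppf(0.975, dof) if dof > 0 else math.inf
    ci = (res.slope - tcrit * res.stderr, res.slope + tcrit * res.stderr)
    return FeedbackProfile(table=table, slope=float(res.slope),
                           slope_ci95=(float(ci[0]), float(ci[1])),
                           intercept=float(res.intercept))
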