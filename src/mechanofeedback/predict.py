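"""Embryo-scale myosin prediction from integrated strain histories.

The integrated feedback law predicts a junction's myosin level from its
cumulative deformation: ``m(edge, t) = A * Lambda(t)**c(DV)``, where
``Lambda`` is the total strain (fold-change of edge length reconstructed
from the strain-rate history), ``c(DV)`` the feedback coefficient at the
edge's DV position, and ``A`` a single global constant fitted by least
squares.  Predictions are compared with measured myosin on bin-averaged DV
profiles, scored by a normalized-L1 accuracy in [0, 1], and wild-type vs
mutant conditions are compared through per-bin rate ratios and residuals
from the wild-type proportionality line.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .feedback import RegionBin, FeedbackFit, fit_proportionality
from .tracks import EdgeTrack

__all__ = [
    "StrainHistory",
    "MyosinPrediction",
    "total_strain",
    "predict_myosin",
    "fit_global_constant",
    "model_accuracy",
    "accuracy_series",
    "condition_comparison",
    "ConditionComparison",
]


@dataclass(frozen=True)
class StrainHistory:
    """Cumulative fold-change of one edge's length, ``Lambda(0) = 1``."""

    edge_id: int
    times: np.ndarray
    total: np.ndarray          # Lambda(t), dimensionless
    dv_position: float

    def __post_init__(self) -> None:
        if abs(self.total[0] - 1.0) > 1e-12:
            raise ValueError("total strain must start at 1")
        if np.any(self.total <= 0):
            raise ValueError("total strain must stay positive")


@dataclass(frozen=True)
class MyosinPrediction:
    """Bin-averaged predicted vs measured myosin profiles over time."""

    times: np.ndarray            # (n_times,)
    dv_centers: np.ndarray       # (n_bins,)
    predicted: np.ndarray        # (n_bins, n_times)
    measured: np.ndarray         # (n_bins, n_times)
    global_constant: float
    accuracy: np.ndarray         # (n_times,), in [0, 1]


def total_strain(track: EdgeTrack) -> StrainHistory:
    """Total strain ``Lambda(t)``: exponentiated integral of the unsmoothed
    incremental strain rate.

    Each raw rate sample is the average rate over one frame interval, so the
    exact quadrature is the cumulative sum of ``rate * dt`` — which telescopes
    to ``Lambda(t) = L(t)/L(0)`` for the log-increment rates used here.
    Defined on the n-1 grid ``times[:-1]``.
    """
    L = np.asarray(track.lengths, dtype=float)
    increments = np.diff(np.log(L))                 # interval log-strains
    t = np.asarray(track.times[:-1], dtype=float)
    integral = np.concatenate([[0.0], np.cumsum(increments[:-1])])
    return StrainHistory(edge_id=track.edge_id, times=t,
                         total=np.exp(integral),
                         dv_position=track.dv_position)


def _bin_index(dv: np.ndarray, n_bins: int, dv_max: float) -> np.ndarray:
    bounds = np.linspace(0.0, dv_max, n_bins + 1)
    return np.clip(np.searchsorted(bounds, dv, side="right") - 1, 0, n_bins - 1)


def predict_myosin(tracks: Sequence[EdgeTrack],
                   c_profile: Callable[[np.ndarray], np.ndarray],
                   n_bins: int = 10,
                   dv_max: float | None = None,
                   global_constant: float | None = None,
                   fit_window: tuple[float, float] | None = None,
                   metric: str = "l1") -> MyosinPrediction:
    """Predict bin-averaged myosin profiles from per-edge total strain.

    ``c_profile`` maps DV position (µm) to feedback coefficient — either a
    measured profile (:meth:`FeedbackProfile.coefficient_at`) or an imposed
    one.  If ``global_constant`` is None it is fitted by least squares over
    ``fit_window`` (minutes; default: all timepoints).  ``metric`` selects
    the accuracy variant (see :func:`model_accuracy`); note the ``pearson``
    variant scores pattern fidelity and is insensitive to the overall scale.
    """
    if not tracks:
        raise ValueError("no tracks given")
    if dv_max is None:
        dv_max = max(t.dv_position for t in tracks)
    if not dv_max > 0:
        raise ValueError("tracks carry no positive dv_position")

    histories = [total_strain(t) for t in tracks]
    times = histories[0].times
    dv = np.array([t.dv_position for t in tracks])
    c = np.asarray(c_profile(dv), dtype=float)
    if not np.all(np.isfinite(c)):
        raise ValueError("c_profile returned non-finite coefficients")
    lam = np.stack([h.total for h in histories])            # (n_edges, n_t)
    shape = lam ** c[:, None]                               # A = 1 prediction
    meas = np.stack([t.myosin_density[:-1] for t in tracks])

    idx = _bin_index(dv, n_bins, dv_max)
    bounds = np.linspace(0.0, dv_max, n_bins + 1)
    centers = 0.5 * (bounds[:-1] + bounds[1:])
    pred_b = np.full((n_bins, times.size), np.nan)
    meas_b = np.full((n_bins, times.size), np.nan)
    for b in range(n_bins):
        sel = idx == b
        if np.any(sel):
            pred_b[b] = shape[sel].mean(axis=0)
            meas_b[b] = meas[sel].mean(axis=0)
    ok = ~np.isnan(pred_b[:, 0])
    if global_constant is None:
        if fit_window is None:
            t_sel = np.ones(times.size, dtype=bool)
        else:
            t_min = times / 60.0
            t_sel = (t_min >= fit_window[0]) & (t_min <= fit_window[1])
            if not np.any(t_sel):
                raise ValueError(f"fit window {fit_window} outside track support")
        A = fit_global_constant(pred_b[ok][:, t_sel], meas_b[ok][:, t_sel])
    else:
        A = float(global_constant)
    pred_b = A * pred_b
    acc = accuracy_series(pred_b[ok], meas_b[ok], metric)
    return MyosinPrediction(times=times, dv_centers=centers,
                            predicted=pred_b, measured=meas_b,
                            global_constant=A, accuracy=acc)


def fit_global_constant(shape: np.ndarray, measured: np.ndarray) -> float:
    """Least-squares scalar: ``A = sum(shape*measured) / sum(shape**2)``."""
    s = np.asarray(shape, dtype=float).ravel()
    y = np.asarray(measured, dtype=float).ravel()
    denom = float(s @ s)
    if denom == 0.0:
        raise ValueError("all-zero prediction shape")
    return float(s @ y) / denom


def model_accuracy(predicted: np.ndarray, measured: np.ndarray,
                   metric: str = "l1") -> float:
    """Agreement between predicted and measured profiles at one timepoint.

    ``l1``: ``max(0, 1 - sum|pred - meas| / sum(meas))`` — interpretable as a
    fraction of the measured profile accounted for.  ``pearson``: profile
    correlation mapped from [-1, 1] to [0, 1].
    """
    p = np.asarray(predicted, dtype=float)
    m = np.asarray(measured, dtype=float)
    if p.shape != m.shape:
        raise ValueError("profiles must have matching shape")
    if metric == "l1":
        denom = float(np.sum(m))
        if denom <= 0:
            raise ValueError("measured profile sums to zero")
        return max(0.0, 1.0 - float(np.sum(np.abs(p - m))) / denom)
    if metric == "pearson":
        # a (numerically) flat profile has no defined correlation: score as
        # neutral rather than raising, so time series over a ramp-up are usable
        if (np.std(p) <= 1e-9 * (abs(float(np.mean(p))) + 1e-30)
                or np.std(m) <= 1e-9 * (abs(float(np.mean(m))) + 1e-30)):
            return 0.5
        r = float(stats.pearsonr(p, m)[0])
        return 0.5 * (r + 1.0)
    raise ValueError(f"unknown metric {metric!r}")


def accuracy_series(predicted: np.ndarray, measured: np.ndarray,
                    metric: str = "l1") -> np.ndarray:
    """``model_accuracy`` at every timepoint of (n_bins, n_times) profiles."""
    return np.array([model_accuracy(predicted[:, j], measured[:, j], metric)
                     for j in range(predicted.shape[1])])


@dataclass(frozen=True)
class ConditionComparison:
    """Per-bin comparison of two conditions (e.g. wild type vs mutant)."""

    table: pd.DataFrame
    # columns: dv_center, strain_ratio, myosin_ratio, residual,
    #          residual_sd_units, flagged
    reference_fit: FeedbackFit
    pooled_strain_ratio: float   # ratio of profile-summed mean rates a/b
    pooled_myosin_ratio: float


def condition_comparison(bins_a: Sequence[RegionBin],
                         bins_b: Sequence[RegionBin]) -> ConditionComparison:
    """Rate ratios a/b per DV bin and condition-b residuals from a's line.

    The reference proportionality is fitted through the origin to condition
    a's per-bin mean (strain rate, myosin rate) points; residuals are
    condition b's bin means relative to that line, also expressed in units of
    the bin's per-edge myosin-rate SD.  Bins with a (near-)zero denominator
    are flagged and their ratios set to NaN.  The pooled ratios divide the
    profile-summed mean rates (dominated by the bins that carry signal, the
    single attenuation factor a study would report).
    """
    if len(bins_a) != len(bins_b):
        raise ValueError("conditions must share the binning")
    xs = np.array([rb.mean_strain_rate for rb in bins_a if rb.usable])
    ys = np.array([rb.mean_myosin_rate for rb in bins_a if rb.usable])
    ref = fit_proportionality(xs, ys, region="condition-a bin means")
    rows = []
    for ra, rb in zip(bins_a, bins_b):
        if (ra.dv_range != rb.dv_range):
            raise ValueError("bin boundaries differ between conditions")
        eps_a, eps_b = ra.mean_strain_rate, rb.mean_strain_rate
        myo_a, myo_b = ra.mean_myosin_rate, rb.mean_myosin_rate
        flagged = (not ra.usable or not rb.usable
                   or abs(eps_b) < 1e-12 or abs(myo_b) < 1e-12)
        strain_ratio = eps_a / eps_b if not flagged else math.nan
        myosin_ratio = myo_a / myo_b if not flagged else math.nan
        residual = myo_b - ref.coefficient * eps_b
        sd = rb.sd_myosin_rate
        rows.append({
            "dv_center": ra.center,
            "strain_ratio": strain_ratio,
            "myosin_ratio": myosin_ratio,
            "residual": residual,
            "residual_sd_units": residual / sd if sd and sd > 0 else math.nan,
            "flagged": flagged,
        })
    use = [(ra, rb) for ra, rb in zip(bins_a, bins_b)
           if ra.usable and rb.usable]
    sum_eps_b = sum(rb.mean_strain_rate for _, rb in use)
    sum_myo_b = sum(rb.mean_myosin_rate for _, rb in use)
    pooled_strain = (sum(ra.mean_strain_rate for ra, _ in use) / sum_eps_b
                     if use and abs(sum_eps_b) > 1e-12 else math.nan)
    pooled_myosin = (sum(ra.mean_myosin_rate for ra, _ in use) / sum_myo_b
                     if use and abs(sum_myo_b) > 1e-12 else math.nan)
    return ConditionComparison(table=pd.DataFrame(rows), reference_fit=ref,
                               pooled_strain_ratio=pooled_strain,
                               pooled_myosin_ratio=pooled_myosin)
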