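"""Plate-reader expression quantification.

Turns raw well time courses into one value per strain: the average rate of
reporter production per cell per second during exponential growth, computed as
the fluorescence gained over the exponential phase divided by the time
integral of the OD curve over the same window.

Processing order mirrors the experimental pipeline: background subtraction
(media for OD, the mCherry-only strain for the YFP channel, the YFP-only
strain for the mCherry channel), robust point-outlier masking, automatic
segmentation of the OD curve into lag / exponential / linear / stationary
phases, then the production ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np

from .io import TimeCourse, ValidationError

__all__ = [
    "GrowthPhases",
    "ExpressionMeasure",
    "CloneFilterResult",
    "NoGrowthError",
    "subtract_background",
    "remove_point_outliers",
    "mask_timecourse_outliers",
    "segment_growth_phases",
    "production_per_cell",
    "process_timecourse",
    "concordant_clone_filter",
]


class NoGrowthError(ValueError):
    """The OD curve never grows enough to define growth phases."""


@dataclass
class GrowthPhases:
    """Four contiguous half-open [t_start, t_end) growth phases, in seconds."""

    lag: tuple[float, float]
    exponential: tuple[float, float]
    linear: tuple[float, float]
    stationary: tuple[float, float]

    def __post_init__(self) -> None:
        order = (self.lag, self.exponential, self.linear, self.stationary)
        for (s, e) in order:
            if e < s:
                raise ValidationError(f"phase interval [{s}, {e}) is reversed")
        for (_, e_prev), (s_next, _) in zip(order, order[1:]):
            if not np.isclose(e_prev, s_next):
                raise ValidationError("growth phases must be contiguous and ordered")
        if not self.exponential[1] > self.exponential[0]:
            raise ValidationError("exponential phase must have positive duration")


@dataclass
class ExpressionMeasure:
    """Per-strain production rate in a.u. per OD-unit per second."""

    strain_id: str
    production: float
    window: tuple[float, float]
    channel: str = "yfp"
    n_outliers_removed: int = 0
    background_roles: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not np.isfinite(self.production):
            raise ValidationError(f"{self.strain_id}: non-finite production value")


# ---------------------------------------------------------------------------
# Background subtraction
# ---------------------------------------------------------------------------

#: Which background role corrects which channel.
_ROLE_FOR_CHANNEL = {
    "od": "media_blank",
    "yfp": "mcherry_background_strain",
    "mcherry": "yfp_background_strain",
}


def _align(target_times: np.ndarray, blank: TimeCourse, channel: str) -> np.ndarray:
    """Blank values on the sample time grid.

    The blank's full grid must be alignable with the sample grid by nearest
    timestamp within half the sampling interval; values are then linearly
    interpolated over the blank's *valid* (unmasked) points, so pre-masked
    blank outliers do not leak into the subtraction.
    """
    idx = np.searchsorted(blank.times, target_times)
    idx = np.clip(idx, 1, len(blank.times) - 1)
    left, right = blank.times[idx - 1], blank.times[idx]
    nearest = np.where(target_times - left <= right - target_times, idx - 1, idx)
    half_interval = np.median(np.diff(blank.times)) / 2.0
    if np.any(np.abs(blank.times[nearest] - target_times) > half_interval):
        raise ValidationError(
            f"blank well {blank.well_id!r} time grid not alignable with sample grid"
        )
    valid = blank.mask
    if valid.sum() < 2:
        raise ValidationError(f"blank well {blank.well_id!r} has < 2 valid points")
    return np.interp(target_times, blank.times[valid], getattr(blank, channel)[valid])


def subtract_background(
    tc: TimeCourse, blanks: Mapping[str, TimeCourse]
) -> TimeCourse:
    """Subtract per-channel backgrounds from a sample well.

    OD uses the media blank; the YFP channel uses the mCherry-only strain;
    the mCherry channel uses the YFP-only strain.  Background series are
    aligned by nearest timestamp (within half the sampling interval).  OD is
    floored at 0; fluorescence may go slightly negative and is left as-is.
    """
    for channel, role in _ROLE_FOR_CHANNEL.items():
        if role not in blanks:
            raise ValidationError(f"missing background role {role!r} (needed for {channel})")
    od = tc.od - _align(tc.times, blanks["media_blank"], "od")
    yfp = tc.yfp - _align(tc.times, blanks["mcherry_background_strain"], "yfp")
    mch = tc.mcherry - _align(tc.times, blanks["yfp_background_strain"], "mcherry")
    od = np.maximum(od, 0.0)
    return TimeCourse(
        well_id=tc.well_id, strain_id=tc.strain_id, times=tc.times,
        od=od, yfp=yfp, mcherry=mch, mask=tc.mask.copy(),
    )


# ---------------------------------------------------------------------------
# Point-outlier removal
# ---------------------------------------------------------------------------


def remove_point_outliers(series: np.ndarray, k: float = 5.0, w: int = 5) -> np.ndarray:
    """Flag points that deviate considerably from their neighbours.

    Point i is flagged iff |x_i - running_median_w(i)| > k * MAD_w(i), where
    the running window is centred (shrunk at the edges) and MAD is the raw
    median absolute deviation within the window.  When MAD is 0 (locally
    constant data) only exact deviations from the local median are flagged.
    Returns a boolean is-outlier array; a QC warning is emitted if more than
    10% of points are flagged.
    """
    if w < 3 or w % 2 == 0:
        raise ValueError("window w must be odd and >= 3")
    x = np.asarray(series, dtype=float)
    if len(x) <= w:
        raise ValueError(f"series length {len(x)} must exceed window {w}")
    half = w // 2
    out = np.zeros(len(x), dtype=bool)
    for i in range(len(x)):
        window = x[max(0, i - half): i + half + 1]
        med = np.median(window)
        mad = np.median(np.abs(window - med))
        dev = abs(x[i] - med)
        out[i] = dev > k * mad if mad > 0 else dev > 0
    if out.sum() > 0.10 * len(x):
        warnings.warn(
            f"outlier filter flagged {out.sum()}/{len(x)} points (> 10%)",
            stacklevel=2,
        )
    return out


def mask_timecourse_outliers(tc: TimeCourse, k: float = 5.0, w: int = 5) -> TimeCourse:
    """Apply :func:`remove_point_outliers` to OD, YFP and mCherry independently."""
    bad = np.zeros(tc.n_points, dtype=bool)
    for channel in ("od", "yfp", "mcherry"):
        bad |= remove_point_outliers(getattr(tc, channel), k=k, w=w)
    return tc.with_mask(tc.mask & ~bad)


# ---------------------------------------------------------------------------
# Growth-phase segmentation
# ---------------------------------------------------------------------------

_LOG_EPS = 1e-4  # OD offset inside the log transform


def _moving_linear_slope(t: np.ndarray, y: np.ndarray, w: int = 5) -> np.ndarray:
    """Slope of a centred moving linear fit (window shrunk at the edges)."""
    half = w // 2
    slopes = np.empty(len(y))
    for i in range(len(y)):
        sl = slice(max(0, i - half), i + half + 1)
        tt, yy = t[sl], y[sl]
        tbar, ybar = tt.mean(), yy.mean()
        denom = np.sum((tt - tbar) ** 2)
        slopes[i] = np.sum((tt - tbar) * (yy - ybar)) / denom if denom > 0 else 0.0
    return slopes


def _moving_quadratic_value(t: np.ndarray, y: np.ndarray, w: int = 7) -> np.ndarray:
    """Centred moving local-quadratic fit evaluated at each point.

    Damps independent measurement noise while reproducing any locally
    quadratic trend exactly; windows shrink at the edges and the series is
    returned unsmoothed when fewer than 4 points fall in a window.
    """
    half = w // 2
    out = np.empty(len(y))
    for i in range(len(y)):
        sl = slice(max(0, i - half), i + half + 1)
        tt, yy = t[sl] - t[i], y[sl]
        if len(tt) < 4:
            out[i] = y[i]
            continue
        A = np.column_stack([np.ones_like(tt), tt, tt * tt])
        coef, *_ = np.linalg.lstsq(A, yy, rcond=None)
        out[i] = coef[0]
    return out


def _model_residual_outliers(
    t: np.ndarray, y: np.ndarray, w: int = 7, k: float = 5.0
) -> np.ndarray:
    """Flag points deviating > k scaled MADs from a local-quadratic trend.

    Two passes: the trend is refit without first-pass flags so that a spike
    cannot hide behind its own influence on the local fit.  The threshold is
    floored at 10% of the local trend magnitude, so only genuine artefacts —
    not ordinary measurement noise in a short window — are ever flagged.
    Catches the moderate artefacts that evade the running-median rule on
    steeply growing series.
    """
    def mad(r: np.ndarray) -> float:
        return 1.4826 * float(np.median(np.abs(r - np.median(r))))

    def flag(resid: np.ndarray, trend: np.ndarray, s: float) -> np.ndarray:
        return np.abs(resid) > np.maximum(k * s, 0.1 * np.abs(trend))

    trend = _moving_quadratic_value(t, y, w)
    resid = y - trend
    flags = flag(resid, trend, mad(resid))
    if flags.any() and (~flags).sum() >= 4:
        ok = ~flags
        trend = np.interp(t, t[ok], _moving_quadratic_value(t[ok], y[ok], w))
        resid = y - trend
        flags = flag(resid, trend, mad(resid[ok]))
    return flags


def _longest_true_run(flags: np.ndarray) -> tuple[int, int]:
    """(start, stop) inclusive indices of the longest contiguous True run."""
    best, best_len = (0, -1), 0
    start = None
    for i, f in enumerate(np.append(flags, False)):
        if f and start is None:
            start = i
        elif not f and start is not None:
            if i - start > best_len:
                best, best_len = (start, i - 1), i - start
            start = None
    if best_len == 0:
        raise NoGrowthError("no exponential-growth run found")
    return best


def segment_growth_phases(
    times: np.ndarray,
    od: np.ndarray,
    mask: np.ndarray | None = None,
    *,
    exp_threshold: float = 0.8,
    stat_threshold: float = 0.05,
    smooth_window: int = 11,
) -> GrowthPhases:
    """Divide a background-subtracted OD curve into the four growth phases.

    The exponential phase is the longest contiguous run where the smoothed
    d(log OD)/dt is at least ``exp_threshold`` times its maximum; lag is
    everything before it; the stationary phase is the trailing run where the
    smoothed d(OD)/dt drops to at most ``stat_threshold`` of its own maximum;
    the linear phase is whatever remains in between.  All boundaries snap to
    sample times.  Requires the OD to reach at least 3x its initial value.
    """
    times = np.asarray(times, dtype=float)
    od = np.asarray(od, dtype=float)
    if mask is not None:
        keep = np.asarray(mask, dtype=bool)
        times, od = times[keep], od[keep]
    if len(od) < 4:
        raise ValidationError("need >= 4 valid points to segment growth phases")
    od_init = max(float(np.median(od[:5])), _LOG_EPS)  # robust to leading artefacts
    if np.max(od) < 3.0 * od_init:
        raise NoGrowthError(
            f"OD grows only {np.max(od) / od_init:.2f}x; need >= 3x"
        )

    def robust_max(v: np.ndarray) -> float:
        # Median of the top 5 values: a single noise-inflated slope estimate
        # (typically at a shrunken edge window) must not set the threshold.
        top = np.sort(v)[-min(5, len(v)):]
        return float(np.median(top))

    def bridge(flags: np.ndarray, gap: int = 2) -> np.ndarray:
        # One or two sub-threshold points inside a run are noise, not a
        # phase change; only longer interruptions split the run.
        out = flags.copy()
        i, n = 0, len(flags)
        while i < n:
            if not out[i]:
                j = i
                while j < n and not out[j]:
                    j += 1
                if 0 < i and j < n and (j - i) <= gap:
                    out[i:j] = True
                i = j
            else:
                i += 1
        return out

    dlog = _moving_linear_slope(times, np.log(od + _LOG_EPS), smooth_window)
    e0, e1 = _longest_true_run(bridge(dlog >= exp_threshold * robust_max(dlog)))
    dod = _moving_linear_slope(times, od, smooth_window)
    flat = dod <= stat_threshold * robust_max(dod)
    s0 = len(od)  # first index of the trailing flat run; len(od) if none
    while s0 > 0 and flat[s0 - 1]:
        s0 -= 1

    dt = float(np.median(np.diff(times)))
    t_end = times[-1] + dt  # exclusive end of the last half-open interval

    def t_at(i: int) -> float:
        return float(times[i]) if i < len(times) else t_end

    b1 = t_at(e0)               # lag -> exponential
    b2 = t_at(e1 + 1)           # exponential -> linear
    b3 = max(b2, t_at(s0))      # linear -> stationary (never before exp end)
    return GrowthPhases(
        lag=(float(times[0]), b1),
        exponential=(b1, b2),
        linear=(b2, b3),
        stationary=(b3, t_end),
    )


# ---------------------------------------------------------------------------
# Production per cell
# ---------------------------------------------------------------------------


def production_per_cell(
    tc: TimeCourse, phases: GrowthPhases, channel: str = "yfp",
    method: str = "regression",
) -> ExpressionMeasure:
    """Fluorescence produced during exponential phase per unit of OD integral.

    The defining measure is (F(t_end) - F(t_start)) / integral of OD over the
    exponential phase (trapezoidal, unmasked points only); units a.u. *
    OD^-1 * s^-1.  Because dF/dt = production * OD throughout the phase, F is
    linear in the running OD integral I(t), and the default ``"regression"``
    estimator takes the least-squares slope of F against I — numerically
    identical for noise-free data but using every point in the window rather
    than only its endpoints.  Points whose raw residual exceeds 5 scaled MADs
    are dropped first (spike artefacts that survived the point-outlier mask),
    then both channels are damped with a centred moving local-quadratic fit
    before the final slope.  ``method="endpoint"`` computes the literal
    endpoint ratio.
    """
    if channel not in ("yfp", "mcherry"):
        raise ValueError("channel must be 'yfp' or 'mcherry'")
    t0, t1 = phases.exponential
    keep = tc.mask & (tc.times >= t0) & (tc.times < t1)
    if keep.sum() < 2:
        raise ValidationError(
            f"{tc.strain_id}: < 2 valid points inside the exponential phase"
        )
    t = tc.times[keep]
    f = getattr(tc, channel)[keep]
    od = tc.od[keep]
    denom = float(np.trapezoid(od, t))
    if denom <= 0:
        raise ValidationError(f"{tc.strain_id}: OD integral over exponential phase is <= 0")
    if method == "endpoint":
        production = float(f[-1] - f[0]) / denom
    elif method == "regression":
        def running_integral(o: np.ndarray, tt: np.ndarray) -> np.ndarray:
            return np.concatenate(
                [[0.0], np.cumsum(0.5 * (o[1:] + o[:-1]) * np.diff(tt))]
            )

        def slope(x: np.ndarray, y: np.ndarray) -> float:
            xc, yc = x - x.mean(), y - y.mean()
            return float(xc @ yc / (xc @ xc))

        good = ~(_model_residual_outliers(t, f) | _model_residual_outliers(t, od))
        if good.sum() < 4:
            good = np.ones(len(f), dtype=bool)
        t2, f2, od2 = t[good], f[good], od[good]
        f2 = _moving_quadratic_value(t2, f2)
        od2 = _moving_quadratic_value(t2, od2)
        production = slope(running_integral(od2, t2), f2)
    else:
        raise ValueError("method must be 'regression' or 'endpoint'")
    return ExpressionMeasure(
        strain_id=tc.strain_id,
        production=production,
        window=(float(t[0]), float(t[-1])),
        channel=channel,
        n_outliers_removed=int((~tc.mask).sum()),
    )


def process_timecourse(
    tc: TimeCourse,
    blanks: Mapping[str, TimeCourse],
    channel: str = "yfp",
    *,
    outlier_k: float = 5.0,
    outlier_w: int = 5,
    normalize_mcherry: bool = False,
) -> ExpressionMeasure:
    """Full per-well pipeline: subtract, mask outliers, segment, integrate.

    By default YFP values are *not* normalised to mCherry; with
    ``normalize_mcherry`` the returned production is the ratio of the YFP and
    mCherry production rates over the same exponential window.
    """
    blanks = {
        role: mask_timecourse_outliers(blank, k=outlier_k, w=outlier_w)
        for role, blank in blanks.items()
    }
    clean = subtract_background(tc, blanks)
    clean = mask_timecourse_outliers(clean, k=outlier_k, w=outlier_w)
    phases = segment_growth_phases(clean.times, clean.od, clean.mask)
    measure = production_per_cell(clean, phases, channel)
    if normalize_mcherry and channel == "yfp":
        ref = production_per_cell(clean, phases, "mcherry")
        measure.production = measure.production / ref.production
    measure.background_roles = tuple(sorted(blanks))
    return measure


# ---------------------------------------------------------------------------
# Clone concordance
# ---------------------------------------------------------------------------


@dataclass
class CloneFilterResult:
    accepted: dict[str, float]
    rejected: dict[str, list[tuple[int, int, float]]]
    unvalidated: list[str]


def concordant_clone_filter(
    measures: Mapping[str, Sequence[float]], tol: float = 0.15
) -> CloneFilterResult:
    """Accept strains with at least one pair of concordant clone measurements.

    A strain is accepted iff some pair of clones satisfies
    |p1 - p2| / mean(p1, p2) <= tol; its value is the mean of the *best*
    (most concordant) such pair.  Strains with a single clone are reported as
    unvalidated; strains with no concordant pair are rejected, listing all
    pairwise discrepancies.
    """
    result = CloneFilterResult(accepted={}, rejected={}, unvalidated=[])
    for strain, clones in measures.items():
        clones = list(clones)
        if len(clones) < 2:
            result.unvalidated.append(strain)
            continue
        pairs = []
        for i, j in combinations(range(len(clones)), 2):
            mean = (clones[i] + clones[j]) / 2.0
            disc = abs(clones[i] - clones[j]) / mean if mean != 0 else np.inf
            pairs.append((i, j, disc))
        best = min(pairs, key=lambda p: p[2])
        if best[2] <= tol:
            i, j, _ = best
            result.accepted[strain] = (clones[i] + clones[j]) / 2.0
        else:
            result.rejected[strain] = pairs
    return result
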