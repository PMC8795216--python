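"""Time-attenuation-curve analysis: delays, velocities, flow patterns.

For every voxel along a centerline path the attenuation-versus-time
curve (TAC) is extracted, resampled to a finer time grid, low-pass
filtered with a zero-phase Butterworth filter and baseline-subtracted.
The arrival-time difference of each TAC relative to the most proximal
marker's TAC is estimated as the lag maximizing their normalized
cross-correlation.  Plotting these delays against arc-length from the
proximal marker gives a delay profile whose per-segment linear-regression
slope is the inverse of the average contrast velocity: a positive slope
(delay growing with distance) means anterograde flow, a negative slope
retrograde flow fed by collaterals.  The daughter-segment directions
classify a case into Pattern I (all anterograde), II (all retrograde)
or III (both).

Zero-phase filtering is essential here: the time shift between TACs is
the measurand, so the conditioning chain must not introduce differential
delays of its own.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
from scipy import signal, stats

from .geometry import CenterlinePath
from .preprocess import DynamicCTA

ANTEROGRADE = "anterograde"
RETROGRADE = "retrograde"
UNRESOLVED = "unresolved"


@dataclass
class TAC:
    """One voxel's attenuation-versus-time curve."""

    times: np.ndarray          # s
    values: np.ndarray         # HU
    voxel: tuple
    arclength_mm: float
    state: str = "raw"         # "raw" or "conditioned"
    valid: bool = True

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have the same length")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class DelayPoint:
    """Estimated arrival delay of one TAC relative to the proximal TAC."""

    arclength_mm: float
    delay_s: Optional[float]
    valid: bool
    correlation_peak: Optional[float]
    voxel: tuple = None
    reason: Optional[str] = None


@dataclass
class SegmentFlow:
    """Per-segment regression of delay on distance.

    ``velocity_mm_s`` is the inverse slope, signed: positive anterograde,
    negative retrograde.  Slopes inside the dead band ±slope_min are
    below the temporal quantization floor of the acquisition and are
    reported as unresolved rather than as a direction.
    """

    path_id: str
    segment_id: str
    slope_s_per_mm: Optional[float]
    velocity_mm_s: Optional[float]
    direction: str
    n_points: int
    r_squared: Optional[float] = None
    residual_sd_s: Optional[float] = None
    reason: Optional[str] = None


@dataclass
class FlowPatternResult:
    """Distal flow pattern of a case, from daughter-segment directions."""

    pattern: str               # "I" | "II" | "III" | "indeterminate"
    daughters: list = field(default_factory=list)
    notes: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# TAC extraction and conditioning

def extract_tacs(dyn: DynamicCTA, path: CenterlinePath) -> List[TAC]:
    """Raw TAC for every voxel of a centerline path."""
    shape = dyn.spatial_shape
    tacs = []
    for voxel, arc in zip(path.voxels, path.arclength_mm):
        if any(not 0 <= v < s for v, s in zip(voxel, shape)):
            raise ValueError(f"path voxel {voxel} outside volume {shape}")
        tacs.append(TAC(dyn.times, dyn.data[voxel], voxel, float(arc)))
    return tacs


def _baseline(values: np.ndarray) -> float:
    """Mean of the pre-arrival samples (before the curve first exceeds
    10% of its dynamic range); the global mean for a flat curve."""
    rng = values.max() - values.min()
    if rng <= 0:
        return float(values.mean())
    thresh = values.min() + 0.1 * rng
    above = np.nonzero(values > thresh)[0]
    first = above[0] if len(above) else len(values)
    if first < 1:
        return float(values[0])
    return float(values[:first].mean())


def condition_tac(tac: TAC, upsample_factor: int = 10,
                  cutoff_hz: float = 0.1, order: int = 4) -> TAC:
    """Baseline-subtract, band-limited upsample and zero-phase low-pass.

    The TAC is resampled to ``dt / upsample_factor`` with a polyphase
    band-limited interpolator and filtered forward-backward with a
    Butterworth low-pass, so the conditioning introduces no time shift.
    """
    if tac.state != "raw":
        raise ValueError("condition_tac expects a raw TAC")
    if upsample_factor < 1:
        raise ValueError("upsample_factor must be >= 1")
    dt = float(np.median(np.diff(tac.times)))
    fs_up = upsample_factor / dt
    if cutoff_hz >= fs_up / 2:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz is at or above the Nyquist frequency "
            f"{fs_up / 2} Hz of the upsampled grid")
    vals = tac.values - _baseline(tac.values)
    if upsample_factor > 1:
        vals = signal.resample_poly(vals, upsample_factor, 1, padtype="line")
        times = tac.times[0] + np.arange(len(vals)) * dt / upsample_factor
    else:
        times = tac.times.copy()
    b, a = signal.butter(order, cutoff_hz, fs=fs_up)
    vals = signal.filtfilt(b, a, vals)
    return TAC(times, vals, tac.voxel, tac.arclength_mm, state="conditioned",
               valid=tac.valid)


def qc_discard(tacs: List[TAC], proximal_reference: TAC,
               fraction: float = 0.05) -> List[TAC]:
    """Flag TACs whose peak is below a fraction of the proximal peak.

    A TAC with maximum strictly less than ``fraction`` times the maximum
    of the proximal reference carries too little contrast for a reliable
    delay estimate and is marked invalid; a TAC at exactly the fraction
    is kept (the comparison is strict).
    """
    ref_max = float(np.max(proximal_reference.values))
    if ref_max <= 0:
        raise ValueError("proximal reference TAC has non-positive maximum")
    cut = fraction * ref_max
    for tac in tacs:
        if float(np.max(tac.values)) < cut:
            tac.valid = False
    return tacs


# ---------------------------------------------------------------------------
# delay estimation

def estimate_delay(values: np.ndarray, reference: np.ndarray, dt: float,
                   max_lag_s: float = None, refine: bool = True):
    """Lag (s) maximizing the normalized cross-correlation.

    The correlation is the Pearson coefficient of the two curves over
    their overlapping support, evaluated at every integer lag within
    ±max_lag_s (default: half the record duration); a positive delay
    means ``values`` lags ``reference``.  Ties at the peak go to the
    smaller |lag|, and the peak is optionally refined to sub-sample
    precision with a quadratic fit.

    Returns (delay_s, peak_correlation).
    """
    a = np.asarray(values, dtype=float)
    b = np.asarray(reference, dtype=float)
    if a.shape != b.shape:
        raise ValueError("TAC and reference must share one time grid")
    n = len(a)
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance TAC")
    if max_lag_s is None:
        max_lag_s = 0.5 * n * dt
    max_lag = min(n - 3, int(round(max_lag_s / dt)))
    lags = np.arange(-max_lag, max_lag + 1)
    corr = _pearson_lag_profile(a, b, max_lag)
    best = np.max(corr)
    if not np.isfinite(best):
        raise ValueError("cross-correlation undefined at every lag")
    cand = np.nonzero(corr >= best - 1e-12)[0]
    # tie-break: smallest |lag|, then the positive one
    i = min(cand, key=lambda j: (abs(int(lags[j])), -int(lags[j])))
    delay = lags[i] * dt
    if refine and 0 < i < len(lags) - 1:
        ym, y0, yp = corr[i - 1], corr[i], corr[i + 1]
        denom = ym - 2 * y0 + yp
        if np.isfinite(ym) and np.isfinite(yp) and denom < -1e-15:
            frac = 0.5 * (ym - yp) / denom
            delay += float(np.clip(frac, -1, 1)) * dt
    return float(delay), float(corr[i])


def _pearson_lag_profile(a, b, max_lag):
    """Pearson correlation over the overlapping support per integer lag,
    for lags -max_lag..max_lag, vectorized with running sums."""
    n = len(a)
    full = np.correlate(a, b, mode="full")  # index k: lag k - (n-1)
    lags = np.arange(-max_lag, max_lag + 1)
    sxy = full[lags + n - 1]
    csum_a = np.concatenate([[0.0], np.cumsum(a)])
    csum_b = np.concatenate([[0.0], np.cumsum(b)])
    csum_a2 = np.concatenate([[0.0], np.cumsum(a * a)])
    csum_b2 = np.concatenate([[0.0], np.cumsum(b * b)])
    m = n - np.abs(lags)
    pos = lags >= 0
    lo_a = np.where(pos, lags, 0)
    lo_b = np.where(pos, 0, -lags)
    sx = csum_a[lo_a + m] - csum_a[lo_a]
    sy = csum_b[lo_b + m] - csum_b[lo_b]
    sx2 = csum_a2[lo_a + m] - csum_a2[lo_a]
    sy2 = csum_b2[lo_b + m] - csum_b2[lo_b]
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sy / m
        var_x = sx2 - sx * sx / m
        var_y = sy2 - sy * sy / m
        corr = cov / np.sqrt(var_x * var_y)
    corr[(m < 3) | ~np.isfinite(corr)] = -np.inf
    return corr


def xcorr_delay(tac: TAC, reference: TAC, max_lag_s: float = None,
                refine: bool = True) -> DelayPoint:
    """Delay of a conditioned TAC relative to the proximal reference."""
    if tac.state != "conditioned" or reference.state != "conditioned":
        raise ValueError("xcorr_delay expects conditioned TACs")
    if not np.allclose(tac.times, reference.times):
        raise ValueError("TAC and reference are not on the same time grid")
    if not tac.valid:
        return DelayPoint(tac.arclength_mm, None, False, None, tac.voxel,
                          reason="discarded by QC")
    dt = float(np.median(np.diff(tac.times)))
    try:
        delay, peak = estimate_delay(tac.values, reference.values, dt,
                                     max_lag_s=max_lag_s, refine=refine)
    except ValueError as exc:
        return DelayPoint(tac.arclength_mm, None, False, None, tac.voxel,
                          reason=str(exc))
    return DelayPoint(tac.arclength_mm, delay, True, peak, tac.voxel)


# ---------------------------------------------------------------------------
# delay profiles, velocities and patterns

def delay_profile(path: CenterlinePath, delaypoints: List[DelayPoint],
                  segments=None, min_points: int = 3):
    """Group valid delay points by path segment.

    Returns (series, flagged): ``series`` maps segment_id to an (n, 2)
    array of (arclength_mm, delay_s) ordered by arc-length, for segments
    with at least ``min_points`` valid points; ``flagged`` lists the
    segments excluded for having fewer.
    """
    if len(delaypoints) != len(path):
        raise ValueError("one delay point per path voxel is required")
    groups = {}
    for seg_id, dp in zip(path.segment_ids, delaypoints):
        if dp.valid:
            groups.setdefault(seg_id, []).append((dp.arclength_mm, dp.delay_s))
    series, flagged = {}, []
    wanted = [s for s in dict.fromkeys(path.segment_ids) if s in set(segments)] \
        if segments is not None else list(dict.fromkeys(path.segment_ids))
    for seg_id in wanted:
        pts = np.asarray(sorted(groups.get(seg_id, [])))
        if len(pts) < min_points:
            flagged.append(seg_id)
        else:
            series[seg_id] = pts
    return series, flagged


def fit_segment_velocity(series: np.ndarray, path_id: str = "path",
                         segment_id: str = "segment",
                         slope_min: float = 0.005,
                         estimator: str = "ols") -> SegmentFlow:
    """Velocity and direction of one segment from its delay profile.

    Ordinary least squares of delay (s) on arc-length (mm); the inverse
    slope is the average contrast velocity in mm/s.  Slopes within
    ±slope_min s/mm (|v| above 1/slope_min mm/s) are unresolved: with a
    2 s frame interval such delays are below the quantization floor and
    the sign carries no information.  A Theil–Sen estimator is available
    for outlier-heavy profiles.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 2 or series.shape[1] != 2 or len(series) < 3:
        return SegmentFlow(path_id, segment_id, None, None, UNRESOLVED,
                           len(series), reason="fewer than 3 valid points")
    x, y = series[:, 0], series[:, 1]
    if np.ptp(x) == 0:
        return SegmentFlow(path_id, segment_id, None, None, UNRESOLVED,
                           len(series), reason="degenerate arc-length range")
    if estimator == "ols":
        fit = stats.linregress(x, y)
        slope, intercept = fit.slope, fit.intercept
        r2 = fit.rvalue ** 2
    elif estimator == "theilsen":
        slope, intercept, *_ = stats.theilslopes(y, x)
        ss_res = np.sum((y - (slope * x + intercept)) ** 2)
        ss_tot = np.sum((y - y.mean()) ** 2)
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else None
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    resid = y - (slope * x + intercept)
    sd = float(np.std(resid, ddof=2)) if len(series) > 2 else None
    if slope > slope_min:
        direction = ANTEROGRADE
    elif slope < -slope_min:
        direction = RETROGRADE
    else:
        direction = UNRESOLVED
    velocity = 1.0 / slope if slope != 0 else None
    return SegmentFlow(path_id, segment_id, float(slope),
                       None if velocity is None else float(velocity),
                       direction, len(series),
                       r_squared=None if r2 is None else float(r2),
                       residual_sd_s=sd,
                       reason="slope within dead band" if direction == UNRESOLVED else None)


def classify_pattern(flows: List[SegmentFlow]) -> FlowPatternResult:
    """Distal flow pattern from the daughter-segment directions.

    Pattern I: every resolved daughter anterograde; II: every resolved
    daughter retrograde; III: both directions present.  Unresolved
    segments are listed in the notes and excluded from the vote; with no
    resolved segment at all the outcome is 'indeterminate'.
    """
    daughters = [{"path_id": f.path_id, "segment_id": f.segment_id,
                  "direction": f.direction,
                  "velocity_mm_s": f.velocity_mm_s} for f in flows]
    notes = [f"{f.segment_id}: unresolved"
             + (f" ({f.reason})" if f.reason else "")
             for f in flows if f.direction == UNRESOLVED]
    dirs = {f.direction for f in flows if f.direction != UNRESOLVED}
    if not dirs:
        return FlowPatternResult("indeterminate", daughters, notes)
    if dirs == {ANTEROGRADE}:
        pattern = "I"
    elif dirs == {RETROGRADE}:
        pattern = "II"
    else:
        pattern = "III"
    return FlowPatternResult(pattern, daughters, notes)
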