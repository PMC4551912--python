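"""Growth normalization and promoter-activity (expression velocity) extraction.

Growth-normalized fluorescence is F(t)/OD(t) in AFU/OD. Background
autofluorescence is removed by subtracting the mean normalized trace of
reporter-free control wells at matched timepoints. Promoter activity is the
raw first difference of the normalized trace per interval, divided by the
interval length in seconds (AFU*OD^-1*s^-1), and the maximum over
post-induction intervals is the velocity used for transfer-function modeling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .datamodel import WellTimeSeries
from .errors import EstimationError, ValidationError

#: OD below this floor is treated as unmeasurable for normalization.
OD_FLOOR = 0.01


@dataclass
class NormalizedSeries:
    """Growth-normalized fluorescence trace of one well."""

    times: np.ndarray
    values: np.ndarray  # AFU/OD
    background_subtracted: bool
    channel: str
    well: str
    n_excluded: int = 0


@dataclass
class VelocitySeries:
    """Per-interval expression rates and the post-induction maximum."""

    interval_midtimes: np.ndarray
    rates: np.ndarray  # AFU * OD^-1 * s^-1
    max_rate: float
    max_rate_time: float


def _control_matrix(
    times: np.ndarray,
    controls: Sequence[WellTimeSeries],
    channel: str,
    od_floor: float,
) -> np.ndarray:
    """Mean control AFU/OD at each requested timepoint.

    Controls must share the well's time grid; nearest-neighbor matching
    within half a sampling interval is accepted, anything farther is an
    error.
    """
    interval = float(np.median(np.diff(times))) if times.size > 1 else np.inf
    traces = []
    for c in controls:
        usable = c.od > od_floor
        ct = c.times[usable]
        cv = c.fluorescence[channel][usable] / c.od[usable]
        if ct.size == 0:
            raise ValidationError(f"control well {c.well}: no samples above the OD floor")
        idx = np.clip(np.searchsorted(ct, times), 0, ct.size - 1)
        idx_prev = np.clip(idx - 1, 0, ct.size - 1)
        pick = np.where(
            np.abs(ct[idx] - times) <= np.abs(ct[idx_prev] - times), idx, idx_prev
        )
        if np.any(np.abs(ct[pick] - times) > interval / 2.0):
            raise ValidationError(
                f"control well {c.well} is on a different time grid "
                "(no sample within half an interval of a well timepoint)"
            )
        traces.append(cv[pick])
    return np.mean(traces, axis=0)


def normalize(
    well: WellTimeSeries,
    controls: Sequence[WellTimeSeries] | None = None,
    channel: str | None = None,
    od_floor: float = OD_FLOOR,
) -> NormalizedSeries:
    """Growth-normalize one well: AFU/OD, optionally background-subtracted.

    Samples with OD at or below ``od_floor`` are excluded with a warning.
    The subtracted trace may be negative.
    """
    channel = channel or well.channels[0]
    usable = well.od > od_floor
    n_excl = int((~usable).sum())
    if n_excl:
        warnings.warn(
            f"well {well.well}: excluded {n_excl} samples with OD <= {od_floor}",
            stacklevel=2,
        )
    times = well.times[usable]
    if times.size < 2:
        raise EstimationError(
            f"well {well.well}: fewer than 2 samples above the OD floor"
        )
    values = well.fluorescence[channel][usable] / well.od[usable]
    subtracted = False
    if controls:
        values = values - _control_matrix(times, controls, channel, od_floor)
        subtracted = True
    return NormalizedSeries(
        times=times,
        values=values,
        background_subtracted=subtracted,
        channel=channel,
        well=well.well,
        n_excluded=n_excl,
    )


def expression_rates(
    series: NormalizedSeries,
    induction_time: float = 0.0,
    smooth_window: int = 0,
) -> VelocitySeries:
    """Per-interval expression rates (first differences per second) and the
    maximum over intervals whose midtime is at or after induction.

    ``smooth_window`` (odd, >= 3) applies an optional rolling median to the
    normalized trace before differencing; it is off by default and the
    default is what the characterization protocol prescribes.
    """
    t = series.times
    y = series.values
    if t.size < 2:
        raise EstimationError("expression_rates requires at least 2 samples")
    if smooth_window:
        if smooth_window < 3 or smooth_window % 2 == 0:
            raise ValueError("smooth_window must be an odd integer >= 3")
        pad = smooth_window // 2
        padded = np.pad(y, pad, mode="edge")
        y = np.array(
            [np.median(padded[i : i + smooth_window]) for i in range(y.size)]
        )
    dt_s = np.diff(t) * 60.0
    rates = np.diff(y) / dt_s
    mid = 0.5 * (t[1:] + t[:-1])
    post = mid >= induction_time
    if not post.any():
        raise EstimationError("no intervals at or after the induction time")
    i = int(np.flatnonzero(post)[np.argmax(rates[post])])
    return VelocitySeries(
        interval_midtimes=mid,
        rates=rates,
        max_rate=float(rates[i]),
        max_rate_time=float(mid[i]),
    )


def normalize_for_display(series: Sequence[NormalizedSeries]) -> list[NormalizedSeries]:
    """Scale a group of traces onto a common axis by dividing every value by
    110% of the group's highest value (the scaled maximum is 1/1.1, so an
    already-scaled group is a fixed point of the transform)."""
    if not series:
        return []
    peak = max(float(np.max(s.values)) for s in series)
    scale = 1.1 * peak
    return [
        NormalizedSeries(
            times=s.times.copy(),
            values=s.values / scale,
            background_subtracted=s.background_subtracted,
            channel=s.channel,
            well=s.well,
            n_excluded=s.n_excluded,
        )
        for s in series
    ]


def display_growth(times: np.ndarray, od: np.ndarray) -> np.ndarray:
    """Display transform for growth curves: divide by the mid-point value,
    then offset so the trace starts at zero."""
    times = np.asarray(times, dtype=float)
    od = np.asarray(od, dtype=float)
    mid_time = 0.5 * (times[0] + times[-1])
    mid_value = od[int(np.argmin(np.abs(times - mid_time)))]
    y = od / mid_value
    return y - y[0]
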