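"""Dose-dependent growth effects of inducer chemicals.

Two normalizations are supported, both against untreated (zero-dose) wells:
the exponential-phase growth-rate ratio, and the endpoint-OD ratio. The
exponential window is detected as the maximal-slope contiguous run of at
least 4 samples whose ln(OD)-vs-time regression reaches R^2 >= 0.99 with a
positive slope, preferring the widest window among slope ties; on a clean
logistic trace this lands on the early post-lag region where ln(OD) is
genuinely linear.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import PlateExperiment, WellTimeSeries
from .errors import EstimationError
from .kinetics import OD_FLOOR


@dataclass(frozen=True)
class GrowthRateFit:
    rate: float  # per minute
    window: tuple[float, float]  # (t_start, t_end) minutes
    r_squared: float
    n_points: int


def growth_rate(
    well: WellTimeSeries,
    od_floor: float = OD_FLOOR,
    min_points: int = 4,
    r2_min: float = 0.99,
) -> GrowthRateFit:
    """Exponential-phase growth rate (per minute) of one well.

    Fits ln(OD) vs time on the maximal-slope qualifying contiguous window
    (widest among near-ties).
    """
    usable = well.od > od_floor
    t = well.times[usable]
    y = np.log(well.od[usable])
    n = t.size
    if n < min_points:
        raise EstimationError(
            f"well {well.well}: fewer than {min_points} samples above the OD floor"
        )
    # Prefix sums give O(1) regression statistics per window.
    one = np.concatenate([[0.0], np.cumsum(np.ones(n))])
    sx = np.concatenate([[0.0], np.cumsum(t)])
    sy = np.concatenate([[0.0], np.cumsum(y)])
    sxx = np.concatenate([[0.0], np.cumsum(t * t)])
    sxy = np.concatenate([[0.0], np.cumsum(t * y)])
    syy = np.concatenate([[0.0], np.cumsum(y * y)])

    best: GrowthRateFit | None = None
    for width in range(min_points, n + 1):
        for start in range(0, n - width + 1):
            end = start + width
            m = one[end] - one[start]
            vx = (sxx[end] - sxx[start]) - (sx[end] - sx[start]) ** 2 / m
            vy = (syy[end] - syy[start]) - (sy[end] - sy[start]) ** 2 / m
            cxy = (sxy[end] - sxy[start]) - (sx[end] - sx[start]) * (sy[end] - sy[start]) / m
            if vx <= 0 or vy <= 0:
                continue  # constant OD (or time) window: R^2 undefined
            slope = cxy / vx
            r2 = (cxy * cxy) / (vx * vy)
            if slope <= 0 or r2 < r2_min:
                continue
            cand = GrowthRateFit(
                rate=float(slope),
                window=(float(t[start]), float(t[end - 1])),
                r_squared=float(r2),
                n_points=int(m),
            )
            if (
                best is None
                or cand.rate > best.rate * (1.0 + 1e-9)
                or (cand.rate >= best.rate * (1.0 - 1e-9) and cand.n_points > best.n_points)
            ):
                best = cand
    if best is not None:
        return best
    raise EstimationError(
        f"well {well.well}: no contiguous window of >= {min_points} points with "
        f"R^2 >= {r2_min} and positive slope"
    )


def _endpoint_od(well: WellTimeSeries, endpoint_min: float | None) -> float:
    if endpoint_min is None:
        return float(well.od[-1])
    i = int(np.argmin(np.abs(well.times - endpoint_min)))
    interval = float(np.median(np.diff(well.times)))
    if abs(well.times[i] - endpoint_min) > interval / 2.0:
        raise EstimationError(
            f"well {well.well}: no sample within half an interval of {endpoint_min} min"
        )
    return float(well.od[i])


def toxicity_profile(
    exp: PlateExperiment,
    mode: str = "rate",
    endpoint_min: float | None = None,
) -> pd.DataFrame:
    """Per chemical x concentration: replicate-mean normalization against the
    untreated (zero-dose) wells.

    ``mode="rate"`` normalizes exponential-phase growth rates; ``"endpoint"``
    normalizes endpoint OD. Returns a tidy table (chemical, concentration,
    normalized_value, n_replicates, mode); zero-dose rows equal 1 by
    construction.
    """
    if mode not in ("rate", "endpoint"):
        raise ValueError("mode must be 'rate' or 'endpoint'")

    def measure(w: WellTimeSeries) -> float:
        if mode == "endpoint":
            return _endpoint_od(w, endpoint_min)
        try:
            return growth_rate(w).rate
        except EstimationError:
            # fully growth-arrested well: no measurable exponential phase
            warnings.warn(
                f"well {w.well}: no detectable exponential growth; rate set to 0",
                stacklevel=2,
            )
            return 0.0

    reference = [
        w for w in exp.wells
        if w.condition.concentration == 0.0 or w.condition.inducer == "none"
    ]
    if not reference:
        raise EstimationError("missing zero-dose control wells")
    ref_mean = float(np.mean([measure(w) for w in reference]))

    groups: dict[tuple[str, float], list[float]] = {}
    for w in exp.wells:
        if w in reference:
            continue
        key = (w.condition.inducer, w.condition.concentration)
        groups.setdefault(key, []).append(measure(w))
    rows = [("none", 0.0, 1.0, len(reference), mode)]
    for (chem, conc), vals in sorted(groups.items()):
        rows.append((chem, conc, float(np.mean(vals)) / ref_mean, len(vals), mode))
    return pd.DataFrame(
        rows, columns=["chemical", "concentration", "normalized_value", "n_replicates", "mode"]
    )
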