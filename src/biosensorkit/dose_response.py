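"""Endpoint transfer functions, fold induction and confidence intervals.

Fold induction is the background-subtracted induced endpoint signal divided
by the background-subtracted uninduced signal,

    F = I_B / U_B,   I_B = mean(I) - mean(C),   U_B = mean(U) - mean(C),

with standard error propagated by nesting the quadratic sums of the
subtraction errors inside the quadratic sum of the fractional uncertainties
of the ratio:

    sigma_F = F * sqrt[ (s_I^2 + s_C^2)/I_B^2 + (s_U^2 + s_C^2)/U_B^2 ],

where s_I, s_U, s_C are standard errors of the induced, uninduced and
control means. When the uninduced mean lies within the background (its
doubled-SE interval touches zero) a point estimate is undefined and a lower
bound is reported instead: the lower 95% bound of I_B divided by the upper
95% bound of U_B, each interval approximated by doubling the standard error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .datamodel import PlateExperiment
from .errors import EstimationError, UndefinedFoldError
from .kinetics import normalize

DEFAULT_ENDPOINT_MIN = 900.0


def t_interval(values: Sequence[float], level: float = 0.95) -> tuple[float, float]:
    """Student's-t confidence interval for the mean of a small sample."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise EstimationError("t_interval requires at least 2 values")
    m = float(x.mean())
    sem = float(x.std(ddof=1) / np.sqrt(x.size))
    half = float(stats.t.ppf(0.5 * (1.0 + level), x.size - 1)) * sem
    return m - half, m + half


def bootstrap_sem_ci(
    values: Sequence[float],
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap confidence interval for the sample mean."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise EstimationError("bootstrap_sem_ci requires at least 2 values")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    means = x[idx].mean(axis=1)
    lo, hi = np.percentile(means, [50 * (1 - level), 50 * (1 + level)])
    return float(lo), float(hi)


@dataclass(frozen=True)
class TransferPoint:
    """Replicate-mean endpoint response at one inducer concentration."""

    concentration: float
    mean: float  # endpoint AFU/OD
    ci_low: float
    ci_high: float
    n_replicates: int
    sensor: str = ""

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise EstimationError("a transfer point needs >= 1 replicate")


def endpoint_index(times: np.ndarray, endpoint_min: float) -> int:
    """Index of the sample nearest the endpoint, within half an interval."""
    i = int(np.argmin(np.abs(times - endpoint_min)))
    interval = float(np.median(np.diff(times))) if times.size > 1 else np.inf
    if abs(times[i] - endpoint_min) > interval / 2.0:
        raise EstimationError(
            f"no sample within half an interval of the {endpoint_min}-min endpoint"
        )
    return i


def endpoint_values(
    exp: PlateExperiment,
    endpoint_min: float = DEFAULT_ENDPOINT_MIN,
    channel: str | None = None,
    subtract_background: bool = False,
) -> dict[tuple[str, float], np.ndarray]:
    """Per (sensor, concentration): replicate endpoint AFU/OD values."""
    channel = channel or exp.channels[0]
    controls = exp.control_wells if subtract_background else None
    groups: dict[tuple[str, float], list[float]] = {}
    missing = []
    for w in exp.sample_wells:
        ns = normalize(w, controls=controls, channel=channel)
        try:
            i = endpoint_index(ns.times, endpoint_min)
        except EstimationError:
            missing.append(w.well)
            continue
        key = (w.condition.sensor, w.condition.concentration)
        groups.setdefault(key, []).append(float(ns.values[i]))
    if missing:
        raise EstimationError(f"wells missing the endpoint sample: {missing}")
    return {k: np.asarray(v) for k, v in groups.items()}


def transfer_function(
    exp: PlateExperiment,
    endpoint_min: float = DEFAULT_ENDPOINT_MIN,
    channel: str | None = None,
    level: float = 0.95,
) -> dict[str, list[TransferPoint]]:
    """Endpoint transfer function per sensor: replicate-mean AFU/OD and its
    Student's-t confidence interval at every concentration."""
    groups = endpoint_values(exp, endpoint_min=endpoint_min, channel=channel)
    out: dict[str, list[TransferPoint]] = {}
    for (sensor, conc), vals in sorted(groups.items()):
        m = float(vals.mean())
        if vals.size >= 2:
            lo, hi = t_interval(vals, level=level)
        else:
            lo = hi = m
        out.setdefault(sensor, []).append(
            TransferPoint(
                concentration=conc,
                mean=m,
                ci_low=lo,
                ci_high=hi,
                n_replicates=int(vals.size),
                sensor=sensor,
            )
        )
    return out


@dataclass(frozen=True)
class FoldInduction:
    """Fold induction with propagated error, or a lower bound when the
    uninduced signal is within background."""

    value: float
    se: float | None
    is_lower_bound: bool
    components: Mapping[str, float] = field(default_factory=dict)


def fold_induction(
    induced: Sequence[float],
    uninduced: Sequence[float],
    control: Sequence[float],
) -> FoldInduction:
    """Fold induction from replicate endpoint AFU/OD values of the induced,
    uninduced, and background-control groups (>= 2 values per group)."""
    groups = {}
    for name, vals in (("induced", induced), ("uninduced", uninduced), ("control", control)):
        x = np.asarray(vals, dtype=float)
        if x.size < 2:
            raise EstimationError(f"{name} group needs >= 2 replicate values")
        groups[name] = x
    means = {g: float(groups[g].mean()) for g in groups}
    sems = {
        g: float(groups[g].std(ddof=1) / np.sqrt(groups[g].size)) for g in groups
    }
    return fold_induction_from_stats(
        means["induced"], sems["induced"],
        means["uninduced"], sems["uninduced"],
        means["control"], sems["control"],
    )


def fold_induction_from_stats(
    i_mean: float,
    s_i: float,
    u_mean: float,
    s_u: float,
    c_mean: float,
    s_c: float,
) -> FoldInduction:
    """Fold induction from group means and standard errors directly."""
    i_b = i_mean - c_mean
    u_b = u_mean - c_mean
    comp = {
        "I": i_mean, "U": u_mean, "C": c_mean,
        "s_I": s_i, "s_U": s_u, "s_C": s_c,
        "I_B": i_b, "U_B": u_b,
    }
    s_ub = float(np.hypot(s_u, s_c))
    s_ib = float(np.hypot(s_i, s_c))
    if u_b - 2.0 * s_ub <= 0.0:
        denom = u_b + 2.0 * s_ub
        if denom <= 0.0:
            raise UndefinedFoldError(
                "fold induction undefined: uninduced signal is within background "
                "and its upper bound is non-positive"
            )
        return FoldInduction(
            value=(i_b - 2.0 * s_ib) / denom,
            se=None,
            is_lower_bound=True,
            components=comp,
        )
    if u_b <= 0.0:
        raise UndefinedFoldError("fold induction undefined: non-positive uninduced signal")
    f = i_b / u_b
    sigma = abs(f) * float(
        np.sqrt((s_i**2 + s_c**2) / i_b**2 + (s_u**2 + s_c**2) / u_b**2)
    )
    return FoldInduction(value=f, se=sigma, is_lower_bound=False, components=comp)


def fold_induction_from_experiment(
    exp: PlateExperiment,
    sensor: str,
    endpoint_min: float = DEFAULT_ENDPOINT_MIN,
    channel: str | None = None,
) -> FoldInduction:
    """Fold induction of one sensor from an experiment with uninduced wells
    and background controls. The induced group is the replicate set at the
    concentration with the highest mean endpoint response."""
    channel = channel or exp.channels[0]
    groups = endpoint_values(exp, endpoint_min=endpoint_min, channel=channel)
    by_conc = {c: v for (s, c), v in groups.items() if s == sensor}
    if 0.0 not in by_conc:
        raise EstimationError(f"sensor {sensor!r} has no uninduced (zero-dose) wells")
    induced_conc = max(
        (c for c in by_conc if c > 0), key=lambda c: by_conc[c].mean(), default=None
    )
    if induced_conc is None:
        raise EstimationError(f"sensor {sensor!r} has no induced wells")
    controls = exp.control_wells
    if not controls:
        raise EstimationError("experiment has no background-control wells")
    ctrl_vals = []
    for w in controls:
        ns = normalize(w, channel=channel)
        ctrl_vals.append(float(ns.values[endpoint_index(ns.times, endpoint_min)]))
    return fold_induction(by_conc[induced_conc], by_conc[0.0], ctrl_vals)
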