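"""Forward simulation of biosensor characterization experiments.

The generator emulates the plate-reader and cytometry experiments the
analysis modules consume: lagged logistic growth with optional dose-dependent
rate inhibition, Hill-regulated per-cell reporter production with optional
stationary-phase shutoff, autofluorescence background, well-level and
per-read measurement noise, lognormal single-cell fluorescence populations
with a small non-responder fraction, saturating toxicity dose curves, and
sensor-based enzyme-variant screens.

Units: time in minutes, expression velocities in AFU*OD^-1*s^-1 (so the
noise-free growth-normalized fluorescence after t minutes of active
expression is ``v * 60 * t``), concentrations canonical (mol/L, or percent
for solvents).

Reproducibility: each well/sample draws from an independent substream keyed
by (master seed, stream index), so adding wells never perturbs existing ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import Condition, CytometrySample, PlateExperiment, WellTimeSeries
from .errors import ConfigError
from .io import state_label

#: OD fraction of carrying capacity defining the onset of stationary phase.
STATIONARY_FRACTION = 0.95

#: Substream block reserved for background-control wells.
CONTROL_STREAM_BASE = 1_000_000


@dataclass(frozen=True)
class GrowthParams:
    """Lagged logistic growth in OD600 units.

    Defaults emulate E. coli in rich medium in a shaken microplate: a short
    lag, a ~35 min doubling time and saturation around OD 1.
    """

    lag_min: float = 20.0
    rate: float = 0.02  # per-minute exponential rate
    carrying_capacity: float = 1.0
    initial_od: float = 0.05

    def __post_init__(self) -> None:
        if min(self.lag_min, self.rate, self.carrying_capacity, self.initial_od) <= 0:
            raise ConfigError("growth parameters must all be positive")
        if self.initial_od >= self.carrying_capacity:
            raise ConfigError("initial_od must be below carrying_capacity")


@dataclass(frozen=True)
class ExpressionParams:
    """Hill-regulated per-cell reporter production.

    ``v_max``/``v_min`` are maximal and basal promoter activities in
    AFU*OD^-1*s^-1; ``k_half`` is the lumped half-maximal parameter in
    canonical concentration units. With ``stationary_shutoff`` the reporter
    stops accumulating at the onset of stationary phase, unless
    ``post_stationary_accumulation`` is set (a behavior seen for
    repressor systems that keep expressing after growth arrest).
    """

    v_max: float
    v_min: float = 0.0
    hill_h: float = 1.0
    k_half: float = 1e-6
    stationary_shutoff: bool = True
    post_stationary_accumulation: bool = False

    def __post_init__(self) -> None:
        if self.v_max < 0 or self.v_min < 0:
            raise ConfigError("v_max and v_min must be >= 0")
        if self.hill_h <= 0 or self.k_half <= 0:
            raise ConfigError("hill_h and k_half must be > 0")


@dataclass(frozen=True)
class NoiseParams:
    """Measurement-noise model for the plate reader.

    ``well_cv`` is the dominant term: a lognormal well-to-well factor on the
    realized expression velocity, representing inoculum and pipetting
    variation between replicate wells. ``fluor_cv`` is the per-read
    multiplicative photometric jitter and ``od_sd`` the additive absorbance
    repeatability; both are small for a plate reader whose consecutive reads
    of one well track each other closely. ``background_slope`` is the
    autofluorescence of the culture in AFU per OD.
    """

    fluor_cv: float = 0.0005
    od_sd: float = 0.0005
    well_cv: float = 0.05
    background_slope: float = 500.0

    def __post_init__(self) -> None:
        if min(self.fluor_cv, self.od_sd, self.well_cv, self.background_slope) < 0:
            raise ConfigError("noise parameters must all be >= 0")


ZERO_NOISE = NoiseParams(fluor_cv=0.0, od_sd=0.0, well_cv=0.0, background_slope=500.0)


@dataclass(frozen=True)
class ToxicityParams:
    """Saturating dose-dependent growth-rate modulation.

    The exponential growth rate is scaled by
    ``1 + (growth_benefit - max_inhibition) * c^s / (c^s + ic50^s)``:
    inhibition saturates at ``max_inhibition`` while metabolizable inducers
    (e.g. sugars) can instead confer a fractional ``growth_benefit``.
    """

    ic50: float
    steepness: float = 1.0
    max_inhibition: float = 1.0
    growth_benefit: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_inhibition <= 1.0:
            raise ConfigError("max_inhibition must lie in [0, 1]")
        if self.ic50 <= 0 or self.steepness <= 0:
            raise ConfigError("ic50 and steepness must be > 0")
        if self.growth_benefit < 0:
            raise ConfigError("growth_benefit must be >= 0")


@dataclass(frozen=True)
class SensorSpec:
    """One simulated sensor: its transfer function and its dose series."""

    expression: ExpressionParams
    inducer: str
    concentrations: tuple[float, ...]
    copy_number: str = "high"

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.concentrations):
            raise ConfigError("concentrations must be >= 0")


@dataclass(frozen=True)
class GeneratorConfig:
    """Full parameterization of a simulated induction experiment.

    Defaults mirror the characterization protocol the analysis assumes:
    3 replicate wells per condition, 5 background-control wells, 10-min
    sampling over 15 h, and a zero-dose (uninduced) condition per sensor.
    """

    sensors: Mapping[str, SensorSpec]
    growth: GrowthParams = field(default_factory=GrowthParams)
    noise: NoiseParams = field(default_factory=NoiseParams)
    toxicity: Mapping[str, ToxicityParams] = field(default_factory=dict)
    replicates: int = 3
    n_control_wells: int = 5
    sampling_interval_min: float = 10.0
    duration_min: float = 900.0
    include_uninduced: bool = True
    channel: str = "GFP"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_interval_min <= 0:
            raise ConfigError("sampling_interval_min must be > 0")
        if self.replicates < 1:
            raise ConfigError("replicates must be >= 1")

    @property
    def times(self) -> np.ndarray:
        return np.arange(0.0, self.duration_min + 1e-9, self.sampling_interval_min)


def logistic_od(times: np.ndarray, growth: GrowthParams, rate_factor: float = 1.0) -> np.ndarray:
    """Lagged logistic OD(t): flat at initial_od through the lag, then logistic."""
    t = np.asarray(times, dtype=float)
    tau = np.clip(t - growth.lag_min, 0.0, None)
    k, od0 = growth.carrying_capacity, growth.initial_od
    r = growth.rate * rate_factor
    e = np.exp(r * tau)
    return k * od0 * e / (k + od0 * (e - 1.0))


def stationary_onset(growth: GrowthParams, rate_factor: float = 1.0) -> float:
    """Time (min) at which OD first reaches 95% of carrying capacity."""
    a = STATIONARY_FRACTION
    k, od0 = growth.carrying_capacity, growth.initial_od
    if a * k <= od0:
        return growth.lag_min
    e = a * (k - od0) / ((1.0 - a) * od0)
    return growth.lag_min + math.log(e) / (growth.rate * rate_factor)


def hill_rate(expr: ExpressionParams, concentration: float) -> float:
    """Promoter activity v(I) = v_min + v_max * I^h / (I^h + K^h)."""
    if concentration <= 0:
        return expr.v_min
    ih = concentration**expr.hill_h
    kh = expr.k_half**expr.hill_h
    return expr.v_min + expr.v_max * ih / (ih + kh)


def toxicity_factor(params: ToxicityParams | None, concentration: float) -> float:
    """Growth-rate scaling factor for one inducer dose (1.0 when untreated)."""
    if params is None or concentration <= 0:
        return 1.0
    ch = concentration**params.steepness
    occ = ch / (ch + params.ic50**params.steepness)
    return 1.0 + (params.growth_benefit - params.max_inhibition) * occ


def _well_rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([seed, stream])


def _simulate_well(
    well: str,
    condition: Condition,
    expr: ExpressionParams | None,
    config: GeneratorConfig,
    response_concentration: float,
    rng: np.random.Generator,
) -> WellTimeSeries:
    """Simulate one well.

    ``response_concentration`` is the concentration seen by this well's
    sensor through its transfer function (zero for off-target chemicals and
    control strains); growth inhibition always follows the applied chemical.
    """
    times = config.times
    noise = config.noise
    tox = toxicity_factor(config.toxicity.get(condition.inducer), condition.concentration)
    od_true = logistic_od(times, config.growth, tox)

    if expr is None or condition.is_control:
        g = np.zeros_like(times)
    else:
        v = hill_rate(expr, response_concentration)
        if noise.well_cv > 0:
            v *= rng.lognormal(0.0, noise.well_cv)
        if expr.stationary_shutoff and not expr.post_stationary_accumulation:
            t_stop = stationary_onset(config.growth, tox)
            active = np.clip(times, 0.0, t_stop)
        else:
            active = np.clip(times, 0.0, None)
        g = v * 60.0 * active

    f_true = (g + noise.background_slope) * od_true
    if noise.fluor_cv > 0:
        f_true = f_true * rng.lognormal(0.0, noise.fluor_cv, size=times.size)
    od_meas = od_true + (
        rng.normal(0.0, noise.od_sd, size=times.size) if noise.od_sd > 0 else 0.0
    )
    return WellTimeSeries(
        well=well,
        condition=condition,
        times=times,
        od=od_meas,
        fluorescence={config.channel: f_true},
    )


def simulate_plate(config: GeneratorConfig) -> PlateExperiment:
    """Simulate a full induction experiment: dose series per sensor,
    optional uninduced wells, and background-control wells."""
    wells: list[WellTimeSeries] = []
    stream = 0
    for name, spec in config.sensors.items():
        concs = list(spec.concentrations)
        if config.include_uninduced and 0.0 not in concs:
            concs = [0.0] + concs
        for conc in concs:
            for rep in range(1, config.replicates + 1):
                cond = Condition(
                    sensor=name,
                    inducer=spec.inducer,
                    concentration=conc,
                    replicate=rep,
                    copy_number=spec.copy_number,
                )
                wells.append(
                    _simulate_well(
                        f"W{stream:03d}",
                        cond,
                        spec.expression,
                        config,
                        response_concentration=conc,
                        rng=_well_rng(config.seed, stream),
                    )
                )
                stream += 1
    for i in range(config.n_control_wells):
        cond = Condition(
            sensor="control",
            inducer="none",
            concentration=0.0,
            replicate=i + 1,
            is_control=True,
        )
        # controls live in a reserved substream block so that adding sensor
        # wells never perturbs them
        wells.append(
            _simulate_well(
                f"W{stream:03d}",
                cond,
                None,
                config,
                0.0,
                _well_rng(config.seed, CONTROL_STREAM_BASE + i),
            )
        )
        stream += 1
    return PlateExperiment(
        wells=wells,
        channels=[config.channel],
        metadata={"seed": config.seed, "kind": "induction"},
    )


def simulate_crossreact_panel(
    config: GeneratorConfig,
    panel: Mapping[str, float],
) -> PlateExperiment:
    """Simulate the cross-reactivity experiment: every sensor exposed to
    every panel chemical at one concentration, plus uninduced wells and
    background controls.

    Each sensor responds through its Hill transfer function only to its
    cognate inducer; off-target chemicals drive basal expression only (the
    orthogonal regime). Panel concentrations are canonical units.
    """
    wells: list[WellTimeSeries] = []
    stream = 0
    for name, spec in config.sensors.items():
        for chem, conc in panel.items():
            for rep in range(1, config.replicates + 1):
                cond = Condition(
                    sensor=name,
                    inducer=chem,
                    concentration=conc,
                    replicate=rep,
                    copy_number=spec.copy_number,
                )
                response = conc if chem == spec.inducer else 0.0
                wells.append(
                    _simulate_well(
                        f"W{stream:03d}",
                        cond,
                        spec.expression,
                        config,
                        response,
                        _well_rng(config.seed, stream),
                    )
                )
                stream += 1
        for rep in range(1, config.replicates + 1):
            cond = Condition(
                sensor=name,
                inducer="none",
                concentration=0.0,
                replicate=rep,
                copy_number=spec.copy_number,
            )
            wells.append(
                _simulate_well(
                    f"W{stream:03d}",
                    cond,
                    spec.expression,
                    config,
                    0.0,
                    _well_rng(config.seed, stream),
                )
            )
            stream += 1
    for i in range(config.n_control_wells):
        cond = Condition(
            sensor="control", inducer="none", replicate=i + 1, is_control=True
        )
        wells.append(
            _simulate_well(
                f"W{stream:03d}", cond, None, config, 0.0,
                _well_rng(config.seed, CONTROL_STREAM_BASE + i),
            )
        )
        stream += 1
    return PlateExperiment(
        wells=wells,
        channels=[config.channel],
        metadata={"seed": config.seed, "kind": "cross-reactivity"},
    )


def simulate_toxicity_plate(
    toxicity: Mapping[str, ToxicityParams],
    series: Mapping[str, Sequence[float]],
    growth: GrowthParams | None = None,
    noise: NoiseParams | None = None,
    replicates: int = 3,
    sampling_interval_min: float = 10.0,
    duration_min: float = 900.0,
    seed: int = 0,
    channel: str = "GFP",
) -> PlateExperiment:
    """Simulate the toxicity experiment: a background (reporter-free) strain
    exposed to each chemical dose series, plus untreated zero-dose wells."""
    unknown = sorted(set(series) - set(toxicity))
    if unknown:
        raise ConfigError(f"dose series given for chemicals without toxicity params: {unknown}")
    growth = growth or GrowthParams()
    noise = noise or NoiseParams()
    times = np.arange(0.0, duration_min + 1e-9, sampling_interval_min)
    cfg = GeneratorConfig(
        sensors={},
        growth=growth,
        noise=noise,
        toxicity=dict(toxicity),
        replicates=replicates,
        sampling_interval_min=sampling_interval_min,
        duration_min=duration_min,
        channel=channel,
        seed=seed,
    )
    wells: list[WellTimeSeries] = []
    stream = 0
    for rep in range(1, replicates + 1):  # untreated reference wells
        cond = Condition(
            sensor="control", inducer="none", concentration=0.0, replicate=rep, is_control=True
        )
        wells.append(
            _simulate_well(f"W{stream:03d}", cond, None, cfg, 0.0, _well_rng(seed, stream))
        )
        stream += 1
    for chem in series:
        for conc in series[chem]:
            for rep in range(1, replicates + 1):
                cond = Condition(
                    sensor="control",
                    inducer=chem,
                    concentration=conc,
                    replicate=rep,
                    is_control=True,
                )
                wells.append(
                    _simulate_well(
                        f"W{stream:03d}", cond, None, cfg, 0.0, _well_rng(seed, stream)
                    )
                )
                stream += 1
    return PlateExperiment(
        wells=wells, channels=[channel], metadata={"seed": seed, "kind": "toxicity"}
    )


@dataclass(frozen=True)
class ChannelModel:
    """Lognormal on/off single-cell fluorescence for one cytometry channel."""

    inducer: str
    median_on: float
    median_off: float
    gcv_on: float = 0.6
    gcv_off: float = 0.6

    def sigma(self, on: bool) -> float:
        gcv = self.gcv_on if on else self.gcv_off
        return math.log1p(gcv)

    def median(self, on: bool) -> float:
        return self.median_on if on else self.median_off


#: Three-channel model emulating well-separated induced/uninduced populations
#: (about two decades apart) for the triple-sensor strain.
DEFAULT_CHANNEL_MODELS: Mapping[str, ChannelModel] = {
    "GFP": ChannelModel("glucarate", 1.0e4, 1.0e2),
    "mCherry": ChannelModel("erythromycin", 1.0e4, 1.0e2),
    "CFP": ChannelModel("acrylate", 1.0e4, 1.0e2),
}

#: Fraction of cells that fail to activate under full induction (the paper's
#: single-cell data bound this below 2%).
DEFAULT_NONRESPONDER_FRAC = 0.01


def simulate_events(
    state: Iterable[str],
    channel_params: Mapping[str, ChannelModel] = DEFAULT_CHANNEL_MODELS,
    n_events: int = 10_000,
    nonresponder_frac: float = DEFAULT_NONRESPONDER_FRAC,
    seed: int = 0,
) -> CytometrySample:
    """Simulate pre-gated cytometry events for one induction state.

    Each event samples the "on" lognormal for channels whose inducer is in
    ``state`` and "off" otherwise; a ``nonresponder_frac`` of events samples
    "off" in every channel regardless of state.
    """
    if not 0.0 <= nonresponder_frac <= 0.05:
        raise ConfigError("nonresponder_frac must lie in [0, 0.05]")
    if not channel_params:
        raise ConfigError("at least one channel model is required")
    state = frozenset(state)
    known = {m.inducer for m in channel_params.values()}
    unknown = state - known
    if unknown:
        raise ConfigError(f"state includes inducers without a channel: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    channels = list(channel_params)
    nonresp = rng.random(n_events) < nonresponder_frac
    cols = []
    for ch in channels:
        m = channel_params[ch]
        on = (m.inducer in state) & ~nonresp
        medians = np.where(on, m.median(True), m.median(False))
        sigmas = np.where(on, m.sigma(True), m.sigma(False))
        cols.append(medians * np.exp(sigmas * rng.standard_normal(n_events)))
    return CytometrySample(
        sample_label=state_label(state),
        channels=channels,
        events=np.column_stack(cols),
        state=state,
    )


def simulate_toxicity_series(
    params: ToxicityParams,
    concentrations: Sequence[float],
    seed: int = 0,
    replicates: int = 3,
    noise_cv: float = 0.02,
) -> pd.DataFrame:
    """Directly simulate normalized exponential growth rates over a dose series.

    Returns a tidy table (concentration, replicate, normalized_rate). If the
    series contains a zero dose, rates are renormalized so the zero-dose mean
    is exactly 1 (the untreated-control convention).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for conc in concentrations:
        f = toxicity_factor(params, conc)
        for rep in range(1, replicates + 1):
            noise = rng.lognormal(0.0, noise_cv) if noise_cv > 0 else 1.0
            rows.append((conc, rep, f * noise))
    df = pd.DataFrame(rows, columns=["concentration", "replicate", "normalized_rate"])
    zero = df["concentration"] == 0
    if zero.any():
        df["normalized_rate"] /= df.loc[zero, "normalized_rate"].mean()
    return df


def simulate_variants(
    n_variants: int,
    activity_range: tuple[float, float],
    transfer: ExpressionParams,
    noise_cv: float = 0.05,
    seed: int = 0,
    replicates: int = 3,
) -> pd.DataFrame:
    """Simulate a sensor-based enzyme-variant screen.

    Each variant receives a latent product titer (geometrically spaced across
    ``activity_range``, in the transfer function's concentration units); its
    fluorescence readout is the sensor transfer function evaluated at that
    titer, with multiplicative replicate noise. Returns a tidy table
    (variant_id, replicate, fluorescence, titer).
    """
    if n_variants < 2:
        raise ConfigError("need at least 2 variants")
    lo, hi = activity_range
    if not 0 < lo < hi:
        raise ConfigError("activity_range must satisfy 0 < lo < hi")
    rng = np.random.default_rng(seed)
    titers = np.geomspace(lo, hi, n_variants)
    rows = []
    for i, titer in enumerate(titers):
        vid = f"variant-{i + 1:02d}"
        signal = hill_rate(transfer, float(titer))
        for rep in range(1, replicates + 1):
            noise = rng.lognormal(0.0, noise_cv) if noise_cv > 0 else 1.0
            rows.append((vid, rep, signal * noise, float(titer)))
    return pd.DataFrame(rows, columns=["variant_id", "replicate", "fluorescence", "titer"])
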