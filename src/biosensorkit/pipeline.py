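"""End-to-end orchestration: velocity extraction, parameter recovery studies,
and per-sensor datasheet assembly.

The recovery study is the package's closed loop: simulate a plate from known
transfer-function parameters, extract per-well maximum expression velocities,
fit the modified Hill function, and compare fitted to generating parameters
across seeds.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import PlateExperiment
from .dose_response import (
    DEFAULT_ENDPOINT_MIN,
    fold_induction_from_experiment,
    transfer_function,
)
from .errors import ConfigError
from .hill import HillFit, fit_hill
from .kinetics import expression_rates, normalize
from .presets import COGNATE, CROSSREACT_PANEL, TABLE1, preset_config
from .simulate import (
    NoiseParams,
    ToxicityParams,
    simulate_crossreact_panel,
    simulate_plate,
    simulate_toxicity_plate,
)


def max_velocities(
    exp: PlateExperiment,
    channel: str | None = None,
    smooth_window: int = 0,
) -> pd.DataFrame:
    """Per-well maximum growth-normalized expression velocity.

    Normalizes each sample well against the plate's background-control wells,
    differences the trace, and records the post-induction maximum rate.
    Returns a tidy table (well, sensor, inducer, concentration, replicate,
    max_rate, max_rate_time).
    """
    controls = exp.control_wells
    rows = []
    for w in exp.sample_wells:
        ns = normalize(w, controls=controls or None, channel=channel)
        vs = expression_rates(ns, induction_time=exp.induction_time, smooth_window=smooth_window)
        c = w.condition
        rows.append(
            (w.well, c.sensor, c.inducer, c.concentration, c.replicate,
             vs.max_rate, vs.max_rate_time)
        )
    return pd.DataFrame(
        rows,
        columns=["well", "sensor", "inducer", "concentration", "replicate",
                 "max_rate", "max_rate_time"],
    )


def fit_sensor(
    exp: PlateExperiment,
    sensor: str,
    exclude: Sequence[float] = (),
    include_uninduced: bool = True,
    channel: str | None = None,
) -> HillFit:
    """Hill fit of one sensor's (concentration, max velocity) points.

    All replicate points enter individually; zero-concentration points enter
    with the Hill term exactly zero. ``exclude`` removes concentrations
    rejected upstream (e.g. for toxicity).
    """
    df = max_velocities(exp, channel=channel)
    df = df[df["sensor"] == sensor]
    if not include_uninduced:
        df = df[df["concentration"] > 0]
    return fit_hill(df["concentration"], df["max_rate"], exclude=exclude)


def recovery_study(
    sensor: str,
    copy_number: str = "high",
    seeds: Sequence[int] = tuple(range(20)),
    n_concentrations: int = 6,
    replicates: int = 3,
    noise: NoiseParams | None = None,
) -> pd.DataFrame:
    """Parameter-recovery study for one preset sensor.

    For each seed: simulate the titration (``replicates`` wells at
    ``n_concentrations`` fold-spaced doses, 10-min sampling over 15 h, plus
    uninduced and background wells), run the velocity/fit pipeline, and
    record the fitted parameters. Returns one row per seed.
    """
    preset = TABLE1[(sensor, copy_number)]
    rows = []
    for seed in seeds:
        cfg = preset_config(
            copy_number=copy_number,
            sensors=(sensor,),
            seed=int(seed),
            noise=noise,
            n_concentrations=n_concentrations,
            replicates=replicates,
        )
        fit = fit_sensor(simulate_plate(cfg), sensor)
        rows.append(
            {
                "sensor": sensor,
                "copy_number": copy_number,
                "seed": int(seed),
                "v_max": fit.v_max,
                "v_min": fit.v_min,
                "h": fit.h,
                "k_half": fit.k_half,
                "true_v_max": preset.expression.v_max,
                "true_v_min": preset.expression.v_min,
                "true_h": preset.expression.hill_h,
                "true_k_half": preset.expression.k_half,
            }
        )
    return pd.DataFrame(rows)


def median_recovered(study: pd.DataFrame) -> dict[str, float]:
    """Median fitted parameters over the seeds of a recovery study."""
    return {p: float(study[p].median()) for p in ("v_max", "v_min", "h", "k_half")}


def _kinetics_summary(
    exp: PlateExperiment, sensor: str, channel: str | None = None
) -> dict[str, float]:
    """Onset and plateau times of the strongest induction condition.

    Onset is the first time the background-subtracted signal exceeds 2% of
    its endpoint value; plateau is the first time it reaches 95%. Both are
    means over replicates.
    """
    controls = exp.control_wells
    wells = [w for w in exp.sample_wells if w.condition.sensor == sensor]
    top = max(w.condition.concentration for w in wells)
    onsets, plateaus = [], []
    for w in wells:
        if w.condition.concentration != top:
            continue
        ns = normalize(w, controls=controls or None, channel=channel)
        final = ns.values[-1]
        if final <= 0:
            continue
        above = ns.times[ns.values >= 0.02 * final]
        high = ns.times[ns.values >= 0.95 * final]
        if above.size:
            onsets.append(float(above[0]))
        if high.size:
            plateaus.append(float(high[0]))
    return {
        "top_concentration": float(top),
        "time_to_signal_min": float(np.mean(onsets)) if onsets else float("nan"),
        "time_to_plateau_min": float(np.mean(plateaus)) if plateaus else float("nan"),
    }


def build_datasheet(
    exp: PlateExperiment,
    sensor: str,
    endpoint_min: float = DEFAULT_ENDPOINT_MIN,
    exclude: Sequence[float] = (),
    channel: str | None = None,
) -> dict:
    """Assemble one sensor's datasheet from an induction experiment:
    transfer-function table, fold induction, Hill-fit row and kinetics
    summary. Toxicity and cross-reactivity sections are attached by
    ``run_pipeline`` when configured."""
    tf = transfer_function(exp, endpoint_min=endpoint_min, channel=channel)[sensor]
    fold = fold_induction_from_experiment(exp, sensor, endpoint_min=endpoint_min, channel=channel)
    fit = fit_sensor(exp, sensor, exclude=exclude, channel=channel)
    wells = [w for w in exp.sample_wells if w.condition.sensor == sensor]
    return {
        "sensor": sensor,
        "copy_number": wells[0].condition.copy_number,
        "inducer": wells[0].condition.inducer,
        "endpoint_min": endpoint_min,
        "transfer_function": [
            {
                "concentration": p.concentration,
                "mean_afu_per_od": p.mean,
                "ci_low": p.ci_low,
                "ci_high": p.ci_high,
                "n": p.n_replicates,
            }
            for p in tf
        ],
        "fold_induction": {
            "value": fold.value,
            "se": fold.se,
            "is_lower_bound": fold.is_lower_bound,
        },
        "hill_fit": {
            "v_max": fit.v_max,
            "v_min": fit.v_min,
            "h": fit.h,
            "k_half": fit.k_half,
            "se": fit.se,
            "rss": fit.rss,
            "n_points": fit.n_points,
            "excluded_concentrations": list(fit.excluded_concentrations),
        },
        "kinetics": _kinetics_summary(exp, sensor, channel=channel),
    }


def _digest(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True).encode()).hexdigest()[:16]


def run_pipeline(config: Mapping | str | Path) -> dict:
    """Run the full characterization pipeline from a configuration mapping
    (or a YAML file path) and return the datasheet bundle.

    Recognized keys: ``scenario`` ("table1-high-copy" or "table1-low-copy"),
    ``sensors`` (subset of preset names), ``seed``, ``replicates``,
    ``endpoint_min``, ``exclude`` (mapping sensor -> concentrations to omit
    from the fit), ``crossreact`` (bool: also simulate and attach the
    cross-reactivity panel), ``toxicity`` (mapping chemical -> dose-curve
    fields plus a concentration list: attaches a growth-effect table),
    ``noise`` (mapping of NoiseParams fields). Every stochastic step records
    its seed; the bundle is reproducible byte-for-byte given the same
    configuration.
    """
    if isinstance(config, (str, Path)):
        import yaml

        with open(config) as fh:
            config = yaml.safe_load(fh)
    if not config:
        raise ConfigError("empty pipeline configuration")
    scenario = config.get("scenario", "table1-high-copy")
    if scenario not in ("table1-high-copy", "table1-low-copy"):
        raise ConfigError(f"unknown scenario {scenario!r}")
    copy_number = "high" if scenario.endswith("high-copy") else "low"
    seed = int(config.get("seed", 0))
    sensors = tuple(config.get("sensors") or (s for s, c in TABLE1 if c == copy_number))
    noise = NoiseParams(**config["noise"]) if config.get("noise") else None
    cfg = preset_config(
        copy_number=copy_number,
        sensors=sensors,
        seed=seed,
        noise=noise,
        replicates=int(config.get("replicates", 3)),
    )
    exp = simulate_plate(cfg)
    endpoint = float(config.get("endpoint_min", DEFAULT_ENDPOINT_MIN))
    exclude = {k: tuple(v) for k, v in (config.get("exclude") or {}).items()}
    datasheets = [
        build_datasheet(exp, s, endpoint_min=endpoint, exclude=exclude.get(s, ()))
        for s in sensors
    ]
    bundle = {
        "scenario": scenario,
        "seed": seed,
        "config_digest": _digest({k: str(v) for k, v in sorted(config.items())}),
        "datasheets": datasheets,
    }
    if config.get("crossreact"):
        from .orthogonality import cross_react, orthogonality_report

        panel_exp = simulate_crossreact_panel(cfg, CROSSREACT_PANEL)
        matrix = cross_react(panel_exp, endpoint_min=endpoint)
        report = orthogonality_report(matrix, COGNATE)
        bundle["crossreact"] = {
            "sensors": matrix.sensors,
            "chemicals": matrix.chemicals,
            "values": matrix.values.tolist(),
            "passed": report.passed,
            "offending_pairs": [list(p) for p in report.offending_pairs],
        }
    if config.get("toxicity"):
        from .toxicity import toxicity_profile

        params, series = {}, {}
        for chem, spec in config["toxicity"].items():
            spec = dict(spec)
            series[chem] = [float(c) for c in spec.pop("concentrations")]
            params[chem] = ToxicityParams(**spec)
        tox_exp = simulate_toxicity_plate(
            params, series, noise=noise, seed=seed,
            replicates=int(config.get("replicates", 3)),
        )
        prof = toxicity_profile(tox_exp, mode=config.get("toxicity_mode", "rate"))
        bundle["toxicity"] = prof.to_dict(orient="records")
    return bundle


def render_datasheet(sheet: Mapping) -> str:
    """Human-readable one-sensor datasheet."""
    lines = [
        f"Sensor {sheet['sensor']} ({sheet['copy_number']} copy), "
        f"inducer {sheet['inducer']}",
        "-" * 60,
        f"Endpoint: {sheet['endpoint_min']:.0f} min",
        "Transfer function (concentration -> endpoint AFU/OD):",
    ]
    for p in sheet["transfer_function"]:
        lines.append(
            f"  {p['concentration']:.4g}: {p['mean_afu_per_od']:.4g} "
            f"[{p['ci_low']:.4g}, {p['ci_high']:.4g}] (n={p['n']})"
        )
    f = sheet["fold_induction"]
    bound = " (lower bound)" if f["is_lower_bound"] else ""
    se = f" +/- {f['se']:.3g}" if f["se"] is not None else ""
    lines.append(f"Fold induction: {f['value']:.3g}{se}{bound}")
    h = sheet["hill_fit"]
    lines.append(
        "Hill fit: "
        f"Vmax {h['v_max']:.4g} +/- {h['se']['v_max']:.2g}, "
        f"Vmin {h['v_min']:.3g} +/- {h['se']['v_min']:.2g}, "
        f"h {h['h']:.3g} +/- {h['se']['h']:.2g}, "
        f"K_L {h['k_half']:.4g} +/- {h['se']['k_half']:.2g} M"
    )
    k = sheet["kinetics"]
    lines.append(
        f"Kinetics at {k['top_concentration']:.3g}: signal onset "
        f"{k['time_to_signal_min']:.0f} min, plateau {k['time_to_plateau_min']:.0f} min"
    )
    return "\n".join(lines)
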