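"""Published induction characteristics used as generator presets.

Each preset carries the fitted transfer-function parameters of one
well-characterized sensor/reporter construct (per plasmid copy number):
maximal and basal expression velocities (AFU*OD^-1*s^-1), Hill coefficient,
lumped half-maximal parameter (converted to mol/L), the cognate inducer, and
the fold step of its published dose series (acrylate and anhydrotetracycline
were titrated in 2-fold increments, the other inducers in 3-fold increments).

These values parameterize the synthetic-data generator so that recovery of
(h, K_L, Vmax) by the analysis pipeline can be tested against known truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import ExpressionParams, GeneratorConfig, NoiseParams, SensorSpec


@dataclass(frozen=True)
class SensorPreset:
    sensor: str
    copy_number: str
    inducer: str
    expression: ExpressionParams
    fold_step: float  # dose-series increment of the published titration


def _p(sensor, copy, inducer, vmax, vmin, h, k_half, step, shutoff=True, post=False):
    return SensorPreset(
        sensor=sensor,
        copy_number=copy,
        inducer=inducer,
        expression=ExpressionParams(
            v_max=vmax,
            v_min=vmin,
            hill_h=h,
            k_half=k_half,
            stationary_shutoff=shutoff,
            post_stationary_accumulation=post,
        ),
        fold_step=step,
    )


#: (sensor, copy_number) -> preset. AcuR keeps accumulating reporter after
#: entry into stationary phase; the other sensors stop by stationary onset.
TABLE1: dict[tuple[str, str], SensorPreset] = {
    ("AcuR", "high"): _p("AcuR", "high", "acrylate", 910.0, 5.0, 3.2, 2.6e-3, 2.0, post=True),
    ("AcuR", "low"): _p("AcuR", "low", "acrylate", 150.0, 15.0, 1.3, 1.0e-3, 2.0, post=True),
    ("AraC", "high"): _p("AraC", "high", "arabinose", 3150.0, 20.0, 1.3, 59e-6, 3.0),
    ("AraC", "low"): _p("AraC", "low", "arabinose", 1260.0, 40.0, 1.3, 250e-6, 3.0),
    ("CdaR", "high"): _p("CdaR", "high", "glucarate", 2600.0, 0.0, 1.0, 490e-6, 3.0),
    ("CdaR", "low"): _p("CdaR", "low", "glucarate", 1000.0, 30.0, 1.0, 8e-3, 3.0),
    ("MphR", "high"): _p("MphR", "high", "erythromycin", 2070.0, 9.0, 1.6, 97e-6, 3.0),
    ("MphR", "low"): _p("MphR", "low", "erythromycin", 66.0, 5.0, 1.6, 22e-6, 3.0),
    ("TetR", "high"): _p("TetR", "high", "aTC", 1760.0, 8.0, 4.2, 81e-9, 2.0),
    ("TetR", "low"): _p("TetR", "low", "aTC", 116.0, 2.0, 3.1, 54e-9, 2.0),
    ("TtgR", "high"): _p("TtgR", "high", "naringenin", 180.0, 4.0, 3.8, 550e-6, 3.0),
    ("TtgR", "low"): _p("TtgR", "low", "naringenin", 25.0, 6.0, 2.3, 190e-6, 3.0),
}

HIGH_COPY_SENSORS = ("AcuR", "AraC", "CdaR", "MphR", "TetR", "TtgR")

#: Published cross-reactivity panel: one concentration per chemical
#: (canonical units; the two solvents are percent v/v).
CROSSREACT_PANEL: dict[str, float] = {
    "acrylate": 5e-3,
    "arabinose": 165e-6,
    "glucarate": 4.4e-3,
    "erythromycin": 51e-6,
    "aTC": 430e-9,  # panel concentration not printed; highest titration level used
    "naringenin": 9e-3,
    "IPTG": 1e-3,
    "rhamnose": 10e-3,
    "cumate": 20e-6,
    "DMSO": 1.0,
    "ethanol": 1.0,
}

#: Cognate inducer of each sensor, for orthogonality reporting.
COGNATE: dict[str, str] = {
    "AcuR": "acrylate",
    "AraC": "arabinose",
    "CdaR": "glucarate",
    "MphR": "erythromycin",
    "TetR": "aTC",
    "TtgR": "naringenin",
}


def default_series(preset: SensorPreset, n: int = 6) -> tuple[float, ...]:
    """Dose series for one sensor: n concentrations at the published fold
    step, log-centered on the half-maximal parameter so the titration spans
    the full transition of the transfer function."""
    k = preset.expression.k_half
    step = preset.fold_step
    exponents = np.arange(n) - (n - 1) / 2.0
    return tuple(float(k * step**e) for e in exponents)


def preset_config(
    copy_number: str = "high",
    sensors: tuple[str, ...] | None = None,
    seed: int = 0,
    noise: NoiseParams | None = None,
    n_concentrations: int = 6,
    replicates: int = 3,
    **kwargs,
) -> GeneratorConfig:
    """Generator configuration for the published sensor panel.

    The default scenario ("table1-high-copy") simulates 3 replicate wells at
    6 fold-spaced concentrations per sensor plus uninduced and background
    wells, sampled every 10 min for 15 h.
    """
    names = sensors or HIGH_COPY_SENSORS
    spec = {}
    for name in names:
        key = (name, copy_number)
        if key not in TABLE1:
            raise KeyError(f"no preset for sensor {name!r} at copy number {copy_number!r}")
        p = TABLE1[key]
        spec[name] = SensorSpec(
            expression=p.expression,
            inducer=p.inducer,
            concentrations=default_series(p, n_concentrations),
            copy_number=copy_number,
        )
    return GeneratorConfig(
        sensors=spec,
        noise=noise if noise is not None else NoiseParams(),
        replicates=replicates,
        seed=seed,
        **kwargs,
    )
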