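"""Cross-reactivity matrix and the orthogonality decision rule.

Each (sensor, chemical) cell is the mean background-subtracted endpoint
AFU/OD above the sensor's own uninduced wells. A cell counts as *activated*
when its value exceeds k standard errors (combined cell + uninduced SE;
k = 3 by default) — the formalization of "no cross-reactivity" as a signal
indistinguishable from the uninduced baseline. A sensor is orthogonal when
the only activation in its row is its cognate chemical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import PlateExperiment
from .errors import EstimationError
from .dose_response import DEFAULT_ENDPOINT_MIN, endpoint_index
from .kinetics import normalize

DEFAULT_ACTIVATION_K = 3.0


@dataclass
class CrossReactMatrix:
    """Sensors x chemicals endpoint-response matrix with activation flags."""

    sensors: list[str]
    chemicals: list[str]
    values: np.ndarray  # background-subtracted mean endpoint AFU/OD
    combined_se: np.ndarray
    panel: dict[str, float] = field(default_factory=dict)
    k: float = DEFAULT_ACTIVATION_K

    def activation_flags(self, k: float | None = None) -> np.ndarray:
        """Flags are derived from the stored values, monotone in cell value
        for fixed SE."""
        k = self.k if k is None else k
        return self.values > k * self.combined_se

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sensors, columns=self.chemicals)


def cross_react(
    exp: PlateExperiment,
    endpoint_min: float = DEFAULT_ENDPOINT_MIN,
    channel: str | None = None,
    k: float = DEFAULT_ACTIVATION_K,
) -> CrossReactMatrix:
    """Build the cross-reactivity matrix from a panel experiment.

    Requires, per sensor, wells for each panel chemical and uninduced
    (zero-dose) reference wells.
    """
    channel = channel or exp.channels[0]

    def endpoint(w) -> float:
        ns = normalize(w, channel=channel)
        return float(ns.values[endpoint_index(ns.times, endpoint_min)])

    cells: dict[tuple[str, str], list[float]] = {}
    uninduced: dict[str, list[float]] = {}
    panel: dict[str, float] = {}
    for w in exp.sample_wells:
        c = w.condition
        if c.concentration == 0.0 or c.inducer == "none":
            uninduced.setdefault(c.sensor, []).append(endpoint(w))
        else:
            cells.setdefault((c.sensor, c.inducer), []).append(endpoint(w))
            panel.setdefault(c.inducer, c.concentration)
    sensors = sorted({s for s, _ in cells})
    chemicals = sorted({c for _, c in cells})
    missing = [s for s in sensors if s not in uninduced]
    if missing:
        raise EstimationError(f"sensors without uninduced reference wells: {missing}")

    values = np.full((len(sensors), len(chemicals)), np.nan)
    ses = np.full_like(values, np.nan)
    for i, s in enumerate(sensors):
        ref = np.asarray(uninduced[s])
        ref_mean = float(ref.mean())
        ref_se = float(ref.std(ddof=1) / np.sqrt(ref.size)) if ref.size >= 2 else 0.0
        for j, chem in enumerate(chemicals):
            vals = np.asarray(cells.get((s, chem), []))
            if vals.size == 0:
                raise EstimationError(f"no wells for sensor {s!r} with chemical {chem!r}")
            se = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size >= 2 else 0.0
            values[i, j] = float(vals.mean()) - ref_mean
            ses[i, j] = float(np.hypot(se, ref_se))
    return CrossReactMatrix(
        sensors=sensors,
        chemicals=chemicals,
        values=values,
        combined_se=ses,
        panel=panel,
        k=k,
    )


@dataclass(frozen=True)
class OrthogonalityReport:
    passed: dict[str, bool]
    offending_pairs: tuple[tuple[str, str], ...]

    @property
    def all_pass(self) -> bool:
        return all(self.passed.values())


def orthogonality_report(
    matrix: CrossReactMatrix,
    cognate: dict[str, str],
    k: float | None = None,
) -> OrthogonalityReport:
    """Pass/fail per sensor: a sensor passes when no non-cognate chemical in
    its row is flagged as activating."""
    flags = matrix.activation_flags(k)
    passed: dict[str, bool] = {}
    offending: list[tuple[str, str]] = []
    for i, s in enumerate(matrix.sensors):
        bad = [
            matrix.chemicals[j]
            for j in range(len(matrix.chemicals))
            if flags[i, j] and matrix.chemicals[j] != cognate.get(s)
        ]
        passed[s] = not bad
        offending.extend((s, chem) for chem in bad)
    return OrthogonalityReport(passed=passed, offending_pairs=tuple(offending))
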