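"""Core data containers for plate-reader and cytometry experiments.

Concentrations are stored in canonical units: molar quantities are converted
to mol/L on construction (unit tag ``M``); volume-fraction solvents stay in
percent (unit tag ``%``). Time is stored in minutes relative to inducer
addition, so pre-induction baseline reads carry negative times.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import ValidationError

#: Multiplicative factors to mol/L for the closed set of molar unit tags.
MOLAR_UNITS: Mapping[str, float] = {
    "M": 1.0,
    "mM": 1e-3,
    "uM": 1e-6,
    "μM": 1e-6,  # μM
    "nM": 1e-9,
}

#: Unit tags for volume-fraction solvents (kept as percent, not converted).
PERCENT_UNITS = ("%", "%v/v")

COPY_NUMBERS = ("high", "low")


def to_canonical(value: float, unit: str) -> tuple[float, str]:
    """Convert a (value, unit) concentration to canonical form.

    Molar units are converted to mol/L and tagged ``M``; percent units are
    returned unchanged and tagged ``%``.
    """
    if value < 0:
        raise ValidationError(f"concentration must be non-negative, got {value}")
    if unit in MOLAR_UNITS:
        return value * MOLAR_UNITS[unit], "M"
    if unit in PERCENT_UNITS:
        return value, "%"
    raise ValidationError(
        f"unknown concentration unit {unit!r}; expected one of "
        f"{sorted(MOLAR_UNITS)} or {list(PERCENT_UNITS)}"
    )


@dataclass(frozen=True)
class Condition:
    """Experimental condition of one well.

    ``concentration`` is canonical (mol/L for molar units, percent for
    solvents); ``concentration_unit`` is ``"M"`` or ``"%"``. Control wells
    describe the background-autofluorescence strain and carry no sensor
    transfer function.
    """

    sensor: str
    inducer: str
    concentration: float = 0.0
    concentration_unit: str = "M"
    replicate: int = 1
    is_control: bool = False
    copy_number: str = "high"

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValidationError("concentration must be non-negative")
        if self.concentration_unit not in ("M", "%"):
            raise ValidationError(
                f"canonical unit must be 'M' or '%', got {self.concentration_unit!r}"
            )
        if self.replicate < 1:
            raise ValidationError("replicate index must be a positive integer")
        if self.copy_number not in COPY_NUMBERS:
            raise ValidationError(f"copy_number must be one of {COPY_NUMBERS}")


@dataclass
class WellTimeSeries:
    """One well's sampled OD and fluorescence trajectory plus its condition.

    ``times`` are minutes from inducer addition (strictly increasing);
    ``fluorescence`` maps channel name to an AFU trace of the same length.
    """

    well: str
    condition: Condition
    times: np.ndarray
    od: np.ndarray
    fluorescence: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        self.fluorescence = {
            ch: np.asarray(v, dtype=float) for ch, v in self.fluorescence.items()
        }
        n = self.times.size
        if n < 2:
            raise ValidationError(f"well {self.well}: need at least 2 samples, got {n}")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError(f"well {self.well}: times must be strictly increasing")
        if self.od.size != n:
            raise ValidationError(f"well {self.well}: od length mismatch")
        for ch, trace in self.fluorescence.items():
            if trace.size != n:
                raise ValidationError(
                    f"well {self.well}: channel {ch!r} length mismatch"
                )

    @property
    def channels(self) -> list[str]:
        return list(self.fluorescence)

    @property
    def n_samples(self) -> int:
        return int(self.times.size)


@dataclass
class PlateExperiment:
    """A collection of wells sharing a channel set and induction time."""

    wells: list[WellTimeSeries]
    channels: list[str] = field(default_factory=list)
    induction_time: float = 0.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.channels and self.wells:
            self.channels = list(self.wells[0].channels)
        chset = set(self.channels)
        for w in self.wells:
            if set(w.channels) != chset:
                raise ValidationError(
                    f"well {w.well}: channel set {sorted(w.channels)} differs "
                    f"from plate channels {sorted(chset)}"
                )

    @property
    def control_wells(self) -> list[WellTimeSeries]:
        return [w for w in self.wells if w.condition.is_control]

    @property
    def sample_wells(self) -> list[WellTimeSeries]:
        return [w for w in self.wells if not w.condition.is_control]

    def sensors(self) -> list[str]:
        seen: dict[str, None] = {}
        for w in self.sample_wells:
            seen.setdefault(w.condition.sensor, None)
        return list(seen)


@dataclass
class CytometrySample:
    """Per-event multi-channel fluorescence for one labeled sample.

    ``state`` is the set of inducers applied; ``events`` is an
    (n_events, n_channels) matrix aligned with ``channels``. Event order is
    meaningful and is never reordered by I/O.
    """

    sample_label: str
    channels: list[str]
    events: np.ndarray
    state: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.events = np.atleast_2d(np.asarray(self.events, dtype=float))
        if self.events.shape[0] < 1:
            raise ValidationError(f"sample {self.sample_label}: needs >= 1 event")
        if self.events.shape[1] != len(self.channels):
            raise ValidationError(
                f"sample {self.sample_label}: event matrix has "
                f"{self.events.shape[1]} columns for {len(self.channels)} channels"
            )
        if np.any(self.events < 0):
            raise ValidationError(
                f"sample {self.sample_label}: fluorescence must be >= 0 before transform"
            )

    @property
    def n_events(self) -> int:
        return int(self.events.shape[0])

    def channel_values(self, channel: str) -> np.ndarray:
        return self.events[:, self.channels.index(channel)]


@dataclass(frozen=True)
class VariantRecord:
    """Replicate summary for one enzyme variant in a sensor-based screen."""

    variant_id: str
    fluorescence: float
    titer: float | None = None
    n_replicates: int = 1
    cv: float | None = None

    def __post_init__(self) -> None:
        if self.n_replicates >= 2 and self.cv is None:
            raise ValidationError(
                f"variant {self.variant_id}: coefficient of variation required "
                "when replicates >= 2"
            )
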