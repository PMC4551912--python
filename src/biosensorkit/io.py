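"""Tidy CSV readers and writers for plates, cytometry events and variants.

All files are UTF-8, comma-separated, '.' decimal, header required. Writers
emit a canonical form (fixed column order, rows sorted by the natural key,
floats in shortest round-trip repr) so write -> read -> write is
byte-identical.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    Condition,
    CytometrySample,
    PlateExperiment,
    VariantRecord,
    WellTimeSeries,
    to_canonical,
)
from .errors import FormatError, ValidationError

PLATE_COLUMNS = ["well", "time_min", "od600", "channel", "value"]
LAYOUT_COLUMNS = [
    "well",
    "sensor",
    "inducer",
    "concentration",
    "unit",
    "replicate",
    "is_control",
    "copy_number",
]
EVENT_COLUMNS = ["sample_label", "event_id", "channel", "value"]
VARIANT_COLUMNS = ["variant_id", "fluorescence", "titer"]


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{what}: missing required column {col!r}")


def _read_csv(path) -> pd.DataFrame:
    try:
        # exact IEEE round-trip parsing keeps write -> read -> write byte-identical
        return pd.read_csv(path, float_precision="round_trip")
    except FileNotFoundError:
        raise
    except (pd.errors.ParserError, pd.errors.EmptyDataError, UnicodeDecodeError) as e:
        raise FormatError(f"{path}: not a readable CSV table ({e})") from e


def read_layout(path) -> dict[str, Condition]:
    """Read a plate-layout CSV mapping well id to its Condition."""
    df = _read_csv(path)
    _require_columns(df, LAYOUT_COLUMNS, f"layout {path}")
    if df["well"].duplicated().any():
        dups = df.loc[df["well"].duplicated(), "well"].tolist()
        raise ValidationError(f"layout {path}: duplicated wells {dups}")
    layout: dict[str, Condition] = {}
    for row in df.itertuples(index=False):
        value, unit = to_canonical(float(row.concentration), str(row.unit))
        layout[str(row.well)] = Condition(
            sensor=str(row.sensor),
            inducer=str(row.inducer),
            concentration=value,
            concentration_unit=unit,
            replicate=int(row.replicate),
            is_control=_parse_bool(row.is_control),
            copy_number=str(row.copy_number),
        )
    return layout


def _parse_bool(x) -> bool:
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    s = str(x).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no"):
        return False
    raise FormatError(f"cannot parse boolean flag from {x!r}")


def read_plate(path, layout) -> PlateExperiment:
    """Read a tidy plate CSV plus its layout into a PlateExperiment.

    Rows are sorted by time within each well. Wells present in the data but
    absent from the layout are rejected.
    """
    conditions = read_layout(layout)
    df = _read_csv(path)
    _require_columns(df, PLATE_COLUMNS, f"plate {path}")
    unknown = sorted(set(df["well"].astype(str)) - set(conditions))
    if unknown:
        raise ValidationError(f"plate {path}: wells not in layout: {unknown}")
    channels = sorted(df["channel"].astype(str).unique())
    wells: list[WellTimeSeries] = []
    for well, wdf in df.groupby("well", sort=True):
        well = str(well)
        if wdf.duplicated(subset=["time_min", "channel"]).any():
            raise ValidationError(
                f"plate {path}: well {well} has duplicate (time, channel) rows; "
                "time is not monotone within the well"
            )
        pivot = wdf.pivot(index="time_min", columns="channel", values="value")
        odt = wdf.drop_duplicates("time_min").set_index("time_min")["od600"]
        if (wdf.groupby("time_min")["od600"].nunique() > 1).any():
            raise ValidationError(
                f"plate {path}: well {well} has conflicting od600 values at one time"
            )
        if pivot.isna().any().any():
            raise ValidationError(
                f"plate {path}: well {well} is missing some (time, channel) readings"
            )
        pivot = pivot.sort_index()
        times = pivot.index.to_numpy(dtype=float)
        fluor = {ch: pivot[ch].to_numpy(dtype=float) for ch in pivot.columns}
        wells.append(
            WellTimeSeries(
                well=well,
                condition=conditions[well],
                times=times,
                od=odt.sort_index().to_numpy(dtype=float),
                fluorescence=fluor,
            )
        )
    return PlateExperiment(wells=wells, channels=channels)


def write_plate(exp: PlateExperiment, path, layout_path=None) -> None:
    """Write a PlateExperiment as a canonical tidy CSV (plus optional layout)."""
    rows = []
    for w in sorted(exp.wells, key=lambda w: w.well):
        for ch in sorted(w.channels):
            trace = w.fluorescence[ch]
            for t, od, v in zip(w.times, w.od, trace):
                rows.append((w.well, t, od, ch, v))
    df = pd.DataFrame(rows, columns=PLATE_COLUMNS)
    df = df.sort_values(["well", "time_min", "channel"], kind="stable")
    df.to_csv(path, index=False)
    if layout_path is not None:
        write_layout(exp, layout_path)


def write_layout(exp: PlateExperiment, path) -> None:
    rows = []
    for w in sorted(exp.wells, key=lambda w: w.well):
        c = w.condition
        rows.append(
            (
                w.well,
                c.sensor,
                c.inducer,
                c.concentration,
                c.concentration_unit,
                c.replicate,
                c.is_control,
                c.copy_number,
            )
        )
    pd.DataFrame(rows, columns=LAYOUT_COLUMNS).to_csv(path, index=False)


def read_events(path) -> list[CytometrySample]:
    """Read a tidy events CSV into CytometrySamples.

    Event order within a sample follows first appearance in the file and is
    never reordered. Ragged channel sets or duplicated
    (sample, event, channel) rows are rejected.
    """
    df = _read_csv(path)
    _require_columns(df, EVENT_COLUMNS, f"events {path}")
    if df.duplicated(subset=["sample_label", "event_id", "channel"]).any():
        raise ValidationError(f"events {path}: duplicated (sample, event, channel) row")
    channels = sorted(df["channel"].astype(str).unique())
    samples: list[CytometrySample] = []
    for label, sdf in df.groupby("sample_label", sort=True):
        counts = sdf.groupby("event_id")["channel"].count()
        if counts.nunique() > 1 or counts.iloc[0] != len(channels):
            raise ValidationError(
                f"events {path}: sample {label!r} has ragged channels across events"
            )
        event_order = sdf["event_id"].drop_duplicates().to_numpy()
        pivot = sdf.pivot(index="event_id", columns="channel", values="value")
        pivot = pivot.loc[event_order, channels]
        samples.append(
            CytometrySample(
                sample_label=str(label),
                channels=list(channels),
                events=pivot.to_numpy(dtype=float),
                state=_state_from_label(str(label)),
            )
        )
    return samples


def _state_from_label(label: str) -> frozenset[str]:
    if label in ("", "none"):
        return frozenset()
    return frozenset(label.split("+"))


def state_label(state: Iterable[str]) -> str:
    """Canonical sample label for a set of applied inducers."""
    parts = sorted(state)
    return "+".join(parts) if parts else "none"


def write_events(samples: Sequence[CytometrySample], path) -> None:
    """Write CytometrySamples as a canonical tidy events CSV."""
    frames = []
    for s in sorted(samples, key=lambda s: s.sample_label):
        n = s.n_events
        order = np.argsort(s.channels, kind="stable")
        for j in order:
            frames.append(
                pd.DataFrame(
                    {
                        "sample_label": s.sample_label,
                        "event_id": np.arange(n),
                        "channel": s.channels[j],
                        "value": s.events[:, j],
                    }
                )
            )
    if frames:
        df = pd.concat(frames, ignore_index=True)
        df = df.sort_values(
            ["sample_label", "event_id", "channel"], kind="stable"
        ).reset_index(drop=True)
    else:
        df = pd.DataFrame(columns=EVENT_COLUMNS)
    df.to_csv(path, index=False)


def read_variants(path) -> list[VariantRecord]:
    """Read a variants CSV (one row per replicate) into replicate summaries.

    Repeated variant_id rows are treated as replicates: the record carries
    the replicate mean and coefficient of variation.
    """
    df = _read_csv(path)
    _require_columns(df, ["variant_id", "fluorescence"], f"variants {path}")
    has_titer = "titer" in df.columns
    records = []
    for vid, vdf in df.groupby("variant_id", sort=True):
        fl = vdf["fluorescence"].to_numpy(dtype=float)
        n = fl.size
        mean = float(fl.mean())
        cv = float(fl.std(ddof=1) / mean) if n >= 2 and mean != 0 else (0.0 if n >= 2 else None)
        titer = float(vdf["titer"].mean()) if has_titer and vdf["titer"].notna().all() else None
        records.append(
            VariantRecord(
                variant_id=str(vid),
                fluorescence=mean,
                titer=titer,
                n_replicates=n,
                cv=cv,
            )
        )
    return records


def write_variants(df: pd.DataFrame, path) -> None:
    """Write a per-replicate variants table (variant_id, fluorescence, titer)."""
    cols = [c for c in ["variant_id", "replicate", "fluorescence", "titer"] if c in df.columns]
    out = df[cols].sort_values(cols[:2], kind="stable")
    out.to_csv(path, index=False)
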