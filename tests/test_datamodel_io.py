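"""Data-model invariants and lossless round trips of the tidy CSV formats."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import biosensorkit as bk
from biosensorkit.errors import FormatError, ValidationError


def test_canonical_concentration_units():
    assert bk.to_canonical(59.0, "uM") == pytest.approx((59e-6, "M"))
    assert bk.to_canonical(81.0, "nM")[0] == pytest.approx(81e-9)
    assert bk.to_canonical(2.6, "mM")[0] == pytest.approx(2.6e-3)
    assert bk.to_canonical(1.0, "%") == (1.0, "%")
    with pytest.raises(ValidationError):
        bk.to_canonical(1.0, "furlongs")
    with pytest.raises(ValidationError):
        bk.to_canonical(-1.0, "mM")


def test_well_time_series_invariants(well_factory):
    with pytest.raises(ValidationError):  # too short
        well_factory([0.0], [0.1], [5.0])
    with pytest.raises(ValidationError):  # non-increasing time
        well_factory([0.0, 10.0, 10.0], [0.1] * 3, [5.0] * 3)
    with pytest.raises(ValidationError):  # ragged channel
        well_factory([0.0, 10.0], [0.1, 0.2], [5.0])


def test_plate_rejects_mismatched_channel_sets(well_factory):
    w1 = well_factory([0, 10], [0.1, 0.2], [1, 2], channel="GFP")
    w2 = well_factory([0, 10], [0.1, 0.2], [1, 2], channel="RFP")
    with pytest.raises(ValidationError):
        bk.PlateExperiment(wells=[w1, w2])


def test_read_plate_toy_table(tmp_path):
    plate = tmp_path / "plate.csv"
    layout = tmp_path / "layout.csv"
    rows = []
    for well in ("A1", "A2"):
        for t in (0, 10, 20):
            rows.append(f"{well},{t},0.1,GFP,{t * 2.0}")
    plate.write_text("well,time_min,od600,channel,value\n" + "\n".join(rows) + "\n")
    layout.write_text(
        "well,sensor,inducer,concentration,unit,replicate,is_control,copy_number\n"
        "A1,AraC,arabinose,59,uM,1,False,high\n"
        "A2,control,none,0,mM,1,True,high\n"
    )
    exp = bk.read_plate(plate, layout)
    assert len(exp.wells) == 2
    assert all(w.n_samples == 3 for w in exp.wells)
    a1 = next(w for w in exp.wells if w.well == "A1")
    assert a1.condition.concentration == pytest.approx(59e-6)
    assert len(exp.control_wells) == 1


def test_read_plate_missing_column_names_it(tmp_path):
    plate = tmp_path / "plate.csv"
    layout = tmp_path / "layout.csv"
    plate.write_text("well,time_min,OD,channel,value\nA1,0,0.1,GFP,1\n")
    layout.write_text(
        "well,sensor,inducer,concentration,unit,replicate,is_control,copy_number\n"
        "A1,S,x,0,mM,1,False,high\n"
    )
    with pytest.raises(FormatError, match="od600"):
        bk.read_plate(plate, layout)


def test_read_plate_rejects_unknown_well_and_duplicate_time(tmp_path):
    layout = tmp_path / "layout.csv"
    layout.write_text(
        "well,sensor,inducer,concentration,unit,replicate,is_control,copy_number\n"
        "A1,S,x,0,mM,1,False,high\n"
    )
    plate = tmp_path / "plate.csv"
    plate.write_text(
        "well,time_min,od600,channel,value\nA1,0,0.1,GFP,1\nB9,0,0.1,GFP,1\nA1,10,0.1,GFP,2\n"
    )
    with pytest.raises(ValidationError, match="B9"):
        bk.read_plate(plate, layout)
    plate.write_text(
        "well,time_min,od600,channel,value\nA1,0,0.1,GFP,1\nA1,0,0.1,GFP,2\n"
    )
    with pytest.raises(ValidationError):
        bk.read_plate(plate, layout)


def test_write_plate_empty_and_single(tmp_path, well_factory):
    out = tmp_path / "empty.csv"
    bk.write_plate(bk.PlateExperiment(wells=[], channels=["GFP"]), out)
    assert out.read_text().strip() == "well,time_min,od600,channel,value"
    w = well_factory([0, 10, 20], [0.1, 0.2, 0.4], [1.0, 2.0, 3.0])
    out2 = tmp_path / "one.csv"
    bk.write_plate(bk.PlateExperiment(wells=[w]), out2)
    assert len(out2.read_text().strip().splitlines()) == 1 + 3  # header + t*ch rows


@pytest.mark.parametrize("seed", [0, 1])
def test_plate_round_trip_byte_identical(tmp_path, seed):
    cfg = bk.preset_config(sensors=("AraC", "TetR"), seed=seed, replicates=2)
    exp = bk.simulate_plate(cfg)
    p1, l1 = tmp_path / "p1.csv", tmp_path / "l1.csv"
    p2, l2 = tmp_path / "p2.csv", tmp_path / "l2.csv"
    bk.write_plate(exp, p1, layout_path=l1)
    bk.write_plate(bk.read_plate(p1, l1), p2, layout_path=l2)
    assert p1.read_bytes() == p2.read_bytes()
    assert l1.read_bytes() == l2.read_bytes()


def test_read_events_toy_and_duplicate(tmp_path):
    path = tmp_path / "events.csv"
    lines = ["sample_label,event_id,channel,value"]
    for e in range(3):
        for ch in ("CFP", "GFP", "mCherry"):
            lines.append(f"s1,{e},{ch},{e + 1}.5")
    path.write_text("\n".join(lines) + "\n")
    samples = bk.read_events(path)
    assert len(samples) == 1 and samples[0].events.shape == (3, 3)
    path.write_text("\n".join(lines + ["s1,0,GFP,9.9"]) + "\n")
    with pytest.raises(ValidationError, match="duplicated"):
        bk.read_events(path)


def test_read_events_ragged_channels(tmp_path):
    path = tmp_path / "events.csv"
    path.write_text(
        "sample_label,event_id,channel,value\n"
        "s1,0,GFP,1\ns1,0,CFP,1\ns1,1,GFP,2\n"
    )
    with pytest.raises(ValidationError, match="ragged"):
        bk.read_events(path)


def test_events_round_trip_and_order(tmp_path):
    sample = bk.simulate_events({"glucarate"}, n_events=10_000, seed=5)
    p1, p2 = tmp_path / "e1.csv", tmp_path / "e2.csv"
    bk.write_events([sample], p1)
    back = bk.read_events(p1)
    for ch in sample.channels:  # event order within each channel is kept
        np.testing.assert_array_equal(
            back[0].channel_values(ch), sample.channel_values(ch)
        )
    bk.write_events(back, p2)
    assert p1.read_bytes() == p2.read_bytes()


@given(
    n_sensors=st.integers(1, 3),
    n_times=st.integers(2, 5),
    seed=st.integers(0, 10_000),
)
def test_round_trip_property_random_small_plates(tmp_path_factory, n_sensors, n_times, seed):
    """Lossless write/read on randomized small experiments."""
    tmp = tmp_path_factory.mktemp("rt")
    names = ["AraC", "TetR", "MphR"][:n_sensors]
    cfg = bk.preset_config(
        sensors=tuple(names),
        seed=seed,
        replicates=1,
        n_concentrations=4,
        duration_min=(n_times - 1) * 10.0,
    )
    exp = bk.simulate_plate(cfg)
    p1, l1, p2 = tmp / f"a{seed}.csv", tmp / f"al{seed}.csv", tmp / f"b{seed}.csv"
    bk.write_plate(exp, p1, layout_path=l1)
    exp2 = bk.read_plate(p1, l1)
    bk.write_plate(exp2, p2)
    assert p1.read_bytes() == p2.read_bytes()
    for w1, w2 in zip(sorted(exp.wells, key=lambda w: w.well), exp2.wells):
        np.testing.assert_array_equal(w1.times, w2.times)
        np.testing.assert_array_equal(w1.fluorescence["GFP"], w2.fluorescence["GFP"])
        assert w1.condition == w2.condition


def test_variants_round_trip(tmp_path):
    df = bk.simulate_variants(
        4, (5e-5, 5e-3), bk.TABLE1[("CdaR", "high")].expression, seed=2
    )
    path = tmp_path / "variants.csv"
    bk.write_variants(df, path)
    records = bk.read_variants(path)
    assert len(records) == 4
    by_id = {r.variant_id: r for r in records}
    for vid, vdf in df.groupby("variant_id"):
        assert by_id[vid].fluorescence == pytest.approx(vdf["fluorescence"].mean())
        assert by_id[vid].n_replicates == 3
        assert by_id[vid].cv is not None  # CV reported when replicates >= 2


def test_variant_record_requires_cv_for_replicates():
    with pytest.raises(ValidationError):
        bk.VariantRecord(variant_id="v", fluorescence=1.0, n_replicates=3, cv=None)
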