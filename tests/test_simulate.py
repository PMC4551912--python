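"""Generator correctness: closed forms, limits, reproducibility."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import biosensorkit as bk
from biosensorkit.errors import ConfigError
from biosensorkit.simulate import hill_rate


def _single_sensor_cfg(expr, conc, noise=bk.ZERO_NOISE, **kwargs):
    spec = bk.SensorSpec(expression=expr, inducer="x", concentrations=(conc,))
    return bk.GeneratorConfig(sensors={"S": spec}, noise=noise, **kwargs)


def test_uninduced_tight_sensor_matches_control():
    """Zero noise, I = 0, v_min = 0: the sensor well is indistinguishable
    from the background strain."""
    expr = bk.ExpressionParams(v_max=1000.0, v_min=0.0, hill_h=2.0, k_half=1e-4)
    cfg = _single_sensor_cfg(expr, 0.0, replicates=1, include_uninduced=False)
    exp = bk.simulate_plate(cfg)
    sensor = exp.sample_wells[0]
    control = exp.control_wells[0]
    np.testing.assert_allclose(
        sensor.fluorescence["GFP"], control.fluorescence["GFP"], rtol=1e-12
    )


def test_saturating_dose_reaches_full_velocity():
    """At I >> K the per-OD fluorescence gains (v_max + v_min) * 60 * dt per
    interval during active expression."""
    expr = bk.ExpressionParams(
        v_max=1000.0, v_min=50.0, hill_h=2.0, k_half=1e-4, stationary_shutoff=False
    )
    cfg = _single_sensor_cfg(expr, 1e2, replicates=1, include_uninduced=False)
    exp = bk.simulate_plate(cfg)
    w = exp.sample_wells[0]
    per_od = w.fluorescence["GFP"] / w.od - cfg.noise.background_slope
    gain = np.diff(per_od)
    np.testing.assert_allclose(gain, (1000.0 + 50.0) * 60.0 * 10.0, rtol=1e-9)


def test_zero_noise_closed_form_accumulation():
    """With shutoff off the background-corrected per-OD trace is v(I)*60*t."""
    expr = bk.ExpressionParams(
        v_max=900.0, v_min=5.0, hill_h=3.2, k_half=2.6e-3, stationary_shutoff=False
    )
    conc = 2.6e-3  # I = K: half occupancy exactly
    cfg = _single_sensor_cfg(expr, conc, replicates=1, include_uninduced=False)
    exp = bk.simulate_plate(cfg)
    w = exp.sample_wells[0]
    g = w.fluorescence["GFP"] / w.od - cfg.noise.background_slope
    v = 5.0 + 900.0 / 2.0
    np.testing.assert_allclose(g, v * 60.0 * w.times, rtol=1e-9, atol=1e-6)


def test_stationary_shutoff_freezes_accumulation():
    expr = bk.ExpressionParams(v_max=1000.0, hill_h=1.0, k_half=1e-6)
    cfg = _single_sensor_cfg(expr, 1e-3, replicates=1, include_uninduced=False)
    exp = bk.simulate_plate(cfg)
    w = exp.sample_wells[0]
    g = w.fluorescence["GFP"] / w.od - cfg.noise.background_slope
    t_stop = bk.stationary_onset(cfg.growth)
    late = w.times >= t_stop + 10
    assert np.ptp(g[late]) < 1e-6 * g[-1]  # flat after onset
    assert g[-1] < 1000.0 * 60.0 * 900.0 * 0.5  # well below shutoff-free level


def test_post_stationary_accumulation_keeps_growing():
    expr = bk.ExpressionParams(
        v_max=1000.0, hill_h=1.0, k_half=1e-6, post_stationary_accumulation=True
    )
    cfg = _single_sensor_cfg(expr, 1e-3, replicates=1, include_uninduced=False)
    w = bk.simulate_plate(cfg).sample_wells[0]
    g = w.fluorescence["GFP"] / w.od - cfg.noise.background_slope
    assert np.all(np.diff(g) > 0)


def test_toxicity_scales_growth_rate_not_capacity():
    tox = bk.ToxicityParams(ic50=1e-3, steepness=1.0, max_inhibition=1.0)
    expr = bk.ExpressionParams(v_max=0.0, v_min=0.0)
    spec = bk.SensorSpec(expression=expr, inducer="x", concentrations=(1e-3,))
    cfg = bk.GeneratorConfig(
        sensors={"S": spec},
        toxicity={"x": tox},
        noise=bk.ZERO_NOISE,
        replicates=1,
        include_uninduced=False,
        duration_min=3000.0,
    )
    w = bk.simulate_plate(cfg).sample_wells[0]
    assert w.od[-1] == pytest.approx(cfg.growth.carrying_capacity, rel=1e-3)
    # half the growth rate: reaching 95% capacity takes twice the post-lag time
    t_half = bk.stationary_onset(cfg.growth, 0.5) - cfg.growth.lag_min
    t_full = bk.stationary_onset(cfg.growth, 1.0) - cfg.growth.lag_min
    assert t_half == pytest.approx(2 * t_full)


def test_simulate_plate_reproducible_and_stable_under_extension():
    cfg1 = bk.preset_config(sensors=("AraC",), seed=9)
    cfg2 = bk.preset_config(sensors=("AraC", "MphR"), seed=9)
    a = bk.simulate_plate(cfg1)
    a_again = bk.simulate_plate(cfg1)
    b = bk.simulate_plate(cfg2)
    for w1, w2 in zip(a.wells, a_again.wells):
        np.testing.assert_array_equal(w1.fluorescence["GFP"], w2.fluorescence["GFP"])
    ara_b = [w for w in b.wells if w.condition.sensor == "AraC"]
    ctl_b = [w for w in b.wells if w.condition.is_control]
    for w1, w2 in zip([w for w in a.wells if not w.condition.is_control], ara_b):
        np.testing.assert_array_equal(w1.fluorescence["GFP"], w2.fluorescence["GFP"])
    for w1, w2 in zip(a.control_wells, ctl_b):
        np.testing.assert_array_equal(w1.fluorescence["GFP"], w2.fluorescence["GFP"])


def test_simulate_events_deterministic_medians_and_empty_state():
    models = {
        "GFP": bk.ChannelModel("glucarate", 1e4, 1e2, gcv_on=0.0, gcv_off=0.0),
        "CFP": bk.ChannelModel("acrylate", 2e4, 2e2, gcv_on=0.0, gcv_off=0.0),
    }
    s = bk.simulate_events({"glucarate"}, models, n_events=1, nonresponder_frac=0.0)
    assert s.channel_values("GFP")[0] == pytest.approx(1e4)
    assert s.channel_values("CFP")[0] == pytest.approx(2e2)
    off = bk.simulate_events(set(), models, n_events=5, nonresponder_frac=0.0)
    assert np.all(off.channel_values("GFP") == 1e2)
    assert off.sample_label == "none"


def test_simulate_events_validation():
    with pytest.raises(ConfigError):
        bk.simulate_events({"glucarate"}, nonresponder_frac=0.2)
    with pytest.raises(ConfigError):
        bk.simulate_events({"unknown-chemical"})


def test_simulate_events_seeded_reproducibility():
    a = bk.simulate_events({"glucarate"}, seed=7)
    b = bk.simulate_events({"glucarate"}, seed=7)
    np.testing.assert_array_equal(a.events, b.events)


def test_toxicity_series_fixed_points():
    params = bk.ToxicityParams(ic50=1e-3, steepness=1.0, max_inhibition=1.0)
    df = bk.simulate_toxicity_series(params, [0.0, 1e-3], noise_cv=0.0)
    zero = df[df["concentration"] == 0.0]["normalized_rate"]
    assert zero.mean() == pytest.approx(1.0)
    at_ic50 = df[df["concentration"] == 1e-3]["normalized_rate"]
    assert at_ic50.mean() == pytest.approx(0.5)


@given(
    ic50=st.floats(1e-6, 1e-2),
    steep=st.floats(0.5, 4.0),
    inhibition=st.floats(0.1, 1.0),
)
def test_toxicity_series_monotone_without_benefit(ic50, steep, inhibition):
    params = bk.ToxicityParams(ic50=ic50, steepness=steep, max_inhibition=inhibition)
    concs = np.geomspace(ic50 / 100, ic50 * 100, 9)
    df = bk.simulate_toxicity_series(params, concs, noise_cv=0.0)
    means = df.groupby("concentration")["normalized_rate"].mean().to_numpy()
    assert np.all(np.diff(means) <= 1e-12)


def test_growth_benefit_raises_rate():
    params = bk.ToxicityParams(
        ic50=1e-3, steepness=1.0, max_inhibition=0.0, growth_benefit=0.3
    )
    assert bk.toxicity_factor(params, 1e-1) == pytest.approx(1.3, rel=1e-2)


def test_variants_monotone_and_concordant():
    transfer = bk.TABLE1[("CdaR", "high")].expression
    df = bk.simulate_variants(6, (5e-5, 5e-3), transfer, noise_cv=0.0, seed=0)
    means = df.groupby("variant_id", sort=True)["fluorescence"].mean()
    titers = df.groupby("variant_id", sort=True)["titer"].mean()
    order = titers.sort_values().index
    assert np.all(np.diff(means.loc[order].to_numpy()) > 0)
    from scipy.stats import spearmanr

    rho, _ = spearmanr(means, titers)
    assert rho == pytest.approx(1.0)


def test_variants_twenty_fold_span():
    """Four variants spanning the screen's dynamic-range regime: roughly a
    20-fold fluorescence spread between weakest and strongest."""
    transfer = bk.TABLE1[("CdaR", "high")].expression
    k = transfer.k_half
    df = bk.simulate_variants(4, (0.05 * k, 20 * k), transfer, noise_cv=0.0, seed=0)
    means = df.groupby("variant_id")["fluorescence"].mean()
    assert means.max() / means.min() == pytest.approx(20.0, rel=0.05)


def test_hill_rate_limits():
    expr = bk.ExpressionParams(v_max=100.0, v_min=7.0, hill_h=2.0, k_half=1e-4)
    assert hill_rate(expr, 0.0) == 7.0
    assert hill_rate(expr, 1e-4) == pytest.approx(57.0)
    assert hill_rate(expr, 1e2) == pytest.approx(107.0, rel=1e-6)
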