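"""Binning, Grynkiewicz calibration, EGTA anchoring and feature extraction."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace
from hypothesis import given, settings
from hypothesis import strategies as st

from platekin.exceptions import (EmptyStreamError, IncompleteProtocolError,
                                 SaturationError)
from platekin.protocol import ProtocolSpec
from platekin.synthetic_cohort import make_donor_stream
from platekin.trace_processing import (CalibrationConstants, EventStream,
                                       FeatureVector, bin_events,
                                       extract_calibration, extract_features,
                                       fibrinogen_relative,
                                       grynkiewicz_calcium, normalize_calcium,
                                       process_stream, ssc_shape_change)

CONSTS = CalibrationConstants(kd_furared=400.0, fi_max=2000.0, fi_min=600.0,
                              r_min=0.2, r_max=3.0)


def _stream_from_arrays(t, **channels):
    df = pd.DataFrame({"time_s": t})
    for name in ("FSC", "SSC_A", "FL405", "FL488", "FL_FIB"):
        df[name] = channels.get(name, np.ones_like(t))
    return EventStream(donor_id="test", events=df)


# ---------------------------------------------------------------- binning

def test_bin_means_match_brute_force_grouping():
    rng = np.random.default_rng(42)
    t = np.sort(rng.uniform(0, 20, size=500))
    v = rng.uniform(0, 100, size=500)
    stream = _stream_from_arrays(t, FL405=v)
    trace = bin_events(stream, bin_width_s=1.0)
    # independent oracle: direct per-bin grouping
    idx = np.floor(t).astype(int)
    for b, center in zip(np.unique(idx), trace.bin_centers_s):
        expected = v[idx == b].mean()
        got = trace.means["FL405"].to_numpy()[trace.bin_centers_s == b + 0.5]
        assert got[0] == pytest.approx(expected)
    assert trace.n_events_per_bin.sum() == 500


def test_constant_channel_gives_constant_bins():
    t = np.linspace(0, 9.99, 200)
    trace = bin_events(_stream_from_arrays(t, SSC_A=np.full(200, 7.5)))
    assert np.allclose(trace.means["SSC_A"], 7.5)


def test_empty_stream_rejected():
    with pytest.raises(EmptyStreamError):
        bin_events(_stream_from_arrays(np.array([])))


def test_event_invariants_enforced():
    with pytest.raises(ValueError):
        _stream_from_arrays(np.array([2.0, 1.0]))
    with pytest.raises(ValueError):
        _stream_from_arrays(np.array([1.0, 2.0]),
                            FL405=np.array([1.0, -3.0]))


# ----------------------------------------------------------- Grynkiewicz

def test_r_min_maps_to_zero_calcium():
    assert grynkiewicz_calcium(CONSTS.r_min, CONSTS) == 0.0


def test_midpoint_identity():
    """At R = (Rmin+Rmax)/2 the ratio term is 1, so Ca = Kd*FImax/FImin."""
    mid = 0.5 * (CONSTS.r_min + CONSTS.r_max)
    expected = CONSTS.kd_furared * CONSTS.fi_max / CONSTS.fi_min
    assert grynkiewicz_calcium(mid, CONSTS) == pytest.approx(expected)


@settings(deadline=None, derandomize=True)
@given(st.floats(min_value=0.201, max_value=2.99),
       st.floats(min_value=0.202, max_value=2.995))
def test_matches_direct_formula_and_is_monotone(r1, r2):
    direct = lambda r: 400.0 * (2000.0 / 600.0) * (r - 0.2) / (3.0 - r)
    assert grynkiewicz_calcium(r1, CONSTS) == pytest.approx(direct(r1))
    lo, hi = sorted((r1, r2))
    if hi - lo > 1e-12:
        assert grynkiewicz_calcium(hi, CONSTS) > grynkiewicz_calcium(lo,
                                                                     CONSTS)


def test_saturation_raises():
    with pytest.raises(SaturationError):
        grynkiewicz_calcium(CONSTS.r_max, CONSTS)


def test_subfloor_ratios_clip_to_zero_with_warning():
    with pytest.warns(UserWarning, match="below r_min"):
        out = grynkiewicz_calcium(np.array([0.1, 0.5]), CONSTS)
    assert out[0] == 0.0 and out[1] > 0


def test_forward_inverse_round_trip_to_machine_precision():
    """Eq-inversion (generator side) composed with the forward formula."""
    ca = np.array([1.0, 8.0, 50.0, 155.0, 1000.0])
    k = CONSTS.k_eff
    r = (CONSTS.r_min + CONSTS.r_max * ca / k) / (1.0 + ca / k)
    assert np.allclose(grynkiewicz_calcium(r, CONSTS), ca, rtol=1e-12)


# ------------------------------------------------ calibration + anchoring

def test_noisy_calibration_recovers_programmed_constants(protocol,
                                                         healthy_features,
                                                         gen_constants):
    stream = make_donor_stream(healthy_features, protocol, seed=3,
                               event_rate=500.0, noise_cv=0.25)
    trace = bin_events(stream)
    consts = extract_calibration(trace, protocol)
    assert consts.r_max == pytest.approx(gen_constants.r_max, rel=0.05)
    assert consts.fi_min == pytest.approx(gen_constants.fi_min, rel=0.05)
    assert consts.fi_max == pytest.approx(gen_constants.fi_max, rel=0.05)


def test_normalize_is_idempotent_and_linear(noiseless_stream, protocol):
    trace = bin_events(noiseless_stream)
    consts = extract_calibration(trace, protocol)
    once = normalize_calcium(trace, consts, protocol)
    twice = normalize_calcium(once, consts, protocol)
    assert np.allclose(once.ca_nM, twice.ca_nM, equal_nan=True)
    # doubling the measured scale halves everything back to the anchor
    doubled = replace(once, ca_nM=once.ca_nM * 2.0)
    renorm = normalize_calcium(doubled, consts, protocol)
    assert np.allclose(renorm.ca_nM, once.ca_nM, equal_nan=True)


def test_miscalibrated_fi_max_corrected_by_anchor(noiseless_stream,
                                                  protocol,
                                                  healthy_features):
    """A wrong FImax scales calcium multiplicatively; the EGTA anchor
    rescales the series back to truth."""
    trace = bin_events(noiseless_stream)
    consts = extract_calibration(trace, protocol)
    bad = CalibrationConstants(kd_furared=consts.kd_furared,
                               fi_max=consts.fi_max * 1.5,
                               fi_min=consts.fi_min,
                               r_min=consts.r_min, r_max=consts.r_max)
    fixed = normalize_calcium(trace, bad, protocol)
    base = (fixed.bin_centers_s >= protocol.agonist_time_s - 30) & \
           (fixed.bin_centers_s < protocol.agonist_time_s)
    ca_basal = np.nanmean(fixed.ca_nM[base])
    assert ca_basal == pytest.approx(healthy_features.ca_basal_nM, rel=0.05)


def test_missing_epoch_raises(noiseless_stream, protocol):
    events = noiseless_stream.events
    clipped = EventStream("clip", events[events.time_s < 400].reset_index(
        drop=True))
    with pytest.raises(IncompleteProtocolError):
        extract_calibration(bin_events(clipped), protocol)


# ------------------------------------------------------------ fibrinogen

def test_fibrinogen_endpoints_and_affine_invariance(noiseless_stream,
                                                    protocol):
    trace = bin_events(noiseless_stream)
    fib = fibrinogen_relative(trace, protocol)
    t = trace.bin_centers_s
    base = (t >= protocol.agonist_time_s - 30) & (t < protocol.agonist_time_s)
    plateau = (t >= protocol.ionomycin_time_s + 300) & \
              (t < protocol.ionomycin_time_s + 600)
    assert np.median(fib[base]) == pytest.approx(0.0, abs=1e-9)
    assert np.median(fib[plateau]) == pytest.approx(1.0, abs=1e-9)
    # gain/offset on the raw channel leaves the relative series unchanged
    scaled = replace(trace, means=trace.means.assign(
        FL_FIB=trace.means["FL_FIB"] * 3.0 + 40.0))
    assert np.allclose(fibrinogen_relative(scaled, protocol), fib)


def test_linear_ramp_crosses_half_at_half_time(protocol):
    """A programmed linear ramp from 0 to plateau reads 0.5 halfway."""
    t = np.arange(0.0, protocol.run_end_s, 0.25)
    t_io = protocol.ionomycin_time_s
    ramp = np.clip((t - 100.0) / (t_io - 100.0), 0.0, 1.0)
    fib_raw = 50.0 + 400.0 * ramp
    stream = _stream_from_arrays(t, FL_FIB=fib_raw)
    trace = bin_events(stream)
    fib = fibrinogen_relative(trace, protocol)
    half_time = 100.0 + 0.5 * (t_io - 100.0)
    i = np.argmin(np.abs(trace.bin_centers_s - half_time))
    assert fib[i] == pytest.approx(0.5, abs=0.01)


# ------------------------------------------------------------------- SSC

def test_constant_ssc_gives_zero_change(protocol):
    t = np.arange(0.0, protocol.run_end_s, 0.2)
    trace = bin_events(_stream_from_arrays(t, SSC_A=np.full_like(t, 5000.0)))
    assert ssc_shape_change(trace, protocol) == pytest.approx(0.0, abs=1e-12)


def test_ssc_change_is_gain_invariant(noiseless_stream, protocol):
    trace = bin_events(noiseless_stream)
    doubled = replace(trace, means=trace.means.assign(
        SSC_A=trace.means["SSC_A"] * 2.0))
    assert ssc_shape_change(doubled, protocol) == pytest.approx(
        ssc_shape_change(trace, protocol))


# --------------------------------------------------------------- features

@pytest.mark.parametrize("features", [
    FeatureVector(8.0, 91.0, 0.16, 0.31),      # healthy
    FeatureVector(15.0, 155.0, 0.21, 0.31),    # ITP high fib binding
    FeatureVector(15.0, 101.0, 0.082, 0.225),  # ITP low fib binding
    FeatureVector(8.0, 81.0, 0.034, 0.225),    # Glanzmann thrombasthenia
], ids=["healthy", "HFB", "LFB", "GT"])
def test_noiseless_feature_recovery_within_1_percent(protocol, features):
    stream = make_donor_stream(features, protocol, seed=0,
                               event_rate=200.0, noise_cv=0.0)
    fv = extract_features(stream, protocol)
    assert fv.ca_basal_nM == pytest.approx(features.ca_basal_nM, rel=0.01)
    assert fv.ca_max_nM == pytest.approx(features.ca_max_nM, rel=0.01)
    assert fv.fib_rel == pytest.approx(features.fib_rel, rel=0.01)
    assert fv.ssc_change == pytest.approx(features.ssc_change, rel=0.01)


def test_no_agonist_stream_has_flat_features(protocol):
    quiet = ProtocolSpec(agonist="none",
                         baseline_end_s=protocol.baseline_end_s,
                         agonist_time_s=protocol.agonist_time_s)
    features = FeatureVector(10.0, 10.0, 0.0, 0.0)
    stream = make_donor_stream(features, quiet, seed=1, event_rate=200.0,
                               noise_cv=0.0)
    fv = extract_features(stream, quiet)
    assert fv.ca_max_nM == pytest.approx(fv.ca_basal_nM, rel=0.02)
    assert abs(fv.fib_rel) < 0.01


def test_gt_donor_binds_little_fibrinogen_despite_normal_calcium(protocol):
    gt = FeatureVector(8.0, 81.0, 0.034, 0.225)
    stream = make_donor_stream(gt, protocol, seed=5, event_rate=500.0,
                               noise_cv=0.25)
    fv = extract_features(stream, protocol)
    assert fv.fib_rel < 0.05
    assert 50.0 < fv.ca_max_nM < 130.0


def test_process_stream_attaches_calcium_and_fibrinogen(noiseless_stream,
                                                        protocol):
    trace, consts = process_stream(noiseless_stream, protocol)
    assert trace.ca_nM is not None and trace.fib_rel is not None
    assert consts.egta_mark_nM == pytest.approx(50.0, abs=2.0)
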