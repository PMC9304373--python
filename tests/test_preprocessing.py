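import numpy as np
import pandas as pd
import pytest
from dataclasses import replace
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import erpadapt as ea
from conftest import synthetic_epochset
from erpadapt.generator import ContinuousRecording
from erpadapt.preprocessing import (
    condition_epochs,
    interpolate_spline,
    lowpass_filter,
    mark_bad_amplitude,
    reject_impedance,
    rereference_average,
    segment_epochs,
)


def make_recording(layout, data, event_samples, impedances=None):
    n = len(event_samples)
    events = pd.DataFrame(
        {
            "sample": np.asarray(event_samples, dtype=int),
            "category": ["human"] * n,
            "block_id": [0] * n,
            "block_type": ["uniform_human"] * n,
        }
    )
    if impedances is None:
        impedances = np.full(layout.n_channels, 50.0)
    return ContinuousRecording(
        data=data, rate_hz=250.0, events=events, impedances=impedances, layout=layout
    )


# --------------------------------------------------------------------------
# low-pass filter


def test_filter_preserves_dc_and_attenuates_60hz(layout128):
    t = np.arange(5000) / 250.0
    data = np.tile(2.0 + np.sin(2 * np.pi * 60.0 * t), (layout128.n_channels, 1))
    rec = make_recording(layout128, data, [2500])
    out = lowpass_filter(rec, 30.0)
    mid = out.data[0, 1000:4000]
    assert mid.mean() == pytest.approx(2.0, abs=1e-6)  # DC passes
    assert np.abs(mid - 2.0).max() < 0.02  # 60 Hz crushed (>30 dB, twice-applied)


def test_filter_is_zero_phase(layout128):
    data = np.zeros((layout128.n_channels, 2001))
    data[:, 1000] = 100.0  # symmetric impulse
    rec = make_recording(layout128, data, [1000])
    out = lowpass_filter(rec, 30.0)
    assert int(np.argmax(out.data[0])) == 1000
    assert np.allclose(out.data[0][:1000], out.data[0][1001:][::-1], atol=1e-9)


def test_filter_rejects_cutoff_at_or_above_nyquist(layout128):
    rec = make_recording(layout128, np.zeros((layout128.n_channels, 500)), [250])
    with pytest.raises(ValueError):
        lowpass_filter(rec, 125.0)


# --------------------------------------------------------------------------
# impedance screening


def test_impedance_screening(layout128):
    data = np.zeros((layout128.n_channels, 500))
    rec = make_recording(layout128, data, [250])
    assert reject_impedance(rec) == ()
    imp = np.full(layout128.n_channels, 50.0)
    imp[layout128.index("E42")] = 250.0
    rec = make_recording(layout128, data, [250], impedances=imp)
    assert reject_impedance(rec) == ("E42",)
    assert len(reject_impedance(rec, threshold=0.0)) == layout128.n_channels


# --------------------------------------------------------------------------
# segmentation


def test_segmentation_window_and_boundary(layout128, caplog):
    n_ch = layout128.n_channels
    data = np.arange(n_ch * 2000, dtype=float).reshape(n_ch, 2000)
    rec = make_recording(layout128, data, [10, 500, 750, 1990])
    with caplog.at_level("WARNING"):
        epochs = segment_epochs(rec)
    assert epochs.n_epochs == 2  # first and last overflow the record
    assert epochs.data.shape == (2, n_ch, 150)
    assert epochs.times_ms[25] == 0.0
    assert epochs.times_ms[0] == -100.0
    assert epochs.times_ms[-1] == 496.0  # half-open window: 500 ms excluded
    assert np.array_equal(epochs.data[0, 0], data[0, 475:625])
    assert "dropped" in caplog.text


# --------------------------------------------------------------------------
# epoch conditioning


def test_conditioning_annihilates_affine_trends(layout128):
    n_ch = layout128.n_channels
    t = np.arange(150, dtype=float)
    data = np.empty((3, n_ch, 150))
    data[0] = 5.0  # constant
    data[1] = 0.2 * t - 7.0  # ramp
    data[2] = np.sin(2 * np.pi * t / 150.0)
    epochs = synthetic_epochset(layout128, 3, data=data)
    out = condition_epochs(epochs)
    assert np.abs(out.data[0]).max() < 1e-9
    assert np.abs(out.data[1]).max() < 1e-9
    assert np.abs(out.data[2, :, :25].mean(axis=1)).max() < 1e-9  # baseline zeroed


@settings(deadline=None, max_examples=25)
@given(
    x=hnp.arrays(
        float, (2, 150), elements=st.floats(-100, 100, allow_nan=False, width=32)
    )
)
def test_conditioning_is_idempotent(x):
    layout = ea.make_layout(16)
    data = np.zeros((1, 16, 150))
    data[0, :2] = x
    once = condition_epochs(synthetic_epochset(layout, 1, data=data))
    twice = condition_epochs(once)
    assert np.allclose(once.data, twice.data, atol=1e-9)


# --------------------------------------------------------------------------
# amplitude marking


def test_marking_rules(layout128):
    n_ch = layout128.n_channels
    data = np.zeros((3, n_ch, 150))
    data[1, 5, 60] = 151.0  # one channel out -> interpolable
    data[2, :13, 60] = -200.0  # 13 channels out -> reject
    epochs = synthetic_epochset(layout128, 3, data=data)
    out = mark_bad_amplitude(epochs)
    assert out.bad_channel_mask.sum() == 14
    assert out.bad_channel_mask[1, 5]
    assert list(out.rejected) == [False, False, True]
    assert out.reject_reason[2] == "bad_channels"


def test_marking_boundary_exactly_12_bad_channels_not_rejected(layout128):
    data = np.zeros((1, layout128.n_channels, 150))
    data[0, :12, 10] = 200.0
    out = mark_bad_amplitude(synthetic_epochset(layout128, 1, data=data))
    assert not out.rejected[0]


def test_globally_bad_channels_marked_everywhere(layout128):
    epochs = synthetic_epochset(layout128, 2)
    out = mark_bad_amplitude(epochs, globally_bad=("E7", "E9"))
    idx = layout128.indices(("E7", "E9"))
    assert out.bad_channel_mask[:, idx].all()
    assert out.bad_channel_mask.sum() == 4


# --------------------------------------------------------------------------
# spline interpolation within the chain


def test_interpolation_recovers_smooth_field(layout128):
    """A low-order spherical field is reproduced nearly exactly on bad channels."""
    pos = layout128.positions
    field = 3.0 * pos[:, 2] + 1.0 * pos[:, 0] - 0.5  # dipole + offset
    data = np.repeat(field[None, :, None], 150, axis=2).reshape(1, -1, 150)
    truth = data.copy()
    bad = layout128.indices(("E10", "E50"))
    data[0, bad] += 500.0  # corrupt, then mark
    epochs = synthetic_epochset(layout128, 1, data=data)
    epochs = mark_bad_amplitude(epochs)
    assert set(np.flatnonzero(epochs.bad_channel_mask[0])) == set(bad)
    out = interpolate_spline(epochs)
    assert np.abs(out.data[0, bad] - truth[0, bad]).max() < 1e-3
    good = np.setdiff1d(np.arange(layout128.n_channels), bad)
    assert np.array_equal(out.data[0, good], truth[0, good])  # untouched
    assert out.interpolated_mask[0, bad].all()


def test_interpolation_independent_of_bad_channel_content(layout128):
    pos = layout128.positions
    field = np.repeat((2.0 * pos[:, 1])[None, :, None], 150, axis=2).reshape(1, -1, 150)
    bad = layout128.indices(("E20",))
    a = field.copy()
    a[0, bad] = 1e4
    b = field.copy()
    b[0, bad] = -1e4
    outs = []
    for data in (a, b):
        epochs = mark_bad_amplitude(synthetic_epochset(layout128, 1, data=data.copy()),
                                    limit_uV=150.0)
        outs.append(interpolate_spline(epochs).data[0, bad])
    assert np.array_equal(outs[0], outs[1])


def test_too_few_good_channels_rejects_epoch():
    layout = ea.make_layout(16)
    data = np.zeros((1, 16, 150))
    data[0, :13, 0] = 200.0  # 13 bad of 16 leaves 3 good (< 4 needed)
    epochs = mark_bad_amplitude(synthetic_epochset(layout, 1, data=data),
                                max_bad_channels=15)
    out = interpolate_spline(epochs)
    assert out.rejected[0]
    assert out.reject_reason[0] == "too_few_good_channels"


# --------------------------------------------------------------------------
# average reference


def test_average_reference_zero_sum_and_idempotent(layout128):
    rng = np.random.default_rng(0)
    data = rng.normal(0, 10, (4, layout128.n_channels, 150))
    out = rereference_average(synthetic_epochset(layout128, 4, data=data))
    assert np.abs(out.data.sum(axis=1)).max() < 1e-9
    again = rereference_average(out)
    assert np.allclose(out.data, again.data, atol=1e-12)


def test_average_reference_arithmetic(layout128):
    n_ch = layout128.n_channels
    data = np.zeros((1, n_ch, 150))
    data[0, 0, :] = 128.0  # one hot channel
    out = rereference_average(synthetic_epochset(layout128, 1, data=data))
    assert np.allclose(out.data[0, 0], 128.0 - 128.0 / n_ch)
    assert np.allclose(out.data[0, 1], -128.0 / n_ch)


# --------------------------------------------------------------------------
# full chain + QC accounting


def test_clean_recording_keeps_every_epoch(clean_epochs, infant_design_1it):
    epochs, report = clean_epochs
    _, trials = infant_design_1it
    assert report.n_events == len(trials)
    assert report.n_segmented == report.n_retained == len(trials)
    assert report.n_rejected == 0
    assert report.n_interpolated == 0
    assert report.globally_bad_channels == ()
    assert report.per_condition["n_retained"].sum() == len(trials)


def test_qc_matches_artifact_log_exactly(layout128):
    cfg = ea.normative_config("infant", profile="validation", n_subjects=1)
    cfg = replace(
        cfg,
        subject_sd_uV=0.0,
        condition_sd_uV=0.0,
        latency_jitter_sd_ms=0.0,
        artifact_rates=ea.ArtifactRates(
            excursion_prob=0.08, reject_prob=0.05, bad_channel_prob=0.01
        ),
    )
    spec, trials = ea.make_design("infant", 1)
    rec, log = ea.simulate_recording(cfg, spec, trials, seed=12, layout=layout128)
    epochs, report = ea.run_preprocessing(rec)

    expected_rejected = {a["epoch"] for a in log.artifacts if a["expected"] == "rejected"}
    expected_interp = [
        (a["epoch"], ch)
        for a in log.artifacts
        if a["expected"] == "interpolated"
        for ch in a["channels"]
    ]
    assert report.globally_bad_channels == tuple(log.globally_bad_channels)
    assert set(np.flatnonzero(epochs.rejected)) == expected_rejected
    for ep, label in expected_interp:
        if ep not in expected_rejected:
            assert epochs.interpolated_mask[ep, layout128.index(label)]
    # conservation: every segmented epoch is either retained or rejected
    assert report.n_retained + report.n_rejected == report.n_segmented
    assert report.n_rejected == len(expected_rejected)
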