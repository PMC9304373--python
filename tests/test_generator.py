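from dataclasses import replace

import numpy as np
import pytest

import erpadapt as ea
from erpadapt.generator import PROFILES, calibrate_amplitudes, make_topography, pink_noise


# --------------------------------------------------------------------------
# normative configuration


def test_normative_amplitudes_and_latencies():
    infant = ea.normative_config("infant").conditions
    assert infant["FF"].n_amplitude_uV == -8.42
    assert infant["FF"].n_latency_ms == 278.2
    assert infant["CC"].n_amplitude_uV == -9.31
    adult = ea.normative_config("adult").conditions
    assert adult["FF"].n_amplitude_uV == -0.11
    assert adult["CC"].n_amplitude_uV == 1.31
    assert adult["FF"].n_latency_ms == 170.7


def test_p1_amplitudes_consistent_with_peak_to_peak():
    """P1 defaults equal N minus the normative peak-to-peak value."""
    infant = ea.normative_config("infant").conditions
    p2p = {"FF": -10.02, "CC": -11.79, "FC": -11.47, "CF": -11.06}
    for c, v in p2p.items():
        assert infant[c].p1_amplitude_uV == pytest.approx(
            infant[c].n_amplitude_uV - v, abs=1e-9
        )
    adult = ea.normative_config("adult").conditions
    p2p = {"FF": -4.08, "CC": -2.96, "FC": -4.58, "CF": -3.26}
    for c, v in p2p.items():
        assert adult[c].p1_amplitude_uV == pytest.approx(
            adult[c].n_amplitude_uV - v, abs=1e-9
        )


def test_profiles_and_validation():
    for profile in PROFILES:
        cfg = ea.normative_config("infant", profile=profile)
        assert cfg.profile == profile
    with pytest.raises(ValueError):
        ea.normative_config("infant", profile="nope")
    with pytest.raises(ValueError):
        ea.normative_config("toddler")
    real = ea.normative_config("infant", profile="realistic")
    val = ea.normative_config("infant", profile="validation")
    assert val.pink_rms_uV < real.pink_rms_uV
    assert val.artifact_rates.excursion_prob == 0.0


# --------------------------------------------------------------------------
# simulation structure


def test_events_match_design(noiseless_recording, infant_design_1it):
    rec, _ = noiseless_recording
    _, trials = infant_design_1it
    assert len(rec.events) == len(trials)
    assert (np.diff(rec.events["sample"]) == 250).all()  # 1000 ms onset-to-onset
    assert list(rec.events["category"]) == list(trials["category"])


def test_simulation_deterministic(infant_design_1it):
    spec, trials = infant_design_1it
    cfg = ea.normative_config("infant", profile="validation", n_subjects=1)
    a, _ = ea.simulate_recording(cfg, spec, trials, seed=7)
    b, _ = ea.simulate_recording(cfg, spec, trials, seed=7)
    c, _ = ea.simulate_recording(cfg, spec, trials, seed=8)
    assert np.array_equal(a.data, b.data)
    assert not np.array_equal(a.data, c.data)


def test_group_mismatch_rejected(noiseless_config):
    spec, trials = ea.make_design("adult", 1)
    with pytest.raises(ValueError):
        ea.simulate_recording(noiseless_config, spec, trials, seed=0)


# --------------------------------------------------------------------------
# zero-noise recovery through the full pipeline


@pytest.mark.parametrize("group", ["infant", "adult"])
def test_noiseless_end_to_end_recovery(group):
    cfg = ea.normative_config(group, profile="validation", n_subjects=1)
    cfg = replace(
        cfg,
        pink_rms_uV=0.0,
        line_noise_uV=0.0,
        subject_sd_uV=0.0,
        condition_sd_uV=0.0,
        latency_jitter_sd_ms=0.0,
    )
    spec, trials = ea.make_design(group, 1)
    rec, log = ea.simulate_recording(cfg, spec, trials, seed=3)
    epochs, _ = ea.run_preprocessing(rec)
    epochs = ea.assign_conditions(epochs)
    table = ea.measure_subject(epochs, group, subject="0")
    collapsed = (
        table.groupby(["condition", "component"])[["amplitude", "latency"]]
        .mean()
        .reset_index()
    )
    assert len(collapsed)  # at least the uniform conditions survive min-epoch rules
    for row in collapsed.itertuples(index=False):
        p = cfg.conditions[row.condition]
        target = p.n_amplitude_uV if row.component == "N" else p.p1_amplitude_uV
        assert row.amplitude == pytest.approx(target, abs=0.05), (
            row.condition,
            row.component,
        )
        # negative-going troughs land within one 4-ms sample of nominal latency
        if row.component == "N" and p.n_amplitude_uV < 0:
            assert abs(row.latency - p.n_latency_ms) <= 4.0


def test_calibration_handles_positive_n_targets():
    """Conditions whose window minimum is positive must stay finite and modest."""
    cfg = ea.normative_config("adult")
    a_p1, a_n = calibrate_amplitudes(cfg.conditions["CC"], group="adult")
    assert abs(a_p1) < 50 and abs(a_n) < 50


# --------------------------------------------------------------------------
# topography and noise primitives


def test_topography_zero_mean_and_roi_normalized(layout128):
    topo = make_topography(layout128)
    assert abs(topo.mean()) < 1e-12
    idx = np.concatenate([layout128.roi_indices(r) for r in ("left", "midline", "right")])
    assert topo[idx].mean() == pytest.approx(1.0, abs=1e-12)
    # evoked weight peaks over the occipital patch
    assert topo[idx].min() > np.median(topo)


def test_pink_noise_rms_and_spectrum():
    rng = np.random.default_rng(0)
    x = pink_noise(rng, 4, 50000, 250.0, 5.0, 0.1)
    rms = np.sqrt((x**2).mean(axis=1))
    assert np.allclose(rms, 5.0, rtol=0.05)
    f = np.fft.rfftfreq(50000, 1 / 250.0)
    p = np.abs(np.fft.rfft(x[0])) ** 2
    low = p[(f > 0.5) & (f < 2)].mean()
    high = p[(f > 50) & (f < 100)].mean()
    assert low > 10 * high  # 1/f: low frequencies dominate


def test_pink_noise_zero_rms_is_silent():
    rng = np.random.default_rng(0)
    assert not pink_noise(rng, 2, 1000, 250.0, 0.0, 0.1).any()


# --------------------------------------------------------------------------
# artifact injection


def _tiny_recording(layout128):
    cfg = ea.normative_config("infant", profile="validation", n_subjects=1)
    cfg = replace(
        cfg,
        pink_rms_uV=0.0,
        subject_sd_uV=0.0,
        condition_sd_uV=0.0,
        latency_jitter_sd_ms=0.0,
    )
    spec, trials = ea.make_design("infant", 1)
    return ea.simulate_recording(cfg, spec, trials, seed=1, layout=layout128)


def test_zero_rates_leave_recording_unchanged(layout128):
    rec, log = _tiny_recording(layout128)
    out, log2 = ea.inject_artifacts(rec, ea.ArtifactRates(), seed=0)
    assert np.array_equal(out.data, rec.data)
    assert log2.artifacts == []


def test_excursions_logged_with_expected_outcomes(layout128):
    rec, log = _tiny_recording(layout128)
    out, log2 = ea.inject_artifacts(
        rec, ea.ArtifactRates(excursion_prob=0.2, reject_prob=0.1), seed=0, log=log
    )
    kinds = {a["kind"] for a in log2.artifacts}
    assert {"excursion", "multi_excursion"} <= kinds
    for a in log2.artifacts:
        if a["kind"] == "excursion":
            assert a["expected"] == "interpolated"
            assert len(a["channels"]) == 1
        elif a["kind"] == "multi_excursion":
            assert a["expected"] == "rejected"
            assert len(a["channels"]) == 13
    # injected excursions exceed the marking limit in the raw data
    a = next(x for x in log2.artifacts if x["kind"] == "excursion")
    s = out.events["sample"].iloc[a["epoch"]]
    ch = out.layout.index(a["channels"][0])
    assert np.abs(out.data[ch, s : s + 125]).max() > 150.0


def test_bad_channels_annotated_by_impedance(layout128):
    rec, _ = _tiny_recording(layout128)
    out, log2 = ea.inject_artifacts(rec, ea.ArtifactRates(bad_channel_prob=0.05), seed=2)
    assert log2.globally_bad_channels
    for label in log2.globally_bad_channels:
        assert out.impedances[out.layout.index(label)] > 200.0


def test_bad_rates_rejected():
    with pytest.raises(ValueError):
        ea.ArtifactRates(excursion_prob=1.5)
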