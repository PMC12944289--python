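"""Feature pipeline: windowing, baseline correction, DE, scaling, labels."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal as sps

from eegfuse.features import (CLASS_NAMES, DEFAULT_BANDS, Band, EEGTrial,
                              FeaturePair, apply_scaler, baseline_correct_de,
                              baseline_correct_time, compute_de, derive_label,
                              extract_features, fit_scaler, segment_windows)


def make_trial(duration_s=60.0, fs=128.0, n_channels=3, baseline_s=3.0,
               valence=7.0, arousal=7.0, seed=0):
    rng = np.random.default_rng(seed)
    return EEGTrial(
        subject_id="s01",
        trial_id="t00",
        signal=rng.standard_normal((n_channels, int(round(duration_s * fs)))),
        baseline=rng.standard_normal((n_channels, int(round(baseline_s * fs)))),
        fs=fs,
        channel_names=[f"ch{i}" for i in range(n_channels)],
        valence=valence,
        arousal=arousal,
    )


# ----------------------------------------------------------------- windowing
def test_segment_windows_deap_shape():
    trial = make_trial(duration_s=60.0, fs=128.0)
    wins = segment_windows(trial, 3.0)
    assert len(wins) == 20
    assert all(w.shape == (3, 384) for w in wins)
    # contiguous, in order, baseline never present
    np.testing.assert_array_equal(wins[1], trial.signal[:, 384:768])


def test_segment_windows_drops_partial_tail():
    trial = make_trial(duration_s=7.0, fs=10.0)
    wins = segment_windows(trial, 3.0)
    assert len(wins) == 2  # last 1 s discarded


@settings(max_examples=50, deadline=None)
@given(
    n_samples=st.integers(min_value=4, max_value=5000),
    fs=st.sampled_from([10.0, 100.0, 128.0, 250.0]),
    window_s=st.sampled_from([0.5, 1.0, 3.0]),
)
def test_window_count_floor_rule(n_samples, fs, window_s):
    w = int(round(window_s * fs))
    trial = EEGTrial(
        "s", "t", np.zeros((2, n_samples)), np.zeros((2, 4)), fs,
        ["a", "b"], 5.0, 5.0,
    )
    if n_samples < w:
        with pytest.raises(ValueError, match="t"):
            segment_windows(trial, window_s)
    else:
        wins = segment_windows(trial, window_s)
        assert len(wins) == n_samples // w
        assert all(x.shape == (2, w) for x in wins)


def test_segment_error_names_trial():
    trial = make_trial(duration_s=1.0, fs=10.0)
    with pytest.raises(ValueError, match="t00"):
        segment_windows(trial, 3.0)


# ---------------------------------------------------------- baseline (time)
def test_baseline_correct_time():
    rng = np.random.default_rng(0)
    win = rng.standard_normal((3, 40))
    # zero baseline -> unchanged
    np.testing.assert_array_equal(
        baseline_correct_time(win, np.zeros((3, 10))), win
    )
    # constant per-channel baseline k -> every sample reduced by k
    k = np.array([[1.0], [2.0], [-3.0]])
    out = baseline_correct_time(win, np.tile(k, (1, 10)))
    np.testing.assert_allclose(out, win - k)
    # baseline = window's own medians -> output medians ~ 0
    med = np.median(win, axis=1, keepdims=True)
    out = baseline_correct_time(win, np.tile(med, (1, 7)))
    np.testing.assert_allclose(np.median(out, axis=1), 0.0, atol=1e-12)
    with pytest.raises(ValueError):
        baseline_correct_time(win, np.empty((3, 0)))


# ------------------------------------------------------------------------ DE
def test_de_closed_form_unit_variance():
    rng = np.random.default_rng(0)
    x = rng.standard_normal(512)
    x = (x - x.mean()) / x.std()  # exactly unit sample variance
    de = compute_de(x, DEFAULT_BANDS[0], fs=128.0, skip_filter=True)
    assert abs(de - 0.5 * np.log(2 * np.pi * np.e)) < 1e-9


def test_de_scale_law():
    rng = np.random.default_rng(1)
    x = rng.standard_normal(384)
    for a in (2.0, 0.5, 7.3):
        d1 = compute_de(x, DEFAULT_BANDS[0], 128.0, skip_filter=True)
        d2 = compute_de(a * x, DEFAULT_BANDS[0], 128.0, skip_filter=True)
        assert abs((d2 - d1) - np.log(a)) < 1e-6


def test_de_sinusoid_band_localization():
    fs = 128.0
    t = np.arange(int(3 * fs)) / fs
    x = np.sin(2 * np.pi * 10.0 * t)  # alpha-band carrier
    de_alpha = compute_de(x, Band("alpha", 8, 14), fs)
    de_gamma = compute_de(x, Band("gamma", 30, 45), fs)
    assert de_alpha > de_gamma + 3.0


def test_de_welch_oracle_on_filtered_noise():
    """Filter-variance DE agrees with a Welch-PSD Gaussian-entropy oracle."""
    fs, n = 128.0, 3840
    rng = np.random.default_rng(2)
    x = rng.standard_normal(n)
    for band in DEFAULT_BANDS:
        de = compute_de(x, band, fs)
        sos = sps.butter(4, [band.low, band.high], btype="bandpass",
                         fs=fs, output="sos")
        filt = sps.sosfiltfilt(sos, x)
        f, psd = sps.welch(filt, fs=fs, nperseg=512)
        var_welch = np.trapezoid(psd, f)
        oracle = 0.5 * np.log(2 * np.pi * np.e * var_welch)
        assert abs(de - oracle) < 0.1


def test_de_nyquist_and_variance_floor():
    with pytest.raises(ValueError, match="Nyquist"):
        compute_de(np.zeros(100), Band("gamma", 30, 45), fs=60.0)
    with pytest.warns(RuntimeWarning):
        de = compute_de(np.zeros(100), DEFAULT_BANDS[0], 128.0, skip_filter=True)
    assert np.isfinite(de)


# --------------------------------------------------------------- baseline DE
def test_baseline_correct_de():
    de = np.ones((4, 3, 5)) * 2.0
    # baseline identical to every window -> zeros
    np.testing.assert_array_equal(baseline_correct_de(de, de[:1]), 0.0)
    # single baseline window: mean equals that window
    bl = np.full((1, 3, 5), 0.5)
    np.testing.assert_allclose(baseline_correct_de(de, bl), 1.5)
    # two baseline windows 1.0 and 3.0 -> subtract 2.0
    bl2 = np.stack([np.full((3, 5), 1.0), np.full((3, 5), 3.0)])
    np.testing.assert_allclose(baseline_correct_de(de, bl2), 0.0)
    with pytest.raises(ValueError):
        baseline_correct_de(de, np.empty((0, 3, 5)))


# ------------------------------------------------------------------- labels
@pytest.mark.parametrize(
    "v,a,expected",
    [(7, 7, "HVHA"), (5, 5, "HVHA"), (4.9, 5.0, "LVHA"),
     (1, 1, "LVLA"), (9, 4.99, "HVLA"), (5.0, 4.99, "HVLA")],
)
def test_derive_label_quadrants(v, a, expected):
    assert CLASS_NAMES[derive_label(v, a)] == expected


def test_derive_label_total_and_four_classes():
    grid = np.linspace(1, 9, 17)
    seen = {derive_label(v, a) for v in grid for a in grid}
    assert seen == {0, 1, 2, 3}
    for bad in (0.5, 9.6):
        with pytest.raises(ValueError):
            derive_label(bad, 5)
        with pytest.raises(ValueError):
            derive_label(5, bad)


# ------------------------------------------------------------------- scaler
def test_scaler_train_stats_standardize_train():
    rng = np.random.default_rng(3)
    feats = FeaturePair(
        de=rng.standard_normal((50, 3, 5)) * 4 + 2,
        time=rng.standard_normal((50, 3, 16)) * 3 - 1,
        labels=np.zeros(50, dtype=int),
    )
    out = apply_scaler(feats, fit_scaler(feats))
    np.testing.assert_allclose(out.de.mean(axis=0), 0.0, atol=1e-9)
    np.testing.assert_allclose(out.de.std(axis=0), 1.0, atol=1e-6)
    np.testing.assert_allclose(out.time.mean(axis=(0, 2)), 0.0, atol=1e-9)
    np.testing.assert_allclose(out.time.std(axis=(0, 2)), 1.0, atol=1e-6)


def test_scaler_single_window_de_zeroed():
    rng = np.random.default_rng(4)
    one = FeaturePair(
        de=rng.standard_normal((1, 3, 5)),
        time=rng.standard_normal((1, 3, 16)),
        labels=np.zeros(1, dtype=int),
    )
    with pytest.warns(RuntimeWarning):
        stats = fit_scaler(one)
    out = apply_scaler(one, stats)
    np.testing.assert_array_equal(out.de, 0.0)


def test_scaler_applies_train_stats_to_test():
    rng = np.random.default_rng(5)
    train = FeaturePair(
        de=rng.standard_normal((40, 2, 5)),
        time=rng.standard_normal((40, 2, 8)),
        labels=np.zeros(40, dtype=int),
    )
    test = FeaturePair(
        de=rng.standard_normal((40, 2, 5)) + 10.0,
        time=rng.standard_normal((40, 2, 8)) + 10.0,
        labels=np.zeros(40, dtype=int),
    )
    out = apply_scaler(test, fit_scaler(train))
    # transformed with training stats, not its own -> mean far from 0
    assert np.all(out.de.mean(axis=0) > 5.0)


# ----------------------------------------------------------- full extraction
def test_extract_features_shapes_and_labels():
    trials = [make_trial(seed=i, valence=v, arousal=a)
              for i, (v, a) in enumerate([(7, 7), (3, 7), (3, 3), (7, 3)])]
    feats = extract_features(trials, window_s=3.0, time_downsample=8)
    assert feats.de.shape == (80, 3, 5)
    assert feats.time.shape == (80, 3, 48)
    np.testing.assert_array_equal(np.unique(feats.labels), [0, 1, 2, 3])
    # each trial contributes 20 identically-labeled windows
    np.testing.assert_array_equal(feats.labels[:20], 0)


def test_extract_features_baseline_correction_applied():
    trial = make_trial(duration_s=6.0, baseline_s=3.0)
    trial.baseline += 5.0  # shift baseline median
    feats = extract_features([trial], window_s=3.0)
    raw = segment_windows(trial, 3.0)[0]
    np.testing.assert_allclose(
        feats.time[0],
        raw - np.median(trial.baseline, axis=1, keepdims=True),
    )
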