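"""Detection, conditioning, ensemble normalization, windowing, file I/O."""

import logging

import numpy as np
import pandas as pd
import pytest

from pdcnet import preprocess as pre


# ---------------------------------------------------------------------------
# event detection / segmentation
# ---------------------------------------------------------------------------

def test_detect_events_recovers_schedule(sim_recording, detected_times):
    _, events = sim_recording
    onsets = events["onset_s"].to_numpy()
    assert detected_times.size == onsets.size
    # threshold crossing happens within a few ms of the planted onset
    np.testing.assert_allclose(detected_times, onsets, atol=0.05)


def test_detect_events_rejects_bad_threshold(sim_recording):
    rec, _ = sim_recording
    with pytest.raises(ValueError):
        pre.detect_events(rec, 0, k_sd=0.0)


def test_detect_events_zero_variance_background():
    chans = pd.DataFrame(
        {"id": [0, 1], "row": [0, 0], "col": [0, 1],
         "layer": ["other", "other"], "active": [True, True]}
    )
    rec = pre.Recording(
        signals=np.zeros((2, 4000)), sampling_rate=1000.0, channels=chans
    )
    with pytest.raises(ValueError):
        pre.detect_events(rec, 0, background=(0.0, 2.0))


def test_extract_segments_alignment_and_bounds(sim_recording, detected_times, caplog):
    rec, _ = sim_recording
    fs = rec.sampling_rate
    with caplog.at_level(logging.WARNING, logger="pdcnet.preprocess"):
        ens = pre.extract_segments(
            rec, np.concatenate([detected_times, [1e6]]), pre_ms=300, post_ms=500
        )
    assert ens.n_realizations == detected_times.size  # out-of-range one skipped
    assert ens.n_samples == int(0.8 * fs)
    assert any("skipped" in r.message for r in caplog.records)
    # detection point sits at the pre_ms sample of every segment
    c = int(round(detected_times[0] * fs))
    np.testing.assert_array_equal(
        ens.data[0], rec.signals[:, c - int(0.3 * fs) : c + int(0.5 * fs)]
    )


# ---------------------------------------------------------------------------
# conditioning
# ---------------------------------------------------------------------------

def test_notch_attenuates_50hz(rng):
    fs = 2000.0
    t = np.arange(4000) / fs
    seg = np.vstack(
        [np.sin(2 * np.pi * 50 * t) + 0.1 * rng.normal(size=t.size) for _ in range(2)]
    )
    out = pre.condition_segment(seg, fs)
    f = np.fft.rfftfreq(t.size, 1 / fs)
    i50 = np.argmin(np.abs(f - 50.0))
    for ch in range(2):
        after = np.abs(np.fft.rfft(out[ch]))
        noise_floor = np.median(after[(f > 60) & (f < 100)])
        assert after[i50] < 0.1 * noise_floor  # >= 20 dB below the floor


def test_condition_zscores(rng):
    seg = rng.normal(loc=3.0, scale=7.0, size=(3, 2000))
    out = pre.condition_segment(seg, 2000.0)
    np.testing.assert_allclose(out.mean(axis=1), 0.0, atol=1e-12)
    np.testing.assert_allclose(out.std(axis=1), 1.0, atol=1e-9)


def test_condition_idempotent(rng):
    seg = rng.normal(size=(4, 2000))
    once = pre.condition_segment(seg, 2000.0)
    twice = pre.condition_segment(once, 2000.0)
    rms = np.sqrt(np.mean((once - twice) ** 2))
    assert rms < 1e-6


def test_condition_iir_mode_available(rng):
    seg = rng.normal(size=(2, 2000))
    out = pre.condition_segment(seg, 2000.0, method="iir")
    assert out.shape == seg.shape
    np.testing.assert_allclose(out.std(axis=1), 1.0, atol=1e-9)


def test_ensemble_normalize_moments(short_ensemble):
    norm = pre.ensemble_normalize(short_ensemble)
    np.testing.assert_allclose(norm.data.mean(axis=0), 0.0, atol=1e-10)
    np.testing.assert_allclose(norm.data.std(axis=0), 1.0, atol=1e-9)


def test_ensemble_normalize_requires_variance():
    data = np.ones((3, 2, 100))
    ens = pre.EventEnsemble(data=data, alignment=0.0, sampling_rate=1000.0)
    with pytest.raises(ValueError, match="zero ensemble SD"):
        pre.ensemble_normalize(ens)


# ---------------------------------------------------------------------------
# windowing
# ---------------------------------------------------------------------------

def test_windowing_bookkeeping_800ms():
    grid = pre.make_windows(800.0)
    assert grid.n_windows == 76
    assert grid.windows[0] == (0.0, 50.0)
    assert grid.windows[-1] == (750.0, 800.0)


def test_stage_assignment_containment():
    grid = pre.assign_stages(pre.make_windows(800.0))
    stages = np.array(grid.stages)
    # early stage 0-240 ms fully contains windows #1-#20 (1-based)
    assert list(np.flatnonzero(stages == "early")) == list(range(0, 20))
    middle = np.flatnonzero(stages == "middle")
    assert grid.windows[middle[0]][0] >= 280.0
    assert grid.windows[middle[-1]][1] <= 520.0
    late = np.flatnonzero(stages == "late")
    assert grid.windows[late[-1]][1] <= 800.0
    # straddling windows belong to no stage
    assert (stages == "none").sum() > 0


def test_stage_overlap_rejected():
    grid = pre.make_windows(800.0)
    with pytest.raises(ValueError):
        pre.assign_stages(grid, {"a": (0.0, 300.0), "b": (200.0, 500.0)})


def test_window_slice_roundtrip():
    grid = pre.make_windows(800.0)
    sl = pre.window_slice(grid, 0, 2000.0)
    assert (sl.start, sl.stop) == (0, 100)
    sl = pre.window_slice(grid, 75, 2000.0)
    assert (sl.start, sl.stop) == (1500, 1600)


def test_make_windows_validation():
    with pytest.raises(ValueError):
        pre.make_windows(40.0, 50.0, 10.0)
    with pytest.raises(ValueError):
        pre.make_windows(800.0, 0.0, 10.0)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def test_recording_roundtrip(tmp_path, sim_recording):
    rec, _ = sim_recording
    path = tmp_path / "rec.h5"
    pre.write_recording(path, rec)
    back = pre.read_recording(path)
    np.testing.assert_array_equal(back.signals, rec.signals)
    assert back.sampling_rate == rec.sampling_rate
    assert list(back.channels["layer"]) == list(rec.channels["layer"])


def test_ensemble_roundtrip(tmp_path, short_ensemble):
    path = tmp_path / "ens.h5"
    pre.write_ensemble(path, short_ensemble)
    back = pre.read_ensemble(path)
    np.testing.assert_array_equal(back.data, short_ensemble.data)
    assert back.sampling_rate == short_ensemble.sampling_rate
    assert back.alignment == short_ensemble.alignment
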