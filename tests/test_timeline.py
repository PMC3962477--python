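"""Smoothers, onset/offset detection, lead/tail arithmetic."""

import numpy as np
import pytest

from pdcnet import preprocess as pre, timeline as tl


def test_moving_average_constant_and_edges():
    y = np.full(20, 3.5)
    np.testing.assert_allclose(tl.moving_average(y, 5), 3.5)
    y = np.arange(5.0)
    out = tl.moving_average(y, 3)
    assert out[0] == pytest.approx(0.5)   # truncated edge: mean of (0, 1)
    assert out[2] == pytest.approx(2.0)
    with pytest.raises(ValueError):
        tl.moving_average(y, 4)


def test_pspline_denoises_smooth_signal():
    rng = np.random.default_rng(0)
    t = np.linspace(0, 1, 400)
    clean = np.sin(2 * np.pi * 2 * t)
    noisy = clean + 0.3 * rng.normal(size=t.size)
    fit = tl.pspline_smooth(noisy)
    assert np.sqrt(np.mean((fit - clean) ** 2)) < 0.3 * np.sqrt(
        np.mean((noisy - clean) ** 2)
    )


def test_pspline_rejects_short_series():
    with pytest.raises(ValueError):
        tl.pspline_smooth(np.arange(5.0))


def test_step_series_detection():
    # step to 10 baseline SDs at window 200 of 696 (70 ms centers spacing);
    # the global-penalty spline spreads the edge, so the detected onset leads
    # the true edge by up to the smoothed shoulder width (~0.4 s here)
    rng = np.random.default_rng(1)
    times = 0.025 + 0.01 * np.arange(696)
    values = rng.normal(scale=0.5, size=696)
    values[200:400] += 10 * 0.5
    interval = tl.strength_onset_offset(
        times, values, baseline=(0.0, 1.0), min_duration_windows=10
    )
    assert interval is not None
    assert interval[0] == pytest.approx(times[200], abs=0.45)
    assert interval[0] <= times[205]  # never later than the edge itself
    assert interval[1] >= times[399] - 0.1  # covers the whole step


def test_flat_series_is_no_event():
    times = 0.025 + 0.01 * np.arange(300)
    values = 0.01 * np.sin(np.arange(300))  # max deviation < 4 baseline SDs
    smoother = lambda y: y  # noqa: E731
    assert tl.strength_onset_offset(times, values, smoother=smoother) is None


def test_min_duration_suppresses_isolated_spike():
    times = 0.025 + 0.01 * np.arange(300)
    values = np.zeros(300) + np.sin(np.arange(300)) * 0.01
    spike = values.copy()
    spike[150] += 5.0
    # identity smoother isolates the run-length rule itself
    smoother = lambda y: y  # noqa: E731
    hit = tl.strength_onset_offset(times, spike, smoother=smoother)
    assert hit is not None
    filtered = tl.strength_onset_offset(
        times, spike, smoother=smoother, min_duration_windows=3
    )
    assert filtered is None


def test_zero_baseline_sd_errors():
    times = 0.025 + 0.01 * np.arange(300)
    values = np.concatenate([np.zeros(150), np.ones(150)])
    smoother = lambda y: y  # noqa: E731
    with pytest.raises(ValueError, match="zero baseline SD"):
        tl.strength_onset_offset(times, values, smoother=smoother)


def _box_ensemble(fs=1000.0, n_s=4.0, boxes=((0, 2.0, 2.5),)):
    """Noise ensemble with box transients: (channel, start_s, end_s)."""
    rng = np.random.default_rng(3)
    n = int(n_s * fs)
    data = 0.05 * rng.normal(size=(6, 3, n))
    t = np.arange(n) / fs
    for ch, a, b in boxes:
        data[:, ch, (t >= a) & (t < b)] += 2.0
    return pre.EventEnsemble(data=data, alignment=1.0, sampling_rate=fs)


def test_waveform_box_transient():
    ens = _box_ensemble()
    interval = tl.waveform_onset_offset(ens, baseline=(0.0, 1.0), min_duration_ms=5.0)
    assert interval is not None
    assert interval[0] == pytest.approx(2.0, abs=0.02)
    assert interval[1] == pytest.approx(2.5, abs=0.02)


def test_waveform_network_min_max_rule():
    ens = _box_ensemble(boxes=((0, 2.0, 2.4), (1, 2.1, 2.6)))
    interval = tl.waveform_onset_offset(ens, baseline=(0.0, 1.0), min_duration_ms=5.0)
    assert interval[0] == pytest.approx(2.0, abs=0.02)
    assert interval[1] == pytest.approx(2.6, abs=0.02)


def test_waveform_zero_signal_is_no_event():
    rng = np.random.default_rng(4)
    data = 0.05 * rng.normal(size=(5, 2, 2000))
    ens = pre.EventEnsemble(data=data, alignment=0.5, sampling_rate=1000.0)
    assert (
        tl.waveform_onset_offset(ens, baseline=(0.0, 1.0), min_duration_ms=5.0)
        is None
    )


def test_strength_series_matches_grid(short_ensemble):
    grid = pre.make_windows(800.0)
    assoc = np.abs(np.random.default_rng(5).normal(size=(76, 4, 4)))
    for W in assoc:
        np.fill_diagonal(W, 0.0)
    times, values = tl.strength_series(assoc, grid)
    assert times.shape == values.shape == (76,)
    assert times[0] == pytest.approx(0.025)
    assert values[0] == pytest.approx(2.0 * assoc[0].sum())
    with pytest.raises(ValueError):
        tl.strength_series(assoc[:10], grid)


def test_lead_tail_arithmetic():
    timing = tl.TimingResult(
        discharge_start=2.0, discharge_end=2.8, network_start=1.8, network_end=6.3
    )
    lead, tail = tl.lead_tail(timing)
    assert lead == pytest.approx(0.2)
    assert tail == pytest.approx(3.5)
    with pytest.raises(ValueError):
        tl.lead_tail(tl.TimingResult(discharge_start=2.0))
    assert not tl.TimingResult(discharge_start=2.0).complete


def test_timing_frame_columns():
    frame = tl.timing_to_frame(
        tl.TimingResult(2.0, 2.8, 1.8, 6.3)
    )
    assert frame.loc[0, "lead_s"] == pytest.approx(0.2)
    assert frame.loc[0, "tail_s"] == pytest.approx(3.5)


def test_plot_timeline_writes_png(tmp_path):
    ens = _box_ensemble()
    grid = pre.make_windows(4000.0)
    rng = np.random.default_rng(6)
    assoc = np.abs(rng.normal(size=(grid.n_windows, 3, 3)))
    for W in assoc:
        np.fill_diagonal(W, 0.0)
    times, values = tl.strength_series(assoc, grid)
    timing = tl.TimingResult(2.0, 2.5, 1.9, 3.0)
    path = tmp_path / "timeline.png"
    tl.plot_timeline(ens, times, values, timing, path=path)
    assert path.stat().st_size > 0
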