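"""Event detection, segment extraction and stationarity conditioning.

Multichannel extracellular recordings of recurrent epileptiform discharges are
nonstationary in two ways: the event-locked mean/variance modulation, and the
slowly drifting correlation structure.  Following the event-related-potential
strategy of Ding et al., the first is removed by pointwise ensemble
normalization across repeated discharges (each discharge treated as one
realization of a common stochastic process) and the second by analysing short,
heavily overlapping windows (50 ms window, 10 ms step) within which the process
is taken to be locally stationary.

Conventions
-----------
* Windows are half-open ``[start, end)`` intervals in milliseconds with
  0-based indexing internally; the traditional 1-based window numbering
  (#1..#76 for an 800 ms segment) appears only in reports.
* Discharge detection uses the absolute value of the reference signal
  (polarity-free threshold crossing).
* Ensemble statistics use the population (divide-by-n) convention by default.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import h5py
import numpy as np
import pandas as pd
from scipy import signal as sps

logger = logging.getLogger(__name__)

__all__ = [
    "Recording",
    "EventEnsemble",
    "WindowGrid",
    "DEFAULT_STAGES",
    "read_recording",
    "write_recording",
    "detect_events",
    "extract_segments",
    "condition_segment",
    "condition_ensemble",
    "ensemble_normalize",
    "make_windows",
    "assign_stages",
    "window_slice",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class Recording:
    """A multichannel recording: ``signals`` is channels x samples."""

    signals: np.ndarray
    sampling_rate: float
    channels: pd.DataFrame | None = None  # columns: id, row, col, layer, active

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        if self.signals.ndim != 2:
            raise ValueError("signals must be a 2-D channels x samples array")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.channels is None:
            n = self.signals.shape[0]
            self.channels = pd.DataFrame(
                {
                    "id": np.arange(n),
                    "row": -1,
                    "col": -1,
                    "layer": "other",
                    "active": True,
                }
            )
        if len(self.channels) != self.signals.shape[0]:
            raise ValueError("channel table length does not match signal rows")
        if int(self.channels["active"].sum()) < 2:
            raise ValueError("a recording needs at least 2 active channels")

    @property
    def n_channels(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate


@dataclass
class EventEnsemble:
    """Aligned event segments: ``data`` is realizations x channels x samples.

    ``alignment`` is the sample index of the detection point within each
    segment (300 ms at the segment's sampling rate for the default 300/500 ms
    extraction).
    """

    data: np.ndarray
    alignment: int
    sampling_rate: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be realizations x channels x samples")
        if not 0 <= self.alignment <= self.data.shape[2]:
            raise ValueError("alignment outside segment")

    @property
    def n_realizations(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]


DEFAULT_STAGES: dict[str, tuple[float, float]] = {
    "early": (0.0, 240.0),
    "middle": (280.0, 520.0),
    "late": (560.0, 800.0),
}


@dataclass(frozen=True)
class WindowGrid:
    """Sliding-window bookkeeping over a segment, in milliseconds."""

    window_ms: float
    step_ms: float
    windows: tuple[tuple[float, float], ...]
    stages: tuple[str, ...] | None = None

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    def centers_ms(self) -> np.ndarray:
        return np.array([(a + b) / 2.0 for a, b in self.windows])

    def stage_of(self, index: int) -> str:
        if self.stages is None:
            return "none"
        return self.stages[index]


# ---------------------------------------------------------------------------
# container I/O (HDF5)
# ---------------------------------------------------------------------------

def write_recording(path, rec: Recording) -> None:
    """Write a recording to an HDF5 container.

    Layout: ``/signals`` (channels x samples), ``/sampling_rate`` scalar and a
    ``/channel_table`` compound dataset (id, row, col, layer, active).
    """
    tab = rec.channels
    dtype = np.dtype(
        [("id", "i8"), ("row", "i8"), ("col", "i8"), ("layer", "S16"), ("active", "?")]
    )
    recs = np.zeros(len(tab), dtype=dtype)
    recs["id"] = tab["id"].to_numpy()
    recs["row"] = tab["row"].to_numpy()
    recs["col"] = tab["col"].to_numpy()
    recs["layer"] = [str(s).encode() for s in tab["layer"]]
    recs["active"] = tab["active"].to_numpy()
    with h5py.File(path, "w") as f:
        f.create_dataset("signals", data=rec.signals)
        f.create_dataset("sampling_rate", data=float(rec.sampling_rate))
        f.create_dataset("channel_table", data=recs)


def read_recording(path) -> Recording:
    with h5py.File(path, "r") as f:
        signals = f["signals"][...]
        fs = float(f["sampling_rate"][()])
        recs = f["channel_table"][...]
    tab = pd.DataFrame(
        {
            "id": recs["id"],
            "row": recs["row"],
            "col": recs["col"],
            "layer": [s.decode() for s in recs["layer"]],
            "active": recs["active"],
        }
    )
    return Recording(signals=signals, sampling_rate=fs, channels=tab)


def write_ensemble(path, ens: EventEnsemble, grid: WindowGrid | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("ensemble", data=ens.data)
        f.create_dataset("alignment", data=int(ens.alignment))
        f.create_dataset("sampling_rate", data=float(ens.sampling_rate))
        if grid is not None:
            f.create_dataset("windows", data=np.array(grid.windows))
            f.attrs["window_ms"] = grid.window_ms
            f.attrs["step_ms"] = grid.step_ms


def read_ensemble(path) -> EventEnsemble:
    with h5py.File(path, "r") as f:
        return EventEnsemble(
            data=f["ensemble"][...],
            alignment=int(f["alignment"][()]),
            sampling_rate=float(f["sampling_rate"][()]),
        )


# ---------------------------------------------------------------------------
# event detection and segment extraction
# ---------------------------------------------------------------------------

def detect_events(
    rec: Recording,
    ref_channel: int,
    k_sd: float = 10.0,
    background: tuple[float, float] = (0.0, 10.0),
    refractory_ms: float = 800.0,
) -> np.ndarray:
    """Detect discharge events by amplitude threshold on one reference channel.

    The threshold is ``k_sd`` times the standard deviation of the background
    signal (a designated quiet interval, default the first 10 s).  A crossing
    of ``|x| > threshold`` marks an event; a refractory lockout of one segment
    length (``refractory_ms``) ensures each event is detected exactly once.

    Returns event times in seconds.
    """
    if k_sd <= 0:
        raise ValueError("k_sd must be positive (degenerate threshold)")
    if not bool(rec.channels["active"].iloc[ref_channel]):
        raise ValueError(f"reference channel {ref_channel} is not active")
    fs = rec.sampling_rate
    b0, b1 = (int(round(t * fs)) for t in background)
    if not 0 <= b0 < b1 <= rec.n_samples:
        raise ValueError("background interval outside recording")
    x = rec.signals[ref_channel]
    bg_sd = float(np.std(x[b0:b1]))
    if bg_sd == 0.0:
        raise ValueError("zero-variance background: cannot set threshold")
    thr = k_sd * bg_sd
    lockout = int(round(refractory_ms * fs / 1000.0))
    above = np.flatnonzero(np.abs(x) > thr)
    times: list[int] = []
    next_ok = 0
    for i in above:
        if i >= next_ok:
            times.append(i)
            next_ok = i + lockout
    times_s = np.array(times, dtype=float) / fs
    if times_s.size and times_s[0] < background[1]:
        warnings.warn(
            "background interval overlaps detected events; "
            "threshold may be inflated",
            stacklevel=2,
        )
    return times_s


def extract_segments(
    rec: Recording,
    times_s: np.ndarray,
    pre_ms: float = 300.0,
    post_ms: float = 500.0,
) -> EventEnsemble:
    """Cut aligned segments around detection times.

    Each segment spans ``[t - pre_ms, t + post_ms)``; the detection point sits
    at sample ``pre_ms`` of every segment.  Events whose segment would fall
    outside the recording are skipped with a log entry.
    """
    fs = rec.sampling_rate
    pre = int(round(pre_ms * fs / 1000.0))
    post = int(round(post_ms * fs / 1000.0))
    segs = []
    for t in np.atleast_1d(np.asarray(times_s, dtype=float)):
        c = int(round(t * fs))
        if c - pre < 0 or c + post > rec.n_samples:
            logger.warning("event at %.3f s outside recording bounds; skipped", t)
            continue
        segs.append(rec.signals[:, c - pre : c + post])
    if not segs:
        data = np.empty((0, rec.n_channels, pre + post))
    else:
        data = np.stack(segs, axis=0)
    return EventEnsemble(data=data, alignment=pre, sampling_rate=fs)


# ---------------------------------------------------------------------------
# conditioning
# ---------------------------------------------------------------------------

def _fft_notch(seg: np.ndarray, fs: float, f0: float, bw_hz: float) -> np.ndarray:
    # zeroing the FFT bins within f0 +/- bw is zero-phase and exactly idempotent
    n = seg.shape[-1]
    spec = np.fft.rfft(seg, axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec[..., np.abs(freqs - f0) <= bw_hz] = 0.0
    return np.fft.irfft(spec, n=n, axis=-1)


def condition_segment(
    seg: np.ndarray,
    fs: float,
    notch_hz: float = 50.0,
    bw_hz: float = 1.0,
    method: str = "fft",
    q: float = 30.0,
) -> np.ndarray:
    """Notch out power-line interference, then standardize each channel.

    The default notch zeroes the FFT bins within ``notch_hz +/- bw_hz``
    (zero-phase and idempotent); ``method='iir'`` uses a second-order IIR notch
    (quality factor ``q``) applied forward-backward instead.  After filtering,
    each channel is centred to temporal mean 0 and scaled to SD 1 within the
    segment.  Channels with zero variance are flagged with a warning and left
    at zero (they carry no signal and are excluded downstream).
    """
    seg = np.asarray(seg, dtype=float)
    if seg.ndim == 1:
        return condition_segment(seg[None, :], fs, notch_hz, bw_hz, method, q)[0]
    if method == "fft":
        out = _fft_notch(seg, fs, notch_hz, bw_hz)
    elif method == "iir":
        b, a = sps.iirnotch(notch_hz, q, fs=fs)
        out = sps.filtfilt(b, a, seg, axis=-1)
    else:
        raise ValueError(f"unknown notch method {method!r}")
    mu = out.mean(axis=-1, keepdims=True)
    sd = out.std(axis=-1, keepdims=True)
    dead = sd[..., 0] == 0.0
    if np.any(dead):
        warnings.warn(
            f"{int(dead.sum())} zero-variance channel(s) flagged inactive, "
            "not normalized",
            stacklevel=2,
        )
        sd = np.where(sd == 0.0, 1.0, sd)
    return (out - mu) / sd


def condition_ensemble(ens: EventEnsemble, **kwargs) -> EventEnsemble:
    """Apply :func:`condition_segment` to every realization."""
    data = np.stack(
        [condition_segment(r, ens.sampling_rate, **kwargs) for r in ens.data]
    )
    return EventEnsemble(data=data, alignment=ens.alignment, sampling_rate=ens.sampling_rate)


def ensemble_normalize(ens: EventEnsemble, ddof: int = 0) -> EventEnsemble:
    """Pointwise ensemble normalization across realizations.

    At every (channel, time) point the mean over realizations is subtracted
    and the SD over realizations divided out, removing the event-locked
    first- and second-moment nonstationarity.  Population SD (``ddof=0``) by
    default.
    """
    if ens.n_realizations < 2:
        raise ValueError("ensemble normalization needs at least 2 realizations")
    mu = ens.data.mean(axis=0)
    sd = ens.data.std(axis=0, ddof=ddof)
    if np.any(sd == 0.0):
        ch, t = np.argwhere(sd == 0.0)[0]
        raise ValueError(
            f"zero ensemble SD at channel {ch}, sample {t}: cannot normalize"
        )
    return EventEnsemble(
        data=(ens.data - mu) / sd,
        alignment=ens.alignment,
        sampling_rate=ens.sampling_rate,
    )


# ---------------------------------------------------------------------------
# windowing
# ---------------------------------------------------------------------------

def make_windows(
    segment_ms: float, window_ms: float = 50.0, step_ms: float = 10.0
) -> WindowGrid:
    """Build the sliding-window grid ``[k*step, k*step + window)`` over a segment.

    The number of windows is ``floor((segment - window)/step) + 1``; an 800 ms
    segment with the default 50/10 ms windowing yields 76 windows.
    """
    if window_ms <= 0 or step_ms <= 0:
        raise ValueError("window_ms and step_ms must be positive")
    if segment_ms < window_ms:
        raise ValueError("segment shorter than one window")
    n = int(np.floor((segment_ms - window_ms) / step_ms + 1e-9)) + 1
    windows = tuple(
        (k * step_ms, k * step_ms + window_ms) for k in range(n)
    )
    return WindowGrid(window_ms=window_ms, step_ms=step_ms, windows=windows)


def assign_stages(
    grid: WindowGrid,
    intervals: dict[str, tuple[float, float]] | None = None,
) -> WindowGrid:
    """Label each window with the discharge stage that fully contains it.

    Defaults to the early/middle/late partition of an 800 ms discharge
    (0-240, 280-520 and 560-800 ms); windows falling in the gaps get stage
    ``"none"``.  Stage intervals must not overlap.
    """
    if intervals is None:
        intervals = DEFAULT_STAGES
    spans = sorted(intervals.items(), key=lambda kv: kv[1][0])
    for (_, (a0, a1)), (_, (b0, b1)) in zip(spans, spans[1:]):
        if b0 < a1:
            raise ValueError("stage intervals overlap")
    stages = []
    for start, end in grid.windows:
        label = "none"
        for name, (lo, hi) in intervals.items():
            if start >= lo and end <= hi:
                label = name
                break
        stages.append(label)
    return replace(grid, stages=tuple(stages))


def window_slice(grid: WindowGrid, index: int, fs: float) -> slice:
    """Sample slice of window ``index`` at sampling rate ``fs`` (Hz)."""
    start, end = grid.windows[index]
    return slice(int(round(start * fs / 1000.0)), int(round(end * fs / 1000.0)))
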