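"""Timing of network alteration relative to the visible discharges.

Long segments (7 s: 2 s pre / 5 s post the detection point) are analysed two
ways: (a) the per-channel ensemble-averaged waveform is smoothed and
thresholded at +/- 4 baseline SDs to find when the discharge itself starts and
ends across the network (earliest start, latest end over channels), and
(b) the network connection strength — computed per sliding window from the
association matrices — is smoothed and thresholded the same way to find when
the *connectivity* starts and stops deviating.  The lead (discharge start
minus network start) and tail (network end minus discharge end) quantify how
much earlier the network reorganizes and how much longer it takes to recover.

The strength series is smoothed with a penalized B-spline (P-spline: cubic
basis, second-difference coefficient penalty, smoothing parameter chosen by
generalized cross-validation); the smoother is pluggable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

from .graph import connection_strength
from .preprocess import EventEnsemble, WindowGrid

__all__ = [
    "TimingResult",
    "moving_average",
    "pspline_smooth",
    "waveform_onset_offset",
    "strength_series",
    "strength_onset_offset",
    "lead_tail",
    "plot_timeline",
]


@dataclass(frozen=True)
class TimingResult:
    """Onset/offset of the discharge and of the network alteration (seconds)."""

    discharge_start: float | None = None
    discharge_end: float | None = None
    network_start: float | None = None
    network_end: float | None = None

    @property
    def complete(self) -> bool:
        return None not in (
            self.discharge_start,
            self.discharge_end,
            self.network_start,
            self.network_end,
        )


# ---------------------------------------------------------------------------
# smoothers
# ---------------------------------------------------------------------------

def moving_average(y: np.ndarray, width: int = 3) -> np.ndarray:
    """Centered moving average with edge truncation (default 3 points)."""
    if width < 1 or width % 2 == 0:
        raise ValueError("width must be a positive odd integer")
    kernel = np.ones(width)
    num = np.convolve(y, kernel, mode="same")
    den = np.convolve(np.ones_like(y), kernel, mode="same")
    return num / den


def pspline_smooth(
    y: np.ndarray,
    n_basis: int | None = None,
    lambdas: np.ndarray | None = None,
) -> np.ndarray:
    """Penalized cubic B-spline smoother with GCV-selected penalty.

    Fits ``y`` on an equally spaced abscissa with a cubic B-spline basis of
    ``n_basis`` functions and a second-difference penalty on the coefficients
    (Eilers-Marx P-spline).  The penalty weight is picked from ``lambdas``
    (default a log grid from 1e-2 to 1e6) by minimizing the GCV score
    ``n * RSS / (n - tr(H))^2``.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 10:
        raise ValueError("series too short to smooth")
    if n_basis is None:
        n_basis = int(np.clip(n // 4, 10, 40))
    if lambdas is None:
        lambdas = 10.0 ** np.arange(-2.0, 6.5, 0.5)
    x = np.linspace(0.0, 1.0, n)
    degree = 3
    inner = np.linspace(0.0, 1.0, n_basis - degree + 1)
    knots = np.concatenate(([0.0] * degree, inner, [1.0] * degree))
    B = BSpline.design_matrix(x, knots, degree).toarray()
    D = np.diff(np.eye(B.shape[1]), n=2, axis=0)
    BtB = B.T @ B
    P = D.T @ D
    Bty = B.T @ y
    best = None
    for lam in lambdas:
        M = BtB + lam * P
        try:
            coef = np.linalg.solve(M, Bty)
            H_trace = float(np.trace(np.linalg.solve(M, BtB)))
        except np.linalg.LinAlgError:
            continue
        fit = B @ coef
        rss = float(np.sum((y - fit) ** 2))
        denom = (n - H_trace) ** 2
        if denom <= 0:
            continue
        gcv = n * rss / denom
        if best is None or gcv < best[0]:
            best = (gcv, fit)
    if best is None:
        raise np.linalg.LinAlgError("P-spline fit failed for all penalties")
    return best[1]


# ---------------------------------------------------------------------------
# onset/offset detection
# ---------------------------------------------------------------------------

def _threshold_interval(
    t: np.ndarray,
    y: np.ndarray,
    k_sd: float,
    baseline_mask: np.ndarray,
    min_samples: int = 1,
) -> tuple[float, float] | None:
    """First/last time |y - baseline mean| exceeds k_sd baseline SDs.

    With ``min_samples > 1`` an exceedance only counts when sustained for at
    least that many consecutive samples, which suppresses isolated noise
    excursions above the threshold.
    """
    base = y[baseline_mask]
    mu = float(base.mean())
    sd = float(base.std())
    if sd == 0.0:
        raise ValueError("zero baseline SD: threshold undefined")
    exceed = np.abs(y - mu) > k_sd * sd
    if min_samples > 1:
        padded = np.concatenate(([False], exceed, [False])).astype(int)
        d = np.diff(padded)
        starts = np.flatnonzero(d == 1)
        stops = np.flatnonzero(d == -1)
        keep = stops - starts >= min_samples
        if not np.any(keep):
            return None
        return float(t[starts[keep][0]]), float(t[stops[keep][-1] - 1])
    idx = np.flatnonzero(exceed)
    if idx.size == 0:
        return None
    return float(t[idx[0]]), float(t[idx[-1]])


def waveform_onset_offset(
    ens: EventEnsemble,
    k_sd: float = 4.0,
    baseline: tuple[float, float] = (0.0, 1.0),
    smooth_width: int = 3,
    min_duration_ms: float = 0.0,
) -> tuple[float, float] | None:
    """Network-level start/end of the discharge waveform.

    Per channel the ensemble mean over realizations (the event-locked
    averaged waveform — compute this on conditioned data, before ensemble
    normalization removes the mean) is smoothed with a centered moving
    average and thresholded at +/- ``k_sd`` times the SD of its baseline
    interval (seconds from segment start; must precede any event content).
    ``min_duration_ms`` optionally requires exceedances to be sustained,
    guarding the first/last-crossing rule against isolated noise excursions.
    Channels that never cross are excluded; the network interval is
    (earliest per-channel start, latest per-channel end).  Returns ``None``
    when no channel crosses.
    """
    fs = ens.sampling_rate
    avg = ens.data.mean(axis=0)  # channels x samples
    t = np.arange(avg.shape[1]) / fs
    mask = (t >= baseline[0]) & (t < baseline[1])
    if not np.any(mask):
        raise ValueError("empty baseline interval")
    min_samples = max(1, int(round(min_duration_ms * fs / 1000.0)))
    starts, ends = [], []
    for ch in range(avg.shape[0]):
        y = moving_average(avg[ch], smooth_width)
        if float(y[mask].std()) == 0.0:
            continue  # flat channel carries no event
        interval = _threshold_interval(t, y, k_sd, mask, min_samples)
        if interval is not None:
            starts.append(interval[0])
            ends.append(interval[1])
    if not starts:
        return None
    return min(starts), max(ends)


def strength_series(
    assoc: np.ndarray, grid: WindowGrid
) -> tuple[np.ndarray, np.ndarray]:
    """Connection strength per window, timestamped at the window center.

    ``assoc`` is the (n_windows, N, N) association-matrix stack produced by
    the connectivity stage on the long-segment window grid.
    """
    if assoc.shape[0] != grid.n_windows:
        raise ValueError("association stack does not match the window grid")
    times = grid.centers_ms() / 1000.0
    values = np.array([connection_strength(W) for W in assoc])
    return times, values


def strength_onset_offset(
    times: np.ndarray,
    values: np.ndarray,
    k_sd: float = 4.0,
    baseline: tuple[float, float] = (0.0, 1.0),
    smoother=pspline_smooth,
    min_duration_windows: int = 1,
) -> tuple[float, float] | None:
    """Start/end of the network-connectivity alteration.

    The strength series is smoothed (default P-spline), centred on its
    baseline mean and thresholded at +/- ``k_sd`` baseline SDs; returns the
    times of the first and last exceedance (optionally requiring
    ``min_duration_windows`` consecutive exceeding windows), or ``None`` for
    a series that never crosses.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if values.size < 10:
        raise ValueError("series too short")
    mask = (times >= baseline[0]) & (times < baseline[1])
    if not np.any(mask):
        raise ValueError("baseline window outside the series")
    y = smoother(values)
    return _threshold_interval(times, y, k_sd, mask, min_duration_windows)


def lead_tail(timing: TimingResult) -> tuple[float, float]:
    """Lead and tail of the network alteration relative to the discharge.

    ``lead = discharge_start - network_start`` (positive when the network
    changed first) and ``tail = network_end - discharge_end`` (positive when
    the network recovered later).
    """
    if not timing.complete:
        raise ValueError("missing onset/offset detection: lead/tail undefined")
    return (
        timing.discharge_start - timing.network_start,
        timing.network_end - timing.discharge_end,
    )


# ---------------------------------------------------------------------------
# plotting
# ---------------------------------------------------------------------------

def plot_timeline(
    ens: EventEnsemble,
    times: np.ndarray,
    values: np.ndarray,
    timing: TimingResult,
    channel: int = 0,
    k_sd: float = 4.0,
    baseline: tuple[float, float] = (0.0, 1.0),
    path=None,
):
    """Two-panel figure: averaged waveform and smoothed strength series with
    thresholds and the detected start/end marks."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fs = ens.sampling_rate
    avg = ens.data.mean(axis=0)[channel]
    t_w = np.arange(avg.size) / fs
    smooth_w = moving_average(avg, 3)
    y_s = pspline_smooth(values)

    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(8, 6), sharex=True)
    ax1.plot(t_w, avg, color="0.7", lw=0.5, label="ensemble mean")
    ax1.plot(t_w, smooth_w, color="crimson", lw=1.0, label="smoothed")
    bmask = (t_w >= baseline[0]) & (t_w < baseline[1])
    mu, sd = smooth_w[bmask].mean(), smooth_w[bmask].std()
    for s in (+1, -1):
        ax1.axhline(mu + s * k_sd * sd, ls="--", color="k", lw=0.7)
    for x in (timing.discharge_start, timing.discharge_end):
        if x is not None:
            ax1.axvline(x, color="k", lw=0.8)
    ax1.set_ylabel("waveform (z)")
    ax1.legend(loc="upper right", fontsize=8)

    ax2.plot(times, values, color="0.7", lw=0.7, label="strength")
    ax2.plot(times, y_s, color="crimson", lw=1.2, label="P-spline")
    bmask = (times >= baseline[0]) & (times < baseline[1])
    mu, sd = y_s[bmask].mean(), y_s[bmask].std()
    for s in (+1, -1):
        ax2.axhline(mu + s * k_sd * sd, ls="--", color="k", lw=0.7)
    for x in (timing.network_start, timing.network_end):
        if x is not None:
            ax2.axvline(x, color="crimson", lw=0.8)
    ax2.set_xlabel("time (s)")
    ax2.set_ylabel("connection strength")
    ax2.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def timing_to_frame(timing: TimingResult) -> pd.DataFrame:
    lead, tail = (None, None)
    if timing.complete:
        lead, tail = lead_tail(timing)
    return pd.DataFrame(
        [
            {
                "discharge_start_s": timing.discharge_start,
                "discharge_end_s": timing.discharge_end,
                "network_start_s": timing.network_start,
                "network_end_s": timing.network_end,
                "lead_s": lead,
                "tail_s": tail,
            }
        ]
    )
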