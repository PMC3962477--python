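"""Ground-truth-labeled synthetic MEA recordings.

Emulates the statistical structure the downstream causal-connectivity analysis
assumes: a 60-site corner-less 8x8 microelectrode grid (200 um pitch), tens of
repeated stereotyped discharge events (800 ms damped-oscillation field
transients with a high-frequency multi-unit burst) superimposed on Gaussian
background noise, and a known directed coupling network from "pyramidal-layer"
source nodes to "granule-layer" sink nodes at short lags.  The network coupling
gain ramps up shortly before each event and decays slowly after it, so the
network alteration genuinely leads and outlasts the visible discharge — the
timing structure the timeline analysis is meant to recover.

The default sampling rate is 2 kHz (configurable up to 20 kHz): a 50 ms
analysis window is then 100 samples and the full 1-300 Hz analysis band is
resolvable, while desk-scale simulations stay fast.

Every generator is deterministic given its seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .preprocess import Recording

__all__ = [
    "MEALayout",
    "Edge",
    "GroundTruthNetwork",
    "SimulationConfig",
    "make_mea_layout",
    "default_ground_truth",
    "simulate_mvar",
    "simulate_discharge_recording",
    "write_ground_truth",
]

PCL = "pcl"
GCL = "gcl"
OTHER = "other"


# ---------------------------------------------------------------------------
# layout
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MEALayout:
    """Electrode grid geometry with per-site layer labels and active flags."""

    positions: tuple[tuple[int, int], ...]
    pitch_um: float
    layers: tuple[str, ...]
    active: tuple[bool, ...]

    def __post_init__(self) -> None:
        if self.pitch_um <= 0:
            raise ValueError("pitch must be positive")
        if len(set(self.positions)) != len(self.positions):
            raise ValueError("duplicate electrode positions")
        if not (len(self.positions) == len(self.layers) == len(self.active)):
            raise ValueError("positions, layers and active flags must align")
        if any(l not in (PCL, GCL, OTHER) for l in self.layers):
            raise ValueError("layer labels must be 'pcl', 'gcl' or 'other'")

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    def layer_of(self, node: int) -> str:
        return self.layers[node]

    def nodes_in_layer(self, layer: str) -> np.ndarray:
        return np.flatnonzero([l == layer for l in self.layers])

    def to_frame(self) -> pd.DataFrame:
        rows, cols = zip(*self.positions)
        return pd.DataFrame(
            {
                "id": np.arange(self.n_sites),
                "row": rows,
                "col": cols,
                "layer": self.layers,
                "active": self.active,
            }
        )


def make_mea_layout(
    n_rows: int = 8,
    n_cols: int = 8,
    pitch_um: float = 200.0,
    pcl_rows: tuple[int, ...] = (1, 2),
    gcl_rows: tuple[int, ...] = (5, 6),
    drop_corners: bool = True,
) -> MEALayout:
    """The standard corner-less 8x8 grid: 60 sites at 200 um pitch.

    Anatomical layers are assigned by horizontal row bands: rows in
    ``pcl_rows`` are labelled as the pyramidal cell layer, rows in
    ``gcl_rows`` as the granule cell layer, everything else ``other``.
    The row bands must be disjoint.
    """
    if set(pcl_rows) & set(gcl_rows):
        raise ValueError("pcl and gcl row bands must be disjoint")
    corners = {(0, 0), (0, n_cols - 1), (n_rows - 1, 0), (n_rows - 1, n_cols - 1)}
    positions, layers = [], []
    for r in range(n_rows):
        for c in range(n_cols):
            if drop_corners and (r, c) in corners:
                continue
            positions.append((r, c))
            layers.append(PCL if r in pcl_rows else GCL if r in gcl_rows else OTHER)
    return MEALayout(
        positions=tuple(positions),
        pitch_um=pitch_um,
        layers=tuple(layers),
        active=tuple(True for _ in positions),
    )


# ---------------------------------------------------------------------------
# ground-truth directed network
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Edge:
    source: int
    target: int
    lag: int          # samples, >= 1
    gain: float


@dataclass(frozen=True)
class GroundTruthNetwork:
    """A sparse directed MVAR coupling structure with known edges."""

    n_nodes: int
    edges: tuple[Edge, ...]
    noise_scale: float = 1.0

    def __post_init__(self) -> None:
        for e in self.edges:
            if e.source == e.target:
                raise ValueError("self-edges are not allowed")
            if e.lag < 1:
                raise ValueError("edge lags must be >= 1 sample")
            if not (0 <= e.source < self.n_nodes and 0 <= e.target < self.n_nodes):
                raise ValueError("edge endpoint outside node range")
        if self.noise_scale <= 0:
            raise ValueError("noise_scale must be positive")

    @property
    def order(self) -> int:
        return max((e.lag for e in self.edges), default=1)

    def coefficient_matrices(self, order: int | None = None) -> np.ndarray:
        """Stack A of shape (p, N, N) with ``A[lag-1, target, source] = gain``."""
        p = self.order if order is None else int(order)
        if p < self.order:
            raise ValueError("order smaller than the maximum edge lag")
        A = np.zeros((p, self.n_nodes, self.n_nodes))
        for e in self.edges:
            A[e.lag - 1, e.target, e.source] += e.gain
        return A

    def spectral_radius(self) -> float:
        return companion_spectral_radius(self.coefficient_matrices())

    def is_stable(self) -> bool:
        return self.spectral_radius() < 1.0


def companion_spectral_radius(A: np.ndarray) -> float:
    """Spectral radius of the companion matrix of VAR coefficients (p, N, N)."""
    p, n, _ = A.shape
    comp = np.zeros((n * p, n * p))
    comp[:n, :] = np.concatenate(list(A), axis=1)
    if p > 1:
        comp[n:, : n * (p - 1)] = np.eye(n * (p - 1))
    return float(np.max(np.abs(np.linalg.eigvals(comp))))


def default_ground_truth(
    layout: MEALayout, gain: float = 0.35, noise_scale: float = 1.0
) -> GroundTruthNetwork:
    """Feed-forward pcl -> gcl coupling: each pyramidal-layer node drives the
    granule-layer nodes in its own and the adjacent column at lags 1-2.

    Being acyclic, the network is always stable regardless of gain.
    """
    pcl = layout.nodes_in_layer(PCL)
    gcl = layout.nodes_in_layer(GCL)
    col_of = {i: layout.positions[i][1] for i in range(layout.n_sites)}
    edges = []
    for s in pcl:
        for t in gcl:
            dc = abs(col_of[int(s)] - col_of[int(t)])
            if dc == 0:
                edges.append(Edge(int(s), int(t), lag=1, gain=gain))
            elif dc == 1:
                edges.append(Edge(int(s), int(t), lag=2, gain=gain / 2))
    return GroundTruthNetwork(
        n_nodes=layout.n_sites, edges=tuple(edges), noise_scale=noise_scale
    )


# ---------------------------------------------------------------------------
# MVAR process simulation
# ---------------------------------------------------------------------------

def simulate_mvar(
    net: GroundTruthNetwork,
    order: int | None = None,
    n_samples: int = 1000,
    n_realizations: int = 1,
    seed: int = 0,
    burn_in: int = 200,
) -> np.ndarray:
    """Draw realizations of the exact MVAR process defined by ``net``.

    ``x(t) = sum_r A(r) x(t-r) + e(t)`` with independent Gaussian innovations
    of SD ``net.noise_scale``.  Returns realizations x channels x samples.
    Deterministic given ``seed``.
    """
    A = net.coefficient_matrices(order)
    rho = companion_spectral_radius(A)
    if rho >= 1.0:
        raise ValueError(
            f"unstable ground-truth network: companion spectral radius {rho:.3f} >= 1"
        )
    p, n = A.shape[0], net.n_nodes
    rng = np.random.default_rng(seed)
    total = n_samples + burn_in
    out = np.empty((n_realizations, n, n_samples))
    for r in range(n_realizations):
        x = rng.normal(scale=net.noise_scale, size=(total, n))
        for t in range(p, total):
            acc = x[t]
            for lag in range(1, p + 1):
                acc += A[lag - 1] @ x[t - lag]
        out[r] = x[burn_in:].T
    return out


# ---------------------------------------------------------------------------
# discharge recording simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic recording.

    Defaults mirror the recorded preparation at desk scale: 50 stereotyped
    800 ms discharges, segments cut 2 s pre / 5 s post the detection point for
    the timing analysis, coupling leading the discharge by 0.2 s and decaying
    over 3.5 s after it, 2 kHz sampling.
    """

    sampling_rate: float = 2000.0
    n_events: int = 50
    event_length_ms: float = 800.0
    pre_window_ms: float = 2000.0
    post_window_ms: float = 5000.0
    seed: int = 0
    coupling_ramp_lead_ms: float = 200.0
    coupling_decay_tail_ms: float = 3500.0
    lead_in_ms: float = 12000.0      # quiet interval for background-SD estimation
    lfp_amplitude: float = 12.0      # transient peak, in units of background SD
    lfp_freq_hz: float = 8.0
    lfp_decay_ms: float = 250.0
    lfp_floor: float = 0.45          # sustained envelope fraction until event end
    lfp_other_scale: float = 0.6     # transient amplitude on non-layer sites
    mua_amplitude: float = 1.0       # high-frequency burst, units of background SD
    mua_lowcut_hz: float = 200.0
    coupling_floor: float = 0.4      # sustained gain fraction through the tail
    coupling_drop_frac: float = 0.06 # final fraction of the tail returning to 0

    def __post_init__(self) -> None:
        if self.sampling_rate < 600.0:
            raise ValueError(
                "sampling_rate must be at least twice the 300 Hz analysis-band top"
            )
        if self.n_events < 0:
            raise ValueError("n_events must be non-negative")
        period = self.pre_window_ms + self.event_length_ms + self.post_window_ms
        needed = (
            self.coupling_ramp_lead_ms
            + self.event_length_ms
            + self.coupling_decay_tail_ms
        )
        if self.n_events > 1 and period < needed:
            raise ValueError(
                "events scheduled closer than event length + coupling tail"
            )


def _event_schedule(cfg: SimulationConfig) -> np.ndarray:
    """Event onset times in ms: evenly spaced after the quiet lead-in."""
    period = cfg.pre_window_ms + cfg.event_length_ms + cfg.post_window_ms
    return cfg.lead_in_ms + cfg.pre_window_ms + period * np.arange(cfg.n_events)


def _coupling_gain(cfg: SimulationConfig, n_samples: int, onsets_ms: np.ndarray) -> np.ndarray:
    """Time course of the network coupling gain in [0, 1].

    Linear ramp over ``coupling_ramp_lead_ms`` before each onset; full gain
    during the event; a slow linear decline to ``coupling_floor`` over the
    tail, returning to zero in the final ``coupling_drop_frac`` of the tail.
    Keeping the gain clearly elevated throughout the tail and ending it in a
    brief terminal drop makes the planted alteration offset identifiable as a
    threshold crossing; a decay that fades linearly all the way to zero has
    no detectable endpoint under any threshold rule.
    """
    fs = cfg.sampling_rate
    g = np.zeros(n_samples)
    t_ms = np.arange(n_samples) / fs * 1000.0
    tail = cfg.coupling_decay_tail_ms
    drop = cfg.coupling_drop_frac
    floor = cfg.coupling_floor
    for on in onsets_ms:
        off = on + cfg.event_length_ms
        ramp = (t_ms - (on - cfg.coupling_ramp_lead_ms)) / cfg.coupling_ramp_lead_ms
        u = (t_ms - off) / tail  # fraction of the tail elapsed
        slow = 1.0 - (1.0 - floor) * u / (1.0 - drop)
        final = floor * (1.0 - u) / drop
        decay = np.where(u <= 1.0 - drop, slow, final)
        decay = np.clip(decay, 0.0, 1.0)
        prof = np.minimum(np.clip(ramp, 0.0, 1.0), decay)
        g = np.maximum(g, prof)
    return g


def _lfp_transient(cfg: SimulationConfig) -> np.ndarray:
    """Stereotyped field transient over one event.

    A sinusoid with an exponentially decaying envelope that settles on a
    sustained floor (``lfp_floor`` of the peak) until the event ends, so the
    discharge stays detectable for its whole planted duration.
    """
    fs = cfg.sampling_rate
    n = int(round(cfg.event_length_ms * fs / 1000.0))
    t = np.arange(n) / fs
    tau = cfg.lfp_decay_ms / 1000.0
    env = cfg.lfp_floor + (1.0 - cfg.lfp_floor) * np.exp(-t / tau)
    return cfg.lfp_amplitude * env * np.sin(2.0 * np.pi * cfg.lfp_freq_hz * t)


def simulate_discharge_recording(
    layout: MEALayout,
    net: GroundTruthNetwork,
    cfg: SimulationConfig,
) -> tuple[Recording, pd.DataFrame]:
    """Synthesize a continuous recording with ground-truth event times.

    The recording is Gaussian background noise driven through the network's
    time-varying coupling, ``x(t) = e(t) + d(t) + g(t) * sum_r A(r) x(t-r)``,
    where ``d(t)`` injects the stereotyped damped-oscillation transient into
    pyramidal-layer source nodes during each event (so granule-layer sinks
    receive it only through the lagged coupling and follow the sources), plus
    a band-limited (> ``mua_lowcut_hz``) burst standing in for multi-unit
    activity.  ``g(t)`` ramps up ``coupling_ramp_lead_ms`` before each onset
    and decays over ``coupling_decay_tail_ms`` after the offset.

    Returns the recording and a table of true (onset_s, offset_s) per event.
    """
    if layout.n_sites != net.n_nodes:
        raise ValueError("layout and network node counts disagree")
    fs = cfg.sampling_rate
    onsets_ms = _event_schedule(cfg)
    total_ms = cfg.lead_in_ms + (
        cfg.n_events * (cfg.pre_window_ms + cfg.event_length_ms + cfg.post_window_ms)
    )
    n_samples = int(round(total_ms * fs / 1000.0))
    n = net.n_nodes
    rng = np.random.default_rng(cfg.seed)

    A = net.coefficient_matrices()
    rho = companion_spectral_radius(A)
    if rho >= 1.0:
        raise ValueError(
            f"unstable ground-truth network: companion spectral radius {rho:.3f} >= 1"
        )
    p = A.shape[0]

    # innovations + injected drive, then the (gated) recursion in place
    x = rng.normal(scale=net.noise_scale, size=(n_samples, n))
    transient = _lfp_transient(cfg) * net.noise_scale
    pcl_nodes = layout.nodes_in_layer(PCL)
    other_nodes = layout.nodes_in_layer(OTHER)
    burst_nodes = np.concatenate([pcl_nodes, layout.nodes_in_layer(GCL)])
    ev_len = transient.size
    for on in onsets_ms:
        i0 = int(round(on * fs / 1000.0))
        i1 = min(i0 + ev_len, n_samples)
        for node in pcl_nodes:
            x[i0:i1, node] += transient[: i1 - i0]
        # field transients spread beyond the cell layers (volume conduction);
        # non-layer sites see a scaled copy, added outside the coupling
        for node in other_nodes:
            x[i0:i1, node] += cfg.lfp_other_scale * transient[: i1 - i0]
        if cfg.mua_amplitude > 0 and burst_nodes.size:
            noise = rng.normal(size=(i1 - i0 + 200, burst_nodes.size))
            sos = sps.butter(
                4, cfg.mua_lowcut_hz, btype="highpass", fs=fs, output="sos"
            )
            burst = sps.sosfilt(sos, noise, axis=0)[200:]
            env = np.exp(-np.arange(i1 - i0) / (cfg.lfp_decay_ms / 1000.0 * fs))
            x[i0:i1, burst_nodes] += (
                cfg.mua_amplitude * net.noise_scale * env[:, None] * burst
            )

    g = _coupling_gain(cfg, n_samples, onsets_ms)
    active_t = np.flatnonzero(g > 0.0)
    for t in active_t:
        if t < p:
            continue
        acc = x[t]
        gt = g[t]
        for lag in range(1, p + 1):
            acc += gt * (A[lag - 1] @ x[t - lag])

    rec = Recording(signals=x.T, sampling_rate=fs, channels=layout.to_frame())
    events = pd.DataFrame(
        {
            "onset_s": onsets_ms / 1000.0,
            "offset_s": (onsets_ms + cfg.event_length_ms) / 1000.0,
        }
    )
    return rec, events


def write_ground_truth(path, net: GroundTruthNetwork, events: pd.DataFrame, cfg: SimulationConfig) -> None:
    """JSON sidecar with the planted edges, true event times and the seed."""
    payload = {
        "n_nodes": net.n_nodes,
        "edges": [asdict(e) for e in net.edges],
        "noise_scale": net.noise_scale,
        "events": events.to_dict(orient="list"),
        "config": asdict(cfg),
    }
    with open(path, "w") as f:
        json.dump(payload, f, indent=2)
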