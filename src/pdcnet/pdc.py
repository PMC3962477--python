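"""Partial directed coherence and surrogate-thresholded association matrices.

PDC (Baccala & Sameshima) reads the directed, frequency-resolved influence
structure off a fitted MVAR model.  With ``Abar(f) = I - sum_r A(r)
exp(-i 2 pi f r / fs)``, the PDC from channel j to channel i is

    |pi_{i<-j}(f)| = |Abar_ij(f)| / sqrt(sum_k |Abar_kj(f)|^2),

so each column is l2-normalized: ``sum_i |pi_{i<-j}(f)|^2 = 1`` identically.

Spurious links are removed by Fourier-transform surrogate testing: each
channel of each realization is phase-randomized (amplitude spectrum kept,
phases i.i.d. uniform), the MVAR + PDC computation repeated, and the
(1 - alpha) quantile of the resulting null distribution used as a per-pair,
per-frequency threshold below which PDC values are zeroed.  The per-window
association matrix then takes the maximum surviving PDC over a low-frequency
band (default 1-300 Hz) and transposes it, so entry (i, j) is the causal
strength i -> j.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mvar import MVARModel, estimate_lag_covariances, fit_lwr
from .preprocess import EventEnsemble, WindowGrid, window_slice

__all__ = [
    "SpectralPDC",
    "AssociationMatrix",
    "default_freqs",
    "coefficient_spectrum",
    "pdc_spectrum",
    "phase_randomize",
    "surrogate_threshold",
    "apply_threshold",
    "association_matrix",
    "window_association_matrices",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpectralPDC:
    """PDC magnitudes on a frequency grid: ``pdc[i, j, f] = |pi_{i<-j}(f)|``."""

    freqs: np.ndarray      # (F,)
    pdc: np.ndarray        # (N, N, F), nonnegative

    @property
    def n_channels(self) -> int:
        return self.pdc.shape[0]


@dataclass(frozen=True)
class AssociationMatrix:
    """Per-window causal-strength matrix: ``W[i, j]`` is the strength i -> j."""

    W: np.ndarray          # (N, N), nonnegative, zero diagonal
    window: int | None = None

    def __post_init__(self) -> None:
        if np.any(self.W < 0):
            raise ValueError("association weights must be nonnegative")
        if np.any(np.diag(self.W) != 0):
            raise ValueError("association matrix must have zero diagonal")


def default_freqs(lo: float = 1.0, hi: float = 300.0, step: float = 1.0) -> np.ndarray:
    """The default analysis grid: 1 Hz spacing over the 1-300 Hz band."""
    return np.arange(lo, hi + step / 2, step)


# ---------------------------------------------------------------------------
# spectral transform
# ---------------------------------------------------------------------------

def coefficient_spectrum(
    model: MVARModel, freqs: np.ndarray, sampling_rate: float
) -> np.ndarray:
    """``Abar(f) = I - sum_r A(r) exp(-i 2 pi f r / fs)`` for each frequency.

    Returns a complex array of shape (F, N, N).
    """
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    if np.any(freqs <= 0) or np.any(freqs > sampling_rate / 2):
        raise ValueError("frequencies must lie in (0, Nyquist]")
    p, n, _ = model.A.shape
    lags = np.arange(1, p + 1)
    phase = np.exp(-2j * np.pi * np.outer(freqs, lags) / sampling_rate)  # (F, p)
    Abar = np.eye(n)[None, :, :] - np.einsum("fr,rij->fij", phase, model.A)
    return Abar


def pdc_spectrum(
    model: MVARModel, freqs: np.ndarray, sampling_rate: float
) -> SpectralPDC:
    """Column-normalized PDC magnitudes of a fitted model."""
    Abar = coefficient_spectrum(model, freqs, sampling_rate)
    mag = np.abs(Abar)                              # (F, N, N)
    colnorm = np.sqrt((mag ** 2).sum(axis=1))       # (F, N): sum over rows k
    if np.any(colnorm == 0):
        raise ValueError("zero column norm in Abar: degenerate model")
    pdc = mag / colnorm[:, None, :]
    return SpectralPDC(
        freqs=np.atleast_1d(np.asarray(freqs, dtype=float)),
        pdc=np.moveaxis(pdc, 0, -1),
    )


# ---------------------------------------------------------------------------
# surrogate significance testing
# ---------------------------------------------------------------------------

def phase_randomize(data: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Independent Fourier-phase randomization of each channel/realization.

    Preserves every amplitude spectrum exactly; phases of the positive
    frequencies are redrawn i.i.d. uniform, destroying all cross-channel (and
    within-channel phase) structure.  DC and Nyquist components stay real.
    """
    data = np.asarray(data, dtype=float)
    n = data.shape[-1]
    spec = np.fft.rfft(data, axis=-1)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=spec.shape)
    phases[..., 0] = 0.0
    if n % 2 == 0:
        phases[..., -1] = 0.0
    return np.fft.irfft(np.abs(spec) * np.exp(1j * phases), n=n, axis=-1)


def _fit_pdc(data: np.ndarray, order: int, freqs, fs, ridge: float) -> np.ndarray:
    cov = estimate_lag_covariances(data, order)
    model = fit_lwr(cov, order, ridge=ridge)
    return pdc_spectrum(model, freqs, fs).pdc


def surrogate_threshold(
    data,
    order: int,
    freqs: np.ndarray,
    sampling_rate: float,
    n_surrogates: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    pooling: str = "per_pair_freq",
    ridge: float = 0.0,
    window=None,
) -> np.ndarray:
    """(1 - alpha) quantile of the surrogate PDC null distribution.

    Each of ``n_surrogates`` iterations phase-randomizes every channel of
    every realization in the window, refits the MVAR model and recomputes the
    PDC.  With ``pooling='per_pair_freq'`` (default) the threshold is computed
    separately for every directed pair and frequency; ``pooling='global'``
    pools all off-diagonal values into a single scalar threshold.

    Returns an (N, N, F) threshold array (broadcast when pooled globally).
    """
    if n_surrogates < 20:
        raise ValueError("n_surrogates < 20: the tail quantile is unstable")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    if isinstance(data, EventEnsemble):
        fsamp = data.sampling_rate
        arr = data.data
        if window is not None:
            if isinstance(window, tuple):
                grid, idx = window
                window = window_slice(grid, idx, fsamp)
            arr = arr[:, :, window]
    else:
        arr = np.asarray(data, dtype=float)
        if arr.ndim == 2:
            arr = arr[None, :, :]
        if window is not None:
            arr = arr[:, :, window]
    rng = np.random.default_rng(seed)
    null = np.empty((n_surrogates,) + (arr.shape[1], arr.shape[1], len(np.atleast_1d(freqs))))
    for s in range(n_surrogates):
        surr = phase_randomize(arr, rng)
        null[s] = _fit_pdc(surr, order, freqs, sampling_rate, ridge)
    if alpha == 1.0:
        # degenerate level: nothing is rejected, every link survives
        return np.zeros_like(null[0])
    if pooling == "per_pair_freq":
        return np.quantile(null, 1.0 - alpha, axis=0)
    if pooling == "global":
        n = arr.shape[1]
        off = ~np.eye(n, dtype=bool)
        thr = float(np.quantile(null[:, off, :], 1.0 - alpha))
        return np.full_like(null[0], thr)
    raise ValueError(f"unknown pooling {pooling!r}")


def apply_threshold(sp: SpectralPDC, threshold: np.ndarray) -> SpectralPDC:
    """Zero out PDC values at or below the surrogate threshold."""
    kept = np.where(sp.pdc > threshold, sp.pdc, 0.0)
    return SpectralPDC(freqs=sp.freqs, pdc=kept)


# ---------------------------------------------------------------------------
# association matrix
# ---------------------------------------------------------------------------

def association_matrix(
    sp: SpectralPDC,
    band: tuple[float, float] = (1.0, 300.0),
    window: int | None = None,
) -> AssociationMatrix:
    """Max-over-band PDC, transposed so ``W[i, j]`` reads i -> j.

    ``M[i, j] = max_{f in band} pdc[i, j, f]`` (influence of j on i), then
    ``W = M^T``; the diagonal is zeroed.
    """
    lo, hi = band
    mask = (sp.freqs >= lo) & (sp.freqs <= hi)
    if not np.any(mask):
        raise ValueError("empty frequency band")
    M = sp.pdc[:, :, mask].max(axis=2)
    W = M.T.copy()
    np.fill_diagonal(W, 0.0)
    return AssociationMatrix(W=W, window=window)


def window_association_matrices(
    ens: EventEnsemble,
    grid: WindowGrid,
    order: int = 5,
    band: tuple[float, float] = (1.0, 300.0),
    freq_step: float = 1.0,
    n_surrogates: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    thresholded: bool = True,
    ridge: float = 0.0,
) -> np.ndarray:
    """Per-window association matrices for a whole window grid.

    For each window: estimate lag covariances across realizations, fit the
    MVAR model (LWR), compute the PDC spectrum, optionally remove spurious
    links by surrogate thresholding (surrogates are drawn fresh per window,
    seeded from the master seed plus the window index), and take the
    max-over-band transposed association matrix.

    Returns an array of shape (n_windows, N, N).
    """
    fs = ens.sampling_rate
    hi = min(band[1], fs / 2)
    freqs = default_freqs(band[0], hi, freq_step)
    n = ens.n_channels
    out = np.empty((grid.n_windows, n, n))
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(grid.n_windows)]
    for w in range(grid.n_windows):
        sl = window_slice(grid, w, fs)
        arr = ens.data[:, :, sl]
        pdc = _fit_pdc(arr, order, freqs, fs, ridge)
        sp = SpectralPDC(freqs=freqs, pdc=pdc)
        if thresholded:
            thr = surrogate_threshold(
                arr,
                order,
                freqs,
                fs,
                n_surrogates=n_surrogates,
                alpha=alpha,
                seed=child_seeds[w],
                ridge=ridge,
            )
            sp = apply_threshold(sp, thr)
        out[w] = association_matrix(sp, band=(band[0], hi), window=w).W
    return out


def association_to_edgelist(W: np.ndarray) -> pd.DataFrame:
    """Weighted edge list (source, target, weight) of the nonzero entries."""
    src, tgt = np.nonzero(W)
    return pd.DataFrame({"source": src, "target": tgt, "weight": W[src, tgt]})
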