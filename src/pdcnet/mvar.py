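"""Multivariate autoregressive model fitting from multi-realization windows.

The model is ``x(t) = sum_{r=1..p} A(r) x(t-r) + e(t)`` with white innovation
noise of covariance Sigma.  Coefficients are estimated from lagged covariance
matrices via the multichannel Yule-Walker equations, solved either by the
order-recursive Levinson-Wiggins-Robinson (Whittle) algorithm — the default —
or by a direct block-Toeplitz linear solve (`fit_direct`), which serves as an
independent cross-check.  With repeated aligned event segments, the lagged
covariances of each realization are averaged before solving; short analysis
windows are usable because many realizations contribute.

Model order is selected by the multivariate Akaike information criterion
``AIC(p) = 2 ln det(Sigma_p) + 2 p N^2 / n_points`` or held fixed (default
order 5, the conventional choice for this recording type).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import EventEnsemble, WindowGrid, window_slice

__all__ = [
    "LagCovariance",
    "MVARModel",
    "estimate_lag_covariances",
    "fit_lwr",
    "fit_direct",
    "aic",
    "aic_curve",
    "select_order",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LagCovariance:
    """Lagged covariance estimates R(0..p_max), averaged over realizations.

    ``R[n]`` estimates ``E[x(t) x(t-n)^T]``; negative lags follow from
    ``R(-n) = R(n)^T`` and are not stored.  The biased (divide-by-T)
    normalization is used, the standard convention for Yule-Walker fitting.
    """

    R: np.ndarray          # (p_max + 1, N, N)
    n_points: int

    @property
    def p_max(self) -> int:
        return self.R.shape[0] - 1

    @property
    def n_channels(self) -> int:
        return self.R.shape[1]

    def at(self, n: int) -> np.ndarray:
        """R(n) for any lag, using R(-n) = R(n)^T."""
        if abs(n) > self.p_max:
            raise ValueError(f"lag {n} beyond p_max={self.p_max}")
        return self.R[n] if n >= 0 else self.R[-n].T


@dataclass(frozen=True)
class MVARModel:
    order: int
    A: np.ndarray          # (p, N, N)
    Sigma: np.ndarray      # (N, N) innovation covariance
    n_points: int

    @property
    def n_channels(self) -> int:
        return self.A.shape[1]

    def is_stable(self) -> bool:
        """Advisory companion-matrix stability flag (not enforced)."""
        from .synthetic import companion_spectral_radius

        return companion_spectral_radius(self.A) < 1.0


# ---------------------------------------------------------------------------
# covariance estimation
# ---------------------------------------------------------------------------

def _window_data(data, window, fs) -> np.ndarray:
    """Accept a raw (R, N, T) array, or an ensemble plus window selector."""
    if isinstance(data, EventEnsemble):
        arr = data.data
        if window is not None:
            if isinstance(window, WindowGrid):
                raise TypeError("pass (grid, index) or a slice, not the grid itself")
            if isinstance(window, tuple):
                grid, idx = window
                window = window_slice(grid, idx, fs or data.sampling_rate)
            arr = arr[:, :, window]
        return arr
    arr = np.asarray(data, dtype=float)
    if arr.ndim == 2:
        arr = arr[None, :, :]
    if window is not None:
        arr = arr[:, :, window]
    return arr


def estimate_lag_covariances(
    data,
    p_max: int,
    window=None,
    fs: float | None = None,
) -> LagCovariance:
    """Estimate R(0..p_max) within a window, averaged across realizations.

    ``data`` may be a realizations x channels x samples array, a single
    channels x samples array, or an :class:`~pdcnet.preprocess.EventEnsemble`
    (optionally restricted to one analysis window via a slice or a
    ``(WindowGrid, index)`` pair).  Per realization,
    ``R_r(n) = (1/T) sum_t x(t) x(t-n)^T`` over the window; the final estimate
    averages ``R_r`` over realizations.
    """
    arr = _window_data(data, window, fs)
    n_real, n_ch, T = arr.shape
    if p_max >= T:
        raise ValueError(f"p_max={p_max} must be smaller than window length {T}")
    if n_real * T <= 1 or (n_real == 1 and np.allclose(arr[0].std(axis=1), 0.0)):
        raise ValueError("degenerate window: no variance to estimate from")
    R = np.zeros((p_max + 1, n_ch, n_ch))
    for n in range(p_max + 1):
        # mean over realizations of (1/T) sum_{t=n}^{T-1} x(t) x(t-n)^T
        a = arr[:, :, n:]
        b = arr[:, :, : T - n]
        R[n] = np.einsum("rit,rjt->ij", a, b) / (T * n_real)
    R[0] = (R[0] + R[0].T) / 2.0
    return LagCovariance(R=R, n_points=n_real * T)


# ---------------------------------------------------------------------------
# Yule-Walker solvers
# ---------------------------------------------------------------------------

def fit_lwr(cov: LagCovariance, order: int, ridge: float = 0.0) -> MVARModel:
    """Solve the multichannel Yule-Walker equations by the LWR recursion.

    The order-recursive Whittle algorithm propagates forward and backward
    prediction coefficients simultaneously; the result is algebraically
    identical to the direct block-Toeplitz solve (see :func:`fit_direct`).
    ``ridge`` adds ``ridge * I`` to R(0) for near-singular short-window
    covariances.
    """
    p = int(order)
    if not 1 <= p <= cov.p_max:
        raise ValueError(f"order must be in 1..{cov.p_max}")
    n = cov.n_channels
    R = [cov.at(k).copy() for k in range(p + 1)]
    if ridge:
        R[0] = R[0] + ridge * np.eye(n)

    V = R[0].copy()            # forward innovation covariance
    W = R[0].copy()            # backward innovation covariance
    Af: list[np.ndarray] = []  # forward coefficients A_1..A_k
    Ab: list[np.ndarray] = []  # backward coefficients
    for k in range(1, p + 1):
        E = R[k] - sum(Af[i] @ R[k - 1 - i] for i in range(k - 1))
        try:
            Ak = np.linalg.solve(W.T, E.T).T
            Bk = np.linalg.solve(V.T, E).T
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "singular covariance block in LWR recursion; consider a ridge "
                "epsilon (fit_lwr(..., ridge=1e-8)) or a longer window"
            ) from exc
        Af_new = [Af[i] - Ak @ Ab[k - 2 - i] for i in range(k - 1)] + [Ak]
        Ab_new = [Ab[i] - Bk @ Af[k - 2 - i] for i in range(k - 1)] + [Bk]
        V = V - Ak @ E.T
        W = W - Bk @ E
        Af, Ab = Af_new, Ab_new

    A = np.stack(Af)
    Sigma = (V + V.T) / 2.0
    return MVARModel(order=p, A=A, Sigma=Sigma, n_points=cov.n_points)


def fit_direct(cov: LagCovariance, order: int, ridge: float = 0.0) -> MVARModel:
    """Direct block-matrix solve of the stacked Yule-Walker system.

    Solves ``[A_1 .. A_p] G = [R(1) .. R(p)]`` where ``G`` is the block
    Toeplitz matrix with block (r, c) = R(c - r).  Used as the independent
    cross-check of :func:`fit_lwr`.
    """
    p = int(order)
    if not 1 <= p <= cov.p_max:
        raise ValueError(f"order must be in 1..{cov.p_max}")
    n = cov.n_channels
    G = np.empty((n * p, n * p))
    for r in range(p):
        for c in range(p):
            blk = cov.at(c - r)
            if r == c and ridge:
                blk = blk + ridge * np.eye(n)
            G[r * n : (r + 1) * n, c * n : (c + 1) * n] = blk
    rhs = np.concatenate([cov.at(k) for k in range(1, p + 1)], axis=1)  # N x Np
    try:
        A_flat = np.linalg.solve(G.T, rhs.T).T  # solves A_flat @ G = rhs
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular Yule-Walker block matrix; consider a ridge epsilon"
        ) from exc
    A = np.stack([A_flat[:, k * n : (k + 1) * n] for k in range(p)])
    Sigma = cov.at(0) - sum(A[k] @ cov.at(k + 1).T for k in range(p))
    Sigma = (Sigma + Sigma.T) / 2.0
    return MVARModel(order=p, A=A, Sigma=Sigma, n_points=cov.n_points)


# ---------------------------------------------------------------------------
# order selection
# ---------------------------------------------------------------------------

def aic(model: MVARModel) -> float:
    """Multivariate AIC: ``2 ln det(Sigma) + 2 p N^2 / n_points``.

    Comparable across orders only for models fitted to the same data.
    """
    sign, logdet = np.linalg.slogdet(model.Sigma)
    if sign <= 0:
        raise ValueError("innovation covariance is not positive definite")
    n = model.n_channels
    return float(
        2.0 * logdet + 2.0 * model.order * n * n / model.n_points
    )


def aic_curve(
    data,
    p_range,
    window=None,
    fs: float | None = None,
    ridge: float = 0.0,
) -> dict[int, float]:
    """AIC as a function of model order on fixed data."""
    p_range = list(p_range)
    if not p_range:
        raise ValueError("empty order range")
    cov = estimate_lag_covariances(data, max(p_range), window=window, fs=fs)
    return {p: aic(fit_lwr(cov, p, ridge=ridge)) for p in p_range}


def select_order(
    data,
    p_range=range(1, 11),
    policy: str = "fixed",
    fixed_order: int = 5,
    elbow_threshold: float = 0.01,
    window=None,
    fs: float | None = None,
) -> int:
    """Choose the MVAR model order.

    Policies: ``"fixed"`` (default, returns ``fixed_order`` — the conventional
    order-5 choice), ``"min_aic"`` (order minimizing the AIC over ``p_range``),
    or ``"elbow"`` (smallest order whose AIC improvement over the previous
    order falls below ``elbow_threshold``).
    """
    p_range = list(p_range)
    if not p_range:
        raise ValueError("empty order range")
    if policy == "fixed":
        return int(fixed_order)
    curve = aic_curve(data, p_range, window=window, fs=fs)
    if policy == "min_aic":
        return min(curve, key=curve.get)
    if policy == "elbow":
        ordered = sorted(curve)
        for prev, cur in zip(ordered, ordered[1:]):
            if curve[prev] - curve[cur] < elbow_threshold:
                return cur
        return ordered[-1]
    raise ValueError(f"unknown order-selection policy {policy!r}")
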