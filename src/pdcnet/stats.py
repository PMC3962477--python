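"""Stage- and layer-wise comparisons with false-discovery-rate control.

Node metrics (in-/out-degree, clustering, small-world curves) are compared
between the pyramidal-cell-layer and granule-cell-layer node groups across
preparations ("slices"): within each slice the metric is averaged over the
nodes of each layer, a paired two-sided t-test is run across slices per
window (or per cost), and the resulting p-value family is corrected by the
Benjamini-Hochberg step-up procedure.  One comparison family = all windows
(or costs) of one metric.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

__all__ = ["paired_t", "fdr_bh", "stage_layer_comparison"]


def paired_t(a, b) -> tuple[float, float]:
    """Paired two-sided Student t-test on per-slice values.

    Identical inputs (all differences exactly zero) return ``(0.0, 1.0)``;
    constant non-zero differences have no within-pair variance and raise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if a.size < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    if np.any(np.isnan(a)) or np.any(np.isnan(b)):
        raise ValueError("missing pairs are not allowed")
    d = a - b
    if np.allclose(d, 0.0):
        return 0.0, 1.0
    if float(d.std(ddof=1)) == 0.0:
        raise ValueError("zero-variance differences: t statistic undefined")
    t, p = sstats.ttest_rel(a, b)
    return float(t), float(p)


def fdr_bh(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up correction.

    Returns (adjusted p-values, boolean significance flags at level ``q``).
    Adjusted values are monotone in the sorted raw-p order and never smaller
    than the raw p.  Empty input yields empty output.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject


def stage_layer_comparison(
    metric: np.ndarray,
    layers,
    layer_a: str = "pcl",
    layer_b: str = "gcl",
    q: float = 0.05,
    unit: str = "window",
) -> pd.DataFrame:
    """Layer-wise paired comparison of a node metric across slices.

    ``metric`` has shape (n_slices, n_units, n_nodes) — units are windows or
    costs — and ``layers`` labels each node.  Per unit, the metric is averaged
    over each layer's nodes within every slice and the two layer means are
    compared by a paired t-test across slices; BH correction runs over the
    whole unit family.  Slices where either layer's nodes are all-NaN are
    dropped with a warning.

    Returns a table with per-unit group means/SEMs, t, raw p, adjusted p and
    a significance flag at ``q``.
    """
    metric = np.asarray(metric, dtype=float)
    if metric.ndim != 3:
        raise ValueError("metric must be slices x units x nodes")
    layers = np.asarray(layers)
    if layers.size != metric.shape[2]:
        raise ValueError("every node needs a layer label")
    ia = np.flatnonzero(layers == layer_a)
    ib = np.flatnonzero(layers == layer_b)
    if ia.size == 0 or ib.size == 0:
        raise ValueError(f"no nodes labelled {layer_a!r} or {layer_b!r}")

    mean_a = metric[:, :, ia].mean(axis=2)  # slices x units
    mean_b = metric[:, :, ib].mean(axis=2)
    ok = ~(np.isnan(mean_a).any(axis=1) | np.isnan(mean_b).any(axis=1))
    if not np.all(ok):
        warnings.warn(
            f"{int((~ok).sum())} slice(s) missing a layer dropped", stacklevel=2
        )
        mean_a, mean_b = mean_a[ok], mean_b[ok]
    n_slices = mean_a.shape[0]
    if n_slices < 2:
        raise ValueError("need at least 2 slices for a paired comparison")

    rows = []
    for u in range(metric.shape[1]):
        t, p = paired_t(mean_a[:, u], mean_b[:, u])
        rows.append(
            {
                unit: u,
                f"mean_{layer_a}": float(mean_a[:, u].mean()),
                f"sem_{layer_a}": float(mean_a[:, u].std(ddof=1) / np.sqrt(n_slices)),
                f"mean_{layer_b}": float(mean_b[:, u].mean()),
                f"sem_{layer_b}": float(mean_b[:, u].std(ddof=1) / np.sqrt(n_slices)),
                "t": t,
                "p": p,
            }
        )
    table = pd.DataFrame(rows)
    p_adj, reject = fdr_bh(table["p"].to_numpy(), q=q)
    table["p_adj"] = p_adj
    table["significant"] = reject
    return table
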