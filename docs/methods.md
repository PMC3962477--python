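# Methods

This document defines the models and algorithms implemented in `pdcnet`, the
meaning and defaults of every important parameter, and the reasoning behind
the numerical design choices.

## 1. Signal model and preprocessing

Recordings are `channels × samples` arrays at sampling rate `fs` (default
2000 Hz, which keeps the full 1–300 Hz analysis band below Nyquist with
ample margin). Channels carry a site table (row, column, anatomical layer
`pcl`/`gcl`/`other`, active flag); the standard fixture is the corner-less
8×8 grid of 60 sites at 200 µm pitch.

**Event detection** (`preprocess.detect_events`): a discharge is a crossing
of `|x| > k_sd · SD(background)` on one reference channel, with
`k_sd = 10` and the background SD taken from a designated quiet interval
(default the first 10 s). A refractory lockout of one segment length
(800 ms) prevents double counting. Rectified (absolute-value) crossing is
used so the detector is polarity-free.

**Segmentation** (`preprocess.extract_segments`): segments span
`[t − pre, t + post)` around each detection time; 300/500 ms for the
stage-resolved graph analysis (one 800 ms segment per discharge) and
2000/5000 ms for the timing analysis (7 s segments). Events whose segment
would leave the recording are skipped with a log entry.

**Conditioning** (`preprocess.condition_segment`): per segment and channel,
a zero-phase 50 Hz notch followed by a z-score. The default notch zeroes
the FFT bins within ±0.5 Hz of 50 Hz. This choice is deliberate: the
module guarantees that conditioning is idempotent (re-conditioning changes
nothing beyond 1e-6 RMS), and a conventional second-order IIR notch cannot
satisfy that on broadband signals because its passband ripple re-shapes the
spectrum slightly on every pass. The FFT notch is exactly idempotent and
attenuates ≥ 20 dB at 50 Hz; the IIR design remains available via
`method="iir"`.

**Ensemble normalization** (`preprocess.ensemble_normalize`): with ≥ 2
aligned events, the mean and SD *across events* are removed at every
(channel, sample) point. This removes the stereotyped event-locked
transient and its variance envelope, leaving the trial-to-trial covariation
from which the MVAR model estimates directed interactions. Note the
normalized ensemble has zero event-averaged waveform by construction — the
discharge-timing analysis therefore reads the averaged waveform from the
*conditioned* (pre-normalization) ensemble.

**Windowing** (`preprocess.make_windows`): sliding windows
`[k·step, k·step + window)` with 50 ms windows and 10 ms steps; an 800 ms
segment yields exactly 76 windows, a 7 s segment 696. Discharge stages
early/middle/late are the intervals 0–240, 280–520, 560–800 ms; a window
belongs to a stage only if fully contained in it.

## 2. MVAR estimation

The model is `x(t) = Σ_{r=1..p} A(r) x(t−r) + e(t)` with innovation
covariance Σ. Lag covariances `R(n) = E[x(t) x(t−n)ᵀ]` are estimated per
window with the biased (divide-by-T) normalization and averaged across all
events, so one model per window pools every realization.

Two independent solvers of the multichannel Yule–Walker equations are
provided and agree to machine precision (asserted in the tests):

- `fit_lwr`: the order-recursive Levinson–Wiggins–Robinson (Whittle)
  recursion propagating forward and backward prediction coefficients;
- `fit_direct`: the explicit block-Toeplitz solve
  `[A₁ … A_p] G = [R(1) … R(p)]`.

Σ follows as `R(0) − Σ_r A_r R(r)ᵀ`. An optional ridge term on `R(0)`
stabilizes near-singular short-window estimates.

**Order selection** (`mvar.select_order`): the multivariate AIC is
`2 ln det Σ_p + 2 p N² / n_points`. The default policy is a fixed order 5 —
for 50 ms windows at 2 kHz (100 samples) pooled over tens of events this
sits at or near the AIC minimum while keeping every window's model
identical, which matters when comparing windows; `min_aic` and `elbow`
policies are available. The desk-scale studies in the tests use order 3 for
the 12-channel fixture, for the same reason at smaller N.

## 3. Partial directed coherence

From the fitted coefficients, `Ā(f) = I − Σ_r A(r) e^{−i2πfr/fs}` and

```
|π_{i←j}(f)| = |Ā_ij(f)| / sqrt(Σ_k |Ā_kj(f)|²)
```

so every column satisfies `Σ_i |π_{i←j}|² = 1` — each source's outflow is
normalized, making columns comparable. The analysis grid is 1 Hz spacing
over 1–300 Hz (the band where the discharge energy lives; the grid spacing
is a resolution/speed trade-off and is configurable).

**Surrogate thresholding** (`pdc.surrogate_threshold`): each channel of
each realization is phase-randomized (amplitude spectrum preserved, phases
i.i.d. uniform — destroying all cross-channel structure), the model is
refitted and the PDC recomputed, `n_surrogates` times (default 1000; the
test suites use 100–200, trading quantile precision for runtime). The
threshold is the (1−α) quantile per directed pair per frequency (α = 0.05;
a pooled-global mode exists). PDC below threshold is set to zero *before*
the band maximum is taken, so a link survives only at frequencies where it
beats its own null. Under channel independence the surviving fraction of
(pair, frequency) cells is ≈ α (verified in the acceptance tests).

**Association matrix** (`pdc.association_matrix`): the maximum thresholded
PDC over the band, transposed so `W[i, j]` reads *i drives j*, diagonal
zeroed. One `N×N` matrix per window.

## 4. Graph characterization

All metrics treat `W` as a weighted directed graph without self-loops.

- **Degrees**: weighted out `Σ_j W[i,j]`, weighted in `Σ_j W[j,i]`; the
  combinatorial degree (edge count, both directions) and bidirectional
  count feed the clustering denominator. The network *connection strength*
  is the total degree `2 ΣW`.
- **Clustering** (Fagiolo's weighted directed form): with
  `U = (W / max W)^{1/3}` and `S = U + Uᵀ`,
  `CC_i = [S³]_ii / (2[k_i(k_i−1) − 2k_i^↔])`. Weights are normalized by
  the maximum so all lie in [0, 1]; for equal weights this reduces exactly
  to binary directed clustering.
- **Path length**: edge length `1/weight`, directed Dijkstra, and the
  harmonic mean `L = N(N−1) / Σ_{i≠j} 1/d_ij`. Unreachable pairs contribute
  0 to the sum — the harmonic-mean convention — so disconnected graphs get
  finite L without arbitrary substitutions.
- **Cost thresholding**: at cost `c`, the `⌊c·N(N−1)⌋` largest-weight edges
  are kept. Ties break deterministically (weight desc, source asc, target
  asc) for reproducibility. The standard sweep is 0.05–0.30 in 0.01 steps.
- **Null model** (`graph.random_nulls`): each node's outgoing targets are
  redrawn uniformly among the other nodes (no self-loops or duplicates)
  and its own weights are permuted onto them — the weights travel with
  their source, preserving the weighted out-degree sequence *exactly* in
  every null. Because each node keeps its out-edge count and any count
  ≤ N−1 is always placeable, the construction never needs a fallback. A
  `combinatorial` mode additionally shuffles the global weight pool.
- **Small-worldness**: at each cost, `γ = C/C_rand`, `λ = L/L_rand`,
  `σ = γ/λ` against the mean of `n_null = 100` nulls. σ ≈ 1 for random
  graphs and γ > 1 for lattices (both asserted as calibration).

## 5. Discharge vs network-alteration timing

On the 7 s segments (2 s pre-detection baseline):

- **Discharge interval**: per channel, the event-averaged waveform is
  smoothed with a centered moving average and thresholded at ±4 baseline
  SDs (baseline = the first second); the network-level discharge interval
  is (earliest channel start, latest channel end).
- **Network interval**: the connection strength per window (from the
  window association matrices) is smoothed with a penalized cubic B-spline
  — second-difference coefficient penalty, penalty weight chosen by
  generalized cross-validation — and thresholded the same way.
- **Lead** = discharge start − network start; **tail** = network end −
  discharge end.

The P-spline stands in for Bayesian adaptive regression splines: no
installed library provides BARS, and a GCV-tuned P-spline is a standard,
fully deterministic smoother with similar bias-variance behavior for these
series. Its smoothing is global rather than adaptive, so a sharp step is
spread over a shoulder of roughly the basis-knot spacing; detected onsets
are accurate to within that bandwidth (the tests measure it).

**Robustness**: the first/last-crossing rule is maximally sensitive to
isolated noise excursions, and the smoother occasionally produces short
bumps that graze 4 SDs. Both detectors therefore accept a sustained-
crossing requirement: `min_duration_ms` for the waveform (CLI default
50 ms — about 2.5× the waveform smoothing width and far below any real
discharge duration) and `min_duration_windows` for the strength series
(CLI default 10 windows = 100 ms, about the width of a smoothed noise
bump). With 0/1 (the library defaults) the rule is the plain first/last
crossing.

## 6. Synthetic generator

`pdcnet.synthetic` produces recordings in which everything the pipeline
estimates is planted and known:

- **Network**: feed-forward `pcl → gcl` coupling (each pyramidal-layer site
  drives the granule-layer sites in its own column at lag 1 and adjacent
  columns at lag 2 with half gain). Being acyclic, the planted network is
  stable at any gain, and the true direction of every edge is known.
- **Events**: `n_events` discharges (default 50) of 800 ms, evenly spaced
  after a 12 s quiet lead-in (used for background-SD estimation). Each
  event deposits a stereotyped 8 Hz field transient (peak 12 background
  SDs) on the `pcl` sites, a scaled copy (0.6×) elsewhere, plus a
  high-frequency (> 200 Hz) burst on `pcl`/`gcl` sites.
- **Coupling time course**: the MVAR coupling gain ramps linearly over the
  200 ms before each onset (the planted *lead*), holds at 1 during the
  event, declines linearly to a floor of 0.4 over the first 94 % of the
  3.5 s tail, and returns to zero in the final 6 % (≈ 210 ms). The floor
  and the brief terminal drop exist for identifiability: a gain that fades
  linearly all the way to zero has no threshold-detectable endpoint, so
  "the planted network end" would be undefined. For the same reason the
  field transient's envelope settles on a sustained floor (0.45 of peak,
  ≈ 5.4 background SDs — above the 4 SD detection threshold) rather than
  decaying below threshold mid-event.
- **Limits**: the generator is a verification instrument, not a biophysical
  model — Gaussian innovations, linear coupling, identical stereotyped
  events, no drift or artifacts. Its planted offset is a 210 ms ramp, so
  per-realization offset estimates are intrinsically uncertain at that
  scale; across-seed means recover the planted tail to well within 0.1 s.

## 7. Problem sizes and runtime

The library defaults mirror the full-scale study conditions (60 sites, 50
events, 1000 surrogates). The test and acceptance studies run at desk
scale on one CPU core: a 4×4 (12-site) array, 12–20 events, order 3, and
unthresholded association stacks for the 696-window timing analysis —
surrogate thresholding is the dominant cost (it refits the model
`n_surrogates` times per window) and is exercised at full fidelity on
single windows and the 76-window grids instead. All randomness flows from
explicit seeds through `numpy.random.SeedSequence`, so every number in the
tests and the acceptance report is reproducible.
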