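# Methods

## Recording model and detection

Extracellular traces are band-pass filtered with a causal 2nd-order
Butterworth filter, 100–3,500 Hz (slow field potentials and high-frequency
noise removed; the causal direction matches online detection, and the first
10 ms are excluded from noise estimation to skip the filter transient).
Noise is estimated robustly as s_V = 1.4826·MAD, a consistent estimator of
the Gaussian standard deviation that ignores the spikes themselves.  Events
are strict sample-resolution local minima below −k·s_V (default k = 5, no
sub-sample interpolation); events closer than the 0.5 ms dead time keep only
the first, so a single spike is never counted twice.  The default sampling
rate is 20 kHz (61 samples spanning the ±1.5 ms waveform window).

The per-electrode **activity map** (spike count, median negative-peak
amplitude) localizes axon initial segments (AIS), which dominate the local
field.  Trigger ("fixed") electrodes are chosen greedily by most-negative
median amplitude with a 100 μm exclusion radius so no neuron is recorded
twice; rank ties break toward the lower electrode id for determinism.

## Configuration planning

A switch matrix connects e electrodes to a ≪ e amplifiers.  With n
amplifiers pinned to fixed electrodes, the array is covered in
c(n) = ⌈(e−n)/(a−n)⌉ configurations — the ceiling is required for coverage,
even though one published table entry suggests round-half rounding — i.e.
C(n) = c(n)/n configurations per neuron, minimized at
n* = e(1−√(1−a/e)) ≈ a/2.  Physical routing conflicts that inflate the
count on real hardware are not modeled.  Throughput helpers expose the
derived arithmetic (spikes per configuration for a cluster gate, total and
per-neuron scan time, root-sum-square noise budgets and the quadratic
recording-time factor between chips).

## Sorting and footprint assembly

Per fixed electrode, event waveforms (61 samples centered on the negative
peak) are reduced to 10 principal components (scikit-learn PCA; typically
>85% of signal energy) and clustered with full-covariance Gaussian mixtures,
the model order K = 1…6 selected by BIC (scikit-learn GaussianMixture; a
penalized-likelihood stand-in for classical unconstrained-covariance
sorters, deterministic under the seed).  Clusters with more than 2,500
events (≈14 spikes in each of 179 configurations, ≈7 spikes/min) define
neurons; smaller clusters give delay maps too noisy to segment.

The STA window is Δt_pre = −2 ms to Δt_post = +6 ms (T = 8 ms): axonal
delays fall in 0–2 ms and the AIS peak leads the trigger only slightly, so
most of the window lies post-trigger.  Per-configuration STAs are combined
into one array-wide footprint; fixed electrodes are shared between
configurations and the version averaged over more spikes wins.  Derived per
electrode: V_n = −min, τ_n = time of the minimum, and s_n = 1.4826·MAD of
the averaged trace outside ±1 ms of its peak (the averaged-trace noise; no
operational definition is standard, so it is estimated from the STA
itself).  The AIS electrode is the fixed electrode with the largest V_n.
Footprints whose amplitude maps have cosine similarity > 0.95 (restricted
to electrodes where either map exceeds 3·s_n) are merged — an automated
surrogate for manual duplicate merging.

## Segmentation

**Method I**: electrode is axonal if V_n > k·s_n (default k = 5).

**Method II**: per electrode, the sample SD s_τ (denominator N−1) of τ over
its hexagonal neighborhood — the electrode plus the ≤6 electrodes nearest
the ideal hexagon vertices at radius scale·pitch (scale ∈ {1,2,3}
reproduces dilated neighborhoods at constant N = 7).  Neighborhoods
truncated below 5 members by the array edge are invalid and never selected
(a sample SD of fewer than 5 delays is too noisy).  Expected modes:
s̄_axon = r/(c√3) (≈30 μs at r = 18 μm, c = 0.3–0.44 m/s) and
s̄_random = T/√12 (≈2.3 ms at T = 8 ms); at N = 7 the sample SD is ~2%
biased low relative to these interval formulas.

The threshold s_min is placed automatically: s_τ values of electrodes
passing the causality gate are histogrammed on a log₁₀ axis
(Freedman–Diaconis bin count, clamped to 10–200 bins; the modes differ by
~2 orders of magnitude, so log spacing separates them robustly), smoothed
with a 3-bin moving average, and s_min is the center of the lowest bin
between the outermost density peaks, taking the middle bin of a tie run.
If the density has no interior valley (e.g. background-only data), the
crossing point of a fitted beta + truncated-exponential mixture is used,
and an (almost) zero axonal weight yields s_min = 0, i.e. an empty
segmentation.  Restricting the histogram to gate-passing electrodes keeps
degenerate zero-signal delays (pinned at Δt_pre) out of the density.

Selected electrodes satisfy s_τ < s_min **and** τ_n > τ_AIS + 0.05 ms (one
sample period of guard, so the AIS itself is never selected): a smooth delay
patch preceding the AIS peak cannot be this neuron's axon.  The method uses
delays only and is invariant to amplitude rescaling.  s_min is estimated
per neuron.

## Evaluation

Hausdorff distance H(A,E) = max of the two directed sup-inf Euclidean
distances between the ground-truth point set and the selected electrode
coordinates, computed exactly (scipy) — sets are small at desk scale.
Ground truth is clipped to the array bounding box (+1 pitch) since
electrodes cannot witness arbor beyond the array.  Empty segmentations give
an undefined (NaN) H rather than an infinite one.

Score mixtures: method I scores x = log(V_n/s_n) fitted with two normals
(EM, exact M-steps, method-of-moments initialization on a quantile split,
10 seeded restarts, best likelihood kept; the component with the smaller
mean is background).  Method II scores x = s_τ/(T/2) ∈ [0,1] fitted with
p_N·Beta(α,β) + p_P·TruncExp(λ), the truncated exponential normalized by
1−e^{−λ} on [0,1] (the only normalization that integrates to one); its
M-step is mean-matching (the exact MLE), the beta M-step is a weighted
numerical MLE warm-started across iterations, so the log-likelihood is
monotone.  TPR and FPR come from the fitted component CDFs over 2,000
thresholds (axon side: high x for method I, low x for method II), AUC by
trapezoidal integration.  Operating points: x = ln 5 for method I,
x = s_min/(T/2) for method II.

## Simulator

The generator emulates exactly the statistics the segmentation relies on,
with all randomness drawn from one seed:

* **Arbors** grow as jittered random walks with fixed 10 μm steps; active
  tips advance round-robin, each step spawns a ±60° collateral with
  probability 0.02, and growth stops at a 2,000 μm total-length budget —
  so the branch count is 1 + Binomial(n_steps, p).
* **Delays** are path length over conduction velocity (default
  c = 0.35 m/s, the middle of the 0.3–0.44 m/s range).
* **Footprints**: each electrode sees a negative-dominant biphasic template
  (difference of Gaussians, ~0.5 ms wide, minimum exactly at the delay of
  the nearest arbor point) scaled by A₀/(1+(d/λ_d)²) with λ_d = 15 μm;
  axonal A₀ = 10 μV (within the observed 5–20 μV range), AIS amplitude
  150 μV with its peak 0.05 ms before the trigger.  Contributions below a
  1 μV floor (about half the chip's circuit noise — unresolvable) are
  zeroed, so distant electrodes are pure noise.  STA noise is
  σ/√n_spikes with σ = 5 μV total RMS.
* **Recordings**: Poisson spike trains (default 2 Hz) insert the noiseless
  template field into white Gaussian noise.

Deliberately not modeled: cable biophysics, myelination/saltatory
conduction, electrode impedance, waveform superposition of crossing
branches (each electrode takes the nearest arbor point only, matching the
single-peak delay definition), and switch-matrix routing constraints.
Passing tests therefore show that the statistical machinery behaves as
designed under its own assumptions, not that it handles every artifact of
real cultures (electrode drift, bursting correlations, overlapping arbors
of many neurons).

## Desk-scale problem sizes

Simulated checks run on 40×40 (or smaller) lattices at 18 μm pitch with
populations of 20 seeded neurons at the standard operating point (5 μV
noise averaged over 14 spikes, T = 8 ms); the closed-loop pipeline test
uses a 1,440-electrode array, 3 neurons, and 20 s per configuration.  These
sizes were chosen so the whole suite runs on a laptop while the arbors
still extend over >50 electrodes; all statistics scale with electrode count
and recording time in the obvious way.

## Known limitations

* The valley position wanders within the (wide, often empty) gap between
  the s_τ modes; per-neuron operating points are correspondingly noisier
  than the AUCs.
* Electrodes at the array edge are reported but never selected; arbors
  leaving the array are invisible, so desk-scale Hausdorff values against
  full (unclipped) ground truth would be dominated by unrecorded arbor.
* The two-pass sorting in the pipeline assumes recordings can be
  regenerated deterministically; with real data the trigger traces would
  be cached instead.
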