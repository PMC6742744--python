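"""Axon segmentation from footprints.

Two binary classifiers decide, per electrode, whether the spike-triggered
average records an axonal signal:

* **Method I** (amplitude thresholding): electrode is axonal when its
  negative-peak amplitude exceeds k times the averaged-trace noise,
  V_n > k * s_n (classically k = 5).

* **Method II** (delay-variance statistic): an action potential sweeping past
  neighboring electrodes produces nearly identical negative-peak delays,
  whereas background electrodes peak anywhere in the averaging window.  The
  sample standard deviation s_tau of the delays over each 7-member hexagonal
  neighborhood therefore separates into two modes: axonal patches near
  r/(c*sqrt(3)) (~30 μs for 18 μm pitch and 0.3-0.44 m/s conduction) and
  background patches near T/sqrt(12) (~2.3 ms for an 8 ms window).  A
  threshold s_min placed automatically in the valley between the modes, plus
  a causality gate (peaks must follow the AIS peak), yields the axonal
  electrode set without manual tuning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import ElectrodeLayout, neighbor_table
from .sort_sta import Footprint

SQRT12 = float(np.sqrt(12.0))

#: Guard added to the AIS delay in the causality gate: one sample period at
#: 20 kHz, so the AIS electrode itself can never be selected as axon.
DEFAULT_GUARD_MS = 0.05

#: Floor applied to s_tau before log-binning (1 μs); exact zeros occur only
#: for noiseless synthetic footprints.
_S_FLOOR_MS = 1e-3


def expected_background_sd(t_ms: float) -> float:
    """Mean sample SD of delays uniform over a window of length T: T/sqrt(12) ms."""
    if t_ms < 0:
        raise ValueError("window length must be non-negative")
    return t_ms / SQRT12

def expected_axon_sd(r_um: float, c_m_s: float) -> float:
    """Mean sample SD of axonal delays across a neighborhood, in μs.

    Delays of a passing action potential spread over [t - r/c, t + r/c], an
    interval of width 2r/c, giving a mean sample SD of r/(c*sqrt(3)).  With
    r in μm and c in m/s the result is directly in μs.
    """
    if r_um < 0:
        raise ValueError("electrode distance must be non-negative")
    if c_m_s <= 0:
        raise ValueError("conduction velocity must be positive")
    return r_um / (c_m_s * np.sqrt(3.0))


@dataclass(frozen=True)
class DelayStatMap:
    """Per-electrode delay and neighborhood delay-SD statistics."""

    electrode_ids: np.ndarray
    tau_ms: np.ndarray
    s_tau_ms: np.ndarray          # NaN where invalid
    n_members: np.ndarray
    valid: np.ndarray             # neighborhood large enough

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "electrode_id": self.electrode_ids,
                "tau_ms": self.tau_ms,
                "s_tau_ms": self.s_tau_ms,
                "valid": self.valid.astype(int),
            }
        )


def delay_sd_map(
    footprint: Footprint,
    layout: ElectrodeLayout,
    scale: int = 1,
    min_members: int = 5,
) -> DelayStatMap:
    """Sample SD (denominator N-1) of negative-peak delays over the hexagonal
    neighborhood of every electrode.

    Neighborhoods truncated by the array edge to fewer than ``min_members``
    electrodes are flagged invalid: a sample SD of fewer than 5 delays is too
    noisy to classify.
    """
    fp_index = {int(e): i for i, e in enumerate(footprint.electrode_ids)}
    try:
        order = np.array([fp_index[int(e)] for e in layout.ids])
    except KeyError as exc:
        raise ValueError("footprint does not cover the layout") from exc
    tau = footprint.tau_ms[order]
    table = neighbor_table(layout, scale=scale)
    s = np.full(layout.n, np.nan)
    counts = (table >= 0).sum(axis=1)
    for i, row in enumerate(table):
        members = row[row >= 0]
        if members.size >= 2:
            s[i] = np.std(tau[members], ddof=1)
    valid = counts >= min_members
    return DelayStatMap(
        electrode_ids=layout.ids.copy(),
        tau_ms=tau,
        s_tau_ms=s,
        n_members=counts,
        valid=valid,
    )


def threshold_from_valley(
    s_values_ms,
    t_ms: float,
    min_values: int = 50,
    rng: np.random.Generator | None = None,
) -> float:
    """Automatic threshold s_min between the axonal and background modes.

    The s_tau values are histogrammed on a log axis (the two modes sit
    roughly two orders of magnitude apart) with Freedman-Diaconis bin count
    and smoothed by a 3-bin moving average; s_min is the center of the lowest
    bin between the outermost density peaks (middle bin of a tie run).  When
    the density has no interior valley, the crossing point of a fitted
    beta + truncated-exponential mixture is used; if that fit assigns (almost)
    no weight to the near-zero axonal component, 0 is returned and the
    segmentation comes out empty.
    """
    s = np.asarray(s_values_ms, dtype=float)
    s = s[np.isfinite(s) & (s >= 0)]
    if s.size < min_values:
        raise ValueError(f"need >= {min_values} valid s values, got {s.size}")
    if t_ms <= 0:
        raise ValueError("window length must be positive")
    cap = expected_background_sd(t_ms)

    y = np.log10(np.maximum(s, _S_FLOOR_MS))
    q75, q25 = np.percentile(y, [75, 25])
    width = 2.0 * (q75 - q25) * s.size ** (-1.0 / 3.0)
    span = y.max() - y.min()
    nbins = int(np.clip(np.ceil(span / width) if width > 0 else 30, 10, 200))
    counts, edges = np.histogram(y, bins=nbins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    smooth = np.convolve(counts, np.ones(3) / 3.0, mode="same")

    from scipy.signal import find_peaks

    peaks, _ = find_peaks(smooth, prominence=0.05 * smooth.max())
    if peaks.size >= 2:
        lo, hi = int(peaks[0]), int(peaks[-1])
        seg = smooth[lo + 1 : hi]
        if seg.size:
            ties = np.flatnonzero(seg == seg.min())
            imin = lo + 1 + int(ties[ties.size // 2])
            return float(min(10.0 ** centers[imin], cap))

    # No interior valley: fall back to the mixture-component crossing.
    from .evaluate import fit_score_mixture_II, truncexp_pdf
    from scipy.stats import beta as beta_dist

    x = np.clip(s / (t_ms / 2.0), 1e-9, 1.0 - 1e-9)
    fit = fit_score_mixture_II(x, rng=rng)
    if fit.weight_pos < 0.02:
        return 0.0
    grid = np.linspace(1e-4, 1.0, 2000)
    pos = fit.weight_pos * truncexp_pdf(grid, fit.params["lambda_p"])
    neg = fit.weight_neg * beta_dist.pdf(grid, fit.params["alpha_n"], fit.params["beta_n"])
    below = pos <= neg
    if below[0]:
        return 0.0
    if not below.any():
        return float(cap)
    x_cross = grid[int(np.argmax(below))]
    return float(min(x_cross * t_ms / 2.0, cap))


@dataclass(frozen=True)
class Segmentation:
    """Electrodes classified as axonal for one neuron by one method."""

    neuron: int | None
    method: str                   # "I" or "II"
    params: dict
    electrode_ids: np.ndarray

    @property
    def n_electrodes(self) -> int:
        return int(self.electrode_ids.size)


def segment_method_I(footprint: Footprint, k: float = 5.0) -> Segmentation:
    """Amplitude thresholding: select electrodes with V_n > k * s_n."""
    sel = footprint.v_n > k * footprint.s_n
    return Segmentation(
        neuron=footprint.neuron,
        method="I",
        params={"k": float(k)},
        electrode_ids=footprint.electrode_ids[sel].copy(),
    )


def segment_method_II(
    footprint: Footprint,
    layout: ElectrodeLayout,
    scale: int = 1,
    min_members: int = 5,
    s_min: float | None = None,
    guard_ms: float = DEFAULT_GUARD_MS,
    rng: np.random.Generator | None = None,
) -> Segmentation:
    """Delay-variance segmentation with automatic valley threshold.

    Selects electrodes whose neighborhood delay SD falls below s_min *and*
    whose negative peak appears after the AIS peak (causality gate): a smooth
    delay patch preceding the AIS cannot belong to this neuron's axon.  The
    threshold is estimated from the gated population when not supplied.
    Uses delays only, so the result is invariant to amplitude rescaling.
    """
    dmap = delay_sd_map(footprint, layout, scale=scale, min_members=min_members)
    gate = dmap.tau_ms > footprint.tau_ais_ms + guard_ms
    pool = dmap.valid & gate & np.isfinite(dmap.s_tau_ms)
    if s_min is None:
        s_min = threshold_from_valley(dmap.s_tau_ms[pool], footprint.T, rng=rng)
    sel = pool & (dmap.s_tau_ms < s_min)
    return Segmentation(
        neuron=footprint.neuron,
        method="II",
        params={"s_min_ms": float(s_min), "scale": int(scale), "guard_ms": float(guard_ms)},
        electrode_ids=dmap.electrode_ids[sel].copy(),
    )
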