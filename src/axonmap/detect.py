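"""Filtering, robust noise estimation, threshold spike detection, and
whole-array activity mapping.

Extracellular spikes appear as negative voltage deflections.  Traces are
band-pass filtered (2nd-order Butterworth, 100-3,500 Hz, causal), the noise
level is estimated robustly as s_V = 1.4826 * MAD, and events are negative
local minima below -k * s_V with a dead time that suppresses double counting.
The per-electrode median negative-peak amplitude over a whole-array block
scan ("activity map") localizes axon initial segments, which produce the
largest extracellular signals.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal
from scipy.stats import median_abs_deviation

from .geometry import ElectrodeLayout

DEFAULT_BAND_HZ = (100.0, 3500.0)

#: Initial stretch excluded from noise estimation (causal filter transient).
FILTER_TRANSIENT_MS = 10.0


def bandpass(
    trace: np.ndarray,
    fs_khz: float,
    band_hz: tuple[float, float] = DEFAULT_BAND_HZ,
    order: int = 2,
) -> np.ndarray:
    """Causal Butterworth band-pass along the last axis.

    Requires the Nyquist frequency above the upper band edge (fs > 7 kHz for
    the default band).
    """
    lo, hi = band_hz
    nyq = fs_khz * 1000.0 / 2.0
    if hi >= nyq:
        raise ValueError(
            f"sampling rate {fs_khz} kHz too low for band edge {hi} Hz"
        )
    sos = signal.butter(order, [lo / nyq, hi / nyq], btype="bandpass", output="sos")
    return signal.sosfilt(sos, np.asarray(trace, dtype=float), axis=-1)


def noise_sd(trace: np.ndarray) -> float:
    """Robust standard-deviation estimate s_V = 1.4826 * MAD (μV)."""
    trace = np.asarray(trace, dtype=float)
    if trace.size < 2:
        raise ValueError("need at least 2 samples to estimate noise")
    return float(median_abs_deviation(trace, scale="normal"))


def detect_spikes(
    trace: np.ndarray,
    fs_khz: float,
    k: float = 5.0,
    dead_time_ms: float = 0.5,
    s_v: float | None = None,
) -> pd.DataFrame:
    """Threshold detection of negative spikes on a filtered trace.

    Events are strict local minima below -k * s_V; among events closer than
    the dead time only the first is kept.  Returns a DataFrame with columns
    ``time_ms`` and ``amplitude_uV`` (peak values, negative).
    """
    trace = np.asarray(trace, dtype=float)
    if s_v is None:
        skip = int(round(FILTER_TRANSIENT_MS * fs_khz))
        s_v = noise_sd(trace[skip:] if trace.size > skip + 1 else trace)
    peaks, _ = signal.find_peaks(-trace)
    peaks = peaks[trace[peaks] < -k * s_v]
    if peaks.size:
        dead = dead_time_ms * fs_khz
        kept = [int(peaks[0])]
        for p in peaks[1:]:
            if p - kept[-1] >= dead:
                kept.append(int(p))
        peaks = np.array(kept)
    return pd.DataFrame(
        {"time_ms": peaks / fs_khz, "amplitude_uV": trace[peaks]}
    )


def detect_spikes_block(
    traces: np.ndarray,
    electrode_ids: np.ndarray,
    fs_khz: float,
    k: float = 5.0,
    dead_time_ms: float = 0.5,
    prefilter: bool = True,
) -> pd.DataFrame:
    """Per-electrode detection over a (electrodes x samples) block.

    Returns events as ``electrode_id, time_ms, amplitude_uV``.
    """
    if prefilter:
        traces = bandpass(traces, fs_khz)
    frames = []
    for eid, row in zip(electrode_ids, traces):
        ev = detect_spikes(row, fs_khz, k=k, dead_time_ms=dead_time_ms)
        ev.insert(0, "electrode_id", int(eid))
        frames.append(ev)
    if not frames:
        return pd.DataFrame(columns=["electrode_id", "time_ms", "amplitude_uV"])
    return pd.concat(frames, ignore_index=True)


def activity_map(events: pd.DataFrame, electrode_ids: np.ndarray) -> pd.DataFrame:
    """Spike count and median negative-peak amplitude per electrode.

    Electrodes without events get count 0 and NaN amplitude.  The median (not
    the mean) summarizes peak amplitude: it is insensitive to the occasional
    large spike from a neighboring unit.
    """
    out = pd.DataFrame(
        {
            "electrode_id": np.asarray(electrode_ids, dtype=np.int64),
            "count": 0,
            "median_amp_uV": np.nan,
        }
    ).set_index("electrode_id")
    if len(events):
        g = events.groupby("electrode_id")["amplitude_uV"]
        out.loc[g.count().index, "count"] = g.count()
        out.loc[g.median().index, "median_amp_uV"] = g.median()
    return out.reset_index()


def select_fixed_electrodes(
    amap: pd.DataFrame,
    layout: ElectrodeLayout,
    min_dist_um: float = 100.0,
    max_n: int | None = None,
) -> list[int]:
    """Greedy selection of trigger ("fixed") electrodes from an activity map.

    Electrodes are ranked by most-negative median amplitude (ties broken by
    lower id); after each pick every electrode within ``min_dist_um`` is
    discarded, so no neuron is recorded twice.
    """
    active = amap[(amap["count"] > 0) & amap["median_amp_uV"].notna()]
    ranked = active.sort_values(
        ["median_amp_uV", "electrode_id"], ascending=[True, True]
    )["electrode_id"].to_numpy()
    selected: list[int] = []
    alive = set(int(e) for e in ranked)
    for eid in ranked:
        eid = int(eid)
        if eid not in alive:
            continue
        selected.append(eid)
        if max_n is not None and len(selected) >= max_n:
            break
        p = layout.position_of(eid)
        d = np.linalg.norm(layout.positions - p, axis=1)
        for other in layout.ids[d <= min_dist_um]:
            alive.discard(int(other))
    return selected
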