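"""Per-trigger-electrode spike sorting and spike-triggered-average footprints.

A neuron's "footprint" is the spatial map of its spike-triggered-average (STA)
waveforms across all electrodes.  Trigger events on a fixed electrode are
waveform-extracted (61 samples at 20 kHz, +/-1.5 ms around the negative peak),
reduced to 10 principal components, and clustered with a full-covariance
Gaussian mixture (model order chosen by BIC).  Clusters with enough events
define single neurons; their STAs over each recording configuration are then
assembled into one array-wide footprint, from which the per-electrode
negative-peak amplitude V_n, delay tau_n and averaged-trace noise s_n are
derived.  Averaging n windows shrinks uncorrelated noise by 1/sqrt(n).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import median_abs_deviation
from sklearn.decomposition import PCA
from sklearn.mixture import GaussianMixture

WAVEFORM_PRE_MS = 1.5
WAVEFORM_POST_MS = 1.5

#: STA window relative to the trigger peak (ms).  Most of the window lies
#: after the trigger because axonal delays are positive (0-2 ms typically)
#: while the AIS peak leads the trigger only slightly.
DEFAULT_T_PRE_MS = -2.0
DEFAULT_T_POST_MS = 6.0

#: Exclusion half-width around the STA peak when estimating s_n (ms).
_PEAK_EXCLUDE_MS = 1.0


@dataclass(frozen=True)
class WaveformSet:
    """Event waveforms from one electrode, rows aligned on the negative peak."""

    waveforms: np.ndarray        # (n_events, n_samples)
    times_ms: np.ndarray         # peak time of each kept event
    electrode_id: int
    fs_khz: float
    n_excluded: int = 0          # events too close to the trace edge

    @property
    def n_events(self) -> int:
        return int(self.waveforms.shape[0])


def extract_waveforms(
    trace: np.ndarray,
    event_times_ms: np.ndarray,
    fs_khz: float,
    electrode_id: int = -1,
    pre_ms: float = WAVEFORM_PRE_MS,
    post_ms: float = WAVEFORM_POST_MS,
) -> WaveformSet:
    """Cut fixed-length windows around each event's negative peak.

    Events whose window would run off either trace edge are excluded and
    counted in :attr:`WaveformSet.n_excluded`.
    """
    trace = np.asarray(trace, dtype=float)
    times = np.asarray(event_times_ms, dtype=float)
    npre = int(round(pre_ms * fs_khz))
    npost = int(round(post_ms * fs_khz))
    centers = np.round(times * fs_khz).astype(int)
    ok = (centers - npre >= 0) & (centers + npost < trace.size)
    idx = centers[ok, None] + np.arange(-npre, npost + 1)[None, :]
    return WaveformSet(
        waveforms=trace[idx] if ok.any() else np.empty((0, npre + npost + 1)),
        times_ms=times[ok],
        electrode_id=int(electrode_id),
        fs_khz=fs_khz,
        n_excluded=int((~ok).sum()),
    )


@dataclass(frozen=True)
class PCAFeatures:
    features: np.ndarray          # (n_events, n_components)
    explained_energy: float       # fraction of signal variance retained


def pca_features(waves: WaveformSet, n_components: int = 10) -> PCAFeatures:
    """Project waveforms onto their top principal axes.

    The first 10 components typically retain well over 85% of the signal
    energy, which is what makes the Gaussian-mixture sorting tractable.
    """
    if waves.n_events < n_components:
        raise ValueError(
            f"need >= {n_components} events for PCA, got {waves.n_events}"
        )
    pca = PCA(n_components=n_components)
    feats = pca.fit_transform(waves.waveforms)
    return PCAFeatures(feats, float(pca.explained_variance_ratio_.sum()))


def cluster_spikes(
    features: np.ndarray,
    rng: np.random.Generator | int | None = None,
    k_max: int = 6,
) -> np.ndarray:
    """Hard labels from the best of K = 1..k_max full-covariance Gaussian
    mixtures by BIC.  Deterministic given the seed."""
    features = np.asarray(features, dtype=float)
    if features.shape[0] < 2:
        raise ValueError("need at least 2 events to cluster")
    if isinstance(rng, np.random.Generator):
        seed = int(rng.integers(2**31))
    else:
        seed = int(rng) if rng is not None else 0
    best, best_bic = None, np.inf
    for k in range(1, min(k_max, features.shape[0]) + 1):
        gm = GaussianMixture(
            n_components=k,
            covariance_type="full",
            n_init=3,
            random_state=seed,
            reg_covar=1e-6,
        ).fit(features)
        bic = gm.bic(features)
        if bic < best_bic - 1e-9:
            best, best_bic = gm, bic
    return best.predict(features)


def filter_clusters(labels: np.ndarray, min_events: int = 2500) -> list[int]:
    """Cluster ids with strictly more than ``min_events`` events.

    At 179 configurations of 115 s the default gate of 2,500 events amounts
    to ~14 spikes per configuration (~7 spikes/min); smaller clusters give
    STAs too noisy for delay mapping.
    """
    ids, counts = np.unique(np.asarray(labels), return_counts=True)
    return [int(i) for i, c in zip(ids, counts) if c > min_events]


@dataclass(frozen=True)
class PartialFootprint:
    """STA over the electrodes of a single recording configuration."""

    electrode_ids: np.ndarray
    waveforms: np.ndarray        # (n_electrodes, n_samples)
    n_spikes: int
    fs_khz: float
    t_pre_ms: float
    t_post_ms: float


def spike_triggered_average(
    traces: np.ndarray,
    electrode_ids: np.ndarray,
    trigger_times_ms: np.ndarray,
    fs_khz: float,
    t_pre_ms: float = DEFAULT_T_PRE_MS,
    t_post_ms: float = DEFAULT_T_POST_MS,
) -> PartialFootprint | None:
    """Mean of trigger-aligned windows for every electrode of one block.

    Returns None when no trigger falls fully inside the trace bounds.
    """
    traces = np.asarray(traces, dtype=float)
    npre = int(round(-t_pre_ms * fs_khz))
    npost = int(round(t_post_ms * fs_khz))
    centers = np.round(np.asarray(trigger_times_ms, dtype=float) * fs_khz).astype(int)
    centers = centers[(centers - npre >= 0) & (centers + npost < traces.shape[1])]
    if centers.size == 0:
        return None
    window = np.arange(-npre, npost + 1)
    sta = traces[:, centers[:, None] + window[None, :]].mean(axis=1)
    return PartialFootprint(
        electrode_ids=np.asarray(electrode_ids, dtype=np.int64),
        waveforms=sta,
        n_spikes=int(centers.size),
        fs_khz=fs_khz,
        t_pre_ms=t_pre_ms,
        t_post_ms=t_post_ms,
    )


@dataclass(frozen=True)
class Footprint:
    """Array-wide STA of one neuron with per-electrode derived quantities.

    ``v_n`` is the negative-peak amplitude (positive μV), ``tau_ms`` the peak
    delay relative to the trigger, ``s_n`` the residual noise of the averaged
    trace (1.4826 * MAD outside +/-1 ms of the peak).
    """

    electrode_ids: np.ndarray
    waveforms: np.ndarray            # (n_electrodes, n_samples)
    fs_khz: float
    t_pre_ms: float
    t_post_ms: float
    n_spikes: np.ndarray             # per electrode
    v_n: np.ndarray
    tau_ms: np.ndarray
    s_n: np.ndarray
    ais_electrode: int
    tau_ais_ms: float
    neuron: int | None = None

    @property
    def T(self) -> float:
        """Total STA window length in ms."""
        return self.t_post_ms - self.t_pre_ms

    @property
    def n_electrodes(self) -> int:
        return int(self.electrode_ids.size)

    def index_of(self, eid: int) -> int:
        hits = np.flatnonzero(self.electrode_ids == int(eid))
        if hits.size != 1:
            raise KeyError(f"electrode id {eid} not in footprint")
        return int(hits[0])

    @classmethod
    def from_waveforms(
        cls,
        electrode_ids: np.ndarray,
        waveforms: np.ndarray,
        fs_khz: float,
        t_pre_ms: float,
        t_post_ms: float,
        n_spikes: np.ndarray | int,
        fixed_ids=None,
        neuron: int | None = None,
    ) -> "Footprint":
        electrode_ids = np.asarray(electrode_ids, dtype=np.int64)
        waveforms = np.asarray(waveforms, dtype=float)
        if np.isscalar(n_spikes):
            n_spikes = np.full(electrode_ids.size, int(n_spikes))
        n_spikes = np.asarray(n_spikes, dtype=np.int64)
        imin = waveforms.argmin(axis=1)
        v_n = -waveforms[np.arange(waveforms.shape[0]), imin]
        tau = t_pre_ms + imin / fs_khz
        excl = int(round(_PEAK_EXCLUDE_MS * fs_khz))
        cols = np.arange(waveforms.shape[1])
        masked = np.ma.masked_array(
            waveforms, mask=np.abs(cols[None, :] - imin[:, None]) <= excl
        )
        med = np.ma.median(masked, axis=1)
        s_n = 1.4826 * np.ma.median(np.ma.abs(masked - med[:, None]), axis=1)
        s_n = np.asarray(s_n.filled(0.0), dtype=float)
        if fixed_ids is not None:
            cand = np.array([np.flatnonzero(electrode_ids == int(f))[0] for f in fixed_ids])
        else:
            cand = np.arange(electrode_ids.size)
        ais_idx = int(cand[np.argmax(v_n[cand])])
        return cls(
            electrode_ids=electrode_ids,
            waveforms=waveforms,
            fs_khz=fs_khz,
            t_pre_ms=t_pre_ms,
            t_post_ms=t_post_ms,
            n_spikes=n_spikes,
            v_n=np.asarray(v_n, dtype=float),
            tau_ms=np.asarray(tau, dtype=float),
            s_n=s_n,
            ais_electrode=int(electrode_ids[ais_idx]),
            tau_ais_ms=float(tau[ais_idx]),
            neuron=neuron,
        )


def assemble_footprint(
    partials: list[PartialFootprint],
    fixed_ids=None,
    neuron: int | None = None,
) -> Footprint:
    """Combine per-configuration STAs into one array-wide footprint.

    Fixed electrodes appear in every partial; for an electrode covered more
    than once the version averaged over more spikes wins (with a warning).
    The AIS electrode is the fixed electrode with the largest V_n.
    """
    if not partials:
        raise ValueError("no partial footprints to assemble")
    ref = partials[0]
    shared = {int(f) for f in fixed_ids} if fixed_ids is not None else set()
    best: dict[int, tuple[np.ndarray, int]] = {}
    for p in partials:
        if (p.t_pre_ms, p.t_post_ms, p.fs_khz) != (ref.t_pre_ms, ref.t_post_ms, ref.fs_khz):
            raise ValueError("partial footprints have inconsistent windows")
        for eid, wave in zip(p.electrode_ids, p.waveforms):
            eid = int(eid)
            if eid in best:
                # fixed electrodes are legitimately shared by every partial;
                # a duplicated variable electrode indicates a planning bug
                if eid not in shared and not np.array_equal(best[eid][0], wave):
                    warnings.warn(
                        f"electrode {eid} covered twice with conflicting data; "
                        "keeping the higher-spike-count version",
                        stacklevel=2,
                    )
                if p.n_spikes <= best[eid][1]:
                    continue
            best[eid] = (wave, p.n_spikes)
    eids = np.array(sorted(best), dtype=np.int64)
    waves = np.stack([best[int(e)][0] for e in eids])
    nsp = np.array([best[int(e)][1] for e in eids], dtype=np.int64)
    return Footprint.from_waveforms(
        eids, waves, ref.fs_khz, ref.t_pre_ms, ref.t_post_ms, nsp,
        fixed_ids=fixed_ids, neuron=neuron,
    )


def footprint_similarity(a: Footprint, b: Footprint, snr: float = 3.0) -> float:
    """Cosine similarity of amplitude maps, restricted to electrodes where
    either footprint's V_n exceeds ``snr`` times its averaged-trace noise."""
    if not np.array_equal(a.electrode_ids, b.electrode_ids):
        raise ValueError("footprints live on different electrode sets")
    mask = (a.v_n > snr * a.s_n) | (b.v_n > snr * b.s_n)
    if not mask.any():
        return 0.0
    va, vb = a.v_n[mask], b.v_n[mask]
    denom = np.linalg.norm(va) * np.linalg.norm(vb)
    return float(va @ vb / denom) if denom > 0 else 0.0


def merge_duplicate_footprints(
    footprints: list[Footprint],
    similarity_threshold: float = 0.95,
) -> list[Footprint]:
    """Merge footprints that are near-identical amplitude maps.

    Split clusters of the same neuron produce the same footprint; pairs whose
    masked cosine similarity exceeds the threshold are pooled (spike-count
    weighted average of waveforms) and the derived maps recomputed.  This is
    an automated surrogate for a manual-merging step.
    """
    n = len(footprints)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if footprint_similarity(footprints[i], footprints[j]) > similarity_threshold:
                parent[find(j)] = find(i)

    groups: dict[int, list[Footprint]] = {}
    for i, fp in enumerate(footprints):
        groups.setdefault(find(i), []).append(fp)

    merged = []
    for members in groups.values():
        if len(members) == 1:
            merged.append(members[0])
            continue
        ref = members[0]
        w = np.stack([m.n_spikes for m in members])          # (m, e)
        waves = np.stack([m.waveforms for m in members])     # (m, e, s)
        tot = w.sum(axis=0)
        avg = (waves * w[:, :, None]).sum(axis=0) / np.maximum(tot, 1)[:, None]
        merged.append(
            Footprint.from_waveforms(
                ref.electrode_ids, avg, ref.fs_khz, ref.t_pre_ms, ref.t_post_ms,
                tot, neuron=ref.neuron,
            )
        )
    merged.sort(key=lambda f: (f.neuron is None, f.neuron))
    return merged
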