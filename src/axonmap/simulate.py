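"""Seeded synthetic-data generator with ground truth.

Emulates exactly the statistical structure the delay-variance segmentation
relies on: branching axonal arbors grown as jittered random walks, conduction
delays proportional to path length (0.3-0.44 m/s for short-range cortical
axons), negative-dominant biphasic spike templates whose amplitude decays
with distance to the arbor, Poisson firing, and additive Gaussian noise
(about 5 μV RMS total in culture).  All randomness flows from one explicit
seed, so every operation is bit-reproducible.

The simulator is a forward model, not a biophysical one: no cable equations,
no myelination, no electrode impedance.  Its role is to provide footprints
and raw recordings whose ground truth (arbor geometry, delays, event times)
is known exactly.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .geometry import ElectrodeLayout
from .io import RecordingBlock
from .sort_sta import DEFAULT_T_POST_MS, DEFAULT_T_PRE_MS, Footprint


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic arbor/recording generator.

    Amplitudes are single-trial negative-peak values in μV; axonal signals
    sit at 5-20 μV against ~5 μV RMS noise, the AIS an order of magnitude
    higher.  ``amplitude_floor_uV`` zeroes contributions that would be far
    below the recording chain's own noise, so distant electrodes are pure
    noise.  ``ais_delay_ms`` is slightly negative: the AIS peak leads the
    trigger peak.
    """

    velocity_m_s: float = 0.35
    step_um: float = 10.0
    angular_jitter_rad: float = 0.35
    branch_prob: float = 0.02
    max_length_um: float = 2000.0
    ais_amplitude_uV: float = 150.0
    axon_amplitude_uV: float = 10.0
    waveform_width_ms: float = 0.5
    decay_lambda_um: float = 15.0
    amplitude_floor_uV: float = 1.0
    noise_sd_uV: float = 5.0
    firing_rate_hz: float = 2.0
    ais_delay_ms: float = -0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.velocity_m_s < 10:
            raise ValueError("conduction velocity out of range")
        if not 0 <= self.branch_prob <= 1:
            raise ValueError("branch_prob must be in [0, 1]")
        for name in ("step_um", "max_length_um", "decay_lambda_um", "waveform_width_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sd_uV < 0 or self.firing_rate_hz < 0:
            raise ValueError("noise and firing rate must be non-negative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class Branch:
    points: np.ndarray        # (m, 2) μm
    path_length: np.ndarray   # (m,) cumulative from the soma, μm
    parent: int               # index of parent branch, -1 for the root


@dataclass(frozen=True)
class SimulatedArbor:
    """Branching polyline ground truth with per-point path length."""

    soma: np.ndarray
    branches: tuple

    @property
    def n_branches(self) -> int:
        return len(self.branches)

    @property
    def total_length_um(self) -> float:
        return float(
            sum(b.path_length[-1] - b.path_length[0] for b in self.branches)
        )

    def points(self) -> np.ndarray:
        return np.concatenate([b.points for b in self.branches])

    def path_lengths(self) -> np.ndarray:
        return np.concatenate([b.path_length for b in self.branches])


def grow_arbor(
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    soma=(0.0, 0.0),
) -> SimulatedArbor:
    """Grow a branching arbor as a jittered random walk.

    Active branch tips advance one fixed-length step in round-robin order
    until the total arbor length reaches the budget; each step spawns a
    side branch with probability ``branch_prob`` (at roughly +/-60 degrees,
    as axon collaterals do), so the expected branch count is
    1 + branch_prob * n_steps.
    """
    rng = rng if rng is not None else cfg.rng()
    soma = np.asarray(soma, dtype=float)
    # mutable growth state: [points, plens, parent index, heading]
    root = [[soma.copy()], [0.0], -1, float(rng.uniform(0, 2 * np.pi))]
    branches = [root]
    queue = deque([0])
    total = 0.0
    while queue and total + cfg.step_um <= cfg.max_length_um:
        bi = queue.popleft()
        b = branches[bi]
        b[3] += float(rng.normal(0.0, cfg.angular_jitter_rad))
        step = cfg.step_um * np.array([np.cos(b[3]), np.sin(b[3])])
        b[0].append(b[0][-1] + step)
        b[1].append(b[1][-1] + cfg.step_um)
        total += cfg.step_um
        if rng.uniform() < cfg.branch_prob:
            sign = 1.0 if rng.uniform() < 0.5 else -1.0
            child = [
                [b[0][-1].copy()],
                [b[1][-1]],
                bi,
                b[3] + sign * np.pi / 3 + float(rng.normal(0.0, cfg.angular_jitter_rad)),
            ]
            branches.append(child)
            queue.append(len(branches) - 1)
        queue.append(bi)
    return SimulatedArbor(
        soma=soma,
        branches=tuple(
            Branch(
                points=np.asarray(pts, dtype=float),
                path_length=np.asarray(plen, dtype=float),
                parent=parent,
            )
            for pts, plen, parent, _ in branches
        ),
    )


def arbor_delays(arbor: SimulatedArbor, c_m_s: float) -> list[np.ndarray]:
    """Conduction delay (ms) at every arbor point: path length / velocity.

    With lengths in μm and c in m/s (= mm/ms), delay_ms = L / (1000 c).
    """
    if c_m_s <= 0:
        raise ValueError("conduction velocity must be positive")
    return [b.path_length / (1000.0 * c_m_s) for b in arbor.branches]


def _resample_branch(b: Branch, spacing_um: float) -> tuple[np.ndarray, np.ndarray]:
    length = b.path_length[-1] - b.path_length[0]
    if length <= 0:
        return b.points[:1], b.path_length[:1]
    n = int(np.ceil(length / spacing_um)) + 1
    plen = np.linspace(b.path_length[0], b.path_length[-1], n)
    x = np.interp(plen, b.path_length, b.points[:, 0])
    y = np.interp(plen, b.path_length, b.points[:, 1])
    return np.column_stack([x, y]), plen


def ground_truth_points(arbor: SimulatedArbor, spacing_um: float) -> np.ndarray:
    """Arbor polylines resampled at most ``spacing_um`` apart: the reference
    point set A for Hausdorff evaluation."""
    if spacing_um <= 0:
        raise ValueError("spacing must be positive")
    return np.concatenate([_resample_branch(b, spacing_um)[0] for b in arbor.branches])


def _arbor_cloud(arbor: SimulatedArbor, cfg: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    spacing = min(2.0, cfg.step_um)
    pts, plen = zip(*(_resample_branch(b, spacing) for b in arbor.branches))
    return np.concatenate(pts), np.concatenate(plen)


def _template(t_ms: np.ndarray, tau_ms, width_ms: float) -> np.ndarray:
    """Negative-dominant biphasic pulse with its minimum at tau.

    Difference of Gaussians: sharp negative lobe (sigma = width/5) followed
    by a smaller, broader positive rebound.
    """
    tau = np.atleast_1d(np.asarray(tau_ms, dtype=float))[:, None]
    sg = width_ms / 5.0
    dt = t_ms[None, :] - tau
    return -np.exp(-(dt**2) / (2 * sg**2)) + 0.35 * np.exp(
        -((dt - 3 * sg) ** 2) / (2 * (1.5 * sg) ** 2)
    )


def _noiseless_waveforms(
    arbor: SimulatedArbor,
    layout: ElectrodeLayout,
    cfg: SimConfig,
    t_pre_ms: float,
    t_post_ms: float,
    fs_khz: float,
) -> np.ndarray:
    """(electrodes x samples) template field of one neuron, no noise.

    Each electrode sees the waveform of the *nearest* arbor point, at that
    point's conduction delay, scaled by A0 / (1 + (d/lambda)^2); the soma
    adds the (much larger) AIS signal slightly before the trigger.
    Amplitudes below the floor are treated as zero.
    """
    if arbor.n_branches == 0:
        raise ValueError("arbor is empty")
    cloud, plen = _arbor_cloud(arbor, cfg)
    delays = plen / (1000.0 * cfg.velocity_m_s)
    d, idx = cKDTree(cloud).query(layout.positions)
    amp = cfg.axon_amplitude_uV / (1.0 + (d / cfg.decay_lambda_um) ** 2)
    amp[amp < cfg.amplitude_floor_uV] = 0.0
    d_soma = np.linalg.norm(layout.positions - arbor.soma, axis=1)
    amp_ais = cfg.ais_amplitude_uV / (1.0 + (d_soma / cfg.decay_lambda_um) ** 2)
    amp_ais[amp_ais < cfg.amplitude_floor_uV] = 0.0

    n_samples = int(round((t_post_ms - t_pre_ms) * fs_khz)) + 1
    t = t_pre_ms + np.arange(n_samples) / fs_khz
    waves = amp[:, None] * _template(t, delays[idx], cfg.waveform_width_ms)
    waves += amp_ais[:, None] * _template(t, cfg.ais_delay_ms, cfg.waveform_width_ms)
    return waves


def render_footprint(
    arbor: SimulatedArbor,
    layout: ElectrodeLayout,
    cfg: SimConfig,
    n_spikes: int = 14,
    rng: np.random.Generator | None = None,
    t_pre_ms: float = DEFAULT_T_PRE_MS,
    t_post_ms: float = DEFAULT_T_POST_MS,
    fs_khz: float = 20.0,
    neuron: int | None = None,
) -> Footprint:
    """Forward-model an n-spike spike-triggered-average footprint.

    Residual noise on the averaged traces is noise_sd / sqrt(n_spikes)
    (0.27x the single-trial noise at the default 14 spikes).
    """
    if n_spikes < 1:
        raise ValueError("n_spikes must be >= 1")
    rng = rng if rng is not None else cfg.rng()
    waves = _noiseless_waveforms(arbor, layout, cfg, t_pre_ms, t_post_ms, fs_khz)
    if cfg.noise_sd_uV > 0:
        waves = waves + rng.normal(
            0.0, cfg.noise_sd_uV / np.sqrt(n_spikes), size=waves.shape
        )
    return Footprint.from_waveforms(
        layout.ids, waves, fs_khz, t_pre_ms, t_post_ms, n_spikes, neuron=neuron
    )


def simulate_recording(
    arbors: list[SimulatedArbor],
    layout: ElectrodeLayout,
    cfg: SimConfig,
    duration_s: float,
    fs_khz: float = 20.0,
    rng: np.random.Generator | None = None,
    config_index: int = 0,
    t_pre_ms: float = DEFAULT_T_PRE_MS,
    t_post_ms: float = DEFAULT_T_POST_MS,
) -> tuple[RecordingBlock, list[np.ndarray]]:
    """Raw multichannel recording: Poisson spike trains insert each neuron's
    noiseless template field into Gaussian background noise.

    Returns the block plus the true event times (ms) per neuron.
    """
    if duration_s <= 0 or fs_khz <= 0:
        raise ValueError("duration and sampling rate must be positive")
    rng = rng if rng is not None else cfg.rng()
    n_samples = int(round(duration_s * fs_khz * 1000.0))
    traces = rng.standard_normal((layout.n, n_samples), dtype=np.float32)
    traces *= np.float32(cfg.noise_sd_uV)
    event_times: list[np.ndarray] = []
    offset = int(round(t_pre_ms * fs_khz))
    for arbor in arbors:
        waves = _noiseless_waveforms(arbor, layout, cfg, t_pre_ms, t_post_ms, fs_khz)
        waves32 = waves.astype(np.float32)
        n_ev = rng.poisson(cfg.firing_rate_hz * duration_s)
        times = np.sort(rng.uniform(0.0, duration_s * 1000.0, size=n_ev))
        for t in times:
            start = int(round(t * fs_khz)) + offset
            lo, hi = max(start, 0), min(start + waves.shape[1], n_samples)
            if lo < hi:
                traces[:, lo:hi] += waves32[:, lo - start : hi - start]
        event_times.append(times)
    block = RecordingBlock(
        traces=traces, electrode_ids=layout.ids.copy(), fs_khz=fs_khz,
        index=config_index,
    )
    return block, event_times
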