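"""Switch-matrix recording-configuration arithmetic and batch construction.

A switch-matrix HD-MEA connects e electrodes to a << e amplifiers, so the
array is tiled by successive recording configurations.  Keeping n amplifiers
on fixed trigger electrodes (one per neuron) and cycling the remaining a - n
amplifiers through the other electrodes scans the whole array in

    c(n) = ceil((e - n) / (a - n))

configurations, i.e. C(n) = c(n)/n configurations per neuron on average.
C(n) is minimized near n = a/2: half the amplifiers should sit on fixed
electrodes.  This module also carries the simple throughput and noise-budget
arithmetic used to compare chip generations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


def _check_ean(e: int, a: int, n: int) -> None:
    if not (0 <= n < a <= e):
        raise ValueError(f"need 0 <= n < a <= e, got e={e}, a={a}, n={n}")


def n_configurations(e: int, a: int, n: int) -> int:
    """Number of configurations to scan e electrodes with a amplifiers and n
    fixed electrodes: ceil((e - n)/(a - n)).  Ceiling, because a fractional
    configuration still has to be recorded for full coverage."""
    _check_ean(e, a, n)
    return math.ceil((e - n) / (a - n))


def mean_configs_per_neuron(e: int, a: int, n: int) -> float:
    """Un-rounded average number of configurations per neuron,
    C(n) = (e - n) / ((a - n) * n)."""
    _check_ean(e, a, n)
    if n == 0:
        raise ValueError("n must be >= 1")
    return (e - n) / ((a - n) * n)


def optimal_fixed_count(e: int, a: int) -> int:
    """Fixed-electrode count minimizing C(n) over 0 < n < a.

    The continuous relaxation has its minimum at n* = e(1 - sqrt(1 - a/e))
    (approximately a/2 for e >> a); the better of floor/ceil is returned.
    """
    if a < 2:
        raise ValueError("need at least 2 amplifiers")
    _check_ean(e, a, 1)
    n_star = e * (1.0 - math.sqrt(1.0 - a / e))
    cands = {min(max(int(f(n_star)), 1), a - 1) for f in (math.floor, math.ceil)}
    return min(cands, key=lambda n: (mean_configs_per_neuron(e, a, n), n))


@dataclass(frozen=True)
class Configuration:
    """One switch-matrix configuration: fixed + this batch's variable ids."""

    index: int
    fixed: tuple[int, ...]
    variable: tuple[int, ...]

    def __post_init__(self) -> None:
        if set(self.fixed) & set(self.variable):
            raise ValueError("fixed and variable electrode sets overlap")

    @property
    def electrodes(self) -> tuple[int, ...]:
        return self.fixed + self.variable


def build_configurations(
    electrode_ids: np.ndarray,
    fixed_ids,
    a: int,
    rng: np.random.Generator,
) -> list[Configuration]:
    """Randomly partition the non-fixed electrodes into batches of size
    <= a - |fixed|; every non-fixed electrode appears in exactly one batch."""
    fixed = tuple(int(i) for i in fixed_ids)
    if len(fixed) >= a:
        raise ValueError("need |fixed| < amplifier count")
    rest = np.array([int(i) for i in electrode_ids if int(i) not in set(fixed)])
    rest = rest[rng.permutation(rest.size)]
    batch = a - len(fixed)
    return [
        Configuration(index=i, fixed=fixed, variable=tuple(int(v) for v in rest[s : s + batch]))
        for i, s in enumerate(range(0, rest.size, batch))
    ]


# --- throughput and noise-budget arithmetic -------------------------------

def spikes_per_configuration(total_events: int, n_configs: int) -> float:
    """Average events per configuration for a cluster-size gate, e.g.
    2,500 events over 179 configurations ~ 14 spikes each."""
    if n_configs < 1:
        raise ValueError("n_configs must be >= 1")
    return total_events / n_configs


def sta_noise_factor(n_spikes: int) -> float:
    """Noise reduction of an n-spike spike-triggered average, 1/sqrt(n)."""
    if n_spikes < 1:
        raise ValueError("n_spikes must be >= 1")
    return 1.0 / math.sqrt(n_spikes)


def total_scan_time_s(n_configs: int, per_config_s: float) -> float:
    return n_configs * per_config_s


def time_per_neuron_s(n_configs: int, per_config_s: float, n_neurons: int) -> float:
    if n_neurons < 1:
        raise ValueError("n_neurons must be >= 1")
    return total_scan_time_s(n_configs, per_config_s) / n_neurons


def total_rms_noise(components_uv) -> float:
    """Root-sum-square of uncorrelated noise sources (μV RMS): circuit,
    electrode and biological background noise add in quadrature."""
    c = np.asarray(components_uv, dtype=float)
    if np.any(c < 0):
        raise ValueError("noise components must be non-negative")
    return float(np.sqrt(np.sum(c**2)))


def averaging_time_factor(noise_uv: float, reference_noise_uv: float) -> float:
    """Factor by which recording time must grow to reach the same
    post-averaging noise as a reference chip: (noise/reference)^2."""
    if noise_uv <= 0 or reference_noise_uv <= 0:
        raise ValueError("noise levels must be positive")
    return (noise_uv / reference_noise_uv) ** 2
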