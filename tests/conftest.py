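"""Shared fixtures: layouts and seeded simulated neurons.

The expensive fixtures are session-scoped so several tests can reuse the
same simulated population.
"""

import numpy as np
import pytest

from axonmap import (
    SimConfig,
    build_hex_layout,
    compare_methods,
    grow_arbor,
    render_footprint,
)


@pytest.fixture(scope="session")
def hex40():
    """40 x 40 lattice at the standard 18 μm pitch (720 x 608 μm area)."""
    return build_hex_layout(40, 40, 18.0)


@pytest.fixture(scope="session")
def hex10():
    return build_hex_layout(10, 10, 18.0)


@pytest.fixture(scope="session")
def simulated_population(hex40):
    """20 seeded neurons at the standard operating point: 5 μV total noise
    averaged over 14 spikes, T = 8 ms, c = 0.35 m/s, 18 μm pitch.

    Returns a list of (footprint, arbor) pairs.
    """
    out = []
    for seed in range(20):
        sim = SimConfig(seed=seed, velocity_m_s=0.35)
        rng = np.random.default_rng(seed)
        soma = hex40.positions.max(axis=0) * rng.uniform(0.3, 0.7, 2)
        arbor = grow_arbor(sim, rng, soma=soma)
        fp = render_footprint(arbor, hex40, sim, n_spikes=14, rng=rng, neuron=seed)
        out.append((fp, arbor))
    return out


@pytest.fixture(scope="session")
def population_report(hex40, simulated_population):
    """Method comparison table over the simulated population."""
    fps = [fp for fp, _ in simulated_population]
    return compare_methods(fps, hex40, rng=np.random.default_rng(12345))
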