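"""End-to-end workflow: simulate -> scan -> plan -> record -> sort -> STA ->
segment -> evaluate, with seeded determinism and JSON run logs.

The stages mirror the experimental workflow on a switch-matrix HD-MEA: a
whole-array block scan locates AISs via the activity map; fixed trigger
electrodes are picked greedily with a 100 μm exclusion radius; the remaining
electrodes are tiled into random batches; each configuration is recorded,
spikes on the fixed electrodes are sorted (pooled over configurations) and
spike-triggered averages are assembled into per-neuron footprints, which are
then segmented by both methods and evaluated against the simulated ground
truth.

Sorting is two-pass: configurations are recorded (deterministically seeded),
trigger waveforms pooled and clustered once per fixed electrode, then the
same configurations are regenerated to compute the per-cluster STAs.  This
keeps only one configuration's traces in memory at a time.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .detect import (
    activity_map,
    bandpass,
    detect_spikes,
    detect_spikes_block,
    select_fixed_electrodes,
)
from .evaluate import clip_to_layout, compare_methods
from .geometry import ElectrodeLayout, build_hex_layout
from .io import PipelineConfig, Session, write_container
from .plan import build_configurations, n_configurations
from .segment import segment_method_I, segment_method_II
from .simulate import SimConfig, SimulatedArbor, grow_arbor, ground_truth_points, simulate_recording
from .sort_sta import (
    WaveformSet,
    assemble_footprint,
    cluster_spikes,
    extract_waveforms,
    filter_clusters,
    merge_duplicate_footprints,
    pca_features,
    spike_triggered_average,
)


def _place_somas(
    layout: ElectrodeLayout, n: int, min_dist_um: float, rng: np.random.Generator
) -> np.ndarray:
    """Rejection-sample soma positions on interior electrodes, pairwise
    farther apart than the fixed-electrode exclusion radius."""
    span = layout.positions.max(axis=0)
    margin = 0.15
    lo, hi = margin * span, (1 - margin) * span
    inner = np.flatnonzero(
        np.all((layout.positions >= lo) & (layout.positions <= hi), axis=1)
    )
    chosen: list[int] = []
    for _ in range(10000):
        cand = int(rng.choice(inner))
        p = layout.positions[cand]
        if all(
            np.linalg.norm(p - layout.positions[c]) > 1.5 * min_dist_um
            for c in chosen
        ):
            chosen.append(cand)
        if len(chosen) == n:
            return layout.positions[np.array(chosen)]
    raise RuntimeError("could not place somas far enough apart; enlarge the array")


def run_all(
    outdir,
    seed: int = 0,
    n_neurons: int = 3,
    n_rows: int = 24,
    n_cols: int = 28,
    pitch_um: float = 18.0,
    amplifiers: int = 128,
    scan_duration_s: float = 10.0,
    config_duration_s: float = 20.0,
    sim: SimConfig | None = None,
    cfg: PipelineConfig | None = None,
    write_blocks: bool = False,
) -> dict:
    """Run the full pipeline on a seeded simulation; returns a summary dict
    and writes ``session.h5``, ``report.csv`` and ``log.json`` to ``outdir``.

    Defaults are desk-scale; pass larger arrays/durations to approach the
    full-experiment regime.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = cfg if cfg is not None else PipelineConfig(seed=seed)
    sim = sim if sim is not None else SimConfig(seed=seed)
    ss = np.random.SeedSequence(seed)
    (s_place, s_grow, s_scan, s_plan, s_cluster, s_eval, s_configs) = ss.spawn(7)

    layout = build_hex_layout(n_rows, n_cols, pitch_um)
    rng_place = np.random.default_rng(s_place)
    somas = _place_somas(layout, n_neurons, cfg.exclusion_um, rng_place)
    rng_grow = np.random.default_rng(s_grow)
    arbors = [grow_arbor(sim, rng_grow, soma=s) for s in somas]
    truth = {i: ground_truth_points(a, spacing_um=5.0) for i, a in enumerate(arbors)}

    # --- whole-array activity scan ---------------------------------------
    scan_block, _ = simulate_recording(
        arbors, layout, sim, scan_duration_s, fs_khz=cfg.fs_khz,
        rng=np.random.default_rng(s_scan),
    )
    events = detect_spikes_block(
        scan_block.traces, scan_block.electrode_ids, cfg.fs_khz,
        k=cfg.detect_k, dead_time_ms=cfg.dead_time_ms,
    )
    amap = activity_map(events, layout.ids)
    fixed = select_fixed_electrodes(amap, layout, min_dist_um=cfg.exclusion_um)
    if not fixed:
        raise RuntimeError("no active electrodes found in the scan")
    fixed = fixed[: min(len(fixed), amplifiers - 1)]

    # --- configuration batches -------------------------------------------
    configs = build_configurations(
        layout.ids, fixed, amplifiers, np.random.default_rng(s_plan)
    )

    def record(config, child_seed):
        sub = layout.subset(config.electrodes)
        block, _ = simulate_recording(
            arbors, sub, sim, config_duration_s, fs_khz=cfg.fs_khz,
            rng=np.random.default_rng(child_seed), config_index=config.index,
        )
        return sub, bandpass(block.traces, cfg.fs_khz, cfg.band_hz)

    config_seeds = s_configs.spawn(len(configs))

    # pass 1: trigger events and waveforms on the fixed electrodes
    waves: dict[int, list[WaveformSet]] = {e: [] for e in fixed}
    for config, child in zip(configs, config_seeds):
        sub, filtered = record(config, child)
        for eid in fixed:
            row = filtered[sub.index_of(eid)]
            ev = detect_spikes(row, cfg.fs_khz, k=cfg.detect_k, dead_time_ms=cfg.dead_time_ms)
            waves[eid].append(
                extract_waveforms(row, ev["time_ms"].to_numpy(), cfg.fs_khz, eid)
            )

    # cluster pooled waveforms per fixed electrode
    rng_cluster = np.random.default_rng(s_cluster)
    neuron_events: dict[int, dict[int, np.ndarray]] = {}   # neuron -> config -> times
    neuron_of: list[tuple[int, int]] = []                  # (fixed electrode, cluster)
    for eid in fixed:
        all_waves = np.concatenate([w.waveforms for w in waves[eid]]) if waves[eid] else np.empty((0, 61))
        counts = [w.n_events for w in waves[eid]]
        if all_waves.shape[0] < 10:
            continue
        pooled = WaveformSet(
            waveforms=all_waves,
            times_ms=np.concatenate([w.times_ms for w in waves[eid]]),
            electrode_id=eid,
            fs_khz=cfg.fs_khz,
        )
        feats = pca_features(pooled, n_components=min(10, all_waves.shape[0]))
        labels = cluster_spikes(feats.features, rng_cluster)
        accepted = filter_clusters(labels, min_events=cfg.min_events)
        bounds = np.cumsum([0] + counts)
        for cl in accepted:
            nid = len(neuron_of)
            neuron_of.append((eid, cl))
            per_config: dict[int, np.ndarray] = {}
            for ci, w in enumerate(waves[eid]):
                sel = labels[bounds[ci] : bounds[ci + 1]] == cl
                per_config[configs[ci].index] = w.times_ms[sel]
            neuron_events[nid] = per_config

    # pass 2: regenerate each configuration, STA per neuron
    partials: dict[int, list] = {nid: [] for nid in neuron_events}
    for config, child in zip(configs, config_seeds):
        sub, filtered = record(config, child)
        for nid, per_config in neuron_events.items():
            times = per_config.get(config.index, np.empty(0))
            p = spike_triggered_average(
                filtered, sub.ids, times, cfg.fs_khz,
                t_pre_ms=cfg.t_pre_ms, t_post_ms=cfg.t_post_ms,
            )
            if p is not None:
                partials[nid].append(p)

    footprints = [
        assemble_footprint(parts, fixed_ids=fixed, neuron=nid)
        for nid, parts in partials.items()
        if parts
    ]
    footprints = merge_duplicate_footprints(footprints)

    # --- segmentation and evaluation --------------------------------------
    rng_eval = np.random.default_rng(s_eval)
    segmentations = {}
    for fp in footprints:
        seg_i = segment_method_I(fp, k=cfg.detect_k)
        seg_ii = segment_method_II(
            fp, layout, scale=cfg.scale, min_members=cfg.min_members,
            rng=rng_eval,
        )
        segmentations[(fp.neuron, "I")] = seg_i
        segmentations[(fp.neuron, "II")] = seg_ii

    # associate each footprint with the nearest simulated soma
    gt_by_neuron = {}
    for fp in footprints:
        ais_pos = layout.position_of(fp.ais_electrode)
        nearest = int(np.argmin(np.linalg.norm(somas - ais_pos, axis=1)))
        gt_by_neuron[fp.neuron] = clip_to_layout(truth[nearest], layout)
    report = compare_methods(
        footprints, layout, rng=rng_eval, ground_truths=gt_by_neuron,
        scale=cfg.scale, min_members=cfg.min_members, k=cfg.detect_k,
    )
    report.to_csv(outdir / "report.csv", index=False)

    session = Session(
        layout=layout,
        blocks=[scan_block] if write_blocks else [],
        events=events,
        footprints={fp.neuron: fp for fp in footprints},
        segmentations=segmentations,
        ground_truth=truth,
    )
    write_container(outdir / "session.h5", session)

    arbors_over_50 = sum(
        1 for (nid, m), seg in segmentations.items()
        if m == "II" and seg.n_electrodes > 50
    )
    summary = {
        "seed": seed,
        "version": __version__,
        "pipeline_config": {**asdict(cfg), "band_hz": list(cfg.band_hz)},
        "sim_config": asdict(sim),
        "n_electrodes": layout.n,
        "n_configurations": len(configs),
        "n_configurations_formula": n_configurations(layout.n, amplifiers, len(fixed)),
        "fixed_electrodes": [int(e) for e in fixed],
        "n_neurons_simulated": n_neurons,
        "n_footprints": len(footprints),
        "electrodes_selected": {
            f"{nid}_{m}": seg.n_electrodes for (nid, m), seg in segmentations.items()
        },
        "arbors_over_50_electrodes": arbors_over_50,
    }
    with open(outdir / "log.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary
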