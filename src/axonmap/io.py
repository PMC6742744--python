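"""HDF5 session container, pipeline configuration and side formats.

No standard interchange format exists for switch-matrix HD-MEA sessions, so
the pipeline uses a small self-describing HDF5 layout:

    /layout                 ids, xy (μm), attr pitch_um
    /blocks/<k>/            traces (float32 μV), electrode_ids,
                            attrs fs_khz, index
    /events                 electrode_id, time_ms, amplitude_uV
    /neurons/<id>/footprint waveforms, v_n, tau_ms, s_n, electrode_ids,
                            n_spikes_per_electrode; attrs t_pre_ms,
                            t_post_ms, fs_khz, ais_electrode, tau_ais_ms,
                            n_spikes
    /neurons/<id>/segmentation_<method>
                            electrodes; attrs method, params (JSON)
    /ground_truth/<id>      points (n, 2) μm

Times are milliseconds (float64), amplitudes microvolts (float32),
electrode indexing 0-based throughout.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from .geometry import ElectrodeLayout
from .segment import Segmentation
from .sort_sta import Footprint


class ContainerFormatError(Exception):
    """Raised when a session container is missing required structure."""


@dataclass(frozen=True)
class RecordingBlock:
    """Voltage traces of one recording configuration (electrodes x samples, μV)."""

    traces: np.ndarray
    electrode_ids: np.ndarray
    fs_khz: float
    index: int = 0

    @property
    def n_samples(self) -> int:
        return int(self.traces.shape[1])

    @property
    def duration_ms(self) -> float:
        return self.n_samples / self.fs_khz


@dataclass
class PipelineConfig:
    """Every tunable of the analysis pipeline, with the standard defaults:
    100-3,500 Hz band, 5*s_V detection threshold, 0.5 ms dead time, 8 ms STA
    window, 2,500-event cluster gate, 100 μm fixed-electrode exclusion."""

    fs_khz: float = 20.0
    band_hz: tuple = (100.0, 3500.0)
    detect_k: float = 5.0
    dead_time_ms: float = 0.5
    t_pre_ms: float = -2.0
    t_post_ms: float = 6.0
    min_events: int = 2500
    scale: int = 1
    min_members: int = 5
    exclusion_um: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.t_pre_ms < 0 < self.t_post_ms):
            raise ValueError("need t_pre_ms < 0 < t_post_ms")
        for name in ("fs_khz", "detect_k", "dead_time_ms", "exclusion_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = json.load(fh)
        if "band_hz" in d:
            d["band_hz"] = tuple(d["band_hz"])
        return cls(**d)


@dataclass
class Session:
    """In-memory view of one container."""

    layout: ElectrodeLayout | None = None
    blocks: list[RecordingBlock] = field(default_factory=list)
    events: pd.DataFrame | None = None
    footprints: dict[int, Footprint] = field(default_factory=dict)
    segmentations: dict[tuple[int, str], Segmentation] = field(default_factory=dict)
    ground_truth: dict[int, np.ndarray] = field(default_factory=dict)

    @property
    def neurons(self) -> list[int]:
        return sorted(self.footprints)


def write_container(path, session: Session) -> None:
    with h5py.File(path, "w") as f:
        if session.layout is not None:
            g = f.create_group("layout")
            g.create_dataset("ids", data=session.layout.ids)
            g.create_dataset("xy", data=session.layout.positions)
            g.attrs["pitch_um"] = session.layout.pitch
        for blk in session.blocks:
            g = f.create_group(f"blocks/{blk.index}")
            g.create_dataset("traces", data=blk.traces.astype(np.float32))
            g.create_dataset("electrode_ids", data=blk.electrode_ids)
            g.attrs["fs_khz"] = blk.fs_khz
            g.attrs["index"] = blk.index
        if session.events is not None:
            g = f.create_group("events")
            g.create_dataset("electrode_id", data=session.events["electrode_id"].to_numpy(np.int64))
            g.create_dataset("time_ms", data=session.events["time_ms"].to_numpy(np.float64))
            g.create_dataset("amplitude_uV", data=session.events["amplitude_uV"].to_numpy(np.float32))
        for nid, fp in session.footprints.items():
            g = f.create_group(f"neurons/{nid}/footprint")
            g.create_dataset("waveforms", data=fp.waveforms.astype(np.float32))
            g.create_dataset("electrode_ids", data=fp.electrode_ids)
            g.create_dataset("v_n", data=fp.v_n.astype(np.float32))
            g.create_dataset("tau_ms", data=fp.tau_ms.astype(np.float64))
            g.create_dataset("s_n", data=fp.s_n.astype(np.float32))
            g.create_dataset("n_spikes_per_electrode", data=fp.n_spikes)
            g.attrs.update(
                t_pre_ms=fp.t_pre_ms, t_post_ms=fp.t_post_ms, fs_khz=fp.fs_khz,
                ais_electrode=fp.ais_electrode, tau_ais_ms=fp.tau_ais_ms,
                n_spikes=int(np.median(fp.n_spikes)),
            )
        for (nid, method), seg in session.segmentations.items():
            g = f.create_group(f"neurons/{nid}/segmentation_{method}")
            g.create_dataset("electrodes", data=seg.electrode_ids)
            g.attrs["method"] = method
            g.attrs["params"] = json.dumps(seg.params)
        for nid, pts in session.ground_truth.items():
            f.create_dataset(f"ground_truth/{nid}", data=np.asarray(pts, dtype=float))


def _require(f, key: str):
    if key not in f:
        raise ContainerFormatError(f"container is missing '{key}'")
    return f[key]


def read_container(path) -> Session:
    """Read a session container; raises :class:`ContainerFormatError` on a
    truncated or structurally invalid file."""
    session = Session()
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise ContainerFormatError(f"not a readable HDF5 container: {exc}") from exc
    with f:
        if "layout" in f:
            g = f["layout"]
            for key in ("ids", "xy"):
                _require(g, key)
            if "pitch_um" not in g.attrs:
                raise ContainerFormatError("container is missing 'layout@pitch_um'")
            session.layout = ElectrodeLayout(
                g["ids"][()], g["xy"][()], float(g.attrs["pitch_um"])
            )
        if "blocks" in f:
            for k in sorted(f["blocks"], key=int):
                g = f[f"blocks/{k}"]
                for key in ("traces", "electrode_ids"):
                    _require(g, key)
                session.blocks.append(
                    RecordingBlock(
                        traces=g["traces"][()],
                        electrode_ids=g["electrode_ids"][()],
                        fs_khz=float(g.attrs["fs_khz"]),
                        index=int(g.attrs.get("index", int(k))),
                    )
                )
        if "events" in f:
            g = f["events"]
            session.events = pd.DataFrame(
                {
                    "electrode_id": _require(g, "electrode_id")[()],
                    "time_ms": _require(g, "time_ms")[()],
                    "amplitude_uV": _require(g, "amplitude_uV")[()],
                }
            )
        if "neurons" in f:
            for nid in f["neurons"]:
                g = f[f"neurons/{nid}"]
                if "footprint" in g:
                    fpg = g["footprint"]
                    for key in ("waveforms", "electrode_ids"):
                        _require(fpg, key)
                    session.footprints[int(nid)] = Footprint.from_waveforms(
                        fpg["electrode_ids"][()],
                        fpg["waveforms"][()],
                        float(fpg.attrs["fs_khz"]),
                        float(fpg.attrs["t_pre_ms"]),
                        float(fpg.attrs["t_post_ms"]),
                        fpg["n_spikes_per_electrode"][()],
                        neuron=int(nid),
                    )
                for key in g:
                    if key.startswith("segmentation_"):
                        method = key.removeprefix("segmentation_")
                        sg = g[key]
                        session.segmentations[(int(nid), method)] = Segmentation(
                            neuron=int(nid),
                            method=method,
                            params=json.loads(sg.attrs.get("params", "{}")),
                            electrode_ids=_require(sg, "electrodes")[()],
                        )
        if "ground_truth" in f:
            for nid in f["ground_truth"]:
                session.ground_truth[int(nid)] = f[f"ground_truth/{nid}"][()]
    return session


# --- CSV / JSON side products ---------------------------------------------

def write_events_csv(path, events: pd.DataFrame) -> None:
    events[["electrode_id", "time_ms", "amplitude_uV"]].to_csv(path, index=False)


def write_activity_csv(path, amap: pd.DataFrame) -> None:
    amap[["electrode_id", "count", "median_amp_uV"]].to_csv(path, index=False)


def write_ground_truth_csv(path, points: np.ndarray) -> None:
    pd.DataFrame(np.asarray(points, float), columns=["x_um", "y_um"]).to_csv(
        path, index=False
    )


def write_segmentation_json(path, seg: Segmentation) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "neuron": seg.neuron,
                "method": seg.method,
                "params": seg.params,
                "electrodes": [int(e) for e in seg.electrode_ids],
            },
            fh,
            indent=2,
        )


def write_configurations_json(path, configs) -> None:
    with open(path, "w") as fh:
        json.dump(
            [
                {"index": c.index, "fixed": list(c.fixed), "variable": list(c.variable)}
                for c in configs
            ],
            fh,
        )
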