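"""Hexagonal electrode lattices and spatially scaled 7-electrode neighborhoods.

High-density microelectrode arrays pack thousands of planar electrodes on a
triangular ("hexagonally packed") lattice, so every interior electrode has six
equidistant nearest neighbors.  The delay-variance segmentation statistic is
computed over such 7-member hexagonal patches, optionally dilated by an
integer ``scale`` factor (same 7 electrodes per patch, larger radius).

Coordinates are micrometres, origin at the array corner.  Electrode ids are
0-based integers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

SQRT3 = float(np.sqrt(3.0))

# Unit offsets to the six ideal hexagon vertices around a lattice site.
_HEX_ANGLES = np.deg2rad(np.arange(0.0, 360.0, 60.0))
_HEX_OFFSETS = np.stack([np.cos(_HEX_ANGLES), np.sin(_HEX_ANGLES)], axis=1)

# An electrode counts as occupying an ideal vertex only if it sits within this
# fraction of the pitch from it; the nearest competing lattice site is a full
# pitch away, so anything < 0.5 is safe against false matches at array edges.
_VERTEX_TOL = 0.25


@dataclass(frozen=True)
class ElectrodeLayout:
    """Planar electrode layout with a nominal nearest-neighbor pitch (μm)."""

    ids: np.ndarray
    positions: np.ndarray
    pitch: float

    def __post_init__(self) -> None:
        ids = np.asarray(self.ids, dtype=np.int64)
        pos = np.asarray(self.positions, dtype=float)
        if ids.ndim != 1 or pos.ndim != 2 or pos.shape != (ids.size, 2):
            raise ValueError("ids must be (n,), positions (n, 2)")
        if np.unique(ids).size != ids.size:
            raise ValueError("electrode ids must be unique")
        if not self.pitch > 0:
            raise ValueError("pitch must be positive")
        object.__setattr__(self, "ids", ids)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(
            self, "_index", {int(e): i for i, e in enumerate(ids)}
        )

    @property
    def n(self) -> int:
        return int(self.ids.size)

    def index_of(self, eid: int) -> int:
        try:
            return self._index[int(eid)]  # type: ignore[attr-defined]
        except KeyError:
            raise KeyError(f"electrode id {eid} not in layout") from None

    def position_of(self, eid: int) -> np.ndarray:
        return self.positions[self.index_of(eid)]

    def subset(self, eids) -> "ElectrodeLayout":
        idx = np.array([self.index_of(e) for e in eids], dtype=int)
        return ElectrodeLayout(self.ids[idx], self.positions[idx], self.pitch)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "id": self.ids,
                "x_um": self.positions[:, 0],
                "y_um": self.positions[:, 1],
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, pitch: float | None = None) -> "ElectrodeLayout":
        df = pd.read_csv(path)
        pos = df[["x_um", "y_um"]].to_numpy(float)
        if pitch is None:
            d, _ = cKDTree(pos).query(pos, k=2)
            pitch = float(d[:, 1].min())
        return cls(df["id"].to_numpy(np.int64), pos, pitch)


def build_hex_layout(n_rows: int, n_cols: int, pitch: float) -> ElectrodeLayout:
    """Pointy-top triangular lattice: odd rows offset by pitch/2, row spacing
    pitch*sqrt(3)/2.  Ids are assigned row-major starting at 0."""
    if n_rows < 1 or n_cols < 1:
        raise ValueError("n_rows and n_cols must be >= 1")
    if not pitch > 0:
        raise ValueError("pitch must be positive")
    rows, cols = np.divmod(np.arange(n_rows * n_cols), n_cols)
    x = (cols + 0.5 * (rows % 2)) * pitch
    y = rows * (pitch * SQRT3 / 2.0)
    return ElectrodeLayout(np.arange(n_rows * n_cols), np.column_stack([x, y]), pitch)


def lattice_density(pitch_um: float) -> float:
    """Electrode density of a triangular lattice, in electrodes per mm^2.

    Each electrode owns a hexagonal cell of area sqrt(3)/2 * pitch^2, hence a
    density of 2 / (sqrt(3) * pitch^2).
    """
    if not pitch_um > 0:
        raise ValueError("pitch must be positive")
    return 2.0 / (SQRT3 * (pitch_um * 1e-3) ** 2)


@dataclass(frozen=True)
class Neighborhood:
    """A hexagonal patch: the center electrode plus up to six ring members."""

    ids: np.ndarray          # center first
    scale: int

    @property
    def size(self) -> int:
        return int(self.ids.size)

    @property
    def complete(self) -> bool:
        return self.size == 7


def neighbor_table(layout: ElectrodeLayout, scale: int = 1) -> np.ndarray:
    """Indices of the 7-member hexagonal patch around every electrode.

    Returns an (n, 7) int array of *positional* indices into the layout; the
    first column is the electrode itself, the remaining six columns hold the
    electrode nearest to each ideal hexagon vertex at radius ``scale * pitch``
    or -1 where no electrode lies within tolerance (array edges).
    """
    if scale < 1:
        raise ValueError("scale must be a positive integer")
    pos = layout.positions
    tree = cKDTree(pos)
    radius = scale * layout.pitch
    targets = pos[:, None, :] + radius * _HEX_OFFSETS[None, :, :]
    dist, idx = tree.query(targets.reshape(-1, 2))
    dist = dist.reshape(layout.n, 6)
    idx = idx.reshape(layout.n, 6)
    ring = np.where(dist <= _VERTEX_TOL * layout.pitch, idx, -1)
    return np.column_stack([np.arange(layout.n), ring])


def neighborhood(layout: ElectrodeLayout, eid: int, scale: int = 1) -> Neighborhood:
    """Hexagonal patch around one electrode, by electrode id.

    The patch has at most 7 members; fewer at array edges, which callers can
    reject via :attr:`Neighborhood.complete`.
    """
    if scale < 1:
        raise ValueError("scale must be a positive integer")
    i = layout.index_of(eid)
    center = layout.positions[i]
    tree = cKDTree(layout.positions)
    targets = center[None, :] + scale * layout.pitch * _HEX_OFFSETS
    dist, idx = tree.query(targets)
    members = [i] + [int(j) for d, j in zip(dist, idx) if d <= _VERTEX_TOL * layout.pitch]
    return Neighborhood(ids=layout.ids[np.array(members)], scale=scale)
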