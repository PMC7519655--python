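"""Hexagonal electrode-array geometry.

The dual-mode MEA exposes 108 x 192 electrodes in a hexagonal arrangement at
18.0 um pitch (19,584 electrodes in total).  Odd rows are shifted by half a
pitch in x and the row spacing is pitch * sqrt(3)/2, so every interior
electrode has exactly six nearest neighbours at distance = pitch.  Electrode
ids are 0-based row-major integers; coordinates are in micrometres with the
origin at electrode (0, 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "ArrayParams",
    "ElectrodeArray",
    "build_hex_array",
    "neighbors_within",
]

#: relative slack used when comparing float distances against a radius
_RADIUS_RTOL = 1e-9


class InvalidParameterError(ValueError):
    """Raised when geometry / simulation parameters are out of range."""


@dataclass(frozen=True)
class ArrayParams:
    """Lattice dimensions of the electrode array.

    Defaults reproduce the full dual-mode chip: 19,584 electrodes at 18.0 um
    pitch.  The vendor describes the pixel matrix as "108 x 192", but a full
    108 x 192 grid would hold 20,736 sites; the device exposes 19,584
    electrodes, which is exactly 102 rows x 192 columns, the convention used
    here.
    """

    n_rows: int = 102
    n_cols: int = 192
    pitch: float = 18.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise InvalidParameterError(
                f"array dimensions must be >= 1, got {self.n_rows}x{self.n_cols}"
            )
        if not self.pitch > 0:
            raise InvalidParameterError(f"pitch must be > 0, got {self.pitch}")


@dataclass
class ElectrodeArray:
    """Electrode ids mapped to planar coordinates in micrometres."""

    ids: np.ndarray
    positions: np.ndarray  # (N, 2) float64, um
    pitch: float = 18.0
    _tree: cKDTree | None = field(default=None, repr=False, compare=False)
    _id_index: dict | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=np.int64)
        self.positions = np.asarray(self.positions, dtype=np.float64)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise InvalidParameterError("positions must be an (N, 2) array")
        if len(self.ids) != len(self.positions):
            raise InvalidParameterError("ids and positions length mismatch")

    @property
    def n_electrodes(self) -> int:
        return len(self.ids)

    @property
    def tree(self) -> cKDTree:
        if self._tree is None:
            self._tree = cKDTree(self.positions)
        return self._tree

    def index_of(self, electrode_id: int) -> int:
        """Row index of an electrode id (KeyError if unknown)."""
        if self._id_index is None:
            self._id_index = {int(e): i for i, e in enumerate(self.ids)}
        return self._id_index[int(electrode_id)]

    def position(self, electrode_id: int) -> np.ndarray:
        return self.positions[self.index_of(electrode_id)]

    def neighbors_within(self, center: int, radius: float) -> np.ndarray:
        """Electrode ids (ascending) within ``radius`` um of ``center``, excluding it."""
        if radius < 0:
            raise InvalidParameterError(f"radius must be >= 0, got {radius}")
        pos = self.position(center)  # raises KeyError for unknown ids
        if radius == 0:
            return np.empty(0, dtype=np.int64)
        idx = self.tree.query_ball_point(pos, radius * (1.0 + _RADIUS_RTOL))
        out = self.ids[np.asarray(idx, dtype=np.int64)]
        out = out[out != int(center)]
        return np.sort(out)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"id": self.ids, "x_um": self.positions[:, 0], "y_um": self.positions[:, 1]}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, pitch: float = 18.0) -> "ElectrodeArray":
        df = pd.read_csv(path)
        return cls(
            ids=df["id"].to_numpy(),
            positions=df[["x_um", "y_um"]].to_numpy(dtype=np.float64),
            pitch=pitch,
        )


def build_hex_array(params: ArrayParams | None = None) -> ElectrodeArray:
    """Construct the hexagonal lattice.

    Electrode at row ``r``, column ``c`` sits at
    ``x = c * pitch + (r % 2) * pitch / 2`` and ``y = r * pitch * sqrt(3) / 2``;
    ids run row-major from 0.
    """
    params = params or ArrayParams()
    r = np.repeat(np.arange(params.n_rows), params.n_cols)
    c = np.tile(np.arange(params.n_cols), params.n_rows)
    x = c * params.pitch + (r % 2) * (params.pitch / 2.0)
    y = r * params.pitch * (math.sqrt(3.0) / 2.0)
    ids = np.arange(params.n_rows * params.n_cols, dtype=np.int64)
    return ElectrodeArray(ids=ids, positions=np.column_stack([x, y]), pitch=params.pitch)


def neighbors_within(array: ElectrodeArray, center: int, radius: float) -> np.ndarray:
    """Module-level convenience wrapper around :meth:`ElectrodeArray.neighbors_within`."""
    return array.neighbors_within(center, radius)
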