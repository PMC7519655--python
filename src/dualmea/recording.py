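"""Dual-mode recording data model and HDF5 container I/O.

A dual-mode recording holds two simultaneously sampled extracellular streams:

* ``aps`` -- the full-frame stream: every electrode of the array at 11.6 kHz,
  10.4 uV rms noise (AP band);
* ``sm`` -- the high-SNR switch-matrix stream: up to 246 selected electrodes
  at 24.4 kHz, 3.0 uV rms noise.

Both streams share one clock origin (``t0_s``); their sampling rates are not
integer multiples of each other, so alignment between the streams is done on
timestamps (see :mod:`dualmea.detection`).  In-memory samples are floating
point microvolts; on disk they are int16 with an explicit uV-per-LSB scale.

Container layout::

    /geometry/positions      (N, 2) float64, um
    /geometry/ids            (N,)   int64
    /aps/data                (N, T) int16, chunked electrode-major
    /aps/attrs               sampling_rate_hz, lsb_uv, t0_s
    /sm/data                 (M, S) int16
    /sm/electrode_ids        (M,)   int64
    /sm/attrs                same keys as /aps
    /units/<k>/spike_times_s optional, float64 seconds
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

from .geometry import ElectrodeArray, InvalidParameterError

__all__ = [
    "ModeParams",
    "DualModeRecording",
    "FormatError",
    "read_recording",
    "write_recording",
]

SM_MAX_CHANNELS = 246
DEFAULT_LSB_UV = 0.0625  # +-2048 uV full scale on int16


class FormatError(IOError):
    """A container is missing a required dataset or attribute."""


@dataclass(frozen=True)
class ModeParams:
    """Per-stream acquisition parameters."""

    mode: str  # "full_frame" | "high_snr"
    sampling_rate: float  # Hz
    noise_rms: float  # uV rms in the AP band (0.3-5 kHz)
    n_channels: int

    def __post_init__(self) -> None:
        if self.mode not in ("full_frame", "high_snr"):
            raise InvalidParameterError(f"unknown mode {self.mode!r}")
        if not self.sampling_rate > 0:
            raise InvalidParameterError("sampling_rate must be > 0")
        if self.noise_rms < 0:
            raise InvalidParameterError("noise_rms must be >= 0")
        if self.mode == "high_snr" and self.n_channels > SM_MAX_CHANNELS:
            raise InvalidParameterError(
                f"high_snr mode supports at most {SM_MAX_CHANNELS} channels"
            )

    @classmethod
    def aps_default(cls, n_channels: int, noise_rms: float = 10.4) -> "ModeParams":
        return cls("full_frame", 11_600.0, noise_rms, n_channels)

    @classmethod
    def sm_default(cls, n_channels: int, noise_rms: float = 3.0) -> "ModeParams":
        return cls("high_snr", 24_400.0, noise_rms, n_channels)


@dataclass
class DualModeRecording:
    """The two signal streams plus geometry and shared time origin."""

    array: ElectrodeArray
    aps: np.ndarray  # (n_electrodes, n_frames) uV
    sm: np.ndarray  # (n_sm, n_samples) uV
    sm_electrodes: np.ndarray  # electrode ids routed to the SM channels
    aps_params: ModeParams
    sm_params: ModeParams
    t0: float = 0.0  # shared clock origin, seconds
    units: dict = field(default_factory=dict)  # unit id -> spike times (s)

    def __post_init__(self) -> None:
        self.sm_electrodes = np.asarray(self.sm_electrodes, dtype=np.int64)
        if not np.isin(self.sm_electrodes, self.array.ids).all():
            raise InvalidParameterError("sm_electrodes must be a subset of array ids")
        if self.aps.shape[0] != self.array.n_electrodes:
            raise InvalidParameterError("aps rows must match array electrodes")
        if self.sm.shape[0] != len(self.sm_electrodes):
            raise InvalidParameterError("sm rows must match sm_electrodes")

    @property
    def n_frames(self) -> int:
        return self.aps.shape[1]

    @property
    def duration(self) -> float:
        """Length of the APS stream in seconds."""
        return self.n_frames / self.aps_params.sampling_rate

    def aps_trace(self, electrode_id: int) -> np.ndarray:
        return self.aps[self.array.index_of(electrode_id)]

    def sm_trace(self, electrode_id: int) -> np.ndarray:
        rows = np.flatnonzero(self.sm_electrodes == int(electrode_id))
        if len(rows) == 0:
            raise KeyError(f"electrode {electrode_id} not routed to the SM stream")
        return self.sm[rows[0]]


def _write_stream(g: h5py.Group, data: np.ndarray, params: ModeParams, t0: float,
                  lsb_uv: float) -> None:
    data = np.asarray(data)
    n_el, n_t = data.shape
    chunk_t = max(1, min(n_t, int(params.sampling_rate)))  # <= 1 s blocks
    chunk_e = max(1, min(n_el, 64))
    ds = g.create_dataset(
        "data", shape=(n_el, n_t), dtype=np.int16,
        chunks=(chunk_e, chunk_t) if n_el and n_t else None,
    )
    for r0 in range(0, n_el, chunk_e):  # quantise in blocks to bound memory
        q = np.rint(data[r0 : r0 + chunk_e] / np.float32(lsb_uv))
        np.clip(q, -32768, 32767, out=q)
        ds[r0 : r0 + chunk_e] = q.astype(np.int16)
    ds.attrs["sampling_rate_hz"] = float(params.sampling_rate)
    ds.attrs["lsb_uv"] = float(lsb_uv)
    ds.attrs["t0_s"] = float(t0)
    ds.attrs["noise_rms_uv"] = float(params.noise_rms)
    ds.attrs["mode"] = params.mode


def _read_stream(f: h5py.File, name: str) -> tuple[np.ndarray, ModeParams, float]:
    if name not in f or "data" not in f[name]:
        raise FormatError(f"container missing dataset /{name}/data")
    ds = f[name]["data"]
    for key in ("sampling_rate_hz", "lsb_uv", "t0_s"):
        if key not in ds.attrs:
            raise FormatError(f"/{name}/data missing attribute {key!r}")
    # float32 represents int16 x LSB exactly and halves the memory footprint;
    # scale in blocks so the int16 source is never duplicated wholesale
    data = np.empty(ds.shape, dtype=np.float32)
    for r0 in range(0, ds.shape[0], 64):
        data[r0 : r0 + 64] = ds[r0 : r0 + 64]
    data *= np.float32(ds.attrs["lsb_uv"])
    params = ModeParams(
        mode=str(ds.attrs.get("mode", "full_frame" if name == "aps" else "high_snr")),
        sampling_rate=float(ds.attrs["sampling_rate_hz"]),
        noise_rms=float(ds.attrs.get("noise_rms_uv", 0.0)),
        n_channels=data.shape[0],
    )
    return data, params, float(ds.attrs["t0_s"])


def write_recording(rec: DualModeRecording, path, lsb_uv: float = DEFAULT_LSB_UV) -> None:
    """Write a recording to the HDF5 container (int16 samples + uV/LSB scale)."""
    with h5py.File(path, "w") as f:
        g = f.create_group("geometry")
        g.create_dataset("positions", data=rec.array.positions)
        g.create_dataset("ids", data=rec.array.ids)
        g.attrs["pitch_um"] = float(rec.array.pitch)
        _write_stream(f.create_group("aps"), rec.aps, rec.aps_params, rec.t0, lsb_uv)
        sm_g = f.create_group("sm")
        _write_stream(sm_g, rec.sm, rec.sm_params, rec.t0, lsb_uv)
        sm_g.create_dataset("electrode_ids", data=rec.sm_electrodes)
        if rec.units:
            ug = f.create_group("units")
            for uid, times in rec.units.items():
                ug.create_group(str(uid)).create_dataset(
                    "spike_times_s", data=np.asarray(times, dtype=np.float64)
                )


def read_units(path) -> dict:
    """Unit spike trains only (no sample data loaded)."""
    units = {}
    with h5py.File(path, "r") as f:
        if "units" in f:
            for uid in f["units"]:
                units[uid] = f["units"][uid]["spike_times_s"][...]
    return units


def read_recording_info(path) -> dict:
    """Stream metadata (rates, sizes, duration) without loading samples."""
    with h5py.File(path, "r") as f:
        if "aps" not in f or "data" not in f["aps"]:
            raise FormatError("container missing dataset /aps/data")
        ds = f["aps"]["data"]
        fs = float(ds.attrs["sampling_rate_hz"])
        n_el, n_frames = ds.shape
        return {
            "aps_sampling_rate_hz": fs,
            "n_electrodes": int(n_el),
            "n_frames": int(n_frames),
            "duration_s": n_frames / fs,
            "t0_s": float(ds.attrs["t0_s"]),
        }


def read_recording(path) -> DualModeRecording:
    """Read a recording container, returning samples scaled to microvolts."""
    with h5py.File(path, "r") as f:
        if "geometry" not in f:
            raise FormatError("container missing group /geometry")
        g = f["geometry"]
        for name in ("positions", "ids"):
            if name not in g:
                raise FormatError(f"container missing dataset /geometry/{name}")
        array = ElectrodeArray(
            ids=g["ids"][...],
            positions=g["positions"][...],
            pitch=float(g.attrs.get("pitch_um", 18.0)),
        )
        aps, aps_params, t0 = _read_stream(f, "aps")
        sm, sm_params, _ = _read_stream(f, "sm")
        if "electrode_ids" not in f["sm"]:
            raise FormatError("container missing dataset /sm/electrode_ids")
        sm_electrodes = f["sm"]["electrode_ids"][...]
        units = {}
        if "units" in f:
            for uid in f["units"]:
                units[uid] = f["units"][uid]["spike_times_s"][...]
    return DualModeRecording(
        array=array,
        aps=aps,
        sm=sm,
        sm_electrodes=sm_electrodes,
        aps_params=aps_params,
        sm_params=sm_params,
        t0=t0,
        units=units,
    )
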