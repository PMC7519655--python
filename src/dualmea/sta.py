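"""Spike-triggered averaging and electrical footprints.

Averaging raw full-frame (APS) windows around spike triggers suppresses
uncorrelated noise by 1/sqrt(N) and reveals axonal signals far below the
single-frame detection limit.  Triggers can come from the low-noise SM
stream, an external sorter, or simulator ground truth; this cross-mode
averaging is what lets a unit invisible to direct APS detection be
reconstructed across the whole array.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

from .recording import DualModeRecording

__all__ = ["Footprint", "EmptyFootprintError", "spike_triggered_average",
           "write_footprints", "read_footprints"]


class EmptyFootprintError(ValueError):
    """No usable trigger fell fully inside the recording."""


@dataclass
class Footprint:
    """Per-electrode spike-triggered-average waveform of one unit.

    ``amplitude`` is the |negative peak| per electrode, ``latency_ms`` the
    negative-peak time relative to the initiation site (the electrode with the
    largest amplitude; ties broken by lowest id), and ``jitter_ms`` the std of
    the peak time across sub-averages of the trigger set (used by footprint
    cleaning).
    """

    unit_id: int
    electrodes: np.ndarray  # electrode ids
    waveforms: np.ndarray  # (n_electrodes, n_samples) uV
    sampling_rate: float
    amplitude: np.ndarray  # uV, |negative peak|
    jitter_ms: np.ndarray
    n_triggers: int
    positions: np.ndarray | None = None  # (n_electrodes, 2) um
    peak_sample: np.ndarray = field(default=None)
    latency_ms: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.electrodes = np.asarray(self.electrodes, dtype=np.int64)
        if self.peak_sample is None:
            self.peak_sample = (
                np.argmin(self.waveforms, axis=1)
                if self.waveforms.size
                else np.empty(0, dtype=np.int64)
            )
        self.peak_sample = np.asarray(self.peak_sample, dtype=np.int64)
        if self.latency_ms is None:
            self.latency_ms = self._latencies()

    def _latencies(self) -> np.ndarray:
        if len(self.electrodes) == 0:
            return np.empty(0)
        ref = self.peak_sample[self.initiation_index()]
        return (self.peak_sample - ref) * 1e3 / self.sampling_rate

    @property
    def n_electrodes(self) -> int:
        return len(self.electrodes)

    def initiation_index(self) -> int:
        """Row of the initiation site: max amplitude, ties to lowest id."""
        if len(self.electrodes) == 0:
            raise EmptyFootprintError("footprint has no electrodes")
        best = np.flatnonzero(self.amplitude == self.amplitude.max())
        return int(best[np.argmin(self.electrodes[best])])

    def initiation_electrode(self) -> int:
        return int(self.electrodes[self.initiation_index()])

    def amplitude_map(self) -> dict:
        return dict(zip(self.electrodes.tolist(), self.amplitude.tolist()))

    def latency_map(self) -> dict:
        return dict(zip(self.electrodes.tolist(), self.latency_ms.tolist()))

    def subset(self, keep: np.ndarray) -> "Footprint":
        """New footprint restricted to a boolean mask / index array of rows."""
        return Footprint(
            unit_id=self.unit_id,
            electrodes=self.electrodes[keep],
            waveforms=self.waveforms[keep],
            sampling_rate=self.sampling_rate,
            amplitude=self.amplitude[keep],
            jitter_ms=self.jitter_ms[keep],
            n_triggers=self.n_triggers,
            positions=None if self.positions is None else self.positions[keep],
            peak_sample=self.peak_sample[keep],
            latency_ms=None,  # re-referenced to the new initiation site
        )


def _group_jitter_ms(
    gmeans: np.ndarray, pk_full: np.ndarray, fs: float, window_ms: float
) -> np.ndarray:
    """Robust std (1.4826 x MAD) of sub-average peak times around the
    footprint peak.  ``gmeans`` is (n_el, n_groups, n_samp)."""
    n_el, n_groups, n_samp = gmeans.shape
    w = max(1, int(round(window_ms * 1e-3 * fs)))
    rel = np.arange(-w, w + 1)
    idx = np.clip(pk_full[:, None] + rel[None, :], 0, n_samp - 1)  # (n_el, 2w+1)
    local = np.take_along_axis(gmeans, idx[:, None, :], axis=2)
    pk = idx[np.arange(n_el)[:, None], np.argmin(local, axis=2)] * 1e3 / fs
    med = np.median(pk, axis=1, keepdims=True)
    return 1.4826 * np.median(np.abs(pk - med), axis=1)


def spike_triggered_average(
    aps: np.ndarray,
    sampling_rate: float,
    trigger_frames: np.ndarray,
    template_ms: float = 12.0,
    unit_id: int = 0,
    electrodes: np.ndarray | None = None,
    positions: np.ndarray | None = None,
    jitter_groups: int = 8,
    jitter_window_ms: float = 2.0,
    chunk: int = 256,
) -> Footprint:
    """Average ``template_ms``-long windows of APS data centred on triggers.

    The peak-time jitter per electrode is the spread of the negative-peak
    time over sub-averages of the triggers (``jitter_groups`` groups, robust
    std, searched within +-``jitter_window_ms`` of the footprint peak); with
    fewer triggers than groups it degenerates to per-window peak times.
    """
    aps = np.asarray(aps)
    n_el, n_frames = aps.shape
    n_samp = int(round(template_ms * 1e-3 * sampling_rate))
    center = n_samp // 2
    trig = np.asarray(trigger_frames, dtype=np.int64)
    trig = trig[(trig - center >= 0) & (trig - center + n_samp <= n_frames)]
    if len(trig) == 0:
        raise EmptyFootprintError("no trigger with a full template window")
    idx = (trig[:, None] - center) + np.arange(n_samp)[None, :]  # (N, n_samp)
    n_groups = max(1, min(jitter_groups, len(trig)))
    group_of = np.arange(len(trig)) % n_groups
    waveforms = np.empty((n_el, n_samp))
    jitter = np.empty(n_el)
    for start in range(0, n_el, chunk):
        block = aps[start : start + chunk]
        windows = block[:, idx]  # (chunk, N, n_samp)
        mean_wf = windows.mean(axis=1)
        waveforms[start : start + chunk] = mean_wf
        gmeans = np.stack(
            [windows[:, group_of == g].mean(axis=1) for g in range(n_groups)], axis=1
        )  # (chunk, n_groups, n_samp)
        jitter[start : start + chunk] = _group_jitter_ms(
            gmeans, np.argmin(mean_wf, axis=1), sampling_rate, jitter_window_ms
        )
    amplitude = np.maximum(-waveforms.min(axis=1), 0.0)
    if electrodes is None:
        electrodes = np.arange(n_el, dtype=np.int64)
    return Footprint(
        unit_id=unit_id,
        electrodes=np.asarray(electrodes, dtype=np.int64),
        waveforms=waveforms,
        sampling_rate=sampling_rate,
        amplitude=amplitude,
        jitter_ms=jitter,
        n_triggers=len(trig),
        positions=positions,
    )


def footprint_from_recording(
    rec: DualModeRecording,
    trigger_frames: np.ndarray,
    unit_id: int = 0,
    template_ms: float = 12.0,
    **kwargs,
) -> Footprint:
    """STA over the full APS stream of a recording, carrying geometry along."""
    return spike_triggered_average(
        rec.aps,
        rec.aps_params.sampling_rate,
        trigger_frames,
        template_ms=template_ms,
        unit_id=unit_id,
        electrodes=rec.array.ids,
        positions=rec.array.positions,
        **kwargs,
    )


def write_footprints(path, footprints: list) -> None:
    """Store footprints as /footprints/<unit>/{electrodes, waveforms, ...}."""
    with h5py.File(path, "w") as f:
        root = f.create_group("footprints")
        for fp in footprints:
            g = root.create_group(str(fp.unit_id))
            g.create_dataset("electrodes", data=fp.electrodes)
            g.create_dataset("waveforms", data=fp.waveforms)
            g.create_dataset("amplitude", data=fp.amplitude)
            g.create_dataset("latency", data=fp.latency_ms)
            g.create_dataset("jitter_ms", data=fp.jitter_ms)
            if fp.positions is not None:
                g.create_dataset("positions", data=fp.positions)
            g.attrs["n_triggers"] = fp.n_triggers
            g.attrs["sampling_rate_hz"] = fp.sampling_rate
            g.attrs["unit_id"] = fp.unit_id


def read_footprints(path) -> list:
    out = []
    with h5py.File(path, "r") as f:
        for key in sorted(f["footprints"], key=lambda s: (len(s), s)):
            g = f["footprints"][key]
            out.append(
                Footprint(
                    unit_id=int(g.attrs["unit_id"]),
                    electrodes=g["electrodes"][...],
                    waveforms=g["waveforms"][...],
                    sampling_rate=float(g.attrs["sampling_rate_hz"]),
                    amplitude=g["amplitude"][...],
                    jitter_ms=g["jitter_ms"][...],
                    n_triggers=int(g.attrs["n_triggers"]),
                    positions=g["positions"][...] if "positions" in g else None,
                )
            )
    return out
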