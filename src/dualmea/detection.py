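"""Filtering, spike detection, electrode preselection and activity maps.

Spike sorting itself is delegated to external tools (the pipeline accepts
unit spike trains from the container or the simulator's ground truth); the
threshold detector here serves trigger extraction on the low-noise SM stream
and whole-sample activity mapping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .geometry import InvalidParameterError
from .recording import DualModeRecording

__all__ = [
    "DetectionParams",
    "SpikeTrain",
    "bandpass",
    "robust_std",
    "detect_spikes",
    "preselect_electrodes",
    "align_triggers",
    "activity_map",
]

AP_BAND = (300.0, 3000.0)
LFP_BAND = (1.0, 300.0)


@dataclass(frozen=True)
class DetectionParams:
    """Spike-detection parameters (defaults follow the recording platform:
    300-3000 Hz band, 7.5x noise threshold, 80 uV electrode preselection,
    12 ms STA template)."""

    band: tuple = AP_BAND
    threshold_k: float = 7.5
    preselect_amp: float = 80.0  # uV
    template_ms: float = 12.0
    lfp_band: tuple = LFP_BAND
    refractory_ms: float = 1.5

    def __post_init__(self) -> None:
        lo, hi = self.band
        if not (0 < lo < hi):
            raise InvalidParameterError(f"invalid band {self.band}")
        if not self.threshold_k > 0:
            raise InvalidParameterError("threshold_k must be > 0")


@dataclass
class SpikeTrain:
    """Sorted spike times of one unit, tagged with their provenance."""

    unit_id: int
    spike_times: np.ndarray  # seconds, strictly increasing
    source: str = "external_sorter"  # sm_detection | external_sorter | ground_truth

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=np.float64)
        if len(self.spike_times) > 1 and not (np.diff(self.spike_times) > 0).all():
            raise InvalidParameterError("spike times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.spike_times)


def bandpass(trace: np.ndarray, band, sampling_rate: float) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass along the last axis."""
    lo, hi = band
    nyq = sampling_rate / 2.0
    if not (0 < lo < hi):
        raise InvalidParameterError(f"invalid band {band}")
    if hi >= nyq:
        raise InvalidParameterError(f"band high {hi} Hz >= Nyquist {nyq} Hz")
    sos = butter(4, [lo, hi], btype="bandpass", fs=sampling_rate, output="sos")
    return sosfiltfilt(sos, np.asarray(trace, dtype=np.float64), axis=-1)


def robust_std(x: np.ndarray, axis=-1) -> np.ndarray:
    """Noise std estimated as median(|x|)/0.6745; insensitive to spikes."""
    return np.median(np.abs(x), axis=axis) / 0.6745


def detect_spikes(
    trace: np.ndarray,
    sampling_rate: float,
    threshold_k: float = 7.5,
    refractory_ms: float = 1.5,
    t0: float = 0.0,
    noise_std: float | None = None,
    template_ms: float = 12.0,
) -> np.ndarray:
    """Negative threshold crossings of a band-passed trace, one per event.

    Crossings closer than ``refractory_ms`` are merged and each event is
    refined to its local minimum.  Returns spike times in seconds.
    """
    trace = np.asarray(trace)
    if len(trace) < int(template_ms * 1e-3 * sampling_rate):
        warnings.warn("trace shorter than one template; no detection", stacklevel=2)
        return np.empty(0)
    sigma = noise_std if noise_std is not None else float(robust_std(trace))
    thr = threshold_k * sigma
    below = np.flatnonzero(trace < -thr)
    if len(below) == 0:
        return np.empty(0)
    gap = int(round(refractory_ms * 1e-3 * sampling_rate))
    splits = np.flatnonzero(np.diff(below) > gap) + 1
    times = []
    for grp in np.split(below, splits):
        idx = grp[np.argmin(trace[grp])]
        times.append(t0 + idx / sampling_rate)
    return np.asarray(times)


def preselect_electrodes(
    rec: DualModeRecording, params: DetectionParams | None = None, chunk: int = 128
) -> np.ndarray:
    """Electrodes whose filtered APS trace swings below -``preselect_amp`` uV."""
    params = params or DetectionParams()
    keep = []
    for start in range(0, rec.array.n_electrodes, chunk):
        block = rec.aps[start : start + chunk]
        filt = bandpass(block, params.band, rec.aps_params.sampling_rate)
        amp = -filt.min(axis=-1)
        keep.append(rec.array.ids[start : start + chunk][amp > params.preselect_amp])
    return np.concatenate(keep) if keep else np.empty(0, dtype=np.int64)


def align_triggers(
    sm_times: np.ndarray, aps_sampling_rate: float, n_frames: int, t0: float = 0.0
):
    """Map SM-detected spike times to nearest APS frame indices.

    The mapping error is at most half an APS frame period (43.1 us at
    11.6 kHz).  Triggers outside the APS span are dropped; returns
    ``(frames, n_dropped)``.
    """
    sm_times = np.asarray(sm_times, dtype=np.float64)
    frames = np.rint((sm_times - t0) * aps_sampling_rate).astype(np.int64)
    ok = (frames >= 0) & (frames < n_frames)
    return frames[ok], int((~ok).sum())


def activity_map(
    rec: DualModeRecording,
    band=AP_BAND,
    threshold_k: float = 7.5,
    chunk: int = 128,
) -> pd.DataFrame:
    """Per-electrode largest |negative peak| and threshold-crossing rate.

    Band presets: the AP band (0.3-3 kHz default here for detection, 0.3-5 kHz
    for noise accounting) or the LFP band (1-300 Hz) for slice/LFP data.
    Returns a DataFrame with columns electrode, amplitude_uv, rate_hz.
    """
    fs = rec.aps_params.sampling_rate
    duration = rec.duration
    amps, rates = [], []
    for start in range(0, rec.array.n_electrodes, chunk):
        block = bandpass(rec.aps[start : start + chunk], band, fs)
        amps.append(-block.min(axis=-1))
        for row in block:
            n_ev = len(detect_spikes(row, fs, threshold_k=threshold_k))
            rates.append(n_ev / duration if duration > 0 else 0.0)
    return pd.DataFrame(
        {
            "electrode": rec.array.ids,
            "amplitude_uv": np.concatenate(amps),
            "rate_hz": np.asarray(rates),
        }
    )
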