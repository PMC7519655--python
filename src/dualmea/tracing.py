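"""Footprint cleaning, backward axonal tracking and conduction-velocity fits.

The tracker walks the delay map of a cleaned footprint backwards in time:
starting from the last frame of a segment (a delay-map local maximum), it
steps frame by frame towards the initiation site, choosing in each preceding
frame the largest-amplitude electrode within an 80 um radius; when a frame
has no candidate (axonal amplitudes of 5-10 uV routinely drop out), the
search expands to frame N-r and radius r x 80 um for r up to R = 5.  Tracking
stops five frames before the initiation frame, where the large AIS/somatic
signal makes peak timings unreliable.  The slope of an ordinary least-squares
fit of summed inter-electrode path distance (um) against peak latency (ms)
is the conduction velocity in mm/s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .detection import robust_std
from .geometry import InvalidParameterError
from .sta import Footprint

__all__ = [
    "CleaningParams",
    "TracingParams",
    "AxonalSegment",
    "NeuronMorphometrics",
    "estimate_footprint_noise",
    "clean_footprint",
    "initiation_site",
    "terminal_candidates",
    "trace_segment",
    "extract_all_segments",
    "fit_velocity",
    "morphometrics",
]


@dataclass(frozen=True)
class CleaningParams:
    """Electrode rejection: keep amplitude > amp_k x noise std AND peak-time
    std < jitter_max (defaults 5.5x and 0.7 ms)."""

    amp_k: float = 5.5
    jitter_max: float = 0.7  # ms

    def __post_init__(self) -> None:
        if not (self.amp_k > 0 and self.jitter_max > 0):
            raise InvalidParameterError("cleaning thresholds must be > 0")


@dataclass(frozen=True)
class TracingParams:
    """Backward-tracking parameters: 80 um search radius, gap expansion up to
    R = 5 frames / R x radius, stop 5 frames before initiation."""

    radius: float = 80.0  # um
    max_gap_frames: int = 5  # R
    stop_frames: int = 5
    min_electrodes: int = 5

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise InvalidParameterError("radius must be > 0")
        if self.max_gap_frames < 1:
            raise InvalidParameterError("max_gap_frames must be >= 1")


@dataclass
class AxonalSegment:
    """Ordered electrode path from initiation-proximal end to terminal."""

    electrodes: np.ndarray  # ids, proximal -> terminal
    latency_ms: np.ndarray  # relative to the initiation frame, non-decreasing
    cumdist_um: np.ndarray  # summed inter-electrode distance, starts at 0
    positions: np.ndarray  # (n, 2) um
    velocity: float = np.nan  # mm/s
    r_squared: float = np.nan
    degenerate: bool = False

    @property
    def length(self) -> float:
        return float(self.cumdist_um[-1]) if len(self.cumdist_um) else 0.0

    def __len__(self) -> int:
        return len(self.electrodes)


@dataclass
class NeuronMorphometrics:
    unit_id: int
    n_segments: int
    longest_um: float
    total_extension_um: float
    velocity_mms: float  # mean over valid segment fits (nan if none)
    r_squared: float
    max_amplitude_uv: float
    firing_rate_hz: float


def estimate_footprint_noise(fp: Footprint) -> np.ndarray:
    """Per-electrode noise std of the averaged waveform (median-based; the
    brief spike transient occupies too few samples to bias the median)."""
    return robust_std(fp.waveforms, axis=-1)


def clean_footprint(
    fp: Footprint,
    noise_std: np.ndarray | float | None = None,
    params: CleaningParams | None = None,
) -> Footprint:
    """Remove electrodes recording mostly noise.

    Keeps electrodes whose |negative peak| exceeds ``amp_k`` times the noise
    std of the averaged signal and whose peak-time std is below
    ``jitter_max``.  An all-removed result is an empty footprint, not an
    error.
    """
    params = params or CleaningParams()
    if noise_std is None:
        noise_std = estimate_footprint_noise(fp)
    noise_std = np.broadcast_to(np.asarray(noise_std, dtype=float), fp.amplitude.shape)
    keep = (fp.amplitude > params.amp_k * noise_std) & (fp.jitter_ms < params.jitter_max)
    return fp.subset(keep)


def initiation_site(fp: Footprint) -> int:
    """Electrode with the maximum |negative peak|; its latency defines 0 ms."""
    return fp.initiation_electrode()


def _frames(fp: Footprint) -> np.ndarray:
    """Peak frame per electrode relative to the initiation frame."""
    return fp.peak_sample - fp.peak_sample[fp.initiation_index()]


def terminal_candidates(
    fp: Footprint, assigned: set | None = None, params: TracingParams | None = None
) -> np.ndarray:
    """Unassigned electrodes that are local maxima of the delay map.

    A candidate's delay is >= the delay of every unassigned cleaned electrode
    within the search radius.  Sorted by decreasing delay, then decreasing
    amplitude, then ascending id.
    """
    params = params or TracingParams()
    assigned = assigned or set()
    if fp.n_electrodes == 0:
        return np.empty(0, dtype=np.int64)
    if fp.positions is None:
        raise InvalidParameterError("footprint carries no electrode positions")
    free = ~np.isin(fp.electrodes, list(assigned))
    idx = np.flatnonzero(free)
    if len(idx) == 0:
        return np.empty(0, dtype=np.int64)
    delay_all = _frames(fp).astype(float)
    cand = []
    for k in idx:
        d = np.linalg.norm(fp.positions - fp.positions[k], axis=1)
        near = d <= params.radius * (1 + 1e-9)
        # local maximum among unassigned neighbours; electrodes of an already
        # traced wavefront suppress equal-delay stragglers (strict comparison)
        if (delay_all[k] >= delay_all[near & free].max()) and (
            not (near & ~free).any() or delay_all[k] > delay_all[near & ~free].max()
        ):
            cand.append(k)
    cand = np.asarray(cand, dtype=np.int64)
    order = np.lexsort((fp.electrodes[cand], -fp.amplitude[cand], -delay_all[cand]))
    return fp.electrodes[cand[order]]


def trace_segment(
    fp: Footprint,
    start: int,
    params: TracingParams | None = None,
    assigned: set | None = None,
) -> AxonalSegment:
    """Walk backward in discrete latency frames from a terminal electrode.

    From the current electrode peaking in frame N, candidates are cleaned,
    unassigned electrodes peaking in frame N-r within r x radius for
    r = 1..R; the largest-amplitude candidate wins (ties to lowest id).  The
    walk stops when the next step would land within ``stop_frames`` of the
    initiation frame or when no candidate remains.  The returned path runs
    initiation-proximal -> terminal with summed inter-electrode distances.
    """
    params = params or TracingParams()
    assigned = assigned or set()
    if fp.positions is None:
        raise InvalidParameterError("footprint carries no electrode positions")
    frames = _frames(fp)
    fs = fp.sampling_rate
    start_row = int(np.flatnonzero(fp.electrodes == int(start))[0])
    stop_limit = params.stop_frames  # frames are already relative to initiation
    path_rows = [start_row]
    degenerate = frames[start_row] < stop_limit
    if not degenerate:
        used = {start_row}
        cur = start_row
        while True:
            stepped = False
            for r in range(1, params.max_gap_frames + 1):
                target = frames[cur] - r
                if target < stop_limit:
                    break
                d = np.linalg.norm(fp.positions - fp.positions[cur], axis=1)
                ok = (
                    (frames == target)
                    & (d <= r * params.radius * (1 + 1e-9))
                    & ~np.isin(fp.electrodes, list(assigned))
                )
                ok[list(used)] = False
                rows = np.flatnonzero(ok)
                if len(rows):
                    # largest amplitude wins; ties broken by ascending id
                    pick = rows[
                        np.lexsort((fp.electrodes[rows], -fp.amplitude[rows]))[0]
                    ]
                    path_rows.append(int(pick))
                    used.add(int(pick))
                    cur = int(pick)
                    stepped = True
                    break
            if not stepped:
                break
    rows = np.asarray(path_rows[::-1], dtype=np.int64)  # proximal -> terminal
    pos = fp.positions[rows]
    step = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    seg = AxonalSegment(
        electrodes=fp.electrodes[rows],
        latency_ms=frames[rows] * 1e3 / fs,
        cumdist_um=np.concatenate([[0.0], np.cumsum(step)]),
        positions=pos,
        degenerate=bool(degenerate),
    )
    if len(seg) >= 3 and not seg.degenerate:
        seg.velocity, seg.r_squared = fit_velocity(seg)
    return seg


def fit_velocity(seg: AxonalSegment) -> tuple:
    """OLS slope of cumulative path distance (um) vs latency (ms) -> mm/s.

    Returns (nan, nan) for fewer than 3 points or zero latency spread
    (undefined velocity).
    """
    if len(seg) < 3:
        return (np.nan, np.nan)
    lat, dist = seg.latency_ms, seg.cumdist_um
    if np.ptp(lat) == 0:
        return (np.nan, np.nan)
    res = stats.linregress(lat, dist)
    return (float(res.slope), float(res.rvalue**2))


def extract_all_segments(
    fp: Footprint, params: TracingParams | None = None
) -> list:
    """Repeat terminal selection -> backward trace until no candidate remains.

    Electrodes of an accepted segment are excluded from later traces (shared
    proximal trunks are attributed to the first-traced branch); segments with
    fewer than ``min_electrodes`` electrodes are discarded, but their
    electrodes are still marked processed so extraction terminates.
    """
    params = params or TracingParams()
    if fp.n_electrodes == 0:
        return []
    segments = []
    assigned: set = set()
    while True:
        cands = terminal_candidates(fp, assigned, params)
        if len(cands) == 0:
            break
        seg = trace_segment(fp, int(cands[0]), params, assigned)
        assigned.update(int(e) for e in seg.electrodes)
        if len(seg) >= params.min_electrodes and not seg.degenerate:
            segments.append(seg)
    return segments


def morphometrics(
    segments: list,
    fp: Footprint,
    spike_times: np.ndarray | None = None,
    duration: float | None = None,
    unit_id: int | None = None,
) -> NeuronMorphometrics:
    """Per-neuron summary: segment count, longest branch, total arbor
    extension (sum of segment lengths), mean velocity, max amplitude, rate."""
    lengths = [s.length for s in segments]
    vels = [s.velocity for s in segments if np.isfinite(s.velocity)]
    r2 = [s.r_squared for s in segments if np.isfinite(s.r_squared)]
    rate = np.nan
    if spike_times is not None and duration:
        rate = len(spike_times) / duration
    return NeuronMorphometrics(
        unit_id=fp.unit_id if unit_id is None else unit_id,
        n_segments=len(segments),
        longest_um=max(lengths) if lengths else 0.0,
        total_extension_um=float(np.sum(lengths)) if lengths else 0.0,
        velocity_mms=float(np.mean(vels)) if vels else np.nan,
        r_squared=float(np.mean(r2)) if r2 else np.nan,
        max_amplitude_uv=float(fp.amplitude.max()) if fp.n_electrodes else 0.0,
        firing_rate_hz=rate,
    )


def segments_table(unit_id: int, segments: list) -> pd.DataFrame:
    """Flat per-electrode table of all segments of one unit."""
    rows = []
    for si, seg in enumerate(segments):
        for k in range(len(seg)):
            rows.append(
                {
                    "unit_id": unit_id,
                    "segment_id": si,
                    "electrode_id": int(seg.electrodes[k]),
                    "order": k,
                    "x_um": seg.positions[k, 0],
                    "y_um": seg.positions[k, 1],
                    "latency_ms": seg.latency_ms[k],
                    "cumdist_um": seg.cumdist_um[k],
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "unit_id", "segment_id", "electrode_id", "order",
            "x_um", "y_um", "latency_ms", "cumdist_um",
        ],
    )
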