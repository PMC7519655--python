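"""Ground-truth simulator for dual-mode MEA recordings.

Generates neurons with branching axonal arbors and per-branch conduction
velocities, Poisson spike trains modulated by network bursts, pairwise
monosynaptic couplings with millisecond latencies, and renders both recording
streams (full-frame APS and high-SNR SM) with mode-specific additive noise.
Everything is deterministic given the random generator, and every rendered
event is attributable to a (neuron, spike, branch point), so the simulator
serves as the oracle for the whole analysis chain.

Model choices (see docs/methods.md):

* the extracellular waveform is a biphasic template (negative then positive
  lobe, 1 ms total) with its negative peak normalised to -1;
* signal amplitude at an electrode is the source amplitude at the nearest
  point of a branch times a lateral decay 1/(1 + d/lambda) with
  lambda = 10 um, with contributions below 1 uV dropped;
* per-stream noise is white Gaussian scaled so that its rms inside the AP
  band (0.3-5 kHz) equals the nominal mode noise (10.4 / 3.0 uV rms).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from .geometry import ElectrodeArray, InvalidParameterError
from .recording import DualModeRecording, ModeParams

__all__ = [
    "Branch",
    "GroundTruthNeuron",
    "NetworkSpec",
    "GroundTruth",
    "SpatialDecay",
    "generate_arbor",
    "generate_network_spikes",
    "render_recording",
    "biphasic_waveform",
]

AP_BAND = (300.0, 5000.0)

# ---------------------------------------------------------------------------
# waveform template


def _raw_waveform(t_ms):
    t = np.asarray(t_ms, dtype=np.float64)
    neg = np.exp(-((t - 0.40) ** 2) / (2 * 0.12**2))
    pos = 0.40 * np.exp(-((t - 0.85) ** 2) / (2 * 0.18**2))
    out = (pos - neg) * ((t >= 0.0) & (t <= 1.4))
    return out


# normalise numerically so the negative peak is exactly -1 at a known time
_grid = np.arange(0.0, 1.4001, 1e-4)
_vals = _raw_waveform(_grid)
_scale = -_vals.min()
WAVEFORM_PEAK_MS = float(_grid[int(np.argmin(_vals))])
WAVEFORM_DURATION_MS = 1.4
del _grid, _vals


def biphasic_waveform(t_ms):
    """Unit biphasic template: min value -1 at ``t = WAVEFORM_PEAK_MS`` ms."""
    return _raw_waveform(t_ms) / _scale


# ---------------------------------------------------------------------------
# ground-truth types


@dataclass
class Branch:
    """One axonal branch: an ordered polyline with a conduction velocity."""

    points: np.ndarray  # (P, 2) um
    velocity: float  # mm/s (== um/ms)
    amp_start: float = 14.0  # uV at the proximal end
    amp_end: float = 9.0  # uV at the distal end

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[0] < 2:
            raise InvalidParameterError("branch polyline needs >= 2 points")
        if not self.velocity > 0:
            raise InvalidParameterError("branch velocity must be > 0")

    @property
    def length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())

    def amplitude_at(self, s: np.ndarray) -> np.ndarray:
        """Source amplitude (uV) at arclength ``s``, linear proximal->distal."""
        L = max(self.length, 1e-12)
        return self.amp_start + (self.amp_end - self.amp_start) * np.asarray(s) / L


@dataclass
class GroundTruthNeuron:
    neuron_id: int
    ais_position: np.ndarray  # (2,) um
    branches: list  # of Branch, all starting at ais_position
    soma_amplitude: float = -150.0  # uV, negative peak near the AIS

    def __post_init__(self) -> None:
        self.ais_position = np.asarray(self.ais_position, dtype=np.float64)
        if not self.soma_amplitude < 0:
            raise InvalidParameterError("soma_amplitude must be negative")
        for b in self.branches:
            if not np.allclose(b.points[0], self.ais_position):
                raise InvalidParameterError("branches must start at ais_position")


@dataclass
class NetworkSpec:
    """Population spiking statistics used by :func:`generate_network_spikes`.

    ``firing_rate`` is the baseline (non-burst) rate per neuron, either a
    scalar applied to all neurons or a sequence of per-neuron rates.
    ``connections`` holds (pre, post, latency_ms, probability) tuples: each
    presynaptic spike elicits one postsynaptic spike at +latency with the
    given probability.
    """

    n_neurons: int = 40
    firing_rate: float | np.ndarray = 2.4  # Hz
    connections: list = field(default_factory=list)
    burst_rate: float = 0.15  # bursts per second
    burst_duration: float = 0.8  # s
    burst_gain: float = 5.0  # rate multiplier inside bursts

    def __post_init__(self) -> None:
        for pre, post, lat, p in self.connections:
            if not 0.0 <= p <= 1.0:
                raise InvalidParameterError(f"transmission probability {p} not in [0,1]")
            if not lat > 0:
                raise InvalidParameterError(f"connection latency {lat} must be > 0")
            if not (0 <= pre < self.n_neurons and 0 <= post < self.n_neurons):
                raise InvalidParameterError(
                    f"connection ({pre}, {post}) references a unit outside "
                    f"0..{self.n_neurons - 1}"
                )
        if self.burst_gain < 1.0:
            raise InvalidParameterError("burst_gain must be >= 1")

    def rates(self) -> np.ndarray:
        r = np.broadcast_to(np.asarray(self.firing_rate, dtype=float), (self.n_neurons,))
        return np.array(r)


@dataclass
class GroundTruth:
    """Everything the simulator knows: the oracle for downstream tests."""

    neurons: list  # of GroundTruthNeuron
    spike_trains: dict  # neuron id -> spike times (s)
    hits: dict  # neuron id -> DataFrame(branch, electrode, s_um, latency_ms, amplitude_uv)
    connections: list = field(default_factory=list)
    seed: int | None = None

    def hit_table(self, neuron_id: int) -> pd.DataFrame:
        return self.hits[neuron_id]


@dataclass(frozen=True)
class SpatialDecay:
    """Amplitude-vs-distance law (isolated here; it is a modelling stand-in).

    Axonal (line-source) signals decay as 1/(1 + d/lambda); the soma, a
    compact source, uses the same law squared so that a 150 uV soma does not
    remain visible millimetres away.  Contributions below ``clip_uv`` are
    dropped.
    """

    lambda_um: float = 10.0
    clip_uv: float = 1.0
    soma_exponent: float = 2.0

    def factor(self, d_um: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.asarray(d_um) / self.lambda_um)

    def soma_factor(self, d_um: np.ndarray) -> np.ndarray:
        return self.factor(d_um) ** self.soma_exponent


# ---------------------------------------------------------------------------
# arbor generation


def _clip_length_to_bounds(origin, angle, length, bounds):
    """Largest t <= length with origin + t*(cos,sin) inside the bounds box."""
    xmin, xmax, ymin, ymax = bounds
    dx, dy = np.cos(angle), np.sin(angle)
    t = length
    for d, lo, hi, o in ((dx, xmin, xmax, origin[0]), (dy, ymin, ymax, origin[1])):
        if d > 1e-12:
            t = min(t, (hi - o) / d)
        elif d < -1e-12:
            t = min(t, (lo - o) / d)
    return max(t, 0.0)


def generate_arbor(
    rng: np.random.Generator,
    bounds,
    n_branches=1,
    velocity_range=(300.0, 700.0),
    length_range=(600.0, 900.0),
    direction_range=(-np.pi, np.pi),
    ais_position=None,
    soma_amplitude: float = -150.0,
    axon_amp=(14.0, 9.0),
    neuron_id: int = 0,
    margin: float = 20.0,
) -> GroundTruthNeuron:
    """Draw a branching arbor with per-branch conduction velocities.

    ``bounds`` is (xmin, xmax, ymin, ymax) in um; all polylines are clipped to
    it.  ``n_branches`` may be an int or an (lo, hi) inclusive range sampled
    uniformly.  Velocities are drawn uniformly from ``velocity_range``.
    """
    xmin, xmax, ymin, ymax = bounds
    if not (xmax > xmin and ymax > ymin):
        raise InvalidParameterError("bounds must span a non-empty area")
    lo, hi = velocity_range
    if not (0 < lo <= hi):
        raise InvalidParameterError("velocity range must be positive")
    if ais_position is None:
        ais_position = np.array(
            [
                rng.uniform(xmin + margin, max(xmin + margin, xmax - margin)),
                rng.uniform(ymin + margin, max(ymin + margin, ymax - margin)),
            ]
        )
    ais_position = np.asarray(ais_position, dtype=np.float64)
    if np.isscalar(n_branches):
        nb = int(n_branches)
    else:
        nb = int(rng.integers(n_branches[0], n_branches[1] + 1))
    branches = []
    for _ in range(nb):
        angle = rng.uniform(*direction_range)
        length = rng.uniform(*length_range)
        length = _clip_length_to_bounds(ais_position, angle, length, bounds)
        end = ais_position + length * np.array([np.cos(angle), np.sin(angle)])
        branches.append(
            Branch(
                points=np.array([ais_position, end]),
                velocity=float(rng.uniform(lo, hi)),
                amp_start=axon_amp[0],
                amp_end=axon_amp[1],
            )
        )
    return GroundTruthNeuron(
        neuron_id=neuron_id,
        ais_position=ais_position,
        branches=branches,
        soma_amplitude=soma_amplitude,
    )


# ---------------------------------------------------------------------------
# spiking


def _burst_windows(rng, rate, duration, burst_duration):
    n = rng.poisson(rate * duration)
    onsets = np.sort(rng.uniform(0.0, duration, n))
    return onsets, onsets + burst_duration


def generate_network_spikes(
    spec: NetworkSpec, duration: float, rng: np.random.Generator
) -> dict:
    """Baseline-Poisson trains with burst modulation and synaptic couplings.

    Returns a dict neuron id -> sorted spike times in seconds, all within
    [0, duration).
    """
    if duration < 0:
        raise InvalidParameterError("duration must be >= 0")
    rates = spec.rates()
    gain = spec.burst_gain
    if spec.burst_rate > 0 and gain > 1.0:
        b_on, b_off = _burst_windows(rng, spec.burst_rate, duration, spec.burst_duration)
    else:
        b_on = b_off = np.empty(0)

    def in_burst(t):
        if len(b_on) == 0:
            return np.zeros(len(t), dtype=bool)
        k = np.searchsorted(b_on, t, side="right") - 1
        ok = k >= 0
        out = np.zeros(len(t), dtype=bool)
        out[ok] = t[ok] < b_off[k[ok]]
        return out

    trains = {}
    for i in range(spec.n_neurons):
        r = rates[i]
        n_cand = rng.poisson(r * gain * duration)
        t = np.sort(rng.uniform(0.0, duration, n_cand))
        accept = in_burst(t) | (rng.random(n_cand) < 1.0 / gain)
        trains[i] = t[accept]
    # monosynaptic couplings: each presynaptic spike may add one postsynaptic
    # spike at +latency
    extra = {i: [] for i in range(spec.n_neurons)}
    for pre, post, lat_ms, p in spec.connections:
        pre_t = trains[pre]
        hit = rng.random(len(pre_t)) < p
        extra[post].append(pre_t[hit] + lat_ms * 1e-3)
    for i in range(spec.n_neurons):
        if extra[i]:
            t = np.concatenate([trains[i]] + extra[i])
        else:
            t = trains[i]
        t = np.unique(t)
        trains[i] = t[(t >= 0.0) & (t < duration)]
    return trains


# ---------------------------------------------------------------------------
# rendering


def _branch_hits(branch: Branch, positions: np.ndarray, decay: SpatialDecay):
    """Nearest-point projection of every electrode onto one branch polyline.

    Returns (electrode row indices, arclength s, latency ms, amplitude uV)
    for electrodes whose amplitude clears the decay clip.
    """
    p = branch.points
    seg_vec = np.diff(p, axis=0)  # (S, 2)
    seg_len = np.linalg.norm(seg_vec, axis=1)
    keep = seg_len > 1e-12
    seg_vec, seg_len, seg_start = seg_vec[keep], seg_len[keep], p[:-1][keep]
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])[:-1]
    # (E, S) projections
    rel = positions[:, None, :] - seg_start[None, :, :]
    t = np.clip(
        np.einsum("esk,sk->es", rel, seg_vec) / (seg_len**2)[None, :], 0.0, 1.0
    )
    proj = seg_start[None] + t[..., None] * seg_vec[None]
    d = np.linalg.norm(positions[:, None, :] - proj, axis=2)
    best = np.argmin(d, axis=1)
    rows = np.arange(len(positions))
    d_min = d[rows, best]
    s = cum[best] + t[rows, best] * seg_len[best]
    amp = branch.amplitude_at(s) * decay.factor(d_min)
    keep_e = amp >= decay.clip_uv
    lat = s / branch.velocity  # um / (um/ms) = ms
    return rows[keep_e], s[keep_e], lat[keep_e], amp[keep_e]


def neuron_hits(
    neuron: GroundTruthNeuron, array: ElectrodeArray, decay: SpatialDecay | None = None
) -> pd.DataFrame:
    """Ground-truth hit table: branch id (-1 = soma), electrode, arclength,
    arrival latency and peak amplitude at every electrode that sees the cell."""
    decay = decay or SpatialDecay()
    pos = array.positions
    frames = []
    d_soma = np.linalg.norm(pos - neuron.ais_position, axis=1)
    # soma_amplitude is defined as the negative peak at the AIS-nearest
    # electrode: normalise the profile so that electrode records it exactly.
    # The reference distance is capped at the lattice covering radius so an
    # out-of-bounds soma is not boosted onto far electrodes.
    ref = min(d_soma.min(), array.pitch / np.sqrt(3.0))
    amp_soma = (
        -neuron.soma_amplitude * decay.soma_factor(d_soma) / decay.soma_factor(ref)
    )
    keep = amp_soma >= decay.clip_uv
    frames.append(
        pd.DataFrame(
            {
                "branch": -1,
                "electrode": array.ids[keep],
                "s_um": 0.0,
                "latency_ms": 0.0,
                "amplitude_uv": amp_soma[keep],
            }
        )
    )
    for j, br in enumerate(neuron.branches):
        rows, s, lat, amp = _branch_hits(br, pos, decay)
        frames.append(
            pd.DataFrame(
                {
                    "branch": j,
                    "electrode": array.ids[rows],
                    "s_um": s,
                    "latency_ms": lat,
                    "amplitude_uv": amp,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _white_noise_sigma(noise_rms: float, fs: float, band=AP_BAND) -> float:
    """White-noise std so that the rms inside ``band`` equals ``noise_rms``."""
    nyq = fs / 2.0
    frac = max(min(band[1], nyq) - band[0], 0.0) / nyq
    if frac <= 0:
        return noise_rms
    return noise_rms / np.sqrt(frac)


def _add_noise(stream: np.ndarray, rng: np.random.Generator, sigma: float,
               chunk: int = 64) -> None:
    """Add white Gaussian noise in place, row blocks to bound temporaries."""
    s = np.float32(sigma)
    for r0 in range(0, stream.shape[0], chunk):
        blk = rng.standard_normal(stream[r0 : r0 + chunk].shape, dtype=np.float32)
        np.multiply(blk, s, out=blk)
        stream[r0 : r0 + chunk] += blk


def _render_stream(
    stream: np.ndarray,
    fs: float,
    row_of_electrode: dict,
    hits: pd.DataFrame,
    spikes: np.ndarray,
) -> None:
    """Add the biphasic template for every (hit, spike) event in place."""
    rows = np.array([row_of_electrode.get(int(e), -1) for e in hits["electrode"]])
    ok = rows >= 0
    if not ok.any() or len(spikes) == 0:
        return
    rows = rows[ok]
    lat = hits["latency_ms"].to_numpy()[ok]
    amp = hits["amplitude_uv"].to_numpy()[ok]
    n_w = int(np.ceil(WAVEFORM_DURATION_MS * 1e-3 * fs)) + 2
    T = stream.shape[1]
    t_start = spikes[None, :] + (lat[:, None] - WAVEFORM_PEAK_MS) * 1e-3  # (H, S)
    f0 = np.ceil(t_start * fs).astype(np.int64)
    offs = np.arange(n_w, dtype=np.int64)
    frames = f0[..., None] + offs  # (H, S, n_w)
    ph_ms = (frames / fs - t_start[..., None]) * 1e3
    vals = amp[:, None, None] * biphasic_waveform(ph_ms)
    flat_idx = rows[:, None, None] * T + frames
    m = (frames >= 0) & (frames < T)
    np.add.at(stream.reshape(-1), flat_idx[m], vals[m].astype(stream.dtype))


def render_recording(
    neurons,
    spike_trains: dict,
    array: ElectrodeArray,
    aps_params: ModeParams | None = None,
    sm_params: ModeParams | None = None,
    sm_electrodes=None,
    rng: np.random.Generator | None = None,
    duration: float | None = None,
    decay: SpatialDecay | None = None,
    noise: bool = True,
    connections=None,
    seed: int | None = None,
):
    """Render both streams for a set of neurons and spike trains.

    For every spike and every branch point the biphasic template, scaled by
    the local amplitude, is added at ``spike time + arclength / velocity``,
    sampled at each stream's rate; mode-specific white Gaussian noise is added
    afterwards.  Returns ``(DualModeRecording, GroundTruth)``.
    """
    rng = rng or np.random.default_rng()
    decay = decay or SpatialDecay()
    sm_electrodes = np.asarray(
        [] if sm_electrodes is None else sm_electrodes, dtype=np.int64
    )
    aps_params = aps_params or ModeParams.aps_default(array.n_electrodes)
    sm_params = sm_params or ModeParams.sm_default(max(len(sm_electrodes), 1))
    if duration is None:
        last = max((t[-1] for t in spike_trains.values() if len(t)), default=0.0)
        duration = last + 0.05
    n_aps = int(round(duration * aps_params.sampling_rate))
    n_sm = int(round(duration * sm_params.sampling_rate))
    aps = np.zeros((array.n_electrodes, n_aps), dtype=np.float32)
    sm = np.zeros((len(sm_electrodes), n_sm), dtype=np.float32)
    aps_row = {int(e): i for i, e in enumerate(array.ids)}
    sm_row = {int(e): i for i, e in enumerate(sm_electrodes)}

    xmin, ymin = array.positions.min(axis=0)
    xmax, ymax = array.positions.max(axis=0)
    hits = {}
    for neuron in neurons:
        ax, ay = neuron.ais_position
        if not (xmin <= ax <= xmax and ymin <= ay <= ymax):
            warnings.warn(
                f"neuron {neuron.neuron_id} lies outside the array bounds; "
                "rendering only in-bounds electrodes",
                stacklevel=2,
            )
        h = neuron_hits(neuron, array, decay)
        # the soma row carries the full (negative-peak) soma amplitude
        hits[neuron.neuron_id] = h
        spikes = np.asarray(spike_trains.get(neuron.neuron_id, ()), dtype=np.float64)
        _render_stream(aps, aps_params.sampling_rate, aps_row, h, spikes)
        if len(sm_electrodes):
            _render_stream(sm, sm_params.sampling_rate, sm_row, h, spikes)
    if noise:
        if aps_params.noise_rms > 0:
            _add_noise(aps, rng, _white_noise_sigma(aps_params.noise_rms,
                                                    aps_params.sampling_rate))
        if sm_params.noise_rms > 0 and len(sm_electrodes):
            _add_noise(sm, rng, _white_noise_sigma(sm_params.noise_rms,
                                                   sm_params.sampling_rate))
    rec = DualModeRecording(
        array=array,
        aps=aps,
        sm=sm,
        sm_electrodes=sm_electrodes,
        aps_params=aps_params,
        sm_params=sm_params,
        t0=0.0,
        units={k: np.asarray(v) for k, v in spike_trains.items()},
    )
    gt = GroundTruth(
        neurons=list(neurons),
        spike_trains={k: np.asarray(v) for k, v in spike_trains.items()},
        hits=hits,
        connections=list(connections or []),
        seed=seed,
    )
    return rec, gt


# ---------------------------------------------------------------------------
# ground-truth persistence (appended to the recording container)


def write_ground_truth(path, gt: GroundTruth) -> None:
    """Append /ground_truth/* groups to an existing recording container."""
    with h5py.File(path, "a") as f:
        if "ground_truth" in f:
            del f["ground_truth"]
        root = f.create_group("ground_truth")
        if gt.seed is not None:
            root.attrs["seed"] = int(gt.seed)
        ng = root.create_group("neurons")
        for neuron in gt.neurons:
            g = ng.create_group(str(neuron.neuron_id))
            g.create_dataset("ais_position", data=neuron.ais_position)
            g.attrs["soma_amplitude_uv"] = float(neuron.soma_amplitude)
            bg = g.create_group("branches")
            for j, br in enumerate(neuron.branches):
                b = bg.create_group(str(j))
                b.create_dataset("points", data=br.points)
                b.attrs["velocity_mms"] = float(br.velocity)
                b.attrs["amp_start_uv"] = float(br.amp_start)
                b.attrs["amp_end_uv"] = float(br.amp_end)
            hits = gt.hits.get(neuron.neuron_id)
            if hits is not None:
                hg = g.create_group("hits")
                for col in ("branch", "electrode", "s_um", "latency_ms", "amplitude_uv"):
                    hg.create_dataset(col, data=hits[col].to_numpy())
        sg = root.create_group("spike_trains")
        for uid, times in gt.spike_trains.items():
            sg.create_dataset(str(uid), data=np.asarray(times, dtype=np.float64))
        if gt.connections:
            conn = np.array(
                [(int(a), int(b), float(l), float(p)) for a, b, l, p in gt.connections],
                dtype=[("pre", "i8"), ("post", "i8"), ("latency_ms", "f8"), ("p", "f8")],
            )
            root.create_dataset("connections", data=conn)


def read_ground_truth(path) -> GroundTruth:
    """Read back /ground_truth/* written by :func:`write_ground_truth`."""
    neurons, hits, trains, connections = [], {}, {}, []
    with h5py.File(path, "r") as f:
        root = f["ground_truth"]
        seed = int(root.attrs["seed"]) if "seed" in root.attrs else None
        for key in sorted(root["neurons"], key=int):
            g = root["neurons"][key]
            branches = [
                Branch(
                    points=g["branches"][j]["points"][...],
                    velocity=float(g["branches"][j].attrs["velocity_mms"]),
                    amp_start=float(g["branches"][j].attrs["amp_start_uv"]),
                    amp_end=float(g["branches"][j].attrs["amp_end_uv"]),
                )
                for j in sorted(g["branches"], key=int)
            ]
            neurons.append(
                GroundTruthNeuron(
                    neuron_id=int(key),
                    ais_position=g["ais_position"][...],
                    branches=branches,
                    soma_amplitude=float(g.attrs["soma_amplitude_uv"]),
                )
            )
            if "hits" in g:
                hits[int(key)] = pd.DataFrame(
                    {col: g["hits"][col][...] for col in g["hits"]}
                )
        for uid in root["spike_trains"]:
            trains[int(uid)] = root["spike_trains"][uid][...]
        if "connections" in root:
            connections = [
                (int(r["pre"]), int(r["post"]), float(r["latency_ms"]), float(r["p"]))
                for r in root["connections"][...]
            ]
    return GroundTruth(
        neurons=neurons, spike_trains=trains, hits=hits,
        connections=connections, seed=seed,
    )
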