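"""Ground-truth validation experiments on the bundled simulator.

Each function builds a self-contained experiment -- simulated recording with
known ground truth, analysis through the public API, comparison against the
truth or against an independently coded oracle -- and returns a dict of
measured quantities.  They are used by the test suite and by
``scripts/acceptance.py``; problem sizes are chosen to run on a single CPU in
minutes (see docs/methods.md).
"""

from __future__ import annotations

import numpy as np

from .detection import align_triggers, bandpass, detect_spikes
from .geometry import ArrayParams, build_hex_array
from .network import (
    CCGParams,
    compute_ccg,
    convolution_null,
    detect_bursts,
    detect_connections,
    population_rate,
    BurstParams,
)
from .simulate import (
    Branch,
    GroundTruthNeuron,
    NetworkSpec,
    WAVEFORM_PEAK_MS,
    biphasic_waveform,
    generate_arbor,
    generate_network_spikes,
    render_recording,
)
from .sta import footprint_from_recording
from .tracing import CleaningParams, TracingParams, clean_footprint, extract_all_segments

APS_FS = 11_600.0
FRAME_MS = 1e3 / APS_FS


# ---------------------------------------------------------------------------
# straight-axon tracker recovery (noiseless, quantisation only)


def _sampled_peaks(lat_ms: np.ndarray, amp: np.ndarray, fs: float = APS_FS):
    """Analytic sampled footprint of isolated events: for an event of
    amplitude ``amp`` peaking at ``lat_ms``, the value recorded at integer
    frames is the continuous template evaluated on the sample grid.  Returns
    (measured amplitude, peak frame index)."""
    period = 1e3 / fs
    j = np.arange(-4, int(np.ceil(lat_ms.max() / period)) + 6)
    vals = amp[:, None] * biphasic_waveform(
        j[None, :] * period - lat_ms[:, None] + WAVEFORM_PEAK_MS
    )
    return -vals.min(axis=1), j[np.argmin(vals, axis=1)]


def expected_backward_track(
    hits, amp_threshold: float, stop_frames: int = 5, fs: float = APS_FS
) -> np.ndarray:
    """Oracle for the backward tracker on an isolated noiseless branch.

    From the ground-truth hit table of one branch, computes each electrode's
    sampled amplitude and peak frame analytically, then applies the stated
    selection rule -- one electrode per frame, largest amplitude (ties to
    lowest id), frames from the terminal back to ``stop_frames`` -- entirely
    independently of the footprint/tracker code path.
    """
    lat = hits["latency_ms"].to_numpy()
    amp_true = hits["amplitude_uv"].to_numpy()
    el = hits["electrode"].to_numpy()
    amp_meas, pk = _sampled_peaks(lat, amp_true, fs)
    ref_amp, ref_pk = _sampled_peaks(np.array([0.0]), np.array([1.0]), fs)
    frames = pk - ref_pk[0]
    sup = amp_meas > amp_threshold
    path = []
    for f in range(stop_frames, int(frames[sup].max()) + 1):
        m = sup & (frames == f)
        if not m.any():
            continue
        k = np.lexsort((el[m], -amp_meas[m]))[0]
        path.append(int(el[m][k]))
    return np.asarray(path, dtype=np.int64)


def straight_axon_experiment(seed: int = 0) -> dict:
    """Noiseless straight axon, 500 mm/s over 800 um on an 18 um lattice.

    The traced path must equal the analytic per-frame hit sequence and the
    fitted velocity must match 500 mm/s up to frame quantisation.
    """
    arr = build_hex_array(ArrayParams(12, 56, 18.0))
    ais_id = 6 * 56 + 2
    ais = arr.position(ais_id)
    branch = Branch(
        points=np.array([ais, ais + [800.0, 0.0]]),
        velocity=500.0,
        amp_start=16.0,
        amp_end=6.0,
    )
    neuron = GroundTruthNeuron(0, ais, [branch], soma_amplitude=-150.0)
    spikes = {0: np.arange(100) * 0.1 + 0.05}  # exact APS frame times
    rec, gt = render_recording(
        [neuron], spikes, arr, rng=np.random.default_rng(seed), duration=10.1,
        noise=False,
    )
    trig = np.rint(spikes[0] * APS_FS).astype(np.int64)
    fp = footprint_from_recording(rec, trig)
    nominal_noise = 1.0  # uV: nominal per-electrode std for the noiseless fixture
    cleaned = clean_footprint(fp, noise_std=nominal_noise)
    params = TracingParams()
    segments = extract_all_segments(cleaned, params)
    seg = max(segments, key=len)
    hits = gt.hits[0]
    expected = expected_backward_track(
        hits[hits["branch"] == 0],
        amp_threshold=CleaningParams().amp_k * nominal_noise,
        stop_frames=params.stop_frames,
    )
    match = np.array_equal(seg.electrodes, expected)
    return {
        "n_segments": len(segments),
        "traced_path": seg.electrodes,
        "expected_path": expected,
        "path_match": bool(match),
        "velocity_mms": float(seg.velocity),
        "velocity_error_pct": float(100 * abs(seg.velocity - 500.0) / 500.0),
        "r_squared": float(seg.r_squared),
    }


# ---------------------------------------------------------------------------
# velocity and arbor-extension recovery under noise


def velocity_recovery_experiment(
    seed: int = 0,
    n_neurons: int = 50,
    velocity_range=(300.0, 700.0),
    n_spikes: int = 300,
) -> dict:
    """Parameter recovery for simulated arbors under full APS noise.

    Each neuron is rendered on its own 20 x 56 sub-array with 10.4 uV rms
    noise, averaged over ``n_spikes`` ground-truth triggers, cleaned, traced
    and fitted.  The ground-truth trackable extension of a branch is the
    suprathreshold hit length beyond the 5-frame initiation region the
    tracker excludes by construction.
    """
    rng = np.random.default_rng(seed)
    arr = build_hex_array(ArrayParams(20, 56, 18.0))
    xmin, ymin = arr.positions.min(axis=0)
    xmax, ymax = arr.positions.max(axis=0)
    bounds = (xmin, xmax, ymin, ymax)
    ymid = (ymin + ymax) / 2.0
    params = TracingParams()
    duration = 12.0
    records = []
    for i in range(n_neurons):
        ais = np.array([xmin + 40.0, ymid + rng.uniform(-40.0, 40.0)])
        neuron = generate_arbor(
            rng,
            bounds,
            n_branches=1,
            velocity_range=velocity_range,
            length_range=(600.0, 900.0),
            direction_range=(-0.15, 0.15),
            ais_position=ais,
            neuron_id=0,
        )
        v_true = neuron.branches[0].velocity
        spikes = {0: np.sort(rng.uniform(0.2, duration - 0.2, n_spikes))}
        rec, gt = render_recording(
            [neuron], spikes, arr, rng=rng, duration=duration, noise=True
        )
        trig = np.rint(spikes[0] * APS_FS).astype(np.int64)
        fp = footprint_from_recording(rec, trig)
        cleaned = clean_footprint(fp)
        segments = extract_all_segments(cleaned, params)
        vels = [s.velocity for s in segments if np.isfinite(s.velocity)]
        total = float(sum(s.length for s in segments))
        hits = gt.hits[0]
        ax = hits[hits["branch"] == 0]
        thr = CleaningParams().amp_k * 10.4 / np.sqrt(n_spikes)
        sup = ax[ax["amplitude_uv"] > thr]
        s_stop = params.stop_frames * FRAME_MS * v_true
        ext_true = max(float(sup["s_um"].max()) - s_stop, 0.0)
        v_fit = float(np.mean(vels)) if vels else np.nan
        records.append(
            {
                "v_true": v_true,
                "v_fit": v_fit,
                "v_error_pct": 100 * abs(v_fit - v_true) / v_true if vels else np.nan,
                "sign_ok": bool(vels and v_fit > 0),
                "n_segments": len(segments),
                "ext_true": ext_true,
                "ext_fit": total,
                "ext_error_pct": 100 * abs(total - ext_true) / ext_true
                if ext_true > 0
                else np.nan,
            }
        )
    v_err = np.array([r["v_error_pct"] for r in records])
    e_err = np.array([r["ext_error_pct"] for r in records])
    return {
        "records": records,
        "n_neurons": n_neurons,
        "n_traced": int(np.isfinite(v_err).sum()),
        "median_velocity_error_pct": float(np.nanmedian(v_err)),
        "median_extension_error_pct": float(np.nanmedian(e_err)),
        "all_signs_ok": bool(all(r["sign_ok"] for r in records if np.isfinite(r["v_error_pct"]))),
    }


# ---------------------------------------------------------------------------
# dual-mode STA: convergence and recovery of a unit invisible to APS


def dual_mode_sta_experiment(
    seed: int = 0,
    soma_uv: float = -40.0,
    n_spikes: int = 1000,
    n_values=(10, 32, 100, 316, 1000),
) -> dict:
    """A -40 uV unit: invisible to direct APS detection (threshold
    7.5 x 10.4 uV) but recovered through SM-stream triggers.

    Spikes sit on both sample grids (multiples of 50 ms), so the noiseless
    rendering is the exact reference footprint; the residual of the noisy STA
    against it measures pure noise averaging (sigma/sqrt(N)).
    """
    arr = build_hex_array(ArrayParams(8, 8, 18.0))
    ais_id = 4 * 8 + 4
    ais = arr.position(ais_id)
    neuron = GroundTruthNeuron(0, ais, [], soma_amplitude=soma_uv)
    spikes = {0: (np.arange(n_spikes) + 1) * 0.05}
    duration = n_spikes * 0.05 + 0.1
    common = dict(
        sm_electrodes=[ais_id], duration=duration, connections=None, seed=seed
    )
    rec, _ = render_recording(
        [neuron], spikes, arr, rng=np.random.default_rng(seed), noise=True, **common
    )
    clean_rec, _ = render_recording(
        [neuron], spikes, arr, rng=np.random.default_rng(seed), noise=False, **common
    )
    fs_sm = rec.sm_params.sampling_rate
    sm_filtered = bandpass(rec.sm_trace(ais_id), (300.0, 3000.0), fs_sm)
    sm_times = detect_spikes(sm_filtered, fs_sm, threshold_k=7.5)
    frames, _ = align_triggers(sm_times, APS_FS, rec.n_frames)
    # direct APS detection at the AIS electrode: at 7.5 x the 10.4 uV mode
    # noise the -40 uV unit is invisible
    aps_filtered = bandpass(rec.aps_trace(ais_id), (300.0, 3000.0), APS_FS)
    aps_det = detect_spikes(
        aps_filtered, APS_FS, threshold_k=7.5, noise_std=rec.aps_params.noise_rms
    )
    residuals = {}
    peak_100 = np.nan
    for n in n_values:
        if n > len(frames):
            continue
        fp = footprint_from_recording(rec, frames[:n])
        ref = footprint_from_recording(clean_rec, frames[:n])
        residuals[n] = float(
            np.sqrt(np.mean((fp.waveforms - ref.waveforms) ** 2))
        )
        if n == 100:
            row = int(np.flatnonzero(fp.electrodes == ais_id)[0])
            peak_100 = float(fp.waveforms[row].min())
    ns = np.array(sorted(residuals))
    errs = np.array([residuals[n] for n in ns])
    slope = float(np.polyfit(np.log10(ns), np.log10(errs), 1)[0])
    return {
        "n_triggers": int(len(frames)),
        "n_aps_detections": int(len(aps_det)),
        "residual_rms_uv": {int(n): residuals[n] for n in residuals},
        "residual_rms_100_uv": residuals.get(100, np.nan),
        "convergence_slope": slope,
        "peak_uv_100": peak_100,
        "peak_error_pct": float(100 * abs(peak_100 - soma_uv) / abs(soma_uv)),
    }


# ---------------------------------------------------------------------------
# connectivity: injected synapses and null calibration


def _random_connections(rng, n_units, n_connections, p, latency_range=(1.0, 5.0)):
    pairs = set()
    while len(pairs) < n_connections:
        i, j = rng.integers(0, n_units, 2)
        if i == j or (i, j) in pairs or (j, i) in pairs:
            continue
        pairs.add((int(i), int(j)))
    return [
        (i, j, float(rng.uniform(*latency_range)), p) for i, j in sorted(pairs)
    ]


def connectivity_experiment(
    seed: int = 0,
    n_units: int = 40,
    n_connections: int = 20,
    rate_hz: float = 10.0,
    duration: float = 300.0,
    p: float = 0.3,
) -> dict:
    """Recovery of injected monosynaptic connections from spike trains alone."""
    rng = np.random.default_rng(seed)
    connections = _random_connections(rng, n_units, n_connections, p)
    spec = NetworkSpec(
        n_neurons=n_units,
        firing_rate=rate_hz,
        connections=connections,
        burst_rate=0.0,
        burst_gain=1.0,
    )
    trains = generate_network_spikes(spec, duration, rng)
    params = CCGParams()
    found = {}
    for i in range(n_units):
        for j in range(i + 1, n_units):
            ccg = convolution_null(compute_ccg(trains[i], trains[j], params), params)
            for conn in detect_connections(ccg, params, pre=i, post=j):
                found[(conn.pre, conn.post)] = conn.latency_ms
    recovered = 0
    lat_errors = []
    for pre, post, lat, _ in connections:
        if (pre, post) in found:
            err = abs(found[(pre, post)] - lat)
            lat_errors.append(err)
            if err <= 1.0 + 1e-9:
                recovered += 1
    extra = len(found) - sum(1 for c in connections if (c[0], c[1]) in found)
    return {
        "n_injected": n_connections,
        "n_recovered": recovered,
        "recovery_pct": 100.0 * recovered / n_connections,
        "latency_errors_ms": lat_errors,
        "median_latency_error_ms": float(np.median(lat_errors)) if lat_errors else np.nan,
        "n_extra_edges": int(extra),
    }


# --- independent oracle of the identical CCG test --------------------------


def _oracle_ccg_counts(a, b, params: CCGParams) -> np.ndarray:
    """Per-bin pair counting via two searchsorted calls per lag bin (a code
    path independent of the production gather-and-histogram CCG)."""
    n = int(round(params.window_ms / params.bin_ms))
    counts = np.empty(2 * n + 1, dtype=np.int64)
    for k, lag in enumerate(np.arange(-n, n + 1) * params.bin_ms):
        lo = (lag - params.bin_ms / 2.0) * 1e-3
        hi = (lag + params.bin_ms / 2.0) * 1e-3
        counts[k] = int(
            (np.searchsorted(b, a + hi, side="left")
             - np.searchsorted(b, a + lo, side="left")).sum()
        )
    return counts


def _oracle_poisson_quantile(mu: float, q: float) -> int:
    """Smallest k with Poisson CDF(k; mu) >= q, by direct pmf summation."""
    if mu <= 0:
        return 0
    k, pmf = 0, np.exp(-mu)
    cdf = pmf
    while cdf < q and k < 10_000:
        k += 1
        pmf *= mu / k
        cdf += pmf
    return k


def _oracle_detect(a, b, params: CCGParams) -> bool:
    """Independent re-implementation of the whole significance test."""
    counts = _oracle_ccg_counts(a, b, params)
    sigma_bins = params.null_sigma_ms / params.bin_ms
    half = int(np.ceil(4 * sigma_bins))
    x = np.arange(-half, half + 1)
    w = np.exp(-(x**2) / (2 * sigma_bins**2))
    w[half] *= 1.0 - params.hollow_fraction
    n = len(counts)
    lags = np.arange(-(n // 2), n // 2 + 1) * params.bin_ms
    for k in range(n):
        if not (0 < abs(lags[k]) <= params.peak_window_ms):
            continue
        num = den = 0.0
        for m in range(-half, half + 1):
            if 0 <= k + m < n:
                num += counts[k + m] * w[m + half]
                den += w[m + half]
        mu = num / den
        if counts[k] > _oracle_poisson_quantile(mu, 1.0 - params.alpha):
            return True
    return False


def null_calibration_experiment(
    seed: int = 0,
    n_pairs: int = 1000,
    rate_hz: float = 10.0,
    duration: float = 300.0,
) -> dict:
    """False-positive calibration on independent stationary Poisson pairs.

    The production test and an independently coded oracle of the identical
    test run on the same pairs; their detection rates must agree within the
    binomial 95% confidence interval.
    """
    rng = np.random.default_rng(seed)
    params = CCGParams()
    det_pkg = det_orc = 0
    for _ in range(n_pairs):
        a = np.sort(rng.uniform(0.0, duration, rng.poisson(rate_hz * duration)))
        b = np.sort(rng.uniform(0.0, duration, rng.poisson(rate_hz * duration)))
        ccg = convolution_null(compute_ccg(a, b, params), params)
        if detect_connections(ccg, params):
            det_pkg += 1
        if _oracle_detect(a, b, params):
            det_orc += 1
    r_pkg, r_orc = det_pkg / n_pairs, det_orc / n_pairs
    half_ci = 1.96 * np.sqrt(max(r_orc * (1 - r_orc), 1e-12) / n_pairs)
    return {
        "n_pairs": n_pairs,
        "rate_package": r_pkg,
        "rate_oracle": r_orc,
        "ci_95_halfwidth": float(half_ci),
        "agrees": bool(abs(r_pkg - r_orc) <= half_ci + 1e-12),
    }


# ---------------------------------------------------------------------------
# bursts


def burst_experiment(
    baseline_hz: float = 200.0,
    duration: float = 10.0,
    windows=((1.0, 1.4), (6.0, 6.4)),
    n_units: int = 100,
) -> dict:
    """Deterministic raster with two elevated-rate windows.

    The extra in-window rate is chosen so that the smoothed population rate
    crosses 1.35x baseline exactly at the window edges, making the expected
    burst durations and the offset-to-onset interburst interval equal to the
    constructed window geometry.
    """
    from scipy.stats import norm

    params = BurstParams()
    w = windows[0][1] - windows[0][0]
    # (r1 - r0) * (Phi(w/sigma) - 0.5) = (f - 1) * r0  => crossings at edges
    factor = norm.cdf(w / params.kernel_sigma) - 0.5
    extra_hz = (params.threshold_factor - 1.0) * baseline_hz / factor
    times = [np.arange(0.0, duration, 1.0 / baseline_hz)]
    for lo, hi in windows:
        times.append(np.arange(lo, hi, 1.0 / extra_hz))
    all_times = np.sort(np.concatenate(times))
    trains = {u: all_times[u::n_units] for u in range(n_units)}
    t, rate = population_rate(trains, duration, params)
    bursts, ibis = detect_bursts(t, rate, params)
    expected_ibi = windows[1][0] - windows[0][1]
    return {
        "n_bursts": len(bursts),
        "durations_s": [b.duration for b in bursts],
        "expected_duration_s": w,
        "ibis_s": ibis.tolist(),
        "expected_ibi_s": expected_ibi,
        "n_spikes": int(len(all_times)),
    }


# ---------------------------------------------------------------------------
# geometry


def geometry_experiment() -> dict:
    """Nearest-neighbour distances of every interior electrode of the full
    default lattice (six neighbours at exactly the 18 um pitch)."""
    arr = build_hex_array(ArrayParams())
    p = ArrayParams()
    rows = arr.ids // p.n_cols
    cols = arr.ids % p.n_cols
    interior = (rows > 0) & (rows < p.n_rows - 1) & (cols > 0) & (cols < p.n_cols - 1)
    d, _ = arr.tree.query(arr.positions[interior], k=7)
    nn = d[:, 1:]  # six nearest neighbours of each interior electrode
    return {
        "n_electrodes": arr.n_electrodes,
        "n_interior": int(interior.sum()),
        "nn_distance_um": float(np.median(nn)),
        "max_nn_deviation_um": float(np.abs(nn - p.pitch).max()),
    }
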