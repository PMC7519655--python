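"""Network bursts and cross-correlogram monosynaptic connectivity.

Burst detection follows the population-rate convention: all spikes are binned
at 0.01 s, smoothed with a Gaussian kernel (sigma = 0.3 s), and contiguous
intervals above 1.35x the baseline rate (median of the smoothed rate) are
bursts; the interburst interval runs from one burst's offset to the next
burst's onset.

Connectivity uses the baseline-corrected cross-correlogram (CCG, 1 ms bins):
the CCG is convolved with a partially hollow Gaussian kernel to form a
slow-comodulation predictor, and a peak within +-5 ms that exceeds the
pointwise Poisson upper band at alpha = 0.01 is called a putative excitatory
monosynaptic connection; the sign of the peak lag gives the direction, the
lag itself the connection latency.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.stats import poisson

from .geometry import InvalidParameterError

__all__ = [
    "BurstParams",
    "Burst",
    "CCGParams",
    "CCGResult",
    "Connection",
    "population_rate",
    "detect_bursts",
    "compute_ccg",
    "convolution_null",
    "detect_connection",
    "build_graph",
]


@dataclass(frozen=True)
class BurstParams:
    bin: float = 0.01  # s
    kernel_sigma: float = 0.3  # s
    threshold_factor: float = 1.35
    baseline: str = "median"  # or "mean"

    def __post_init__(self) -> None:
        if not (self.bin > 0 and self.kernel_sigma > 0 and self.threshold_factor > 0):
            raise InvalidParameterError("burst parameters must be > 0")


@dataclass
class Burst:
    onset: float
    offset: float
    peak_time: float
    peak_rate: float

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass(frozen=True)
class CCGParams:
    bin_ms: float = 1.0
    window_ms: float = 50.0
    peak_window_ms: float = 5.0
    alpha: float = 0.01
    null_sigma_ms: float = 10.0  # std of the hollow Gaussian null kernel
    hollow_fraction: float = 1.0  # weight removed from the centre bin
    min_spikes: int = 50  # pairs below this are skipped as untested

    def __post_init__(self) -> None:
        if self.peak_window_ms > self.window_ms:
            raise InvalidParameterError("peak_window must be <= window")
        if not (0 < self.alpha < 1):
            raise InvalidParameterError("alpha must be in (0, 1)")


@dataclass
class CCGResult:
    """Binned spike-time differences t_b - t_a with the convolution null."""

    lags_ms: np.ndarray  # bin centres
    counts: np.ndarray  # integer counts per bin
    predictor: np.ndarray | None = None
    upper: np.ndarray | None = None

    def significant(self) -> np.ndarray:
        if self.upper is None:
            raise ValueError("null bands not computed")
        return self.counts > self.upper


@dataclass
class Connection:
    pre: int
    post: int
    latency_ms: float  # > 0, pre -> post
    excess: float  # counts above the predictor at the peak
    distance_um: float = np.nan


@dataclass
class NetworkGraph:
    graph: nx.DiGraph
    edges: pd.DataFrame
    degrees: pd.DataFrame
    n_tested: int = 0
    n_untested: int = 0


# ---------------------------------------------------------------------------
# bursts


def population_rate(
    trains, duration: float, params: BurstParams | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Summed spike counts per bin over all units, in Hz, Gaussian-smoothed.

    Returns ``(t, rate)`` with bin-centre times.  The kernel is normalised,
    so the integral of the rate equals the total spike count up to edge
    effects.
    """
    params = params or BurstParams()
    trains = list(trains.values()) if isinstance(trains, dict) else list(trains)
    n_bins = int(np.ceil(duration / params.bin)) if duration > 0 else 0
    edges = np.arange(n_bins + 1) * params.bin
    counts = np.zeros(n_bins)
    for t in trains:
        t = np.asarray(t)
        if len(t):
            counts += np.histogram(t, bins=edges)[0]
    rate = counts / params.bin
    rate = gaussian_filter1d(rate, params.kernel_sigma / params.bin, mode="constant")
    t = edges[:-1] + params.bin / 2.0
    return t, rate


def detect_bursts(
    t: np.ndarray, rate: np.ndarray, params: BurstParams | None = None
) -> tuple[list, np.ndarray]:
    """Contiguous supra-threshold intervals of the smoothed population rate.

    Threshold = threshold_factor x baseline (median of the smoothed rate by
    default).  Returns ``(bursts, interburst intervals)`` with the IBI taken
    from one burst's offset to the next burst's onset.
    """
    params = params or BurstParams()
    if len(rate) == 0 or not rate.any():
        return [], np.empty(0)
    baseline = np.median(rate) if params.baseline == "median" else np.mean(rate)
    if baseline == 0:
        return [], np.empty(0)
    thr = params.threshold_factor * baseline
    above = rate > thr
    if not above.any():
        return [], np.empty(0)
    d = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if above[0]:
        starts = np.concatenate([[0], starts])
    if above[-1]:
        ends = np.concatenate([ends, [len(above)]])
    bursts = []
    bin_s = params.bin
    for s, e in zip(starts, ends):
        if e - s < 2:  # a single supra-threshold bin has no crossing pair
            continue
        pk = s + int(np.argmax(rate[s:e]))
        bursts.append(
            Burst(
                onset=float(t[s] - bin_s / 2.0),
                offset=float(t[e - 1] + bin_s / 2.0),
                peak_time=float(t[pk]),
                peak_rate=float(rate[pk]),
            )
        )
    ibis = np.array([b2.onset - b1.offset for b1, b2 in zip(bursts, bursts[1:])])
    return bursts, ibis


# ---------------------------------------------------------------------------
# cross-correlograms


def _lag_bins(params: CCGParams) -> np.ndarray:
    n = int(round(params.window_ms / params.bin_ms))
    return np.arange(-n, n + 1) * params.bin_ms


def compute_ccg(
    train_a: np.ndarray, train_b: np.ndarray, params: CCGParams | None = None
) -> CCGResult:
    """Histogram of spike-time differences ``t_b - t_a`` (1 ms bins).

    The lag-0 bin is centred on zero; counts[l] is the number of spike pairs
    with difference inside bin l.
    """
    params = params or CCGParams()
    lags = _lag_bins(params)
    a = np.asarray(train_a, dtype=np.float64)
    b = np.asarray(train_b, dtype=np.float64)
    counts = np.zeros(len(lags), dtype=np.int64)
    if len(a) and len(b):
        half = params.bin_ms * 1e-3 / 2.0
        w = params.window_ms * 1e-3 + half
        lo = np.searchsorted(b, a - w, side="left")
        hi = np.searchsorted(b, a + w, side="right")
        diffs = np.concatenate(
            [b[l:h] - ai for ai, l, h in zip(a, lo, hi) if h > l]
            or [np.empty(0)]
        )
        edges = np.concatenate([lags - params.bin_ms / 2.0, [lags[-1] + params.bin_ms / 2.0]])
        counts = np.histogram(diffs * 1e3, bins=edges)[0].astype(np.int64)
    return CCGResult(lags_ms=lags, counts=counts)


def _hollow_kernel(params: CCGParams) -> np.ndarray:
    sigma_bins = params.null_sigma_ms / params.bin_ms
    half = int(np.ceil(4 * sigma_bins))
    x = np.arange(-half, half + 1)
    k = np.exp(-(x**2) / (2 * sigma_bins**2))
    k[half] *= 1.0 - params.hollow_fraction
    return k / k.sum()


def convolution_null(ccg: CCGResult, params: CCGParams | None = None) -> CCGResult:
    """Predictor from a partially hollow Gaussian convolution of the CCG.

    The centre-bin weight of the kernel is removed (renormalised), so the
    predictor at each lag estimates the slow-comodulation baseline without
    the bin's own (possibly monosynaptic) counts.  The upper band is the
    pointwise Poisson (1 - alpha) quantile at the predicted mean.
    """
    params = params or CCGParams()
    kernel = _hollow_kernel(params)
    if len(kernel) > 2 * len(ccg.counts):
        raise InvalidParameterError("null kernel wider than the CCG window")
    counts = ccg.counts.astype(np.float64)
    # normalise by in-range kernel mass so edges are unbiased
    num = np.convolve(counts, kernel, mode="same")
    den = np.convolve(np.ones_like(counts), kernel, mode="same")
    predictor = num / den
    upper = poisson.ppf(1.0 - params.alpha, predictor)
    return CCGResult(
        lags_ms=ccg.lags_ms, counts=ccg.counts, predictor=predictor, upper=upper
    )


def detect_connection(
    ccg: CCGResult, params: CCGParams | None = None, pre: int = 0, post: int = 1
) -> Connection | None:
    """Call a putative monosynaptic connection from a CCG with null bands.

    Significant bins within +-peak_window (lag 0 excluded: it cannot be
    directional) are screened; the maximal-excess lag wins.  A positive lag
    means ``pre -> post``; a negative lag the reverse.  Returns ``None`` when
    nothing is significant (or only lag 0 is, flagging likely common input).
    """
    params = params or CCGParams()
    if ccg.upper is None:
        ccg = convolution_null(ccg, params)
    inwin = np.abs(ccg.lags_ms) <= params.peak_window_ms + 1e-9
    sig = ccg.significant() & inwin & (ccg.lags_ms != 0)
    if not sig.any():
        return None
    excess = ccg.counts - ccg.predictor
    masked = np.where(sig, excess, -np.inf)
    k = int(np.argmax(masked))
    lag = float(ccg.lags_ms[k])
    if lag > 0:
        return Connection(pre=pre, post=post, latency_ms=lag, excess=float(excess[k]))
    return Connection(pre=post, post=pre, latency_ms=-lag, excess=float(excess[k]))


def detect_connections(
    ccg: CCGResult, params: CCGParams | None = None, pre: int = 0, post: int = 1
) -> list:
    """Directional variant: screen the positive- and negative-lag sides of the
    peak window separately, yielding at most one edge per direction."""
    params = params or CCGParams()
    if ccg.upper is None:
        ccg = convolution_null(ccg, params)
    inwin = np.abs(ccg.lags_ms) <= params.peak_window_ms + 1e-9
    sig = ccg.significant() & inwin & (ccg.lags_ms != 0)
    excess = ccg.counts - ccg.predictor
    out = []
    for side in (ccg.lags_ms > 0, ccg.lags_ms < 0):
        m = sig & side
        if not m.any():
            continue
        k = int(np.argmax(np.where(m, excess, -np.inf)))
        lag = float(ccg.lags_ms[k])
        if lag > 0:
            out.append(Connection(pre=pre, post=post, latency_ms=lag, excess=float(excess[k])))
        else:
            out.append(Connection(pre=post, post=pre, latency_ms=-lag, excess=float(excess[k])))
    return out


def build_graph(
    trains: dict,
    centers: dict | None = None,
    params: CCGParams | None = None,
) -> NetworkGraph:
    """All-to-all pairwise CCG scan -> directed graph of putative connections.

    ``centers`` maps unit id to its (x, y) position in um (the electrode of
    the footprint amplitude maximum); edge distance is the Euclidean
    centre-to-centre distance.  Pairs where either train has fewer than
    ``min_spikes`` spikes are skipped and counted as untested.
    """
    params = params or CCGParams()
    units = sorted(trains)
    g = nx.DiGraph()
    for u in units:
        pos = None if centers is None else tuple(np.asarray(centers[u], dtype=float))
        g.add_node(u, pos=pos, n_spikes=len(trains[u]))
    n_tested = n_untested = 0
    rows = []
    for i, u in enumerate(units):
        for v in units[i + 1 :]:
            if len(trains[u]) < params.min_spikes or len(trains[v]) < params.min_spikes:
                n_untested += 1
                continue
            n_tested += 1
            ccg = convolution_null(compute_ccg(trains[u], trains[v], params), params)
            for conn in detect_connections(ccg, params, pre=u, post=v):
                if centers is not None:
                    conn.distance_um = float(
                        np.linalg.norm(
                            np.asarray(centers[u], float) - np.asarray(centers[v], float)
                        )
                    )
                g.add_edge(
                    conn.pre,
                    conn.post,
                    latency_ms=conn.latency_ms,
                    distance_um=conn.distance_um,
                    excess=conn.excess,
                )
                rows.append(
                    {
                        "pre": conn.pre,
                        "post": conn.post,
                        "latency_ms": conn.latency_ms,
                        "distance_um": conn.distance_um,
                        "excess": conn.excess,
                    }
                )
    edges = pd.DataFrame(
        rows, columns=["pre", "post", "latency_ms", "distance_um", "excess"]
    )
    degrees = pd.DataFrame(
        {
            "unit_id": units,
            "in_degree": [g.in_degree(u) for u in units],
            "out_degree": [g.out_degree(u) for u in units],
            "degree": [g.in_degree(u) + g.out_degree(u) for u in units],
        }
    )
    return NetworkGraph(
        graph=g, edges=edges, degrees=degrees, n_tested=n_tested, n_untested=n_untested
    )
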