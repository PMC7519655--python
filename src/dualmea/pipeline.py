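"""End-to-end orchestration: simulate -> detect/STA -> trace -> network.

Each stage persists its intermediate (HDF5 recording + ground truth,
footprints, segment/neuron CSVs, burst/edge/degree CSVs) so that every number
in the final session report can be recomputed from stored artefacts.  Runs
are deterministic given the configuration and seed, which are embedded in
the report provenance.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .detection import align_triggers, bandpass, detect_spikes
from .geometry import ArrayParams, build_hex_array
from .network import BurstParams, CCGParams, build_graph, detect_bursts, population_rate
from .recording import (
    ModeParams,
    read_recording,
    read_recording_info,
    read_units,
    write_recording,
)
from .simulate import (
    NetworkSpec,
    generate_arbor,
    generate_network_spikes,
    render_recording,
    write_ground_truth,
)
from .sta import footprint_from_recording, read_footprints, write_footprints
from .tracing import (
    CleaningParams,
    TracingParams,
    clean_footprint,
    extract_all_segments,
    morphometrics,
    segments_table,
)

__all__ = ["PipelineConfig", "SessionReport", "run_pipeline", "compare_sessions"]

log = logging.getLogger("dualmea")

DEFAULT_CONFIG = {
    "seed": 0,
    "stages": ["simulate", "sta", "trace", "network"],
    "units_from": "ground_truth",  # or "sm_detection"
    # desk-scale demo preset: a long, narrow sub-array with arbors oriented
    # along it, 90 s of activity (enough averaged spikes for axonal SNR)
    "array": {"n_rows": 10, "n_cols": 48, "pitch": 18.0},
    "simulate": {
        "n_neurons": 3,
        "duration": 90.0,
        "firing_rate": 2.4,
        "burst_rate": 0.15,
        "burst_duration": 0.8,
        "burst_gain": 5.0,
        "velocity_mean": 480.0,
        "velocity_std": 90.0,
        "n_branches": 1,
        "length_range": [500.0, 800.0],
        "direction_range": [-0.12, 0.12],
        "ais_x_frac": [0.05, 0.25],
        "ais_y_frac": [0.2, 0.8],
        "soma_amplitude": -150.0,
        "connections": [[0, 1, 2.5, 0.3], [1, 2, 1.5, 0.3]],
        "noise": True,
        "aps_noise_rms": 10.4,
        "sm_noise_rms": 3.0,
    },
    "detection": {"template_ms": 12.0, "threshold_k": 7.5},
    "cleaning": {"amp_k": 5.5, "jitter_max": 0.7},
    "tracing": {"radius": 80.0, "max_gap_frames": 5, "stop_frames": 5,
                "min_electrodes": 5},
    "burst": {"bin": 0.01, "kernel_sigma": 0.3, "threshold_factor": 1.35},
    "ccg": {"bin_ms": 1.0, "window_ms": 50.0, "peak_window_ms": 5.0,
            "alpha": 0.01, "null_sigma_ms": 10.0, "min_spikes": 50},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
    return out


@dataclass
class PipelineConfig:
    raw: dict

    @classmethod
    def from_dict(cls, d: dict | None = None) -> "PipelineConfig":
        return cls(raw=_merge(DEFAULT_CONFIG, d or {}))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f) or {})

    def __getitem__(self, key):
        return self.raw[key]

    @property
    def seed(self) -> int:
        return int(self.raw["seed"])

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.raw, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class SessionReport:
    neuron_table: pd.DataFrame
    network_summary: dict
    provenance: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "neuron_table": self.neuron_table.to_dict(orient="list"),
            "network_summary": self.network_summary,
            "provenance": self.provenance,
        }
        Path(path).write_text(json.dumps(payload, indent=2, default=float))

    @classmethod
    def from_json(cls, path) -> "SessionReport":
        d = json.loads(Path(path).read_text())
        return cls(
            neuron_table=pd.DataFrame(d["neuron_table"]),
            network_summary=d["network_summary"],
            provenance=d.get("provenance", {}),
        )


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are preserved on disk."""


def _stage_simulate(cfg: PipelineConfig, out: Path, rng: np.random.Generator) -> Path:
    sim = cfg["simulate"]
    array = build_hex_array(ArrayParams(**cfg["array"]))
    xmin, ymin = array.positions.min(axis=0)
    xmax, ymax = array.positions.max(axis=0)
    bounds = (xmin, xmax, ymin, ymax)
    neurons = []
    for i in range(int(sim["n_neurons"])):
        v = max(rng.normal(sim["velocity_mean"], sim["velocity_std"]), 50.0)
        ais = np.array(
            [
                xmin + rng.uniform(*sim["ais_x_frac"]) * (xmax - xmin),
                ymin + rng.uniform(*sim["ais_y_frac"]) * (ymax - ymin),
            ]
        )
        neurons.append(
            generate_arbor(
                rng,
                bounds,
                n_branches=sim["n_branches"],
                velocity_range=(v, v),
                length_range=tuple(sim["length_range"]),
                direction_range=tuple(sim["direction_range"]),
                ais_position=ais,
                soma_amplitude=sim["soma_amplitude"],
                neuron_id=i,
            )
        )
    spec = NetworkSpec(
        n_neurons=len(neurons),
        firing_rate=sim["firing_rate"],
        connections=[tuple(c) for c in sim["connections"]],
        burst_rate=sim["burst_rate"],
        burst_duration=sim["burst_duration"],
        burst_gain=sim["burst_gain"],
    )
    trains = generate_network_spikes(spec, float(sim["duration"]), rng)
    # route each neuron's AIS-nearest electrode to the SM stream
    sm_electrodes = [
        int(array.ids[np.argmin(np.linalg.norm(array.positions - n.ais_position, axis=1))])
        for n in neurons
    ]
    sm_electrodes = sorted(set(sm_electrodes))
    rec, gt = render_recording(
        neurons,
        trains,
        array,
        aps_params=ModeParams.aps_default(
            array.n_electrodes, noise_rms=float(sim["aps_noise_rms"])
        ),
        sm_params=ModeParams.sm_default(
            max(len(sm_electrodes), 1), noise_rms=float(sim["sm_noise_rms"])
        ),
        sm_electrodes=sm_electrodes,
        rng=rng,
        duration=float(sim["duration"]),
        noise=bool(sim["noise"]),
        connections=spec.connections,
        seed=cfg.seed,
    )
    path = out / "recording.h5"
    write_recording(rec, path)
    write_ground_truth(path, gt)
    return path


def _sm_trigger_times(cfg: PipelineConfig, rec) -> dict:
    """Trigger extraction on the low-noise SM channels, one unit per channel."""
    det = cfg["detection"]
    fs = rec.sm_params.sampling_rate
    out = {}
    for row, eid in enumerate(rec.sm_electrodes):
        filt = bandpass(rec.sm[row], (300.0, 3000.0), fs)
        out[int(eid)] = detect_spikes(
            filt, fs, threshold_k=det["threshold_k"], t0=rec.t0,
            template_ms=det["template_ms"],
        )
    return out


def _stage_sta(cfg: PipelineConfig, out: Path) -> Path:
    rec = read_recording(out / "recording.h5")
    if cfg["units_from"] == "sm_detection":
        units = _sm_trigger_times(cfg, rec)
    else:
        units = {int(k): v for k, v in rec.units.items()}
    fps = []
    for uid in sorted(units):
        frames, _ = align_triggers(
            units[uid], rec.aps_params.sampling_rate, rec.n_frames, rec.t0
        )
        if len(frames) == 0:
            log.warning("unit %d has no usable triggers; skipped", uid)
            continue
        fps.append(
            footprint_from_recording(
                rec, frames, unit_id=uid, template_ms=cfg["detection"]["template_ms"]
            )
        )
    path = out / "footprints.h5"
    write_footprints(path, fps)
    return path


def _stage_trace(cfg: PipelineConfig, out: Path) -> tuple[Path, Path]:
    rec_path = out / "recording.h5"
    duration = read_recording_info(rec_path)["duration_s"]
    units = {int(k): v for k, v in read_units(rec_path).items()}
    fps = read_footprints(out / "footprints.h5")
    cparams = CleaningParams(**cfg["cleaning"])
    tparams = TracingParams(**cfg["tracing"])
    seg_tables, rows = [], []
    for fp in fps:
        cleaned = clean_footprint(fp, params=cparams)
        segments = extract_all_segments(cleaned, tparams)
        seg_tables.append(segments_table(fp.unit_id, segments))
        m = morphometrics(segments, fp, units.get(fp.unit_id), duration)
        rows.append(
            {
                "unit_id": m.unit_id,
                "n_segments": m.n_segments,
                "longest_um": m.longest_um,
                "total_um": m.total_extension_um,
                "velocity_mms": m.velocity_mms,
                "r2": m.r_squared,
                "max_amp_uv": m.max_amplitude_uv,
                "rate_hz": m.firing_rate_hz,
            }
        )
    seg_path, neu_path = out / "segments.csv", out / "neurons.csv"
    pd.concat(seg_tables, ignore_index=True).to_csv(seg_path, index=False) if seg_tables \
        else segments_table(0, []).to_csv(seg_path, index=False)
    pd.DataFrame(rows).to_csv(neu_path, index=False)
    return seg_path, neu_path


def _stage_network(cfg: PipelineConfig, out: Path) -> None:
    rec_path = out / "recording.h5"
    duration = read_recording_info(rec_path)["duration_s"]
    units = {int(k): np.asarray(v) for k, v in read_units(rec_path).items()}
    bparams = BurstParams(**cfg["burst"])
    t, rate = population_rate(units, duration, bparams)
    bursts, ibis = detect_bursts(t, rate, bparams)
    pd.DataFrame(
        [
            {"onset_s": b.onset, "offset_s": b.offset, "peak_s": b.peak_time,
             "duration_s": b.duration}
            for b in bursts
        ],
        columns=["onset_s", "offset_s", "peak_s", "duration_s"],
    ).to_csv(out / "bursts.csv", index=False)
    pd.DataFrame({"ibi_s": ibis}).to_csv(out / "ibis.csv", index=False)
    centers = None
    fp_path = out / "footprints.h5"
    if fp_path.exists():
        fps = read_footprints(fp_path)
        centers = {
            fp.unit_id: fp.positions[fp.initiation_index()]
            for fp in fps
            if fp.positions is not None and fp.n_electrodes
        }
        centers = {u: centers[u] for u in units if u in centers} or None
    cparams = CCGParams(**cfg["ccg"])
    net = build_graph(units, centers, cparams)
    net.edges.to_csv(out / "edges.csv", index=False)
    net.degrees.to_csv(out / "degrees.csv", index=False)
    plain = nx.DiGraph()
    plain.add_nodes_from(int(n) for n in net.graph.nodes)
    for u, v, d in net.graph.edges(data=True):
        plain.add_edge(int(u), int(v), **{k: float(x) for k, x in d.items()
                                          if np.isscalar(x)})
    nx.write_graphml(plain, out / "graph.graphml")


def run_pipeline(config: PipelineConfig | dict | None = None, out_dir="pipeline_out") -> SessionReport:
    """Execute the enabled stages in order, persisting every intermediate.

    Idempotent for a fixed config and seed.  A stage failure aborts with the
    stage name; earlier outputs remain on disk.
    """
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_dict(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    stages = list(config["stages"])
    for stage in stages:
        start = time.perf_counter()
        try:
            if stage == "simulate":
                _stage_simulate(config, out, rng)
            elif stage == "sta":
                _stage_sta(config, out)
            elif stage == "trace":
                _stage_trace(config, out)
            elif stage == "network":
                _stage_network(config, out)
            else:
                raise StageError(f"unknown stage {stage!r}")
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001 - re-tag with the stage name
            raise StageError(f"stage {stage!r} failed: {exc}") from exc
        log.info("stage %s finished in %.1f s", stage, time.perf_counter() - start)

    provenance = {
        "seed": config.seed,
        "config_hash": config.hash(),
        "version": __version__,
        "stages": stages,
    }
    neuron_table = (
        pd.read_csv(out / "neurons.csv")
        if (out / "neurons.csv").exists()
        else pd.DataFrame()
    )
    network_summary = {}
    if (out / "bursts.csv").exists():
        bursts = pd.read_csv(out / "bursts.csv")
        ibis = pd.read_csv(out / "ibis.csv")
        edges = pd.read_csv(out / "edges.csv")
        degrees = pd.read_csv(out / "degrees.csv")
        network_summary = {
            "n_bursts": int(len(bursts)),
            "burst_duration_mean_s": float(bursts["duration_s"].mean()) if len(bursts) else None,
            "ibi_mean_s": float(ibis["ibi_s"].mean()) if len(ibis) else None,
            "n_connections": int(len(edges)),
            "mean_degree": float(degrees["degree"].mean()) if len(degrees) else None,
            "mean_latency_ms": float(edges["latency_ms"].mean()) if len(edges) else None,
            "mean_distance_um": float(edges["distance_um"].mean()) if len(edges) else None,
        }
    report = SessionReport(
        neuron_table=neuron_table,
        network_summary=network_summary,
        provenance=provenance,
    )
    report.to_json(out / "report.json")
    return report


NEURON_METRICS = ["n_segments", "longest_um", "total_um", "velocity_mms",
                  "max_amp_uv", "rate_hz"]


def compare_sessions(reports: list, labels=None) -> pd.DataFrame:
    """Side-by-side longitudinal table of per-metric medians and quartiles.

    Raises a ValueError listing the differences when the reports' metric
    schemas do not match.
    """
    labels = labels or [f"session_{i}" for i in range(len(reports))]
    cols = [set(r.neuron_table.columns) for r in reports]
    for i, c in enumerate(cols[1:], 1):
        if c != cols[0]:
            raise ValueError(
                f"metric schema mismatch between session 0 and {i}: "
                f"{sorted(cols[0] ^ c)}"
            )
    rows = []
    for metric in NEURON_METRICS:
        if reports and metric not in reports[0].neuron_table.columns:
            continue
        for rep, lab in zip(reports, labels):
            col = rep.neuron_table[metric].dropna()
            rows.append(
                {
                    "metric": metric,
                    "session": lab,
                    "median": float(col.median()) if len(col) else np.nan,
                    "q1": float(col.quantile(0.25)) if len(col) else np.nan,
                    "q3": float(col.quantile(0.75)) if len(col) else np.nan,
                    "n": int(len(col)),
                }
            )
    return pd.DataFrame(rows, columns=["metric", "session", "median", "q1", "q3", "n"])
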