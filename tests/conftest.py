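"""Shared fixtures: synthetic footprints and small rendered recordings."""

from __future__ import annotations

import numpy as np
import pytest

from dualmea.geometry import ArrayParams, build_hex_array
from dualmea.sta import Footprint

APS_FS = 11_600.0


def make_footprint(
    positions: np.ndarray,
    peak_frames: np.ndarray,
    amplitudes: np.ndarray,
    jitter_ms: np.ndarray | float = 0.0,
    fs: float = APS_FS,
    n_samples: int = 139,
    electrodes: np.ndarray | None = None,
) -> Footprint:
    """Construct a footprint with prescribed peak samples and amplitudes.

    Each electrode's waveform is zero except for a single negative deflection
    of the given amplitude at the given sample index.
    """
    positions = np.asarray(positions, dtype=float)
    peak_frames = np.asarray(peak_frames, dtype=np.int64)
    amplitudes = np.asarray(amplitudes, dtype=float)
    n = len(positions)
    wf = np.zeros((n, n_samples))
    wf[np.arange(n), peak_frames] = -amplitudes
    return Footprint(
        unit_id=0,
        electrodes=np.arange(n) if electrodes is None else np.asarray(electrodes),
        waveforms=wf,
        sampling_rate=fs,
        amplitude=amplitudes.copy(),
        jitter_ms=np.broadcast_to(np.asarray(jitter_ms, dtype=float), (n,)).copy(),
        n_triggers=100,
        positions=positions,
    )


@pytest.fixture(scope="session")
def small_array():
    return build_hex_array(ArrayParams(8, 10, 18.0))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20_251_001)
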