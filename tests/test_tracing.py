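"""Footprint cleaning and the backward axonal tracker on constructed delay maps."""

import numpy as np
import pytest

from dualmea.sta import EmptyFootprintError
from dualmea.tracing import (
    AxonalSegment,
    CleaningParams,
    TracingParams,
    clean_footprint,
    extract_all_segments,
    fit_velocity,
    initiation_site,
    morphometrics,
    terminal_candidates,
    trace_segment,
)

from conftest import make_footprint

FS = 11_600.0
FRAME_MS = 1e3 / FS
STEP_UM = 43.1  # one frame of travel at ~500 mm/s


def straight_footprint(n=16, drop=(), extra=None, amps=None):
    """Soma at frame 20 plus one axonal electrode per subsequent frame.

    ``extra`` adds electrodes as (x, y, frame_offset, amplitude) tuples.
    """
    keep = [k for k in range(1, n) if k not in drop]
    pos = [(0.0, 0.0)] + [(STEP_UM * k, 0.0) for k in keep]
    frames = [20] + [20 + k for k in keep]
    amp = [150.0] + [
        (amps[k] if amps else 12.0 - 0.2 * k) for k in keep
    ]
    if extra:
        for x, y, f, a in extra:
            pos.append((x, y))
            frames.append(20 + f)
            amp.append(a)
    return make_footprint(np.array(pos), np.array(frames), np.array(amp),
                          n_samples=64)


class TestCleaning:
    def test_amplitude_below_5p5_sigma_is_excluded(self):
        fp = make_footprint(np.zeros((2, 2)), [10, 12], [5.0, 50.0])
        cleaned = clean_footprint(fp, noise_std=1.9)  # threshold 10.45 uV
        assert np.array_equal(cleaned.electrodes, [1])

    def test_jitter_above_0p7_ms_is_excluded_regardless_of_amplitude(self):
        fp = make_footprint(np.zeros((2, 2)), [10, 12], [500.0, 50.0],
                            jitter_ms=[0.8, 0.1])
        cleaned = clean_footprint(fp, noise_std=1.0)
        assert np.array_equal(cleaned.electrodes, [1])

    def test_all_removed_yields_empty_footprint_not_error(self):
        fp = make_footprint(np.zeros((2, 2)), [10, 12], [1.0, 2.0])
        cleaned = clean_footprint(fp, noise_std=10.0)
        assert cleaned.n_electrodes == 0
        assert extract_all_segments(cleaned) == []

    def test_cleaning_params_validation(self):
        with pytest.raises(Exception):
            CleaningParams(amp_k=0.0)


class TestInitiationSite:
    def test_maximum_amplitude_wins_and_defines_zero_latency(self):
        fp = straight_footprint()
        assert initiation_site(fp) == 0
        assert fp.latency_ms[0] == 0.0
        assert (fp.latency_ms[1:] > 0).all()

    def test_equal_maxima_tie_break_to_lower_id(self):
        fp = make_footprint(np.zeros((3, 2)), [10, 11, 12], [50.0, 50.0, 10.0],
                            electrodes=[7, 2, 5])
        assert initiation_site(fp) == 2

    def test_empty_footprint_raises(self):
        fp = straight_footprint().subset(np.zeros(16, dtype=bool))
        with pytest.raises(EmptyFootprintError):
            initiation_site(fp)


class TestTerminalCandidates:
    def test_single_straight_axon_yields_the_far_end(self):
        fp = straight_footprint()
        cands = terminal_candidates(fp)
        assert cands[0] == fp.electrodes[-1]

    def test_two_branch_tips_for_a_y_arbor(self):
        # two arms leaving the soma in opposite directions, one per frame
        pos = [(0.0, 0.0)]
        frames, amps = [20], [150.0]
        for k in range(1, 10):
            pos += [(STEP_UM * k, 0.0), (-STEP_UM * k, 0.0)]
            frames += [20 + k, 20 + k]
            amps += [10.0, 9.0]
        fp = make_footprint(np.array(pos), np.array(frames), np.array(amps),
                            n_samples=64)
        cands = terminal_candidates(fp)
        tips = {int(fp.electrodes[-2]), int(fp.electrodes[-1])}
        assert set(cands[:2].tolist()) == tips

    def test_no_candidates_once_everything_is_assigned(self):
        fp = straight_footprint()
        assigned = set(int(e) for e in fp.electrodes)
        assert len(terminal_candidates(fp, assigned)) == 0


class TestTraceSegment:
    def test_one_candidate_per_frame_recovers_the_chain(self):
        fp = straight_footprint()
        seg = trace_segment(fp, int(fp.electrodes[-1]))
        # walks back to 5 frames before initiation: relative frames 5..15
        assert np.array_equal(seg.electrodes, fp.electrodes[5:])
        assert np.allclose(np.diff(seg.latency_ms), FRAME_MS)
        assert np.allclose(np.diff(seg.cumdist_um), STEP_UM)
        assert (np.diff(seg.latency_ms) >= 0).all()

    def test_largest_amplitude_wins_within_a_frame(self):
        # a decoy electrode shares frame 14 with the true path at 6 uV vs 8 uV
        fp = straight_footprint(
            amps={k: 8.0 for k in range(1, 16)},
            extra=[(STEP_UM * 14, 40.0, 14, 6.0)],
        )
        seg = trace_segment(fp, int(fp.electrodes[15]))
        decoy = fp.electrodes[-1]
        assert decoy not in seg.electrodes

    def test_two_frame_gap_bridged_by_expanded_radius(self):
        fp = straight_footprint(drop={10})
        seg = trace_segment(fp, int(fp.electrodes[-1]))
        # 86.2 um jump <= 2 x 80 um expanded radius
        assert len(seg) == 10
        assert np.any(np.isclose(np.diff(seg.cumdist_um), 2 * STEP_UM))

    def test_gap_beyond_max_expansion_stops_the_walk(self):
        fp = straight_footprint(drop={8, 9, 10, 11, 12})  # 6-frame, 258 um gap
        seg = trace_segment(fp, int(fp.electrodes[-1]))
        assert len(seg) == 3  # 13, 14, 15 only

    def test_start_inside_initiation_region_is_degenerate(self):
        fp = straight_footprint()
        seg = trace_segment(fp, int(fp.electrodes[2]))  # relative frame 2 < 5
        assert seg.degenerate and len(seg) == 1


class TestFitVelocity:
    def test_exact_line_gives_500_mm_per_s(self):
        seg = AxonalSegment(
            electrodes=np.array([0, 1, 2]),
            latency_ms=np.array([0.0, 0.0862, 0.1724]),
            cumdist_um=np.array([0.0, 43.1, 86.2]),
            positions=np.zeros((3, 2)),
        )
        v, r2 = fit_velocity(seg)
        assert v == pytest.approx(500.0)
        assert r2 == pytest.approx(1.0)

    def test_quantised_latencies_recover_velocity_within_5_pct(self, rng):
        s = np.arange(0.0, 800.0, 18.0)
        lat = np.round((s / 500.0) / FRAME_MS) * FRAME_MS
        seg = AxonalSegment(
            electrodes=np.arange(len(s)),
            latency_ms=lat,
            cumdist_um=s,
            positions=np.zeros((len(s), 2)),
        )
        v, _ = fit_velocity(seg)
        assert v == pytest.approx(500.0, rel=0.05)

    def test_reversed_path_gives_same_speed_magnitude(self):
        lat = np.array([0.0, 0.0862, 0.1724, 0.2586])
        dist = np.array([0.0, 40.0, 86.0, 130.0])
        fwd = AxonalSegment(np.arange(4), lat, dist, np.zeros((4, 2)))
        rev = AxonalSegment(
            np.arange(4)[::-1],
            lat[-1] - lat[::-1],
            dist[-1] - dist[::-1],
            np.zeros((4, 2)),
        )
        assert fit_velocity(rev)[0] == pytest.approx(fit_velocity(fwd)[0])

    def test_degenerate_fits_are_flagged_undefined(self):
        flat = AxonalSegment(
            np.arange(3), np.zeros(3), np.array([0.0, 10.0, 20.0]), np.zeros((3, 2))
        )
        assert np.isnan(fit_velocity(flat)[0])
        short = AxonalSegment(
            np.arange(2), np.array([0.0, 1.0]), np.array([0.0, 10.0]), np.zeros((2, 2))
        )
        assert np.isnan(fit_velocity(short)[0])


class TestExtractAllSegments:
    def test_y_arbor_gives_two_segments_covering_both_arms(self):
        pos = [(0.0, 0.0)]
        frames, amps = [20], [150.0]
        for k in range(1, 12):
            pos += [(STEP_UM * k, 0.0), (-STEP_UM * k, 0.0)]
            frames += [20 + k, 20 + k]
            amps += [10.0, 9.0]
        fp = make_footprint(np.array(pos), np.array(frames), np.array(amps),
                            n_samples=64)
        segments = extract_all_segments(fp)
        assert len(segments) == 2
        covered = set()
        for seg in segments:
            covered.update(int(e) for e in seg.electrodes)
        relative = fp.peak_sample - fp.peak_sample[0]
        expected = {int(e) for e, f in zip(fp.electrodes, relative) if f >= 5}
        assert len(covered & expected) / len(expected) >= 0.95

    def test_soma_only_footprint_has_no_segments(self):
        fp = make_footprint(
            np.array([(0.0, 0.0), (18.0, 0.0), (9.0, 15.6)]),
            [20, 21, 22],
            [150.0, 80.0, 40.0],
        )
        assert extract_all_segments(fp) == []

    def test_latency_monotone_along_every_segment(self):
        fp = straight_footprint(drop={7})
        for seg in extract_all_segments(fp):
            assert (np.diff(seg.latency_ms) > 0).all()
            assert (np.diff(seg.cumdist_um) > 0).all()


class TestMorphometrics:
    def test_lengths_and_totals(self):
        segs = []
        for L in (300.0, 500.0):
            n = 6
            segs.append(
                AxonalSegment(
                    np.arange(n),
                    np.linspace(0, 1, n),
                    np.linspace(0, L, n),
                    np.zeros((n, 2)),
                    velocity=500.0,
                    r_squared=1.0,
                )
            )
        fp = straight_footprint()
        m = morphometrics(segs, fp, np.arange(10) * 0.1, duration=10.0)
        assert m.longest_um == 500.0
        assert m.total_extension_um == 800.0
        assert m.n_segments == 2
        assert m.velocity_mms == 500.0
        assert m.max_amplitude_uv == 150.0
        assert m.firing_rate_hz == pytest.approx(1.0)

    def test_zero_segments_yield_zeros_and_undefined_velocity(self):
        fp = straight_footprint()
        m = morphometrics([], fp)
        assert m.n_segments == 0
        assert m.longest_um == 0.0 and m.total_extension_um == 0.0
        assert np.isnan(m.velocity_mms)


def test_tracing_params_validation():
    with pytest.raises(Exception):
        TracingParams(radius=0.0)
    with pytest.raises(Exception):
        TracingParams(max_gap_frames=0)
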