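import numpy as np
import pytest

from glymphwave.preprocess import BoldSession, bandpass_session, trim_volumes
from glymphwave.synthetic import SimulationConfig, generate_session
from glymphwave.waves import (
    MeanWavePattern,
    Segment,
    TimePositionGraph,
    average_propagations,
    compare_wave_groups,
    detect_propagation,
    detect_session_propagations,
    interpolate_series,
    pg_bin,
    segment_by_troughs,
    snapshot,
    time_position_graph,
)


class TestPgBin:
    def test_even_split(self):
        bins = pg_bin(np.random.default_rng(0).standard_normal(700), 70)
        sizes = np.bincount(bins)
        assert np.all(sizes == 10)

    def test_remainder_goes_to_highest_pg_bins(self):
        bins = pg_bin(np.arange(701), 70)
        sizes = np.bincount(bins)
        assert sizes[-1] == 11
        assert np.all(sizes[:-1] == 10)

    def test_reversing_pg_reverses_bins(self):
        pg = np.random.default_rng(1).standard_normal(210)
        fwd = pg_bin(pg, 70)
        rev = pg_bin(-pg, 70)
        np.testing.assert_array_equal(rev, 69 - fwd)

    def test_bins_ordered_by_pg(self):
        pg = np.random.default_rng(2).uniform(size=140)
        bins = pg_bin(pg, 70)
        order = np.argsort(pg)
        assert np.all(np.diff(bins[order]) >= 0)

    def test_too_few_units_errors(self):
        with pytest.raises(ValueError):
            pg_bin(np.arange(69), 70)


class TestInterpolation:
    def test_tr3_factor5_gives_point6s(self):
        _, dt = interpolate_series(np.zeros(10), tr=3.0, interp_factor=5)
        assert dt == pytest.approx(0.6)

    def test_factor_one_is_identity(self):
        x = np.random.default_rng(3).standard_normal(20)
        out, dt = interpolate_series(x, tr=3.0, interp_factor=1)
        np.testing.assert_array_equal(out, x)
        assert dt == 3.0

    def test_interpolant_passes_through_samples(self):
        x = np.random.default_rng(4).standard_normal(15)
        out, _ = interpolate_series(x, tr=3.0, interp_factor=5)
        np.testing.assert_allclose(out[::5], x, atol=1e-12)

    def test_bad_factor_errors(self):
        with pytest.raises(ValueError):
            interpolate_series(np.zeros(10), 3.0, 0)


def _graph_from_bold(bold, tr=3.0, interp=5):
    sess = BoldSession(
        bold=bold, csf=np.zeros(bold.shape[1]),
        motion=np.zeros((bold.shape[1], 6)), tr=tr,
    )
    return time_position_graph(sess, np.arange(bold.shape[0]), interp)


class TestTimePositionGraph:
    def test_constant_input_constant_graph(self):
        g = _graph_from_bold(np.full((4, 20), 2.0))
        np.testing.assert_allclose(g.data, 2.0, atol=1e-9)

    def test_bin_means_after_interpolation(self):
        rng = np.random.default_rng(5)
        bold = rng.standard_normal((4, 30))
        sess = BoldSession(
            bold=bold, csf=np.zeros(30), motion=np.zeros((30, 6)), tr=3.0
        )
        graph = time_position_graph(sess, np.array([0, 0, 1, 1]), 5)
        fine, _ = interpolate_series(bold, 3.0, 5)
        np.testing.assert_allclose(graph.data[0], fine[:2].mean(axis=0), atol=1e-12)


class TestSegmentByTroughs:
    def test_sinusoid_cycles(self):
        tr, interp = 3.0, 5
        k, period = 4, 60.0
        t = np.arange(int(k * period / tr) + 1) * tr  # exactly k full cycles
        g = np.sin(2 * np.pi * t / period)
        graph = _graph_from_bold(np.tile(g, (2, 1)), tr=tr, interp=interp)
        segs = segment_by_troughs(graph)
        assert len(segs) == k - 1
        for seg in segs:
            # gBOLD maxima of a sine sit at period/4 + m*period
            peak_t = seg.gbold_peak_time
            assert (peak_t - period / 4) % period < 1.0 or (
                (peak_t - period / 4) % period > period - 1.0
            )

    def test_monotone_ramp_gives_no_segments(self):
        graph = _graph_from_bold(np.tile(np.linspace(0, 1, 50), (2, 1)))
        assert segment_by_troughs(graph) == []

    def test_segments_tile_without_overlap(self, session_and_truth):
        sess, _ = session_and_truth
        prepped = bandpass_session(trim_volumes(sess))
        graph = time_position_graph(prepped, pg_bin(np.arange(80), 70))
        segs = segment_by_troughs(graph)
        assert len(segs) >= 2
        for a, b in zip(segs[:-1], segs[1:]):
            assert a.end == b.start
        for s in segs:
            assert s.start <= s.gbold_peak_index <= s.end


def _bump_graph(peak_frames, n_frames=120, interval=0.6, width=8):
    """Graph whose bin b has a single interior bump peaking at peak_frames[b]."""
    n_bins = len(peak_frames)
    data = np.zeros((n_bins, n_frames))
    t = np.arange(n_frames)
    for b, pf in enumerate(peak_frames):
        if np.isfinite(pf):
            data[b] = np.exp(-0.5 * ((t - pf) / width) ** 2)
    gbold = data.mean(axis=0)
    return TimePositionGraph(data=data, interval=interval, gbold=gbold)


class TestDetectPropagation:
    def test_noise_free_bottom_up_event(self):
        cfg = SimulationConfig(n_parcels=140, noise_sd=0.0, direction_mix=1.0)
        sess, truth = generate_session(cfg, seed=17)
        graph, events = detect_session_propagations(sess, pg_bin(np.arange(140), 70))
        directional = [e for e in events if e.direction != "none"]
        assert directional
        for ev in directional:
            assert ev.direction == "bottom_up"
            assert ev.time_position_r > 0.9

    def test_constant_timing_gives_none(self):
        graph = _bump_graph([60.0] * 70)
        seg = Segment(start=0, end=119, gbold_peak_index=60, gbold_peak_time=36.0)
        ev = detect_propagation(graph, seg)
        assert ev.direction == "none"
        assert ev.n_bins_with_peak == 70

    def test_too_few_bins_is_invalid(self):
        peaks = [40.0 + b for b in range(40)] + [np.nan] * 30
        graph = _bump_graph(peaks)
        seg = Segment(start=0, end=119, gbold_peak_index=60, gbold_peak_time=36.0)
        ev = detect_propagation(graph, seg)
        assert ev.n_bins_with_peak == 40
        assert ev.direction == "invalid"

    def test_boundary_maxima_are_not_peaks(self):
        data = np.tile(np.linspace(0, 1, 50), (70, 1))  # max at segment edge
        graph = TimePositionGraph(data=data, interval=0.6, gbold=data.mean(axis=0))
        seg = Segment(start=0, end=49, gbold_peak_index=49, gbold_peak_time=29.4)
        ev = detect_propagation(graph, seg)
        assert ev.n_bins_with_peak == 0
        assert ev.direction == "invalid"

    @pytest.mark.parametrize("r_target,expected", [
        (0.40, "bottom_up"), (0.25, "none"), (-0.25, "none"), (-0.40, "top_down"),
    ])
    def test_threshold_strictness(self, r_target, expected):
        """Classification flips only when the time-position r crosses +/-0.3."""
        rng = np.random.default_rng(99)
        pos = np.arange(70, dtype=float)
        for _ in range(200):
            noise = rng.standard_normal(70)
            timings = r_target * (pos - pos.mean()) / pos.std() + np.sqrt(
                1 - r_target**2
            ) * (noise - noise.mean()) / noise.std()
            r = np.corrcoef(timings, pos)[0, 1]
            if abs(r - r_target) < 0.02:
                break
        frames = 60 + 25 * timings  # frame indices, well inside the segment
        ev = detect_propagation(
            _bump_graph(list(frames)), Segment(0, 119, 60, 36.0)
        )
        assert ev.direction == expected

    def test_valid_fraction_non_increasing_in_noise(self):
        fracs = []
        for noise in (0.1, 0.4, 0.8):
            cfg = SimulationConfig(n_parcels=140, noise_sd=noise)
            counts = valid = 0
            for seed in (60, 61):
                sess, _ = generate_session(cfg, seed=seed)
                prepped = bandpass_session(trim_volumes(sess))
                _, events = detect_session_propagations(prepped, pg_bin(np.arange(140), 70))
                counts += len(events)
                valid += sum(e.direction != "invalid" for e in events)
            fracs.append(valid / counts)
        assert fracs[0] >= fracs[1] >= fracs[2]


class TestAveragePropagations:
    def _graph_and_events(self):
        cfg = SimulationConfig(n_parcels=140, noise_sd=0.05, direction_mix=1.0)
        sess, _ = generate_session(cfg, seed=23)
        graph, events = detect_session_propagations(sess, pg_bin(np.arange(140), 70))
        return graph, [e for e in events if e.direction == "bottom_up"]

    def test_single_event_pattern_is_its_window(self):
        graph, events = self._graph_and_events()
        ev = events[1]
        pat = average_propagations([ev], graph)
        c = ev.segment.gbold_peak_index
        assert pat.data.shape == (70, 21)
        np.testing.assert_array_equal(pat.data, graph.data[:, c - 10 : c + 11])

    def test_mean_is_idempotent_for_identical_events(self):
        graph, events = self._graph_and_events()
        one = average_propagations([events[1]], graph)
        two = average_propagations([events[1], events[1]], graph)
        np.testing.assert_allclose(one.data, two.data, atol=1e-12)
        assert two.n_events == 2

    def test_zero_events_flagged_empty(self):
        graph, _ = self._graph_and_events()
        pat = average_propagations([], graph)
        assert pat.empty
        assert pat.n_events == 0

    def test_snapshot_times_map_to_frames(self):
        graph, events = self._graph_and_events()
        pat = average_propagations(events, graph)
        for t in (-3.0, 0.0, 3.6):
            snap = snapshot(pat, t)
            assert snap.shape == (70,)
        np.testing.assert_array_equal(snapshot(pat, 0.0), pat.data[:, 10])
        with pytest.raises(ValueError):
            snapshot(pat, 8.0)


class TestCompareWaveGroups:
    def _patterns(self, rng, n, offset=0.0, element=None):
        pats = []
        for _ in range(n):
            data = rng.standard_normal((70, 21))
            if element is not None:
                data[element] += offset
            pats.append(
                MeanWavePattern(
                    data=data, times=(np.arange(21) - 10) * 0.6, interval=0.6, n_events=5
                )
            )
        return pats

    def test_identical_groups_t_near_zero(self):
        rng = np.random.default_rng(31)
        shared = self._patterns(rng, 4)
        t, p = compare_wave_groups(shared, [MeanWavePattern(p.data.copy(), p.times, 0.6, 5) for p in shared])
        assert np.abs(t).max() < 1e-10
        assert np.all(p > 0.99)

    def test_offset_sign_convention_a_minus_b(self):
        rng = np.random.default_rng(32)
        a = self._patterns(rng, 6)
        b = [
            MeanWavePattern(p.data.copy(), p.times, 0.6, 5) for p in self._patterns(rng, 6)
        ]
        for p in b:
            p.data[5, 3] += 4.0  # B larger at one element -> negative t there
        t, _ = compare_wave_groups(a, b)
        assert t[5, 3] < 0

    def test_attenuated_group_contrast_concentrates_in_high_pg(self):
        """A DMN-attenuated group vs controls shows its deficit in high-PG bins."""
        hits = 0
        n_seeds = 5
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            control, attenuated = [], []
            for grp, att in ((control, 0.0), (attenuated, 0.6)):
                for _ in range(6):
                    cfg = SimulationConfig(n_parcels=140, direction_mix=1.0)
                    sess, _ = generate_session(
                        cfg, overrides={"attenuation": att}, seed=int(rng.integers(2**31))
                    )
                    prepped = bandpass_session(trim_volumes(sess))
                    graph, events = detect_session_propagations(
                        prepped, pg_bin(np.arange(140), 70)
                    )
                    bu = [e for e in events if e.direction == "bottom_up"]
                    pat = average_propagations(bu, graph)
                    if not pat.empty:
                        grp.append(pat)
            t, p = compare_wave_groups(control, attenuated)
            sig = (p < 0.05) & (t > 0)
            if sig[-23:].mean() > sig[:23].mean():
                hits += 1
        assert hits >= 0.8 * n_seeds
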