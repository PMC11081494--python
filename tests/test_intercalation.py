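"""T1 detection, productivity scoring, exchange rates, and swap alignment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epimorph import intercalation as ic
from epimorph import synth


class TestProductivity:
    @pytest.mark.parametrize("angle,expected", [(90.0, 1.0), (45.0, 0.0),
                                                (0.0, -1.0)])
    @pytest.mark.parametrize("form", ["cos", "linear"])
    def test_anchor_values_for_both_forms(self, angle, expected, form):
        assert ic.t1_productivity(angle, form) == pytest.approx(expected,
                                                                abs=1e-12)

    @settings(deadline=None, max_examples=60)
    @given(st.floats(0.0, 90.0))
    def test_antisymmetric_under_axis_swap(self, angle):
        # exchanging the roles of AP and DV maps angle -> 90 - angle
        v = ic.t1_productivity(angle)
        assert ic.t1_productivity(90.0 - angle) == pytest.approx(-v, abs=1e-12)
        assert -1.0 <= v <= 1.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ic.t1_productivity(91.0)


class TestDetection:
    def test_static_movie_no_events(self):
        mesh = synth.generate_tessellation(60, seed=0)
        movie = synth.simulate_movie(mesh, synth.UniformFlow(),
                                     np.arange(0, 5.01, 0.5))
        ts = synth.movie_to_trackset(movie)
        assert ic.detect_t1(ts) == []

    def test_single_scripted_swap_quartet(self):
        mesh = synth.generate_tessellation(60, jitter=0.15, seed=8)
        schedule = synth.make_swap_schedule(mesh, 1, t_range_min=(5.0, 5.0),
                                            seed=1)
        movie = synth.simulate_movie(mesh, synth.UniformFlow(),
                                     np.arange(0, 10.01, 0.5), schedule)
        ts = synth.movie_to_trackset(movie)
        events = ic.detect_t1(ts)
        assert len(events) == 1
        ev = events[0]
        assert ev.losing_pair == schedule[0].losing_pair
        assert ev.gaining_pair == schedule[0].gaining_pair
        assert ev.quartet == schedule[0].quartet

    def test_all_scheduled_swaps_recovered(self, swap_movie):
        ts = synth.movie_to_trackset(swap_movie)
        events = ic.detect_t1(ts)
        truth = swap_movie.truth_events
        assert len(events) == len(truth) == 25
        detected = {
            (frozenset(e.losing_pair), frozenset(e.gaining_pair)):
                e.swap_time_min
            for e in events
        }
        dt_frame = swap_movie.frame_interval_s / 60.0
        for row in truth.itertuples():
            key = (frozenset((row.losing_a, row.losing_b)),
                   frozenset((row.gaining_a, row.gaining_b)))
            assert key in detected
            assert abs(detected[key] - row.swap_time_min) <= dt_frame

    def test_event_contact_contract(self, swap_movie):
        # before the swap the losing pair touch and the gaining pair do not;
        # after, the reverse
        ts = synth.movie_to_trackset(swap_movie)
        for ev in ic.detect_t1(ts):
            before = ts.frames[ev.last_contact_frame]
            after = ts.frames[ev.first_contact_frame]
            assert ev.losing_pair in before.interfaces
            assert ev.gaining_pair not in before.interfaces
            assert ev.gaining_pair in after.interfaces
            assert ev.losing_pair not in after.interfaces


class TestFlickerSuppression:
    def test_short_interior_runs_reverted(self):
        s = np.array([1, 1, 1, 0, 1, 1, 1], dtype=bool)
        out = ic._suppress_flickers(s, persistence=2)
        assert out.all()

    def test_persistent_changes_kept(self):
        s = np.array([1, 1, 1, 0, 0, 0, 0], dtype=bool)
        out = ic._suppress_flickers(s, persistence=2)
        assert (out == s).all()


class TestExchangeRates:
    def constructed_events(self, angles, t=0.5):
        return [
            ic.T1Event(t, frozenset((1, 2)), frozenset((3, 4)), a,
                       ic.t1_productivity(a), 0, 1)
            for a in angles
        ]

    def frame_with_dv_interfaces(self, n_dv, n_ap=0):
        from epimorph.mesh import Frame, Interface

        interfaces = {}
        for k in range(n_dv):
            pair = frozenset((2 * k, 2 * k + 1))
            interfaces[pair] = Interface.from_endpoints(pair, (k, 0.0),
                                                        (k, 5.0))
        for k in range(n_ap):
            pair = frozenset((1000 + 2 * k, 1001 + 2 * k))
            interfaces[pair] = Interface.from_endpoints(pair, (0.0, k),
                                                        (5.0, k))
        return Frame(0, 0.0, {}, interfaces, np.empty((0, 2)))

    def make_ts(self, n_dv):
        from epimorph.mesh import TrackSet

        frames = [self.frame_with_dv_interfaces(n_dv) for _ in range(2)]
        for i, f in enumerate(frames):
            f.index, f.time_s = i, i * 30.0
        return TrackSet(frames, 30.0)

    def test_no_events_zero_rates(self):
        ts = self.make_ts(50)
        rates = ic.exchange_rates([], ts, np.array([0.0, 1.0]))
        assert rates.swap_rate.iloc[0] == 0.0
        assert rates.productive_rate.iloc[0] == 0.0

    def test_five_dv_swaps_among_100_interfaces(self):
        ts = self.make_ts(100)
        events = self.constructed_events([90.0] * 5)
        rates = ic.exchange_rates(events, ts, np.array([0.0, 1.0]))
        assert rates.swap_rate.iloc[0] == pytest.approx(0.05)
        assert rates.productive_rate.iloc[0] == pytest.approx(0.05)

    def test_45_degree_swaps_are_unproductive(self):
        ts = self.make_ts(100)
        events = self.constructed_events([45.0] * 5)
        rates = ic.exchange_rates(events, ts, np.array([0.0, 1.0]))
        assert rates.swap_rate.iloc[0] == pytest.approx(0.05)
        assert rates.productive_rate.iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_raw_rate_bounds_productive_rate(self, swap_movie):
        ts = synth.movie_to_trackset(swap_movie)
        events = ic.detect_t1(ts)
        rates = ic.exchange_rates(events, ts, np.arange(0.0, 31.0, 1.0))
        ok = rates.swap_rate.notna()
        assert (rates.swap_rate[ok] >= rates.productive_rate[ok].abs() - 1e-12).all()

    def test_45_degree_interfaces_count_as_ap(self):
        from epimorph.mesh import Frame, Interface

        pair = frozenset((1, 2))
        diag = Interface.from_endpoints(pair, (0.0, 0.0), (3.0, 3.0))
        frame = Frame(0, 0.0, {}, {pair: diag}, np.empty((0, 2)))
        assert ic.count_dv_oriented_interfaces(frame) == 0


class TestAlignment:
    def test_aligned_lags_and_roles(self, swap_movie):
        ts = synth.movie_to_trackset(swap_movie)
        events = ic.detect_t1(ts)
        aligned = ic.align_to_swap(events, ts)
        shr = aligned[aligned.role == "shrinking"]
        grw = aligned[aligned.role == "growing"]
        assert (shr.lag_min < 0).all()  # shrinking traced before the swap
        assert (grw.lag_min > 0).all()  # growth indexed after the swap
        # shrinking junction lengths decrease toward the swap on average
        ens = ic.aligned_ensemble(aligned, "length_um", "shrinking")
        ens = ens.sort_values("lag_min")
        assert ens.mean_value.iloc[-1] < ens.mean_value.iloc[0]

    def test_scripted_linear_shrinkage_rates(self):
        # constructed trajectory: 6 um to 0 over 6 min => -1 um/min absolute,
        # proportional rate steepening toward the swap
        from epimorph.mesh import Frame, Interface, TrackSet

        pair = frozenset((1, 2))
        frames = []
        dt_min = 0.5
        for k in range(13):
            t = k * dt_min
            length = 6.0 - t
            interfaces = {}
            if length > 1e-9:
                interfaces[pair] = Interface.from_endpoints(
                    pair, (0.0, 0.0), (0.0, length)
                )
            frames.append(Frame(k, t * 60.0, {}, interfaces, np.empty((0, 2))))
        ts = TrackSet(frames, 30.0)
        ev = ic.T1Event(6.0, pair, frozenset((3, 4)), 90.0, 1.0, 11, 12)
        aligned = ic.align_to_swap([ev], ts)
        shr = aligned[aligned.role == "shrinking"].dropna(subset=["rate_um_min"])
        assert np.allclose(shr.rate_um_min, -1.0)
        prop = shr.sort_values("lag_min").rate_pp_min.to_numpy()
        assert (np.diff(prop) < 0).all()  # steepens (more negative) nearer swap

    def test_myosin_on_shrinking_interfaces_rises_toward_swap(self, swap_movie):
        # painted ground truth: density proportional to 1/length
        ts = synth.movie_to_trackset(swap_movie)
        events = ic.detect_t1(ts)
        myo = {}
        for i, frame in enumerate(ts.frames):
            for pair, iface in frame.interfaces.items():
                if iface.length_um > 0:
                    myo[(i, pair)] = 100.0 / max(iface.length_um, 0.5)
        aligned = ic.align_to_swap(events, ts, myosin_density=myo)
        ens = ic.aligned_ensemble(aligned, "myosin_density", "shrinking")
        # within the shrink window the aligned density rises monotonically
        ens = ens[(ens.n >= 10) & (ens.lag_min >= -3.5)].sort_values("lag_min")
        assert len(ens) >= 5
        assert (np.diff(ens.mean_value) > 0).all()


class TestNewNeighbourAngle:
    def test_angle_series_follows_geometry(self, swap_movie):
        ts = synth.movie_to_trackset(swap_movie)
        events = ic.detect_t1(ts)
        ev = events[0]
        series = ic.new_neighbour_angle(ev, ts, n_frames=6)
        assert len(series) > 0
        assert (series.lag_min >= 0).all()
        c, d = sorted(ev.gaining_pair)
        f = ts.frames[ev.first_contact_frame]
        from epimorph.geometry import acute_angle_from_ap

        expected = acute_angle_from_ap(
            f.cells[d].centroid - f.cells[c].centroid
        )
        assert series.angle_deg.iloc[0] == pytest.approx(expected, abs=1e-9)

    def test_swaps_on_dv_junctions_gain_dv_neighbours(self, swap_movie):
        # scripted productive T1s: gaining pairs stack along DV
        truth = swap_movie.truth_events
        assert (truth.centroid_angle_deg > 45.0).mean() > 0.9
        assert (truth.productivity > 0).mean() > 0.9
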