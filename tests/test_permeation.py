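import numpy as np
import pytest

from aquaflux.errors import EmptyInputError, ParameterError
from aquaflux.permeation import (
    ABOVE,
    BELOW,
    INSIDE,
    OUTSIDE,
    ChannelSpec,
    count_events,
    cumulative_curve,
    diffusive_permeability,
    permeation_rate,
    track_regions,
    water_specific_volume,
)
from conftest import make_water_trajectory

# conftest channel: z in [15, 25], buffer 2, radial cutoff 5, box z = 40


def transit_path(n_pre=3, n_in=5, n_post=3):
    """z path below -> inside -> above, strictly through the channel."""
    return np.concatenate([
        np.full(n_pre, 10.0), np.linspace(16.0, 24.0, n_in),
        np.full(n_post, 30.0)])


class TestTrackRegions:
    def test_midpoint_is_inside(self, simple_channel):
        traj = make_water_trajectory([[20.0] * 5])
        rs = track_regions(traj, simple_channel)
        assert (rs.regions == INSIDE).all()

    def test_below_buffer(self, simple_channel):
        traj = make_water_trajectory([[simple_channel.z_lo - 2.0 - 1.0] * 3])
        rs = track_regions(traj, simple_channel)
        assert (rs.regions == BELOW).all()

    def test_buffer_zone_is_not_bulk(self, simple_channel):
        traj = make_water_trajectory([[14.0] * 3])  # in [z_lo-buffer, z_lo)
        rs = track_regions(traj, simple_channel)
        assert (rs.regions == OUTSIDE).all()

    def test_radially_excluded(self, simple_channel):
        # z inside the span but 2x radial cutoff off-axis
        traj = make_water_trajectory([[20.0] * 3], box=(40.0, 40.0, 40.0),
                                     xy=(20.0 + 10.0, 20.0))
        rs = track_regions(traj, simple_channel)
        assert (rs.regions == OUTSIDE).all()

    def test_no_waters_is_input_error(self, simple_channel):
        from aquaflux.synthetic_data import gen_gating_fixture
        from aquaflux.traj_io import Trajectory

        top, frame = gen_gating_fixture(4.0, 7.0)
        with pytest.raises(EmptyInputError):
            track_regions(Trajectory(top, [frame]), simple_channel)

    def test_pbc_wrap_does_not_fake_transit(self, simple_channel):
        # water drifts upward through the box boundary: above -> below via
        # wrap, never transiting the channel
        z = np.linspace(30.0, 50.0, 21) % 40.0
        traj = make_water_trajectory([z])
        rs = track_regions(traj, simple_channel)
        assert count_events(rs) == []


class TestCountEvents:
    def test_single_forward_transit(self, simple_channel):
        traj = make_water_trajectory([transit_path()])
        events = count_events(track_regions(traj, simple_channel))
        assert len(events) == 1
        assert events[0].direction == +1
        assert events[0].exit_frame > events[0].entry_frame

    def test_time_reversed_is_backward(self, simple_channel):
        traj = make_water_trajectory([transit_path()[::-1]])
        events = count_events(track_regions(traj, simple_channel))
        assert [e.direction for e in events] == [-1]

    def test_mouth_recrossing_counts_zero(self, simple_channel):
        z = [10.0, 20.0, 10.0, 20.0, 10.0]  # dips in and returns below
        events = count_events(track_regions(make_water_trajectory([z]),
                                            simple_channel))
        assert events == []

    def test_buffer_touch_does_not_complete(self, simple_channel):
        # reaches the upper buffer (26.5 < z_hi + delta) but not bulk
        z = [10.0, 20.0, 26.5, 20.0, 10.0, 20.0, 30.0]
        events = count_events(track_regions(make_water_trajectory([z]),
                                            simple_channel))
        assert [e.direction for e in events] == [+1]

    def test_double_transit_counted_twice(self, simple_channel):
        z = np.concatenate([transit_path(), transit_path()[::-1]])
        events = count_events(track_regions(make_water_trajectory([z]),
                                            simple_channel))
        assert [e.direction for e in events] == [+1, -1]


def oracle_events(z_path, channel, box_z):
    """Exhaustive path-scan oracle: independent region labeling + scan."""
    events = []
    last_bulk = None
    first_inside = None
    for f, z in enumerate(np.asarray(z_path) % box_z):
        if z < channel.z_lo - channel.buffer:
            r = "below"
        elif z > channel.z_hi + channel.buffer:
            r = "above"
        elif channel.z_lo <= z <= channel.z_hi:
            r = "inside"
        else:
            r = "buffer"
        if r == "inside":
            if last_bulk is not None and first_inside is None:
                first_inside = f
        elif r in ("below", "above"):
            if (last_bulk is not None and r != last_bulk
                    and first_inside is not None):
                events.append((+1 if r == "above" else -1, first_inside, f))
            last_bulk = r
            first_inside = None
    return events


class TestOracleEquivalence:
    def test_1000_random_walk_paths(self, simple_channel, rng):
        n_paths, n_frames = 1000, 120
        steps = rng.normal(0, 2.5, size=(n_paths, n_frames - 1))
        z = np.concatenate([
            rng.uniform(5, 35, size=(n_paths, 1)),
            np.zeros((n_paths, n_frames - 1))], axis=1)
        z[:, 1:] = z[:, [0]] + np.cumsum(steps, axis=1)
        traj = make_water_trajectory(z % 40.0)
        got = count_events(track_regions(traj, simple_channel))
        got_by_water = {}
        for e in got:
            got_by_water.setdefault(e.water_id, []).append(
                (e.direction, e.entry_frame, e.exit_frame))
        total = 0
        for w in range(n_paths):
            expected = oracle_events(z[w], simple_channel, 40.0)
            assert got_by_water.get(w, []) == expected
            total += len(expected)
        assert total > 50  # the comparison actually exercised transits

    def test_time_reversal_antisymmetry(self, simple_channel, rng):
        steps = rng.normal(0, 2.5, size=(200, 99))
        z = np.cumsum(np.concatenate(
            [rng.uniform(5, 35, (200, 1)), steps], axis=1), axis=1)
        fwd = count_events(track_regions(
            make_water_trajectory(z % 40.0), simple_channel))
        rev = count_events(track_regions(
            make_water_trajectory(z[:, ::-1] % 40.0), simple_channel))
        n_pos_f = sum(1 for e in fwd if e.direction > 0)
        n_neg_f = sum(1 for e in fwd if e.direction < 0)
        n_pos_r = sum(1 for e in rev if e.direction > 0)
        n_neg_r = sum(1 for e in rev if e.direction < 0)
        assert (n_pos_f, n_neg_f) == (n_neg_r, n_pos_r)

    def test_rigid_translation_invariance(self, simple_channel, rng):
        steps = rng.normal(0, 2.5, size=(50, 79))
        z = np.cumsum(np.concatenate(
            [rng.uniform(5, 35, (50, 1)), steps], axis=1), axis=1)
        base = count_events(track_regions(
            make_water_trajectory(z % 40.0), simple_channel))
        shift = 7.3
        moved_channel = ChannelSpec(
            z_lo=simple_channel.z_lo + shift, z_hi=simple_channel.z_hi + shift,
            buffer=simple_channel.buffer,
            radial_cutoff=simple_channel.radial_cutoff)
        moved = count_events(track_regions(
            make_water_trajectory((z + shift) % 40.0), moved_channel))
        key = [(e.water_id, e.direction) for e in base]
        assert [(e.water_id, e.direction) for e in moved] == key


class TestRates:
    def test_symmetric_counts(self, simple_channel):
        paths = [transit_path() for _ in range(10)]
        paths += [transit_path()[::-1] for _ in range(10)]
        # pad to equal length 11 frames, dt=1 ns -> 10 ns window
        traj = make_water_trajectory(np.array(paths), dt_ns=1.0)
        events = count_events(track_regions(traj, simple_channel))
        rate = permeation_rate(events, traj.times)
        assert rate.n_pos == rate.n_neg == 10
        assert rate.q0 == pytest.approx(1.0)

    def test_zero_events(self):
        rate = permeation_rate([], np.arange(11) * 1.0)
        assert rate.q0 == 0.0

    def test_empty_window_rejected(self):
        with pytest.raises(ParameterError):
            permeation_rate([], np.arange(11) * 1.0, t0=5.0, t1=5.0)

    def test_slope_matches_constant_rate(self, simple_channel):
        # one + transit every 10 frames, dt=1 ns
        z = np.tile(transit_path(3, 4, 3), 12)
        traj = make_water_trajectory([z], dt_ns=1.0)
        events = count_events(track_regions(traj, simple_channel))
        rate = permeation_rate(events, traj.times)
        assert rate.slope == pytest.approx(rate.q0, rel=0.25)

    def test_cumulative_curve_direction_average(self):
        from aquaflux.permeation import PermeationEvent

        events = [PermeationEvent(0, +1, 1, 3),
                  PermeationEvent(1, -1, 2, 5)]
        curve = cumulative_curve(events, np.arange(8) * 1.0)
        np.testing.assert_allclose(curve, [0, 0, 0, 0.5, 0.5, 1, 1, 1])


class TestPermeabilityArithmetic:
    def test_specific_volume_of_water(self):
        assert water_specific_volume(18.0) == pytest.approx(2.989e-23,
                                                            rel=1e-3)

    def test_specific_volume_linear(self):
        assert water_specific_volume(36.0) == pytest.approx(
            2 * water_specific_volume(18.0))

    def test_zero_molar_volume_rejected(self):
        with pytest.raises(ParameterError):
            water_specific_volume(0.0)

    def test_pd_arithmetic(self):
        v_w = water_specific_volume(18.0)
        assert diffusive_permeability(1.0, v_w) == pytest.approx(2.99e-14,
                                                                 rel=1e-3)

    def test_pd_zero_and_linear(self):
        v_w = water_specific_volume(18.0)
        assert diffusive_permeability(0.0, v_w) == 0.0
        assert diffusive_permeability(2.0, v_w) == pytest.approx(
            2 * diffusive_permeability(1.0, v_w))

    def test_negative_rate_rejected(self):
        with pytest.raises(ParameterError):
            diffusive_permeability(-1.0, 1e-23)


class TestChannelSpec:
    def test_invalid_bounds(self):
        with pytest.raises(ParameterError):
            ChannelSpec(z_lo=10.0, z_hi=5.0)

    def test_length(self, simple_channel):
        assert simple_channel.length == pytest.approx(10.0)
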