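"""Track linking, relative nuclear intensity, and the positive-rate rule."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clocksync.errors import ClockSyncError
from clocksync.synth import TimelapseScenario, gen_timelapse
from clocksync.tracking import (
    CellTrack,
    link_tracks,
    max_fold_change,
    max_fold_changes,
    positive_rate,
    relative_nuclear_series,
    tracks_to_frame,
)


def _stack_with_disk(T, pos_per_frame, radius=3, shape=(40, 40), value=10.0):
    """Tiny helper: one disk per frame at the given positions."""
    nl = np.zeros((T, *shape), np.int32)
    im = np.zeros((T, *shape), float)
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    for f, (r0, c0) in enumerate(pos_per_frame):
        mask = (rr - r0) ** 2 + (cc - c0) ** 2 <= radius ** 2
        nl[f][mask] = 1
        im[f][mask] = value
    return nl, im


class TestLinking:
    def test_static_cells_keep_identity_for_all_frames(self):
        tl = gen_timelapse(
            TimelapseScenario(n_cells=15, n_frames=20, motion_sd_px=0.0, seed=3),
            render=True,
        )
        tracks = link_tracks(tl.nuclear_labels, tl.cell_labels, tl.intensity,
                             tl.times_min[:20], max_disp=5.0)
        assert len(tracks) == 15
        assert all(len(tr) == 20 for tr in tracks)

    def test_slowly_moving_cell_stays_one_track(self):
        pos = [(10 + f, 10 + f) for f in range(10)]
        nl, im = _stack_with_disk(10, pos)
        tracks = link_tracks(nl, nl, im, max_disp=3.0)
        assert len(tracks) == 1
        assert len(tracks[0]) == 10

    def test_long_jump_ends_the_track_instead_of_swapping(self):
        pos = [(10, 10)] * 5 + [(30, 30)] * 5
        nl, im = _stack_with_disk(10, pos)
        tracks = link_tracks(nl, nl, im, max_disp=5.0)
        assert len(tracks) == 2
        assert sorted(len(t) for t in tracks) == [5, 5]

    def test_shape_mismatch_rejected(self):
        nl = np.zeros((3, 10, 10), np.int32)
        with pytest.raises(ClockSyncError):
            link_tracks(nl, nl[:2], np.zeros((3, 10, 10)))

    def test_round_trips_through_tidy_frame(self):
        pos = [(10, 10)] * 4
        nl, im = _stack_with_disk(4, pos)
        tracks = link_tracks(nl, nl, im, max_disp=3.0)
        df = tracks_to_frame(tracks)
        assert set(df.columns) == {"cell_id", "frame", "time_min", "x", "y",
                                   "nuc_sum", "cell_sum"}
        assert len(df) == 4


class TestRelativeNuclearSeries:
    def _track(self, nuc, cell):
        n = len(nuc)
        return CellTrack(0, pd.DataFrame({
            "frame": range(n), "time_min": np.arange(n, dtype=float),
            "x": 0.0, "y": 0.0, "nuc_sum": nuc, "cell_sum": cell,
        }))

    def test_equal_intensities_give_one(self):
        s = relative_nuclear_series(self._track([5.0] * 4, [5.0] * 4))
        assert np.allclose(s, 1.0)

    def test_zero_nucleus_gives_zero(self):
        s = relative_nuclear_series(self._track([0.0] * 4, [5.0] * 4))
        assert np.allclose(s, 0.0)

    def test_zero_cell_marks_missing(self):
        s = relative_nuclear_series(self._track([1.0, 1.0], [2.0, 0.0]))
        assert np.isnan(s.iloc[1]) and s.iloc[0] == 0.5

    def test_sigmoid_plateau_recovered(self):
        tl = gen_timelapse(
            TimelapseScenario(n_cells=12, responder_fraction=1.0,
                              latency_sd_min=0.0, rel_noise_sd=0.005,
                              motion_sd_px=0.0, seed=5),
            render=True,
        )
        tracks = link_tracks(tl.nuclear_labels, tl.cell_labels, tl.intensity,
                             tl.times_min, max_disp=5.0)
        for tr in tracks:
            s = relative_nuclear_series(tr)
            plateau = s.iloc[-3:].mean()
            x, y = tr.frames["x"].mean(), tr.frames["y"].mean()
            k = np.argmin(np.hypot(tl.truth["x"] - x, tl.truth["y"] - y))
            expected = tl.truth["baseline"].iloc[k] + tl.truth["amplitude"].iloc[k]
            assert plateau == pytest.approx(expected, rel=0.05)


class TestMaxFoldChange:
    def _series(self, vals):
        return pd.Series(vals, index=np.arange(len(vals), dtype=float) * 3.0)

    def test_constant_series_gives_one(self):
        assert max_fold_change(self._series([2.0] * 10), stimulus_time=15.0) == 1.0

    def test_step_doubles(self):
        vals = [1.0] * 5 + [2.0] * 5
        assert max_fold_change(self._series(vals), stimulus_time=15.0) == 2.0

    @given(st.floats(0.1, 100.0))
    @settings(max_examples=50, deadline=None)
    def test_invariant_to_global_scaling(self, scale):
        vals = np.array([1.0, 1.1, 0.9, 1.0, 1.5, 2.0, 1.8])
        s = self._series(vals)
        assert max_fold_change(s * scale, 9.0) == pytest.approx(
            max_fold_change(s, 9.0), rel=1e-12
        )

    def test_zero_baseline_is_an_error(self):
        with pytest.raises(ClockSyncError):
            max_fold_change(self._series([0.0] * 5 + [1.0] * 5), stimulus_time=12.0)


class TestPositiveRate:
    def test_control_against_itself_is_a_quarter(self, rng):
        fc = rng.uniform(0.9, 2.0, 200)     # continuous, no ties
        res = positive_rate(fc, fc)
        assert res.rate == pytest.approx(0.25, abs=1e-12)

    def test_treated_below_control_minimum_scores_zero(self, rng):
        ctl = rng.uniform(2.0, 3.0, 50)
        res = positive_rate(rng.uniform(0.5, 1.0, 40), ctl)
        assert res.rate == 0.0

    def test_rate_monotone_in_quantile(self, rng):
        ctl = rng.uniform(0.9, 2.0, 100)
        trt = rng.uniform(0.9, 2.5, 100)
        rates = [positive_rate(trt, ctl, q=q).rate for q in (0.25, 0.5, 0.75, 0.9)]
        assert all(a >= b for a, b in zip(rates, rates[1:]))

    def test_prescribed_responder_fraction_recovered(self):
        tl = gen_timelapse(TimelapseScenario(n_cells=100, seed=21), render=True)
        tracks = link_tracks(tl.nuclear_labels, tl.cell_labels, tl.intensity,
                             tl.times_min, max_disp=8.0)
        ctl = gen_timelapse(
            TimelapseScenario(n_cells=100, responder_fraction=0.0, seed=22),
            render=True,
        )
        ctracks = link_tracks(ctl.nuclear_labels, ctl.cell_labels, ctl.intensity,
                              ctl.times_min, max_disp=8.0)
        res = positive_rate(tracks, ctracks, stimulus_time=30.0)
        # 80% responders + ~25% of non-responders above a 75th-pct threshold
        assert res.rate == pytest.approx(0.85, abs=0.12)

    def test_track_and_array_inputs_agree(self):
        tl = gen_timelapse(TimelapseScenario(n_cells=10, seed=9), render=True)
        tracks = link_tracks(tl.nuclear_labels, tl.cell_labels, tl.intensity,
                             tl.times_min, max_disp=8.0)
        fcs = max_fold_changes(tracks, stimulus_time=30.0)
        a = positive_rate(tracks, tracks, stimulus_time=30.0)
        b = positive_rate(fcs, fcs)
        assert a.rate == b.rate and a.threshold == b.threshold

    def test_empty_arm_rejected(self):
        with pytest.raises(ClockSyncError):
            positive_rate([], [1.0, 2.0])
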