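"""Trial QC and behavioral metrics (PE, RE, time series, aggregation)."""

import numpy as np
import pytest

from gazebeta.gaze import (
    GAZE_DT_S,
    N_SERIES_BINS,
    ExclusionReason,
    GazeTrial,
    gaze_xy_series,
    participant_aggregate,
    pe_time_series,
    position_error_at_response,
    qc_trial,
    response_error,
)
from gazebeta.kinematics import Condition, landing_position_px


def make_trial(
    press=4.6,
    n=None,
    x=None,
    y=None,
    valid=None,
    condition=Condition.CLOSE,
):
    if n is None:
        n = int(np.floor(press / GAZE_DT_S + 1e-9)) + 1
    times = np.arange(n) * GAZE_DT_S
    return GazeTrial(
        times=times,
        x_px=np.full(n, 400.0) if x is None else x,
        y_px=np.full(n, 500.0) if y is None else y,
        valid=np.ones(n, dtype=bool) if valid is None else valid,
        press_time=press,
        condition_label=condition,
        participant="p1",
        group="A",
    )


def landing_trial(close_params, geometry, press=4.6, offset=(0.0, 0.0)):
    lx, ly = landing_position_px(close_params, geometry)
    n = int(np.floor(press / GAZE_DT_S + 1e-9)) + 1
    return make_trial(
        press=press,
        n=n,
        x=np.full(n, lx + offset[0]),
        y=np.full(n, ly + offset[1]),
    )


class TestQC:
    def test_clean_trial_kept(self):
        res = qc_trial(make_trial(), False)
        assert res.kept and res.reason is ExclusionReason.OK

    def test_blink_in_window_excludes(self):
        valid = np.ones(231, dtype=bool)
        valid[100] = False
        res = qc_trial(make_trial(valid=valid), False)
        assert not res.kept and res.reason is ExclusionReason.BLINK_OR_DROPOUT

    def test_invalid_samples_after_press_are_ignored(self):
        trial = make_trial(press=4.0, n=231)
        trial.valid[210:] = False  # after the press
        assert qc_trial(trial, False).kept

    def test_gaze_loss_takes_precedence_over_artifact(self):
        valid = np.ones(231, dtype=bool)
        valid[50] = False
        res = qc_trial(make_trial(valid=valid), True)
        assert res.reason is ExclusionReason.BLINK_OR_DROPOUT

    def test_stepwise_accounting_on_toy_set(self):
        """5 trials: 2 with in-window blinks, 1 EEG-flagged → 2 kept."""
        trials = [make_trial() for _ in range(5)]
        trials[1].valid[30] = False
        trials[3].valid[10] = False
        flags = [False, False, False, True, True]
        results = [qc_trial(t, f) for t, f in zip(trials, flags)]
        reasons = [r.reason for r in results]
        assert sum(r.kept for r in results) == 2
        assert reasons.count(ExclusionReason.BLINK_OR_DROPOUT) == 2
        assert reasons.count(ExclusionReason.EEG_ARTIFACT) == 1

    def test_press_beyond_recording_raises(self):
        with pytest.raises(ValueError):
            qc_trial(make_trial(press=5.0, n=100), False)

    def test_qc_is_idempotent(self):
        trial = make_trial()
        assert qc_trial(trial, False) == qc_trial(trial, False)


class TestScalarMetrics:
    def test_gaze_on_landing_gives_zero_pe(self, close_params, geometry):
        tr = landing_trial(close_params, geometry)
        assert position_error_at_response(tr, close_params, geometry) == pytest.approx(
            0.0, abs=1e-12
        )

    @pytest.mark.parametrize(
        "offset,expected",
        [((100.0, 0.0), 100 * 35.66 / 1280), ((0.0, -100.0), 100 * 28.86 / 1024)],
    )
    def test_pe_uses_per_axis_conversion(self, close_params, geometry, offset, expected):
        tr = landing_trial(close_params, geometry, offset=offset)
        assert position_error_at_response(tr, close_params, geometry) == pytest.approx(
            expected, abs=1e-9
        )

    def test_pe_translation_invariance(self, close_params, geometry, rng):
        """Shifting gaze and landing by a common pixel offset leaves PE
        unchanged — checked via two different gaze offsets from landing."""
        off = rng.uniform(-50, 50, 2)
        tr1 = landing_trial(close_params, geometry, offset=tuple(off))
        tr2 = landing_trial(close_params, geometry, offset=tuple(off))
        tr2.x_px += 30.0
        lx, ly = landing_position_px(close_params, geometry)
        from gazebeta.gaze import position_error_deg

        pe1 = position_error_deg((tr1.x_px[0], tr1.y_px[0]), (lx, ly), geometry)
        pe2 = position_error_deg((tr2.x_px[0] + 5, tr2.y_px[0]), (lx + 35, ly), geometry)
        assert pe1 == pytest.approx(pe2, abs=1e-12)

    @pytest.mark.parametrize("press,expected", [(4.6, 0.0), (5.15, 0.55), (4.05, 0.55)])
    def test_response_error_is_unsigned(self, press, expected):
        assert response_error(make_trial(press=press)) == pytest.approx(expected, abs=1e-12)


class TestSeries:
    def test_gaze_pinned_at_landing_gives_zero_series(self, close_params, geometry):
        tr = landing_trial(close_params, geometry)
        series = pe_time_series(tr, close_params, geometry)
        covered = ~np.isnan(series)
        assert covered.sum() == tr.times.size
        np.testing.assert_allclose(series[covered], 0.0, atol=1e-12)

    def test_gaze_at_launch_gives_constant_landing_distance(
        self, close_params, geometry
    ):
        from gazebeta.kinematics import target_position_px
        from gazebeta.gaze import position_error_deg

        launch = target_position_px(close_params, geometry, 0.0)
        n = 231
        tr = make_trial(n=n, x=np.full(n, launch[0]), y=np.full(n, launch[1]))
        series = pe_time_series(tr, close_params, geometry)
        expected = position_error_deg(
            launch, landing_position_px(close_params, geometry), geometry
        )
        covered = ~np.isnan(series)
        np.testing.assert_allclose(series[covered], expected, atol=1e-9)
        assert expected > 20  # the landing offset spans >20° at this geometry

    def test_series_truncates_at_press(self, close_params, geometry):
        tr = landing_trial(close_params, geometry, press=3.0)
        series = pe_time_series(tr, close_params, geometry)
        press_bin = int(np.floor(3.0 / GAZE_DT_S))
        assert not np.isnan(series[: press_bin + 1]).any()
        assert np.isnan(series[press_bin + 1 :]).all()

    def test_pe_at_press_bin_matches_scalar_pe(self, close_params, geometry, rng):
        n = 231
        tr = make_trial(
            n=n,
            x=rng.uniform(300, 900, n),
            y=rng.uniform(300, 900, n),
            press=4.37,
        )
        series = pe_time_series(tr, close_params, geometry)
        press_bin = int(np.floor(tr.press_time / GAZE_DT_S))
        scalar = position_error_at_response(tr, close_params, geometry)
        assert series[press_bin] == pytest.approx(scalar, abs=1e-12)

    def test_invalid_samples_are_nan(self, close_params, geometry):
        tr = landing_trial(close_params, geometry)
        tr.valid[10] = False
        series = pe_time_series(tr, close_params, geometry)
        assert np.isnan(series[10])


class TestAggregate:
    def test_single_trial_aggregate_equals_trial(
        self, close_params, params_by_condition, geometry
    ):
        tr = landing_trial(close_params, geometry, offset=(100.0, 0.0))
        agg = participant_aggregate([tr], params_by_condition, geometry)
        assert agg.pe_at_response == pytest.approx(
            position_error_at_response(tr, close_params, geometry)
        )
        assert agg.re == pytest.approx(response_error(tr))
        assert agg.n_trials == 1

    def test_mean_of_two_trials(self, close_params, params_by_condition, geometry):
        t1 = landing_trial(close_params, geometry, offset=(1280 / 35.66, 0.0))  # 1°
        t2 = landing_trial(close_params, geometry, offset=(3 * 1280 / 35.66, 0.0))  # 3°
        agg = participant_aggregate([t1, t2], params_by_condition, geometry)
        assert agg.pe_at_response == pytest.approx(2.0, abs=1e-9)

    def test_bin_covered_by_one_trial_keeps_its_value(
        self, close_params, params_by_condition, geometry
    ):
        t1 = landing_trial(close_params, geometry, press=4.6)
        t2 = landing_trial(close_params, geometry, press=2.0, offset=(50.0, 0.0))
        agg = participant_aggregate([t1, t2], params_by_condition, geometry)
        late_bin = 200  # 4.0 s: only t1 covers it
        assert agg.series_counts[late_bin] == 1
        assert agg.pe_series[late_bin] == pytest.approx(0.0, abs=1e-12)

    def test_zero_trials_raise(self, params_by_condition, geometry):
        with pytest.raises(ValueError):
            participant_aggregate([], params_by_condition, geometry)

    def test_xy_series_reports_pixels(self, close_params, geometry):
        tr = landing_trial(close_params, geometry)
        xs, ys = gaze_xy_series(tr)
        lx, ly = landing_position_px(close_params, geometry)
        assert xs[0] == pytest.approx(lx)
        assert ys[0] == pytest.approx(ly)
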