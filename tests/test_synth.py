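"""Synthetic cohort generator: determinism, calibration, monotonicity."""

import dataclasses

import numpy as np
import pytest

from gazebeta import gaze as gazemod
from gazebeta import pipeline as pl
from gazebeta.kinematics import Condition
from gazebeta.synth import (
    DEFAULT_STRATEGY_A,
    DEFAULT_STRATEGY_B,
    GROUP_A,
    BetaEffect,
    CohortConfig,
    EEGGenConfig,
    GazeStrategyParams,
    generate_cohort,
    generate_eeg_epochs,
    generate_gaze_trial,
    default_beta_effects,
)


def small_config(**kw):
    defaults = dict(trials_per_participant=4, seed=7, include_eeg=False, eeg_config=None)
    defaults.update(kw)
    return CohortConfig(**defaults)


class TestDeterminism:
    def test_same_seed_gives_identical_cohort(self):
        c1 = generate_cohort(small_config())
        c2 = generate_cohort(small_config())
        for s1, s2 in zip(c1, c2):
            assert s1.participant_id == s2.participant_id
            assert s1.group == s2.group
            for t1, t2 in zip(s1.trials, s2.trials):
                np.testing.assert_array_equal(t1.x_px, t2.x_px)
                np.testing.assert_array_equal(t1.valid, t2.valid)
                assert t1.press_time == t2.press_time
                assert t1.condition_label == t2.condition_label

    def test_same_seed_gives_identical_eeg(self, rng):
        cfg = EEGGenConfig()
        e1 = generate_eeg_epochs(cfg, GROUP_A, 3, np.random.default_rng(3))
        e2 = generate_eeg_epochs(cfg, GROUP_A, 3, np.random.default_rng(3))
        np.testing.assert_array_equal(e1, e2)

    def test_different_seeds_differ(self):
        c1 = generate_cohort(small_config(seed=1))
        c2 = generate_cohort(small_config(seed=2))
        assert c1[0].trials[0].press_time != c2[0].trials[0].press_time


class TestCohortStructure:
    def test_default_cohort_is_17_sessions_of_180_trials(self):
        cfg = CohortConfig(include_eeg=False, eeg_config=None, seed=0)
        assert cfg.n_group_a == 6 and cfg.n_group_b == 11
        assert cfg.trials_per_participant == 180
        sessions = generate_cohort(
            dataclasses.replace(cfg, trials_per_participant=3)
        )
        assert len(sessions) == 17
        assert sum(s.group == GROUP_A for s in sessions) == 6
        assert all(len(s.trials) == 3 for s in sessions)
        assert all(t.press_time > 0 for s in sessions for t in s.trials)

    def test_eeg_epoch_shape(self):
        cfg = small_config(trials_per_participant=2, include_eeg=True,
                           eeg_config=EEGGenConfig())
        sessions = generate_cohort(cfg)
        assert sessions[0].eeg_epochs.shape == (2, 19, 2500)

    def test_conditions_drawn_from_cycle(self):
        sessions = generate_cohort(small_config(trials_per_participant=30))
        labels = {t.condition_label for s in sessions for t in s.trials}
        assert labels == set(Condition)


class TestGazeCalibration:
    def test_noise_free_strategy_gives_zero_pe(self, params_by_condition, geometry, rng):
        strategy = GazeStrategyParams(
            endpoint_sd=0.0, endpoint_bias=0.0, fixation_noise_sd=0.0,
            endpoint_sd_between_cv=0.0, blink_rate=0.0, press_error_sd=0.0,
        )
        p = params_by_condition[Condition.CLOSE]
        tr = generate_gaze_trial(strategy, p, geometry, rng)
        assert gazemod.position_error_at_response(tr, p, geometry) == pytest.approx(
            0.0, abs=1e-9
        )

    def test_group_a_mean_pe_matches_configured_target(
        self, params_by_condition, geometry
    ):
        """Monte Carlo over 2000 trials: mean PE within ±0.15° of the 2.0°
        calibration target."""
        rng = np.random.default_rng(0)
        p = params_by_condition[Condition.CLOSE]
        pes = []
        for _ in range(2000):
            tr = generate_gaze_trial(DEFAULT_STRATEGY_A, p, geometry, rng)
            pes.append(gazemod.position_error_at_response(tr, p, geometry))
        assert np.mean(pes) == pytest.approx(2.0, abs=0.15)

    def test_endpoint_sd_monotonically_increases_pe(self, params_by_condition, geometry):
        p = params_by_condition[Condition.CLOSE]

        def mean_pe(sd, seed):
            rng = np.random.default_rng(seed)
            strat = dataclasses.replace(DEFAULT_STRATEGY_A, endpoint_sd=sd)
            return np.mean(
                [
                    gazemod.position_error_at_response(
                        generate_gaze_trial(strat, p, geometry, rng), p, geometry
                    )
                    for _ in range(400)
                ]
            )

        assert mean_pe(0.5, 1) < mean_pe(1.5, 2) < mean_pe(3.0, 3)

    def test_blink_spanning_trial_fails_qc(self, params_by_condition, geometry, rng):
        strategy = dataclasses.replace(
            DEFAULT_STRATEGY_A, blink_rate=8.0, blink_duration=(6.0, 0.0)
        )
        p = params_by_condition[Condition.CLOSE]
        tr = generate_gaze_trial(strategy, p, geometry, rng)
        res = gazemod.qc_trial(tr, False)
        assert not res.kept
        assert res.reason is gazemod.ExclusionReason.BLINK_OR_DROPOUT

    def test_exclusion_scale_matches_reported_magnitudes(self):
        """At default blink rates, excluded trials per participant land in
        a ±50% band around the reported scales (≈49 and ≈77 of 180)."""
        counts = {"A": [], "B": []}
        for seed in range(3):
            sessions = generate_cohort(
                CohortConfig(
                    n_group_a=2, n_group_b=2, trials_per_participant=180,
                    seed=seed, include_eeg=False, eeg_config=None,
                )
            )
            for s in sessions:
                excluded = sum(
                    not gazemod.qc_trial(t, False).kept for t in s.trials
                )
                counts[s.group].append(excluded)
        mean_a = np.mean(counts["A"])
        mean_b = np.mean(counts["B"])
        assert 24 <= mean_a <= 74
        assert 38 <= mean_b <= 116
        assert mean_a < mean_b


class TestEEGGeneration:
    def test_artifact_rate_one_rejects_everything(self, rng):
        cfg = EEGGenConfig(artifact_rate=1.0, beta_effects=())
        ep = generate_eeg_epochs(cfg, GROUP_A, 20, rng)
        pre = pl.preprocess_epochs(ep)
        assert pl.artifact_flags(pre).all()

    def test_artifact_rate_recovered(self):
        cfg = EEGGenConfig(artifact_rate=0.3, beta_effects=())
        ep = generate_eeg_epochs(cfg, GROUP_A, 300, np.random.default_rng(5))
        pre = pl.preprocess_epochs(ep)
        rate = pl.artifact_flags(pre).mean()
        assert rate == pytest.approx(0.3, abs=0.08)

    def test_beta_gain_monotonically_increases_envelope_difference(self):
        """Larger injected gain raises the mean log-envelope at the
        injected channel/window relative to a no-effect epoch set."""
        from gazebeta.montage import MONTAGE_19

        ci = MONTAGE_19.index("CP5")
        win = slice(754, 820)  # 0.554–0.619 s within the −0.2-offset epoch

        def win_env(gain, seed):
            effects = (BetaEffect(GROUP_A, "CP5", 0.554, 0.619, gain),)
            cfg = EEGGenConfig(beta_effects=effects, artifact_rate=0.0)
            ep = generate_eeg_epochs(cfg, GROUP_A, 30, np.random.default_rng(seed))
            from gazebeta.eeg import batch_lowbeta_envelope

            env = batch_lowbeta_envelope(pl.preprocess_epochs(ep))
            return env[:, ci, win].mean()

        e0, e1, e2 = win_env(0.0, 9), win_env(20.0, 9), win_env(60.0, 9)
        assert e0 < e1 < e2

    def test_effects_target_only_their_group(self, rng):
        effects = (BetaEffect(GROUP_A, "CP5", 0.5, 0.7, 50.0),)
        cfg = EEGGenConfig(beta_effects=effects, artifact_rate=0.0)
        a = generate_eeg_epochs(cfg, "A", 10, np.random.default_rng(1))
        b = generate_eeg_epochs(cfg, "B", 10, np.random.default_rng(1))
        from gazebeta.montage import MONTAGE_19

        ci = MONTAGE_19.index("CP5")
        assert np.abs(a[:, ci, 700:900]).max() > np.abs(b[:, ci, 700:900]).max()

    def test_default_effects_validate_windows(self):
        for eff in default_beta_effects():
            assert -0.2 <= eff.window_start < eff.window_end <= 2.3

    def test_invalid_effect_window_raises(self):
        with pytest.raises(ValueError):
            BetaEffect(GROUP_A, "CP5", 2.0, 2.5, 1.0)
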