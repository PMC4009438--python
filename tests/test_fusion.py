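"""Stream synchronization, activity gating and the five-command rule table."""

import dataclasses

import numpy as np
import pytest

from nirseeg import eeg as E
from nirseeg import fusion as F
from nirseeg import paradigm as P
from nirseeg.errors import InvalidArgumentError, StateError
from nirseeg.simulate import SimulationConfig, simulate_session


class TestFrameGrid:
    def test_300_second_session_has_543_frames(self):
        times = F.frame_times(300.0, 1.81)
        assert len(times) == 543
        assert times[-1] == pytest.approx(300.0)

    def test_grid_spacing(self):
        times = F.frame_times(60.0, 1.81)
        assert np.allclose(np.diff(times), 1.0 / 1.81)


class TestDecodeCommand:
    @pytest.mark.parametrize(
        "eeg_state,nirs_state,command",
        [
            ("left_hand", "rest", "Left"),
            ("right_hand", "rest", "Right"),
            ("rest", "arithmetic", "Back"),
            ("rest", "counting", "Forward"),
            ("rest", "rest", "Stop"),
        ],
    )
    def test_rule_table(self, eeg_state, nirs_state, command):
        cmd, conflict = F.decode_command(eeg_state, nirs_state)
        assert cmd == command and conflict is False

    @pytest.mark.parametrize(
        "eeg_state,nirs_state",
        [("left_hand", "counting"), ("right_hand", "arithmetic")],
    )
    def test_bimodal_conflict_maps_to_stop(self, eeg_state, nirs_state):
        cmd, conflict = F.decode_command(eeg_state, nirs_state)
        assert cmd == "Stop" and conflict is True

    def test_hand_mapping_configurable(self):
        swapped = F.FusionConfig(left_hand_command="Right", right_hand_command="Left")
        assert F.decode_command("left_hand", "rest", swapped)[0] == "Right"

    def test_invalid_state_rejected(self):
        with pytest.raises(InvalidArgumentError):
            F.decode_command("jumping", "rest")


class TestEndToEnd:
    def _noise_free(self):
        cfg = SimulationConfig(seed=0).noise_free()
        rec = simulate_session(cfg, n_samples=5)
        return rec, F.train_models(rec)

    def test_noise_free_session_decodes_every_block(self, noise_free_session):
        models = F.train_models(noise_free_session)
        stream, summary = F.decode_session(noise_free_session, models)
        assert summary["block_accuracy"] == 100.0
        assert summary["n_conflicts"] == 0
        # Stop completeness: every frame inside a rest block decodes to Stop
        sched = noise_free_session.schedule
        for frame in stream.frames:
            if sched.label_at(frame.time - 1e-9) == P.REST:
                assert frame.command == "Stop"

    def test_exactly_one_command_per_frame(self, noisy_session, trained_models):
        stream, _ = F.decode_session(noisy_session, trained_models)
        assert len(stream.frames) == 543
        assert all(f.command in F.COMMANDS for f in stream.frames)
        times = [f.time for f in stream.frames]
        assert np.allclose(np.diff(times), 1.0 / stream.rate)

    def test_stop_iff_both_rest_unless_conflict(self, noisy_session, trained_models):
        stream, _ = F.decode_session(noisy_session, trained_models)
        for f in stream.frames:
            both_rest = f.eeg_state == "rest" and f.nirs_state == "rest"
            if f.command == "Stop":
                assert both_rest or f.conflict
            else:
                assert not both_rest

    def test_rest_only_session_all_stop(self, trained_models):
        sched = P.EventSchedule(
            tuple(P.TaskBlock(P.REST, 5.0 * i, 5.0) for i in range(12))
        )
        cfg = SimulationConfig(seed=0).noise_free()
        rec = simulate_session(cfg, schedule=sched)
        stream, _ = F.decode_session(rec, trained_models)
        assert all(f.command == "Stop" for f in stream.frames)

    def test_cross_session_block_accuracy(self, trained_models):
        rec = simulate_session(SimulationConfig(seed=321), n_samples=5)
        _, summary = F.decode_session(rec, trained_models)
        assert summary["block_accuracy"] >= 80.0

    def test_missing_models_rejected(self, noisy_session):
        with pytest.raises(StateError):
            F.decode_session(noisy_session, None)


class TestActivityGate:
    def test_infinite_threshold_silences_everything(self, noisy_session):
        models = F.train_models(noisy_session)
        cfg = F.FusionConfig(k=1e9)
        stream, _ = F.decode_session(noisy_session, models, cfg)
        assert all(f.command == "Stop" for f in stream.frames)
        assert all(f.eeg_state == "rest" and f.nirs_state == "rest" for f in stream.frames)

    def test_frame_in_tap_block_classified_left(self, noise_free_session):
        models = F.train_models(noise_free_session)
        stream, _ = F.decode_session(noise_free_session, models)
        block = noise_free_session.schedule.blocks_with_label(P.TAP_LEFT)[0]
        mid = [f for f in stream.frames if block.onset + 2 < f.time <= block.end - 1]
        states = [f.eeg_state for f in mid]
        # the hold window intentionally undershoots one tap period, so a
        # minority of in-block frames lapse to rest; none may flip hands
        assert states.count("left_hand") > len(mid) / 2
        assert "right_hand" not in states

    def test_missing_baseline_rejected(self, trained_models):
        frame = F.FeatureFrame(1.0, {}, 0.0, (0.0, 0.0))
        with pytest.raises(StateError):
            F.activity_state(frame, None, trained_models)


class TestCausality:
    def test_truncation_leaves_earlier_frames_unchanged(self, noisy_session, trained_models):
        """No decision frame depends on data after its own timestamp."""
        rec = noisy_session
        cfg = F.FusionConfig()
        band = E.bandpass_beta(rec.eeg, rec.eeg_rate)
        from nirseeg.fusion import _smoothed_hemoglobin

        t_cut = 150.0
        _, hbo_full = _smoothed_hemoglobin(rec, trained_models.optics, cfg)
        full = F.synchronize(
            band, rec.eeg_rate, hbo_full, rec.nirs_rate, trained_models.baselines, cfg
        )
        n_e = int(t_cut * rec.eeg_rate) + 1
        n_n = int(t_cut * rec.nirs_rate) + 1
        rec_cut = dataclasses.replace(
            rec, eeg=rec.eeg[:n_e], nirs_intensity=rec.nirs_intensity[:n_n]
        )
        band_cut = E.bandpass_beta(rec_cut.eeg, rec.eeg_rate)
        _, hbo_cut = _smoothed_hemoglobin(rec_cut, trained_models.optics, cfg)
        cut = F.synchronize(
            band_cut, rec.eeg_rate, hbo_cut, rec.nirs_rate, trained_models.baselines, cfg
        )
        kept = [f for f in full if f.time <= t_cut]
        assert len(cut) >= len(kept)
        for a, b in zip(kept, cut):
            assert a.time == b.time
            assert a.nirs_slope == pytest.approx(b.nirs_slope)
            assert a.nirs_group_means == pytest.approx(b.nirs_group_means)
            for ch in ("C3", "C4"):
                assert np.allclose(a.eeg_peak_amps[ch], b.eeg_peak_amps[ch])


class TestModelPersistence:
    def test_save_load_round_trip(self, trained_models, tmp_path):
        trained_models.save(tmp_path / "models")
        back = F.TrainedModels.load(tmp_path / "models")
        assert np.allclose(back.eeg_lda.w, trained_models.eeg_lda.w)
        assert back.baselines.nirs_slope_sd == pytest.approx(
            trained_models.baselines.nirs_slope_sd
        )

    def test_missing_artifact_is_state_error(self, tmp_path):
        with pytest.raises(StateError):
            F.TrainedModels.load(tmp_path / "nope")
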