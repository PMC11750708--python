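import numpy as np
import pytest

from fingerbci import (
    Decoder,
    DecoderConfig,
    TrainingSet,
    make_population,
    refit_relabel,
)
from fingerbci.decoder import windows_from_sbp
from fingerbci.session import make_open_loop_training_set
from fingerbci.tasks import TargetSet, TrialRecord


def small_config(dof=2, dropout=0.5):
    return DecoderConfig(
        n_channels=16, dof=dof, hidden_widths=(32, 32, 32, dof), dropout_rate=dropout
    )


class TestInitialization:
    def test_same_seed_gives_identical_parameters(self):
        a = Decoder(small_config(), seed=3)
        b = Decoder(small_config(), seed=3)
        for pa, pb in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(pa, pb)

    def test_kaiming_scale_of_wide_layer(self):
        cfg = DecoderConfig(n_channels=64, dof=2, hidden_widths=(256, 256, 256, 2))
        dec = Decoder(cfg, seed=0)
        w = dec.hidden[0][0].w  # fan-in 64*16 = 1024, width 256
        expected = np.sqrt(2.0 / 1024)
        assert w.std() == pytest.approx(expected, rel=0.10)

    def test_last_width_must_equal_dof(self):
        with pytest.raises(ValueError):
            DecoderConfig(n_channels=8, dof=2, hidden_widths=(32, 32, 32, 3))

    def test_time_bins_fixed_at_three(self):
        with pytest.raises(ValueError):
            DecoderConfig(n_channels=8, dof=2, n_time_bins=4)


class TestForward:
    def test_zero_final_weights_give_exact_zero_output(self):
        dec = Decoder(small_config(), seed=1)
        dec.final.w[...] = 0.0
        win = np.random.default_rng(0).random((16, 3))
        out = dec.forward(win, "inference")
        np.testing.assert_array_equal(out, np.zeros(2))

    def test_inference_is_deterministic(self):
        dec = Decoder(small_config(), seed=2)
        win = np.random.default_rng(1).random((16, 3))
        np.testing.assert_array_equal(
            dec.forward(win, "inference"), dec.forward(win, "inference")
        )

    def test_shape_mismatch_raises(self):
        dec = Decoder(small_config(), seed=2)
        with pytest.raises(ValueError):
            dec.forward(np.zeros((16, 4)), "inference")

    def test_trained_output_is_mean_free_on_its_ensemble(self, noiseless_2d):
        """No-affine output + variance-only batchnorm: near-zero output mean
        on the (sign-symmetric) ensemble the decoder was trained on."""
        _, dec, train = noiseless_2d
        raw = dec.forward(train.windows, "inference")
        ratio = np.abs(raw.mean(axis=0)) / raw.std(axis=0)
        assert np.all(ratio < 0.05)


class TestNormalizationAndGain:
    def test_unset_statistics_raise_state_error(self):
        dec = Decoder(small_config(), seed=1)
        with pytest.raises(RuntimeError):
            dec.apply_normalization_and_gain(np.zeros(2))

    def test_centering_gain_and_speed_formula(self, noiseless_2d):
        _, dec, _ = noiseless_2d
        np.testing.assert_allclose(
            dec.apply_normalization_and_gain(dec.output_mean), np.zeros(2), atol=1e-12
        )
        saved = dec.gains.copy()
        try:
            dec.gains = np.zeros(2)
            np.testing.assert_array_equal(
                dec.apply_normalization_and_gain(np.array([3.0, -2.0])), np.zeros(2)
            )
            dec.gains = np.array([1.5, 2.0])
            one_sd = dec.output_mean + dec.output_sd
            v = dec.apply_normalization_and_gain(one_sd)
            np.testing.assert_allclose(
                v, dec.gains * dec.config.speed_scale, rtol=1e-12
            )
        finally:
            dec.gains = saved


class TestTraining:
    def test_zero_targets_shrink_outputs(self):
        model = make_population(16, 2, 1.0, 0.5, 0, seed=1)
        ts = make_open_loop_training_set(model, 10, 2, seed=2)
        zero_ts = TrainingSet(ts.windows, np.zeros_like(ts.targets))
        dec = Decoder(small_config(), seed=3)
        before = np.mean(np.abs(dec.forward(ts.windows, "inference")))
        dec.train_supervised(zero_ts, epochs=20, seed=4)
        after = np.mean(np.abs(dec.forward(ts.windows, "inference")))
        assert after <= 0.5 * before

    def test_one_epoch_decreases_fixed_batch_loss_on_average(self):
        model = make_population(16, 2, 1.0, 0.5, 0, seed=5)
        ts = make_open_loop_training_set(model, 8, 2, seed=6)
        t_std = (ts.targets - ts.targets.mean(0)) / ts.targets.std(0)
        xb, tb = ts.windows[:64], t_std[:64]
        ratios = []
        for seed in range(5):
            dec = Decoder(small_config(dropout=0.0), seed=seed)
            before = np.mean((dec.forward(xb, "train", np.random.default_rng(0)) - tb) ** 2)
            dec.train_supervised(ts, epochs=1, seed=seed)
            after = np.mean((dec.forward(xb, "train", np.random.default_rng(0)) - tb) ** 2)
            ratios.append(after / before)
        assert np.mean(ratios) < 1.0

    def test_training_is_deterministic(self):
        model = make_population(16, 2, 1.0, 0.5, 0, seed=7)
        ts = make_open_loop_training_set(model, 6, 1, seed=8)
        decs = []
        for _ in range(2):
            d = Decoder(small_config(), seed=9)
            d.train_supervised(ts, epochs=3, seed=10)
            decs.append(d)
        for pa, pb in zip(decs[0].parameters(), decs[1].parameters()):
            np.testing.assert_array_equal(pa, pb)

    def test_empty_training_set_raises(self):
        dec = Decoder(small_config(), seed=1)
        empty = TrainingSet(np.zeros((0, 16, 3)), np.zeros((0, 2)))
        with pytest.raises(ValueError):
            dec.train_supervised(empty)

    def test_noiseless_linear_recovery_beats_095(self, noiseless_2d):
        model, dec, _ = noiseless_2d
        held = make_open_loop_training_set(model, 15, 3, seed=99)
        pred = dec.decode(held.windows)
        for d in range(2):
            r = np.corrcoef(np.asarray(pred)[:, d], held.targets[:, d])[0, 1]
            assert r >= 0.95


def _session_records(model, dec_callable, n=12, seed=0):
    from fingerbci import TaskConfig, run_closed_loop_session

    return run_closed_loop_session(TaskConfig("cl2d"), dec_callable, model, n, seed=seed)


class TestRefitRelabel:
    def test_sign_inverted_when_pointing_away(self):
        ts = TargetSet(np.array([0.8]), width=0.2)
        rec = TrialRecord(
            task_kind="cl2d",
            target_set=ts,
            positions=np.array([[0.4], [0.385], [0.4]]),
            decoded_velocities=np.array([[-0.3], [0.3]]),
            sbp=np.ones((2, 4)),
            dof_labels=("thumb_flex",),
        )
        out = refit_relabel([rec])
        # away-from-target velocity flips; toward-target stays
        np.testing.assert_allclose(out.targets, [[0.3], [0.3]])

    def test_zero_velocity_is_fixed_point_and_inside_is_zeroed(self):
        ts = TargetSet(np.array([0.5]), width=0.2)
        rec = TrialRecord(
            task_kind="cl2d",
            target_set=ts,
            positions=np.array([[0.55], [0.55], [0.9]]),
            decoded_velocities=np.array([[0.0], [0.4]]),
            sbp=np.ones((2, 4)),
            dof_labels=("thumb_flex",),
        )
        out = refit_relabel([rec])
        np.testing.assert_array_equal(out.targets[0], [0.0])   # zero stays zero
        np.testing.assert_array_equal(out.targets[1], [0.0])   # inside target

    def test_magnitudes_preserved_on_random_logs(self, noisy_2d_population):
        from fingerbci import oracle_decoder

        recs = _session_records(noisy_2d_population, oracle_decoder(0.7), seed=3)
        out = refit_relabel(recs, zero_inside=False)
        decoded = np.concatenate([r.decoded_velocities for r in recs])
        np.testing.assert_allclose(np.abs(out.targets), np.abs(decoded))

    def test_vector_mode_keeps_group_magnitude(self):
        ts = TargetSet(np.array([0.8, 0.2]), width=0.2)
        rec = TrialRecord(
            task_kind="cl2d",
            target_set=ts,
            positions=np.array([[0.5, 0.5], [0.5, 0.5]]),
            decoded_velocities=np.array([[0.3, 0.4]]),
            sbp=np.ones((1, 4)),
            dof_labels=("thumb_flex", "thumb_abd"),
        )
        out = refit_relabel([rec], mode="vector", vector_groups=[(0, 1)])
        assert np.linalg.norm(out.targets[0]) == pytest.approx(0.5)
        err = np.array([0.3, -0.3])
        np.testing.assert_allclose(
            out.targets[0], 0.5 * err / np.linalg.norm(err), rtol=1e-12
        )

    def test_missing_decoded_velocities_raise(self):
        ts = TargetSet(np.array([0.8]), width=0.2)
        rec = TrialRecord(
            task_kind="cl2d",
            target_set=ts,
            positions=np.array([[0.4]]),
            decoded_velocities=np.zeros((0, 1)),
            sbp=None,
            dof_labels=("thumb_flex",),
        )
        with pytest.raises(ValueError):
            refit_relabel([rec])


class TestRefitUpdate:
    def test_requires_trained_decoder(self):
        dec = Decoder(small_config(), seed=1)
        ts = TrainingSet(np.zeros((4, 16, 3)), np.zeros((4, 2)))
        with pytest.raises(RuntimeError):
            dec.refit_update(ts)

    def test_deterministic_for_fixed_seed(self):
        model = make_population(16, 2, 1.0, 0.5, 0, seed=1)
        ts = make_open_loop_training_set(model, 8, 2, seed=2)
        results = []
        for _ in range(2):
            dec = Decoder(small_config(), seed=3)
            dec.train_supervised(ts, epochs=5, seed=4)
            dec.refit_update(ts, seed=5, n_iterations=50)
            results.append(dec.forward(ts.windows[:8], "inference"))
        np.testing.assert_array_equal(results[0], results[1])

    def test_update_on_consistent_set_barely_changes_outputs(self):
        """Refit on labels the decoder already produces is near-stationary
        at the level of the decoded function."""
        model = make_population(16, 2, 1.0, 0.0, 0, seed=6)
        ts = make_open_loop_training_set(model, 20, 4, seed=7)
        dec = Decoder(small_config(dropout=0.0), seed=8)
        dec.train_supervised(ts, epochs=100, seed=9)
        pred0 = np.asarray(dec.decode(ts.windows))
        dec.refit_update(TrainingSet(ts.windows, pred0), seed=10)
        pred1 = np.asarray(dec.decode(ts.windows))
        rel_change = np.sqrt(np.mean((pred1 - pred0) ** 2)) / np.sqrt(
            np.mean(pred0**2)
        )
        assert rel_change < 0.10
        for d in range(2):
            assert np.corrcoef(pred0[:, d], pred1[:, d])[0, 1] > 0.99


class TestWindowing:
    def test_windows_edge_padded_and_most_recent_last(self):
        sbp = np.arange(12, dtype=float).reshape(4, 3)  # 4 bins, 3 channels
        w = windows_from_sbp(sbp)
        np.testing.assert_array_equal(w[0, :, 0], sbp[0])
        np.testing.assert_array_equal(w[0, :, 2], sbp[0])
        np.testing.assert_array_equal(w[3, :, 0], sbp[1])
        np.testing.assert_array_equal(w[3, :, 2], sbp[3])


class TestSerialization:
    def test_roundtrip_preserves_decode(self, noiseless_2d, tmp_path):
        model, dec, train = noiseless_2d
        path = tmp_path / "dec.npz"
        dec.save(path)
        dec2 = Decoder.load(path)
        w = train.windows[:16]
        np.testing.assert_array_equal(dec.decode(w), dec2.decode(w))
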