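import math

import numpy as np
import pytest

from dihedralkd.kd_model import (
    BindingDistillationModel,
    BindingDistillationResults,
    DistillConfig,
    StudentConfig,
    TeacherConfig,
    bce,
    build_student,
    build_teacher,
    distillation_loss,
    total_student_loss,
)


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


@pytest.fixture(scope="module")
def tiny_training_data():
    """Linearly separable synthetic features: sign of the mean angle."""
    rng = np.random.default_rng(0)
    n = 200
    x = rng.uniform(-1, 1, size=(n, 17, 4, 1)).astype(np.float32)
    y = (x.mean(axis=(1, 2, 3)) > 0).astype(int)
    return x, y


class TestArchitecture:
    def test_forward_outputs_in_open_unit_interval(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(-1, 1, size=(8, 17, 4, 1)).astype(np.float32)
        for build in (build_teacher, build_student):
            p = _sigmoid(build(rng=0).forward(x))
            assert np.all(p > 0) and np.all(p < 1)

    def test_student_smaller_than_teacher_same_depth(self):
        teacher = build_teacher(rng=0)
        student = build_student(rng=0)
        assert student.n_params() < teacher.n_params()
        assert len(student.layers) == len(teacher.layers)

    def test_seeded_builds_identical(self):
        a = build_teacher(rng=5)
        b = build_teacher(rng=5)
        assert all(np.array_equal(x, y) for x, y in zip(a.params, b.params))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            TeacherConfig(leaky_slope=1.5)
        with pytest.raises(ValueError):
            StudentConfig(conv_filters=(0, 1, 2))
        with pytest.raises(ValueError):
            DistillConfig(alpha=1.5)
        with pytest.raises(ValueError):
            DistillConfig(temperature=0.0)

    def test_input_too_small_rejected(self):
        with pytest.raises(ValueError, match="input too small"):
            build_teacher(input_shape=(2, 4, 1), rng=0)


class TestLosses:
    def test_kl_zero_iff_equal(self):
        assert distillation_loss(0.37, 0.37, temperature=2.0) == pytest.approx(0.0, abs=1e-12)
        for q in (0.1, 0.5, 0.9):
            assert distillation_loss(0.37, q if q != 0.37 else 0.4, 1.0) > 0

    def test_hand_computed_bernoulli_kl(self):
        expected = 0.8 * math.log(0.8 / 0.6) + 0.2 * math.log(0.2 / 0.4)
        assert expected == pytest.approx(0.0915, abs=5e-5)  # the closed form itself
        assert distillation_loss(0.8, 0.6, temperature=1.0) == pytest.approx(expected, abs=1e-6)

    def test_alpha_one_reduces_to_bce(self):
        cfg = DistillConfig(alpha=1.0, temperature=3.0)
        for y, s, t in [(1, 0.6, 0.9), (0, 0.2, 0.7)]:
            assert total_student_loss(y, s, t, cfg) == bce(y, s)

    def test_alpha_zero_teacher_equals_student_is_zero(self):
        cfg = DistillConfig(alpha=0.0, temperature=2.0)
        assert total_student_loss(1, 0.42, 0.42, cfg) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_total_loss(self):
        cfg = DistillConfig(alpha=0.5, temperature=1.0)
        kl = 0.8 * math.log(0.8 / 0.6) + 0.2 * math.log(0.2 / 0.4)
        expected = 0.5 * (-math.log(0.6)) + 0.5 * kl
        assert total_student_loss(1, 0.6, 0.8, cfg) == pytest.approx(expected, abs=1e-6)
        assert expected == pytest.approx(0.3012, abs=5e-5)

    def test_temperature_softening_moves_towards_half(self):
        # softened distributions are flatter, so the KL shrinks with T
        assert distillation_loss(0.9, 0.2, 4.0) < distillation_loss(0.9, 0.2, 1.0)


class TestTraining:
    def test_degenerate_training_set_rejected(self):
        x = np.zeros((10, 17, 4, 1), dtype=np.float32)
        with pytest.raises(ValueError, match="degenerate training set"):
            BindingDistillationModel(x, np.ones(10)).fit()

    def test_student_loss_decreases_on_separable_data(self, tiny_training_data):
        x, y = tiny_training_data
        cfg = DistillConfig(epochs=12, batch_size=32, seed=0)
        results = BindingDistillationModel(x, y, distill_config=cfg).fit()
        h = results.history
        assert h["student_loss"][-1] < h["student_loss"][0]
        assert h["teacher_loss"][-1] < h["teacher_loss"][0]
        # smoothed trend is non-increasing
        smoothed = np.convolve(h["student_loss"], np.ones(3) / 3, mode="valid")
        assert smoothed[-1] <= smoothed[0]
        assert all(np.isfinite(v) for vals in h.values() for v in vals)

    def test_identical_seed_identical_history(self, tiny_training_data):
        x, y = tiny_training_data
        cfg = DistillConfig(epochs=3, batch_size=64, seed=9)
        h1 = BindingDistillationModel(x, y, distill_config=cfg).fit().history
        h2 = BindingDistillationModel(x, y, distill_config=cfg).fit().history
        assert h1 == h2

    def test_alpha_one_first_epoch_equals_pure_bce_training(self, tiny_training_data):
        x, y = tiny_training_data
        cfg = DistillConfig(alpha=1.0, epochs=2, batch_size=64, seed=4)
        h = BindingDistillationModel(x, y, distill_config=cfg).fit().history
        # with alpha=1 the soft term has zero weight: total == hard BCE
        assert h["student_loss"] == pytest.approx(h["student_bce"], abs=1e-12)


@pytest.fixture(scope="module")
def fitted(tiny_training_data):
    x, y = tiny_training_data
    cfg = DistillConfig(epochs=6, batch_size=64, seed=2)
    return BindingDistillationModel(x, y, distill_config=cfg).fit(), x


class TestPrediction:

    def test_duplicates_and_order(self, fitted):
        results, x = fitted
        batch = np.concatenate([x[:5], x[:5]])
        p = results.predict(batch)
        assert np.array_equal(p[:5], p[5:])
        perm = np.array([3, 1, 4, 0, 2])
        assert np.array_equal(results.predict(x[:5][perm]), p[:5][perm])

    def test_shape_mismatch_rejected(self, fitted):
        results, _ = fitted
        with pytest.raises(ValueError, match="input shape mismatch"):
            results.predict(np.zeros((2, 15, 4, 1), dtype=np.float32))

    def test_checkpoint_round_trip(self, fitted, tmp_path):
        results, x = fitted
        results.save(tmp_path / "ckpt")
        loaded = BindingDistillationResults.from_checkpoint(tmp_path / "ckpt")
        for use in ("teacher", "student"):
            assert np.allclose(
                loaded.predict(x[:20], use=use), results.predict(x[:20], use=use),
                atol=0,
            )
        assert loaded.state.distill_config == results.state.distill_config
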