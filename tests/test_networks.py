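"""Contracts of the architecture family: shapes, fusion, training, determinism."""

import numpy as np
import pytest

from ecogfm.errors import ConfigurationError, ValidationError
from ecogfm.networks import (
    VARIANTS,
    ModelSpec,
    SubblockDataset,
    build_model,
    fuse_domains,
    load_model,
    predict_subblocks,
    save_model,
    small_spec,
    train_model,
    weights_hash,
)
from ecogfm.nn.train import TrainConfig

T, A, S = 10, 6, 3


def spec_for(variant, n_features=None):
    nf = n_features or (3 if variant in ("AT_AR3_EF", "AT_AR3_LF1", "AT_AR3_LF2") else 1)
    ar = None if variant in ("AT1", "AT2") else A
    return small_spec(variant, n_windows=T, n_features=nf, ar_dim=ar, n_stories=S)


def toy_batch(rng, spec, n):
    if spec.variant == "PER_STORY":
        xt = rng.standard_normal((n, S, T, spec.n_features))
        xf = rng.standard_normal((n, S, A))
    else:
        xt = rng.standard_normal((n, T, spec.n_features))
        xf = None if spec.ar_dim is None else rng.standard_normal((n, A))
    return xt, xf


def separable_dataset(spec, n=20, seed=0):
    """Two Gaussian classes split along every input dimension's mean."""
    rng = np.random.default_rng(seed)
    xt, xf = toy_batch(rng, spec, n)
    y = np.arange(n) % 2
    shift = np.where(y == 1, 2.0, -2.0)
    xt = xt + shift.reshape((-1,) + (1,) * (xt.ndim - 1))
    if xf is not None:
        xf = xf + shift.reshape((-1,) + (1,) * (xf.ndim - 1))
    cids = np.array([f"c{i}" for i in range(n)])  # one channel per instance
    return SubblockDataset(x_time=xt, y=y.astype(float), channel_ids=cids, x_freq=xf)


class TestBuild:
    @pytest.mark.parametrize("variant", VARIANTS)
    def test_scalar_probability_output(self, variant):
        spec = spec_for(variant)
        model = build_model(spec, seed=1)
        xt, xf = toy_batch(np.random.default_rng(0), spec, 4)
        out = model.forward(xt, xf)
        assert out.data.shape == (4, 1)

    def test_time_only_variant_builds_without_frequency_path(self):
        build_model(small_spec("AT1", n_windows=T))

    def test_fusion_variant_requires_frequency_path(self):
        with pytest.raises(ConfigurationError, match="frequency"):
            small_spec("AT_AR3", n_windows=T, ar_dim=None)

    def test_time_only_variant_rejects_frequency_path(self):
        with pytest.raises(ConfigurationError):
            small_spec("AT2", n_windows=T, ar_dim=5)

    def test_per_story_has_per_story_modules(self):
        model = build_model(spec_for("PER_STORY"))
        for st in range(S):
            assert f"story{st}.time.conv0.w" in model.params
            assert f"story{st}.freq.fc0.w" in model.params
        assert "merge.w" in model.params

    def test_shape_mismatch_rejected(self):
        spec = spec_for("AT_AR3")
        model = build_model(spec)
        xt, xf = toy_batch(np.random.default_rng(0), spec, 2)
        with pytest.raises(ValidationError, match="shape"):
            model.forward(xt[:, :-1], xf)
        with pytest.raises(ValidationError, match="frequency"):
            model.forward(xt, None)


class TestFusion:
    def test_concatenation_widths(self):
        t = np.zeros((4, 64))
        f = np.zeros((4, 20))
        assert fuse_domains(t, f).shape == (4, 84)

    def test_sequence_fusion_tiles_frequency(self):
        t = np.ones((2, 7, 3))
        f = np.arange(4.0).reshape(1, 4).repeat(2, axis=0)
        fused = fuse_domains(t, f)
        assert fused.shape == (2, 7, 7)
        np.testing.assert_array_equal(fused[0, 3, 3:], np.arange(4.0))

    def test_zero_frequency_vector_passes_through(self):
        t = np.arange(6.0).reshape(2, 3)
        fused = fuse_domains(t, np.zeros((2, 2)))
        np.testing.assert_array_equal(fused[:, :3], t)
        np.testing.assert_array_equal(fused[:, 3:], 0.0)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValidationError):
            fuse_domains(np.array([[np.nan]]), np.zeros((1, 1)))


class TestTraining:
    @pytest.mark.parametrize("variant", VARIANTS)
    def test_overfits_separable_toy_set(self, variant):
        spec = spec_for(variant)
        ds = separable_dataset(spec, n=20, seed=3)
        cfg = TrainConfig(epochs=60, batch_size=10, learning_rate=3e-3,
                          dropout=0.0, val_fraction=0.0, seed=0)
        trained = train_model(build_model(spec, seed=0), ds, cfg)
        probs, labels = predict_subblocks(trained, ds.x_time, ds.x_freq)
        assert np.all((probs >= 0) & (probs <= 1))
        acc = np.mean((probs > 0.5) == ds.y.astype(bool))
        assert acc == 1.0, f"{variant} failed to overfit (acc={acc})"

    def test_single_class_rejected(self):
        spec = spec_for("AT1")
        ds = separable_dataset(spec, n=8)
        ds.y[:] = 1.0
        with pytest.raises(ValidationError, match="both classes"):
            train_model(build_model(spec), ds, TrainConfig(epochs=1))

    def test_same_seed_identical_weights_hash(self):
        spec = spec_for("AT_AR3")
        ds = separable_dataset(spec, n=16, seed=5)
        cfg = TrainConfig(epochs=5, batch_size=8, seed=11)
        h1 = weights_hash(train_model(build_model(spec, seed=11), ds, cfg))
        h2 = weights_hash(train_model(build_model(spec, seed=11), ds, cfg))
        h3 = weights_hash(train_model(build_model(spec, seed=12), ds, cfg))
        assert h1 == h2
        assert h1 != h3

    def test_permuted_labels_stay_near_chance(self):
        spec = spec_for("AT_AR3")
        rng = np.random.default_rng(7)
        xt, xf = toy_batch(rng, spec, 60)  # pure noise, balanced labels
        ds = SubblockDataset(
            x_time=xt, y=(np.arange(60) % 2).astype(float),
            channel_ids=np.array([f"c{i}" for i in range(60)]), x_freq=xf,
        )
        cfg = TrainConfig(epochs=10, batch_size=16, dropout=0.0, val_fraction=0.0, seed=1)
        trained = train_model(build_model(spec, seed=1), ds, cfg)
        fresh_xt, fresh_xf = toy_batch(np.random.default_rng(99), spec, 200)
        probs, _ = predict_subblocks(trained, fresh_xt, fresh_xf)
        acc = np.mean((probs > 0.5) == (np.arange(200) % 2).astype(bool))
        assert 0.3 < acc < 0.7  # binomial 95% band around chance, n=200, widened

    def test_history_recorded(self):
        spec = spec_for("AT1")
        ds = separable_dataset(spec, n=12, seed=2)
        trained = train_model(build_model(spec), ds,
                              TrainConfig(epochs=4, val_fraction=0.0))
        assert len(trained.history["train_loss"]) == 4


class TestInference:
    def test_tie_probability_is_negative_call(self):
        # exactly 0.5 must not be called positive: strict-majority convention
        from ecogfm.nn.train import sigmoid as s
        assert s(np.array([0.0]))[0] == 0.5
        spec = spec_for("AT1")
        trained = train_model(
            build_model(spec, seed=0), separable_dataset(spec, n=8, seed=0),
            TrainConfig(epochs=1, val_fraction=0.0),
        )
        probs, labels = predict_subblocks(trained, np.zeros((1, T, 1)))
        # zero logits are not guaranteed here; assert the rule directly instead
        assert (labels == "PRC").all() == bool((probs > 0.5).all())

    def test_duplicated_instance_identical_probabilities(self):
        spec = spec_for("AT_AR3")
        ds = separable_dataset(spec, n=10, seed=4)
        trained = train_model(build_model(spec), ds, TrainConfig(epochs=2, val_fraction=0.0))
        xt = np.repeat(ds.x_time[:1], 2, axis=0)
        xf = np.repeat(ds.x_freq[:1], 2, axis=0)
        probs, _ = predict_subblocks(trained, xt, xf)
        assert probs[0] == probs[1]


class TestPersistence:
    def test_save_load_roundtrip(self, tmp_path):
        spec = spec_for("AT_AR3_LF2")
        ds = separable_dataset(spec, n=12, seed=6)
        trained = train_model(build_model(spec, seed=3), ds,
                              TrainConfig(epochs=3, val_fraction=0.0, seed=3))
        p = tmp_path / "m.npz"
        save_model(trained, p, extra={"note": "toy"})
        loaded, extra = load_model(p)
        assert extra == {"note": "toy"}
        probs1, _ = predict_subblocks(trained, ds.x_time, ds.x_freq)
        probs2, _ = predict_subblocks(loaded, ds.x_time, ds.x_freq)
        np.testing.assert_array_equal(probs1, probs2)
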