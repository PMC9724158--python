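"""Training loops: augmentation statistics, smoke runs, determinism,
edge-net freezing, and pairing isolation."""

import warnings

import numpy as np
import pytest

from eggan.losses import LossWeights
from eggan.nets import DiscriminatorConfig, EdgeNetConfig, EdgeUNet, GeneratorConfig
from eggan.phantoms import PhantomSpec, make_dataset
from eggan.train import (
    AugmentConfig,
    TrainConfig,
    augment_batch,
    canny_edges,
    edge_dice,
    train_edge_detector,
    train_eggan,
    train_paired,
    unpaired_defaults,
)

TINY_GEN = dict(input_size=32, levels=2, base_channels=4,
                res_blocks_per_level=1, dilation_rates=(2, 4))


@pytest.fixture(scope="module")
def tiny_spec():
    return PhantomSpec(image_size=32, n_tissues=4,
                       geometry_ranges={"skull_axes": (0.28, 0.38),
                                        "center_jitter": 0.01,
                                        "inner_axes": (0.08, 0.15)},
                       seed=3)


class TestAugment:
    def test_disabled_returns_copies(self, rng):
        batch = [(rng.normal(size=(8, 8)), rng.normal(size=(8, 8)))]
        out = augment_batch(batch, AugmentConfig(enabled=False),
                            np.random.default_rng(0))
        np.testing.assert_array_equal(out[0][0], batch[0][0])
        assert out[0][0] is not batch[0][0]

    def test_flip_is_involution(self, rng):
        img = rng.normal(size=(8, 8))
        flipped_twice = img[:, ::-1][:, ::-1]
        np.testing.assert_array_equal(flipped_twice, img)

    def test_paired_images_share_draws(self, rng):
        img = rng.normal(size=(16, 16))
        cfg = AugmentConfig(crop_fraction=0.8)
        out = augment_batch([(img, img.copy())], cfg, np.random.default_rng(1))
        np.testing.assert_array_equal(out[0][0], out[0][1])

    def test_shapes_preserved(self, rng):
        cfg = AugmentConfig(crop_fraction=0.7)
        out = augment_batch([(rng.normal(size=(16, 16)), None)], cfg,
                            np.random.default_rng(2))
        assert out[0][0].shape == (16, 16)

    def test_flip_frequency_near_half(self):
        # flips only (no crop/rotation): detect horizontal flips on an
        # asymmetric probe over many draws; binomial check of p = 0.5
        cfg = AugmentConfig(flip_prob=0.5, crop_fraction=1.0,
                            rotation_degrees=(0.0, 0.0))
        probe = np.arange(16.0).reshape(4, 4)
        rng = np.random.default_rng(7)
        n = 10_000
        batch = [(probe, None)] * n
        out = augment_batch(batch, cfg, rng)
        freq = np.mean([not np.array_equal(img, probe) for img, _ in out])
        # P(any flip) = 1 - (1-p)^2 = 0.75 at p = 0.5
        assert 0.73 <= freq <= 0.77

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            AugmentConfig(flip_prob=1.5)


class TestEdgeDetectorTraining:
    def test_smoke_and_freeze(self, tiny_spec):
        imgs = make_dataset(tiny_spec, 4).sources
        cfg = TrainConfig(epochs=1, batch_size=2, learning_rate=1e-3, seed=0,
                          augment=AugmentConfig(enabled=False))
        net, state = train_edge_detector(imgs, cfg, EdgeNetConfig(2, 4))
        assert np.isfinite(state.history[-1].e_t)
        assert len(net.parameters()) == 0  # frozen

    def test_canny_targets_are_binary(self, tiny_spec):
        img = make_dataset(tiny_spec, 1).sources[0]
        edges = canny_edges(img)
        assert set(np.unique(edges)) <= {0.0, 1.0}
        assert edges.sum() > 0

    def test_dice_of_perfect_prediction_is_one(self, tiny_spec):
        imgs = make_dataset(tiny_spec, 2).sources

        class Oracle:
            def edge_map_array(self, x):
                target = canny_edges(
                    type(imgs[0])((np.asarray(x) + 1) / 2 * 4095))
                return target

        assert edge_dice(Oracle(), imgs) == 1.0

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            train_edge_detector([], TrainConfig(epochs=1), EdgeNetConfig(2, 4))


class TestPairedTraining:
    def test_one_epoch_smoke(self, tiny_spec):
        ds = make_dataset(tiny_spec, 4, paired=True)
        cfg = TrainConfig(epochs=1, batch_size=2, seed=0,
                          augment=AugmentConfig(enabled=False))
        gen, state = train_paired(ds, GeneratorConfig(**TINY_GEN), cfg)
        assert all(np.isfinite(r.e_t) for r in state.history)
        assert state.epoch == 1

    def test_rejects_unpaired(self, tiny_spec):
        ds = make_dataset(tiny_spec, 4, paired=False)
        with pytest.raises(ValueError, match="paired"):
            train_paired(ds, GeneratorConfig(**TINY_GEN), TrainConfig(epochs=1))

    def test_checkpoint_schedule_writes_files(self, tiny_spec, tmp_path):
        ds = make_dataset(tiny_spec, 4, paired=True)
        cfg = TrainConfig(epochs=2, batch_size=2, seed=0, checkpoint_every=1,
                          augment=AugmentConfig(enabled=False))
        _, state = train_paired(ds, GeneratorConfig(**TINY_GEN), cfg,
                                checkpoint_dir=tmp_path)
        assert len(state.checkpoint_paths) == 2
        from eggan.nets import load_checkpoint
        kind, _, _ = load_checkpoint(state.checkpoint_paths[-1])
        assert kind == "generator"

    def test_deterministic_given_seed(self, tiny_spec):
        ds = make_dataset(tiny_spec, 4, paired=True)
        cfg = TrainConfig(epochs=2, batch_size=2, seed=5)
        _, s1 = train_paired(ds, GeneratorConfig(**TINY_GEN), cfg)
        _, s2 = train_paired(ds, GeneratorConfig(**TINY_GEN), cfg)
        h1 = [r.e_t for r in s1.history]
        h2 = [r.e_t for r in s2.history]
        np.testing.assert_allclose(h1, h2, rtol=1e-4)


class _NoPeek:
    """Duck-typed sample set that forbids reading the pairing permutation."""

    def __init__(self, samples):
        self._samples = samples
        self.paired = samples.paired

    @property
    def pairing_permutation(self):
        raise AssertionError("trainer read the withheld pairing permutation")

    def unpaired_view(self):
        return self._samples.unpaired_view()

    def __len__(self):
        return len(self._samples)


@pytest.fixture(scope="module")
def frozen_edge_net(tiny_spec):
    imgs = make_dataset(tiny_spec, 8).sources
    cfg = TrainConfig(epochs=2, batch_size=4, learning_rate=2e-3, seed=0,
                      augment=AugmentConfig(enabled=False))
    net, _ = train_edge_detector(imgs, cfg, EdgeNetConfig(2, 4))
    return net


class TestEgganTraining:
    def test_smoke_all_terms_finite(self, tiny_spec, frozen_edge_net):
        ds = make_dataset(tiny_spec, 8, paired=False)
        cfg = unpaired_defaults(epochs=1, seed=0,
                                augment=AugmentConfig(enabled=False))
        (g_ab, g_ba), (d_a, d_b), state = train_eggan(
            ds, GeneratorConfig(**TINY_GEN), DiscriminatorConfig(2, 4),
            frozen_edge_net, cfg)
        for r in state.history:
            for name in ("e_lsgan_1", "e_lsgan_2", "e_cyc", "e_iden",
                         "e_em", "e_cg", "e_t"):
                assert np.isfinite(getattr(r, name))

    def test_edge_net_unchanged_by_training(self, tiny_spec, frozen_edge_net):
        ds = make_dataset(tiny_spec, 4, paired=False)
        before = frozen_edge_net.checksum()
        cfg = unpaired_defaults(epochs=1, batch_size=4, seed=0,
                                augment=AugmentConfig(enabled=False))
        train_eggan(ds, GeneratorConfig(**TINY_GEN), DiscriminatorConfig(2, 4),
                    frozen_edge_net, cfg)
        assert frozen_edge_net.checksum() == before

    def test_never_reads_pairing_permutation(self, tiny_spec, frozen_edge_net):
        ds = make_dataset(tiny_spec, 4, paired=False)
        cfg = unpaired_defaults(epochs=1, batch_size=4, seed=0,
                                augment=AugmentConfig(enabled=False))
        train_eggan(_NoPeek(ds), GeneratorConfig(**TINY_GEN),
                    DiscriminatorConfig(2, 4), frozen_edge_net, cfg)

    def test_paired_input_warns(self, tiny_spec, frozen_edge_net):
        ds = make_dataset(tiny_spec, 4, paired=True)
        cfg = unpaired_defaults(epochs=1, batch_size=4, seed=0,
                                augment=AugmentConfig(enabled=False))
        with pytest.warns(UserWarning, match="unpaired"):
            train_eggan(ds, GeneratorConfig(**TINY_GEN),
                        DiscriminatorConfig(2, 4), frozen_edge_net, cfg)

    def test_unfrozen_edge_net_rejected(self, tiny_spec, rng):
        ds = make_dataset(tiny_spec, 4, paired=False)
        live_net = EdgeUNet(EdgeNetConfig(2, 4), np.random.default_rng(0))
        with pytest.raises(ValueError, match="frozen"):
            train_eggan(ds, GeneratorConfig(**TINY_GEN),
                        DiscriminatorConfig(2, 4), live_net,
                        unpaired_defaults(epochs=1))


def test_train_config_validation():
    with pytest.raises(ValueError):
        TrainConfig(epochs=0)
    with pytest.raises(ValueError):
        TrainConfig(learning_rate=0.0)
    with pytest.raises(ValueError):
        TrainConfig(optimizer="lion")
    cfg = unpaired_defaults()
    assert cfg.batch_size == 4 and cfg.learning_rate == 5e-4
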