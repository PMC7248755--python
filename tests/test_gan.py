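"""DCGAN construction, variants, training loop and generation."""

import numpy as np
import pytest

from emgaug import gan, nn
from emgaug.errors import (ConfigurationError, DataInsufficiencyError,
                           InvalidArgumentError)
from emgaug.preprocess import moving_average_array
from emgaug.signal import EmgSignal
from emgaug.synthdata import TremorParams, synth_tremor


@pytest.fixture(scope="module")
def short_record():
    return synth_tremor(TremorParams(duration=3.0, seed=8))


def small_specs(variant):
    return gan.variant_specs(variant, gen_filters=2, disc_filters=2,
                             disc_final_filters=2)


class TestGenerator:
    def test_latent_sample_maps_400_to_2000(self, rng):
        g = gan.build_generator(gan.GeneratorSpec(), seed=0)
        out = g.forward(rng.standard_normal(400))
        assert out.shape == (1, 2000)

    def test_output_bounded_by_tanh(self, rng):
        g = gan.build_generator(gan.GeneratorSpec(filters=2), seed=0)
        out = g.forward(rng.standard_normal((4, 400)))
        assert np.all(out >= -1.0) and np.all(out <= 1.0)

    def test_inference_deterministic(self, rng):
        g = gan.build_generator(gan.GeneratorSpec(filters=2), seed=0)
        z = rng.standard_normal(400)
        a = g.forward(z)
        b = g.forward(z)
        np.testing.assert_array_equal(a, b)

    def test_ma_head_equals_explicit_moving_average(self, rng):
        spec = gan.GeneratorSpec(filters=2, use_output_moving_average=True)
        g = gan.build_generator(spec, seed=3)
        z = rng.standard_normal((2, 400))
        full = g.forward(z)
        # the MA head is the last three (parameter-free) layers
        h = z
        for layer in g.net.layers[:-3]:
            h = layer.forward(h, train=False)
        expected = np.stack([moving_average_array(row, spec.ma_window)
                             for row in h])
        np.testing.assert_allclose(full, expected, atol=1e-6)

    def test_noise_mode_latent_100(self, rng):
        spec = gan.GeneratorSpec(latent_mode="noise", latent_len=100,
                                 filters=2, use_output_moving_average=False)
        g = gan.build_generator(spec, seed=0)
        assert g.forward(rng.standard_normal(100)).shape == (1, 2000)

    def test_inconsistent_shape_chain_rejected(self):
        with pytest.raises(ConfigurationError, match="shape chain"):
            gan.build_generator(gan.GeneratorSpec(upsample=4, filters=2))

    def test_wrong_latent_length_rejected(self, rng):
        g = gan.build_generator(gan.GeneratorSpec(filters=2), seed=0)
        with pytest.raises(InvalidArgumentError):
            g.forward(rng.standard_normal(399))


class TestDiscriminator:
    def test_scores_strictly_in_unit_interval(self, rng):
        d = gan.build_discriminator(
            gan.DiscriminatorSpec(filters=2, final_filters=2), seed=0)
        p = d.score(rng.uniform(-1, 1, (3, 2000)))
        assert np.all(p > 0) and np.all(p < 1)

    def test_inference_deterministic(self, rng):
        d = gan.build_discriminator(
            gan.DiscriminatorSpec(filters=2, final_filters=2), seed=0)
        x = rng.uniform(-1, 1, (3, 2000))
        np.testing.assert_array_equal(d.score(x), d.score(x))

    def test_wrong_input_length_rejected(self, rng):
        d = gan.build_discriminator(
            gan.DiscriminatorSpec(filters=2, final_filters=2), seed=0)
        with pytest.raises(InvalidArgumentError):
            d.score(rng.uniform(-1, 1, (2, 1999)))

    def test_needs_at_least_one_pipeline(self):
        with pytest.raises(ConfigurationError):
            gan.DiscriminatorSpec(pipelines=())

    def test_first_layer_feature_shapes(self, rng):
        spec = gan.DiscriminatorSpec(filters=4, final_filters=4)
        d = gan.build_discriminator(spec, seed=0)
        feats = d.extractor("discriminator").features(
            rng.uniform(-1, 1, (2, 2000)))
        # stride-2 'same' convolution halves each pipeline's input length
        assert feats["raw"].shape == (2, 4, 1000)
        assert feats["fft"].shape == (2, 4, 501)
        assert feats["envelope"].shape == (2, 4, 1000)
        assert feats["raw"].shape[1:] == d.first_layer_shape("raw")

    def test_style_extractor_uses_envelope_spectrum(self, rng):
        # the style-path envelope view is envelope -> FFT magnitude, so
        # its positional axis is spectral (about half the time axis)
        spec = gan.DiscriminatorSpec(filters=4, final_filters=4)
        d = gan.build_discriminator(spec, seed=0)
        x = rng.uniform(-1, 1, (1, 2000))
        disc_view = d.extractor("discriminator").features(x)["envelope"]
        style_view = d.extractor("style").features(x)["envelope"]
        assert disc_view.shape == (1, 4, 1000)
        assert style_view.shape == (1, 4, 501)


class TestVariants:
    @pytest.mark.parametrize("variant", gan.VARIANTS)
    def test_all_variants_train_one_step(self, variant, short_record):
        gen_spec, disc_spec = small_specs(variant)
        cfg = gan.GanTrainingConfig(epochs=1, batch_size=4, seed=0,
                                    variant=variant)
        bundle = gan.train_gan([short_record], cfg, gen_spec, disc_spec)
        assert len(bundle.history.d_loss) == 1
        assert np.isfinite(bundle.history.d_loss[0])
        assert np.isfinite(bundle.history.g_loss[0])

    def test_latent_mode_is_pure_configuration(self):
        # 3CNN-NOISE and 3CNN differ only in the latent sampler: the
        # discriminators are identical and the generator conv stacks agree
        g_noise, d_noise = gan.variant_specs("3CNN-NOISE")
        g_sample, d_sample = gan.variant_specs("3CNN")
        assert d_noise == d_sample
        assert (g_noise.latent_mode, g_noise.latent_len) == ("noise", 100)
        assert (g_sample.latent_mode, g_sample.latent_len) == ("sample", 400)
        assert g_noise.filters == g_sample.filters
        assert g_noise.use_output_moving_average == g_sample.use_output_moving_average

    def test_reference_variant_has_mbd_and_ma(self):
        g, d = gan.variant_specs("4CNN-MBD-MA")
        assert d.use_minibatch_discrimination
        assert g.use_output_moving_average
        assert set(d.pipelines) == {"raw", "fft", "envelope", "wavelet"}

    def test_unknown_variant_rejected(self):
        with pytest.raises(ConfigurationError):
            gan.variant_specs("5CNN")


class TestTraining:
    def test_zero_epochs_returns_initialized_models(self, short_record):
        gen_spec, disc_spec = small_specs("4CNN")
        cfg = gan.GanTrainingConfig(epochs=0, batch_size=4, seed=0,
                                    variant="4CNN")
        bundle = gan.train_gan([short_record], cfg, gen_spec, disc_spec)
        assert bundle.history.d_loss == []
        assert bundle.history.g_loss == []
        out = bundle.generator.forward(np.zeros(400))
        assert out.shape == (1, 2000)

    def test_insufficient_data_rejected(self):
        gen_spec, disc_spec = small_specs("4CNN")
        cfg = gan.GanTrainingConfig(epochs=1, batch_size=4, seed=0,
                                    variant="4CNN")
        short = EmgSignal(np.sin(np.arange(500) * 0.1))
        with pytest.raises(DataInsufficiencyError):
            gan.train_gan([short], cfg, gen_spec, disc_spec)

    def test_training_reproducible_from_seed(self, short_record):
        gen_spec, disc_spec = small_specs("4CNN")
        cfg = gan.GanTrainingConfig(epochs=2, batch_size=4, seed=5,
                                    variant="4CNN")
        b1 = gan.train_gan([short_record], cfg, gen_spec, disc_spec)
        b2 = gan.train_gan([short_record], cfg, gen_spec, disc_spec)
        assert b1.history.d_loss == b2.history.d_loss
        assert b1.history.g_loss == b2.history.g_loss
        z = np.zeros(400)
        np.testing.assert_array_equal(b1.generator.forward(z),
                                      b2.generator.forward(z))


@pytest.fixture(scope="module")
def tiny_bundle(short_record):
    gen_spec, disc_spec = small_specs("4CNN")
    cfg = gan.GanTrainingConfig(epochs=1, batch_size=4, seed=0,
                                variant="4CNN")
    return gan.train_gan([short_record], cfg, gen_spec, disc_spec)


class TestGenerate:
    def test_contract_length_and_range(self, tiny_bundle):
        out = gan.generate(tiny_bundle, 10, seed=1)
        assert len(out) == 10
        for s in out:
            assert len(s) == 2000
            assert np.all(s.samples >= -1.0) and np.all(s.samples <= 1.0)

    def test_same_seed_reproducible(self, tiny_bundle):
        a = gan.generate(tiny_bundle, 1, seed=4)[0]
        b = gan.generate(tiny_bundle, 1, seed=4)[0]
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_different_seeds_differ(self, tiny_bundle):
        a = gan.generate(tiny_bundle, 1, seed=4)[0]
        b = gan.generate(tiny_bundle, 1, seed=5)[0]
        assert not np.array_equal(a.samples, b.samples)

    def test_save_load_round_trip(self, tiny_bundle, tmp_path, rng):
        tiny_bundle.save(tmp_path / "ckpt")
        loaded = gan.GanBundle.load(tmp_path / "ckpt")
        x = rng.uniform(-1, 1, (2, 2000))
        np.testing.assert_allclose(loaded.discriminator.score(x),
                                   tiny_bundle.discriminator.score(x),
                                   atol=1e-12)
        z = rng.standard_normal((1, 400))
        np.testing.assert_allclose(loaded.generator.forward(z),
                                   tiny_bundle.generator.forward(z),
                                   atol=1e-12)

    def test_missing_checkpoint_names_path(self, tmp_path):
        with pytest.raises(ConfigurationError, match="nowhere"):
            gan.GanBundle.load(tmp_path / "nowhere")


def test_minibatch_discrimination_wrapper(rng):
    f = rng.standard_normal((4, 6))
    T = rng.standard_normal((6, 3, 2))
    np.testing.assert_array_equal(gan.minibatch_discrimination(f, T),
                                  nn.minibatch_features(f, T))
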