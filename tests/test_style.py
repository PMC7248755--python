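"""Style-transfer losses and the optimization loop."""

import numpy as np
import pytest

from emgaug import gan
from emgaug.errors import ConfigurationError, InvalidArgumentError
from emgaug.signal import EmgSignal
from emgaug.style import (StyleConfig, content_loss, emg_content_loss,
                          run_style_transfer, style_layer_loss, style_loss,
                          total_loss)


class TestContentLoss:
    def test_identical_features_zero(self, rng):
        f = rng.standard_normal(64)
        assert content_loss(f, f) == 0.0

    def test_hand_example(self):
        assert content_loss([1.0, 1.0], [0.0, 0.0]) == pytest.approx(1.0)

    def test_matches_loop_oracle(self, rng):
        a, b = rng.standard_normal(100), rng.standard_normal(100)
        acc = 0.0
        for x, y in zip(a, b):
            acc += (x - y) ** 2
        assert content_loss(a, b) == pytest.approx(acc / 100, abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(InvalidArgumentError):
            content_loss([1.0], [1.0, 2.0])


class TestEmgContentLoss:
    def test_all_subthreshold_is_zero(self, rng):
        f_c = rng.uniform(-0.1, 0.1, 50)
        f_g = rng.standard_normal(50) * 100
        assert emg_content_loss(f_c, f_g, alpha_cs=10.0, eps_cs=0.1) == 0.0

    def test_identical_features_zero(self, rng):
        f = rng.standard_normal(30)
        assert emg_content_loss(f, f, alpha_cs=5.0, eps_cs=0.1) == 0.0

    def test_hand_example(self):
        # mask keeps indices 0 and 2; (0.5*2 + 0.5*2) / 3 = 2/3
        got = emg_content_loss([0.5, 0.0, -0.5], [0.0, 0.0, 0.0],
                               alpha_cs=2.0, eps_cs=0.1)
        assert got == pytest.approx(2.0 / 3.0, abs=1e-12)

    def test_matches_loop_oracle(self, rng):
        f_c = rng.standard_normal(80)
        f_g = rng.standard_normal(80)
        alpha, eps = 3.0, 0.4
        acc = sum(abs(c - g) * alpha for c, g in zip(f_c, f_g)
                  if abs(c) > eps)
        assert emg_content_loss(f_c, f_g, alpha, eps) == pytest.approx(
            acc / 80, abs=1e-12)


class TestStyleLosses:
    def test_identical_grams_zero(self, rng):
        G = rng.standard_normal((4, 4))
        assert style_layer_loss(G, G, 4, 16) == 0.0

    def test_scalar_case(self):
        # N=1, M=1: (4-2)^2 / (4*1*1) = 1
        assert style_layer_loss(np.array([[4.0]]), np.array([[2.0]]),
                                1, 1) == pytest.approx(1.0)

    def test_matches_loop_oracle(self, rng):
        G = rng.standard_normal((8, 8))
        A = rng.standard_normal((8, 8))
        acc = 0.0
        for i in range(8):
            for j in range(8):
                acc += (G[i, j] - A[i, j]) ** 2
        expected = acc / (4 * 8 ** 2 * 30 ** 2)
        assert style_layer_loss(G, A, 8, 30) == pytest.approx(expected,
                                                              abs=1e-12)

    def test_style_loss_weighted_sum(self, rng):
        e = rng.uniform(0, 1, 4)
        w = rng.uniform(0, 2, 4)
        assert style_loss(e, w) == pytest.approx(float(np.sum(w * e)),
                                                 abs=1e-12)
        assert style_loss([0.0, 0.0], [1.0, 2.0]) == 0.0
        assert style_loss([3.0], [2.0]) == pytest.approx(6.0)

    def test_length_mismatch(self):
        with pytest.raises(InvalidArgumentError):
            style_loss([1.0, 2.0], [1.0])

    def test_total_loss(self, rng):
        assert total_loss(0.0, 0.0, 1.0, 1.0) == 0.0
        assert total_loss(2.0, 3.0, 1.0, 1.0) == pytest.approx(5.0)
        ls, lc, ws, wc = rng.uniform(0, 5, 4)
        assert total_loss(ls, lc, ws, wc) == pytest.approx(ws * ls + wc * lc)


class TestStyleConfig:
    def test_requires_a_positive_weight(self):
        with pytest.raises(ConfigurationError):
            StyleConfig(w_sty=0.0, w_cont=0.0)

    def test_layer_weights_need_a_positive_entry(self):
        with pytest.raises(ConfigurationError):
            StyleConfig(layer_weights=(0.0, 0.0, 0.0, 0.0))


class TestRunStyleTransfer:
    WINDOW = 2000

    def _signals(self, rng):
        from emgaug.synthdata import TremorParams, synth_tremor
        sig = synth_tremor(TremorParams(duration=1.0, seed=21))
        return sig

    def test_noop_fixed_point(self, tiny_extractor):
        sig = self._signals(None)
        cfg = StyleConfig(epochs=2, iters_per_epoch=20, init="content",
                          window_len=self.WINDOW, trace_dtw=False)
        out, trace = run_style_transfer(sig, sig, tiny_extractor, cfg)
        rms = np.sqrt(np.mean((out.samples - sig.samples) ** 2))
        assert rms < 1e-3
        assert trace[-1]["l_total"] <= 1e-9

    def test_content_only_objective_keeps_content(self, tiny_extractor, rng):
        from emgaug.synthdata import TremorParams, synth_tremor
        content = self._signals(None)
        style = synth_tremor(TremorParams(duration=1.0, seed=77,
                                          tremor_freq=7.0))
        cfg = StyleConfig(w_sty=0.0, w_cont=2.0, eps_cs=0.0,
                          epochs=2, iters_per_epoch=20, init="content",
                          window_len=self.WINDOW, trace_dtw=False)
        out, _ = run_style_transfer(content, style, tiny_extractor, cfg)
        rms = np.sqrt(np.mean((out.samples - content.samples) ** 2))
        assert rms < 1e-3

    def test_style_only_objective_descends(self, tiny_extractor):
        from emgaug.synthdata import MovementParams, synth_movement
        from emgaug.synthdata import TremorParams, synth_tremor
        content = synth_movement(MovementParams(
            active_s=0.5, rest_s=0.5, n_repetitions=1, seed=3)
        ).with_samples(np.resize(
            synth_movement(MovementParams(active_s=0.5, rest_s=0.5,
                                          n_repetitions=1, seed=3)).samples,
            self.WINDOW))
        style = synth_tremor(TremorParams(duration=1.0, seed=9))
        cfg = StyleConfig(w_sty=2.0, w_cont=0.0, epochs=3,
                          iters_per_epoch=30, init="content",
                          window_len=self.WINDOW, seed=1, trace_dtw=False)
        out, trace = run_style_transfer(content, style, tiny_extractor, cfg)
        l_sty = [row["l_sty"] for row in trace]
        assert l_sty[-1] <= l_sty[0] + 1e-12
        # total loss never increases from its initial value
        totals = [row["l_total"] for row in trace]
        assert totals == sorted(totals, reverse=True) or totals[-1] <= totals[0]

    def test_window_length_mismatch_rejected(self, tiny_extractor):
        sig = self._signals(None)
        cfg = StyleConfig(window_len=self.WINDOW + 2)
        with pytest.raises(InvalidArgumentError):
            run_style_transfer(sig, sig, tiny_extractor, cfg)
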