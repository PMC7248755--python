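"""Numerical correctness of the neural-network engine: every layer's
backward pass is checked against central finite differences, and the
mini-batch discrimination closed forms are verified."""

import numpy as np
import pytest

from emgaug import nn
from emgaug.errors import ConfigurationError, InvalidArgumentError


def numerical_gradient(fn, x, eps=1e-6):
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        x[i] += eps
        fp = fn()
        x[i] -= 2 * eps
        fm = fn()
        x[i] += eps
        g[i] = (fp - fm) / (2 * eps)
    return g


def assert_grad_ok(layer, x, train=True, check_params=True, tol=1e-6):
    gen = np.random.default_rng(99)
    y0 = layer.forward(x, train=train)
    w = gen.standard_normal(y0.shape)

    def loss():
        return float((w * layer.forward(x, train=train)).sum())

    layer.forward(x, train=train)
    gx = layer.backward(w.copy())
    ngx = numerical_gradient(loss, x)
    scale = max(np.abs(ngx).max(), 1e-8)
    assert np.abs(gx - ngx).max() / scale < tol
    if check_params:
        for pi, p in enumerate(layer.params):
            layer.zero_grad()
            layer.forward(x, train=train)
            layer.backward(w.copy())
            ag = layer.grads[pi].copy()
            ng = numerical_gradient(loss, p)
            if np.abs(ag).max() < 1e-10 and np.abs(ng).max() < 1e-3:
                # analytically zero gradient (e.g. a conv bias feeding a
                # train-mode batch norm); finite differences only see
                # rounding noise there
                continue
            scale = max(np.abs(ng).max(), np.abs(ag).max(), 1e-6)
            assert np.abs(ag - ng).max() / scale < tol


@pytest.mark.parametrize("make,shape", [
    (lambda r: nn.Dense(5, 3, r), (4, 5)),
    (lambda r: nn.Conv1d(2, 4, 5, r, stride=2), (3, 2, 21)),
    (lambda r: nn.Conv1d(2, 3, 4, r, stride=1), (2, 2, 15)),
    (lambda r: nn.ConvTranspose1d(2, 3, 6, r, stride=2), (2, 2, 9)),
    (lambda r: nn.ConvTranspose1d(2, 3, 3, r, stride=1), (2, 2, 11)),
    (lambda r: nn.BatchNorm1d(2), (3, 2, 12)),
    (lambda r: nn.MovingAverage1d(5), (2, 2, 17)),
    (lambda r: nn.Envelope(7), (2, 1, 25)),
    (lambda r: nn.DWT("db2", 2), (2, 1, 32)),
    (lambda r: nn.MinibatchDiscrimination(6, 3, 2, r), (4, 6)),
    (lambda r: nn.ResidualBlock1d(2, 3, r), (3, 2, 13)),
    (lambda r: nn.SubtractMean(), (2, 2, 12)),
    (lambda r: nn.Tanh(), (2, 2, 9)),
    (lambda r: nn.LeakyReLU(0.2), (2, 2, 9)),
    (lambda r: nn.Upsample1d(3), (2, 2, 8)),
])
def test_backward_matches_finite_differences(make, shape, rng):
    layer = make(rng)
    x = rng.standard_normal(shape) + 0.1
    assert_grad_ok(layer, x)


@pytest.mark.parametrize("n", [20, 21])
def test_fft_magnitude_gradient(n, rng):
    # both even and odd lengths exercise the Nyquist-bin handling
    layer = nn.FFTMagnitude()
    x = rng.standard_normal((2, 1, n)) + 2.0   # keep |F| away from 0
    assert_grad_ok(layer, x, check_params=False)


def test_batchnorm_inference_uses_running_stats(rng):
    bn = nn.BatchNorm1d(3)
    x = rng.standard_normal((8, 3, 10)) * 4 + 2
    for _ in range(700):        # running stats converge as 0.99**k
        bn.forward(x, train=True)
    y = bn.forward(x, train=False)
    # after many identical batches the running stats match the batch stats
    assert abs(y.mean()) < 0.05
    assert abs(y.std() - 1.0) < 0.05


def test_dropout_inference_is_identity(rng):
    d = nn.Dropout(0.5, rng)
    x = rng.standard_normal((4, 2, 10))
    np.testing.assert_array_equal(d.forward(x, train=False), x)


def test_moving_average_layer_matches_preprocess(rng):
    from emgaug.preprocess import moving_average_array
    layer = nn.MovingAverage1d(10)
    x = rng.standard_normal((2, 1, 50))
    out = layer.forward(x)
    np.testing.assert_allclose(out[0, 0], moving_average_array(x[0, 0], 10),
                               atol=1e-12)


class TestMinibatchDiscrimination:
    def test_identical_batch_outputs_n_minus_one(self, rng):
        f = np.tile(rng.standard_normal(6), (5, 1))
        T = rng.standard_normal((6, 3, 2))
        o = nn.minibatch_features(f, T)
        np.testing.assert_array_equal(o, np.full((5, 3), 4.0))

    def test_two_samples_symmetric_exponential(self, rng):
        f = rng.standard_normal((2, 4))
        T = rng.standard_normal((4, 3, 2))
        A, B, C = T.shape
        M = (f @ T.reshape(A, B * C)).reshape(2, B, C)
        d = np.abs(M[0] - M[1]).sum(axis=1)
        o = nn.minibatch_features(f, T)
        np.testing.assert_allclose(o[0], np.exp(-d), atol=1e-12)
        np.testing.assert_allclose(o[1], np.exp(-d), atol=1e-12)

    def test_matches_triple_loop_oracle(self, rng):
        n, A, B, C = 5, 6, 3, 2
        f = rng.standard_normal((n, A))
        T = rng.standard_normal((A, B, C))
        M = np.einsum("na,abc->nbc", f, T)
        expected = np.zeros((n, B))
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                for b in range(B):
                    expected[i, b] += np.exp(-np.abs(M[i, b] - M[j, b]).sum())
        np.testing.assert_allclose(nn.minibatch_features(f, T), expected,
                                   atol=1e-9)

    def test_single_sample_rejected(self, rng):
        with pytest.raises(InvalidArgumentError):
            nn.minibatch_features(rng.standard_normal((1, 4)),
                                  rng.standard_normal((4, 2, 2)))


def test_residual_block_zeroed_weights_is_identity(rng):
    block = nn.ResidualBlock1d(3, 3, rng)
    for layer in block.body.layers:
        if isinstance(layer, nn.Conv1d):
            layer.params[0][...] = 0.0
            layer.params[1][...] = 0.0
    x = rng.standard_normal((2, 3, 16))
    np.testing.assert_allclose(block.forward(x, train=False), x, atol=1e-12)


def test_bce_bookkeeping_perfect_discriminator():
    # a perfectly confident correct discriminator drives its own loss to 0
    # while the generator's loss (fakes labelled real) diverges
    big = 500.0
    d_real, _ = nn.bce_with_logits(np.full(8, big), np.ones(8))
    d_fake, _ = nn.bce_with_logits(np.full(8, -big), np.zeros(8))
    g_loss, _ = nn.bce_with_logits(np.full(8, -big), np.ones(8))
    assert d_real < 1e-12 and d_fake < 1e-12
    assert g_loss > 100.0


def test_bce_gradient_direction():
    z = np.array([0.0])
    _, g1 = nn.bce_with_logits(z, np.ones(1))
    _, g0 = nn.bce_with_logits(z, np.zeros(1))
    assert g1[0] < 0 < g0[0]


def test_conv_transpose_requires_kernel_ge_stride(rng):
    with pytest.raises(ConfigurationError):
        nn.ConvTranspose1d(1, 1, 2, rng, stride=3)


def test_adam_reduces_quadratic():
    p = np.array([5.0])
    opt = nn.Adam([p], lr=0.1)
    for _ in range(300):
        opt.step([2 * p])
    assert abs(p[0]) < 1e-2
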