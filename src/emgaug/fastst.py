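"""Fast neural style transfer: a feed-forward 1D residual transformer.

Optimization-based style transfer solves one optimization problem per
content/style pair.  The fast variant instead trains a *transformer
network* once per style; afterwards any content signal is stylized in a
single forward pass.  The network is a 1-D adaptation of the residual
image-transformer design: strided downsampling convolutions, a chain of
residual blocks, transposed-convolution upsampling back to the input
length, and a tanh output.

Training minimizes the same style/content objective as the
optimization-based module, evaluated on transformer outputs over random
batches of content windows with a fixed style window, using Adam.  Both
content terms — the plain MSE and the masked amplified loss — are
applied and can be disabled individually.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .errors import (ConfigurationError, InvalidArgumentError,
                     TrainingDivergedError)
from .gan import FeatureExtractor, _draw_windows, _records
from .signal import EmgSignal
from .style import StyleConfig, gram_from_maps, style_loss, total_loss

__all__ = ["TransformerSpec", "Transformer", "build_transformer",
           "train_transformer"]


@dataclass(frozen=True)
class TransformerSpec:
    """Residual transformer architecture.  The length chain is
    L -> L/2 -> L/4 -> (residual blocks) -> L/2 -> L, so ``input_len``
    must be divisible by 4."""

    input_len: int = 20000
    base_filters: int = 16
    res_filters: int = 32
    n_residual_blocks: int = 5
    down_kernel: int = 9
    stride_kernel: int = 4
    res_kernel: int = 3

    def __post_init__(self):
        if self.input_len % 4 != 0:
            raise ConfigurationError(
                f"input_len must be divisible by 4 (length chain "
                f"L -> L/2 -> L/4 -> L/2 -> L), got {self.input_len}")
        if self.stride_kernel < 2:
            raise ConfigurationError(
                "stride_kernel must be >= 2 (transposed conv needs "
                "kernel >= stride)")
        if self.n_residual_blocks < 0:
            raise ConfigurationError("n_residual_blocks must be >= 0")


class Transformer:
    """Length-preserving feed-forward stylizer with outputs in [-1, 1]."""

    def __init__(self, spec: TransformerSpec, rng: np.random.Generator):
        self.spec = spec
        B, R = spec.base_filters, spec.res_filters
        layers: list[nn.Layer] = [
            nn.Conv1d(1, B, spec.down_kernel, rng),
            nn.BatchNorm1d(B), nn.ReLU(),
            nn.Conv1d(B, R, spec.stride_kernel, rng, stride=2),
            nn.BatchNorm1d(R), nn.ReLU(),
            nn.Conv1d(R, R, spec.stride_kernel, rng, stride=2),
            nn.BatchNorm1d(R), nn.ReLU(),
        ]
        layers += [nn.ResidualBlock1d(R, spec.res_kernel, rng)
                   for _ in range(spec.n_residual_blocks)]
        layers += [
            nn.ConvTranspose1d(R, R, spec.stride_kernel, rng, stride=2),
            nn.BatchNorm1d(R), nn.ReLU(),
            nn.ConvTranspose1d(R, B, spec.stride_kernel, rng, stride=2),
            nn.BatchNorm1d(B), nn.ReLU(),
            nn.Conv1d(B, 1, spec.down_kernel, rng),
            nn.Tanh(),
        ]
        self.net = nn.Sequential(layers)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 1:
            x = x[None, None, :]
        elif x.ndim == 2:
            x = x[:, None, :]
        if x.shape[2] % 4 != 0:
            raise InvalidArgumentError(
                f"input length must be divisible by 4, got {x.shape[2]}")
        return self.net.forward(x, train=train)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return self.net.backward(g)

    def __call__(self, signal: EmgSignal) -> EmgSignal:
        y = self.forward(signal.samples, train=False)
        return EmgSignal(y[0, 0], rate=signal.rate, label="fast-stylized")

    def parameters(self):
        return self.net.parameters()

    def gradients(self):
        return self.net.gradients()

    def zero_grad(self):
        self.net.zero_grad()


    def save(self, directory) -> None:
        from pathlib import Path
        import json
        from dataclasses import asdict
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(directory / "transformer.npz", **self.net.state_dict())
        bn = {}
        for i, layer in enumerate(nn.iter_batchnorms(self.net)):
            bn[f"bn_{i}_mean"] = layer.running_mean
            bn[f"bn_{i}_var"] = layer.running_var
        np.savez(directory / "batchnorm.npz", **bn)
        (directory / "transformer.json").write_text(
            json.dumps(asdict(self.spec), indent=2))

    @classmethod
    def load(cls, directory) -> "Transformer":
        from pathlib import Path
        import json
        directory = Path(directory)
        meta_path = directory / "transformer.json"
        if not meta_path.exists():
            raise ConfigurationError(
                f"no transformer checkpoint found at {directory}")
        spec = TransformerSpec(**json.loads(meta_path.read_text()))
        model = build_transformer(spec)
        with np.load(directory / "transformer.npz") as z:
            model.net.load_state_dict(dict(z))
        with np.load(directory / "batchnorm.npz") as z:
            bn = dict(z)
        for i, layer in enumerate(nn.iter_batchnorms(model.net)):
            layer.running_mean = bn[f"bn_{i}_mean"]
            layer.running_var = bn[f"bn_{i}_var"]
        return model


def build_transformer(spec: TransformerSpec, seed: int = 0) -> Transformer:
    """Build an initialized transformer with seeded weights."""
    return Transformer(spec, np.random.default_rng([seed, 404]))


def train_transformer(content_data, style: EmgSignal,
                      extractor: FeatureExtractor, config: StyleConfig,
                      spec: TransformerSpec | None = None,
                      steps: int = 200, batch_size: int = 2,
                      learning_rate: float = 1e-3,
                      use_plain_content: bool = True,
                      use_masked_content: bool = True,
                      content_layer: str = "raw",
                      ) -> tuple[Transformer, list[float]]:
    """Train a transformer to imprint one style onto arbitrary content.

    ``content_data`` is a collection of EmgSignal records to draw
    ``config.window_len``-point windows from; ``style`` is a fixed
    window of the same length.  Returns the trained transformer and the
    per-step total-loss trace.
    """
    if spec is None:
        spec = TransformerSpec(input_len=config.window_len)
    if spec.input_len != config.window_len:
        raise ConfigurationError(
            f"transformer input_len {spec.input_len} != config.window_len "
            f"{config.window_len}")
    s = style.samples
    if s.size != config.window_len:
        raise InvalidArgumentError(
            f"style window must have window_len={config.window_len} "
            f"samples, got {s.size}")
    recs = _records(content_data)
    if not any(r.size >= config.window_len for r in recs):
        raise InvalidArgumentError(
            f"no content record has >= {config.window_len} samples")

    model = build_transformer(spec, seed=config.seed)
    rng = np.random.default_rng([config.seed, 11])
    opt = nn.Adam(model.parameters(), lr=learning_rate)

    names = list(extractor.pipelines)
    if config.layer_weights is None:
        layer_weights = np.full(len(names), 1.0 / len(names))
    else:
        layer_weights = np.asarray(config.layer_weights, dtype=float)
    sfeat = extractor.features(s)
    style_grams = {n: gram_from_maps(sfeat[n][0]) for n in names}

    trace: list[float] = []
    for step in range(steps):
        batch = _draw_windows(recs, config.window_len, batch_size, rng)
        # content feature targets (no gradient path)
        F_c = extractor.features(batch)[content_layer].copy()

        y = model.forward(batch, train=True)            # (n, 1, L)
        feats = extractor.features(y[:, 0, :])
        nb = batch.shape[0]

        grads: dict[str, np.ndarray] = {}
        contributions = []
        for w_l, name in zip(layer_weights, names):
            F = feats[name]                              # (n, N, M)
            N_l, M_l = F.shape[1], F.shape[2]
            denom = 4.0 * N_l ** 2 * M_l ** 2
            e = 0.0
            gF = np.empty_like(F)
            for i in range(nb):
                diff = F[i] @ F[i].T - style_grams[name]
                e += float(np.sum(diff ** 2) / denom)
                gF[i] = (4.0 / denom) * (diff @ F[i])
            contributions.append(e / nb)
            grads[name] = config.w_sty * w_l * gF / nb
        l_sty = style_loss(contributions, layer_weights)

        F_g = feats[content_layer]
        resid = F_c - F_g
        el_cont = 0.0
        gF_c = np.zeros_like(F_g)
        if use_masked_content:
            mask = np.abs(F_c) > config.eps_cs
            el_cont += float(np.sum(np.abs(resid) * mask)
                             * config.alpha_cs / resid[0].size) / nb
            gF_c += (-config.alpha_cs / resid[0].size
                     * np.sign(resid) * mask) / nb
        if use_plain_content:
            el_cont += float(np.mean(resid ** 2))
            gF_c += -2.0 * resid / resid.size
        gF_c *= config.w_cont
        if content_layer in grads:
            grads[content_layer] = grads[content_layer] + gF_c
        else:
            grads[content_layer] = gF_c

        loss = total_loss(l_sty, el_cont, config.w_sty, config.w_cont)
        if not np.isfinite(loss):
            raise TrainingDivergedError(
                f"non-finite loss at step {step}", epoch=step)
        trace.append(loss)

        gy = extractor.backward(grads)                   # (n, 1, L)
        model.zero_grad()
        model.backward(gy)
        opt.step(model.gradients())

    return model, trace
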