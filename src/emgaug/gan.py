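"""1-D DCGAN for patient-specific tremor EMG synthesis.

The generator maps a latent window — either 100 Gaussian noise values or
a 400-point (0.2 s) sample of the patient's real signal — to a 2000-point
(1 s) synthetic signal through an upsampling convolution stack, a dense
layer, a tanh output, and an optional 10-point moving-average head.

The discriminator scores 2000-point windows through up to four parallel
convolutional pipelines operating on complementary views of the signal
(raw waveform, FFT magnitude, EMG envelope, 2-level db7 wavelet
coefficients), optionally augmented with mini-batch discrimination to
penalize mode collapse.  Its first-layer activations double as the
feature extractor for style transfer.

Six named architecture variants are exposed as pure configuration
(`variant_specs`): 3CNN-NOISE, 3CNN, WAVELET, 4CNN, 4CNN-MBD and
4CNN-MBD-MA, differing only in latent mode, pipeline set, mini-batch
discrimination, and the moving-average head.

Training follows the standard alternating DCGAN loop: per epoch, one
discriminator update on a real batch (label 1) and a generated batch
(label 0) with binary cross-entropy, then one generator update through
the frozen discriminator with the generated batch labelled 1.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from . import nn
from .errors import (ConfigurationError, DataInsufficiencyError,
                     InvalidArgumentError, TrainingDivergedError)
from .metrics import MetricReport, evaluate_batch
from .signal import EmgSignal

__all__ = [
    "GeneratorSpec", "DiscriminatorSpec", "GanTrainingConfig",
    "TrainingHistory", "GanBundle", "Generator", "Discriminator",
    "FeatureExtractor", "minibatch_discrimination",
    "build_generator", "build_discriminator", "variant_specs",
    "train_gan", "generate", "VARIANTS",
]

VARIANTS = ("3CNN-NOISE", "3CNN", "WAVELET", "4CNN", "4CNN-MBD",
            "4CNN-MBD-MA")

ALL_PIPELINES = ("raw", "fft", "envelope", "wavelet")


@dataclass(frozen=True)
class GeneratorSpec:
    """Generator architecture.  ``latent_mode='sample'`` draws 400-point
    windows of the real signal as latent input; ``'noise'`` draws 100
    Gaussian values (mapped to 400 points by a dense layer)."""

    latent_mode: str = "sample"
    latent_len: int = 400
    output_len: int = 2000
    filters: int = 32
    kernel: int = 16
    upsample: int = 5
    use_output_moving_average: bool = True
    ma_window: int = 10

    def __post_init__(self):
        if self.latent_mode not in ("noise", "sample"):
            raise ConfigurationError(
                f"latent_mode must be 'noise' or 'sample', got {self.latent_mode!r}")
        if self.latent_mode == "sample" and self.latent_len > self.output_len:
            raise ConfigurationError("sample latent cannot exceed output_len")

    @property
    def conv_input_len(self) -> int:
        # noise latents are expanded to a 400-point base by a dense layer
        return self.latent_len if self.latent_mode == "sample" else 400

    def validate_chain(self) -> None:
        reached = self.conv_input_len * self.upsample
        if reached != self.output_len:
            raise ConfigurationError(
                "generator shape chain cannot reach output_len: "
                f"{self.conv_input_len} (conv input) x {self.upsample} "
                f"(upsample) = {reached} != {self.output_len}")


@dataclass(frozen=True)
class DiscriminatorSpec:
    """Discriminator architecture: 4 conv blocks per enabled pipeline,
    32 filters per block (the last block is configurable between 32 and
    64), LeakyReLU activations, batch norm and dropout throughout."""

    pipelines: tuple[str, ...] = ALL_PIPELINES
    input_len: int = 2000
    filters: int = 32
    final_filters: int = 64
    n_blocks: int = 4
    kernel: int = 16
    stride: int = 2
    dropout_rate: float = 0.25
    leaky_alpha: float = 0.2
    use_minibatch_discrimination: bool = False
    mbd_kernels: int = 32      # B
    mbd_dim: int = 8           # C

    def __post_init__(self):
        if not self.pipelines:
            raise ConfigurationError("at least one pipeline must be enabled")
        bad = set(self.pipelines) - set(ALL_PIPELINES)
        if bad:
            raise ConfigurationError(
                f"unknown pipelines {sorted(bad)}; choose from {ALL_PIPELINES}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigurationError(
                f"dropout_rate must be in [0, 1), got {self.dropout_rate}")


@dataclass(frozen=True)
class GanTrainingConfig:
    learning_rate: float = 0.002
    epochs: int = 5000
    batch_size: int = 100
    seed: int = 0
    variant: str = "4CNN-MBD-MA"
    # generator optimizer passes per epoch; the default alternation is
    # one (against the two-pass real/fake discriminator update)
    generator_updates: int = 1
    metric_every: int = 0       # 0 disables per-epoch MetricReports
    metric_batch: int = 10
    dtw_radius: int = 1

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be > 0")
        if self.epochs < 0 or self.batch_size < 1:
            raise ConfigurationError("epochs >= 0 and batch_size >= 1 required")
        if self.variant not in VARIANTS:
            raise ConfigurationError(
                f"unknown variant {self.variant!r}; choose from {VARIANTS}")


@dataclass
class TrainingHistory:
    d_loss: list[float] = field(default_factory=list)
    g_loss: list[float] = field(default_factory=list)
    reports: list[MetricReport] = field(default_factory=list)


def variant_specs(variant: str, gen_filters: int = 32,
                  disc_filters: int = 32,
                  disc_final_filters: int = 64) -> tuple[GeneratorSpec,
                                                         DiscriminatorSpec]:
    """Generator/discriminator specs for each named architecture variant.

    The six variants form an ablation ladder: latent noise vs. latent
    sample, wavelet features, all four pipelines, mini-batch
    discrimination, and the generator moving-average head.
    """
    if variant not in VARIANTS:
        raise ConfigurationError(
            f"unknown variant {variant!r}; choose from {VARIANTS}")
    three = ("raw", "fft", "envelope")
    gen = GeneratorSpec(latent_mode="sample", latent_len=400,
                        filters=gen_filters, use_output_moving_average=False)
    disc = DiscriminatorSpec(pipelines=ALL_PIPELINES, filters=disc_filters,
                             final_filters=disc_final_filters)
    if variant == "3CNN-NOISE":
        gen = replace(gen, latent_mode="noise", latent_len=100)
        disc = replace(disc, pipelines=three)
    elif variant == "3CNN":
        disc = replace(disc, pipelines=three)
    elif variant == "WAVELET":
        disc = replace(disc, pipelines=("wavelet",))
    elif variant == "4CNN":
        pass
    elif variant == "4CNN-MBD":
        disc = replace(disc, use_minibatch_discrimination=True)
    elif variant == "4CNN-MBD-MA":
        disc = replace(disc, use_minibatch_discrimination=True)
        gen = replace(gen, use_output_moving_average=True)
    return gen, disc


class Generator:
    """Callable generator network: latent batch -> signal batch in [-1, 1]."""

    def __init__(self, spec: GeneratorSpec, rng: np.random.Generator):
        spec.validate_chain()
        self.spec = spec
        layers: list[nn.Layer] = []
        if spec.latent_mode == "noise":
            layers += [nn.Dense(spec.latent_len, spec.conv_input_len, rng),
                       nn.ReLU()]
        F, k = spec.filters, spec.kernel
        layers += [
            nn.Reshape((1, spec.conv_input_len)),
            nn.Conv1d(1, F, k, rng), nn.BatchNorm1d(F), nn.ReLU(),
            nn.Upsample1d(spec.upsample),
            nn.Conv1d(F, F, k, rng), nn.BatchNorm1d(F), nn.ReLU(),
            nn.Conv1d(F, 1, k, rng),
            nn.Flatten(),
            nn.Dense(spec.output_len, spec.output_len, rng),
            nn.Tanh(),
        ]
        if spec.use_output_moving_average:
            layers += [nn.Reshape((1, spec.output_len)),
                       nn.MovingAverage1d(spec.ma_window),
                       nn.Flatten()]
        self.net = nn.Sequential(layers)

    def forward(self, latent: np.ndarray, train: bool = False) -> np.ndarray:
        z = np.atleast_2d(np.asarray(latent, dtype=np.float64))
        if z.shape[1] != self.spec.latent_len:
            raise InvalidArgumentError(
                f"latent length {z.shape[1]} != spec.latent_len "
                f"{self.spec.latent_len}")
        return self.net.forward(z, train=train)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return self.net.backward(g)

    def __call__(self, latent: np.ndarray, rate: float = 2000.0) -> EmgSignal:
        out = self.forward(latent, train=False)
        return EmgSignal(out[0], rate=rate, label="generated")

    def parameters(self):
        return self.net.parameters()

    def gradients(self):
        return self.net.gradients()

    def zero_grad(self):
        self.net.zero_grad()


_TRANSFORMS = {
    "raw": lambda: None,
    "fft": nn.FFTMagnitude,
    "envelope": lambda: nn.Envelope(100),
    "wavelet": lambda: nn.DWT("db7", 2),
}


class Discriminator:
    """Multi-pipeline discriminator; `score` returns P(real) in (0, 1)."""

    def __init__(self, spec: DiscriminatorSpec, rng: np.random.Generator):
        self.spec = spec
        self.transforms: dict[str, nn.Layer | None] = {}
        self.stacks: dict[str, nn.Sequential] = {}
        for name in spec.pipelines:
            self.transforms[name] = _TRANSFORMS[name]()
            blocks: list[nn.Layer] = []
            c_in = 1
            for b in range(spec.n_blocks):
                c_out = spec.final_filters if b == spec.n_blocks - 1 else spec.filters
                blocks += [
                    nn.Conv1d(c_in, c_out, spec.kernel, rng, stride=spec.stride),
                    nn.BatchNorm1d(c_out),
                    nn.LeakyReLU(spec.leaky_alpha),
                    nn.Dropout(spec.dropout_rate, rng),
                ]
                c_in = c_out
            self.stacks[name] = nn.Sequential(blocks)
        self._feat_dims = {name: self._flat_dim(name) for name in spec.pipelines}
        total = sum(self._feat_dims.values())
        self.mbd = None
        if spec.use_minibatch_discrimination:
            self.mbd = nn.MinibatchDiscrimination(
                total, spec.mbd_kernels, spec.mbd_dim, rng)
            total += spec.mbd_kernels
        self.head = nn.Dense(total, 1, rng)

    # -- shape bookkeeping --------------------------------------------
    def _pipeline_input_len(self, name: str) -> int:
        L = self.spec.input_len
        if name == "fft":
            return L // 2 + 1
        if name == "wavelet":
            from .features import dwt_features
            return dwt_features(np.zeros(L)).size
        return L

    def _flat_dim(self, name: str) -> int:
        L = self._pipeline_input_len(name)
        for b in range(self.spec.n_blocks):
            L = -(-L // self.spec.stride)
        c = self.spec.final_filters
        return c * L

    def first_layer_shape(self, name: str) -> tuple[int, int]:
        """(N_l feature maps, M_l positions) of a pipeline's first block."""
        L = self._pipeline_input_len(name)
        return self.spec.filters, -(-L // self.spec.stride)

    # -- forward / backward -------------------------------------------
    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 1:
            x = x[None, :]
        if x.ndim == 2:
            x = x[:, None, :]
        if x.shape[2] != self.spec.input_len:
            raise InvalidArgumentError(
                f"input length {x.shape[2]} != spec.input_len "
                f"{self.spec.input_len}")
        return x

    def logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = self._check_input(x)
        n = x.shape[0]
        parts = []
        self._part_shapes = []
        for name in self.spec.pipelines:
            t = self.transforms[name]
            h = t.forward(x, train=train) if t is not None else x
            h = self.stacks[name].forward(h, train=train)
            self._part_shapes.append(h.shape)
            parts.append(h.reshape(n, -1))
        feats = np.concatenate(parts, axis=1)
        if self.mbd is not None:
            feats = self.mbd.forward(feats, train=train)
        return self.head.forward(feats, train=train)[:, 0]

    def score(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """P(real) for a batch; strictly inside (0, 1)."""
        p = nn.sigmoid(self.logits(x, train=train))
        tiny = np.finfo(np.float64).tiny
        return np.clip(p, tiny, 1.0 - tiny)

    def backward(self, g_logits: np.ndarray) -> np.ndarray:
        """Backprop from logits to the input batch (accumulates grads)."""
        g = self.head.backward(np.asarray(g_logits).reshape(-1, 1))
        if self.mbd is not None:
            g = self.mbd.backward(g)
        gx = None
        offset = 0
        for name, shape in zip(self.spec.pipelines, self._part_shapes):
            size = shape[1] * shape[2]
            gseg = g[:, offset:offset + size].reshape(shape)
            offset += size
            gt = self.stacks[name].backward(gseg)
            t = self.transforms[name]
            gpart = t.backward(gt) if t is not None else gt
            gx = gpart if gx is None else gx + gpart
        return gx

    def parameters(self):
        out = []
        for name in self.spec.pipelines:
            out.extend(self.stacks[name].parameters())
        if self.mbd is not None:
            out.extend(self.mbd.params)
        out.extend(self.head.params)
        return out

    def gradients(self):
        out = []
        for name in self.spec.pipelines:
            out.extend(self.stacks[name].gradients())
        if self.mbd is not None:
            out.extend(self.mbd.grads)
        out.extend(self.head.grads)
        return out

    def zero_grad(self):
        for name in self.spec.pipelines:
            self.stacks[name].zero_grad()
        if self.mbd is not None:
            self.mbd.zero_grad()
        self.head.zero_grad()

    def extractor(self, mode: str = "style") -> "FeatureExtractor":
        """Feature-extractor handle over the first conv block of each
        pipeline (used by the style-transfer losses)."""
        return FeatureExtractor(self, mode=mode)


class FeatureExtractor:
    """First-block activations of each discriminator pipeline.

    ``mode='discriminator'`` reproduces the discriminator's own views
    (time-domain envelope); ``mode='style'`` uses the style-loss feature
    stacks, where the envelope pipeline operates on the FFT magnitude of
    the envelope ("FFT over envelopes").  Inputs of any length are
    accepted — convolutions are length-agnostic.
    """

    def __init__(self, disc: Discriminator, mode: str = "style"):
        if mode not in ("style", "discriminator"):
            raise ConfigurationError(
                f"mode must be 'style' or 'discriminator', got {mode!r}")
        self.disc = disc
        self.mode = mode
        self.pipelines = disc.spec.pipelines
        self.transforms: dict[str, list[nn.Layer]] = {}
        self.blocks: dict[str, list[nn.Layer]] = {}
        for name in self.pipelines:
            chain: list[nn.Layer] = []
            if name == "fft":
                chain = [nn.FFTMagnitude()]
            elif name == "envelope":
                chain = [nn.Envelope(100)]
                if mode == "style":
                    # burst-rate spectrum in envelope-amplitude units:
                    # the DC level is standardized by conditioning and is
                    # removed, and the spectrum is 2/n-normalized so its
                    # scale matches the time-domain envelopes this
                    # pipeline's conv/batch-norm weights were trained on
                    chain += [nn.SubtractMean(), nn.FFTMagnitude(amplitude=True)]
            elif name == "wavelet":
                chain = [nn.DWT("db7", 2)]
            self.transforms[name] = chain
            # conv + batch norm + activation of the first block (no dropout)
            self.blocks[name] = disc.stacks[name].layers[:3]

    def features(self, x: np.ndarray,
                 train: bool = False) -> dict[str, np.ndarray]:
        """Per-pipeline first-block activations, shape (n, N_l, M_l)."""
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 1:
            x = x[None, None, :]
        elif x.ndim == 2:
            x = x[:, None, :]
        out = {}
        for name in self.pipelines:
            h = x
            for layer in self.transforms[name]:
                h = layer.forward(h, train=train)
            for layer in self.blocks[name]:
                h = layer.forward(h, train=train)
            out[name] = h
        return out

    def backward(self, grads: dict[str, np.ndarray]) -> np.ndarray:
        """Backprop per-pipeline feature gradients to the input signal.
        Must be called right after :meth:`features` (layer caches)."""
        gx = None
        for name in self.pipelines:
            if name not in grads:
                continue
            g = grads[name]
            for layer in reversed(self.blocks[name]):
                g = layer.backward(g)
            for layer in reversed(self.transforms[name]):
                g = layer.backward(g)
            gx = g if gx is None else gx + g
        if gx is None:
            raise InvalidArgumentError("no pipeline gradients supplied")
        return gx


def minibatch_discrimination(features: np.ndarray, T: np.ndarray) -> np.ndarray:
    """Closed-form mini-batch discrimination output (n x B matrix); see
    :func:`emgaug.nn.minibatch_features`."""
    return nn.minibatch_features(features, T)


def build_generator(spec: GeneratorSpec, seed: int = 0) -> Generator:
    """Build an initialized generator with seeded weights."""
    return Generator(spec, np.random.default_rng([seed, 101]))


def build_discriminator(spec: DiscriminatorSpec, seed: int = 0) -> Discriminator:
    """Build an initialized discriminator with seeded weights."""
    return Discriminator(spec, np.random.default_rng([seed, 202]))


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class GanBundle:
    """A trained (or initialized) generator/discriminator pair plus the
    configuration and history needed to reproduce and reuse it."""

    generator: Generator
    discriminator: Discriminator
    gen_spec: GeneratorSpec
    disc_spec: DiscriminatorSpec
    config: GanTrainingConfig
    history: TrainingHistory
    latent_source: list[np.ndarray] | None = None   # records for 'sample' mode

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(directory / "generator.npz", **self.generator.net.state_dict())
        disc_state = {f"param_{i}": p
                      for i, p in enumerate(self.discriminator.parameters())}
        np.savez(directory / "discriminator.npz", **disc_state)
        bn_state = {}
        for pi, name in enumerate(self.disc_spec.pipelines):
            for li, layer in enumerate(self.discriminator.stacks[name].layers):
                if isinstance(layer, nn.BatchNorm1d):
                    bn_state[f"{name}_{li}_mean"] = layer.running_mean
                    bn_state[f"{name}_{li}_var"] = layer.running_var
        for li, layer in enumerate(self.generator.net.layers):
            if isinstance(layer, nn.BatchNorm1d):
                bn_state[f"gen_{li}_mean"] = layer.running_mean
                bn_state[f"gen_{li}_var"] = layer.running_var
        np.savez(directory / "batchnorm.npz", **bn_state)
        meta = {"gen_spec": asdict(self.gen_spec),
                "disc_spec": asdict(self.disc_spec),
                "config": asdict(self.config)}
        (directory / "bundle.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "GanBundle":
        directory = Path(directory)
        meta_path = directory / "bundle.json"
        if not meta_path.exists():
            raise ConfigurationError(
                f"no GAN checkpoint found at {directory} "
                f"(missing {meta_path.name})")
        meta = json.loads(meta_path.read_text())
        meta["disc_spec"]["pipelines"] = tuple(meta["disc_spec"]["pipelines"])
        gen_spec = GeneratorSpec(**meta["gen_spec"])
        disc_spec = DiscriminatorSpec(**meta["disc_spec"])
        config = GanTrainingConfig(**meta["config"])
        gen = build_generator(gen_spec, seed=config.seed)
        disc = build_discriminator(disc_spec, seed=config.seed)
        with np.load(directory / "generator.npz") as z:
            gen.net.load_state_dict(dict(z))
        with np.load(directory / "discriminator.npz") as z:
            state = dict(z)
        for i, p in enumerate(disc.parameters()):
            p[...] = state[f"param_{i}"]
        with np.load(directory / "batchnorm.npz") as z:
            bn = dict(z)
        for name in disc_spec.pipelines:
            for li, layer in enumerate(disc.stacks[name].layers):
                if isinstance(layer, nn.BatchNorm1d):
                    layer.running_mean = bn[f"{name}_{li}_mean"]
                    layer.running_var = bn[f"{name}_{li}_var"]
        for li, layer in enumerate(gen.net.layers):
            if isinstance(layer, nn.BatchNorm1d):
                layer.running_mean = bn[f"gen_{li}_mean"]
                layer.running_var = bn[f"gen_{li}_var"]
        return cls(generator=gen, discriminator=disc, gen_spec=gen_spec,
                   disc_spec=disc_spec, config=config,
                   history=TrainingHistory())


def _records(data) -> list[np.ndarray]:
    recs = []
    for d in data:
        recs.append(d.samples if isinstance(d, EmgSignal) else
                    np.asarray(d, dtype=np.float64).reshape(-1))
    return recs


def _draw_windows(recs: list[np.ndarray], length: int, n: int,
                  rng: np.random.Generator) -> np.ndarray:
    eligible = [r for r in recs if r.size >= length]
    out = np.empty((n, length))
    for i in range(n):
        r = eligible[int(rng.integers(0, len(eligible)))]
        start = int(rng.integers(0, r.size - length + 1))
        out[i] = r[start:start + length]
    return out


def _draw_latent(recs, gen_spec: GeneratorSpec, n: int,
                 rng: np.random.Generator) -> np.ndarray:
    if gen_spec.latent_mode == "noise":
        return rng.standard_normal((n, gen_spec.latent_len))
    return _draw_windows(recs, gen_spec.latent_len, n, rng)


def train_gan(data, config: GanTrainingConfig,
              gen_spec: GeneratorSpec | None = None,
              disc_spec: DiscriminatorSpec | None = None,
              reference: np.ndarray | None = None) -> GanBundle:
    """Adversarial training on windows drawn from the given records.

    ``data`` is a collection of EmgSignal records (one patient).  Specs
    default to the configured variant's architecture.  The run is fully
    reproducible from ``config.seed``.
    """
    if gen_spec is None or disc_spec is None:
        v_gen, v_disc = variant_specs(config.variant)
        gen_spec = gen_spec or v_gen
        disc_spec = disc_spec or v_disc
    recs = _records(data)
    if not any(r.size >= disc_spec.input_len for r in recs):
        raise DataInsufficiencyError(
            f"need at least one record with >= {disc_spec.input_len} samples")
    if gen_spec.latent_mode == "sample" and not any(
            r.size >= gen_spec.latent_len for r in recs):
        raise DataInsufficiencyError(
            f"need at least one record with >= {gen_spec.latent_len} samples "
            "for sample-mode latents")
    if disc_spec.use_minibatch_discrimination and config.batch_size < 2:
        raise ConfigurationError(
            "mini-batch discrimination requires batch_size >= 2")

    gen = build_generator(gen_spec, seed=config.seed)
    disc = build_discriminator(disc_spec, seed=config.seed)
    rng_data = np.random.default_rng([config.seed, 1])
    opt_d = nn.Adam(disc.parameters(), lr=config.learning_rate)
    opt_g = nn.Adam(gen.parameters(), lr=config.learning_rate)
    history = TrainingHistory()
    bs = config.batch_size

    for epoch in range(config.epochs):
        # ---- discriminator update: real batch then generated batch ----
        real = _draw_windows(recs, disc_spec.input_len, bs, rng_data)
        z = _draw_latent(recs, gen_spec, bs, rng_data)
        fake = gen.forward(z, train=True)

        disc.zero_grad()
        logit_r = disc.logits(real, train=True)
        loss_r, g_r = nn.bce_with_logits(logit_r, np.ones(bs))
        disc.backward(g_r)
        opt_d.step(disc.gradients())

        disc.zero_grad()
        logit_f = disc.logits(fake, train=True)
        loss_f, g_f = nn.bce_with_logits(logit_f, np.zeros(bs))
        disc.backward(g_f)
        opt_d.step(disc.gradients())
        d_loss = 0.5 * (loss_r + loss_f)

        # ---- generator update(s) through the frozen discriminator -----
        g_loss = 0.0
        for _ in range(max(1, config.generator_updates)):
            z = _draw_latent(recs, gen_spec, bs, rng_data)
            gen.zero_grad()
            disc.zero_grad()
            fake = gen.forward(z, train=True)
            logit = disc.logits(fake, train=True)
            g_loss, g_l = nn.bce_with_logits(logit, np.ones(bs))
            gx = disc.backward(g_l)        # discriminator params frozen
            gen.backward(gx[:, 0, :])
            opt_g.step(gen.gradients())

        if not (np.isfinite(d_loss) and np.isfinite(g_loss)):
            raise TrainingDivergedError(
                f"non-finite loss at epoch {epoch} "
                f"(d_loss={d_loss}, g_loss={g_loss})", epoch=epoch)
        history.d_loss.append(d_loss)
        history.g_loss.append(g_loss)

        if config.metric_every and (epoch + 1) % config.metric_every == 0:
            ref = _draw_windows(recs, disc_spec.input_len,
                                config.metric_batch, rng_data)
            zz = _draw_latent(recs, gen_spec, config.metric_batch, rng_data)
            samples = gen.forward(zz, train=False)
            history.reports.append(
                evaluate_batch(list(ref), list(samples), epoch=epoch + 1,
                               radius=config.dtw_radius))

    return GanBundle(generator=gen, discriminator=disc, gen_spec=gen_spec,
                     disc_spec=disc_spec, config=config, history=history,
                     latent_source=recs)


def generate(bundle: GanBundle, n: int, seed: int,
             rate: float = 2000.0) -> list[EmgSignal]:
    """Draw ``n`` signals from a bundle under a seeded latent stream."""
    if n < 1:
        raise InvalidArgumentError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng([seed, 3])
    spec = bundle.gen_spec
    if spec.latent_mode == "sample":
        if not bundle.latent_source:
            raise ConfigurationError(
                "sample-mode bundle has no latent source records")
        z = _draw_windows(bundle.latent_source, spec.latent_len, n, rng)
    else:
        z = rng.standard_normal((n, spec.latent_len))
    out = bundle.generator.forward(z, train=False)
    return [EmgSignal(out[i], rate=rate,
                      label=f"generated-{bundle.config.variant}")
            for i in range(n)]
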