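"""End-to-end orchestration: synthesize -> preprocess -> train GAN ->
generate -> evaluate -> (optional) style transfer, with every artifact
and a manifest written to the output directory."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, gan, io, metrics, style, synthdata
from .config import RunConfig
from .errors import EmgaugError, PipelineError
from .signal import EmgSignal

__all__ = ["run_pipeline"]

log = logging.getLogger("emgaug")


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            log.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(name, str(exc)) from exc
        return wrapped
    return deco


@_stage("synth")
def _synth(cfg: RunConfig, out: Path) -> tuple[EmgSignal, EmgSignal]:
    tremor = synthdata.synth_tremor(synthdata.TremorParams(
        tremor_freq=cfg.tremor_freq, rate=cfg.rate,
        duration=cfg.tremor_duration_s, seed=cfg.seed))
    movement = synthdata.synth_movement(synthdata.MovementParams(
        n_repetitions=cfg.movement_repetitions, rate=cfg.rate,
        seed=cfg.seed + 1))
    data_dir = out / "data"
    data_dir.mkdir(parents=True, exist_ok=True)
    io.write_emg_csv(data_dir / "tremor.csv", tremor)
    io.write_emg_csv(data_dir / "movement.csv", movement)
    return tremor, movement


@_stage("train_gan")
def _train(cfg: RunConfig, tremor: EmgSignal, out: Path) -> gan.GanBundle:
    gen_spec, disc_spec = gan.variant_specs(
        cfg.variant, gen_filters=cfg.gen_filters,
        disc_filters=cfg.disc_filters,
        disc_final_filters=cfg.disc_final_filters)
    config = gan.GanTrainingConfig(
        learning_rate=cfg.learning_rate, epochs=cfg.epochs,
        batch_size=cfg.batch_size, seed=cfg.seed, variant=cfg.variant,
        metric_every=cfg.metric_every)
    bundle = gan.train_gan([tremor], config, gen_spec, disc_spec)
    ckpt = out / "gan"
    bundle.save(ckpt)
    rows = [{"epoch": i + 1, "d_loss": d, "g_loss": g}
            for i, (d, g) in enumerate(zip(bundle.history.d_loss,
                                           bundle.history.g_loss))]
    hist = pd.DataFrame(rows)
    for rep in bundle.history.reports:
        hist.loc[hist["epoch"] == rep.epoch,
                 ["dtw", "fft_mse", "env_xcorr"]] = (
            rep.dtw, rep.fft_mse, rep.env_xcorr)
    hist.to_csv(ckpt / "history.csv", index=False)
    return bundle


@_stage("generate")
def _generate(cfg: RunConfig, bundle: gan.GanBundle,
              out: Path) -> list[EmgSignal]:
    samples = gan.generate(bundle, cfg.n_generate, seed=cfg.seed,
                           rate=cfg.rate)
    gen_dir = out / "generated"
    gen_dir.mkdir(parents=True, exist_ok=True)
    io.write_emg_csv(gen_dir / "samples.csv",
                     [s.with_samples(s.samples, label=f"sample{i}")
                      for i, s in enumerate(samples)])
    return samples


@_stage("evaluate")
def _evaluate(cfg: RunConfig, tremor: EmgSignal,
              samples: list[EmgSignal], out: Path) -> metrics.MetricReport:
    rng = np.random.default_rng([cfg.seed, 5])
    L = samples[0].samples.size
    refs = gan._draw_windows([tremor.samples], L, len(samples), rng)
    report = metrics.evaluate_batch(list(refs), samples)
    pd.DataFrame([report.as_row()]).to_csv(out / "metrics.csv", index=False)
    return report


@_stage("style_transfer")
def _style(cfg: RunConfig, bundle: gan.GanBundle, tremor: EmgSignal,
           movement: EmgSignal, out: Path) -> None:
    rng = np.random.default_rng([cfg.seed, 6])
    L = cfg.style_window_len
    c = gan._draw_windows([movement.samples], L, 1, rng)[0]
    s = gan._draw_windows([tremor.samples], L, 1, rng)[0]
    sc = style.StyleConfig(
        w_sty=cfg.w_sty, w_cont=cfg.w_cont, eps_cs=cfg.eps_cs,
        alpha_cs=cfg.alpha_cs, epochs=cfg.style_epochs,
        iters_per_epoch=cfg.style_iters_per_epoch, init=cfg.style_init,
        window_len=L, seed=cfg.seed)
    stylized, trace = style.run_style_transfer(
        EmgSignal(c, rate=cfg.rate, label="content"),
        EmgSignal(s, rate=cfg.rate, label="style"),
        bundle.discriminator.extractor("style"), sc)
    sdir = out / "style"
    sdir.mkdir(parents=True, exist_ok=True)
    io.write_emg_csv(sdir / "stylized.csv", stylized)
    pd.DataFrame(trace).to_csv(sdir / "trace.csv", index=False)


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the configured stage chain; returns the artifact directory.

    Writes synthetic data, GAN checkpoint + loss history, generated
    samples, a MetricReport CSV, optional style-transfer outputs, and a
    ``manifest.json`` recording the full configuration, seed and library
    versions.  Identical configurations produce identical artifacts.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), 20),
                        format="%(asctime)s %(name)s %(levelname)s %(message)s")
    tremor, movement = _synth(cfg, out)
    bundle = _train(cfg, tremor, out)
    samples = _generate(cfg, bundle, out)
    report = _evaluate(cfg, tremor, samples, out)
    if cfg.run_style:
        _style(cfg, bundle, tremor, movement, out)
    manifest = {
        "config": asdict(cfg),
        "seed": cfg.seed,
        "versions": {"emgaug": __version__, "numpy": np.__version__,
                     "pandas": pd.__version__},
        "metrics": report.as_row(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    log.info("pipeline complete: %s", out)
    return out
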