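"""Reduced-scale reference experiments.

These functions bundle the package's main end-to-end studies at a size a
single CPU can run in minutes: GAN training on synthetic 5 Hz tremor,
the mode-collapse/diversity comparison with and without mini-batch
discrimination, style-transfer descent, and the fast-transformer
comparison.  Problem sizes (two 16 s records, batch 12, 8 filters,
300 epochs, 2 s style windows) are the package's standard small-scale
study conditions; the same functions back both the test suite and
``scripts/acceptance.py``.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from . import fastst, gan, metrics, style, synthdata
from .features import envelope
from .signal import EmgSignal

__all__ = [
    "make_tremor_records", "make_movement_record", "train_variant",
    "dominant_envelope_peak_hz", "frequency_recovery", "pairwise_diversity",
    "style_descent", "fast_style_study",
]

TREMOR_HZ = 5.0
RECORD_SECONDS = 16.0
N_RECORDS = 2
EPOCHS = 300
DIVERSITY_EPOCHS = 300      # same budget for the 4CNN vs 4CNN-MBD pair
BATCH_SIZE = 12
FILTERS = 8
STYLE_WINDOW = 4000         # 2 s at 2 kHz


def make_tremor_records(seed: int, n_records: int = N_RECORDS,
                        duration_s: float = RECORD_SECONDS) -> list[EmgSignal]:
    """Synthetic one-patient tremor record set (5 Hz bursts)."""
    return [synthdata.synth_tremor(synthdata.TremorParams(
        tremor_freq=TREMOR_HZ, duration=duration_s, seed=seed + k))
        for k in range(n_records)]


def make_movement_record(seed: int, n_repetitions: int = 2) -> EmgSignal:
    """Synthetic healthy functional-movement record (5 s on / 3 s off)."""
    return synthdata.synth_movement(
        synthdata.MovementParams(n_repetitions=n_repetitions, seed=seed))


def train_variant(records, variant: str, seed: int,
                  epochs: int = EPOCHS, batch_size: int = BATCH_SIZE,
                  filters: int = FILTERS) -> gan.GanBundle:
    """Train one reduced-width GAN variant on the given records."""
    gen_spec, disc_spec = gan.variant_specs(
        variant, gen_filters=filters, disc_filters=filters,
        disc_final_filters=filters)
    config = gan.GanTrainingConfig(epochs=epochs, batch_size=batch_size,
                                   seed=seed, variant=variant)
    return gan.train_gan(records, config, gen_spec, disc_spec)


def dominant_envelope_peak_hz(signal: EmgSignal) -> float:
    """Frequency (Hz) of the strongest non-DC peak of the envelope spectrum."""
    env = envelope(signal)
    env = env - env.mean()
    mag = np.abs(np.fft.rfft(env))
    freqs = np.fft.rfftfreq(env.size, 1.0 / signal.rate)
    return float(freqs[1:][np.argmax(mag[1:])])


def frequency_recovery(bundle: gan.GanBundle, seed: int, n: int = 20,
                       target_hz: float = TREMOR_HZ,
                       tol_hz: float = 1.0) -> tuple[float, list[float]]:
    """Fraction of generated samples whose dominant envelope-spectrum peak
    lies within ``tol_hz`` of the tremor frequency."""
    samples = gan.generate(bundle, n, seed=seed)
    peaks = [dominant_envelope_peak_hz(s) for s in samples]
    hits = sum(abs(p - target_hz) <= tol_hz for p in peaks)
    return hits / n, peaks


def pairwise_diversity(bundle: gan.GanBundle, seed: int,
                       n: int = 10) -> float:
    """Mean pairwise FastDTW distance among generated samples (low values
    indicate mode collapse)."""
    samples = gan.generate(bundle, n, seed=seed)
    dists = [metrics.dtw_fast(a.samples, b.samples)
             for a, b in combinations(samples, 2)]
    return float(np.mean(dists))


def _draw(record: EmgSignal, length: int, rng) -> EmgSignal:
    start = int(rng.integers(0, len(record) - length + 1))
    return record.with_samples(record.samples[start:start + length])


def style_descent(bundle: gan.GanBundle, records, seed: int,
                  window_len: int = STYLE_WINDOW,
                  weights: tuple[tuple[float, float], ...] = ((2.0, 2.0),
                                                              (1.0, 4.0)),
                  epochs: int = 20, iters_per_epoch: int = 100) -> dict:
    """Optimization-based style transfer on synthetic content/style.

    Runs one transfer per (w_sty, w_cont) pair from the same content and
    style windows and returns the traces plus content/style similarity
    summaries for each.
    """
    rng = np.random.default_rng([seed, 21])
    movement = make_movement_record(seed + 50)
    # centre the content window on the first activation offset (5 s into
    # the record) so it spans an on->off transition: the envelope then has
    # the structure the content-preservation comparison is about
    mid = int(5.0 * movement.rate)
    content = movement.with_samples(
        movement.samples[mid - window_len // 2: mid + window_len // 2])
    style_sig = _draw(records[0], window_len, rng)
    extractor = bundle.discriminator.extractor("style")
    layer_weights = style.balanced_layer_weights(extractor, content,
                                                 style_sig)
    out = {"content": content, "style": style_sig,
           "layer_weights": layer_weights, "runs": []}
    for w_sty, w_cont in weights:
        cfg = style.StyleConfig(w_sty=w_sty, w_cont=w_cont,
                                layer_weights=layer_weights,
                                epochs=epochs,
                                iters_per_epoch=iters_per_epoch,
                                init="random", window_len=window_len,
                                seed=seed, trace_dtw=False)
        stylized, trace = style.run_style_transfer(content, style_sig,
                                                   extractor, cfg)
        out["runs"].append({
            "w_sty": w_sty, "w_cont": w_cont,
            "output": stylized, "trace": trace,
            "fft_mse_style_epoch1": trace[0]["fft_mse_vs_style"],
            "fft_mse_style_final": trace[-1]["fft_mse_vs_style"],
            "env_xcorr_content": metrics.envelope_cross_correlation(
                stylized.samples, content.samples),
        })
    return out


def fast_style_study(bundle: gan.GanBundle, descent: dict, seed: int,
                     steps: int = 400, batch_size: int = 2,
                     window_len: int = STYLE_WINDOW) -> dict:
    """Train the feed-forward transformer on the same style window and
    held-out synthetic content; compare with the optimization route."""
    style_sig = descent["style"]
    extractor = bundle.discriminator.extractor("style")
    train_content = make_movement_record(seed + 60)
    # uniform layer weights: the feed-forward route is trained with
    # spectral emphasis (the FFT-layer Gram dominates), which is what
    # makes its outputs' spectra track the style; the optimization route
    # uses the balanced weights instead (see style_descent)
    cfg = style.StyleConfig(window_len=window_len, seed=seed,
                            layer_weights=None, trace_dtw=False)
    spec = fastst.TransformerSpec(input_len=window_len,
                                  base_filters=8, res_filters=16,
                                  n_residual_blocks=3)
    model, trace = fastst.train_transformer(
        [train_content], style_sig, extractor, cfg, spec=spec,
        steps=steps, batch_size=batch_size)
    held_out = make_movement_record(seed + 70)
    # transition-spanning probe window (see style_descent): half active,
    # half rest, so content preservation and style imprinting both show
    mid = int(5.0 * held_out.rate)
    content = held_out.with_samples(
        held_out.samples[mid - window_len // 2: mid + window_len // 2])
    output = model(content)
    # also stylize the optimization run's content window, so the two
    # routes can be compared on the same content/style pair
    output_on_descent_content = model(descent["content"])
    return {
        "fft_mse_same_pair_style": metrics.fft_mse(
            output_on_descent_content.samples, style_sig.samples),
        "model": model, "trace": trace,
        "content": content, "output": output,
        "fft_mse_output_style": metrics.fft_mse(output.samples,
                                                style_sig.samples),
        "fft_mse_content_style": metrics.fft_mse(content.samples,
                                                 style_sig.samples),
        "env_xcorr_output_content": metrics.envelope_cross_correlation(
            output.samples, content.samples),
        "env_xcorr_style_content": metrics.envelope_cross_correlation(
            style_sig.samples, content.samples),
    }
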