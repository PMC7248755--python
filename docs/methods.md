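# Methods

## Signal model and conditioning

All signals are single-channel sEMG sampled at 2 kHz (configurable). Before
any training or scoring a record is conditioned: an optional 10-point
trailing moving average (5 ms; suppresses high-frequency noise while
leaving 4–6 Hz tremor bursts intact), then an affine min–max rescale of the
whole record to [−1, +1] followed by subtraction of the rescaled mean. The
order — rescale first, then mean-subtract — means the final range can
slightly exceed [−1, 1]; this is accepted, since the tanh output range of
the generator only needs approximate agreement with the data scale. The
moving average uses a *trailing* window with partial-window warm-up so that
output length equals input length: generated and reference windows must be
comparable sample-for-sample. Rescaling statistics are per record and per
channel; windows extracted later inherit the record's scaling.

## Synthetic data

Real parkinsonian recordings cannot be shipped, so the test bed generates
two signal families that reproduce the features the models actually
exploit:

* **Rest tremor**: Gaussian white noise band-passed to 20–450 Hz (the
  standard sEMG band, 4th-order zero-phase Butterworth) is gated by a
  raised-cosine bump covering a `burst_duty` fraction (default 0.5) of
  each tremor cycle at `tremor_freq` (default 5 Hz), with per-burst
  log-free amplitude jitter (relative σ 0.1) and a 2% background noise
  floor. By construction the envelope spectrum peaks at the tremor
  frequency and its harmonics — the property the discriminator's envelope
  and FFT pipelines key on.
* **Functional movement**: repetitions of 5 s activation / 3 s rest, with
  0.5 s raised-cosine onset/offset ramps, same carrier and noise floor.

What these generators do *not* model: motor-unit recruitment, electrode
artifacts, inter-channel correlation, slow drift, or variation of tremor
frequency over time. Tests passing on this data therefore demonstrate that
the machinery (training dynamics, losses, metrics) behaves as designed for
burst-structured signals, not that clinical-grade realism is achieved on
patient data.

## The GAN

Architecture defaults follow the DCGAN recommendations: strided
convolutions instead of pooling in the discriminator, batch normalization
in both networks, ReLU hidden / tanh output activations in the generator,
LeakyReLU (α = 0.2) throughout the discriminator.

* **Generator**: latent input (400-point signal sample, or 100 Gaussian
  values expanded to 400 by a dense layer) → Conv(k16) + BN + ReLU →
  nearest-neighbour ×5 upsampling → Conv(k16) + BN + ReLU → Conv(k16) →
  dense 2000→2000 → tanh → optional 10-point moving-average head.
  The ×5 upsample is what turns the 0.2 s latent window into a 1 s output.
* **Discriminator**: per enabled pipeline, four blocks of
  Conv(k16, stride 2) + BN + LeakyReLU + Dropout(0.25); 32 filters per
  block with the final block configurable between 32 and 64. Pipeline
  inputs: raw window (2000), FFT magnitude (1001 bins), envelope
  (|x| → 100-point MA, 2000), 2-level db7 DWT coefficients (2024,
  symmetric extension, coarsest-first). Flattened pipeline features are
  concatenated; mini-batch discrimination (B = 32 kernels, C = 8 dims,
  o(x_i)_b = Σ_{j≠i} exp(−‖M_{i,b} − M_{j,b}‖₁)) is appended when enabled;
  a dense layer with sigmoid head yields P(real).
* **Training**: per epoch, two discriminator Adam steps (real batch
  labelled 1, generated batch labelled 0, binary cross-entropy on logits
  for stability) then one generator step through the frozen discriminator
  with generated samples labelled 1. Learning rate 0.002, batch-norm
  momentum 0.99 / ε 1e-3 (pinned), one model per patient record set. All
  randomness flows from named substreams of a single seed.

The six named variants differ only in configuration: latent mode
(noise/sample), pipeline set (3CNN uses raw + FFT + envelope; WAVELET uses
the wavelet pipeline alone, isolating the wavelet features' discriminative
power), MBD, and the generator MA head.

## Neural-network engine

No deep-learning framework is used; `emgaug.nn` implements the required
layers (1D convolution and transposed convolution with 'same' semantics,
batch norm, dropout, dense, upsampling, moving-average, mini-batch
discrimination, residual blocks) with explicit backward passes, plus Adam.
Every backward pass — including the fixed signal transforms the style loss
must differentiate through (FFT magnitude via the adjoint of the real FFT,
envelope via the moving-average adjoint and sign subgradient, DWT via a
cached sparse analysis operator and its transpose) — is verified against
central finite differences in the test suite. Weight initialization is
Glorot-uniform; the |x| subgradient at 0 is taken as 0.

## Style transfer

Content features are the first-layer activations of the raw-signal
pipeline on the content window; style targets are Gram matrices of the
first-layer activations of all four pipelines on the style window. For the
style path the envelope pipeline operates on the burst-rate spectrum
rather than the burst waveform: the envelope is mean-removed (its DC level
is already standardized by conditioning and would otherwise dominate the
Gram matrices) and its FFT magnitude is scaled by 2/n into envelope-
amplitude units, so the input scale matches the time-domain envelopes this
pipeline's convolution and batch-norm weights were trained on. The masked
content loss sums α_cs·|F_c − F_g| over positions with |F_c| > ε_cs only,
normalized by the full feature length; below-threshold positions contribute
nothing — that is the mask's purpose (defaults α_cs = 10, ε_cs = 0.1, in
conditioned-amplitude units). Per-layer style weights ω_l default to
uniform 1/L; because the raw per-layer contributions E_l span several
orders of magnitude (their normalization depends on map counts and
positions, and the four pipelines see very differently scaled inputs),
`balanced_layer_weights` is provided to equalize the layers at a reference
signal — with balanced ω_l the initial style loss is 1, commensurate with
the content term, and the global weights ω_sty/ω_cont act as true
trade-off dials (raising ω_cont visibly raises the output's envelope
correlation with the content). Default ω_sty = ω_cont = 2 (the balanced
setting of the weight sweep).
Optimization is scipy's L-BFGS-B over the output signal, 20 epochs × 100
iterations by default, initialized from the content signal (faster
convergence) or uniform noise; a momentum fallback exists, and the best
point seen is returned so the final loss never exceeds the initial one.

The fast variant trains a feed-forward transformer — Conv(k9) →
two stride-2 Conv(k4) downsampling stages → 5 residual blocks of width 32
(no post-add activation, so zeroed blocks are exact identities) → two
stride-2 transposed-conv upsampling stages → Conv(k9) → tanh — with Adam
(lr 1e-3) against the same objective, where the content term is the sum of
the plain MSE and the masked loss (both individually switchable). Input
length must be divisible by 4 (the length chain L → L/2 → L/4 → L/2 → L).

## Metrics

* **FFT MSE**: mean squared error between |rfft| spectra; phase-blind.
* **DTW**: exact O(nm) dynamic programming with local cost |a_i − b_j|
  (squared cost available) is the oracle. `dtw_fast` is the
  multiresolution approximation: coarsen by pairwise averaging, solve
  coarse, refine within a window of radius + 1 cells around the projected
  path at both resolutions — and additionally bound the result by a
  constant-width Sakoe–Chiba band around the diagonal, returning the
  smaller. Both searches are restricted-lattice DPs, so the result never
  underestimates exact DTW and cost stays linear; the band covers the
  unstructured-noise regime where coarsening discards the detail needed to
  find the near-diagonal optimum (measured fidelity at radius 1:
  ≈0.8% mean error on iid-noise pairs, ≈2% on random walks, 150 points).
* **Envelope cross-correlation**: envelopes (100-point window) are
  mean-centred and unit-variance scaled; per-lag products are normalized by
  overlap length and the maximum over lags |lag| ≤ n/4 is returned. The lag
  cap defines how much tremor-phase misalignment the metric forgives;
  larger displacements have unstable overlap estimates.

## Reduced-scale study conditions

Full-scale training (5000 epochs, batch 100, 32–64 filters, 20 000-point
style windows) is impractical for a CPU test suite, so the reference
experiments in `emgaug.experiments` fix a reduced standard: two 16 s
synthetic tremor records per "patient", 8 filters everywhere, batch 12,
300 epochs for frequency-recovery training, 2 s (4000-point) style windows
with the full 20 × 100 optimizer budget, and a 400-step transformer
(width 8/16, 3 residual blocks). Style/content windows are centred on an
activation transition of the movement record (half active, half rest) so
that envelope-based content-preservation measures have structure to
preserve. The optimization route runs with initialization-balanced layer
weights (to expose the weight trade-off); the feed-forward route trains
with uniform layer weights, under which the FFT-layer Gram dominates and
the output spectra track the style — the setting where the route shows
its published behaviour. These sizes are stated with each reported
number; behaviours demonstrated at this scale (frequency recovery,
loss descent, quality orderings) are qualitative properties of the method,
not estimates of full-scale metric values.

## Known limitations

* The numpy engine is single-threaded and eager; wall-clock cost bounds
  the practical epoch count, and no convergence heuristics (label
  smoothing, two-timescale updates) are applied.
* Mode collapse is weakly expressed at the reduced scale: with sample
  latents and few hundred epochs the plain 4CNN generator remains
  latent-driven, so diversity comparisons between MBD and non-MBD variants
  are noisier than at full scale.
* Adversarial training at the 300-epoch reduced scale is seed-sensitive:
  the discriminator dominates early (tiny discriminator loss, generator
  loss in the 5–15 range — the same signature as full-scale runs), and
  whether the generator locks onto the tremor modulation within the
  budget varies across initializations. The reference experiments
  therefore pin their study seed; re-runs at other seeds can show lower
  frequency-recovery rates.
* Style transfer quality depends on the extractor's training; an untrained
  extractor still defines a valid objective but an uninformative style
  representation.
* Multi-channel records are treated as independent channels throughout.
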