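# Methods

This note documents the models, the synthetic-data design, the numerical
choices and the open design decisions behind `migraph`. It states no
empirical number that the test suite or `scripts/acceptance.py` does not
itself compute.

## Structural connectivity: montage graph and embedding

The packaged 22-channel montage (`bci2a-22`) fixes integer grid
coordinates for the frontal-to-parietal electrode rows used in four-class
motor-imagery recordings (Fz; FC3–FC4; C5–C6; CP3–CP4; P1–P2; POz).
Channels are adjacent when their grid cells are at Chebyshev distance 1,
so interior channels have eight neighbours (for Cz: FC1, FCz, FC2, C1, C2,
CP1, CPz, CP2) and boundary channels fewer. The layout ships as JSON; a
user-supplied JSON layout can replace it, and the adjacency is always
derived from the grid, never hand-entered.

Normalisation follows the spectral (GCN) convention: `Ã = A + I`,
`D̃ = deg(Ã)`, `Â = D̃^(−1/2) Ã D̃^(−1/2)`. `Â` is symmetric, its
spectrum lies in [−1, 1], and the square-root-degree vector is a fixed
point — properties asserted by the test suite. The trial embedding
`G = Â·X` is linear and shape-preserving; channel *i* of the output
depends only on channel *i* and its neighbours. The embedding is a
neighbourhood *average*: it raises signal-to-noise for activity that is
spatially coherent across neighbouring electrodes (as volume-conducted
cortical sources are) and attenuates activity confined to a single
electrode.

**Input scaling.** Trials are z-scored *globally per trial* (one mean and
one standard deviation over all channels × samples) before embedding and
training. Per-channel z-scoring was rejected deliberately: it equalises
every channel's variance and thereby erases the across-channel power
topography that event-related desynchronisation (ERD) classification
depends on. A `scale` parameter (`"trial"`, `"channel"`, `None`) keeps the
alternatives available; `None` is used in tests that check the embedding's
exact arithmetic.

## Functional connectivity: band-limited PLV

Band-passing uses a 4th-order Butterworth applied forward–backward
(`sosfiltfilt`, zero phase). Packaged bands: broadband 1–51 Hz, δ 1–4,
θ 4–8, α 8–12, μ 8–13, β 12–30, the sensorimotor 8–30 Hz range, γ 30–51.
Instantaneous phase is the angle of the analytic (Hilbert) signal; the
phase of an all-zero channel is undefined and raises.

The PLV of a channel pair is the magnitude of the time-averaged unit
phasor of the phase difference over the M samples of the trial (the
standard pairwise time-averaged definition; the per-trial matrix is what a
per-trial classifier requires). Because both the filter and the Hilbert
transform smear epoch edges, 125 samples (0.5 s at 250 Hz) are trimmed
from each end before averaging; the trim is a parameter and is set to 0 in
unit tests that verify the phasor arithmetic exactly. PLV matrices are
used dense — no edge thresholding — since the classifier consumes edge
*weights*; broadband (1–51 Hz) PLV is computed identically even though a
broadband "phase" is physically ambiguous, and the per-band results should
be preferred for interpretation. One model is trained per band; bands are
never stacked.

## Architectures and training regimes

Both architectures are described as framework-independent layer graphs
(`ModelSpec`) with symbolic shape propagation, then instantiated in the
package's numpy CNN engine. All convolutions and pools are "valid" (no
padding); pooling stride equals the pool size. The engine implements
im2col convolution, max-pooling, inverted dropout, dense layers, softmax
cross-entropy and Adam; backpropagation is verified against central
finite differences, and a fixed seed reproduces initial weights and the
training trajectory bit-for-bit on the same machine. No deep-learning
framework is required anywhere.

* Structural model: conv (22, 45) × 64, stride (2, 2), ReLU → max-pool
  (1, 50) → flatten (576) → dropout 0.25 → dense softmax. Regime: Adam
  lr 1e-4, batch 128, up to 1000 epochs, early stopping with patience 250
  monitoring the loss on a 10 % stratified split carved from the training
  data, best weights restored.
* Functional model: conv (3, 3) × 32 ReLU → max-pool (2, 2) → conv
  (3, 3) × 64 ReLU → dropout 0.25 → flatten (4096) → dense softmax.
  Regime: Adam lr 1e-3, batch 64, 800 epochs, no early stopping. ReLU is
  used on both convolutions.
* Ablation baselines: "no structural graph" is the identical wide-kernel
  architecture fed raw (unembedded) trials; "no functional graph" adapts
  the small CNN to raw band-passed trials with its first kernel widened to
  (3, 45) for a comparable temporal receptive field — this adaptation is
  the package's own (non-canonical) choice, since a 22×22 connectivity
  input does not exist once PLV is removed.

First-layer feature maps (per-kernel activation arrays) are exportable as
CSV for numeric inspection of which channels each kernel attends to; the
wide-kernel model's maps have height 1 because the kernel spans all
channels.

## Evaluation

Cross-validation uses k = 9 folds over 15 independent runs at full scale
(both reducible). Folds are class-stratified (to within one trial per
class) and mix trials across subjects. Every run draws a fresh fold
assignment *and* fresh model initialisation from seeds derived via
`numpy.random.SeedSequence`, so a single integer reproduces the entire
plan; a flag to freeze folds across runs is available through the plan
object. Early stopping's validation split is carved from the training
fold only; all preprocessing (z-scoring, PLV) is strictly per-trial, so no
statistic crosses a fold boundary.

Metrics per fold: accuracy, macro/micro F1, macro/micro precision, and
one-vs-rest ROC-AUC (macro = unweighted class mean, micro = pooled) from
the softmax scores. For single-label multiclass predictions micro-F1 =
micro-precision = accuracy exactly; the suite asserts this identity on
every report. The summary spread ("SD") is the standard deviation of
fold-level accuracies pooled across runs. Degenerate folds (a missing
class) produce a warning and NaN for undefined metrics rather than an
abort. The hyperparameter harness sweeps parameter grids (packaged grids:
filter counts {32, 64, 128, 256} and kernel widths {22, 45, 65, 85} for
the structural model; filter pairs × kernel sizes, 8 combinations, for the
functional model), marks failed configurations, and flags the best row by
accuracy.

## Synthetic data: what is emulated and what is not

The generator reproduces the geometry of a standard four-class
motor-imagery session: 22 channels × 1000 samples (4 s at 250 Hz), four
classes, 9 pseudo-subjects assigned round-robin (each with a fixed ±10 %
log-normal gain), defaulting to 648 trials/class = 2592 trials. Three
ingredients plant recoverable class structure:

1. **Phase-coupled pairs.** A coupled pair shares one narrowband
   oscillator whose instantaneous frequency wanders around the band
   centre (AR(1) drift, ρ = 0.995, stationary std 0.5 Hz, clipped at
   ±1.5 Hz — narrowband but never a pure tone). Each member channel adds
   independent Gaussian phase jitter of std σ/√2, so the pair's phase
   *difference* has std σ and the expected PLV is the closed form
   `exp(−σ²/2)`. The jitter is smoothed to a ≈2 Hz bandwidth (Gaussian
   kernel, rescaled to the exact target marginal std) so it survives the
   analysis band-pass; smoothing changes the correlation but not the
   marginal law, so the expectation is unchanged. Two biases bracket the
   closed form in practice: a narrow analysis band clips the outer
   sidebands of large-σ jitter (biasing PLV up), and the finite number of
   effective samples in a 3-s trimmed epoch biases the magnitude up,
   while in-band noise biases both phases down. The generator-level
   recovery test therefore plants β-band coupling with ≈4 Hz jitter
   bandwidth and low noise, conditions under which the closed form is the
   dominant term; the preset-level recovery test (σ = 0.3, μ band,
   default noise) checks the regime the classifiers actually use.
2. **Coherent regional sources (ERD).** A `RegionalSource` projects one
   oscillator with zero lag onto a centre electrode (weight 1) and its
   grid neighbours (weight 1/√2 — power halves per grid step), a crude
   but essential stand-in for volume conduction. Per-class factors on a
   source's power (±50 % at the C3/C4/Cz sources in the shipped preset)
   mimic ERD. Coherence matters: with independent per-channel
   oscillators, the neighbourhood-averaging embedding *destroys* a planted
   single-channel power anomaly instead of denoising it, and the
   structural classifier stays near chance — the regional-source design is
   both the physically defensible one and the one under which the
   embedding behaves as intended.
3. **Background noise.** Each channel receives a 50/50 pink (1/f) + white
   mixture. `snr_db` (default 0 dB) is the *broadband* oscillator-to-noise
   power ratio; since the noise spreads over 1–125 Hz, the share falling
   inside any single analysis band is roughly an order of magnitude
   smaller, which keeps analytic-signal phases usable at the default
   setting.

Shipped presets (`preset_spec`): `plv-separable` (two disjoint coupled
pairs per class, σ = 0.3, μ band — classes differ only in *which* pairs
lock), `erd-separable` (the three sensorimotor sources with per-class
±50 % power topographies — classes differ only in *where* power sits) and
`both`. `planted_oracle` returns the analytic expectations: `exp(−σ²/2)`
on coupled entries, 1 on pure single-source co-member pairs, the
uniform-phase floor `√π/2/√M` elsewhere (optimistic for band-limited
signals, whose effective sample count is smaller), and the per-channel
expected power map.

Not emulated: leadfield/volume-conduction mixing beyond the fixed regional
taper, eye/muscle artifacts, session non-stationarity, and
subject-specific spatial patterns. Passing tests therefore demonstrate
that the pipeline recovers the structure it models — not that the shipped
hyperparameters reach any particular accuracy on recorded EEG.

## Evaluation scales used by the automated checks

Chosen once for single-CPU tractability and documented here as the
package's own study conditions:

* Functional route: `plv-separable`, 200 trials/class, μ-band PLV, 3-fold
  CV, 40 training epochs.
* Structural route: `erd-separable`, 200 trials/class, 3-fold CV, 45
  epochs at lr 3e-4 (a shortened schedule standing in for the long
  low-rate default regime).
* Ablation pair and label-shuffled control: 100 trials/class; the
  baseline CNN on raw band-passed trials trains for 5 epochs on a 2-fold
  split (its per-epoch cost is ~30× the functional model's); the shuffled
  control averages 3 runs of 3-fold CV.

## Known limitations

* PLV edge-trimming, filter order and jitter bandwidth interact; the
  closed-form recovery guarantees hold in the documented regimes, not for
  arbitrary band/σ combinations.
* The broadband-PLV model inherits the ambiguity of broadband phase.
* The numpy engine targets these small architectures; it keeps full
  im2col buffers in memory and is not suitable for large models.
* The optional GDF ingest applies epoching and channel selection only; it
  performs no artifact rejection or re-referencing.
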