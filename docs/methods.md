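# Methods

## Model

The descriptor under study is a multi-scale Gabor filter bank (MS-GFB) with
`Nf` filters, each parameterised by six quantities:

| parameter | meaning | units | domain | default role |
| --- | --- | --- | --- | --- |
| `m` | square convolution window | pixels (integer) | [1, 20] | spatial scale of the neighbourhood |
| `σ` | Gaussian envelope scale | pixels | [1, 5] | spatial extent of the filter |
| `θ` | carrier orientation | radians | [0, π] | texture direction selected |
| `λ` | carrier wavelength | pixels/cycle | [1, 10] | spatial frequency selected |
| `γ` | envelope aspect ratio | — | [0, 1] | elongation of the envelope |
| `ψ` | carrier phase offset | radians | [0, 2π] | even/odd symmetry mix |

The kernel is the product of a Gaussian envelope and a **sine** carrier,

    g(x, y) = exp(−(x′² + γ² y′²)/(2σ²)) · sin(2π x′/λ + ψ),

with x′ = x cos θ + y sin θ, y′ = −x sin θ + y cos θ, x indexing rows and y
columns. The sine carrier is deliberate — most image libraries default to a
cosine ("real Gabor") carrier with a frequency-normalised envelope, which is
a different function family — so kernels are synthesized directly from the
formula. Sampling uses integer offsets −(m−1)/2 … (m−1)/2 for odd m and
symmetric half-integer offsets for even m, so the grid is always centred and
no anisotropic bias enters for even windows. A useful analytic consequence,
used as a test oracle: for odd m and ψ = 0 the kernel is point-antisymmetric
and sums exactly to zero.

The image descriptor is F = [μ₁, σ₁, …, μ_Nf, σ_Nf], where μ_j and σ_j are
the mean and **population** (divisor M·N) standard deviation of the j-th
same-size filter response over all pixels of the ROI crop, including the
zeroed background pixels inside the mask's bounding box.

## Preprocessing

Images are converted to grayscale with ITU-R BT.601 weights
(0.299/0.587/0.114) — the most common luminance convention, recorded in
config so it can be swapped. Image and mask are first rescaled to a common
working resolution (720×480, the PH2 protocol resolution; bilinear for
images, bilinear + 0.5-threshold for masks so they stay binary), then pixels
outside the mask are zeroed and the result is cropped to the mask's tight
bounding box. That order — rescale the full frame, then mask-and-crop —
keeps all images on a homogeneous spatial grid while letting the crop
dimensions adapt to each lesion. Synthetic benchmark images are generated at
the working resolution directly, so their pipeline skips the rescale.

## Optimization

The `6·Nf` parameters form one flat decision vector (blocks of six per
filter, order m, σ, θ, λ, γ, ψ; 24 coordinates for the default `Nf = 4`).
DE/best/1/bin evolves a population of such vectors:

- **mutation** `V = Θ_best + F·(Θ_a − Θ_b)` with scale factor `F = 0.8`;
  a and b are drawn uniformly without replacement from the population
  excluding the target and the current best;
- **crossover** binomial with rate `CR = 0.9` plus a forced coordinate
  `j_rand`, so every trial inherits at least one donor coordinate;
- **repair** out-of-bound coordinates are reflected back via the modulus of
  the range: below L ↦ U − |x mod (U−L)|, above U ↦ L + |x mod (U−L)|, with
  the truncated (C-style) remainder. This convention makes, e.g., −0.5 on
  [0, π] fold to π − 0.5 and 12 on [1, 10] fold to 4; it is idempotent and
  always lands inside the bounds (fuzz-tested on 10⁴ random vectors).
  Reflection rather than clamping preserves population diversity;
- **selection** greedy with a strict inequality: ties keep the incumbent.

Defaults: population 30, at most 30 generations, error threshold 10⁻⁶
(termination when the best fitness reaches it), `Nf = 4`. DE runs in
continuous space throughout; the integer window size is produced only when a
vector is decoded into a bank, by half-away-from-zero rounding clamped to
[1, 20]. One seeded generator drives a whole run with a fixed draw order
(per target: the a/b pair, then j_rand, then the CR uniforms), so every run
replays bit-identically from its seed.

## Fitness

A candidate bank's fitness is `E = 1 − (1/K) Σ Acc_k`: the complement of the
mean held-out accuracy of a linear SVM (C = 1) over stratified K-fold
cross-validation (K = 5 by default) on the training set. Design choices:

- **Folds are frozen per run.** The stratified partition is built once from
  the run's fold seed and reused for every candidate, so all candidates are
  compared on identical partitions and fitness differences reflect the
  descriptor, not partition noise.
- **Standardisation is on by default.** Raw Gabor μ components reach
  hundreds while σ components for near-zero-sum kernels sit near zero; a
  fixed-C linear SVM is scale-sensitive, so features are z-scored with
  statistics fitted on the training folds only (never the held-out fold —
  verified by an independent per-fold refit in the tests). The flag is in
  `CVConfig` and echoed into every artifact.
- Degenerate folds (a single class in a training split) raise with the fold
  index rather than silently scoring.

## Two-stage protocol

Stage 1 runs `n_runs` (31 by default) independent DE optimizations on the
training split only; run i uses seed `base_seed + i` for both the population
initialisation and the fold partition, so runs differ in both. Final best
fitnesses are summarised (min/max/mean/median and sample n−1 standard
deviation) and the best, median (⌈R/2⌉-th order statistic, ties broken by
seed) and worst runs are kept as descriptors. Stage 2 takes one descriptor,
fits a single linear SVM on the full training split (no cross-validation)
and reports accuracy, precision, recall and F1 on the untouched test split,
with melanoma (label 1) as the positive class and a `collapsed` flag set
whenever the model predicts a single class for every input — the signature
of majority/minority collapse on imbalanced data, which scores exactly the
class-proportion accuracy.

## Numerical choices

- Convolution is a true convolution (kernel flipped), same-size output,
  borders handled by edge replication. Edge replication is chosen so the
  constant-image/zero-sum-kernel identity holds exactly at the borders. The
  backend (`scipy.signal.convolve` on an edge-padded frame) is validated
  against a nested-loop oracle to 10⁻¹² absolute.
- μ/σ use the population (M·N) divisor, matching the descriptor definition;
  run summaries use the sample (n−1) divisor, recorded in their metadata.
- Precision/recall/F1 are defined as 0 when their denominators vanish.

## Synthetic benchmark

The generator emulates the core premise — class-dependent *directional*
texture — with none of the photographic nuisance of real dermoscopy. Class 0
images are sinusoidal gratings at one orientation (default 0, i.e.
horizontal stripes); class 1 images are gratings at a second orientation
(default π/2) plus a third component at π/3 past it whose amplitude is
scaled by a `heterogeneity` factor (default 0.5), emulating directional
disorganisation. Both classes share base intensity 128, amplitude 50, a
random per-sample carrier phase, additive Gaussian noise (sd 5 by default)
and 8-bit quantisation; each sample gets a filled elliptical lesion mask
with randomised centre and semi-axes (55–85 % of the half-frame). Defaults
are 20 images per class at 64×64 with an 80/20 stratified split — small
enough that a full 31-run optimization study completes in seconds. Base
intensity, amplitude and the semi-axis range were chosen once as
representative of mid-gray 8-bit dermoscopy crops with lesions filling most
of the frame.

Because the class difference lives purely in orientation and heterogeneity —
never in mean intensity — success requires genuinely directional features: a
descriptor blind to orientation collapses to chance here. The benchmark does
**not** emulate hair, glare, colour variation, illumination gradients, or
intra-class lesion diversity, so passing it demonstrates the machinery
(feature extraction, optimization, evaluation, no train/test leakage) and
the orientation-recovery capability, not clinical performance on real
dermoscopy.

On this benchmark the task is deliberately easy for a matched filter: random
Gabor banks already separate the classes often, and DE drives the
cross-validated error to 0 in essentially every seeded run, with held-out
accuracy 1.0. Harder variants (more noise, higher heterogeneity, closer
orientations) can be configured for studying failure modes.

## Reference banks

Three optimized four-filter banks from a 31-run study on the PH2
melanoma-vs-nevus task (the best-, median- and worst-fitness solutions) are
bundled as JSON so feature extraction and the CLI can be exercised on real
parameter values without rerunning the search or downloading data.

## Known limitations

- Real-data performance claims require the real datasets; the test suite's
  end-to-end guarantees are about the synthetic benchmark only.
- The SVM is fixed to a linear kernel with C = 1 by design (interpretability
  and comparability), not tuned per dataset.
- The even-window convolution centre is a convention (documented above);
  centre-value identities are asserted only for odd windows.
- Whether features should be standardised before the SVM is an open
  modelling choice; both modes are supported (`CVConfig.standardize`) and
  the choice is recorded in every artifact.
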