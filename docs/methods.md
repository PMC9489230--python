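# Methods

`spectransfer` studies a practical chemometrics problem: a regression model
that predicts leaf chlorophyll content from VIS–NIR reflectance (430–2500 nm,
1 nm grid) is calibrated on one measurement domain — one cultivar, batch or
instrument — and must be reused on another. The package implements and
validates one answer: *ensemble spectral preprocessing plus fine-tuning
transfer of a 1D convolutional network*, benchmarked against conventional
chemometric regressors (PLS, RBF-SVR) and classical calibration-transfer
methods (direct standardization, transfer component analysis).

## The synthetic two-domain generator

Paired-cultivar leaf spectra with reference chemistry are rarely public, so
the whole pipeline is validated on a generator whose ground truth is known.

Each clean spectrum is a smooth logistic continuum (≈0.1 reflectance in the
visible rising to ≈0.5 in the NIR, the gross shape of a green-leaf curve)
minus Gaussian absorption features:

* **informative bands** tied to the chlorophyll value `c` — defaults at
  670 nm (red absorption valley, width 12 nm, sensitivity 0.12), 550 nm
  (green reflectance region, 10 nm, 0.06) and 715 nm (red edge, 18 nm,
  0.08). Band depth is `s·(c' + κ·c'²)` with `c' = c/c_max`, strictly
  increasing in `c`.
* **nuisance bands** with chlorophyll-independent random depth — water
  bands at 1450/1940 nm and a protein/N band at 2200 nm.

Reference values are uniform on 9.7–56.1 (arbitrary units; typical
extract-assay chlorophyll values for field cotton leaves).

The clean spectrum is corrupted by the Martens scatter model that SNV, MSC
and derivatives are designed to invert: per-sample multiplicative factor
`a ~ LogNormal(0, 0.08)`, additive offset `b ~ Normal(0, 0.01)`, a smooth
random linear+quadratic baseline tilt (SD 0.01), and i.i.d. noise
(SD 0.002 reflectance).

The **target domain** differs from the source in three ways, emulating a
cultivar change: the scatter distributions shift
(`log a` mean +0.08, offset mean +0.01), the informative peak centres move
by +3 nm, and the chlorophyll→depth map acquires a mild quadratic
nonlinearity (κ = 0.15). These defaults are fixed study conditions, not
tuning knobs: they produce a domain gap large enough that a source-only
model visibly degrades on the target, while remaining within the range of
realistic between-cultivar variation.

What the generator does **not** emulate: radiative-transfer leaf optics
(PROSPECT-style multiple scattering), growth-stage factor structure,
instrument-specific noise colouring, or wavelength-dependent spectral
resolution. Passing benchmarks therefore demonstrate correctness and the
method's comparative behaviour under the modelled distortions — not field
performance on real cotton spectra.

## Preprocessing

Eight named pipelines (`none, msc, snv, fd, msc+fd, snv+fd, fd+msc,
fd+snv`; names read left-to-right in application order). Implementation
choices where conventions differ:

* SNV uses the sample standard deviation (divisor n−1).
* MSC regresses each spectrum on a reference by OLS; the reference defaults
  to the calibration-set column mean, is stored at fit time and reapplied
  unchanged to every other split and domain.
* Detrending subtracts a per-spectrum least-squares polynomial, order 2
  (the standard Barnes default), on a conditioning-scaled wavelength axis.
* FD is the Savitzky–Golay first derivative (window 15, polyorder 2 —
  common for spectroradiometer resolution; both configurable) with respect
  to wavelength in nm. Edges are filled with the nearest interior value so
  the matrix width (and hence the CNN input width) is preserved.
  `fd_mode="difference"` gives the alternative reading (first difference
  after SG smoothing).

The core algebraic property — verified in the test suite — is that
`fd → snv` exactly removes any per-spectrum affine corruption
`a·x + b` on noiseless data: the derivative kills the offset, SNV the
surviving scale. This is the mechanism that makes FD+SNV the strongest
pretreatment for cross-domain transfer.

## CNN regressors and training

Six 1D architectures: `cnn1..cnn4` (one to four blocks of 32 kernels of
size 3 with max pooling, then 512- and 32-node FC layers), plus 1D
adaptations of AlexNet and a 9-layer VGGNet (4096/4096 FC). All take a
(1 × width) spectrum, start with a batch-normalization layer as the
standardization step, and end in a single output node. The self-designed
nets carry a BN layer after each conv block (order conv→ReLU→pool→BN; a
flag swaps BN before the pool). Max-pool window/stride is 2.

Training: L2 loss, Adam, batch 64, initial learning rate 0.005 divided by
10 every 200 epochs, stopping when the loss stabilizes (no relative
improvement of the epoch loss over the running best exceeding 1e-4 for 50
consecutive epochs) or at `max_epochs` (default 600); the best-validation
checkpoint is kept. The output node's bias is initialized to the
training-set mean response — a pure conditioning choice that speeds up
convergence of the L2 objective without changing the model class.

The layer engine (`nn.py`) is written directly in numpy (float32):
explicit forward/backward passes, seeded He initialization, per-layer
freezing, and input gradients for saliency. Training is bit-reproducible
given (seed, config, data).

**Scaled benchmark conditions.** The RMSE-ordering benchmarks run at
600 samples/domain on a 10 nm grid (208 variables) with 150 epochs and a
learning-rate decade every 50 epochs — the full-scale schedule (600/200)
scaled by 4 — so the complete suite runs on a single CPU. Exact-protocol
checks (split sizes, trim width) and the saliency benchmark use the full
1 nm / 2071-variable grid.

## Fine-tuning transfer

All layers of the pretrained network are frozen except the last two fully
connected layers — read as the 32-node layer plus the output node; the
512-node layer stays frozen (`trainable_fc_layers` widens this; the
convention is an interpretation of an ambiguous protocol and is flagged
as such). Frozen BN layers run in inference mode, so the frozen prefix is
a fixed deterministic map; its activations are precomputed once and only
the trainable suffix is optimized. Fine-tuning reuses the training
schedule with initial LR 0.0005 (one decade below pretraining) and keeps
the pretrained output bias. When a fraction of the target calibration set
is used, the subsample is rank-stratified over the reference values
(seeded), and the batch size drops to 32 when fewer than 64 samples
remain.

## Classical standardization baselines

**DS.** Standard samples cannot be physically paired across cultivars, so
the `n_standards` (default 100) samples drawn from each domain are paired
by reference-value *rank* — the only order statistic the domains share;
this is an interpretation, documented as such. The transformation matrix
solves `T·F ≈ S` in least squares with a ridge penalty of
`1e-6 · trace(TᵀT)/p` for the wide system (penalty 0 recovers the
classical pseudo-inverse).

**TCA.** Linear kernel on the stacked domains (RBF optional), solving the
generalized eigenproblem `K H K w = λ (K L K + μI) w` with μ = 1 and 30
components by default (unstated in common references at this scale;
configurable). The MMD statistic reported by `mmd()` is the squared
distance of domain means divided by the pooled total variance, making it
comparable between the raw and projected spaces.

## Gradient saliency

For every *correctly predicted sample* (relative error within 5%,
inclusive), the gradient of the output with respect to each input
wavelength is computed at the network input — i.e. after pretreatment,
before the input BN. Each sample's top-100 wavelengths by |gradient|
(ties broken toward the lower wavelength) are counted into a frequency
spectrum; `sum(frequency) = n_correct × 100` by construction.

The saliency validation runs on the full 2071-variable grid: the
informative bands span ≈163 columns there, so a well-localized top-100
can concentrate inside them, whereas on the coarse benchmark grid
(208 columns) a top-100 would necessarily cover half the spectrum and no
attribution method could reach high in-band mass. The benchmark model for
this check is trained on MSC-corrected spectra: MSC inverts the scatter
corruption sample-by-sample without SNV's global rescaling (whose
normalization constant depends on band depths and therefore smears
chlorophyll information over all wavelengths) and without the derivative's
edge effects, so the attribution target is clean — chlorophyll information
exists only inside the generator's informative bands.

Two caveats documented for interpretation: max-pooling makes per-sample
gradients sparse (roughly half the input columns receive little gradient
through losing pool slots), which is inherent to plain gradient saliency
on pooled architectures; and the error-rate gate means saliency reflects
the samples the model already predicts well. Together with the
overparameterized fully connected stage (tens of millions of weights
against a few hundred calibration spectra at full width), these give each
sample's top-100 list a noise floor of out-of-band wavelengths, so the
in-band frequency mass — reported by the acceptance script — is far above
the ≈8% chance level but does not approach 100%.

## Outlier screening

PCA + Hotelling T² (components chosen to explain ≥95% variance, capped at
10; limit `k(n²−1)/(n(n−k)) · F(0.99; k, n−k)`) combined by union with
Tukey boxplot fences (k = 1.5) on the reference values (optionally on
PC1 scores). The union convention and the 0.99 confidence are
conservative defaults; both configurable.

## Degenerate inputs and numerical choices

Constant spectra (SNV/MSC), zero-variance references, non-uniform grids,
empty training sets, excessive pooling depth and sub-minimal split sizes
raise descriptive errors rather than propagating NaNs. R² is defined as
`1 − SS_res/SS_tot` (may be negative; `pearson2` mode available) and is
reported as NaN for zero-variance measurements. Grid-search ties resolve
toward the least complex model (smallest c, then g). All randomness in a
component flows from a single integer seed.

## Known limitations

* The CNN engine is CPU-only and single-threaded apart from BLAS; the
  4096-wide AlexNet/VGG variants train slowly at full spectral width.
* The generator's linear-in-`c` band model (quadratic in the target
  domain) is far simpler than real leaf optics; absolute RMSE values on
  the benchmark are not comparable to field studies.
* DS rank-pairing assumes the two domains sample similar reference
  distributions; under strong covariate shift the pairing degrades.
* Saliency is plain input-gradient attribution; smoothing variants are
  deliberately out of scope.
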