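# Methods

## Model

The package calibrates NIR absorbance spectra (matrix X, n samples × p
channels, default p = 700 on the 1,100–2,498 nm grid) against constituent
concentrations y (percent by weight) through three regression routes.

**CAE + MLR (the featured method).** A 1-D convolutional autoencoder is
trained unsupervised on the calibration spectra only:

    encoder  Conv1D(16, k=5, same, tanh) → MaxPool(2)
             → Conv1D(32, k=5, same, tanh) → MaxPool(2)
             → Flatten(5600) → Dense(64, tanh) → Dense(32, tanh)
    decoder  Dense(5600, tanh) → Reshape(175, 32)
             → ConvT(32, k=3, same, tanh) → Upsample(2)
             → ConvT(16, k=3, same, tanh) → Upsample(2)
             → ConvT(1, k=3, same, linear)

Max pooling is non-overlapping (stride = pool size = 2, forced by the
700 → 350 → 175 length chain); upsampling is nearest-neighbour repetition.
The decoder's transposed convolutions have stride 1 and same padding
(forced by the printed output shapes); at stride 1 a transposed
convolution is exactly a convolution with a flipped kernel, so they are
implemented as same-padded convolutions with the stated filter counts —
the trainable-parameter counts (filters·kernel·in_channels + filters) are
identical. The final layer is linear: a tanh output on centered data
would needlessly compress the reconstruction range.

Training minimises the mean squared reconstruction error with Adam
(η = 0.001, β₁ = 0.9, β₂ = 0.999, ε = 1e−8, bias-corrected moments),
batch size 8, at most 20 epochs. A seeded 20% holdout of the calibration
spectra provides the validation loss; training stops when it rises on two
consecutive epochs, and the weights of the best-validation epoch are
restored (also when the epoch budget is exhausted — the standard
convention). Weights are initialised with seeded Glorot-uniform draws;
biases start at zero. All randomness (initialisation, validation split,
batch shuffling) flows from a single integer seed, so training is exactly
reproducible. The network is plain NumPy with hand-derived reverse-mode
gradients; the test suite validates every layer's gradient against
central finite differences (relative error < 1e−4 at float64).

Prediction then uses ordinary least squares with intercept (MLR) of each
constituent on the shared 32-column latent matrix. With 60 calibration
samples and 32 latents the design is overdetermined; rank-deficient
designs raise an error naming the collinear columns (a minimum-norm
fallback is available explicitly).

**Input scaling.** Spectra are scaled by centering each channel on its
calibration mean and dividing the whole matrix by half the global
calibration range, mapping the dataset's full contrast into roughly
[−1, 1] while keeping the network's operating point at zero, where tanh
is linear at initialisation. Reconstructions are inverse-scaled before
RMSPE is computed, so percentages refer to the positive absorbance scale.
Per-channel min–max scaling (each channel stretched to [−1, 1]
independently) was evaluated and rejected: it whitens away the amplitude
structure, amplifies the small sample-to-sample variation to order one,
saturates the tanh bottleneck (|h| → 0.998), and destroys the *linear*
readability of the latents even while reconstruction stays good — the
training seed with the best reconstruction had the worst prediction R²
under that scaling.

**Baselines.** PLSR (single-response NIPALS, via scikit-learn) and PCR
(full-SVD PCA of centered X, then OLS of centered y on the leading
scores), each returned as an equivalent affine predictor
ŷ = x·β + β₀. Both center X and y on calibration means. The component
count k ∈ {1..10} is chosen per (preprocessing, family, target) by
5-fold cross-validated RMSE with seeded shuffled folds shared across all
candidates and families (paired comparisons); ties go to the smaller k;
k is clipped with a warning when a training fold cannot support it.
With all components retained on a full-rank design, both families
reproduce OLS predictions to 1e−6 — a test-suite invariant.

**Preprocessing operators.** SNV (row-wise centering and scaling to unit
sample standard deviation, n−1 denominator per chemometrics convention),
MSC (per-spectrum least-squares regression x ≈ a + b·ref against the
calibration mean spectrum, corrected to (x−a)/b; |b| < 1e−12 raises),
Savitzky–Golay (scipy implementation; defaults window 11, polynomial
order 2, derivative 0, i.e. smoothing; derivatives scale with the channel
spacing via `delta`), and mean centering. MSC and mean centering learn
state from calibration only; SNV and SG are per-spectrum and stateless.
SG edges use scipy's `interp` mode — the polynomial fitted to the last
full window is evaluated at the edge points, so output length equals
input length and no data beyond the spectrum ends is fabricated.

**Metrics.** R² = 1 − SS_res/SS_tot, RMSE, and RMSPE
(100·√mean(((y−ŷ)/y)²), per spectrum over its channels for
reconstruction quality, summarised min/max/mean/std across samples).
R² is only guaranteed in [0, 1] for a least-squares model evaluated on
its own calibration data; for out-of-sample prediction it can be
negative, and the implementation permits that. Reports round R²/RMSE to
4 decimals and RMSPE to 2.

## Synthetic study conditions

The generator follows Beer–Lambert mixing — the approximation underlying
every linear calibration method tested:

    x_i(λ) = m_i · ( Σ_k c_ik/100 · s_k(λ) + a_i + b_i·λ̃ ) + ε_i

- s_k: pure-component absorbance curves for moisture/oil/protein/starch,
  each a sum of Gaussian bands — one broad band (600–1,000 nm width)
  setting the absorbance floor plus 2–5 narrow bands (30–120 nm) as a
  fingerprint. Curves are non-negative, mixtures strictly positive
  (RMSPE needs nonzero denominators), and pairwise correlations are
  checked < 0.999.
- c_ik: compositions in percent, truncated-normal with means/stds
  matching the corn benchmark summary (moisture 10.23 ± 0.38,
  oil 3.50 ± 0.18, protein 8.67 ± 0.50, starch 64.70 ± 0.82).
- **Closure correlations (default).** Constituent percentages in real
  material respect approximate mass closure — they sum toward a stable
  total — so the dominant constituent must anticorrelate with the rest.
  The default correlation matrix sets starch vs moisture/oil/protein to
  −0.55/−0.30/−0.65 (marginals unchanged), bringing the std of the summed
  percentages to ≈ 0.37 from ≈ 1.05 under independence. This matters
  beyond realism: with independent draws, total absorbance is essentially
  a starch proxy, so a multiplicative scatter factor destroys exactly the
  information SNV/MSC also discard, and scatter correction shows no
  benefit over raw-spectra PLSR no matter how it is implemented. Closure
  decouples the constituents from the overall scale, reproducing the
  regime in which scatter correction is actually useful. Independent
  draws remain available (`composition_corr=None`).
- Artifacts: multiplicative scatter m_i ~ LogNormal(0, σ_m), additive
  affine baseline a_i + b_i·λ̃ on the normalised wavelength axis, and
  i.i.d. Gaussian channel noise. Defaults emulate a well-controlled
  benchtop instrument measuring similar samples: σ_m = 0.002,
  σ_a = 0.002 AU, σ_b = 0.001 AU, σ_noise = 1e−4 AU (a typical NIR noise
  floor). σ_m must stay well below the starch signal-to-total-absorbance
  ratio (≈ 0.013) for compositions to remain linearly identifiable at
  all — the scatter direction nearly coincides with the starch
  contribution. Scatter-dominated conditions for preprocessing studies
  use σ_m = 0.05 explicitly.
- An optional `quadratic` coefficient adds a mild Beer–Lambert deviation
  (x + q·x² on the mixture term) for experiments where a nonlinear
  feature extractor should have an edge; it is off by default.

**What the generator does and does not emulate.** It produces smooth,
positive, linearly mixed spectra with scalar scatter and affine baseline
artifacts. Real NIR data adds wavelength-dependent scatter, instrument
response functions, band shifts with temperature and moisture state,
chemical interactions violating linear mixing, and reference-method error
in y. Passing the end-to-end tests therefore demonstrates that the
pipeline recovers known structure under its stated assumptions — not that
it attains any particular accuracy on real corn spectra.

## Experiment orchestration

`run_experiment` executes the full comparison on one dataset: a seeded
random 60/20 split (sampling without replacement; one split reusable
across instruments measuring the same samples), the 5 × 2 preprocessing ×
family grid with CV component selection, and one CAE trained on the raw
calibration spectra — no chemometric preprocessing, since feature
extraction is the point — whose latents are shared by all four MLR
models. No stage ever fits on prediction data (every fit event is logged
with its data provenance, and the tests assert it). Reports carry 11 rows
per constituent; rendering flags the best prediction R² and RMSE per
target block (ties: all flagged) and appends the percent change of the
featured method's prediction R² against each baseline family's best row.

## Problem sizes in tests

Unit tests run the full 700-channel architecture only where the printed
numbers require it; training-loop behaviour is exercised on reduced
64-channel configurations, and the finite-difference gradient check uses
a tiny network (input 8, filters (2, 2), latent 2) where exhaustive
perturbation of every weight is cheap. End-to-end quality checks train
the default 700-channel model on the default 80-sample dataset with
three training seeds.

## Known limitations

- The corn benchmark's native binary format is not read; convert to the
  wide CSV dialect first (one row per sample, wavelength headers,
  `target:`-prefixed reference columns).
- Multi-response PLS2, EMSC/OSC/detrending, variable selection, outlier
  screening, and calibration transfer between instruments are out of
  scope.
- The random-search lookup table defaults (kernel {3,5,7}, latent
  {2,4,8,16,32}, batch {8,16,32}) are package choices; search trains one
  model per configuration and ranks by best validation loss with ties
  toward smaller latent width, then fewer parameters.
- Early stopping monitors a 12-spectrum validation holdout at the default
  sizes; its loss is noisy, so stopping epochs vary across seeds. The
  best-epoch restore makes this benign for the delivered weights.
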