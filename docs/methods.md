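# Methods

## The estimation problem

Tea polyphenols (TP) are the main bioactive fraction of tea leaf and a
standard quality indicator, measured destructively by permanganate
titration (`titration_to_tp` implements the conversion
X = ((A−B)·ω·0.00582/0.318)/m·(V₁/V₂); the printed formula is typeset
ambiguously and this parenthesization is the package's documented
reading). The pipeline estimates TP (%) nondestructively from two
sensor modalities and is explicitly *cross-category*: one model covers
black, green and yellow teas spanning roughly 10–30 % TP.

## Synthetic study design

The generator reproduces a 110-sample design: 10 varieties (8 with
n = 10, 2 with n = 15) whose per-variety TP mean, SD and range are
transcribed constants (`default_variety_table`). TP is drawn from a
normal distribution truncated to the variety range — the truncation
reconciles the published mean/SD with the published range. Note the
truncated mean differs from the nominal mean where the range is
asymmetric (up to ≈0.3 % for the widest varieties); tests therefore
compare Monte-Carlo means against the closed-form truncated-normal mean
rather than the nominal one.

**E-nose records.** Each sensor trace is an exponential saturation
1 + a_j·(1−exp(−t/τ_j))·(1+ε): the single-time-constant rise is the
simplest kinetic model consistent with traces that stabilize before the
55-s steady-state onset (all τ_j ≤ 13 s, so 1−e^{−55/τ} ≥ 0.98 — within
2 % of plateau). Plateau amplitudes are affine in TP with
sensor-specific sign and slope: W5S, W1S, W1W, W2S, W2W respond above 1
(W1W strongest), W1C, W3C, W5C slightly below 1, W6S and W3S near 1.
Amplitudes are perturbed multiplicatively by (i) a fixed per-(variety,
sensor) offset (SD 10 %, derived deterministically from a CRC of the
variety name) that creates genuine cross-category structure, and (ii) a
per-sample relative noise (SD 12 %); the trace itself carries 1 %
point-wise noise. In the noise-free limit every steady-state average is
strictly monotone in TP — the hook that makes recovery tests meaningful.

**Cubes.** 64 × 64 × 397 reflectance (908–1700 nm at 2 nm), float32:
smooth baseline minus Gaussian absorption features at 1106 nm (σ = 12)
and 1375 nm (σ = 18) whose depths are affine in TP (relative depth noise
12 %), multiplied by a unit-mean spatial texture field (Gaussian-smoothed
white noise, σ = 1.5 px) whose amplitude is affine in TP (relative noise
16 %), plus per-pixel noise (SD 0.004) inflated fivefold outside
944–1688 nm to motivate the spectral crop. The desk-scale 64 × 64
spatial size replaces the instrument's 636 × 815 frame; all ROI logic is
size-independent.

The noise levels above are the package's chosen study conditions: they
were set so that fused-feature validation R² of the best regressor lands
in the 0.85–0.95 regime on 110-sample datasets, with image-only models
clearly weaker — the performance ordering the method is meant to
demonstrate. What the generator does *not* emulate: real sensor drift,
inter-session calibration error, physically derived absorption line
shapes, or spatially structured sample heterogeneity (leaves vs powder).
Passing tests show the pipeline recovers signal it was designed to
carry, not that it would reach the same accuracy on real instruments.

## Feature extraction

Time-domain statistics use population moments (divisor N) for variance
and kurtosis and the adjusted Fisher–Pearson coefficient for skewness,
matching the formulary they transcribe; the integral value is the
rectangle-rule sum Σcᵢ·Δt. The steady-state onset t₀ = 55 s is global
and configurable; no adaptive onset detection is attempted. Zero-
variance traces make kurtosis/skewness undefined: the default is a
per-sensor error, with an opt-in zero-with-warning sentinel.

The CWT uses the Mexican-hat mother wavelet (a common choice for MOS
transients; the choice is configurable and recorded) at dyadic scales
2¹…2¹⁰; per-sensor energy S_j sums squared coefficients over the full
scale × time plane (the per-time-point alternative is not supported).
Scales beyond the 75-point trace rely on zero-padded convolution at the
boundaries. WM/WA are taken *across* sensors (2 scalars, not 2 per
sensor) — the only reading under which the fused bookkeeping
(18 + 2 + 6 = 26) closes.

HSI band images are the centered ROI crop decomposed with db4 in
`periodization` mode, which keeps the decimated transform orthonormal so
sub-band energies satisfy Parseval exactly (verified to 1e−9 on sizes
divisible by 4; odd intermediate sizes — e.g. level 2 of a 50 × 50
image — involve a one-sample pad and conserve energy only approximately).
WEN is the normalized-energy Shannon entropy −(1/MN)Σp·log₂p,
p = coeff²/Σcoeff², with 0·log₂0 ≔ 0: applying log₂ to raw (frequently
negative) coefficients is undefined, so the standard wavelet-entropy
definition is used deliberately. Sub-bands whose energy is below
1e−24 × image energy count as empty, otherwise the entropy would
amplify floating-point dust on constant images.

SPA builds one projection chain per start column (always adding the
column with maximal residual norm under orthogonal projection onto the
selected span), scores each chain by multilinear-regression RMSE on a
deterministic internal split (every 4th sample held out), and breaks
ties toward the lowest band index. It matches an exhaustive-search
oracle on ≤ 8-band problems. By default the pipeline re-derives the two
feature wavelengths from the data at hand (calibration samples only);
a `--wavelengths 1106,1375` override pins the canonical pair, with
nearest-band snapping (1375 nm is off the 2-nm grid and snaps to
1374 nm).

## Selection, split, models

Importance selection fits one XGBoost regressor per time-domain family
(10 features each) and scores by split-occurrence count ("weight"), not
gain; retention is ceil(0.30 × 10) = 3 per family. WM/WA always bypass
selection. Both selectors (and min–max statistics) are fit on the
calibration set only — stricter than the source protocol may have been,
but leakage-safe. Pearson selection keeps round(0.25 × 24) = 6 features
by |r|, ties by name order, zero-variance features scored 0 with a
warning.

The split holds out 3 samples per variety (7/3 per 10-sample variety,
12/3 per 15-sample variety — the unique near-7:3 per-variety rule giving
80/30 overall). Grid search minimizes 5-fold cross-validated RMSE on
calibration. Default ladders span the published ranges — SVR: 8 geometric
points each for cost ∈ (0, 20] and RBF γ ∈ (0, 10], 5 log points for
ε ∈ [0.001, 1] (the opaque published parameters are read in the libsvm
convention: c = cost, g = γ, p = ε, s = 3 ⇒ epsilon-SVR); RF:
n_estimators {100, 500, 1000, 2000} × depth {1, 3, 5, 10}, bootstrap off
(each tree sees the full calibration set, `max_features="sqrt"`
subsampling only) with one round of permutation importance; XGBoost:
learning rate {0.1, 0.3, 1} × n_estimators {100, 400, 1000} × depth
{3, 5, 10} with γ = 0.1, subsample = 0.9, min_child_weight = 5. The
published optima are grid members. Repeated end-to-end runs (the
20-dataset recovery suite and the acceptance script) use documented
coarsened ladders — SVR 4 × 4 × 2, RF {100, 500} × {3, 10}, XGBoost
{0.1} × {100, 400} × {3, 5} — to keep a full 20-dataset sweep around
five minutes on one CPU; the problem sizes (110 samples, 80/30 split,
64 × 64 × 397 cubes) are unchanged.

Adjusted R² follows 1 − (1−R²)(n−1)/(n−p−1) with p = number of model
variables and n = set size, verbatim. Published tables of this quantity
elsewhere are not always consistent with that formula at n = 30, p = 26
(which caps adjusted R² far below R²); this package reports the formula's
value and makes no attempt to reverse-engineer alternative n/p.

## Determinism and degenerate inputs

Every stochastic step threads an explicit seed (NumPy `SeedSequence`
spawning per sample; XGBoost/sklearn `random_state`; single-threaded
tree construction), so a fixed seed reproduces a byte-identical dataset
and identical winning hyperparameters. Degenerate cases are errors with
the offending sample/sensor named (trace length ≠ 75, zero-variance
trace, empty crop, ROI larger than the frame, duplicate feature names),
except where a warning-and-continue is the documented behavior
(constant features in min–max scaling and correlation scoring, empty
HSI selection).

## Known limitations

* The generator's realism is statistical, not physical; absolute
  R²/RMSE values characterize the synthetic regime only.
* SPA on smooth synthetic spectra need not pick exactly 1106/1375 nm —
  neighboring bands carry nearly identical information and the texture
  signal is band-global, so downstream accuracy is insensitive to the
  exact pair.
* The E-nose CSV dialect is a repository convention (instrument export
  layouts vary); the ENVI reader covers BSQ/BIL/BIP with the metadata
  the pipeline needs, not the full header vocabulary.
* With n = 30 and p = 26 the adjusted-R² penalty is extreme; compare
  models on validation R²/RMSE instead.
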