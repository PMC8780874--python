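# Methods

This note documents the models implemented in `aquanir`, the defaults and
why they were chosen, the numerical conventions, and the known limits of the
synthetic benchmarks.

## Data model

A dataset is an N × P absorbance matrix on an evenly spaced wavelength grid
(default 740–1700 nm at 2 nm, 481 points) with one metadata row per
spectrum: sample type (variety label + Robusta fraction in % w/w), physical
form (ground or liquid), and the acquisition hierarchy indices replicate
(independently prepared sample), refill (cuvette loading) and scan
(consecutive measurement).  The 2 nm step is an assumption, not an
instrument fact; every wavelength the analyses single out (908, 954, 1019,
1044, 1060, 1364, 1512 nm, …) lies on or within one step of this grid.
Grid uniformity is validated at construction so downstream code may assume
it.

## Synthetic mixture generator

The generator emulates a two-endmember adulteration experiment.  Endmembers
are sums of Gaussian absorption bands over a constant baseline; mixtures are
Beer–Lambert linear in the mass fraction.  Each (sample type, replicate,
refill) draws one scatter triple — multiplicative gain g ~ N(1, σ_g),
additive offset o ~ N(0, σ_o), and a linear baseline tilt t ~ N(0, σ_t)
per nm — shared by that refill's consecutive scans, since scans of one
loading share the physical presentation.  Per-point i.i.d. noise ε is drawn
per scan.  The emitted spectrum is g·A_f + o + t·(λ − λ_mid) + ε.

The default endmember pair shares the dominant water bands (970 nm and
1450 nm) and differs where the two coffee varieties differ in practice:
Robusta-associated bands at 908 and 954 nm (water shells, weakly hydrogen
bonded water) and 1364/1512 nm, Arabica-associated bands at 1018, 1036,
1044 and 1060 nm (water clusters with two to four hydrogen bonds, strongly
hydrogen-bonded water) and 1410/1488 nm.  The between-class difference
amplitude is ≈0.1 absorbance units.

Noise presets (standard deviations, chosen once):

| preset | σ_g | σ_o | σ_t (per nm) | σ_ε | intent |
|---|---|---|---|---|---|
| none | 0 | 0 | 0 | 0 | algebraic identities |
| low | 0.003 | 0.003 | 2·10⁻⁶ | 5·10⁻⁴ | high-SNR benchtop conditions; σ_ε ≈ 0.5% of the class-difference amplitude |
| realistic | 0.02 | 0.02 | 2·10⁻⁵ | 4·10⁻³ | strong enough that blends below ~2 % w/w overlap with pure Arabica |

No published noise magnitudes exist for this design, so the presets are
calibrated to reproduce qualitative behaviour (separability of pure
varieties; confusion between adjacent low fractions; monotone aquagram
patterns), not any particular instrument.  Marketed-blend sample types can
optionally be generated from a perturbed endmember pair (heights jittered
relatively, centers by a few nm) to mimic blends of different provenance.

The default designs are: liquid — mixture levels 0.5, 1, 2, 3, 5, 10, 20,
35 % w/w, pure controls 0 and 100 %, marketed blends at 10 and 30 %, each
measured 3 replicates × 3 refills × 3 scans (324 spectra for 12 sample
types); ground — the same sample types without refilling (108 spectra).

## Preprocessing conventions

- **Savitzky–Golay**: 2nd-order polynomial windows of 11, 17 or 19 points;
  the (window−1)/2 edge columns per side are dropped rather than
  extrapolated, so every retained point is a true centered fit and the grid
  shrinks accordingly.  Derivatives are divided by step^deriv to be per nm,
  keeping regression vectors comparable across grids.
- **MSC**: each spectrum is regressed on a reference (default: the mean of
  the block the correction is fit on) and inverted, (A − a)/b.  The fitted
  reference is a model artifact: validation data are corrected against the
  calibration reference, never their own mean.
- **SNV**: per-row standardization with the sample standard deviation
  (n − 1); the same ddof convention is used everywhere a standard deviation
  appears, including the aquagram.
- **Detrend**: per-row least-squares polynomial subtraction, default
  degree 2 (the usual NIR detrend), degree exposed.
- **Averaging**: scan-level averaging collapses consecutive scans,
  refill-level additionally collapses refills, replicate-level yields one
  spectrum per sample type.  Averaging does not commute with row-wise
  nonlinear steps such as SNV; chains are applied strictly in listed order.

## PCA

SVD of the mean-centered matrix (no covariance formation, no column
scaling — spectra share units).  Loading signs are fixed so each loading's
largest-magnitude element is positive, making fixtures platform-stable.

## PCA-LDA classification

LDA operates in the space of the first NrPCs principal-component scores.
With equal priors and pooled within-class covariance S_w (regularized by a
ridge of 1e-8 · tr(S_w)/NrPCs, floored at 1e-12 so exactly noiseless data
remain factorizable), assignment is to the class with the smallest
Mahalanobis distance to its centroid — the standard linear rule.
Discriminant directions (eigenvectors of S_w⁻¹S_b) are retained for plots.

Cross-validation is grouped and stratified: all rows of one replicate (its
refills and scans) stay in one fold, and each class's replicate groups are
dealt round-robin over the folds after a seeded shuffle, so every class
appears in every calibration set.  *Recognition* accuracy is the mean
calibration accuracy over folds; *prediction* accuracy is the pooled
validation accuracy; the confusion matrix (rows = true class, columns =
assigned, row-normalized percentages) is pooled over folds.

NrPC selection: among candidate counts whose prediction accuracy is within
1 percentage point of the best, choose the one minimizing the
recognition-prediction gap; ties go to the smaller count.  The 1-point
tolerance is the parameter that makes the two-criterion rule operational
and is exposed as an argument.

## PLSR

Single-response NIPALS with X and y mean-centered, never scaled.  For each
latent variable the weight vector is X_centeredᵀy (normalized), scores
t = Xw, loadings p = Xᵀt/tᵀt, q = yᵀt/tᵀt, followed by rank-one deflation.
The model is exported both as the latent decomposition and as a regression
vector b = W(PᵀW)⁻¹q with intercept ȳ − x̄ᵀb; the two prediction paths agree
to 1e-10 by construction (tested).

Cross-validation refits centering and the model per calibration fold and
pools out-of-fold predictions into one PRESS: R²CV = 1 − PRESS/TSS (TSS
about the global mean) and RMSECV = √(PRESS/N), in % w/w.  The component
count is the global RMSECV minimum with ties to fewer components; the
per-component table is reported so users can inspect the curve.  The
leave-one-scan-triplet-out scheme holds out the three consecutive scans of
one replicate refill at a time.

## Aquagram

The classical aquagram: after a preprocessing chain (default: truncate to
the overtone range, Savitzky–Golay 19/2 smoothing, MSC against the set
mean), every wavelength is z-standardized across *all* spectra passed in
(sample s.d.), and the z-values are averaged per sample group at the WAMAC
wavelengths — 890, 908, 924, 946, 954, 975, 1001, 1019, 1036, 1044, 1060 nm
for the second overtone; 1342, 1364, 1374, 1384, 1412, 1426, 1440, 1452,
1462, 1476, 1488, 1512 nm for the first.  WAMACs are looked up at the
nearest grid point; a coordinate pushed off the grid by truncation or
filter edge-dropping raises a coverage error rather than silently moving.

The normalization population is deliberately "the rows passed in": the same
samples shown against different companions produce different patterns,
which is how aquagrams are used in practice.  Standardizing against
periodic pure-water reference spectra instead of the sample population is a
possible extension, not implemented.

By construction the count-weighted mean of the group values is zero at
every WAMAC, and the pattern is invariant to a global additive offset or a
common positive scaling of all spectra.

## Experiment suite

`pipeline.run_experiment_suite` chains four experiments on one generated
dataset: (1) pure-variety PCA + PCA-LDA discrimination; (2) all-level
mixture classification with the confusion matrix ordered by fraction;
(3) PLSR quantification under both leave-scan-triplet-out and grouped
3-fold CV, first holding the marketed blends out as an external test set
(reporting their RMSEP against the cross-validated error) and then
including them; (4) aquagrams for the pure extracts (per replicate), the
blends panel, and the full level series.  Everything derives from a single
seed; two runs with the same config produce byte-identical reports.

## Problem sizes used in tests and benchmarks

The test suite and the acceptance script use the full default designs (324
liquid / 108 or 81 ground spectra, 481-point grid) for single-run checks,
and reduced designs (4–7 levels, ≤5 latent variables, truncated grids) for
multi-seed trend tests — 20 seeds for the bias and accuracy-ordering
trends, 50 permutations for the chance-level null, 10 seeds for the
aquagram monotonicity trend.  These sizes make every statistical assertion
stable without being wasteful.

## What the synthetic benchmarks do and do not show

Passing tests demonstrate that the algorithms are implemented correctly
(exact oracles), that the pipeline recovers known mixture parameters under
its own generative assumptions, and that qualitative field behaviour
(adjacent-fraction confusion, monotone WASP, external blends predicted
worse than CV suggests) emerges from those assumptions.  They do not show
performance on real coffee: real spectra have band shapes, covariance
structure, temperature sensitivity and chemistry-driven nonlinearity that a
Gaussian-band, linear-mixing generator does not attempt to model.  Reported
accuracies on synthetic data are analogs, not reproductions, of results on
physical samples.

## Known limitations

- Univariate-response PLS1 only; no OPLS, interval-PLS or multivariate y.
- No outlier detection/removal stage.
- MSC inside a chain always uses the fit-block mean; chains embedded in CV
  are applied before fold-splitting by the pipeline (the fold-refit
  guarantee covers centering, PCA, LDA and PLS artifacts).
- The aquagram implements sample-population standardization only.
- Classification assumes a balanced design (equal priors, equal group
  counts); unbalanced data raise stratification errors rather than being
  reweighted.
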