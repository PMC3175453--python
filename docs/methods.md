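# Methods

`icaclean` implements an automatic classifier of artifactual ICA components
for EEG cleaning: a second-order blind source separation, a 38-feature
description of every source component, sparse linear-programming feature
selection, a shrinkage-regularized linear discriminant, and downstream
artifact removal including a CSP motor-imagery evaluation. This note
documents the models, the numerical choices, and what the synthetic data do
and do not establish.

## Source separation (TDSEP)

The recording `X` (channels x samples, microvolts) is mean-centered,
reduced to `k` principal components (default `k = 30`), and whitened so the
zero-lag covariance is the identity. Mutually independent, temporally
correlated sources have diagonal lagged cross-covariances, so an orthogonal
demixing `V` is sought that jointly diagonalizes the whitened,
*symmetrized* lagged covariances `(C(tau) + C(tau)^T)/2` for
`tau = 1..99`. Symmetrization guarantees the applicability of Jacobi
rotations and is standard practice for this family of algorithms.

The joint diagonalizer runs pairwise Jacobi sweeps; the optimal plane
rotation for a pair is the principal eigenvector of the 2x2 Gram matrix of
`(C_pp - C_qq, 2 C_pq)` over the matrix set, which makes the off-diagonal
cost non-increasing per rotation. Iteration stops when all rotation angles
in a sweep fall below `1e-8` radians or after 100 sweeps (a warning carries
the residual cost if that cap is hit).

Composite sensor-space quantities: patterns are the PCA back-projection of
the mixing columns, filters the rows of the demixing composed with the PCA
projection. Components are ordered by descending impact
`Var(std(pattern) * source)`, with the sign fixed so each pattern's
largest-magnitude entry is positive. Sources sharing a power spectrum are
identifiable only up to rotation by any second-order method; the test suite
therefore asserts recovery for spectrally distinct sources and
pattern-level recovery for the spectrally distinct members of a scene.

## Features

All raw statistics are log-transformed. Statistics that can be non-positive
before the log (a zero range, a zero fit error, a zero filter response, a
negative histogram entropy) are floored at `eps = 1e-8` and flagged with a
`DegenerateFeatureWarning`.

**Temporal (13).** `Variance` is `log Var(std(pattern) * source)`, an
estimate of the component's impact that is invariant to the scale
indeterminacy of the decomposition; everything else is computed after
scaling the source to unit variance. Local statistics use non-overlapping
windows of 1 s and 15 s (a recording shorter than a window shrinks it with
a warning); local skewness enters as the mean absolute window skewness.
Kurtosis is logged as `log(g2 + 3)` (Pearson form, strictly positive).
Shannon entropy is histogram differential entropy (100 equal-width bins
over +-5 SD). The complexity feature is Lempel-Ziv (1976) phrase counting
of the median-binarized source, normalized by `n / log2 n`, computed on the
first 8192 samples — the parsing cost grows super-linearly and the estimate
is stable well before that length.

**Spectral (9).** Spectra are Welch estimates (1 s Hann windows, 50%
overlap, 1 Hz resolution) of the unit-variance source; the DC bin is
dropped because per-segment detrending biases it. The prototypical
spectrum shape `P(f) = k1 * f^-lambda + k2` (all parameters positive) is
fitted exactly through three anchors of the log spectrum: the value at
2 Hz and the local minima within 5-13 Hz and 33-39 Hz (band minimum, with
a flag, when no interior local minimum exists). The steepness `lambda`
solves a one-dimensional root problem on `[1e-3, 50]`; when the anchors
are inconsistent with a positive decreasing curve — typically a muscle-like
spectrum rising above 20 Hz — `lambda` is clamped at the upper bound and
`k1` clipped at the floor, which reproduces the known behaviour that
muscle spectra are approximated by a steep curve with high `lambda` and
low `k1`. Features are `log k1`, `log lambda`, `log k2` and the log mean
squared error of the fit over 2-45 Hz, plus the average log band power in
the five classical bands (0-3, 4-7, 8-13, 14-30, 31-45 Hz).

**Spatial (16).** Patterns are normalized to unit Euclidean norm. Group
means use absolute activation (the source sign is indeterminate) over
seven scalp sectors derived geometrically from the projected positions
(azimuthal-equidistant projection from the vertex; `central` is radius
< 0.35, the rest is split by azimuth at 30/75/130 degrees from the
anterior direction). The border set is the convex hull of the projected
cap. The 2D-DFT and Laplacian features interpolate the pattern linearly
onto a 64x64 grid over the bounding square (nearest-neighbour outside the
hull); the DFT feature averages the log squared magnitude over the
high-frequency half (column index >= 32) of the unshifted spectrum, and
the Laplacian feature is the log Frobenius norm after valid-mode
convolution with the standard 3x3 kernel. Border activation is +1 iff the
global extremum lies on the border, or some group peaks at its outermost
electrode at least two group standard deviations above the group mean;
both the pattern and its negation are tested, making the feature
sign-invariant.

**Current density (4).** The head is a three-shell concentric-spheres
model (radii 0.87/0.92/1.0 of a 10 cm head, conductivities 1 : 1/80 : 1),
solved per spherical-harmonic degree with a 5x5 interface system and 60
degrees of the Legendre series. Sources live on a 1 cm lattice; the 2142
grid points closest to the head centre are kept (sorted by radius with a
deterministic lexicographic tie-break — a pure radius cutoff cannot land
exactly on that count for a cubic lattice). The diagonal depth equalizer
`Gamma` carries each location's forward gain, so depth-equalized source
triplets have equal cost; the unit convention gives them gain 20, which
places the regularizer `lambda = 100` (chosen from {0, 1, 10, 100, 1000})
inside the operator's spectrum: smooth cortical topographies have gains
above it and spatially rough ones below it. This is the regime in which
the regularized minimum-norm estimate
`Gamma z = B^T (B B^T + lambda I)^-1 a`, `B = F Gamma^-1`, assigns small
norms to patterns explainable by compact brain sources and large norms to
patterns no brain source can produce. The operator is precomputed on the
115-electrode reference cap and column-subselected by channel name for
smaller caps, so values are comparable across montages (at some cost in
accuracy for small caps). The source location `(x, y, z)` is the grid
point maximizing the depth-equalized moment magnitude `|Gamma z|`; the raw
`|z|` over-boosts deep grid points and biases the peak inward. This plain
localizer resolves superficial under-cap dipoles to a median of about
1.5 cm on the reference cap; it is not a dipole fit, and individual errors
of 2-3 cm occur.

## Feature selection and classification

Features are standardized to zero mean and unit variance on the training
set. The Linear Programming Machine solves

    min  (1/n) sum_i xi_i + C ||w||_1
    s.t. y_i (w.x_i + b) >= 1 - xi_i,  xi >= 0

as an exact linear program (weights split into nonnegative parts, HiGHS).
`C` is the sparsity knob; the default `C = 0.1` keeps clearly informative
features while zeroing uninformative ones exactly. Feature ranking is the
absolute mean of the fold-wise `w / ||w||_1` over 5x10 repeated stratified
cross-validation (L1 normalization matches the machine's geometry; ties
break by canonical feature order; stratification guards against unbalanced
corpora). The retained feature count is the smallest whose
cross-validated error is within one standard error of the minimum. The
final classifier is LDA with the pooled covariance shrunk toward
`nu * I` (`nu` = mean eigenvalue) at the analytic Ledoit-Wolf intensity
(via scikit-learn's estimator); the bias places the boundary midway
between the projected class means. The reported "error" is throughout the
mean 0/1 loss of sign predictions, the quantity conventionally reported
as a percentage.

The shipped pretrained model carries the published six-feature weight
vector (current density norm 0.342, range within pattern 0.574, mean local
skewness 15 s 0.317, lambda 0.569, 8-13 Hz band power -0.219, fit error
-0.286). No bias or standardization constants are published with it, so
those were calibrated once on the package's synthetic component corpus
(seed 0) and frozen; they are a package convention, flagged as such in the
model metadata. The logistic squashing exposed as `artifact_probability`
is likewise a convention for turning scores into a surrogate probability.

## Synthetic data

The generators emulate the statistics the classifier discriminates, not
biophysics. Source kinds: band-limited alpha (8-13 Hz filtered noise),
blinks (gamma-shaped positive ~300 ms pulses at about 20 per minute, the
physiological rate, over a small pink floor), muscle (amplitude-modulated
noise high-passed at 20 Hz), line interference (50 Hz, European
convention, configurable), and pink `1/f` background. Neural sources get
dipolar patterns from the forward model at cortex-like locations (radius
4.5-7.8 cm, under the cap); blinks get an anterior gradient, muscle a
focal pattern at a border electrode, line noise a spatially white pattern.
The component corpus samples kinds at weights 0.35/0.15/0.20/0.20/0.10
(alpha/pink/blink/muscle/line) — line components are a minority of
artifacts in practice — admixes 30% pink into each time course and
perturbs patterns by 5% noise, because estimated components are never
pure. The motor-imagery surrogate plants two lateralized alpha sources
whose amplitude allocation (ratio 2.5, i.e. variance ratio 6.25) depends
on the class while a shared lognormal trial gain (sd 0.75 on the log
scale) emulates global amplitude drift: either source alone is a noisy
class indicator, their contrast a clean one, which is what makes the
retain-1 breakdown in the BCI curve diagnostic.

Passing on this corpus shows the chain is internally correct and that the
features separate the planted classes; it does not establish performance
on real EEG, where artifacts are less stereotyped, sources are mixed, and
expert labels are noisy.

## Problem sizes and defaults

The test suite and the acceptance script use desk-scale sizes chosen for
statistical adequacy: 3-source mixtures of 2 min at 100 Hz for source
recovery, 300 training plus 300 test components (64-channel cap, 120 s at
200 Hz each) for the end-to-end benchmark, 60 + 60 trials of 3 s at
120 Hz for the BCI analogue with 10 retained-count settings, and 100
paired draws for the current-density contrast. Default `k = 30` applies
to full-size recordings; the synthetic scenes use `k` equal to their
planted source counts.

## Known limitations

- Second-order separation cannot split sources with identical spectra.
- The spherical head model and the geometric electrode groups are
  idealizations; real caps need a montage file with matching names from
  the reference cap for the current-density features.
- The EDF writer is 16-bit (quantization ~1e-5 of the signal range); the
  BDF writer (24-bit) is preferred for lossless-grade fixtures.
- The pretrained model's decision threshold is synthetic-data calibrated;
  on real data a user should expect to re-threshold (or retrain) even
  though the weight vector is the published one.
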