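# Methods

`sonoderm` quantifies skin in two stages that mirror a
shear-wave-elastography (SWE) workflow for localized scleroderma (LS):
B-mode image denoising by non-local means (NLM) and a regularized
refinement of it, and quantification of an elastic-modulus map around an
outlined lesion ("shell" statistics), followed by standard diagnostic
statistics (ROC/AUC, Youden cutoff, two-group tests). Because no public
image or per-lesion data set exists for this application, all inputs are
synthetic phantoms with known ground truth; this note records the models,
the defaults and why, the numerical choices, and what the synthetic
results do and do not show.

## Noise model and denoising

The observation model is additive zero-mean white Gaussian noise on an
8-bit intensity scale: f = y + n, n ~ N(0, sigma^2) i.i.d. per pixel.
A multiplicative speckle mode (f = y·(1 + sigma·g)) exists for
ultrasound realism but is off by default; none of the shipped studies
use it.

### Classic NLM

Each pixel i is replaced by a weighted average of the pixels j in a
(2s+1)^2 search window:

    NLM[a](i) = (1/sigma(i)) * sum_j w(i,j) a(j),     sigma(i) = sum_j w(i,j)
    w(i,j)    = exp(-d(i,j)/mu),
    d(i,j)    = sum_k G_k (P_i[k] - P_j[k])^2,

with P_i the (2p+1)^2 patch around i and G a normalized Gaussian kernel
over patch offsets (s.d. `gaussian_patch_sd`, default 1 px). Defaults
p = 1, s = 5 are standard for small images. The self-weight w(i,i) is
set to the maximum of the other window weights (`max_other`), the usual
practice; `one` and `zero` are available. Boundaries are mirror-reflected
(`reflect`), which keeps patch statistics unbiased near edges; `edge`
replication is available. The filter parameter mu is tied to the noise
level as mu = 2·sigma^2 (`mu_for_sigma`): with a normalized patch kernel
the expected distance between two noisy realizations of the same clean
patch is 2·sigma^2, so structurally matching pairs receive weight around
exp(-1).

### Cosine similarity factor

The refined weight multiplies in a structural factor

    w~(i,j) = exp(-d(i,j)/mu) * ((1 + S_c(i,j))/2)^gamma,

where S_c is the cosine similarity of the two mean-centred (unweighted)
patch vectors. A constant patch has no direction: two constant patches
get S_c = 1, a constant against a structured patch gets S_c = 0. The
factor is 1 for structurally identical patches, 0 for anti-phase ones,
and leaves classic NLM exactly recovered at gamma = 0. gamma defaults
to 1. The multiplicative form was chosen because it preserves weight
positivity and is insensitive to intensity offsets, so it penalizes
structural disagreement specifically.

### MAP/ADMM regularization

The regularized variant treats denoising as maximum-a-posteriori
estimation with a Gaussian likelihood ||u - v||^2 / (2 alpha^2) (v the
noisy image, alpha the noise level) and the quadratic NLM prior
(beta/2)·u^T(u - NLM(u)). Normalizing the objective so the data weight
is one gives

    u* = argmin_u  ||u - v||^2 / 2 + (lambda/2) u^T (u - NLM(u)),
    lambda = 2·beta·alpha_hat^2,

with beta = 0.02 and alpha_hat a robust noise estimate: the median
absolute deviation of the 5-point-Laplacian response, scaled by
1.4826/sqrt(20) (the Laplacian of white noise has s.d. sigma·sqrt(20)).
The problem is solved by ADMM splitting u = y with penalty delta and
scaled dual x:

    u^k = (v + delta (y^{k-1} - x^{k-1})) / (1 + delta)
    y^k ~ argmin_y (lambda/2) y^T(y - NLM(y)) + (delta/2)||y - z||^2,
          z = u^k + x^{k-1}
    x^k = x^{k-1} + u^k - y^k.

The y-subproblem is approximated by 3 Jacobi sweeps
y <- (delta·z + lambda·NLM(y)) / (delta + lambda), with NLM weights
recomputed from each sweep iterate. Two adaptive elements control the
smoothing strength inside the prior solve:

* the filter parameter is matched per sweep to the iterate's residual
  noise, mu_k = min(mu, 2·alpha_hat(y)^2) — repeated passes on a
  progressively cleaner iterate would otherwise oversmooth;
* a Laplacian edge map (|5-point Laplacian|, border values replicated
  from the interior, normalized to [0,1] by its maximum) modulates the
  parameter per pixel as mu_k·(1 - 0.5·edge_map), reducing smoothing at
  detected edges.

Defaults: 6 outer iterations × 3 inner sweeps,
delta = max(0.2, alpha_hat/5), stopping also when the relative L2 change
of u falls below 1e-4. delta only controls the splitting dynamics, not
the fixed point; it was set small relative to lambda so the splitting
variable is driven by the prior solve while the u-update retains data
fidelity. These solver settings were selected on the layered-phantom
benchmark during development: with a single Jacobi sweep and a larger
delta the variant loses to classic NLM at sigma = 10, because the
splitting then under-resolves the prior subproblem at exactly the noise
level where classic NLM is already near the optimal bias–variance
trade-off. beta = 0 (or a noise-free input, alpha_hat = 0) returns the
input unchanged by construction.

Both denoisers are shift-equivariant (adding a constant to the input
adds it to the output) and the classic path is checked against a naive
triple-loop reference to 1e-10 on random images.

## Quality metrics

MSE uses the population 1/(m·n) normalization. PSNR = 10·log10(L^2/MSE)
with L = 255 by default, and identical images report +infinity. SSIM is
computed from whole-image statistics with the population (1/N)
variance/covariance convention, matching the MSE normalization;
stabilizers default to c1 = (0.01·L)^2, c2 = (0.03·L)^2. A windowed
mean-SSIM (uniform square windows) is available as an option. The sweep
harness averages all three metrics over independent noise seeds per
noise level for the methods {noisy, nlm, nlm_improved}.

## Elastography quantification

Stiffness is the elastic (Young's) modulus E = S/e in kPa. Around an
outlined lesion mask, the *shell* of width w mm is the set of non-mask
pixels whose Euclidean distance to the nearest mask pixel is at most
w/spacing pixels. The distance-transform definition (rather than a
composition of disk dilations) is unambiguous for arbitrary mask shapes
and exactly testable against a brute-force nearest-distance scan; the
width threshold is real-valued, with no rounding. Emax/Emean/Emin are
plain extrema/mean over the region; Esd is the sample standard deviation
(n-1 denominator, 0 for a single pixel) — the scanner convention is
unknown, and the choice is recorded here. Shell statistics are reported
for the ring alone; callers who want ring ∪ lesion can union the masks.
A shell mean exceeding the lesion mean is the quantitative "hard ring
sign". The relative modulus difference between lesion and control skin
is reported as the signed percentage 100·(E_lesion - E_control)/E_control
(the conventional form; no authoritative formula exists for this
quantity).

Thickness is measured per image column (A-line): the column is smoothed
with a centred moving average (default 5 px), and the two
largest-magnitude extrema of the axial derivative separated by at least
`min_thickness_mm` (default 0.5 mm) are taken as the entry echo and the
dermis–subcutis interface; the reported thickness is the median over
columns of their separation times the pixel spacing. The moving average
is computed by direct convolution rather than a running sum so that
gradient-plateau ties resolve identically at both interfaces; on
noise-free phantoms the recovered thickness is then exactly the
constructed one. Repeated-measurement averaging (`average_repeats`)
takes the arithmetic mean of exactly three values, matching the
three-acquisitions-per-site protocol.

## Diagnostic statistics

ROC curves are built over distinct score thresholds with the
"predicted case when score > t" rule and tied scores grouped; the
trapezoidal AUC is then algebraically identical to the Mann–Whitney
pairwise statistic with half credit for ties (asserted to 1e-12 in
tests). The operating point maximizes Youden's J = sensitivity +
specificity - 1 over midpoints between adjacent distinct scores plus the
two trivial cutoffs, ties breaking toward the smallest threshold, so the
result always agrees with an exhaustive search over all cutoffs. The
two-group comparison applies Welch's t-test when both groups pass a
Shapiro–Wilk normality check at alpha = 0.05 and a two-sided
Mann–Whitney rank-sum test otherwise; groups too small to assess (n < 3)
or with zero variance use the rank-sum branch. Stage summaries report
percentages rounded to two decimals.

## Synthetic phantoms: what they emulate, and what they do not

*B-mode phantom* (default 128×128, 0.05 mm/px — a typical high-frequency
skin-ultrasound resolution): three horizontal layers (coupling gel,
dermis, subcutis) at intensities 40/170/90 on the 8-bit scale, entry
echo at row 40 and dermis base at row 100, i.e. a 3.0 mm dermis,
consistent with sclerotic-stage skin; within-layer texture is zero-mean
Gaussian with s.d. 4. The phantom reproduces the axial layer structure
that thickness measurement relies on. It does *not* model beamforming,
attenuation, point-spread anisotropy, or real speckle statistics, so
passing tests demonstrate correctness of the measurement pipeline, not
clinical image realism. Within-layer texture is i.i.d. and therefore
indistinguishable from noise in distribution — an intentionally hard
case for denoisers, which bounds how much texture any method can
preserve.

*Elasticity phantom* (default 64×64 at 0.1 mm/px): uniform 20 kPa
background (normal dermis range), a 12 px-radius disk lesion at 60 kPa
(sclerotic lesions are several-fold stiffer than normal skin), an
optional 1 mm margin band at 90 kPa emulating the hard-ring sign, and
2 kPa Gaussian jitter (values floored at 0.1 kPa to stay physical).

*Cohorts*: per-subject scalar measurements, controls ~
N(base_mean, base_sd), cases shifted by `effect_size` standard
deviations. Defaults 50 cases / 50 controls (the study sizes this
emulates), base 1.3 mm, s.d. 0.3 mm and effect 2.2 s.d., which places
the case mean about 50% above the control mean — the reported scale of
sclerotic-stage thickness elevation. The closed-form AUC for a Gaussian
shift of delta s.d. is Phi(delta/sqrt(2)); at delta = 3 this is 0.983,
which the simulations reproduce.

The SWE study additionally draws a per-subject multiplicative stiffness
factor N(1, 0.15) to model biological between-subject variation, so
control shells are not degenerate and AUCs are non-trivial.

## Numerical choices and degenerate inputs

* All images are float64 internally; files are float32/uint8/uint16 TIFF,
  masks 0/255 PNG, tables CSV, configs JSON.
* Patch "constant" detection for the cosine factor uses a relative
  threshold of 1e-12 on the centred sum of squares.
* If every NLM weight underflows at a pixel, the filter returns the
  input value there.
* The Laplacian edge map treats images whose maximum |Laplacian| is
  below 1e-9·(max|image| + 1) as affine and returns all zeros,
  skipping normalization.
* Empty masks, empty ROIs, mismatched shapes, non-finite inputs,
  zero strain and constant images (for thickness) raise typed errors
  before any computation.
* Every stochastic operation is a pure function of (spec, seed);
  study stages derive child seeds from the global seed by hashing the
  stage name, so stages are independently reproducible.

## Problem sizes in the shipped studies

The benchmark study and test suite use the 128×128 phantom with noise
levels sigma in {10, 15, 20, 25} (10 seeds in the tests, 5 in the
acceptance script); cohort calibration uses 100 simulations for power
and 500 for the null. These sizes give stable means (the dominance
margins are reproduced across disjoint seed sets) while keeping a full
run in the minutes range on a single CPU.

## Known limitations

* The phantom's i.i.d. texture means reported MSE floors include
  unavoidable texture loss; relative orderings, not absolute values,
  are the meaningful output.
* Global-statistics SSIM on these phantoms discriminates weakly (values
  cluster near 1); the windowed variant is more sensitive but is not the
  default because the headline definition is whole-image.
* Thickness measurement assumes a horizontally layered geometry and
  isotropic spacing; oblique interfaces would need per-column interface
  tracking.
* The diagnostic study's AUCs depend strongly on the configured
  lesion/background contrast and jitter; they characterize the pipeline,
  not any patient population.
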