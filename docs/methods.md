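# Methods

## The model

A sort-seq experiment sorts cells carrying a mutagenized promoter into K
fluorescence gates and sequences each gate, yielding records (s, y) of a
sequence s and an ordinal expression bin y in 1..K.  Relative to a fixed
wild type, each of the L sites carries three binary mutation indicators
x (one per possible substitution, in a fixed cyclic code over the base
order A, T, C, G), so a sequence is a 3L-dimensional 0/1 vector with at
most one indicator set per site.  The genotype-phenotype map is modeled
as a polynomial in these indicators:

    g(y) = alpha + sum_i beta_i x_i
                 + sum_{i<j} J_ij x_i x_j          (pairwise epistasis)
                 + sum_{i<j<k} T_ijk x_i x_j x_k   (optional 3rd order)
                 + noise

with the interaction sums running over distinct *sites* (one mutation per
site per genome), giving 1 + 3L + 9 C(L,2) [+ 27 C(L,3)] coefficients —
25,201 for the pairwise model at L = 75.

`g` is a monotone non-decreasing transform of the bin labels, defined
only at the K bin values and pinned at g(1) = 1, g(K) = K to fix its
scale.  It absorbs the mean nonlinearity of the readout (logarithmic
gates, background fluorescence dominating the lowest bins) so that the
interaction terms cannot masquerade as readout nonlinearity.  g is
learned once against the additive model and then frozen for every
higher-order fit; this deliberately biases epistasis estimates downward
rather than upward.

## Fitting

* **Additive model.**  OLS with an unpenalized intercept, solved through
  the pseudo-inverse of the augmented Gram matrix (minimum-norm on
  rank-deficient designs; R^2 = 0 by convention for a constant response).
* **Bin transform.**  Alternating optimization: (a) OLS for the
  coefficients given g; (b) exact R^2 maximization over the K-2 interior
  g values given the fit.  Given the fitted values, both the residual and
  total sums of squares are quadratics in the g values, so step (b) is a
  small smooth program solved by SLSQP under the monotonicity chain,
  started at the incumbent (always feasible).  Both half-steps are
  non-decreasing in R^2, so the procedure can never end below the
  plain-OLS R^2; iteration stops when the gain falls below 1e-6 or after
  100 rounds.  Ties (flat segments) are allowed — the background-floor
  regime makes them expected.
* **Epistatic models.**  LASSO over all penalized coefficients (additive
  and interaction alike; intercept free) on the unstandardized 0/1
  features, via coordinate descent with warm starts (scikit-learn) on
  sparse design matrices.  The penalty grid is geometric from
  lambda_max = max_j |x_j . (y - ybar)| / n downward; the library default
  is 100 points spanning 4 decades.  Solutions satisfy the stationarity
  (KKT) conditions to 1e-6 on the instances the tests check.  Coefficients
  are reported as the LASSO leaves them: unpenalized refits on the
  selected support ("relaxed" LASSO) and adaptively reweighted penalties
  were both evaluated on ground-truth recovery and found to *hurt* —
  refitting un-shrinks the false-positive coefficients faster than it
  repairs the true ones.

## Model selection

Ten-fold cross-validation (seeded permutation folds, pooled held-out
R^2) ranks the penalties, but the library samples only a thin shell
around the wild type (~9% of sites mutated), so CV cannot detect
overfitting that only shows up far from the data.  The extrapolation
diagnostic is the variance of predictions over uniformly random
sequences (75% of sites mutated): it is compared per penalty against the
in-sample fitted-value variance, capped at `variance_cap_ratio` times.
Because the diagnostic exists to catch overfitting that CV misses, it
only ever makes the choice *more* constrained: the selected penalty is
the larger of the cap boundary and the CV optimum, with a warning (and a
CV fallback) if the cap fails everywhere.

The cap needs calibration to the sampling geometry.  Under a
region-blind mutagenesis rate r, library sequences carry rL mutations
against 0.75 L for uniform random sequences, so even the *true* model
predicts roughly (0.75/r)-fold higher variance for random sequences.
The analyses therefore use cap = 2.0 x 0.75/r (about 16 for r = 7/75);
the uncalibrated library default is 2.0.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes,
with one top-level seed feeding named substreams per stage:

* **Landscape.**  Additive effects are strong and mostly deleterious
  inside named binding-site blocks (default blocks: CRP1 [-75,-65),
  CRP2 [-65,-50), RNAP1 [-40,-25), RNAP2 [-15,-1) in -L..-1 display
  coordinates) and an order of magnitude weaker outside.  Pairwise
  interactions live only within/between blocks at an overall density of
  3% of all 9 C(L,2) entries; 62% of them are antagonistic (J opposing
  the shared sign of the marginals) by default.  Interaction magnitudes
  are half-normal with scale 0.4 against an additive scale of 1.0.
* **Library.**  i.i.d. per-site substitution at rate 7/75 (mean load 7),
  optionally restricted to intervals.  The study library pools three
  designs in equal thirds — whole-window, CRP-area-targeted and
  RNAP-area-targeted, each at the rate giving ~7 mutations per sequence —
  mirroring the combined multi-experiment datasets such assays produce;
  targeting concentrates the same load on fewer sites and multiplies the
  coverage of within-block mutation pairs.
* **Interaction geography.**  80% of the planted interactions join sites
  within one protein's block family (CRP1/CRP2 or RNAP1/RNAP2), 20%
  bridge the families, reproducing the near-diagonal clustering of real
  interaction maps.
* **Readout.**  The latent phenotype (log-expression scale) is floored
  at a background level, perturbed by Gaussian noise, and thresholded
  into K = 9 gates.  Default gates span the 2nd-99.5th latent
  percentiles of the library; the floor sits 0.6 gate widths above the
  lowest threshold, so the bottom bins are background-dominated and the
  learned transform should flatten there.  Noise defaults to 0.6 gate
  widths at the dim end and shrinks linearly by half toward the bright
  end: strong expressors are measured more precisely, which is also what
  makes replicate wild-type controls an *under*-estimate of the average
  noise while duplicate-disagreement gives an *over*-estimate.  A
  configurable fraction of sequences is recorded twice with
  independently re-sampled bins.

What the generator does **not** model: sequencing errors, read-depth and
count statistics, FACS optics, linkage between mutations, or any
biophysical (thermodynamic/kinetic) structure.  Passing recovery tests
therefore shows the inference machinery is correct under the stated
statistical assumptions, not that those assumptions hold for any
particular real assay.

## Noise accounting

The intrinsic-noise fraction (variance among repeated measurements of
one genotype over total variance of g(y)) is bracketed from two sides:

* duplicates: the mean within-group sample variance of g(y) over
  identical-sequence groups that span at least two distinct bins,
  divided by the total variance.  Restricting to disagreeing groups
  biases the ratio upward (an upper bound); if duplicates exist but all
  agree the estimate is 0, and with no duplicates at all it is
  undefined and flagged.
* controls: the sample variance of replicate wild-type measurements over
  the data variance — an underestimate, because the wild type is a
  bright, precisely measured sequence.

R^2 values divide by (1 - noise fraction) to give shares of the
*explainable* variance; the epistatic share is the R^2 increment of the
pairwise model over the additive one on the same scale.

## Landscape exploration

Adaptive walks model a large population in the weak-mutation regime:
from a start sequence, all 3L single substitutions are scored, strictly
improving moves are kept, and one is fixed with probability proportional
to its increment in g (the transformed bins are a log-fluorescence
scale, so the increment is already a log-scale difference; a log(1+d)
variant is available).  Walks stop at local maxima; a census over seeded
walks reports distinct endpoints, and exhaustive 4^m enumeration over
site subsets (m <= 10) gives exact maxima for cross-checking.  The
two-environment analysis counts sequences strictly better than the wild
type in both environments (higher predicted expression where expression
is wanted, lower where it is costly); a near-zero fraction places the
wild type near the Pareto front.

## Problem sizes and numerical choices

The test-suite simulations use the study-condition scales: additive
recovery at L = 20, n = 2x10^4; pairwise recovery at L = 75, n = 5x10^4
with 3% nonzero J; third-order null/control at L = 10, n = 3x10^4; noise
bracketing over 50 replicates of n = 2,500.  The heavy pairwise run uses
a 40-point penalty grid spanning 3 decades and the analysis drivers a
30-point grid — the informative stretch of the full default grid — and
cross-validation fold fits use a looser coordinate-descent tolerance
(1e-4) than the reported path (1e-8), since CV consumes only
predictions.  The analysis drivers run a 2x10^4-record library, scaled
down from the ~1.3x10^5 of the emulated assay.

Degenerate inputs: constant design columns are dropped with a warning
before penalized fits; a constant response gives R^2 = 0; bin levels
absent from the data make the transform ill-posed and raise an error;
ties in model selection resolve toward the larger penalty.

## Known limitations

* Recovery of individual weak interactions at n = 5x10^4 is at the edge
  of detectability by design (a specific mutation pair appears in tens to
  ~160 sequences depending on the library design).  An oracle OLS on the
  true support reaches a union-support correlation of ~0.92 with the
  generating coefficients; support-free sparse estimation plateaus around
  0.78 on the same data, with near-perfect (~0.99) sign agreement on the
  interactions it does recover.  More data, not a different penalty, is
  what closes that gap.
* The transform optimizer finds a stationary point of an alternating
  scheme; with heavily degenerate bin occupancies the interior g values
  can be under-determined (flat segments are then reported).
* The walk census is exact only relative to the fitted model; endpoints
  tens of mutations from the wild type are extrapolations and say
  nothing about the real system's distant landscape.
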