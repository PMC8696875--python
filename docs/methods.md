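# Methods

This note records the models, the defaults and the judgement calls behind
them, and what the synthetic data can and cannot establish.

## Composite indices

All scores use min–max normalisation with the extreme values taken over
the *whole* analysed table (all floral types pooled). Per-type pooling is
not offered as a default because the index is meant to compare samples
across types; the scoring functions accept any subset table, so a user who
wants within-type extremes can simply pass a subset.

RACI averages four scores (TPC, TFC, TCC higher-better; DPPH IC50
lower-better). Including DPPH IC50 in RACI follows the orientation rule
that names DPPH among the lower-better assays; it is a documented modelling
choice, not separable from the index definition here. RAI averages eight
lower-better MIC scores. Power of Honey = (RACI + RAI)/2 exactly.

Censored MICs (">37.5" % w/v) must be made numeric before scoring. The
default imputes 75.0, the next two-fold dilution step above the grid, which
preserves the penalty ordering (censored is strictly worse than every
on-grid value). Alternatives: `grid_max` (censored scored like 37.5 —
flattens the penalty) and `nan` (caller excludes). Missing assay values are
an error: the index is undefined on incomplete panels unless the user
explicitly opts into a policy.

Degenerate ranges (max = min) raise an error naming the variable; a
constant assay carries no ranking information and silently scoring it 0 or
1 would bias the average.

## The synthetic cohort

The generator emulates the study design: 100 samples, 25 per floral type
(acacia, sunflower, meadow, forest), with

1. **pooled pairwise Pearson correlations equal to the reported
   coefficients**, and
2. **the reported qualitative floral-type contrasts** (forest: highest free
   acidity, a\*, bioactivity, lowest L\*; acacia/meadow: highest L\*).

Mechanism: Gaussian copula. A 23-variable latent normal vector (15
continuous fields + 8 latent MIC "resistance" scores) is drawn per sample;
continuous fields go through truncated-normal marginals with
floral-type-specific locations; MICs are cut at pooled empirical quantiles
onto the dilution grid (probability mass 5/10/20/30/25 % on
2.3/4.6/9.3/18.7/37.5 % w/v and 10 % censored), monotonically in the
latent score.

Three numerical choices matter:

- **Correlation completion.** The ~30 reported coefficients with zeros
  elsewhere form an indefinite matrix (e.g. TFC–L\* = −0.8305 and
  TFC–b\* = 0.7395 jointly force L\*–b\* strongly negative, so 0 there is
  infeasible). Plain eigenvalue clipping would smear the error across the
  *reported* cells (drift up to 0.29). Instead the completion pins the
  reported cells and adjusts only unreported ones by alternating
  projections (clip negative eigenvalues → restore pinned cells and unit
  diagonal → repeat), finishing with one clip-and-rescale pass. On this
  fixture the completion converges: reported cells are preserved to ~1e−12.
- **Between-type compensation.** Type mean shifts add between-group
  covariance, so pooled correlations would overshoot the within-type ones.
  The within-type latent matrix is therefore set to
  C_w[ij] = R[ij]·√((1+B[ii])(1+B[jj])) − B[ij], with B the covariance of
  the standardized type offsets, and then PSD-completed with the
  reported-pair cells pinned. The reported coefficients are read as pooled
  over all 100 samples (whether the original correlations were pooled or
  within-type is not stated; pooled is the natural reading for a single
  correlation table).
- **Marginal placement.** Locations/scales sit inside legal honey ranges
  (e.g. moisture 17.5 ± 1.3 % w/w, free acidity 22 ± 7 meq/kg, TPC
  80 ± 20 mg GAE/100 g, DPPH IC50 60 ± 12 mg/mL), with truncation bounds
  kept ≳3 SD from the bulk so the monotone marginal transform distorts
  Pearson correlations negligibly. Type offsets are ±0.6–1.0 SD — large
  enough that the type contrasts hold essentially surely at n = 25/type,
  small enough to leave the compensated matrix feasible.

Verified behaviour (tests): at n = 10,000 every reported coefficient is
recovered within ±0.03 (worst observed drift ≈ 0.02, consistent with
Monte-Carlo noise); at the default n = 100 the type contrasts and the
forest-highest Power of Honey ordering hold.

**What the generator does not emulate:** assay noise structure, units-level
measurement error, within-type substructure (e.g. country effects are
decorative labels only), higher-order dependence beyond the Gaussian
copula, and any marginal shape beyond the truncated normal. In particular,
multivariate predictability is *emergent*: only pairwise correlations are
controlled, so the Power of Honey is less predictable from (free acidity,
L\*, a\*) here (linear ceiling R² ≈ 0.57) than in the original data.
Passing tests establish the machinery and the encoded structure, not
real-data effect sizes.

The seed default is 20180101; one `numpy.random.default_rng` instance per
generator call drives every draw, so tables are bit-reproducible.

## The network

3-10-1 logistic MLP, Y = f1(W2·f2(W1X + B1) + B2) with f1 = f2 = logistic.
The published tables fix all 51 parameters and are embedded verbatim
(input row order L\*, a\*, free acidity). The normalisation ranges used by
the original fit were not published, so predictions from the published
weights require a user-supplied `NormalizationSpec`; the shipped default
uses the synthetic generator's nominal ranges (L\* 15–95, a\* −8–15, free
acidity 1–55 meq/kg, output 0–1) and is explicitly non-canonical —
absolute reproduction of the original predictions is not possible from the
published information.

Training minimises sum-of-squares on min–max-normalised data by BFGS
(scipy), from uniform [−0.5, 0.5] initial weights, best of 10 restarts by
validation SOS, max 400 iterations, gradient tolerance 1e−8, with
backpropagated analytic gradients. **Early stopping** is on by default: the
returned weights are the iterate along each trajectory with the lowest
validation SOS. With 51 parameters and 60 training rows a fully converged
fit memorises the training split (observed test r² of −0.58 on the default
cohort versus +0.56 with early stopping); a reported stopping iteration as
small as 12 only makes sense under such validation-based selection.
`FitReport.n_iterations` is that selected iteration.

Split sizes use largest-remainder rounding so 60/20/20 fractions sum
exactly to n (100 → 60/20/20, 10 → 6/2/2); the partition is a seeded
shuffle, disjoint and exhaustive.

Recovery properties (tests): data generated noiselessly from the published
network are refit to train r² ≥ 0.999 (the function is exactly realisable;
weights themselves are not identifiable due to hidden-unit symmetry); with
Gaussian noise sd 0.02 on 500 rows the refit reaches test r² ≥ 0.95.

## Sensitivity analysis

Exact derivative of the logistic network,
∂y/∂xᵢ = y(1−y) Σⱼ w2ⱼ hⱼ(1−hⱼ) w1ᵢⱼ, evaluated on a 10-point equally
spaced grid per input spanning that input's [min, max] (endpoints
included), other inputs at the midpoint of their ranges (configurable to
explicit values). Derivatives are reported on the raw scale via the chain
rule (× out-span / in-span). The finite-difference column uses the
+0.0001 % relative forward perturbation; a central-difference mode exists
for verification, where the round-off-optimal relative step is ~1e−5
(eps^⅓): smaller steps lose to subtractive cancellation before reaching a
1e−6 relative agreement band. At exactly 0 the relative step degenerates,
so an absolute step of 1e−8 is substituted.

## PCA

Correlation-matrix PCA (standardised variables) over free acidity, L\*,
a\* and Power of Honey — the variables carry incommensurate units, so
covariance PCA would be dominated by free acidity. Eigen-decomposition via
`numpy.linalg.eigh`; components ordered by descending eigenvalue; sign
fixed by making the largest-magnitude loading of each component positive.
Contributions are squared unit-eigenvector entries × 100 (sum to 100 per
component). Whether the original ordination standardised is not stated;
standardisation is assumed and is the package default
(`standardize=False` gives covariance PCA). Explained variance on the
default synthetic cohort (PC1+PC2 ≈ 81 %) is reported, not asserted against
any external figure — it is a property of the emulated, not the real,
data.

## Pipeline

`run_pipeline` chains data → indices → training → sensitivity → PCA,
writing CSV/JSON artifacts with a fixed float format ("%.10g") so repeated
runs with one configuration are byte-identical. Any stage failure raises a
stage-named error and is recorded in the run log; a table too small to
train (< 20 rows) still gets its indices before the training stage refuses.

## Known limitations

- Absolute predictions from the published weights depend on an unpublished
  normalisation; only the function's *shape* is reproducible.
- The generator controls pairwise structure only; joint higher-order
  behaviour, and therefore any multivariate statistic not pinned by
  pairwise correlations, will differ from the original data.
- Grid MICs are interval-censored by nature; treating the censored class
  via single-value imputation is a pragmatic scoring device, not a survival
  model.
- PCA group separation at n = 25/type is seed-dependent in detail (centroid
  geometry), though the encoded orderings are stable.
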