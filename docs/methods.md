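# Methods

This note documents the statistical models behind `multicna`, the
parameters that matter, the design choices made where several defensible
options existed, and what the synthetic validation does and does not show.

## Data model and conventions

All signals are dense P × I matrices over a shared marker map
(`marker_id`, `chromosome`, `position`).  Marker positions are 1-based
points; emitted segment intervals are 0-based half-open (BED), bounded by
the positions of the first and last marker of the segment.  Chromosomes
are ordered 1..22, X, Y and a leading `chr` prefix is stripped on read.
Missing values are not permitted — every downstream algorithm assumes a
dense per-chromosome series — so callers must impute or drop markers
upstream.  Allele B fractions outside [0, 1] (a common artifact of
upstream normalization) are clipped with a warning; negative copy numbers
are rejected.

Count data (e.g. sequencing coverage) can be brought to the Gaussian
regime with `anscombe_transform` (2·√(x + 3/8)), which stabilizes the
variance of Poisson-like counts near 1 for large means.

## Segmentation

Within a chromosome the signal is modelled as piecewise-constant plus
homoscedastic Gaussian noise, so the fitting contrast is the
within-segment sum of squares (SSE).  The homoscedastic form is the one
consistent with both penalties below; per-segment variances are a
non-goal.

**Fixed-K dynamic program ("cghseg" route, default).**  For K = 1..Kmax
the exact optimum is found by the classical O(Kmax·P²) recursion, with all
pairwise segment costs obtained from prefix sums (the full P × P cost
matrix is materialized for P up to a few thousand, which covers
per-chromosome marker counts after array downsampling; memory is the
practical limit).  Kmax defaults to min(P/2, 30).  When two partitions tie,
the earlier breakpoint wins, making results deterministic.

**Penalty and slope heuristic.**  The segment count is chosen by
minimizing SSE(K) + C·K·(2.5 + log(P/K)).  C is calibrated by the slope
heuristic: in the overfitting regime the contrast decreases approximately
linearly in the penalty shape s(K) = K·(2.5 + log(P/K)), so a robust
(Theil–Sen) line fit of SSE(K) against s(K) over the largest-K half of
1..Kmax estimates the slope −ŝ, and C = 2ŝ (the factor-2 rule).  The fit
range is configurable.  A flat contrast (constant series) falls back to a
scale-aware positive C so that K = 1 is selected.

Calibrating per chromosome (rather than per genome) keeps the noise
estimate local; this mirrors the chromosome-by-chromosome processing of
the whole pipeline.

*Known limitation.*  The factor-2 rule occasionally keeps one spurious
segment: on profiles with 3-σ jumps, roughly 6% of replicates select K
one too large, because the best spurious split can absorb more than
2σ̂²·Δs of noise.  The companion localization error (a true breakpoint
missed by more than 2 markers at a 3-σ jump) affects ~2% of profiles.
Users who need harder guarantees should inspect the K-vs-penalty curve or
use the PELT route with a manually raised ρ.

**PELT route.**  Minimizes SSE + K·ρ·log(P) exactly; pruning uses the
standard validity condition for additive concentrated costs (pruning
constant 0), so the solution equals unpruned optimal partitioning.  ρ is
calibrated by a *stability plateau*: pelt is run over 40 log-spaced ρ
values spanning [0.05, 50]·σ̂², where σ̂² is a robust noise variance
estimate (squared MAD of first differences, halved); the returned ρ is the
geometric midpoint of the widest log-ρ interval with constant K(ρ).  Ties
prefer smaller K, then larger ρ.  The rationale: segmentations that
persist over a broad penalty range are not noise artifacts.  This
calibration is this package's own construction (simple, deterministic, and
exactly scale-equivariant: scaling the data by a scales ρ by a²); other
calibrations of ρ exist and may differ.  Series shorter than 20 points
fall back to ρ = σ̂² with a warning.

The default route is the fixed-K one because a single DP sweep is cheaper
than the ~40 PELT runs the ρ calibration requires.

## Allele-B-fraction preparation

Naive genotyping of the matched normal uses symmetric tercile thresholds
(AA below 1/3, BB above 2/3, AB in between, boundaries inclusive for AB);
the thresholds are configurable.  On BAF bands typical of normalized
arrays (AA ≈ N(0.03, 0.02), AB ≈ N(0.5, 0.04), BB ≈ N(0.97, 0.02)) this
rule is >99% accurate per class.  Genotyping is restricted to normal
samples — tumor aberrations break the bi-allelic clustering — which is why
BAF segmentation requires a normal/tumor pairing table and refuses
tumor-only input.

Mirroring maps b to max(b, 1−b), the upper-half convention of mirrored-BAF
practice, giving a one-sided signal in [0.5, 1] (0.5 = balanced, →1 under
LOH) that is segmented with the unchanged copy-number machinery.  Note the
mirrored noise is folded-Gaussian (and LOH bands are clipped), so the
Gaussian segmentation model is mildly misspecified there; in validation
this occasionally costs an extra spurious segment but not boundary
accuracy.

## Calling

Segment means are taken to log2(CN/2) (copies floored at 0.05 before the
log), corrected for cellularity, and fitted with a three-component
Gaussian mixture: ordered means μ_loss < μ_normal < μ_gain, one shared
variance, mixing weights, each segment weighted by its probe count.
Design choices, in order of consequence:

* **Diploid anchoring.**  The normal component's mean is constrained to
  [−0.2, +0.2] log2; loss below −0.2, gain above +0.2.  Without it, EM on
  a profile that lacks one of the three states re-purposes the free
  component to split the diploid cluster.  The ±0.2 band matches the
  threshold-fallback cutoffs, and one-copy events at typical purity sit
  well outside it (±0.58/−1).
* **Shared variance.**  Unconstrained per-component variances exhibit the
  classical narrow/broad degeneracy (a wide component absorbing scattered
  segments across state boundaries); the homoscedastic mixture matches
  the segmentation model's noise assumption.
* **Deterministic EM.**  Initialization at the weighted 0.1/0.5/0.9
  quantiles (normal at the weighted median), equal weights, pooled sd; no
  random restarts, so calling is reproducible without seeds.
* **Per-sample fit.**  Each profile is called separately (`pooled=True`
  fits one mixture across the cohort for very small profiles).  Fewer
  than 10 segments or fewer than 3 distinct means raise a degenerate-fit
  error; `threshold_fallback=True` then labels by fixed cutoffs (log2
  ratio < −0.2 loss, > 0.2 gain).

Labels are maximum-posterior; exact posterior ties resolve to `normal`;
the three posterior probabilities are kept as columns.

**Cellularity.**  c ∈ (0, 1] is the tumor-cell fraction; the observed
ratio is modelled as c·r_tumor + (1−c) and inverted on the ratio scale
(with a floor at 0.025 to keep logs finite) before fitting.  c = 1 is the
default ("pure tumor") and is exactly the identity.  The inversion is this
package's formulation of the dilution model; only the parameter and its
default are inherited from common calling practice.  With c
correctly supplied, calling diluted data matches the pure-data calls in
validation; leaving c = 1 on diluted data compresses the aberration
amplitudes and degrades loss/gain sensitivity.

## Marker selection

The objective for a continuous outcome is the un-halved lasso criterion
g_λ(β) = Σ(yᵢ − (Xβ)ᵢ)² + λΣ|βₚ|.  Consequences of this convention:
λ_max = 2·max_p |x_pᵀy| on centered data, and the orthonormal-design
solution is the soft threshold S(β̂_OLS, λ/2).  Columns are standardized
to unit variance internally (the field default when markers have
heterogeneous scales); reported coefficients are mapped back to the input
scale.

**LARS homotopy.**  The full piecewise-linear path is computed with
variable addition *and* deletion, i.e. it is the exact lasso path, not
plain forward LARS.  The active Gram matrix carries a Cholesky factor that
is updated on additions (O(I·|A| + |A|²) per knot) and recomputed on the
rare deletions.  Ties (e.g. duplicate columns) admit the lowest column
index; zero-variance columns are excluded.  The path stops at λ = 0 or
when the active set reaches min(I−1, P).  KKT residuals at every knot are
below 1e−8 (relative to λ_max) by construction and are asserted in the
tests against an independent coordinate-descent solver.

**Cross-validation.**  λ is chosen on a grid of 100 log-spaced values from
λ_max down to λ_max/1000, by k-fold CV (k = 10 by default, k = I below 10
patients), stratified by outcome quantile (continuous) or class (binary),
with the fold split seeded and recorded.  The default rule is the minimum
mean CV error; the 1-SE rule is available by flag.  Min-CV lasso
deliberately over-selects a little (small-coefficient companions alongside
the true markers); this is the standard trade-off favoring sensitivity.

**Binary outcomes.**  L1-penalized logistic deviance (intercept
unpenalized; λ_max = max_p |x_pᵀ(y − ȳ)|), minimized by IRLS with
coordinate-wise soft-threshold updates, warm starts along the grid,
sequential strong-rule screening with a full KKT check, and convergence
when the largest coefficient change falls below 1e−7.  This route is fast
but iterative rather than path-exact; at λ → 0 it agrees with an
unpenalized logistic fit to ~1e−4.  Under (quasi-)separation coefficients
are bounded only by the penalty; a warning is raised.

**Optional smoothing.**  `smooth_segments` replaces marker values by their
segment means before selection (noise and effective-dimension reduction);
selection then operates on the piecewise-constant design.

## Synthetic cohorts

The generator emulates exactly the structure the methods assume: latent
integer copy states (regions with a carrier fraction per patient), CN =
c·state + (1−c)·2 + N(0, sd) floored at 0; germline genotypes from
per-marker allele frequencies (uniform 0.05–0.95, Hardy–Weinberg); normal
BAF in the three bands above; tumor BAF from the per-region allelic fate
(loss → het SNPs at 0/1, gain → 1/3 / 2/3) mixed with diploid signal by
cellularity; outcome linear (or logistic) in the observed values at causal
markers.  A single seed feeds named substreams (carriers, noise,
genotypes, BAF, response) so adding an output never perturbs the others;
everything is bitwise reproducible.

It does **not** simulate probe-level intensities, GC waves, batch or
dye effects, wavy baselines, or marker-specific noise — so passing
validation demonstrates correctness of the algorithms under their stated
model, not robustness to real-array artifacts.

The five standard validation cohorts (`default_validation_suite`, seeds
11–15):

1. *segmentation-recovery* — 200 profiles × 1000 markers, states 2/1/3/2
   (copies) with boundaries after markers 217/504/789, noise sd 1/3 (the
   smallest jump is 3σ).
2. *pure-noise* — 100 flat diploid profiles, noise sd 1.
3. *calling* — 20 profiles, two chromosomes, one loss + one gain region
   per chromosome (≥ 20 probes each), noise sd 0.2 (≈ 0.15 on log2 at the
   diploid level).
4. *linear-selection* — 100 patients × 1000 markers, five single-marker
   causal gains (carrier fraction 0.5, effect 1.0, outcome noise sd 0.5 so
   the per-marker effect-to-noise ratio is ≈ 1.1), plus wider non-causal
   decoy regions.  Causal CNVs are single-marker by design: a wide causal
   region would contain many nearly-collinear columns and the lasso could
   legitimately pick a sibling, making "the planted marker was selected"
   ill-posed.
5. *logistic-selection* — 200 patients × 500 markers, three single-marker
   causal CNVs with logistic coefficients +2/−2/+2.

## Numerical choices

* Segment means are computed from slices, not prefix-sum differences, so
  constant data yields exactly the constant (no 1-ulp overshoot of, e.g.,
  mirrored-BAF bounds).
* Text writers emit floats with 17 significant digits and readers parse
  with round-trip precision, making every write→read cycle bit-exact —
  the basis of the pipeline's determinism guarantee.
* EM stops on relative log-likelihood change < 1e−10 (cap 500 iterations);
  component sd floor 1e−3.
* PELT's pruning tolerance is 1e−12 on the cost scale; DP tie-breaks are
  always "earliest breakpoint" / "lowest column index".
* The logistic solver clamps IRLS weights at 1e−5 and linear predictors at
  ±30 to keep the working response finite.

## Validation problem sizes

The test suite checks every recovery property at its full study size
(e.g. 200 profiles for breakpoint recovery, 100 cohorts per selection
route); unit tests exercise the same properties at reduced replicate
counts.  `scripts/acceptance.py` recomputes the headline numbers with
100 profiles (breakpoint recovery), 60 noise profiles, 100 LOH replicates,
30 random instances for the lasso/DP oracle comparisons and 30 cohorts per
selection route — sizes chosen to keep a full from-scratch rerun within a
few minutes on a single CPU while leaving Monte-Carlo error on reported
rates below a few percentage points.
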