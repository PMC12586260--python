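# Methods

## Measurement model

All computations assume the graded response model (GRM) in the pure
logistic metric (no 1.7 scaling constant), slope–threshold
parameterization: for an item with discrimination a > 0 and ordered
thresholds b_1 < … < b_{K−1},

    P(X ≥ k | θ) = 1 / (1 + exp(−a (θ − b_{k−1}))),    k = 2..K,

with category probabilities as adjacent differences. This is the convention
of the PROMIS calibrations that define the target metric; the T metric is
the fixed linear map T = 50 + 10·θ. Categories are coded 1..K everywhere,
matching instrument scoring (the 10-item scale is scored 1–3, raw sums
10–30; the 20-item anchor 1–5).

Missing responses contribute nothing to any likelihood (ignorable
missingness). Persons who left an entire questionnaire blank are removed by
the screening step, not by the scoring code; partial patterns are scored on
their observed items without proration, because EAP handles them natively
(the half-scale proration rule is a sum-score convention that has no place
in pattern scoring; the crosswalk side enforces complete cases instead,
since a raw sum requires every item).

## Quadrature and scoring

The latent prior is discretized on an equally spaced grid, by default 49
nodes on [−6, 6] with standard-normal weights renormalized to 1. Against a
2001-node dense grid this resolves EAP estimates to ~1e−3 in θ — an order
of magnitude below the 0.1-T reporting precision — while keeping every
E-step a small matrix product. The scoring prior is N(0,1) for both
instruments and is never sample-centered: T = 50 + 10θ is only meaningful
relative to the fixed reference metric.

EAP posterior moments are computed in log space (log-sum-exp) so floor or
ceiling patterns on high-slope items cannot underflow. With zero observed
items the posterior equals the discretized prior; scorers drop such persons
by default and count them in `n_dropped_`.

## Crosswalk construction

`summed_score_likelihoods` implements the Lord–Wingersky recursion over
items: the distribution of the category-sum given θ is convolved one item
at a time, giving L(s|θ_g) for every achievable sum (columns sum to 1).
Summed-score EAP against the same N(0,1) prior yields one (θ, SE, T, T-SE)
row per raw score. Lookup is exact; the tabulated range is mathematically
exhaustive for the generating bank, so an out-of-range raw score is treated
as corrupt input, not extrapolated. The table CSV round-trips bit-exactly
(full-precision reprs plus `#` metadata lines) so externally published
tables can be loaded in place of internally built ones.

One caveat the implementation respects: monotonicity of the summed-score
EAP in the raw score is *not* a theorem for the GRM — monotone likelihood
ratio of the summed score holds for partial-credit-family models but can
fail for graded models with sufficiently heterogeneous slopes. Within the
instrument-realistic parameter family used throughout (slopes ~1.2–3.5,
ordered thresholds with moderate gaps) no violation occurs, and the
pipeline's consistency checker (`derive_summary_checks`) flags any
non-monotone table rather than silently accepting it.

## Fixed-parameter calibration

Re-estimation is marginal maximum likelihood by EM on the quadrature grid.
The E-step computes per-person posterior weights using all observed items —
fixed anchors plus current free parameters — under the N(0,1) prior; the
latent density is *not* re-estimated, because fixing both the anchors and
the prior is what keeps the metric anchored. The M-step maximizes, per free
item, the expected complete-data log-likelihood, which depends on the data
only through a G × K table of expected counts; the maximization runs over
(log a, b_1, log threshold-gaps) so positivity of the slope and strict
threshold ordering hold by construction. The inner maximizer is L-BFGS-B
with box bounds (a ∈ [0.05, 12], b_1 ∈ [−8, 8]); an update is accepted only
if it does not decrease the expected complete-data objective, preserving
the EM ascent guarantee, and the marginal log-likelihood trace is checked
to be nondecreasing (tolerance 1e−6). Convergence: maximum absolute
parameter change < 1e−4, at most 500 cycles; non-convergence returns a
result with `converged=False` rather than raising.

Starting values are a = 1.5 with thresholds at normal quantiles of the
observed cumulative category proportions (clipped to ±3.5, nudged to strict
ordering). Categories observed fewer than 5 times are collapsed into their
neighbor toward the modal category before estimation (logged mapping);
thresholds for near-empty categories are not identifiable at desk-scale n.

## Assumption checks

The dimensionality diagnostics run on the polychoric correlation matrix of
the pooled 30-item set. Polychorics use the standard two-step estimator:
thresholds from the marginals, then one-dimensional ML for ρ over
(−0.999, 0.999), with bivariate-normal rectangle probabilities computed by
Gauss–Legendre quadrature along the correlation path (48 nodes, ~1e−7
accuracy). Perfectly concordant tables short-circuit to ρ = ±1; pairs with
a constant margin fall back to Spearman with a warning.

The one-factor fit is unweighted least squares via iterated principal-axis
extraction (Heywood communalities clipped at 0.995). The discrepancy is the
sum of squared off-diagonal residuals; T = (n−1)·F gives a χ²-type
statistic from which CFI, TLI and RMSEA are formed against the independence
baseline, and SRMR is the RMS residual correlation. This deliberately
approximates the robust weighted-least-squares estimators used in
confirmatory software — index values on real data would differ somewhat,
so the printed benchmark flags (CFI > 0.95, TLI > 0.95, RMSEA < 0.06,
SRMR < 0.08) are configurable conventions, not reproduction targets.

Bifactor indices come from Schmid–Leiman orthogonalization of an oblique
(promax, power 4) principal-axis solution with, by default, 4 group factors
(the physical-function subdomains: mobility, dexterity, central regions,
complex activities). A one-factor model of the factor correlations supplies
the second-order loadings γ; general loadings are Λγ and group loadings
Λ·diag(√(1−γ²)). ECV = Σλ²_gen / Σλ²_all and
ω_H = (Σλ_gen)² / [(Σλ_gen)² + Σ_f (Σλ_f)² + Σ uniqueness]. Exploratory
Schmid–Leiman ECV is biased downward when the general factor is only
moderate — with loadings ~0.5–0.85 pure one-factor data yields ECV ≈ 0.82 —
so the "pure one-factor ⇒ high ECV" behavior is demonstrated at
physical-function-typical loadings (0.7–0.9).

DIF screening fits, per item, three nested proportional-odds logit models
(statsmodels `OrderedModel`): M1 item ~ trait, M2 + group dummies,
M3 + trait × group. The matching trait is the pooled-item EAP under the
current parameters, single pass, no iterative purification (purification is
not part of the default screen). Nagelkerke R² uses the intercept-only
log-likelihood as the common baseline for every model, so
ΔR² = R²(M3) − R²(M1) is a difference of comparable quantities; ΔR² > 0.03
flags potentially relevant DIF, jointly testing uniform and non-uniform
effects. Null simulations at n = 1000 over 30 items produce ΔR² well below
0.01; a planted uniform threshold shift of 1.0 produces ΔR² ≈ 0.08.

## Agreement statistics

Direction convention: differences are observed (benchmark) − linked, so a
negative MD means the linked scores sit above the benchmark. The SD of
differences uses n−1, so RMSE² = MD² + SD²·(n−1)/n holds as an identity and
is re-verified on every report. The paired SMD divides MD by the pooled SD
of the two score sets, √((SD_obs² + SD_linked²)/2) — the denominator under
which published MD/SD/SMD triples are mutually consistent, whereas an
SD-of-differences denominator is not. |SMD| < 0.2 is read as negligible.
Bootstrap CIs are percentile intervals over B = 1000 person-level resamples
with a mandatory seed; Bland–Altman output is the per-person
(average, difference) records, MD ± 1.96·SD limits, and a least-squares
trend of difference on average per subsample (omitted below n = 3). Report
tables round to 2 decimals, half away from zero.

## Synthetic data generator

The generator emulates the validation study's structure: three clinical
subsamples (cardiology n=185, rheumatology n=172, psychosomatic n=262;
initial recruitment 201/200/266 when contamination is simulated) with
latent traits θ ~ N(−0.65, 0.78), N(−1.06, 0.90), N(−0.60, 0.86) — the
published T summaries mapped by θ = (T − 50)/10, the only transform the
metric admits. The anchor bank is 20 items × 5 categories with slopes
U(1.5, 3.5) and threshold centers U(−2.5, 1.0) at fixed offsets
(−1.5, −0.5, +0.5, +1.5); the linked bank 10 items × 3 categories with
slopes U(1.2, 3.0), centers U(−2.5, 0.5), offsets ±0.8. Under these ranges
the 10-item scale's marginal reliability is ≈ 0.85–0.90, consistent with
the observed between-instrument correlation of ≈ 0.88. Responses are drawn
category-wise from the GRM probabilities; all randomness flows through
explicit seeds.

Two contamination processes mirror the exclusion screen's targets: a
random subset of persons answers the linked scale with reversed coding
(k → K+1−k), and a disjoint subset leaves one instrument entirely blank
(defaults 43/667 and 5/667). The screen drops wholly missing instruments
unconditionally and flags probable reversed coders by either of two
heuristics: the joint marginal likelihood of the full pattern improves by
more than 5 nats when the linked codes are reversed, or the standardized
within-sample person scores on the two instruments differ by more than 3 SD
with opposite signs. Both thresholds are conventions of this package
(argument-exposed); evaluated against planted truth they achieve aggregate
sensitivity ≈ 0.96 at false-positive rate ≈ 0.0003 under the default
conditions. No claim is made that they reproduce the original study's
specific exclusion counts beyond expectation-level emulation.

What the generator does *not* emulate: multidimensional residual structure,
subdomain group factors, DIF between clinical samples (available only as an
option for power tests), item-level missingness patterns, or response
styles other than wholesale reversal. Passing tests therefore demonstrate
correctness of the machinery under the model's own assumptions — they do
not certify that real PF-10 data satisfy those assumptions, which is
exactly what the assumption-check module is for.

## Problem sizes and numerical choices

Default test and pipeline runs use the study-scale n = 619 (667 when
contaminated), 49-node grids, B = 1000 bootstrap resamples, and
recovery simulations at n = 500–4000; a full synthetic validation run
completes in seconds on one core. Degenerate inputs are handled explicitly:
zero-variance score vectors report r as missing rather than NaN,
all-missing patterns return the prior with the person counted, empty
observed categories collapse with a logged mapping, and non-PSD polychoric
matrices are repaired by eigenvalue clipping at 1e−6 before factoring.

## Known limitations

* The factor-fit indices are ULS approximations; they are comparable across
  runs of this package but not numerically interchangeable with robust
  WLSMV output from confirmatory software.
* Equipercentile linking is out of scope by design.
* The crosswalk assumes the raw sum is formed from complete responses;
  no proration rule is provided.
* Calibration assumes the sample is exchangeable with respect to the
  anchor's metric (no anchor DIF); anchor misfit propagates silently into
  the re-estimated parameters, which is why the DIF screen runs first.
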