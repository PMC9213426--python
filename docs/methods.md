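# Methods

## Model family and likelihood

Each gradient × metric relationship is modelled on transformed scales:
surface area and depth as log₁₀(x) (they span several orders of magnitude and
log spacing gives even leverage), vegetation cover on its raw percent scale.
Response transforms follow a per-metric registry — log₁₀ for TP, TN, chl a,
CH₄ flux, k₆₀₀ and DTR (right-skewed, positive), identity for pH and the
signed metabolism metrics GPP, R, NEP. The registry is configurable because
the appropriate transform is a property of the data at hand; non-positive
values under a log transform are dropped with a logged count, never silently.

Four forms are fit by (nonlinear) least squares, equivalent to maximum
likelihood under i.i.d. Gaussian residuals on the transformed response scale:
a flat mean, a line, a one-breakpoint segmented regression, and a 4-parameter
logistic. The residual SD σ is estimated by ML (√(RSS/n)) and counted as a
parameter, so k = 2, 3, 5, 5 for null/linear/segmented-continuous/logistic
and 6 for the discontinuous segmented variant. Counting σ consistently across
forms leaves AICc *rankings* invariant to the convention. AICc =
−2·loglik + 2k + 2k(k+1)/(n−k−1); it is reported as +∞ (with a warning) when
n ≤ k + 1.

### Segmented fit

The breakpoint is profiled: candidates are every interior midpoint between
consecutive distinct x values with at least 5 observations per side (both the
per-side minimum and the overall minimum n = 10 are configurable); the
conditional fit at each candidate is exact OLS on the basis
{1, x, (x − bp)₊}, which enforces continuity; the winning candidate is then
refined by bounded scalar minimisation of the RSS profile within its
bracketing interval of distinct x values, where the profile is smooth. The
search is deterministic and globally exhaustive at the resolution of the
data; on small instances the returned RSS is verified in tests against an
independent exhaustive-grid oracle. Because the continuous segmented basis
nests the line (coefficient of (x − bp)₊ equal to zero) and the line nests
the constant, log-likelihoods are monotone in model complexity — a property
test.

A discontinuous variant (free intercepts on both sides, the printed two-line
form) is available via `continuous=False`; the default is continuous because
that is what the standard segmented-regression toolchain fits.

### Logistic fit

`y = f + (g − f)/(1 + exp((bp − x)/h))` is fit by Levenberg–Marquardt from a
deterministic 18-point start grid: plateaus at the 10th/90th percentiles of y
(both orientations), bp at the 25th/50th/75th percentiles of x, and h at
range(x)/20, /8, /4. The lowest-RSS converged start is returned; if no start
converges the fit is flagged `converged=False` and excluded from selection
(with a log line) rather than assigned an infinite AICc.

### Standard errors for the boundary parameter

Both nonlinear fitters report an SE for bp by the delta method using the
Gauss–Newton curvature: cov = σ̂²(JᵀJ)⁻¹ with the analytic Jacobian (for the
continuous segmented model, ∂m/∂bp = (d₁ − d₂)·1[x > bp]) and σ̂² = RSS/(n−p).
A full-Newton numerical Hessian was rejected: the second-order residual terms
make the bp curvature noisy and produced badly anticonservative SEs in
simulation, whereas the Gauss–Newton SE achieves ~92% nominal-95% coverage at
the study conditions (n = 200, σ = 0.3, slope change 1.0). A nonparametric
pair-resampling bootstrap (default 500 draws, seeded) is available as a
cross-check (`se_method="bootstrap"`); for the discontinuous variant the
curvature in bp is zero almost everywhere, so only the bootstrap applies.

## Model selection and boundary extraction

The minimum-AICc converged fit wins provisionally. The published selection
rule — consider fits within 11 AICc units "using RMSE and parsimony" — is not
a fully specified algorithm; this package operationalises it as: a strictly
simpler form (smaller k) within 11 units of the minimum whose RMSE is at most
10% worse (relative) than the winner's is selected instead, simplest first.
Both the 11-unit window and the 10% RMSE tolerance are configuration, and the
full ΔAICc/RMSE table is always emitted so users can apply their own
judgment. AICc ties break toward smaller k, then the fixed order null <
linear < segmented < logistic. Selection is a pure function of the fit set.

When the winner is segmented (breakpoint) or logistic (inflection), bp is the
boundary, back-transformed with 10^bp on log₁₀ gradients. On the log scale
the SE becomes the multiplicative factor 10^SE — reporting it additively
would imply negative areas for estimates like 0.8 ha with SE factor 1.2; the
`se_kind` field records the convention.

## Aggregation and reference tests

Per-gradient summaries are the unweighted arithmetic mean, SE of the mean
(sample SD/√n) and median of the back-transformed point estimates; no
meta-analytic weighting by per-fit SEs is applied. Aggregating on the
original scale (not the log scale) reproduces the published cross-metric
summary rows from the published per-metric values. The one-sample two-sided
t-test compares a gradient's estimates against an external threshold (the
30% emergent-vegetation wetland bound): t = (x̄ − μ₀)/(s/√n), df = n − 1.

## Group comparisons

One-way ANOVA per metric across waterbody-type labels, on the same per-metric
transform registry (log₁₀ for the skewed nutrients/chlorophyll, raw pH) since
the variance-ratio F test assumes roughly Gaussian residuals. Post-hoc LSD:
all pairwise t statistics share the pooled within-group mean square and its
df; letters are assigned as the maximal cliques of the non-significance graph
(ordered by group mean), which guarantees two groups share a letter iff their
pairwise test fails to reject at α. LSD runs only when the omnibus ANOVA is
significant (Fisher-protected, toggleable). The coefficient of variation is
always computed on untransformed values (CV of a log is not the CV of the
quantity). Levene's test uses median centering (Brown–Forsythe) by default,
mean centering optionally.

## Classification

Two rule sets. The literature candidate screen keeps waterbodies ≤ 20 ha and
≤ 9 m (inclusive, matching the stated "≤"); records missing depth are
retained by default with a logged count, records missing area are dropped.
The functional definition tests vegetation first — a heavily vegetated small
basin is a wetland, not a pond, following the USFWS-style ≥ 30% emergent
cover precedence — then splits open-water bodies by depth (< 5 m) and area
(< 5 ha) into pond, shallow lake and lake; any missing required field gives
`unclassified`. Pond bounds are strict `<` by default (the "(< 5 ha)"
phrasing) with per-threshold inclusivity flags, since the prose "maximum of
5 ha" admits either reading. The classifier is total on complete records and
its soundness (pond ⟹ all three bounds) is property-tested.

## Synthetic data

`generate_gradient` inverts the four forms into data-generating processes: x
uniform on the transformed domain (defaults: area 10⁻³–10³ ha, depth
0.1–50 m, vegetation 0–100%), y = form(x) + N(0, σ) on the transformed
response scale — the same scale the likelihood uses, so generator σ and
fitted σ are commensurable. Recovery studies in the tests and acceptance
script use n = 200 and σ = 0.3 with slope change 1.0 (segmented) and plateau
separation 3.0 with width h = 0.3 (logistic): effect sizes at which the true
form is decisively identifiable, chosen to represent the strong-signal regime
the boundary analysis targets; 200 replicates keep the Monte-Carlo error on a
90% coverage bound near 2 percentage points while the full suite stays in the
minutes range.

`generate_population` draws waterbody records by type with log-normal TP, TN
and chl a, normal pH, type-specific log-uniform morphometry ranges, and
Bernoulli hydroperiod/origin mixtures (defaults 74% permanent, 65%
constructed — the mixture reported for compiled pond data). The per-type
distribution locations/scales are qualitative placeholders encoding only the
reported orderings (ponds highest in TN; ponds and wetlands high in TP with
ponds most variable; wetland chl a lowest and most variable); they are not
empirical estimates, and passing group-comparison tests on these populations
demonstrates correctness of the statistics, not real-world effect sizes.
What the generator does not emulate: measurement error structure, censoring
and detection limits, spatial/source heterogeneity, correlated metrics within
a waterbody, and the empirical distributions of the large lake/wetland
monitoring databases.

## Numerical choices and edge cases

- Perfect fits (RSS = 0) are kept finite via a σ floor of 1e-12; the
  parsimony override is suppressed when the winner's RMSE is exactly 0.
- Degenerate inputs raise typed errors: all-identical x (rank deficiency),
  fewer than 5 points per side of every candidate breakpoint, zero-variance
  t-test input.
- Log base is log₁₀ throughout; boundaries are back-transformed by 10^bp so
  the base choice cannot alter reported boundaries.
- All fits, generators and the pipeline are deterministic given their seeds;
  the run manifest echoes config, seed and library versions.

## Known limitations

- One breakpoint only; no multi-breakpoint or non-Gaussian extensions.
- The delta-method SE for bp is asymptotic and mildly anticonservative near
  the boundary-identifiability limit (few points on one side).
- The parsimony rule is one defensible reading of a verbal criterion; other
  readings can pick different winners inside the 11-unit window.
- The cross-metric mean/SE/median treat boundary estimates as exchangeable;
  metrics with very different precision contribute equally.
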