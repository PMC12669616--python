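# Methods

## Enzyme stoichiometry and the vector model

Per-sample ratios are ratios of natural logarithms of activities:
E_C:N = ln BG / ln(NAG+LAP), E_C:P = ln BG / ln ALP,
E_N:P = ln(NAG+LAP) / ln ALP. NAG and LAP are always summed before the log.
Two consequences shape the implementation:

- **Working units are part of the definition.** A ratio of logs is not
  invariant to a common rescaling of all activities, and it requires every
  logged quantity (BG, NAG+LAP, ALP) to exceed 1 in working units
  (nmol g⁻¹ dry soil h⁻¹ here) so the logs are strictly positive. Inputs at
  or below 1 raise a domain error naming the offending variable; a
  `rescale` factor is available for tables recorded in other units and is
  logged loudly when used. A property test asserts that rescaling *does*
  change the ratios, guarding against a silent switch to log-of-ratio.
- **Two written conventions exist for x and y.** Alongside the ratio-of-logs
  definition, a log-of-ratio form (ln(BG/ALP), ln(BG/(NAG+LAP))) appears in
  some figure captions in this literature. The tabulated ratio values are
  consistent only with ratio-of-logs, so that is the default; the
  alternative is exposed as `convention="log_of_ratio"`.

Vector metrics use x = E_C:P, y = E_C:N: length = √(x²+y²), angle =
atan(y/x) in degrees (the spreadsheet-style two-argument arctangent whose
first argument is the abscissa). With all logged activities above 1,
angle > 45° is algebraically equivalent to ALP > NAG+LAP — phosphatase
dominance — which is what makes the 45° threshold readable as N vs P
limitation; this equivalence is asserted on randomized inputs. Angles
within 1e-9 of 45°, and quadrant ratios within 1e-9 of 1, are labelled
`boundary` rather than silently binned.

The quadrant classification plots q_x = (NAG+LAP)/ALP against
q_y = BG/(NAG+LAP) with baselines of 1. The four-group mapping follows the
geometric reading (q_y > 1 ⇒ C acquisition dominant over N; q_x < 1 ⇒ P
acquisition dominant over N): (q_x<1, q_y>1) → C & P limitation;
(q_x<1, q_y<1) → P; (q_x>1, q_y<1) → N; (q_x>1, q_y>1) → N & P. The mapping
is a dictionary argument and can be overridden.

Cell summaries report mean/sd/se/n per zone × depth cell; grand means are
unweighted means of cell means, which equals the sample-level mean on the
balanced design (unbalanced tables are summarized with a warning). On the
published nine-cell means this convention reproduces the enzyme C:P and N:P
grand means at two decimals and the C:N grand mean to within 0.01 (0.85 vs
0.84 — mean-of-cell-means vs sample-level averaging differ in the second
decimal for that ratio).

## Synthetic study generator

The generator emulates the field design: three zones at increasing distance
from a mine-water outlet (littoral 0–20 m, riparian 30–60 m, upland
70–100 m; encoded by band midpoints 10/45/85 m), six plots per zone, three
depth layers (midpoints 5/15/25 cm when a numeric depth is needed), and two
laboratory fractions per pooled sample. One value set is drawn per
(zone, depth, plot) and emitted once per fraction, so per-cell counts match
the sampling table (18 enzyme-fraction samples per zone, 36 in all) while
every column is available on every row. Subsample pooling is not simulated
mechanistically: cell sd is the post-pooling, between-plot variability.

Distribution families per variable: lognormal for enzyme activities
(structural positivity; parameters moment-matched so the arithmetic mean
and sd equal the design values) and truncated normal for physicochemistry
(truncated at 0, and at 14 for pH, 100% for moisture). Truncation pulls the
mean of a naive truncated normal away from its location parameter, so the
location is solved (closed-form mean expression, bracketed root-find) to
make the realized mean equal the design mean; a moment-convergence test at
n = 10,000 per cell holds all 144 cell × variable means inside three
standard errors.

Preset cell means encode the study's qualitative spatial structure, chosen
once as field-realistic values: BG falls with depth (upland baseline
60/25/8 nmol g⁻¹ h⁻¹) while ALP rises (250/700/1600); the littoral zone is
highest in all four enzymes (×1.8 for BG/NAG/LAP, ×1.6 for ALP, riparian
intermediate); ALP exceeds NAG+LAP in every cell, so expected vector angles
exceed 45° everywhere and increase with depth; moisture and salinity peak
littoral, moisture rises and available P falls with depth; biomass C/N fall
with depth outside the littoral zone. Enzyme CVs are 0.25 (lognormal);
physicochemical sds are fixed per variable. The generator does *not*
emulate spatial autocorrelation, heavy-metal water chemistry, assay error
structure, or non-normal field tails beyond lognormality — so passing
pipeline tests demonstrate correct computation and qualitative-pattern
recovery, not distributional realism of any particular field site.

`inject_effect` shifts cell means additively along one factor for power and
recovery experiments without touching the base design.

## Factorial statistics

One-way ANOVA uses the classical fixed-effects decomposition; zero
within-group variance raises a "degenerate" error rather than an infinite
F. Tukey HSD uses the studentized-range distribution (Tukey–Kramer
harmonic-mean form for unbalanced groups, with a warning). Letters are
assigned by the insertion algorithm: start with one column containing all
groups, split every column containing both members of each significant
pair, absorb columns contained in others, then letter columns in order of
their smallest group index — groups share a letter iff not significantly
different. Letters reflect the Tukey verdicts alone; the omnibus F is
reported alongside but does not gate the pairwise tests, since the study's
figures annotate letters universally. Two-way ANOVA (zone, depth,
interaction) uses Type II sums of squares, identical to Types I/III on the
balanced design (asserted). Normality and homogeneity pre-checks
(Shapiro–Wilk, Levene) are advisory only: they warn and never block,
because no remedial branch is defined for the analysis. Alpha defaults to
0.05. No multiplicity correction is applied across variables.

## Ordination

RDA: center responses and (default) scale them to unit variance — the
response sets mix units; standardize predictors; drop collinear predictor
columns via rank-revealing QR with a warning; regress Y on X by least
squares and take the SVD of the fitted values. Eigenvalue_i = s_i²/(n−1);
percent explained = eigenvalue / total variance of the centered responses.
Site scores are U·s (orthogonal across axes by construction); response
scores are the right singular vectors. The analysis requires n > rank(X),
checked on the raw predictor matrix. The two study ordinations use
responses {BG, NAG, LAP, ALP, E_C:N, E_C:P, E_N:P} and
{vector length, vector angle}, with predictors = physicochemistry +
biomass + numeric depth + mining distance. The
detrended-correspondence-analysis gradient-length diagnostic is out of
scope (it only motivates choosing RDA) and its omission is logged.

envfit: regress the environmental vector on the first two site-score axes;
r² is the squared multiple correlation; significance comes from permuting
the vector (999 permutations by default) with the add-one estimator
p = (1 + #{r²_perm ≥ r²}) / (1 + n_perm), so p is never zero and is
deterministic given a seed. Arrow direction is the normalized coefficient
pair. Axis percentages, envfit r² and PLS R²/SRMR on synthetic data are
data-dependent and are reported, never asserted against any published
field values.

The C-vs-N/P limitation relationship is an ordinary least-squares
regression of vector length on vector angle with Pearson r and its t-test
p; it requires ≥ 3 pairs and non-degenerate angles.

## PLS path model

Estimation is the classical composite PLS algorithm: z-score indicators;
initialize equal outer weights; iterate (a) inner proxies under the path
weighting scheme — predecessors contribute via regression coefficients,
successors via correlations — and (b) mode-A outer weights (indicator ×
proxy correlations), until the largest weight change is below tol = 1e-7
(max 300 iterations; non-convergence is an error reporting the last
delta). Latent scores are standardized composites; each latent is oriented
to correlate positively with its first indicator so signs are stable
across runs and resamples. Single-indicator blocks (mining distance, soil
depth, each limitation endpoint) are fixed to the z-scored indicator.
Structural coefficients are OLS of each endogenous latent on its
predecessors; R² comes from the same regressions. Total effects are the
Neumann closure (I − B)⁻¹ − I of the coefficient matrix, equal to the sum
over all directed paths of edge-coefficient products (asserted against a
path-enumeration oracle); cycles are rejected.

Bootstrap significance resamples rows with replacement, refits, and refers
estimate / bootstrap-SE to the standard normal (two-sided), with 2.5/97.5
percentile intervals alongside; 5000 resamples by default (tests use
100–200). Failed refits are skipped and counted; more than 10% failures is
an error. Missing data are handled complete-case with a logged count.

SRMR is the root mean square of observed-minus-implied indicator
correlations over all off-diagonal pairs. Implied correlations use the
factor-model reading of the fitted composites: one-factor
(principal-axis) loadings fitted per block reproduce within-block
correlations (exactly, for a rank-one block), and between-block implied
correlations are λ_i φ* λ_j with φ* the composite-score correlation
disattenuated by each composite's correlation with its block factor
(clipped to [−1, 1]). Composite loadings alone would systematically
over-imply within-block correlations on well-fitting data, which is why
the factor-model reconstruction is used. The NFI fit index is not
implemented (its null-model convention is software-specific).

The default driver topology has mining distance and depth as exogenous
blocks; nutrients (AP, NO₃⁻-N), biomass (MBC, MBN), enzyme activity
(BG, LAP, ALP) and enzyme stoichiometry (E_C:N, E_C:P, E_N:P) as
composites; and one limitation endpoint (vector length for C, vector angle
for P). The same spec is fitted twice with the endpoint swapped. Block
membership is fully user-definable.

## Problem sizes and numerical choices

Tolerances: algebraic identities 1e-12; RDA-vs-eigendecomposition 1e-8;
envfit-vs-regression 1e-10; boundary tolerance 1e-9; PLS tol 1e-7. Test
simulations use sizes chosen for tight conclusions at small cost: identity
checks on 10,000 random activity sets; RDA oracle on 50 random instances;
envfit calibration on 400 null vectors at 99 permutations; PLS bootstrap
calibration on 200 null datasets (n = 200, 100 resamples) of the smallest
model exercising the full bootstrap path; Tukey family-wise error on 500
null datasets at the study's n = 6 per cell; PLS recovery at n = 2000 on
the full study topology (every path within 0.08 of the realized
latent-level coefficients); ANOVA power at n = 200 per cell over 60
replicates. Under the complete null, each letter family individually is
all-"a" in ≥ 90% of seeds; jointly across the six families of a variable
the clean rate is necessarily lower (≈ 0.95⁶), which is a property of
running six independent 5%-level families, not of the implementation.

## Known limitations

- The generator draws cells independently: no spatial autocorrelation, no
  correlated measurement error between variables beyond what the means
  impose.
- PLS composite estimation attenuates structural coefficients relative to
  a true latent-variable model when loadings are below 1; recovery
  tolerances account for this.
- The quadrant-label mapping and the default path-model block memberships
  are conventions (configurable), not identified by the data.
- Advisory assumption checks do not alter the analysis path.
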