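# Methods

This note documents the statistical model behind `fjordapcs`, the choices
made where the procedure admits more than one reading, and what the
synthetic ground-truth tests do and do not establish about real survey data.

## Data model and pre-treatment

The unit of analysis is a station × depth table of n water samples by p
measured parameters with per-parameter units and detection limits. Cells can
be `measured`, `below_lod` (censored by the analytical method), `imputed`,
or `missing`. Censored cells are replaced by independent uniform draws on
[0, LOD): a censored measurement carries only the information "between zero
and the detection limit", and the uniform is the minimal-assumption
distribution on that interval. One standard-uniform deviate is drawn per
cell and multiplied by the LOD, so the imputation scales linearly with the
detection limit and is bitwise reproducible for a given seed (default
20200701; every run's randomness traces to the single pipeline seed).
Imputation happens once, upstream of all stages. Genuinely missing values in
the analyzed parameter subset are rejected rather than imputed — the
eigen-decomposition has no missing-data treatment, and silently dropping
rows of a 14-sample survey would change the analysis more than it saves.

Standardization is the ordinary z-score with the sample SD (divisor n − 1),
the default of the mainstream statistics environments this class of analysis
is run in. River samples share the table but are excluded from
standardization and PCA; the multivariate model describes the fjord water
column, while river rows only feed the river-endmember means.

## Component model

PCA is the eigen-decomposition of the correlation matrix under the
psychometric convention **Z** = **P B**ᵀ: loadings **B** = **V** Λ^½ are
variable–component correlations and scores **P** = **Z V** Λ^−½ have unit
sample variance. This is the convention under which "partial values"
(below) and the zero-sample projection of APCS are well defined. Component
signs are arbitrary; they are pinned by making the largest-magnitude loading
of each column positive, which makes repeated fits byte-identical. With
n − 1 < p the correlation matrix is rank deficient and only the leading
min(n − 1, p) components are computed (with a warning).

Retention uses the Guttman–Kaiser criterion, counting eigenvalues strictly
greater than 1 — a component at exactly λ = 1 explains no more than a single
original variable and is excluded. Scree-plot judgement is deliberately not
automated; the CLI prints the scree series and accepts a fixed k.

Varimax rotation uses the classic SVD update with Kaiser row normalization
(rows scaled to unit communality during rotation, so high-communality
variables do not dominate the criterion). The iteration stops when the
rotation matrix is stationary to 1e−12 (at most 5000 iterations): the
tolerance is deliberately tight so that exact-recovery comparisons against
ground truth are limited by arithmetic, not by the optimizer. Scores and the
score-coefficient matrix are rotated by the same orthogonal matrix, so
**Z** = **P B**ᵀ and per-variable communalities are preserved; rotated
components are re-ordered by explained variance and re-sign-pinned, and
rotated variance fractions are column sums of **B**² / p. Rotation of a
single component is undefined and returns the truncated model unchanged.
The rotation optimizer is cross-checked in the tests against an independent
implementation (statsmodels' factor-rotation routines).

### Broken-stick loading significance

The broken-stick distribution b_m = (1/k) Σ_{i=m..k} 1/i is the expected
m-th largest fraction when a unit of variance splits at random into k
pieces. For each variable, its squared loadings across the k retained
components are ranked descending and compared sequentially to b_1, b_2, …;
components are flagged significant from the top rank down and the walk stops
at the first rank whose squared loading falls below its expectation. The
sequential stop matters: a variable whose communality is spread evenly
(squared loadings ≈ 1/k each) exceeds the *lower-rank* expectations but not
b_1, and flagging its lower ranks while its dominant share is unremarkable
would invert the logic of the screen — such a variable flags nothing.
An across-variables variant (per component, squared loadings normalized by
the column sum and compared to the p-piece broken stick) is available as
`method="per_component"`, and is also what the per-variable rule falls back
to at k = 1, where a k-piece stick is degenerate. Which variant the original
analysis used is not recoverable from published material; the per-variable
rule is the default because it is the one whose behavior on hand-checkable
cases is unambiguous.

### Independence check

Principal components are uncorrelated but need not be independent when the
data are not multivariate normal. Each retained score column is discretized
into four equal-width bins spanning its observed range, and each component
pair is chi-square tested on the resulting contingency table (empty rows and
columns dropped before computing degrees of freedom; decision at α = 0.05).
A pooled k × 4 component-by-bin construction is also exposed, as the
published description of the cross-table shape is ambiguous. Note what this
test measures: on the synthetic generator the pelagic and benthic processes
are built linearly orthogonal yet are both driven by depth, and the test
correctly *rejects* independence for that pair — a rejection flags nonlinear
coupling, not an error.

## Ward clustering of loadings

Parameters are clustered in loading space with the Ward minimum-variance
criterion (scipy's `ward`, the Ward.D2 form on Euclidean input; checked
equivalent on these data to the classical Ward on squared distances in R's
`hclust`). By default the loadings are first masked by the broken-stick
screen — non-significant entries are zeroed — so that grouping reflects only
process affinities exceeding random expectation. This choice is empirical:
on the published Kongsfjorden loading matrix, clustering the full vectors
attaches dCu (a split-affinity parameter, 0.55 on mixing / 0.60 on benthic)
to the mixing-group metals, while the masked clustering reproduces the
published five groups exactly, including the benthic group
{Si(OH)₄, dFe, dCu, dZn}. Cluster labels are reported by size then by
first-member order and the merge tree is exported as newick text; labels
are presentation only, and the partition is invariant under input
reordering.

## APCS-MLR quantification

Thurston–Spengler absolute scores re-zero each component against the
artificial sample with all concentrations equal to zero: z₀ⱼ = −meanⱼ/sdⱼ,
P₀ = z₀ᵀ**W** with **W** the (rotated) score-coefficient matrix, and
APCS = **P** − P₀. Each parameter's concentrations — in original units, the
receptor-modeling convention; the shares below are invariant to that choice
— are regressed on the APCS columns with an intercept. Backward elimination
removes one factor per round (the largest p-value ≥ 0.1), then refits, until
every retained factor is significant; the intercept is never a candidate.
The 0.1 cutoff reflects the small survey sizes this method targets: with
n ≈ 14, a stricter cutoff discards real but modest process contributions.
Coefficient p-values that are numerically undetermined (0/0 t-statistics
from an exact fit) or whose contribution is negligible relative to the
response scale are treated as non-significant rather than propagated.

The contribution of factor f to parameter j is the sample mean of
|a_jf · APCS_if|, and R_S is that mean normalized over the retained factors
to sum to 100 %. Absolute values prevent sign cancellation for negatively
loaded parameters; eliminated factors carry no share. Because the zero-
sample offset P₀ enters every |a·APCS| term, a factor can carry a sizeable
share even where its loading is modest — that is a property of the method,
visible in published APCS-MLR tables, and the synthetic ground truth is
defined through the same formula so recovery is measured like-for-like.

## Endmember estimation

For parameters significant on the conservative-mixing component, the partial
value P_i1 · B_j1 isolates the mixing part of the signal; de-standardized
and regressed on measured salinity it extrapolates to a freshwater
endmember at S = 0 and a marine endmember at the reference salinity 34.86.
Negative extrapolations are reported with a flag, never truncated: a
strongly scavenged element genuinely produces a negative statistical
endmember, and hiding it would misrepresent the method. River endmembers are
the arithmetic mean ± population SD (divisor n) of the outlet samples —
with three rivers, the population convention is what reproduces the
published dissolved-manganese dispersion (6,572 → "7,000" at one significant
figure; the sample convention gives 8,049 → "8,000"). Report rounding is two
significant figures for river means, one for their SDs, three for
fjord-derived endmembers; raw values are retained in the JSON outputs.
The estuarine removal factor is 100·(1 − receiving/source), reported as-is
(negative = enrichment).

## Hydrography

Water masses follow the Cottier-style T–S boxes for West Svalbard fjords
(AW: T > 3 °C, S > 34.65; TAW: 1 < T ≤ 3, S > 34.65; SW: S < 34;
IW: T > 1, 34 ≤ S ≤ 34.65; LW: T ≤ 1, S > 34.3), shipped as an ordered,
user-editable rule list (first match wins, fallback `unclassified`) because
published schemes differ in detail. Freshwater content integrates
(S_ref − S(z))/S_ref over depth by the trapezoidal rule, extending the
shallowest measurement to the surface and the deepest to the bottom depth;
negative local anomalies (S > S_ref) keep their sign so dilution budgets
conserve mass. FWC_sp divides by the bottom depth, falling back to the
deepest sampled depth when the true bottom is unknown.

## Synthetic generator and what the tests show

The generator builds a salinity field S(x, z) = S_max − A·exp(−z/h − x/L)
(a freshwater lens, surface-intensified and decaying along-fjord; defaults
A = 2.84, h = 12 m, L = 0.7 reproduce the 32.07–34.91 survey range), and
three latent processes: the freshwater anomaly, a pelagic signal with a
sub-surface maximum weakening seaward, and a benthic signal increasing
toward the seabed. Defaults are 10 stations × 10 depths (n = 100) with 10 %
measurement noise — the conditions of the recovery checks — and
`SyntheticConfig.study()` reproduces the survey footprint (4 stations,
3–4 depths, 14 fjord + 3 river samples). Parameter scales are plausible
study-like means and SDs per constituent; the loading template follows the
published 18-parameter pattern with salinity forced to a pure mixing tracer,
since salinity *defines* the mixing axis by construction.

Identifiability conventions: realized latent scores are made exactly
orthonormal by Gram–Schmidt; loading rows are scaled to unit norm; the truth
loading matrix is stored in varimax-canonical orientation (with the mixing
column oriented so salinity loads negatively); and the true contribution
shares and endmembers are defined as the noiseless large-sample limits of
the pipeline's own statistics (the APCS share formula evaluated at the true
scores, and the closed-form OLS limit of mixing partials on the measured
salinity column). Under these conventions a noiseless table is recovered
*exactly* (loadings to ~1e−13), so any recovery error measures noise and
estimation, not convention mismatch. Salinity is excluded from the
endmember-recovery error metric because its own true freshwater endmember is
≈ 0 by construction, making a relative error undefined.

Recovery at the default conditions (20 seeds): variance fractions within
±1 pp, contribution shares within ~1.5 pp mean absolute error, and S = 0
endmembers of strongly mixing-loaded parameters (|loading| > 0.8) within
5 % relative as a 20-seed aggregate of the estimates. The aggregate is the
right unit for the endmember check: for carbonate-system parameters the
intercept is a small difference of large numbers (an extrapolation ~70
salinity-SDs beyond the data), so single-seed relative errors reach ~10 %
from OLS attenuation alone while the aggregate stays ~2 %.

What passing these tests does *not* show: the generator draws Gaussian noise
around an exactly low-rank structure with orthogonal processes, while real
fjord data have non-normal parameters, partially coupled processes
("pelagic" and "benthic" both track depth), nonlinear mixing, and analytical
error that varies by element. Synthetic recovery therefore validates the
*implementation* of each stage and its statistical behavior under the
stated conditions, not the geochemical interpretation of any particular
survey. The river samples are scattered around the freshwater extrapolation
for convenience and do not emulate the distinct proglacial weathering
signature (high-alkalinity rivers vs. low-alkalinity subglacial discharge)
of real catchments.

## Reproducing the original survey

The full reproduction of the study's eigenvalues (8.6, 5.2, 2.4), rotated
variance fractions (45/29/14 %), endmembers (e.g. A_T 182 µmol kg⁻¹, dMn
33,600 ng L⁻¹ at S = 0) and station freshwater contents requires the
deposited station table, which is not redistributable with this repository.
Place it as `data/kongsfjorden_table.csv` with a column-mapping schema
`data/kongsfjorden_table.yaml` (roles `sample_id`, `station`, `depth`,
`type` plus the 18 parameter columns, as in the schema files written by
`fjordapcs simulate`), and the acceptance test
`test_deposited_station_table_reproduction` runs the comparison end to end.
Until then that test fails by design rather than silently skipping.

## Problem sizes and numerical choices

Tests and the acceptance script use n = 100 synthetic samples, 20-seed
aggregates, 200-replicate null simulations for the independence check
(n = 1000 per replicate) and 500-replicate null regressions at the survey's
n = 14 — sizes at which every stochastic band asserted is stable across
seeds. Degenerate inputs are errors, not warnings: constant columns
(standardization and score binning), missing LODs under censoring,
non-increasing depth grids, non-positive removal-factor sources. Ties in
cluster labeling are broken by cluster size then first-member order;
eigenvalue ties are resolved by the deterministic LAPACK ordering plus the
sign convention.
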