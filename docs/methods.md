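# Methods

`manuresub` implements the quantitative analysis of a manure-substitution
field trial: five treatments (CK = all-chemical N, and 25/50/75/100 %
dairy-manure N substitution), three replicates in a randomized complete
block design, soil sampled at 0–20 and 20–40 cm. This note documents the
models, the defaults and why they were chosen, and what the synthetic-data
generator does and does not emulate.

## Fertilizer design

The five canonical treatment rows (chemical and manure N-P-K in
kg ha⁻¹ yr⁻¹) ship as a packaged lookup table, because the printed values
carry rounding that exact arithmetic does not reproduce (0.25 × 187.5 =
46.875, printed 47.0). Plans for intermediate substitution fractions split
the nominal 187.5 kg N dose linearly and scale manure P and K by the
manure-N fraction of the full-substitution row (1.66/187 and 5.81/187).
The control dose is stated as 187.5 kg N in the protocol and printed as
187 in the treatment table; the package exposes both constants
(`TOTAL_N_NOMINAL`, `TOTAL_N_PRINTED`) rather than resolving the
discrepancy. Plan validation accepts totals within 0.2 kg of
chemical + manure, the slack implied by the printed rounding.

## Radar-area soil quality index

Each indicator is rescaled to a linear score SLᵢ ∈ [0, 1] by a
direction-aware min-max transform, and the index is

SQI = 0.5 · Σᵢ SLᵢ² · sin(2π/n)

over the n indicators laid out as radar spokes. Choices that were
genuinely open:

* **Scoring is per depth layer.** The index is reported and compared
  within each depth, so min and max are taken over the samples of one
  layer; no cross-depth pooling.
* **Per-spoke squared terms, not polygon area.** The formula above
  assigns each spoke its own SLᵢ² term, which makes the index
  order-invariant. A literal radar polygon would use adjacent products
  SLᵢ·SLᵢ₊₁; that variant is available via `sqi_area(..., polygon=True)`
  but is not the default, because the per-spoke form is the one the
  analysis this package mirrors states.
* **All indicators default to more-is-better.** Whether bulk density or
  dissolved organic N should be reverse-scored is not decidable from the
  reported results; directions are fully user-configurable and a
  ready-made sensitivity map with BD as less-is-better ships as
  `BD_REVERSED_DIRECTIONS`.
* **Constant columns score 0.5.** A constant indicator carries no ranking
  information; the neutral score keeps n identical across depths instead
  of silently changing the index's upper bound 0.5·n·sin(2π/n).
* The default indicator set is the 11 physicochemical variables (SOC, TN,
  MBC, MBN, DOC, DON, AHN, AP, AK, BD, SW) plus the six hydrolases.

## Ecoenzymatic stoichiometry vectors

With C = BG + CB + XYL, the ratios x = C/(C + ALP) and
y = C/(C + LAP + NAG) summarise microbial C-vs-P and C-vs-N investment.
Vector length is √(x² + y²) (the printed source omits the root sign — a
rendering artifact; the un-rooted sum of squares is kept as a diagnostic
field). Vector angle is the planar angle of (x, y) from the positive
x-axis in degrees, following the spreadsheet two-argument arctangent
convention in which the first listed argument (the C:P ratio) is the
x-coordinate; under it, higher phosphatase pushes the angle above 45°.
ACP/ALP, CE/CB, BX/XYL are treated as name aliases of the same enzymes.
Interpretation thresholds (length ∝ C limitation, 45° as the N/P
boundary) are the conventional reading, stated but not asserted.

## Treatment statistics

One-way ANOVA is implemented from group summaries — MSB = n·Σ(mᵢ−m̄)²/(k−1),
MSW = mean SDᵢ², F = MSB/MSW on (k−1, k(n−1)) df — because agronomy
tables print exactly those summaries; for balanced raw data the two
routes agree identically, and the raw route is cross-checked against
scipy's independent implementation. Two-way treatment × depth ANOVA with
interaction is a fixed-effects decomposition (statsmodels); block
(replicate) effects are not modelled, mirroring the analysis this
package reproduces. Degenerate inputs: MSW = 0 with MSB > 0 reports
F = ∞, p = 0; both zero reports F = 0, p = 1.

Compact letter displays use the Piepho insert-and-absorb construction on
a pairwise significance matrix, so two groups share a letter iff their
pairwise test is non-significant. The comparison family is Tukey HSD
(studentized range on MSW) by default, with Fisher LSD and Duncan's
multiple range test (span-dependent protection levels) as options — the
letter displays in this literature rarely name their test, and rounded
summary data cannot reproduce the original letters exactly under any
standard family, so p-values, not letter strings, are the reproduction
target. p-values are formatted to three decimals with "<0.001" flooring.

## Community summaries

The community module starts from a taxon × sample count table with a
taxon → phylum map. Phylum names are normalised to the post-2021
nomenclature (Actinobacteriota → Actinomycetota, Proteobacteria →
Pseudomonadota, …) so mixed-vintage inputs aggregate consistently.
Diversity is the Gini–Simpson index 1 − Σpᵢ² (the inverse form is a
flag); the Gini form is used because the analyses mirrored here report
substitution *increasing* the index alongside diversity gains. Distances
are Bray–Curtis on relative abundances — no rarefaction, which is out of
scope. Community-structure differences are tested by PERMANOVA:
pseudo-F from among/within sums of squared dissimilarities, null by
label permutation, p = (1 + #{F* ≥ F}) / (1 + n_perm). The add-one rule
means p is never 0 and never below 1/(1+n_perm). Note that label
permutations that preserve the grouping reproduce the observed F
exactly, so even perfectly separated clusters have attainable minimum p
of roughly (#group-preserving permutations)/(n_perm + 1).

## Driver analysis

Mantel tests correlate the upper triangles of two distance matrices,
permuting rows and columns of one simultaneously (one-tailed, add-one
rule). Variable blocks (physicochemical / enzymes / stoichiometry) are
z-scored and converted to Euclidean sample distances — the metric is this
package's choice, as the mirrored analysis names none.

Permutation importance follows the rfPermute scheme: a bagged ensemble
of regression trees (scikit-learn `DecisionTreeRegressor` base learners,
max_features = 1/3, explicit bootstrap bookkeeping so out-of-bag sets
are exact and seeded); a feature's importance is the mean increase in
OOB squared error when its OOB values are shuffled; significance comes
from refitting the whole ensemble with the response permuted n_null
times, p = (1 + #{null ≥ observed}) / (1 + n_null). The default ensemble
size is 500 trees (the randomForest convention); at small trial sizes
importance rankings are noticeably noisier below ~300 trees. Correlated
features share importance — on trial data where every topsoil variable
shifts monotonically with substitution rate, no importance method can
attribute signal uniquely, which is why power studies use the
`null_config` generator (all treatment effects switched off) and inject
a known signal. Star thresholds are 0.05/0.01/0.001; no multiplicity
correction by default (a Benjamini–Hochberg column is optional in the
correlation table path), matching the mirrored analysis.

## Synthetic-data generator

The generator emulates the trial's statistical skeleton, not its
field reality. Per variable, treatment × depth cell means are CK means
times multiplicative effects; draws are independent Gaussians with
SD = CV·mean, truncated at 0 (at the default CVs of 3–10 % the
truncation bias is negligible; a test exercises truncation at CV = 5).
Defaults house the trial's printed anchors: CK topsoil SOC 21.9 g kg⁻¹,
AHN 99.8 mg kg⁻¹, BD 1.58 g cm⁻³; yield and root traits use the printed
per-treatment means and SDs directly (plot-level, depth label "plot");
effect multipliers interpolate the reported percent-change ranges
linearly from the 25 % to the 100 % rate (topsoil gains in SOC, TN,
MBC/MBN, AP, SW and all six enzymes with DON down; subsoil gains only in
MBC/MBN, SW, LAP, ALP against declines in TN, DON, AP, AK, BD and the
C/N-acquiring hydrolases). Remaining baselines (TN, MBC, …) are typical
Mollisol cropland values chosen once. Communities are Dirichlet phylum
proportions (concentration 500) times a 10,000-read multinomial, three
taxa per phylum with weights drawn once per trial; baseline
compositions are typical agricultural-soil profiles and fold changes
follow the reported directions.

Not emulated: within-season dynamics, spatial/block autocorrelation
(an optional multiplicative block term and a shared-latent
cross-indicator correlation exist but default to off), sequencing reads
and OTU inference, and any correlation between soil variables beyond
what the treatment structure induces. Passing tests therefore show the
*machinery* is correct and calibrated, not that the field conclusions
would replicate on new data.

## Numerical and reproducibility choices

All randomness flows through explicit integer seeds
(`numpy.random.default_rng`); the community stream is a child
(`SeedSequence([seed, 1])`) of the trial seed so trial and community are
independently reproducible. Permutation p-values use the add-one rule
throughout. The pipeline's manifest records seed, package and library
versions and a config hash (excluding the output directory), and
identical configurations produce byte-identical output trees. Test-time
problem sizes — 500-run null calibrations for Mantel/PERMANOVA/two-way
ANOVA, 50 seeded recovery runs, exhaustive enumeration on 4×4 (Mantel)
and 6-sample (PERMANOVA) instances — are the package's chosen balance
between statistical resolution and a test suite that completes in
minutes.

## Known limitations

* Letter displays from rounded printed summaries will not match letters
  computed from unrounded raw data; this is inherent, not a defect.
* The summary-ANOVA route requires equal n per group.
* Min-max scoring makes the SQI scale run-relative: percent changes
  between treatments are comparable within a dataset but not across
  datasets with different spreads (synthetic SQI percent changes are
  therefore much larger than field-reported ones, while directions and
  ordering reproduce).
* Permutation importance attributes shared signal among collinear
  features arbitrarily; rankings on strongly treatment-structured data
  should be read as groups, not individual variables.
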