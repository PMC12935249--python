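# Methods

This note records the statistical model behind each stage of `isoniche`,
the defaults and why they were chosen, what the synthetic generator does
and does not emulate, and the numerical decisions a maintainer would
otherwise have to reverse-engineer.

## Data model

One row per individual: δ¹³C (‰ vs V-PDB), δ¹⁵N (‰ vs AIR), optionally
δ³⁴S (‰ vs V-CDT); mass-percent C, N and optionally S; taxon
(wildcat / domestic_cat / hybrid), region, case-study label, collection
year and month, sex, optional morphometrics, and arbitrary numeric
covariates. Enum fields are normalised case-insensitively and region
names are matched after German-umlaut transliteration and diacritic
stripping ("Markgräflerland" ≡ "Markgraeflerland"). Sanity windows
(δ¹³C ∈ [−40, 0], δ¹⁵N ∈ [−10, 20], δ³⁴S ∈ [−20, 25], percentages in
[0, 100]) raise validation errors rather than dropping rows: the reader
guarantees `rows_in == rows_out + rows_rejected` with a reason per
rejected row.

## Elemental QC

Atomic ratios use the molar masses 12.007 (C), 14.011 (N), 32.060 (S):
`C/N = (%C·14.011)/(%N·12.007)`, and analogously for C/S and N/S. Intact
hair keratin has a narrow atomic C/N; deviations indicate surface lipids,
soil contamination or degradation.

Exclusion rules (defaults in `QCConfig`): atomic C/N outside
**[3.0, 4.05]**, %C > 50, %N > 20, or missing region. Both window edges
are inclusive and the %C rule is strict-greater, so boundary samples are
retained. The hair literature also cites a narrower general keratin
window of 2.9–3.6 (`KERATIN_CN_WINDOW`); it is exposed but not the
default because the wider window is what multi-decade archival surveys
actually apply. C/S ∈ (300, 900) and N/S ∈ (100, 300) are *advisory*:
they flag a sample but never exclude it, since sulfur content of hair is
too variable for a hard rule. QC is idempotent and order-preserving.

## δ¹³C corrections

Applied in a fixed order: lipid first, then Suess.

1. **Lipid correction** — hair lipids are depleted in ¹³C relative to
   keratin protein; without chemical lipid extraction the standard
   post-hoc affine map is used:
   `δ¹³C_lipid-free = 0.982 · δ¹³C_measured − 0.028`.
2. **Suess correction** — fossil-fuel CO₂ has progressively depleted
   atmospheric δ¹³C; tissue grown in 2020 is ~2‰ lighter than
   pre-industrial tissue on the same diet. The correction is the
   additive shift `δ_cor = δ − (δ_atm(year) − baseline)` with baseline
   −6.4‰. It is a pure per-year shift: within-year differences are
   preserved exactly, and later years under a declining series receive
   strictly larger positive shifts. Years outside the supplied series
   raise an error; there is no silent extrapolation.

The packaged atmospheric series
(`data/suess_atmospheric_d13c_synthetic.csv`, 1850–2023) is a **synthetic
stand-in**: the smooth parameterisation
δ_atm(t) = −6.429 − 0.006·exp(0.0217·(t − 1740)) ‰, which tracks the
well-documented observational decline (≈ −8.1‰ at 2000). For
publication-grade work a measured annual series should be substituted via
`load_suess_model`; all downstream results shift accordingly.

## Niche metrics

All niche analysis is strictly bivariate (δ¹³C × δ¹⁵N); δ³⁴S enters only
the trend and correlation stages.

**Layman metrics.** dC/dN ranges (max − min per axis), TA (area of the
2-D convex hull; qhull), CD (mean Euclidean distance to the arithmetic
centroid), NND (mean distance of each point to its nearest distinct
neighbour) and SDNND (sample standard deviation, n−1, of those
distances). TA requires n ≥ 3 and is 0 for collinear clouds; NND/SDNND
require n ≥ 2. Groups below these thresholds return explicit `None`
markers, never NaN — mirroring how community tables omit such groups.

**Standard ellipses.** The unbiased sample covariance Σ̂ gives
SEA = π√(λ₁λ₂) = π√det(Σ̂), the area of the one-Mahalanobis-unit contour
containing χ²₂(1) ≈ 39.35% of a bivariate normal ("the 40% core").
SEAc = SEA·(n−1)/(n−2) corrects the small-sample bias. Collinear groups
(smallest eigenvalue ≤ 10⁻¹² of the largest) raise a degenerate-group
error before any area is reported.

**SEAb (Bayesian).** Likelihood x_i ~ N(μ, Σ); vague conjugate priors
μ ~ N(0, 10³·I) and Σ⁻¹ ~ Wishart(2, I). Gibbs alternation of the exact
full conditionals (normal for μ | Σ; Wishart for Σ⁻¹ | μ, drawn by
Bartlett decomposition with hand-coded 2×2 algebra for speed), recording
π√det(Σ) per retained draw. Defaults: 20,000 iterations, 3 chains,
burn-in 1,000, thinning 10 → 5,700 pooled draws. Chains are seeded from
independent `SeedSequence` child streams, so results are exactly
reproducible and adding chains never perturbs existing ones. Posterior
summaries: mean, kernel-density mode (Gaussian KDE, Silverman
bandwidth), and central 50/75/95% quantile intervals. With vague priors
the posterior concentrates on the sample covariance, so the SEAb mean
approaches SEAc as n grows — a relation the tests exploit.

**Overlap.** Each group's ellipse is its bivariate-normal contour; by
default the radius² is (n−1)/(n−2), i.e. the standard ellipse inflated
so the drawn area equals SEAc exactly (an explicit `coverage`
probability maps through χ²₂ instead). The intersection area is
integrated on a uniform cell-centre grid over the intersection of the
two bounding boxes, doubling resolution (128² up to 4096²) until two
successive refinements agree to 0.1% relative (configurable); each cell
is tested analytically against both quadratic forms. Disjoint bounding
boxes short-circuit to zero. Grid integration was chosen over polygon
clipping because it has no edge-case geometry and its error is
controlled directly by the refinement criterion; the test suite
cross-checks it against independent polygon clipping. The headline
"overlap of the wildcat niche" is reported on the pooled all-region
groups; per-region values are separate rows.

## Trends and screens

- **Season assignment.** Cats moult in spring and autumn and hair
  integrates diet over its growth period, so collection month December–
  April ⇒ summer-grown hair, May–November ⇒ winter-grown; missing month
  ⇒ unclassified. The twelve months partition exactly.
- **Trend fits.** Per region × taxon × season subset (n ≥ 3, ≥ 2
  distinct years): OLS (slope, intercept, R², two-sided slope p) and a
  Huber M-estimator (tuning constant 1.345 on MAD scale, IRLS on
  coefficients, tol 10⁻⁸, max 50 iterations). Both are always emitted
  side by side: the robust slope is the headline for outlier-prone
  archival series, the OLS fit carries the inferential quantities. When
  no residual exceeds the Huber cutoff the two coincide exactly. A
  constant response is reported as slope 0 with R² = 0.
- **Pairwise Wilcoxon.** Two-sided rank-sum per unordered taxon pair;
  exact null when both n ≤ 10 and the pooled data are tie-free,
  otherwise the normal approximation with continuity and tie
  correction. The statistic reported is the rank sum of the first group
  (W = U₁ + n₁(n₁+1)/2). Benjamini–Hochberg adjustment is applied across
  the pairs within each isotope.
- **Sex t-test.** Pooled-variance Student's t (df = n₁ + n₂ − 2) on the
  retrospective-case-study wildcats, the convention implied by reporting
  a single integer df for a two-group comparison.
- **Correlation screen.** Pearson r per isotope × variable on
  pairwise-complete rows, restricted in the pipeline to the
  retrospective wildcats. Sex is numerically coded male = 2, female = 1
  *only here* (unknown excluded); elsewhere it stays categorical so the
  arbitrary coding cannot leak into other stages. Entries with < 3
  complete pairs or a zero-variance column are flagged
  (`too_few_pairs` / `zero_variance`) with `r = None`, never NaN.

## Synthetic data generator

Each group (taxon × region × case study) draws n individuals from a
trivariate normal on the *corrected* isotope scale; the stored measured
δ¹³C is obtained by inverting the correction chain, so the pipeline's own
corrections reproduce the configured means exactly. On top of the group
mean: a per-year linear drift β_year·(year − midpoint), an additive male
sex effect, and named covariates (normal, with per-isotope linear
effects). Elemental composition is keratin-like (%C ≈ 45 ± 2,
%N derived with correlation 0.98 to %C, %S ≈ 0.2 ± 0.03); the high C–N
correlation reflects keratin stoichiometry and keeps clean samples
inside the C/N window (independent draws would fail QC ~8% of the time,
which real uncontaminated keratin does not). A `qc_fail_rate` fraction
of rows is contaminated by one of the two empirically observed modes —
inflated %C (> 50) or depressed %N (pushing C/N above 4.05). Sex-
dependent morphometrics use adult-wildcat-scale normals. All randomness
flows from one seed through per-group `SeedSequence` children
(PCG64), so tables are byte-reproducible and group-order stable.

`wildcat_survey_scenario()` fixes the generator to the published survey's
structure: 17 groups over 7 regions whose sizes (23 domestic cats, 11
hybrids, 38 wildcats), means and SDs are transcribed from the study's
descriptive table; spatial case-study rows are pinned to spring 2021,
retrospective rows spread over 1995–2021; default contamination 6/78,
the study's own exclusion fraction. Isotope axes are independent
(diagonal Σ) because the source summaries print no covariances —
correlated scenarios are available but opt-in. Single-individual groups
reuse their taxon's overall SDs since their spread is unidentifiable
from a summary table.

What the generator does **not** emulate: prey-choice mechanisms, spatial
autocorrelation, non-normal isotope distributions, measurement error
structure, unbalanced missingness patterns, or real covariances between
isotopes. Passing parameter-recovery tests therefore demonstrates the
*estimators* are correct under the stated model, not that real wildcat
data satisfy that model.

## Pipeline

Stage order is fixed and logged: input → QC → corrections → summaries →
Layman/SEA/SEAb → overlaps → trends → tests/correlations. Outputs are
tidy CSVs plus a JSON report naming the config hash (SHA-256 of the
canonical config JSON, also embedded in every output filename), the
seed, versions and counts. The global seed spawns one child stream per
stochastic stage, and within the SEAb stage one grand-child per group,
so runs are exactly reproducible and structurally stable under config
growth. A publication-style view rounds ‰ and ‰² columns to one decimal;
machine outputs keep full precision (CSV floats at 12 significant
digits).

## Problem sizes in the validation suite

The test suite validates at sizes where the relevant asymptotics are
informative yet runs stay interactive: closed-form SEA recovery at
n = 1000 (< 10% relative error), SEAb credible-interval calibration at
n = 50 over 100 replicates using thinned single chains (4,000
iterations, burn-in 500, thinning 5 — the full 3 × 20,000 default is the
production setting), slope recovery at n = 200 over 20 seeds (±0.02 on
β = 0.10 ‰/yr), brute-force hull/nearest-neighbour equivalence
exhaustively to n = 8 and by quadratic scan at n = 200.

## Known limitations

- The Suess series is a parametric stand-in (see above); absolute
  corrected values carry its (small, smooth) deviation from the measured
  atmospheric record.
- Overlap percentages depend on the chosen contour; the SEAc-matched
  default is the natural companion to reported SEAc values, but other
  conventions (e.g. 95% contours) give different percentages and should
  be stated when comparing across studies.
- The exact-Wilcoxon branch requires tie-free data; heavily tied small
  samples fall back to the tie-corrected normal approximation.
- No mixed-effects or multivariate models: groups are analysed
  marginally, by design, matching small-sample survey practice.
- Niche analysis is 2-D only; δ³⁴S niche volumes are out of scope.
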