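# isoniche

Stable-isotope trophic niche analysis for hair-based wildlife surveys.

`isoniche` implements the complete quantitative pipeline used to compare
the trophic ecology of European wildcats (*Felis silvestris*), domestic
cats and their hybrids from hair keratin δ¹³C/δ¹⁵N/δ³⁴S measurements —
but nothing in it is cat-specific: any per-individual isotope table with
elemental composition, taxon/region labels and collection dates fits.

It is aimed at ecologists running retrospective isotope monitoring on
archived tissue: museum pelts, lure-stick hair traps, road-kill
collections.

## What it computes

1. **Elemental QC.** Atomic ratios from mass percentages, e.g.
   C/N = (%C × 14.011)/(%N × 12.007). Samples are excluded when atomic
   C/N falls outside 3.0–4.05, %C > 50, %N > 20, or the regional
   assignment is missing; atomic C/S ∈ (300, 900) and N/S ∈ (100, 300)
   are advisory flags. Every exclusion carries a machine-readable reason.
2. **δ¹³C corrections.** The lipid correction
   δ¹³C_lipid-free = 0.982 · δ¹³C_measured − 0.028, then a Suess-effect
   shift δ_cor = δ − (δ_atm(year) − δ_atm,pre-industrial) restating all
   values against a pre-industrial atmospheric baseline (−6.4‰), so
   samples collected decades apart are comparable.
3. **Layman community metrics** in δ¹³C × δ¹⁵N space: per-axis ranges,
   convex-hull total area (TA), mean centroid distance (CD), mean
   nearest-neighbour distance (NND) and its standard deviation (SDNND).
4. **Standard ellipse areas.** SEA = π√det(Σ̂) (the ≈ 40% core niche),
   the small-sample-corrected SEAc = SEA·(n−1)/(n−2), and the Bayesian
   posterior SEAb sampled by a conjugate Gibbs sampler (default 20,000
   iterations × 3 chains, burn-in 1,000, thinning 10).
5. **Niche overlap**: intersection area of two groups' SEAc-matched
   ellipses as a percentage of one group's ellipse.
6. **Trend and screening statistics**: moult-based season assignment
   (December–April collections = summer-grown hair), OLS and Huber-robust
   δ-vs-year trends per region × taxon × season, pairwise Wilcoxon
   rank-sum tests with Benjamini–Hochberg correction, pooled-variance sex
   t-tests, and a Pearson correlation screen of isotopes against
   morphometric and land-use covariates on pairwise-complete rows.
7. **Synthetic data** with known ground truth emulating a two-case-study
   survey (spatial comparison in 2021 + a 1995–2021 retrospective), used
   throughout the test suite for parameter-recovery validation.

## Worked example

```python
import numpy as np
from isoniche import *

table, truth = generate_samples(wildcat_survey_scenario(seed=42))
retained, report = apply_qc(table)
print("retained", report.n_retained, "of", report.n_input, report.n_excluded_by_reason)
corrected = correct_table(retained)

pts = np.array([(s.d13C_cor, s.d15N) for s in corrected if s.taxon == "wildcat"])
group = IsotopePoints("wildcat", pts)
lay = layman_metrics(group)
print(f"n = {lay.n}: TA = {lay.TA:.1f} permil^2, CD = {lay.CD:.1f}, NND = {lay.NND:.1f}")
fit = fit_standard_ellipse(group)
print(f"SEA = {fit.SEA:.1f}, SEAc = {fit.SEAc:.1f} permil^2")
post = sample_seab(group, SEAbConfig(), seed=42)
lo, hi = post.credible_interval(0.95)
print(f"SEAb mean = {post.mean:.1f}, 95% CI = [{lo:.1f}, {hi:.1f}]")

hyb = IsotopePoints("hybrid", np.array(
    [(s.d13C_cor, s.d15N) for s in corrected if s.taxon == "hybrid"]))
res = ellipse_overlap(fit_standard_ellipse(hyb), fit)
print(f"hybrids occupy {res.prop_of_B:.1f}% of the wildcat core niche")
```

prints

```
retained 70 of 72 {'cn_out_of_range': 2, 'pctC_high': 1}
n = 38: TA = 31.8 permil^2, CD = 2.1, NND = 0.6
SEA = 8.3, SEAc = 8.5 permil^2
SEAb mean = 8.3, 95% CI = [6.0, 11.4]
hybrids occupy 94.0% of the wildcat core niche
```

Reading: of 72 simulated hairs, two failed the keratin C/N window and
one was carbon-contaminated. The 38 wildcats span a 31.8‰² convex hull
but a much tighter 8.5‰² core ellipse; the Bayesian posterior brackets
that estimate. The hybrid core ellipse sits almost entirely (94%) inside
the wildcat one — the trophic-redundancy signal the overlap statistic is
designed to expose.

The same analysis runs from the shell:

```sh
isoniche simulate --seed 42 --out cats.csv     # synthetic table + truth JSON
isoniche qc cats.csv --out clean.csv           # QC + corrections
isoniche run --config pipeline.yaml            # full pipeline -> CSV/JSON bundle
```

`isoniche run` writes tidy CSVs (group summaries, Layman/SEA table, SEAb
posteriors, overlaps, trends, tests, correlations), a JSON run report
(config echo, seed, versions, counts) and a log; re-running with the same
config and seed reproduces every number, MCMC included.

## Real data

`read_sample_table` ingests UTF-8 CSV/TSV with one row per individual
(mandatory columns: `sample_id`, `taxon`, `d13C_measured`, `d15N`,
`pctC`, `pctN`; XLSX sources should be exported to CSV once). Unknown
numeric columns ride along as covariates for the correlation screen. The
packaged atmospheric δ¹³C series is a documented synthetic stand-in;
swap in a measured annual series via `load_suess_model("series.csv")`
for publication work.
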