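# Methods

## Scope and data model

All tabular inputs are tidy, tab-separated UTF-8 files (one header row,
decimal point ".", empty cell = missing) validated on load against the
schemas in `fermentome.io.SCHEMAS`. Ambiguous species identifications
are kept as single `a / b` labels: one row is one taxon, never split.
Cell densities are log10 cfu per g (dough) or per mL (liquid medium);
the unit is contextual and never converted. A consequence of the
row-as-taxon convention is that "species counts" are convention-dependent
wherever ambiguous pairs overlap with resolved names; the package only
ever asserts row counts.

## Classification rules

* **Dominance (culturomics):** density ≥ `dominance_cfu` (default 6.0
  log cfu/g). The boundary is inclusive: equality is dominant.
* **Dominance (metagenomics):** relative abundance ≥ `dominance_abund`
  (default 5 %) in at least one sample.
* **Precedence:** when both layers carry a call and disagree, the
  culturomics call wins for the final label, because the inoculum
  densities used downstream in community assembly are culturomics
  measurements. This is a package decision; the source analysis does not
  state a conflict rule.
* **Core vs dispensable:** presence in every sample vs a strict subset.
  Metagenomic "presence" is abundance > `presence_floor` (default 0; no
  detection floor is asserted by default).
* **Satellite:** any non-LAB bacterium, regardless of dominance.
* **Activity:** transcriptionally active requires both any tpm > 0 and
  relative abundance > `activity_abund` (0.1 %) somewhere; taxa never
  reaching the floor are "not evaluated" rather than inactive.
* **Prevalence percent** is `round(100·count/subtotal)` with half away
  from zero, which reproduces every printed value of the bundled survey.

## Redundancy statistics

The core/unique/accessory partition is computed on per-sample presence
(any taxon, copy ≥ 1) and is a true partition of the observed universe
by construction. Pathway-core status is function-level: encoded in every
sample by any taxon.

Differential function tests build a 2×2 table per function (count vs
remainder in each of two samples). With all expected cells ≥ 5 a
log-likelihood-ratio (G) test with Yates continuity correction is used
(`scipy.stats.chi2_contingency`, observed values moved 0.5 toward
expected; zero observations contribute 0 via the x·ln x → 0 limit);
otherwise Fisher's exact two-sided test. This expected-cell switching
rule is a standard convention; the source software names both tests
without stating its switch. A zero row/column margin (a function absent
or saturated in both samples) is reported as G = 0, p = 1. BH adjustment
is statsmodels' `fdr_bh`; tests are two-sided throughout.

## Community design

Key genes are an explicit input flag on the pathway map. The bundled
default map covers the starch/sucrose, pentose-phosphate, pyruvate and
nitrogen enzyme portfolios by EC number with key flags on the central
enzymes; the ≥ 20 criterion counts **distinct** key functions (not
copies) over the carbohydrate + pyruvate/energy + nitrogen mega-pathways.
Quota filling is deterministic (lexicographic) unless a seed is given,
making the published "random strain choice" opt-in and reproducible.
Member densities come from the source sample's culturomics record, with
a fallback to the taxon's highest density in any sample and explicit
overrides — the published community compositions mix source samples for
some members, so provenance cannot be a single sample. Depletion is
computed on encoded functions by default with an `expressed` switch
(tpm > 0) for transcriptome readouts; the lost set of a removal is the
set of functions whose only in-community contributor was the removed
member, which satisfies the identity
`covered(C) = covered(C∖{m}) ∪ contributions(m)` exactly.

## Stability

GC-MS peaks are retained iff area > 1 × 10⁶ **and** spectral match >
85 % (both strict, per "larger/higher than"); quantification is
single-point against 2-methyl-4-pentanol at 33 mg/l with response
factor 1 for all analytes — an assumption, stated here because the
source does not give per-analyte response factors. The differential test
is a two-sided Welch t-test per compound with BH correction within each
community's compound set (each community's timepoint contrast is tested
separately); compounds with < 2 replicates at either timepoint are
excluded with a warning, and summary-only input is refused. Class deltas
sum mean(t1) − mean(t0) over significant compounds only, so they are
additive over disjoint significant sets. PCA operates on z-scored
replicate-averaged compound columns; zero-variance compounds are
dropped, and each component's sign is fixed so its largest-magnitude
loading is positive.

Persistence uses the latest-record rule: a member survives at sampling
day *d* iff its most recent record at or before *d* says detected;
re-detection after a missed sampling restores survivorship.

Growth is the Zwietering re-parameterization of the Gompertz curve,
`y(t) = A·exp(−exp(µₘe/A(λ−t)+1))`, with A the asymptotic log-increase,
µₘ the maximum specific rate (1/h) and λ the lag (h). The fit is
bounded non-linear least squares with a heuristic start (A from the
maximum, µₘ from the steepest observed slope, λ from the 10 %-of-A
crossing) plus four jittered restarts; the best residual wins. A flat
series returns a degenerate A = 0 fit rather than an optimizer error.

## Synthetic data

The generators plant the structure each stage is supposed to recover and
return the truth alongside the fixture. Defaults follow the study scale:
8 samples; a 1163-function core with per-sample unique sets (684, 33,
100 ×6 — the published range endpoints with unreported middles set to
100) and 500 accessory functions shared by 2–7 samples; a 49-taxon
candidate pool of which exactly 13 qualify (one planted exactly at the
20-key-gene, 4-of-8 boundary); 54 volatile compounds with 45 planted
8σ shifts in the unstable community and none in the stable one
(lognormal replicate noise, CV 5 %, 3 replicates); a 9-member
persistence schedule losing 3 strains before day 10 and 2 at day 10;
Gompertz growth at (A = 3, µₘ = 0.5 /h, λ = 2 h) with Gaussian noise and
10-minute online OD sampling over 24 h — the information content of the
lag estimate depends on sampling density, and 10-minute reads are the
realistic regime for benchtop online spectrophotometry. Abundance-like
compositions use a Dirichlet with extra mass on planted dominant taxa
(heavy-tailed, as observed), and copy numbers a truncated geometric on
1–10.

What the generators do **not** emulate: taxon-correlated function
content (functions pick carriers independently), compositional coupling
between omic layers, chromatographic artefacts, or strain-level
variation within a species. Passing the planted-recovery suites
therefore demonstrates correctness of the accounting and statistics, not
robustness to real-data pathologies such as annotation noise or
cross-mapping between taxon label spaces.

## Numerical and degenerate-input choices

* Rounding half away from zero for prevalence percents.
* Welch test with two zero-variance groups: p = 1 if means are equal,
  else p = 0.
* PCA requires ≥ 2 observations and ≥ 2 compounds; collinear data give
  a ≈ 0 second component.
* Empty communities give all-zero multiplicities and zero coverage;
  empty pathways warn and score 0 copies.
* All randomness flows through `numpy.random.default_rng(seed)`; every
  generator is byte-deterministic given its spec.

## Known limitations

* The default key-gene list is a curated EC set covering the documented
  enzyme portfolios; a user with annotation-specific key genes should
  supply their own pathway map (the filter is monotone in both
  thresholds, so stricter maps only shrink the candidate set).
* Yeast dominance in published community labels can derive from the
  metagenomic layer; with culturomics-only input the package will call
  such members subdominant.
* The G-test/Fisher switch at expected < 5 is a convention; near the
  boundary the two tests can disagree in p by more than rounding.
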