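# Methods

## Scope and data model

The package operates entirely on tables: SpliceSeq-style PSI matrices
(events × samples, values in [0, 1], missing allowed), FPKM expression
matrices, minimal MAF mutation records, and right-censored clinical
records, linked per cancer type into a `CohortBundle`. Splice events are
identified by gene symbol, AS type (ES / AA / AD / RI), and gene-level exon
labels kept as opaque strings; no genomic coordinates are used anywhere,
because none of the downstream statistics need them. Tables are UTF-8 TSV
with "" or "NA" for missing cells; PSI is serialized to 4 decimals.
Validation is total: every malformed cell raises an error naming the row
and column, and unknown MAF variant-class spellings degrade to `other` with
a logged warning rather than failing a whole file. Tissue labels come from
an explicit column or from trailing TCGA barcode codes (01–09 tumor, 10–19
normal); mixing the two sources in one file is rejected for
reproducibility. When a patient has several tumor samples, the first in
file order is used.

## Event screen conventions

ΔΨ is tumor − normal (positive = more inclusion in cancer). The per-type
test is a pooled-variance two-tailed Student's t (not Welch). Two
cross-cancer notions are kept distinct because data sparsity and effect
presence are different failure modes:

* **quantified** — both tissue groups have ≥ `min_n` (default 10)
  non-missing samples;
* **detected** — quantified, and p < 0.05 or |ΔΨ| > 0.01.

Events pass the filter when quantified in ≥ 80 % of the cancer types
(inclusive, so 12/15 passes) *and* detected in ≥ 12 of them. The pan-cancer
score is the mean of |ΔΨ| over quantified types only; zero-imputing
unquantified types would penalize sparsely covered events twice. Ties in
every ranking break by identifier, so output is independent of input order.
Note that the filter removes null decoy events by construction (they are
undetected); rank-against-decoys comparisons therefore use the ranking of
all quantified events, while the pipeline reports the filtered ranking.

Paired alterations use the strict inequality |ΔΨ| > 0.15, and the frequency
denominator counts evaluable pairs only (both PSI present). Patients
contribute once per (patient, cancer type).

## Factor screen

Per-type correlations use tumor samples only, Pearson r of event Ψ against
log2(FPKM + 1) (the log transform is configurable off), pairwise-complete
over missing values, unevaluated below 10 pairs or on constant series. The
per-factor summary is the **median** r across evaluable types — robust to a
single discordant type — reported with the count of types below r = −0.3.
No multiple-testing correction is applied inside the screen (the ranking is
by effect size, not significance). The cross-cancer mode correlates
per-type ΔΨ with per-type Δ(mean log2(FPKM + 1)), one point per type,
requiring ≥ 3 points.

## Stratification and survival

Mutation status for the target gene: any non-silent mutation ⇒ `Mut`;
otherwise tumor FPKM below the 12th percentile of non-mutant tumors ⇒
`LowExpr`; else `WT`. "Below 12 %" is read as a percentile of the
non-mutant distribution — the only reading consistent with a "low-FPKM
group" of roughly fixed size — and the percentile is a parameter.
Expression splits default to the median rule with ties going high; tertile
and fixed-threshold rules are available, and every pipeline report records
the rule used. The marker (PD-L1-like) flag is strictly greater than the
cut (default 1.75 normalized FPKM); the normalization of the input matrix
is the caller's responsibility.

The Kaplan–Meier estimator and the k-sample log-rank test are implemented
in-package (lifelines serves only as a test oracle). Deaths are processed
before censorings at tied times. The log-rank statistic is the
observed-minus-expected quadratic form with hypergeometric covariance over
pooled death times, df = k − 1. Group comparisons of marker expression use
the pooled t for two groups and one-way ANOVA with Bonferroni-adjusted
pairwise t contrasts for more; Dunnett many-to-one contrasts are estimated
by seeded Monte-Carlo sampling of the max-|t| null (200 000 draws by
default), reported with their binomial standard error — simpler to verify
than multivariate-t quadrature, and reproducible bit-for-bit given a seed.
Closed-form distribution functions (t, F, χ²) come from scipy.

## Synthetic cohorts

The generator emulates the statistical shape of a 15-type tumor/normal
study: 60 tumor and 30 normal samples per type by default, all normals from
paired patients; 36 driver genes × 3 exon-skipping events; a 172-factor
expression panel; Bernoulli per-gene mutations (rate 0.4 for the target
gene, 0.08 otherwise, with a mixture of variant classes); exponential
survival with uniform-in-time censoring at rate 0.3 over two treatment
arms.

Decoy event PSI comes from Beta(μ·30, (1−μ)·30) patient baselines with
μ ~ U(0.1, 0.9), plus N(0, 0.03) within-patient residual noise, clamped to
[0, 1]. The planted event uses a fixed baseline of 0.35 with N(0, 0.08)
patient-level noise; a random baseline near the boundaries would clamp away
the planted shift. Three planted effects share one construction:

* **Group shift + paired alterations.** A Bernoulli(0.5) subset of tumor
  patients in 12 of the 15 types receives a shift of
  planted_delta / altered_fraction (= +0.4), so the group-mean ΔΨ equals
  the nominal +0.2 *and* the paired alteration fraction at the 0.15
  threshold equals the altered fraction. The same per-sample noise applied
  independently to both tissues would make these two targets incompatible
  (pair-delta noise alone would cross the threshold in ~20 % of unaltered
  pairs), which is why patient baselines are shared across a patient's two
  tissues and only a small within-patient residual separates them.
* **Regulator coupling.** A standard-normal patient latent z drives both
  the regulator's measured tumor log-expression (μ + z) and the planted
  event's PSI through an additive term b·z shared by both tissues of the
  patient. b is set per type from the target correlation r and the other
  variance components, b = r/√(1−r²)·σ_other, so the realized tumor-sample
  correlation lands near the −0.6 target (clamping attenuates it by
  ~5–8 %). The regulator's tumor mean log2 expression is additionally
  lowered by 1 in the planted types, giving the cross-cancer ΔΨ-vs-Δexpr
  plot its negative sign. |r| ≥ 0.95 is rejected as infeasible for the
  clamped link.
* **Marker and survival.** Marker FPKM = lognormal baseline +
  2·Ψ_planted for patients without a non-silent target-gene mutation
  (baseline only for mutants), reproducing the WT-only marker coupling.
  Patients who are target-gene non-mutant, regulator-low (z < 0), and on
  the first arm carry hazard λ·HR (defaults 1/1000 per day × 2.5); a
  censored patient's time is uniform over their event time.

All randomness streams from one seed via `default_rng([seed, type_index])`,
so outputs are byte-identical across runs and adding a cancer type does not
reshuffle existing ones. The ground truth (per-type true ΔΨ, per-patient
altered flags, strata and hazards) is emitted as a JSON manifest alongside
the TSVs.

### What the generator does and does not emulate

It reproduces the *decision structure* the screens face — sparse
quantification is absent but decoy noise, mutation co-occurrence, marker
coupling and censoring are present at realistic magnitudes. It does not
model read-level quantification error, batch effects, correlated gene
networks, copy number, or non-proportional hazards; passing recovery tests
therefore demonstrates correctness of the screening logic and its operating
points under the stated model, not robustness to every artefact of
consortium data.

## Numerical choices and problem sizes

Tolerances in tests: exact formulas to 1e-10–1e-12 against independent
oracles (scipy, lifelines, hand tabulations); Monte-Carlo quantities to a
few standard errors. Recovery and calibration checks run 20 studies at the
default conditions, alteration-frequency calibration 50 single-type studies
at 100 pairs, and the log-rank operating points 1000 null / 50 alternative
replicates at n = 120 — sizes chosen so the whole suite completes in well
under a minute of simulation time while keeping Monte-Carlo error small
relative to the acceptance margins.

## Known limitations

* The event screen covers the four simple AS classes; mutually exclusive
  exons and complex events are out of scope.
* Survival analysis is the log-rank test and the product-limit curve; no
  Cox modelling or covariate adjustment.
* The driver stage ranks raw mutation frequency; it does not model
  background mutation rates.
* The "normalized FPKM" behind the marker cut is whatever the supplied
  matrix contains; no normalization is performed internally.
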