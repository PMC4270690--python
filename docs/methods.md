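# Methods

## The statistical problem

A case-control cohort typed at six classical HLA loci (HLA-A, -C, -B, -DRB3,
-DRB1, -DQB1) and genotyped/imputed at SNPs across the MHC shows many
overlapping association signals because the region is inherited as long
conserved haplotypes. The package's job is to decide how many *independent*
signals exist and which variables best represent them. All analyses operate
on additive dosage columns in [0, 2]; fractional dosages (imputed SNPs) are
used as-is so imputation uncertainty propagates into the regression rather
than being rounded away.

## Models and procedures

**Single-variant scan.** For each variable v,
`logit P(case) = α + β·d_v + Σ γ_j·d_cj` with optional conditioning
covariates c_j. Estimation is maximum likelihood (Newton; an L-BFGS refit
backs up the rare fits where a quasi-separated covariate stalls Newton —
the tested variable's coefficient and the log-likelihood are stable in those
fits even though the offending covariate's coefficient is not). Scan
p-values are Wald by default (standard for region-wide scans; a
likelihood-ratio variant is exposed through `ScanSettings.test_kind`), CIs
are exp(β ± 1.96·se). A fit is reported non-converged, with a reason and no
OR, when the tested variable itself separates (|β| > 10 or se > 25) or the
dosage is constant. Subjects missing the dosage or a covariate are dropped
per test (complete-case), recorded in `n_used`. The family-wise threshold is
Bonferroni α/N over the variable manifest.

**Conditional strategies.** A strategy is an ordered list of steps, each an
explicit variant id (an analyst's anchor choice) or `top_remaining` (the most
significant variant of the previous step's scan, ties broken by smaller p,
then larger |β|, then lexicographic id, with p and |β| compared at 10
significant digits so exact mirror-encodings tie deterministically). Step k
conditions on exactly the variants chosen at steps 1..k−1; the run stops when
no variant remains below the family threshold, and a terminal scan always
verifies the stop state.

**Multivariate selection.** Locus sufficiency: for a baseline locus, an LRT
of each other locus's allele columns added to the baseline-allele model, df
counting only linearly independent added columns (per locus the most frequent
control allele is the implicit reference; additional collinearity is removed
by a QR rank filter and logged). Stepwise: bidirectional moves from an
intercept-only start, accepting the single add/drop that lowers
AIC = −2·logL + 2k the most, ties lexicographic; a forward-leaning start is
the appropriate default when candidates number ~10% of subjects. Pruning:
iteratively drop the covariate with the largest single-covariate LRT p until
all remaining are ≤ 0.01 (boundary inclusive). Greedy stepwise is not a
global optimizer in general; on the well-separated candidate sets it is used
for here it attains the exhaustive best-subset AIC, which the test suite
verifies by brute force for small k. In final-model tables a covariate whose
Wald se exceeds 10 is flagged `stable=False`: its LRT p remains valid but the
Wald CI is uninformative (rare covariates near separation).

**SNP QC.** Hardy–Weinberg uses the exact conditional test (probabilities of
heterozygote counts given allele counts; two-sided p = sum of outcomes no
more probable than observed), computed in controls only — exact tests are
the standard for panels of this size, where chi-square approximations
misbehave at low MAF. Filter order is call rate → MAF → HWE and the first
failure is recorded. The imputation filter splits SNPs into half-open MAF
bins [1%, 3%), [3%, 5%), [5%, 50%] (the bin boundaries are otherwise
ambiguous) and chooses, per bin, the smallest r² cutoff whose retained set
has mean r² above 0.8 — the maximal retained set subject to the mean
constraint, found by a monotone sweep over observed cutpoints (provably
optimal because the retained mean is monotone in the cutoff). The
alternative reading — mean over *all* SNPs in the bin — is available via
`mean_over_all=True`.

**LD.** r² is the squared Pearson correlation of dosage vectors (composite
genotypic r², equal to haplotype r² under random mating), computed in
controls by default since control LD describes population haplotype
structure undistorted by case enrichment. Extension profiles categorize SNPs
at r² > 0.2 / 0.5 / 0.8 around an anchor and report each category's
base-pair span; categories are nested by construction. A constant vector has
undefined r² and raises — it is never silently 0.

**DRB1–DQB1 blocks.** Phase is forced whenever at most one of the two loci
is heterozygous. Double heterozygotes are resolved by a two-locus
haplotype-frequency EM fitted on controls, followed by most-probable-phase
hard assignment (ties break lexicographically on the block-label pair).
Hard assignment is appropriate here because the blocks of interest are in
strong LD, where the posterior is near-degenerate; on the study-scale
synthetic cohort the assignment matches the generator's true phases for ~99%
of subjects. `known_phases` bypasses the EM when truth is available
(simulated data). Pairings matching no block rule go to an explicit
`other-DRB1-DQB1` column, never silently dropped.

## The synthetic cohort generator

**What it emulates.** A Scandinavian-style case-control study: 365 cases,
368 controls; conserved haplotype families (an AH8.1 analog at frequency
0.105 plus 3% recombinant B\*08 haplotypes, an AH7.1-like B\*07 family
totalling 8%, a DRB1\*13:01–DQB1\*06:03 family at 5.5%,
DRB1\*04–DQB1\*03 at 14%, rare protective blocks at 0.5–1.5%, and common
neutral fillers); 10 tag SNPs whose LD with the B\*08 anchor spans r²
0.43–0.83, decaying with distance; a 7-SNP class III block in perfect
internal LD, carried independently of every HLA family (latent frequency
0.18); and 103 null SNPs. Planted per-copy odds ratios: 4.3 (B\*08), 1.7
(B\*07), 2.5 (C\*06), 4.9 (13:01 block), 0.4 / 0.1 / 0.3 (protective
blocks), 2.32 (class III tag). Family frequencies are not published for the
motivating study; the values above were fixed once from population-genetics
expectations, with the rare protective-block frequencies back-solved from
the width of their reported multivariate confidence intervals.

**Mechanics.** Each individual is two draws from the family pool; a
recombination "leak" (default 0.01 per adjacent-segment interval across the
layout A–C–B–MICA–classIII–DRB3–DRB1–DQB1) swaps downstream segments between
the two gametes, so conserved haplotypes are realistically mosaic. SNP
alleles are emitted per gamete from per-family Bernoulli rates (the
background rate for each tag SNP is solved in closed form to hit its target
haplotype r² with the anchor). Disease probability is
`expit(α + Σ β_v·d_v)` with effects evaluated on the *realized* (mosaic)
gametes — exactly the quantities the encoder later measures — and the
baseline prevalence is 1/10,000 (α = logit(1e-4)); screening proceeds in
seeded batches until the case and control targets are met, with a hard
attempt cap that raises rather than looping forever. Retrospective sampling
under a logistic model leaves per-copy ORs invariant, so planted effects are
the estimands of the adjusted fits.

**Presets.** `study_preset` is the default study condition above.
`recovery_preset` exists for parameter-recovery experiments: a dedicated
16-family pool in which every planted variable spans several families with
mixed backgrounds and the recombination leak is raised to 0.12, so no
candidate column is a strong proxy of a planted one — in a fully conserved
pool "which variable carries the effect" is statistically unidentifiable and
parameter recovery would test luck, not correctness. It uses baseline
prevalence 5% and n = 600/600; by OR invariance the prevalence choice only
affects how fast cases accrue. `null_preset` (no effects, 200+200, 50
family-independent SNPs, prevalence 0.3) drives type-I calibration.
`qc_fixture` is a fully deterministic 471-SNP genotyped panel built from
rounded Hardy–Weinberg expectations: 405 clean SNPs plus 30 call-rate, 20
MAF and 16 control-HWE violations, each breaking exactly one filter, with a
manifest of intended fail reasons. `category_count_fixture` reproduces the
study-scale variable-category sizes (18,644 + 95 + 20 + 7 + 4 + 1 = 18,771)
for manifest and threshold checks.

**Imputation noise.** `add_imputation_noise` blurs hard calls with Gaussian
noise truncated to [0, 2]; the noise scale is bisected per SNP until the
realized squared correlation with the truth hits the per-MAF-bin target
(within 0.03, asserted when n ≥ 1000). Truncation makes realized r²
monotone in the noise scale, so bisection is exact.

**What the generator does not emulate.** LD structure is declarative, not
evolved (no coalescent, mutation or genealogy); SNP alleles are conditionally
independent given the family, so inter-SNP LD beyond the anchor tags and the
class III block is absent; HLA typing is error-free and complete; there are
no covariates (age, sex, population strata) — the emulated design is a
single-population, matched study. Passing tests therefore demonstrate that
the statistical machinery recovers a known architecture under the stated LD
model, not that it is robust to typing error, stratification or fine-scale
recombination heterogeneity.

## Analysis conventions

The synthetic study analyses use the emulated study's family-wise threshold
P ≤ 2.66e-6 (0.05 over its 18,771-variable comparison family) even though
the preset's SNP panel is down-sampled to 120 markers for tractability: the
threshold is a property of the emulated analysis, not of the panel size. In
parameter-recovery checks, the planted OR is compared against the fit
adjusted for the other planted signals: with ~50% cases in the sample, the
univariate marginal OR of a variant is attenuated by noncollapsibility and
is not expected to equal the planted conditional OR, so the adjusted model
is the correct estimand. Problem sizes in the test suite (replicate counts
of 10–50 for stochastic properties, 500 for null calibration; n of 300–1,200
for unit-level fits) were chosen so each check's expected statistical margin
comfortably exceeds its binomial sampling noise.

## Numerical choices and degenerate inputs

- Dosages outside [0, 2] are an error naming the offending cell — never
  clipped.
- VCF dosage prefers the DS field, falls back to hard-calling GT, and errors
  when a record has neither.
- The exact HWE recurrence works in log space; monomorphic samples return
  p = 1, and p is floored at the smallest positive double.
- Wald CI exponents are clipped at ±700 to avoid overflow in near-collinear
  fits (which are flagged anyway).
- Empty manifest parts warn and are skipped; duplicate variant ids across
  parts are an error.
- Subjects joining HLA and SNP sources are intersected in HLA-table order,
  with dropped ids reported.

## Known limitations

Stepwise AIC on strongly confounded candidate sets (the conserved study
pool) returns *a* minimal tagging set, not necessarily the planted
variables — that is a property of the region's LD, visible in the analysis
scripts, and the reason the recovery preset exists. Wald CIs for rare
covariates near separation are uninformative (flagged, LRT p still valid);
no Firth-type penalization is implemented. The EM phaser is two-locus only,
by design. No support for MACH-format dosage files or phased input beyond
the generator's own truth structures.
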