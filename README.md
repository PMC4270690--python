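# mhcfinemap

Fine-mapping disease associations inside the major histocompatibility
complex (MHC) is hard for a specific reason: the region combines a very high
density of immune genes with long conserved haplotypes (e.g. the ancestral
haplotype AH8.1, `A*01-C*07-B*08-DRB3*01:01-DRB1*03:01-DQB1*02:01`), so
dozens of variants tag each other and marginal association signals cannot be
read as causal. `mhcfinemap` implements the statistical toolkit used to
dissect such a region in a case-control cohort — built for primary
sclerosing cholangitis (PSC)-style studies where HLA typing, MHC SNPs and
candidate functional variants (DR-beta amino acids, KIR-ligand epitopes,
MICA5.1) must be analyzed in one frame — together with a synthetic cohort
generator that reproduces the relevant LD structure so every method can be
validated against a known truth.

## What it does

Every tested variable is an additive **dosage** column: the per-subject count
(0–2, fractional after imputation) of copies of a SNP allele, a classical HLA
allele (serotype-level groups at HLA-A/-B, two-digit at HLA-C, four-digit at
DRB3/DRB1/DQB1), a DRB1–DQB1 haplotype block (phase-resolved by a two-locus
EM on controls), a DR-beta residue at position 37 or 86, a KIR epitope
(Bw4/Bw6, C1/C2) or MICA5.1. On that manifest the package provides:

- **SNP QC** (`mhcfinemap.qc`): call rate ≥ 95%, MAF ≥ 1%, exact conditional
  Hardy–Weinberg test in controls at p ≥ 1e-4; plus the MAF-stratified
  imputation filter — SNPs split into MAF bins 1–3% / 3–5% / >5%, each bin's
  r² cutoff set as low as possible subject to the retained SNPs' mean
  r² > 0.8.
- **Association scan** (`mhcfinemap.association`): per-variant additive
  logistic regression `logit P(case) = α + β·dosage (+ conditioning
  covariates)`, Wald OR/CI/p, Bonferroni family threshold α/N.
- **Conditional strategies** (`mhcfinemap.conditional`): declarative
  sequences of conditioning choices (explicit anchors or greedy
  `top_remaining`) with per-step residual-signal reports — the machinery for
  demonstrating that signals are independent (or are not).
- **Multivariate selection** (`mhcfinemap.selection`): single-locus
  sufficiency likelihood-ratio tests; bidirectional stepwise selection
  minimizing AIC = −2·logL + 2k over allele/block candidates; LRT pruning at
  P ≤ 0.01 yielding the final multivariate OR table.
- **LD profiling** (`mhcfinemap.ld`): composite genotypic r² and
  haplotype-extension spans at r² > 0.2 / 0.5 / 0.8 around an anchor.
- **Synthetic cohorts** (`mhcfinemap.simulate`): individuals drawn as two
  mosaic haplotypes from a pool of conserved families, disease assigned by a
  prospective logistic model over planted per-copy log-odds, then sampled
  retrospectively to the target case/control counts — which preserves odds
  ratios, making parameter recovery testable. The study preset emulates a
  365-case / 368-control Scandinavian cohort with planted ORs 4.3 (B\*08),
  1.7 (B\*07), 2.5 (C\*06), 4.9 (DRB1\*13:01–DQB1\*06:03), 0.4 / 0.1 / 0.3
  (protective class II blocks) and 2.32 (an independent class III SNP block).

## Worked example

The analysis is organised as numbered drivers; run them in order from the
repository root (outputs land under `results/`):

```
python analysis/01_simulate_cohort.py     # the synthetic study cohort
python analysis/02_encode_variants.py     # the unified dosage manifest
python analysis/03_snp_qc.py              # genotyped-panel QC + imputation filter
python analysis/04_association_scan.py    # primary scan
python analysis/05_conditional_strategies.py
python analysis/06_model_selection.py     # Table-1-style multivariate model
python analysis/07_ld_profiles.py         # haplotype extension
```

Selected output (seed 17):

```
genotyped panel: 471 SNPs -> 405 pass (30 call-rate, 20 MAF, 16 HWE failures)

primary scan: 197 variables tested, 40 below P <= 2.66e-06
top signal per category:
  amino_acid       Asn37                    OR= 3.66 [2.84, 4.72]  P=1.18e-23
  hla_allele       B*08                     OR= 3.12 [2.40, 4.07]  P=3.52e-17
  snp              tagB8_04                 OR= 3.02 [2.33, 3.91]  P=5.26e-17

strategy-I: conditioning sequence B*08 -> DQB1*06:03 -> cIII_2
  [B*08 + DQB1*06:03 + cIII_2] 0 signals below threshold  -- exhausted
```

Reading this the way an analyst would: the strongest single signal is the
aggregate amino-acid variable Asn37 (it pools the planted B\*08/AH8.1 and
DRB1\*13:01 risk haplotypes), the strongest classical allele is the planted
class-I anchor B\*08, and the top SNPs are its LD tags. Conditioning on the
class-I anchor exposes the class II block (here via its DQB1\*06:03 proxy,
r² ≈ 1 with the block), then the class III SNP block; after those three
choices nothing in the region remains study-wide significant — the planted
architecture, recovered. The multivariate step (06) retains the planted risk
variables with ORs bracketing their planted values and rejects every
"protective" variable whose case deficit is only displacement by the risk
haplotypes.

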