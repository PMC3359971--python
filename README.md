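# epiloci

Knowledge-driven SNP–SNP interaction (epistasis) analysis for quantitative
traits, with an adaptive locus-based validation procedure designed to
overcome tag-SNP LD attenuation of interaction effects.

The package provides, as tested, reusable components:

- **`epiloci.geno_qc`** — genotype I/O (VCF via cyvcf2, PLINK bed/bim/fam via a
  built-in reader/writer), posterior hard-calling (info ≥ 0.6, max posterior
  ≥ 0.8), individual/variant QC (missingness > 10 %, call rate < 90 %,
  MAF ≤ 1 %, exact-test HWE p < 10⁻⁶), composite LD r², 3×3 genotype cell
  tables and the per-pair eligibility rule (all cells > 20 discovery / > 10
  validation, pair r² < 0.1).
- **`epiloci.pheno_prep`** — visit averaging, log-TG transform, medication
  exclusion, covariate design (sex, age, age², BMI, plate dummies, top-10
  PCs by SVD of the standardized genotype matrix), pedigree kinship, and
  REML mixed-model residualization for related samples.
- **`epiloci.epistasis_test`** — orthogonal Cockerham coding
  (x ∈ {−1,0,+1}, z = +0.5 het / −0.5 hom), nested OLS fits of the
  no-interaction and full two-locus models, the 4-df interaction F-test,
  the 1-df additive-only variant, per-component t-tests (A×A, A×D, D×A,
  D×D), ΔR², and Bonferroni correction.
- **`epiloci.candidate_pairs`** — candidate pair generation from hit lists
  (all pairs), gene-pair (PPI) lists (cross products), and gene sets
  (all pairs over the union), with ±5 kb SNP-to-gene mapping.
- **`epiloci.adaptive_validation`** — three-stage sequential locus-based
  validation (anchor pair → anchor × 200 kb windows → 100 kb window ×
  window) with per-stage Bonferroni correction and early stopping, fine
  mapping, and Fisher-combined cross-cohort evidence.
- **`epiloci.scan_engine`** — scan orchestration, full eligibility
  bookkeeping, deterministic output ordering, QQ-plot data.
- **`epiloci.synthetic_data`** — generators for HWE genotypes, tag–causal
  haplotype LD at exact target r², Cockerham-parameterized phenotypes,
  multi-tag locus windows, population stratification, and sibling-block
  kinship, so the whole pipeline is testable without restricted cohort data.

## CLI

```sh
epiloci simulate --n 5000 --seed 1 --i-aa 1.0 --out scratch/cohort
epiloci qc       --genotypes scratch/cohort.bed --out scratch/clean
epiloci scan     --genotypes scratch/cohort.bed --pheno scratch/cohort.pheno.tsv \
                 --pairs-file pairs.txt --out scratch/scan
epiloci finemap  --genotypes ... --pheno ... --snp-a rs1 --snp-b rs2 --out scratch/fm
epiloci validate --genotypes ... --pheno ... --snp-a rs1 --snp-b rs2 --out scratch/val
epiloci report   --results scratch/scan.results.tsv --out scratch/qq.tsv
```

All outputs are tab-delimited text plus small JSON manifests.

## Conventions

- Genotype calls count copies of the alternate (counted) allele; `-1`/NaN is
  missing. Positions are 1-based (VCF/.bim convention).
- LD r² is the composite dosage-correlation surrogate (phase unknown).
- HWE uses the exact conditional test by default (`chisq` available).
- Complete-case analysis per SNP pair; pairs whose design becomes rank
  deficient are skipped with a logged reason, never fitted degenerate.
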