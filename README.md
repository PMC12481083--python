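# panelprs

Polygenic risk scoring from targeted next-generation-sequencing panels, with
linkage-disequilibrium proxy substitution and a full method-comparison
validation suite.

## The problem

The 313-variant breast-cancer polygenic risk score (PRS₃₁₃) used by
BOADICEA/CanRisk was developed and validated on SNP microarrays with
imputation. Clinical oncogenetics laboratories, however, already sequence
targeted gene panels; computing the PRS from the same sequencing run removes
the need for a separate genotyping platform. Targeted sequencing has its own
failure modes — homopolymers and repeats resist accurate capture and
alignment, and some targets are systematically under-covered — so an
NGS-adapted panel replaces problem sites with nearby **proxy SNPs** in strong
linkage disequilibrium, and any site with no usable surrogate is scored as
homozygous wild-type. `panelprs` implements that scoring scheme and the
battery of checks used to validate it against an array reference.

## The model

For a sample with effect-allele dosages *d_v* ∈ {0, 1, 2} over model
variants *v* with per-allele log-odds weights *w_v*:

```
PRS = Σ_v  w_v · d_eff(v)
```

where the effective dosage `d_eff(v)` is

* the variant's own called dosage (*direct*),
* the surrogate's dosage when a proxy is mapped in positive LD (*proxy*),
* `2 − d(proxy)` when target and surrogate effect alleles are in **negative
  LD** — the surrogate's counted allele travels with the target's
  non-effect allele, so the observed count is reversed (*proxy_reversed*),
* `0` for sites declared unsequenceable (*wildtype_fallback*) or missing
  after resolution (*missing_as_wildtype*).

Proxy selection uses the standard two-locus LD statistics computed from
haplotype counts: `D = p_AB − p_A p_B`, `D′ = |D| / D_max`, and
`r² = D² / (p_A(1−p_A) p_B(1−p_B))`; candidates within a 50 kb window are
ranked by r², then D′, then distance, and the sign of D fixes the
orientation.

Validation compares a test call set against a reference method with:
TP/TN/FP/FN classification on the carrier dichotomy (≥1 effect allele) and
the derived sensitivity/specificity/PPV/NPV; exact three-level genotype
concordance per SNP and per sample; effect-allele frequency agreement;
squared Pearson correlation of the scores; per-target mean-depth QC
(<30× low, >100× good); and a 1-df Hardy–Weinberg chi-square screen.
Risk percentages can be banded into NICE categories (lifetime: <17 % /
17–30 % / ≥30 %; 10-year: <3 % / 3–8 % / >8 %) and category changes
cross-tabulated between methods.

A cohort simulator generates ground-truth genotypes with controlled LD
between proxied pairs, an array observation with higher miscall rates at
imputed sites, and an NGS observation with negative-binomial depth,
depth-dropout, read-sampling genotype calls, and systematic miscalls in
low-complexity context — so the whole pipeline is testable end to end
without patient data.

## Worked example

```python
from panelprs import (SimulationConfig, simulate_study, prs_series,
                      coefficient_of_determination, confusion_counts,
                      confusion_metrics, resolve_matrix, DosageMatrix)

config = SimulationConfig(n_samples=154, seed=42)
study = simulate_study(config)
cohort = study.cohort

array = DosageMatrix(resolve_matrix(study.array_obs, cohort.model)[0].astype(float))
ngs = DosageMatrix(
    resolve_matrix(study.ngs_obs, cohort.model, cohort.proxy_map)[0].astype(float)
)

metrics = confusion_metrics(confusion_counts(array, ngs)).rounded()
print(f"calls compared : {confusion_counts(array, ngs).total}")
print(f"sensitivity    : {metrics['sensitivity']} %")
print(f"specificity    : {metrics['specificity']} %")

prs_array = prs_series(array, cohort.model)
prs_ngs = prs_series(study.ngs_obs, cohort.model, cohort.proxy_map)
r2 = coefficient_of_determination(prs_array, prs_ngs)
print(f"PRS range      : {prs_array.min():.4f} to {prs_array.max():.4f}")
print(f"PRS R^2        : {r2:.3f}")
```

Output:

```
calls compared : 48202
sensitivity    : 98.09 %
specificity    : 97.28 %
PRS range      : -3.0650 to 0.4613
PRS R^2        : 0.898
```

48,202 is 154 samples × 313 variants — every call lands in exactly one
confusion cell. Sensitivity/specificity measure carrier-call agreement of
the proxy-substituted NGS panel against the array reference, and the PRS R²
is the squared correlation of the two score vectors over the cohort.

The same workflows are available from the shell:

```
panelprs simulate --seed 42 --out fixtures/
panelprs score --model fixtures/model.tsv --proxy-map fixtures/proxy_map.tsv \
    --panel-extra fixtures/panel_extra.tsv --vcf fixtures/ngs_optimized.vcf \
    --out scores/
panelprs validate --model fixtures/model.tsv --proxy-map fixtures/proxy_map.tsv \
    --panel-extra fixtures/panel_extra.tsv --ref fixtures/array.vcf \
    --test fixtures/ngs_optimized.vcf --depths fixtures/ngs_depths.tsv --out report/
```

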