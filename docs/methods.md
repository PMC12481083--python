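# Methods

## Scoring model

The PRS is a weighted allele count: for each model variant the number of
effect-allele copies in the diploid genotype (0, 1 or 2) is multiplied by
the variant's per-allele log-odds weight, and the products are summed. Hard
genotype calls are used throughout; when a call cannot be reduced to an
unambiguous count (uncalled or half-called genotype, non-diploid call, or a
genotype carrying an allele outside the model's ref/alt pair) the cell is
missing and is logged. Variants are matched between model and VCF by
(chromosome, position, ref, alt) after stripping any `chr` prefix and
reducing ref/alt to their left-aligned minimal representation, so padded
indel spellings match.

Proxy resolution replaces the *genotyping* of a site, never its
coefficient: a substituted variant contributes the surrogate's dosage —
reversed to `2 − d` when the surrogate's effect-aligned allele is in
negative LD with the target's — multiplied by the **original** variant's
weight. Sites declared unsequenceable, and any cell still missing after
resolution, are scored as homozygous wild-type (dosage 0). This fallback is
applied regardless of the weight's sign and is always surfaced in the
per-sample resolution log, because silently scoring absent data is the one
failure mode a clinical pipeline must be able to audit. Scores are kept at
full floating precision; rounding (4 decimals) happens only in the output
table.

## LD statistics and proxy ranking

From the four two-locus haplotype counts, with A/B the effect alleles:
`D = p_AB − p_A·p_B`; `D′ = |D|/D_max` with
`D_max = min(p_A(1−p_B), (1−p_A)p_B)` for positive D and
`min(p_A p_B, (1−p_A)(1−p_B))` for negative D; and
`r² = D²/(p_A(1−p_A)p_B(1−p_B))`. LD is undefined (an error) at a
monomorphic locus. Candidate surrogates within a 50 kb window are ranked by
r² descending, then D′ descending, then distance ascending; r² leads
because it directly bounds the accuracy of dosage substitution, while D′
can be 1 even when allele frequencies differ enough to make the surrogate a
poor dosage predictor. Exclusion for repeat/low-complexity context is a
caller-supplied flag: deciding it requires genome-context inspection that
is out of scope here. The orientation recorded in the proxy map is the sign
of D between the two effect alleles.

## Validation battery

* **Confusion classification.** A call is *positive* when it carries at
  least one effect allele. Both methods positive → TP, both negative → TN,
  test-only positive → FP, reference-only positive → FN. Under this carrier
  dichotomy a heterozygous/homozygous swap is a TP — both methods call a
  carrier — while still counting as discordant in the genotype-concordance
  metric; the two statistics answer different questions. Every resolved
  (sample, variant) cell lands in exactly one class, so the four counts sum
  to samples × variants, a structural identity the suite asserts on every
  cohort. Sensitivity = TP·100/(TP+FN), specificity = TN·100/(TN+FP),
  PPV = TP·100/(TP+FP), NPV = TN·100/(TN+FN); a zero denominator yields
  "not available", never 0. Report display uses 2-decimal half-up rounding;
  machine-readable output keeps raw values.
* **Concordance** is exact three-level genotype identity per SNP and per
  sample, over cells evaluable in both matrices; SNPs under a 0.90 fraction
  are flagged.
* **Allele frequency** per variant is Σdosage / (2 × non-missing samples).
* **Score agreement** is the squared Pearson correlation; it is sign-blind,
  which is documented rather than "fixed".
* **Depth QC** flags a target low when its mean depth across samples is
  below 30× and good above 100×; the dropout threshold used in simulation
  (8 reads per call) is a different, per-call quantity.
* **Hardy–Weinberg screening** is the 1-df chi-square of observed genotype
  counts against expectations at the estimated allele frequency;
  monomorphic input returns (0, 1).

## Risk categorization

Risk percentages (CanRisk/BOADICEA output) are inputs; the package only
bands them. Lifetime risk: <17 % near-population, 17 ≤ r < 30 moderate,
≥30 high. Ten-year risk: <3 near-population, 3 ≤ r ≤ 8 moderate, >8 high —
the boundaries land where the category definitions put them (17 and 3 are
moderate; 8 is still moderate; 30 is high). Category changes between
methods are counted over records matched by (subject, scenario, horizon),
with a complete 3×3 cross-tab whose off-diagonal sum equals the change
count; the changed percentage is emitted both at one decimal and at integer
display rounding.

## Cohort simulator

The simulator exists so that every operation above can be tested without
patient data. Its default geometry is a 154-sample cohort scored on a
313-variant model (46 indels) of which 105 sites are directly array-typed
and 208 imputed; 29 problem sites drawn from the imputed stratum, 27 of
them substituted by surrogates (2 in negative LD) and 2 assumed wild-type;
15 under-covered targets on the unoptimized panel; and a 559× mean target
depth.

* **Truth genotypes.** Unlinked variants draw dosages binomial(2, p) with
  effect-allele frequencies uniform on (0.05, 0.95). Each proxied pair is
  drawn jointly from the four-haplotype distribution at its designed
  correlation r; the surrogate's allele frequency is set equal to the
  target's (positive LD) or its complement (negative LD), which makes any
  |r| ≤ 1 feasible and gives D′ = |r| analytically. Weights are
  N(0, 0.06²), which at these frequencies yields a population score
  standard deviation near 0.6, in line with published PRS₃₁₃
  distributions.
* **Array observation.** Each call is independently replaced by one of the
  other two genotype classes with probability 0.001 at directly typed
  sites and 0.03 at imputed sites. The imputed-site rate is chosen to
  reproduce the qualitative pattern of imputation error (concordance
  failures concentrated at imputed sites, method-comparison sensitivity in
  the mid-90s); no quantitative per-site imputation error rate is
  published for this panel, so the value is a calibration of plausibility,
  not a measured constant.
* **NGS observation.** Per cell, depth is negative-binomial (dispersion
  10) around the site's mean; calls with fewer than 8 reads are missing.
  Effect-allele reads follow binomial(depth, q) with q ∈ {e, ½, 1−e} by
  true dosage and symmetric per-read error e = 0.001, and the call is the
  maximum-likelihood genotype — giving depth-dependent accuracy that is
  negligible at 559×. Low-complexity sites additionally suffer a per-call
  miscall probability (default 0.30) applied after the read-based call:
  random read error averages out at high depth, whereas real homopolymer/
  repeat failures are systematic alignment artifacts, so they are modelled
  at the call level. Dead sites have mean depth 0 (all calls missing);
  other under-covered sites have mean depth 5, below the dropout
  threshold for most calls.
* The "unoptimized panel" observation is the same process without the
  surrogate targets; scoring it without a proxy map reproduces the
  missing-as-wildtype degradation that proxy substitution repairs.

All randomness flows from a single seed; identical configurations produce
bit-identical outputs.

### What the simulator does not emulate

Haplotype-reference mis-phasing (imputation error is modelled as
independent per-call miscalls, not as a mechanism), multi-locus LD beyond
each target/surrogate pair, population structure and relatedness,
reference-allele bias, and read-level artifacts (no FASTQ simulation).
Passing tests therefore demonstrate the correctness of the scoring and
validation machinery under controlled error processes, not the real-world
accuracy of any particular sequencing panel; the empirical concordance of
a real panel must still be established on paired patient data.

## Numerical and design notes

* Ties in expected-dosage rounding cannot arise because only hard calls
  are consumed; probabilistic dosages are out of scope.
* D′ and r² are clipped at 1 to absorb float round-off in degenerate count
  tables; D = 0 defines D′ = 0 and positive sign.
* Half-up rounding uses `decimal.Decimal` on `repr(value)` to avoid binary
  float surprises at the .x5 boundary.
* `classify_call` isolates the carrier-dichotomy rule in one function so a
  different TP definition for het/hom swaps would be a one-line revision.
* Concordance denominators use evaluable (jointly non-missing) cells;
  fully resolved matrices make the two conventions coincide.
* The acceptance script's problem sizes are the default study geometry
  (154 samples, 313 variants); property tests that need tighter sampling
  error use purpose-built cohorts of up to 5,000–10,000 samples over
  reduced variant sets.
* `synthetic_lifetime_risk` is a monotone exponential stand-in
  (11.5 % · e^(0.35·PRS)) used only to exercise the categorization
  workflow on simulated scores; it is labelled synthetic and is not a risk
  model.

## Limitations

The shipped proxy-selection step ranks candidates from supplied haplotype
counts; it does not query external LD reference services, and the final
empirical step of a real panel redesign (re-sequencing candidates and
keeping a surrogate only if it beats the original) requires wet-lab data
and is documented but not implemented. Published per-variant weights for
PRS₃₁₃ are licensed/distributed separately and are treated as user input;
all shipped models are synthetic.
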