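"""Method-comparison battery for paired genotype call sets.

Given a reference dosage matrix (e.g. array + imputation genotypes) and a
test matrix (e.g. targeted-sequencing genotypes), this module provides:

* per-call confusion classification on the carrier dichotomy (a call is
  "positive" when it carries at least one effect allele) and the derived
  sensitivity / specificity / PPV / NPV percentages;
* exact three-level genotype concordance per variant and per sample;
* effect-allele frequencies and their comparison;
* squared Pearson correlation (coefficient of determination) between two
  score vectors;
* per-variant mean-depth QC flags;
* a one-degree-of-freedom Hardy-Weinberg chi-square screen.

Heterozygous-vs-homozygous swaps count as concordance failures but are both
"positive" under the carrier dichotomy, so they land in the TP cell of the
confusion table.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import DepthTable, DosageMatrix


class CallClass(str, Enum):
    TP = "TP"
    TN = "TN"
    FP = "FP"
    FN = "FN"


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int
    stratum: str = "all_snps"

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class ConfusionMetrics:
    """Percentages in [0, 100]; None when the defining ratio is 0/0."""

    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]

    def rounded(self, ndigits: int = 2) -> Dict[str, Optional[float]]:
        """Half-up rounding for report display (e.g. 88.57, not 88.56)."""
        out = {}
        for name in ("sensitivity", "specificity", "ppv", "npv"):
            value = getattr(self, name)
            out[name] = None if value is None else round_half_up(value, ndigits)
        return out


def round_half_up(value: float, ndigits: int = 2) -> float:
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def classify_call(ref_dosage: int, test_dosage: int) -> CallClass:
    """Classify one paired call on the carrier dichotomy.

    A dosage >= 1 counts as a carrier.  Both carriers -> TP; both
    non-carriers -> TN; carrier only in the test method -> FP; carrier only
    in the reference -> FN.  Missing dosages are a caller error: apply the
    missing-data policy (e.g. wild-type resolution) first.
    """
    for name, d in (("ref", ref_dosage), ("test", test_dosage)):
        if d is None or (isinstance(d, float) and np.isnan(d)):
            raise ValueError(f"{name} dosage is missing; resolve missingness first")
        if d not in (0, 1, 2):
            raise ValueError(f"{name} dosage must be 0, 1 or 2, got {d!r}")
    ref_carrier, test_carrier = ref_dosage >= 1, test_dosage >= 1
    if ref_carrier and test_carrier:
        return CallClass.TP
    if not ref_carrier and not test_carrier:
        return CallClass.TN
    return CallClass.FP if test_carrier else CallClass.FN


def confusion_counts(
    ref: DosageMatrix,
    test: DosageMatrix,
    variant_ids: Optional[Sequence[str]] = None,
    stratum: str = "all_snps",
) -> ConfusionCounts:
    """Tally TP/TN/FP/FN over all (sample, variant) cells of a stratum.

    Both matrices must be fully resolved (no missing cells) over the
    selected variants; totals then satisfy tp+tn+fp+fn = samples x variants.
    """
    cols = list(variant_ids) if variant_ids is not None else ref.variant_ids
    r = ref.data[cols].reindex(index=test.data.index).to_numpy(dtype=float)
    t = test.data[cols].to_numpy(dtype=float)
    if np.isnan(r).any() or np.isnan(t).any():
        raise ValueError("confusion counts need fully resolved matrices")
    ref_carrier, test_carrier = r >= 1, t >= 1
    return ConfusionCounts(
        tp=int((ref_carrier & test_carrier).sum()),
        tn=int((~ref_carrier & ~test_carrier).sum()),
        fp=int((~ref_carrier & test_carrier).sum()),
        fn=int((ref_carrier & ~test_carrier).sum()),
        stratum=stratum,
    )


def confusion_metrics(counts: ConfusionCounts) -> ConfusionMetrics:
    """Sensitivity, specificity, PPV and NPV as percentages.

    sensitivity = TP*100/(TP+FN); specificity = TN*100/(TN+FP);
    PPV = TP*100/(TP+FP); NPV = TN*100/(TN+FN).  A zero denominator yields
    None (not available), never 0.
    """

    def ratio(num: int, den: int) -> Optional[float]:
        return None if den == 0 else num * 100.0 / den

    return ConfusionMetrics(
        sensitivity=ratio(counts.tp, counts.tp + counts.fn),
        specificity=ratio(counts.tn, counts.tn + counts.fp),
        ppv=ratio(counts.tp, counts.tp + counts.fp),
        npv=ratio(counts.tn, counts.tn + counts.fn),
    )


@dataclass
class ConcordanceReport:
    per_snp: pd.Series  # variant_id -> fraction concordant in [0, 1]
    per_sample: pd.Series  # sample_id -> fraction concordant in [0, 1]
    flagged_snps: List[str]  # per-SNP concordance below threshold
    threshold: float


def concordance(
    ref: DosageMatrix,
    test: DosageMatrix,
    threshold: float = 0.90,
) -> ConcordanceReport:
    """Exact three-level genotype concordance per variant and per sample.

    A cell is concordant when the genotype class (non-carrier, heterozygous,
    homozygous) matches exactly.  Cells missing in either matrix are skipped
    and the fractions use evaluable counts; variants (or samples) with no
    evaluable cells get NaN.
    """
    shared_samples = [s for s in ref.sample_ids if s in set(test.sample_ids)]
    shared_variants = [v for v in ref.variant_ids if v in set(test.variant_ids)]
    if not shared_samples or not shared_variants:
        raise ValueError("reference and test matrices share no samples/variants")
    r = ref.data.loc[shared_samples, shared_variants].to_numpy(dtype=float)
    t = test.data.loc[shared_samples, shared_variants].to_numpy(dtype=float)
    evaluable = ~np.isnan(r) & ~np.isnan(t)
    match = (r == t) & evaluable
    with np.errstate(invalid="ignore"):
        per_snp = match.sum(axis=0) / evaluable.sum(axis=0)
        per_sample = match.sum(axis=1) / evaluable.sum(axis=1)
    per_snp = pd.Series(per_snp, index=shared_variants, name="concordance")
    per_sample = pd.Series(per_sample, index=shared_samples, name="concordance")
    flagged = [v for v in shared_variants if per_snp[v] < threshold]
    return ConcordanceReport(
        per_snp=per_snp,
        per_sample=per_sample,
        flagged_snps=flagged,
        threshold=threshold,
    )


def allele_frequency(dosages: DosageMatrix) -> pd.Series:
    """Effect-allele frequency per variant: sum(dosages) / (2 x non-missing).

    Variants with no non-missing calls get NaN.
    """
    values = dosages.data.to_numpy(dtype=float)
    n_obs = (~np.isnan(values)).sum(axis=0)
    with np.errstate(invalid="ignore"):
        freq = np.nansum(values, axis=0) / (2.0 * n_obs)
    freq = np.where(n_obs == 0, np.nan, freq)
    return pd.Series(freq, index=dosages.variant_ids, name="effect_allele_frequency")


def coefficient_of_determination(x: Sequence[float], y: Sequence[float]) -> float:
    """Squared Pearson correlation between two paired vectors.

    Note R^2 is sign-blind: perfectly anti-correlated vectors also give 1.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if xa.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.var(xa) == 0 or np.var(ya) == 0:
        raise ValueError("R^2 undefined for a zero-variance vector")
    r = np.corrcoef(xa, ya)[0, 1]
    return float(r * r)


class DepthFlag(str, Enum):
    LOW = "low"
    INTERMEDIATE = "intermediate"
    GOOD = "good"


def depth_qc(
    depths: DepthTable,
    low_mean: float = 30.0,
    good_mean: float = 100.0,
) -> pd.DataFrame:
    """Per-variant mean depth with QC flags.

    Flags: ``low`` when mean < low_mean (default 30x), ``good`` when
    mean > good_mean (default 100x), else ``intermediate``.
    """
    if depths.data.empty:
        raise ValueError("depth table is empty")
    means = depths.data.mean(axis=0)
    flags = np.where(
        means < low_mean,
        DepthFlag.LOW.value,
        np.where(means > good_mean, DepthFlag.GOOD.value, DepthFlag.INTERMEDIATE.value),
    )
    return pd.DataFrame(
        {"mean_depth": means, "flag": flags}, index=depths.variant_ids
    ).rename_axis("variant_id")


def hwe_chi2(n_hom_ref: int, n_het: int, n_hom_alt: int) -> Tuple[float, float]:
    """1-df chi-square test of Hardy-Weinberg genotypic proportions.

    The alternate-allele frequency is estimated from the counts; expected
    genotype counts follow (1-p)^2 : 2p(1-p) : p^2.  Monomorphic input gives
    (0.0, 1.0).
    """
    counts = (n_hom_ref, n_het, n_hom_alt)
    if min(counts) < 0:
        raise ValueError("genotype counts must be non-negative")
    total = sum(counts)
    if total == 0:
        raise ValueError("genotype counts sum to zero")
    p = (2 * n_hom_alt + n_het) / (2 * total)
    if p == 0.0 or p == 1.0:
        return 0.0, 1.0
    expected = np.array([(1 - p) ** 2, 2 * p * (1 - p), p * p]) * total
    chi2 = float((((np.array(counts) - expected) ** 2) / expected).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))
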