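"""Two-locus linkage-disequilibrium statistics and proxy-SNP ranking.

The statistics are computed from the four two-locus haplotype counts, where
the "A" and "B" labels denote the effect alleles of the target and the
candidate proxy:

    D  = p_AB - p_A * p_B
    D' = |D| / D_max,   D_max = min(p_A (1-p_B), (1-p_A) p_B)   if D > 0
                        D_max = min(p_A p_B, (1-p_A) (1-p_B))   if D < 0
    r2 = D^2 / (p_A (1-p_A) p_B (1-p_B))

The sign of D decides the proxy orientation: with negative D the proxy's
effect allele tags the target's non-effect allele, and observed dosages
must be reversed (d -> 2 - d) before scoring.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from .model import ModelError, Orientation, ProxyAction, ProxyMapEntry, VariantDefinition


@dataclass(frozen=True)
class HaplotypeCounts:
    """Counts of the four two-locus haplotypes (A/B = effect alleles)."""

    n_AB: int
    n_Ab: int
    n_aB: int
    n_ab: int

    def __post_init__(self) -> None:
        if min(self.n_AB, self.n_Ab, self.n_aB, self.n_ab) < 0:
            raise ValueError("haplotype counts must be non-negative")
        if self.total == 0:
            raise ValueError("haplotype counts must sum to a positive total")

    @property
    def total(self) -> int:
        return self.n_AB + self.n_Ab + self.n_aB + self.n_ab

    @property
    def p_A(self) -> float:
        return (self.n_AB + self.n_Ab) / self.total

    @property
    def p_B(self) -> float:
        return (self.n_AB + self.n_aB) / self.total

    @property
    def p_AB(self) -> float:
        return self.n_AB / self.total

    @classmethod
    def from_haplotypes(
        cls, alleles_a: Sequence[int], alleles_b: Sequence[int]
    ) -> "HaplotypeCounts":
        """Tally phased haplotypes; alleles are 0/1 with 1 = effect allele."""
        a = np.asarray(alleles_a, dtype=int)
        b = np.asarray(alleles_b, dtype=int)
        if a.shape != b.shape:
            raise ValueError("haplotype vectors must have equal length")
        return cls(
            n_AB=int(((a == 1) & (b == 1)).sum()),
            n_Ab=int(((a == 1) & (b == 0)).sum()),
            n_aB=int(((a == 0) & (b == 1)).sum()),
            n_ab=int(((a == 0) & (b == 0)).sum()),
        )


@dataclass(frozen=True)
class LdStats:
    D: float
    d_prime: float
    r2: float
    sign: Orientation


def ld_stats(counts: HaplotypeCounts) -> LdStats:
    """Compute D, D' and r2 from haplotype counts.

    Raises ``ValueError`` when either locus is monomorphic (LD undefined).
    """
    p_a, p_b = counts.p_A, counts.p_B
    if not (0.0 < p_a < 1.0) or not (0.0 < p_b < 1.0):
        raise ValueError("LD is undefined at a monomorphic locus")
    d = counts.p_AB - p_a * p_b
    if d > 0:
        d_max = min(p_a * (1.0 - p_b), (1.0 - p_a) * p_b)
    elif d < 0:
        d_max = min(p_a * p_b, (1.0 - p_a) * (1.0 - p_b))
    else:
        d_max = 0.0
    d_prime = abs(d) / d_max if d_max > 0 else 0.0
    r2 = d * d / (p_a * (1.0 - p_a) * p_b * (1.0 - p_b))
    sign = Orientation.NEGATIVE if d < 0 else Orientation.POSITIVE
    # guard against float round-off just above 1
    return LdStats(D=d, d_prime=min(d_prime, 1.0), r2=min(r2, 1.0), sign=sign)


@dataclass
class ProxyCandidate:
    """A candidate surrogate for a target variant, with its LD statistics."""

    variant_id: str
    distance_bp: int
    stats: Optional[LdStats] = None
    excluded: bool = False
    exclusion_reason: str = ""

    def __post_init__(self) -> None:
        if self.distance_bp < 0:
            raise ValueError("distance_bp must be non-negative")


def rank_proxies(
    target: VariantDefinition,
    candidates: Sequence[ProxyCandidate],
    window_bp: int = 50_000,
    top_k: int = 3,
) -> List[ProxyCandidate]:
    """Rank eligible proxy candidates for a target variant.

    Candidates outside the window or flagged as excluded (repeats,
    low-complexity context) are dropped; the remainder are sorted by r2
    descending, then D' descending, then distance ascending, and the top_k
    best are returned.  An empty result means no usable surrogate exists
    and the caller should fall back to assuming the wild-type genotype.
    """
    eligible = [
        c
        for c in candidates
        if not c.excluded and c.distance_bp <= window_bp and c.stats is not None
    ]
    eligible.sort(key=lambda c: (-c.stats.r2, -c.stats.d_prime, c.distance_bp))
    return eligible[:top_k]


def proxy_entry(target: VariantDefinition, candidate: ProxyCandidate) -> ProxyMapEntry:
    """Build the proxy-map row for a chosen candidate.

    Orientation is the sign of D between the two effect alleles.
    """
    if candidate.stats is None:
        raise ModelError(f"candidate {candidate.variant_id} carries no LD statistics")
    return ProxyMapEntry(
        original_id=target.variant_id,
        proxy_id=candidate.variant_id,
        r2=candidate.stats.r2,
        d_prime=candidate.stats.d_prime,
        orientation=candidate.stats.sign,
        action=ProxyAction.SUBSTITUTE,
    )


def wildtype_entry(target: VariantDefinition) -> ProxyMapEntry:
    """Proxy-map row recording that a site must be assumed wild-type."""
    return ProxyMapEntry(
        original_id=target.variant_id,
        proxy_id="",
        r2=0.0,
        d_prime=0.0,
        orientation=Orientation.POSITIVE,
        action=ProxyAction.ASSUME_WILDTYPE,
    )
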