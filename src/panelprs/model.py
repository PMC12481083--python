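"""PRS model and proxy-map registry.

A PRS model is an ordered table of risk variants (GRCh37 coordinates,
ref/alt alleles, the effect allele whose dosage is counted, and a
per-effect-allele log-odds weight).  A proxy map records, for a subset of
model variants that cannot be genotyped reliably on the sequencing panel,
either a surrogate variant in linkage disequilibrium (with its r2, D' and
orientation) or the instruction to assume the wild-type genotype.

Both tables are stored as plain tab-separated files with fixed headers so
they can be versioned and diffed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Dict, Iterator, List, Sequence, Tuple, Union

import pandas as pd

VALID_CHROMOSOMES = {str(i) for i in range(1, 23)} | {"X"}

MODEL_COLUMNS = [
    "variant_id",
    "chromosome",
    "position",
    "ref",
    "alt",
    "effect_allele",
    "weight",
    "array_status",
    "low_complexity",
]

PROXY_COLUMNS = ["original_id", "proxy_id", "r2", "d_prime", "orientation", "action"]


class ModelError(ValueError):
    """Raised when a model or proxy table violates its invariants."""


def normalize_chromosome(chrom: str) -> str:
    """Normalize chromosome names: 'chr15' and '15' both map to '15'."""
    c = str(chrom).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    c = c.upper() if c.lower() == "x" else c
    if c not in VALID_CHROMOSOMES:
        raise ModelError(f"unsupported chromosome {chrom!r} (expected 1-22 or X)")
    return c


def trim_alleles(position: int, ref: str, alt: str) -> Tuple[int, str, str]:
    """Reduce a ref/alt pair to its left-aligned minimal representation.

    Shared suffix bases are removed first, then shared prefix bases (advancing
    the position), always leaving at least one base on each allele.  SNVs are
    returned unchanged; padded indel spellings collapse to the conventional
    anchored form.
    """
    ref, alt = ref.upper(), alt.upper()
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        position += 1
    return position, ref, alt


def make_variant_id(chromosome: str, position: int, ref: str, alt: str) -> str:
    return f"{chromosome}:{position}:{ref}:{alt}"


class ArrayStatus(str, Enum):
    """Whether the reference array typed the variant directly or imputed it."""

    GENOTYPED = "genotyped"
    IMPUTED = "imputed"


@dataclass(frozen=True)
class VariantDefinition:
    """One PRS variant: identity, effect allele and weight.

    The effect allele is the allele whose diploid copy number (0/1/2) is
    multiplied by ``weight``; it may be either the reference or the
    alternate allele.
    """

    variant_id: str
    chromosome: str
    position: int
    ref_allele: str
    alt_allele: str
    effect_allele: str
    weight: float
    array_status: ArrayStatus = ArrayStatus.GENOTYPED
    low_complexity: bool = False

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ModelError(f"{self.variant_id}: position must be >= 1")
        if self.effect_allele not in (self.ref_allele, self.alt_allele):
            raise ModelError(
                f"{self.variant_id}: effect allele {self.effect_allele!r} is "
                f"neither ref ({self.ref_allele!r}) nor alt ({self.alt_allele!r})"
            )
        if not math.isfinite(self.weight):
            raise ModelError(f"{self.variant_id}: weight must be finite")

    @property
    def effect_is_alt(self) -> bool:
        return self.effect_allele == self.alt_allele

    @property
    def key(self) -> Tuple[str, int, str, str]:
        """Matching key (chromosome, position, ref, alt) after normalization."""
        pos, ref, alt = trim_alleles(self.position, self.ref_allele, self.alt_allele)
        return (normalize_chromosome(self.chromosome), pos, ref, alt)


@dataclass
class PrsModel:
    """An ordered, uniquely-keyed collection of PRS variants."""

    name: str
    variants: Tuple[VariantDefinition, ...]
    genome_build: str = "GRCh37"
    _index: Dict[str, VariantDefinition] = field(
        init=False, repr=False, compare=False, default_factory=dict
    )

    def __post_init__(self) -> None:
        self.variants = tuple(self.variants)
        index: Dict[str, VariantDefinition] = {}
        for v in self.variants:
            if v.variant_id in index:
                raise ModelError(f"duplicate variant_id {v.variant_id!r} in model")
            index[v.variant_id] = v
        self._index = index

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self) -> Iterator[VariantDefinition]:
        return iter(self.variants)

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def __getitem__(self, variant_id: str) -> VariantDefinition:
        return self._index[variant_id]

    @property
    def variant_ids(self) -> List[str]:
        return [v.variant_id for v in self.variants]

    @property
    def weights(self) -> pd.Series:
        return pd.Series(
            [v.weight for v in self.variants], index=self.variant_ids, name="weight"
        )

    def subset(self, status: ArrayStatus) -> List[VariantDefinition]:
        return [v for v in self.variants if v.array_status is status]


class Orientation(str, Enum):
    """Sign of linkage disequilibrium between target and proxy effect alleles.

    With negative orientation the proxy's counted allele travels with the
    target's non-effect allele, so an observed proxy dosage d corresponds to
    a target effect-allele dosage of 2 - d.
    """

    POSITIVE = "positive"
    NEGATIVE = "negative"


class ProxyAction(str, Enum):
    SUBSTITUTE = "substitute"
    ASSUME_WILDTYPE = "assume_wildtype"


@dataclass(frozen=True)
class ProxyMapEntry:
    """Link from a model variant to its panel surrogate (or wild-type rule)."""

    original_id: str
    proxy_id: str
    r2: float
    d_prime: float
    orientation: Orientation = Orientation.POSITIVE
    action: ProxyAction = ProxyAction.SUBSTITUTE

    def __post_init__(self) -> None:
        if not (0.0 <= self.r2 <= 1.0):
            raise ModelError(f"{self.original_id}: r2 must be in [0, 1], got {self.r2}")
        if not (0.0 <= self.d_prime <= 1.0):
            raise ModelError(
                f"{self.original_id}: d_prime must be in [0, 1], got {self.d_prime}"
            )
        if self.action is ProxyAction.ASSUME_WILDTYPE and self.proxy_id:
            raise ModelError(
                f"{self.original_id}: assume_wildtype entries must leave proxy_id empty"
            )
        if self.action is ProxyAction.SUBSTITUTE and not self.proxy_id:
            raise ModelError(f"{self.original_id}: substitute entries need a proxy_id")


ProxyMap = Dict[str, ProxyMapEntry]


def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    s = str(value).strip().lower()
    if s in {"true", "1", "yes"}:
        return True
    if s in {"false", "0", "no", ""}:
        return False
    raise ModelError(f"cannot parse boolean flag from {value!r}")


def load_model(path: Union[str, Path], name: str | None = None) -> PrsModel:
    """Load a PRS model from its tab-separated table.

    Raises :class:`ModelError` on duplicate variant ids, effect alleles that
    match neither ref nor alt, or a malformed header; the offending row is
    named in the message.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in MODEL_COLUMNS if c not in df.columns]
    if missing:
        raise ModelError(f"{path}: missing model columns {missing}")
    variants = []
    for i, row in df.iterrows():
        try:
            variants.append(
                VariantDefinition(
                    variant_id=row["variant_id"],
                    chromosome=normalize_chromosome(row["chromosome"]),
                    position=int(row["position"]),
                    ref_allele=row["ref"].upper(),
                    alt_allele=row["alt"].upper(),
                    effect_allele=row["effect_allele"].upper(),
                    weight=float(row["weight"]),
                    array_status=ArrayStatus(row["array_status"]),
                    low_complexity=_parse_bool(row["low_complexity"]),
                )
            )
        except (ModelError, ValueError) as exc:
            raise ModelError(
                f"{path} row {i + 2} ({row['variant_id']!r}): {exc}"
            ) from exc
    return PrsModel(name=name or path.stem, variants=tuple(variants))


def save_model(model: PrsModel, path: Union[str, Path]) -> None:
    rows = [
        {
            "variant_id": v.variant_id,
            "chromosome": v.chromosome,
            "position": v.position,
            "ref": v.ref_allele,
            "alt": v.alt_allele,
            "effect_allele": v.effect_allele,
            "weight": repr(float(v.weight)),
            "array_status": v.array_status.value,
            "low_complexity": str(v.low_complexity).lower(),
        }
        for v in model.variants
    ]
    pd.DataFrame(rows, columns=MODEL_COLUMNS).to_csv(path, sep="\t", index=False)


def load_proxy_map(path: Union[str, Path], model: PrsModel) -> ProxyMap:
    """Load the proxy map, checking every original_id against the model.

    Returns a dict keyed by original variant id; an empty file yields an
    empty map (all variants scored directly).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in PROXY_COLUMNS if c not in df.columns]
    if missing:
        raise ModelError(f"{path}: missing proxy-map columns {missing}")
    entries: ProxyMap = {}
    for i, row in df.iterrows():
        original_id = row["original_id"]
        if original_id not in model:
            raise ModelError(
                f"{path} row {i + 2}: original_id {original_id!r} not in model"
            )
        if original_id in entries:
            raise ModelError(
                f"{path} row {i + 2}: duplicate entry for {original_id!r}"
            )
        try:
            entries[original_id] = ProxyMapEntry(
                original_id=original_id,
                proxy_id=row["proxy_id"],
                r2=float(row["r2"]),
                d_prime=float(row["d_prime"]),
                orientation=Orientation(row["orientation"]),
                action=ProxyAction(row["action"]),
            )
        except (ModelError, ValueError) as exc:
            raise ModelError(f"{path} row {i + 2}: {exc}") from exc
    return entries


def save_proxy_map(proxy_map: ProxyMap, path: Union[str, Path]) -> None:
    rows = [
        {
            "original_id": e.original_id,
            "proxy_id": e.proxy_id,
            "r2": repr(float(e.r2)),
            "d_prime": repr(float(e.d_prime)),
            "orientation": e.orientation.value,
            "action": e.action.value,
        }
        for e in proxy_map.values()
    ]
    pd.DataFrame(rows, columns=PROXY_COLUMNS).to_csv(path, sep="\t", index=False)


def save_variants(variants: Sequence[VariantDefinition], path: Union[str, Path]) -> None:
    """Persist an arbitrary variant list (e.g. panel proxy additions)."""
    save_model(PrsModel(name="panel", variants=tuple(variants)), path)
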