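"""Extraction of effect-allele dosages and read depths into matrices.

Dosages are hard diploid calls converted to effect-allele copy number
(0, 1 or 2); anything that cannot be resolved to an unambiguous count
(uncalled or half-called genotypes, non-diploid calls, alleles that do not
match the model's ref/alt pair) is recorded as missing and logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import pysam

from .model import (
    PrsModel,
    VariantDefinition,
    normalize_chromosome,
    trim_alleles,
)

logger = logging.getLogger(__name__)

VariantSource = Union[PrsModel, Sequence[VariantDefinition]]


def _variant_list(variants: VariantSource) -> List[VariantDefinition]:
    if isinstance(variants, PrsModel):
        return list(variants.variants)
    return list(variants)


@dataclass
class DosageMatrix:
    """Samples x variants matrix of effect-allele dosages.

    Values are floats so that missing cells can be NaN; every non-missing
    entry is 0, 1 or 2.
    """

    data: pd.DataFrame  # index: sample_ids, columns: variant_ids

    def __post_init__(self) -> None:
        values = self.data.to_numpy(dtype=float, copy=False)
        observed = values[~np.isnan(values)]
        if observed.size and not np.isin(observed, (0.0, 1.0, 2.0)).all():
            bad = sorted(set(observed[~np.isin(observed, (0.0, 1.0, 2.0))]))
            raise ValueError(f"dosages must be 0, 1 or 2; found {bad[:5]}")

    @property
    def sample_ids(self) -> List[str]:
        return list(self.data.index)

    @property
    def variant_ids(self) -> List[str]:
        return list(self.data.columns)

    @property
    def n_missing(self) -> int:
        return int(self.data.isna().to_numpy().sum())

    def select(self, variant_ids: Sequence[str]) -> "DosageMatrix":
        return DosageMatrix(self.data[list(variant_ids)])

    def to_tsv(self, path: Union[str, Path]) -> None:
        self.data.to_csv(path, sep="\t", index_label="sample", na_rep="NA")

    @classmethod
    def from_tsv(cls, path: Union[str, Path]) -> "DosageMatrix":
        df = pd.read_csv(path, sep="\t", index_col="sample", na_values=["NA"])
        df.index = df.index.astype(str)
        return cls(df.astype(float))


@dataclass
class DepthTable:
    """Samples x variants matrix of read depths (non-negative integers)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        values = self.data.to_numpy()
        if values.size and (values < 0).any():
            raise ValueError("read depths must be non-negative")

    @property
    def sample_ids(self) -> List[str]:
        return list(self.data.index)

    @property
    def variant_ids(self) -> List[str]:
        return list(self.data.columns)

    def to_tsv(self, path: Union[str, Path], variants: VariantSource) -> None:
        """Write the long-format per-site depth table (sample/chrom/pos/depth)."""
        coords = {
            v.variant_id: (v.chromosome, v.position) for v in _variant_list(variants)
        }
        rows = []
        for sample in self.data.index:
            for vid in self.data.columns:
                chrom, pos = coords[vid]
                rows.append((sample, chrom, pos, int(self.data.at[sample, vid])))
        pd.DataFrame(rows, columns=["sample", "chrom", "pos", "depth"]).to_csv(
            path, sep="\t", index=False
        )


def read_dosages(path: Union[str, Path], variants: VariantSource) -> DosageMatrix:
    """Read effect-allele dosages for the given variants from a VCF.

    Variants are matched by (chromosome, position, ref, alt) after
    chromosome-name normalization and left-alignment of indel alleles.
    Multiallelic records are decomposed per ALT allele; genotypes carrying
    an allele outside the matched ref/alt pair become missing.  When the
    effect allele is REF, the dosage is 2 minus the ALT-allele count.
    """
    variant_list = _variant_list(variants)
    by_key: Dict[Tuple[str, int, str, str], VariantDefinition] = {}
    for v in variant_list:
        by_key[v.key] = v

    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if not samples:
            raise ValueError(f"{path}: VCF has no sample genotype columns")
        data = pd.DataFrame(
            np.nan, index=samples, columns=[v.variant_id for v in variant_list]
        )
        for rec in vcf:
            chrom = normalize_chromosome(rec.chrom)
            alts = rec.alts or ()
            for alt_index, alt in enumerate(alts, start=1):
                key = trim_alleles(rec.pos, rec.ref, alt)
                variant = by_key.get((chrom, *key))
                if variant is None:
                    continue
                allowed = {0, alt_index}
                col = data.columns.get_loc(variant.variant_id)
                for s_i, sample in enumerate(samples):
                    gt = rec.samples[sample].get("GT")
                    if gt is None or len(gt) != 2 or any(a is None for a in gt):
                        if gt is not None and any(a is not None for a in gt):
                            logger.warning(
                                "%s %s: half-called or non-diploid genotype -> missing",
                                variant.variant_id,
                                sample,
                            )
                        continue
                    if any(a not in allowed for a in gt):
                        logger.warning(
                            "%s %s: genotype alleles outside model ref/alt -> missing",
                            variant.variant_id,
                            sample,
                        )
                        continue
                    alt_count = sum(1 for a in gt if a == alt_index)
                    dosage = alt_count if variant.effect_is_alt else 2 - alt_count
                    data.iat[s_i, col] = float(dosage)
    return DosageMatrix(data)


def read_depths(
    path: Union[str, Path],
    variants: VariantSource,
    sample_ids: Sequence[str] | None = None,
) -> DepthTable:
    """Read per-site read depths keyed by (sample, chromosome, position).

    Rows absent for a model variant are counted as depth 0; negative depths
    are a hard error.
    """
    variant_list = _variant_list(variants)
    df = pd.read_csv(
        path, sep="\t", dtype={"sample": str, "chrom": str, "pos": int, "depth": int}
    )
    for col in ("sample", "chrom", "pos", "depth"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing depth column {col!r}")
    if len(df) and (df["depth"] < 0).any():
        bad = df[df["depth"] < 0].iloc[0]
        raise ValueError(
            f"{path}: negative depth for sample {bad['sample']} at "
            f"{bad['chrom']}:{bad['pos']}"
        )
    by_pos: Dict[Tuple[str, int], str] = {
        (normalize_chromosome(v.chromosome), v.position): v.variant_id
        for v in variant_list
    }
    samples = list(sample_ids) if sample_ids is not None else sorted(
        df["sample"].unique()
    )
    data = pd.DataFrame(
        0, index=samples, columns=[v.variant_id for v in variant_list], dtype=int
    )
    for row in df.itertuples(index=False):
        vid = by_pos.get((normalize_chromosome(row.chrom), row.pos))
        if vid is None or row.sample not in data.index:
            continue
        data.at[row.sample, vid] = row.depth
    return DepthTable(data)


def write_vcf(
    path: Union[str, Path],
    variants: VariantSource,
    dosages: DosageMatrix,
) -> None:
    """Write effect-allele dosages back out as a minimal VCF 4.2 with GT.

    Effect-allele dosages are converted to ref/alt genotypes using each
    variant's effect-allele orientation; missing cells become './.'.
    """
    variant_list = sorted(
        _variant_list(variants),
        key=lambda v: (_chrom_sort_key(v.chromosome), v.position),
    )
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for chrom in sorted({v.chromosome for v in variant_list}, key=_chrom_sort_key):
        header.add_line(f"##contig=<ID={chrom}>")
    for sample in dosages.sample_ids:
        header.add_sample(sample)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in variant_list:
            rec = out.new_record(
                contig=v.chromosome,
                start=v.position - 1,
                alleles=(v.ref_allele, v.alt_allele),
            )
            rec.id = v.variant_id
            col = dosages.data[v.variant_id] if v.variant_id in dosages.data else None
            for sample in dosages.sample_ids:
                d = np.nan if col is None else col[sample]
                if np.isnan(d):
                    rec.samples[sample]["GT"] = (None, None)
                    continue
                alt_copies = int(d) if v.effect_is_alt else 2 - int(d)
                gt = {0: (0, 0), 1: (0, 1), 2: (1, 1)}[alt_copies]
                rec.samples[sample]["GT"] = gt
                rec.samples[sample].phased = False
            out.write(rec)


def _chrom_sort_key(chrom: str) -> int:
    c = normalize_chromosome(chrom)
    return 23 if c == "X" else int(c)
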