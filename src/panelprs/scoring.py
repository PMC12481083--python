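"""Weighted-sum PRS computation with proxy substitution.

Each model variant is resolved to an effective effect-allele dosage:

* no proxy-map entry: the variant's own called dosage (``direct``);
* ``substitute`` entry, positive orientation: the proxy's dosage;
* ``substitute`` entry, negative orientation: ``2 - proxy dosage`` — the
  proxy's counted allele travels with the target's non-effect allele, so
  the observed count must be reversed;
* ``assume_wildtype`` entry: dosage 0 (homozygous wild-type);
* any resolved site that is still missing: dosage 0, logged separately.

The PRS is the sum over all model variants of weight x effective dosage.
The original variant's weight is always used, including under proxy
substitution: the surrogate replaces the genotyping of the site, not its
coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .genotypes import DosageMatrix
from .model import (
    Orientation,
    ProxyAction,
    ProxyMap,
    PrsModel,
    VariantDefinition,
)


class Resolution(str, Enum):
    """How a model variant's effective dosage was obtained for one sample."""

    DIRECT = "direct"
    PROXY = "proxy"
    PROXY_REVERSED = "proxy_reversed"
    WILDTYPE_FALLBACK = "wildtype_fallback"
    MISSING_AS_WILDTYPE = "missing_as_wildtype"


@dataclass
class ScoreResult:
    sample_id: str
    prs: float
    per_variant_contributions: Dict[str, float]
    resolution_log: Dict[str, Resolution]

    def resolution_counts(self) -> Dict[Resolution, int]:
        counts = {r: 0 for r in Resolution}
        for res in self.resolution_log.values():
            counts[res] += 1
        return counts


def resolve_dosage(
    variant: VariantDefinition,
    dosages: DosageMatrix,
    proxy_map: Optional[ProxyMap],
    sample_id: str,
) -> Tuple[int, Resolution]:
    """Resolve one variant's effective dosage for one sample."""
    entry = (proxy_map or {}).get(variant.variant_id)
    if entry is not None and entry.action is ProxyAction.ASSUME_WILDTYPE:
        return 0, Resolution.WILDTYPE_FALLBACK
    if entry is None:
        source_id = variant.variant_id
        hit, reversed_ = Resolution.DIRECT, False
    else:
        source_id = entry.proxy_id
        reversed_ = entry.orientation is Orientation.NEGATIVE
        hit = Resolution.PROXY_REVERSED if reversed_ else Resolution.PROXY
    if source_id not in dosages.data.columns:
        return 0, Resolution.MISSING_AS_WILDTYPE
    value = dosages.data.at[sample_id, source_id]
    if np.isnan(value):
        return 0, Resolution.MISSING_AS_WILDTYPE
    dosage = int(value)
    return (2 - dosage if reversed_ else dosage), hit


def resolve_matrix(
    dosages: DosageMatrix,
    model: PrsModel,
    proxy_map: Optional[ProxyMap] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Resolve every (sample, model variant) cell.

    Returns an integer effective-dosage frame and a parallel frame of
    :class:`Resolution` values, both indexed by sample and keyed by the
    model's variant ids.
    """
    proxy_map = proxy_map or {}
    samples = dosages.sample_ids
    n = len(samples)
    eff = pd.DataFrame(index=samples, columns=model.variant_ids, dtype=float)
    res = pd.DataFrame(index=samples, columns=model.variant_ids, dtype=object)
    for v in model.variants:
        entry = proxy_map.get(v.variant_id)
        if entry is not None and entry.action is ProxyAction.ASSUME_WILDTYPE:
            eff[v.variant_id] = 0.0
            res[v.variant_id] = Resolution.WILDTYPE_FALLBACK
            continue
        if entry is None:
            source_id, hit, reversed_ = v.variant_id, Resolution.DIRECT, False
        else:
            reversed_ = entry.orientation is Orientation.NEGATIVE
            source_id = entry.proxy_id
            hit = Resolution.PROXY_REVERSED if reversed_ else Resolution.PROXY
        if source_id in dosages.data.columns:
            col = dosages.data[source_id].to_numpy(dtype=float)
        else:
            col = np.full(n, np.nan)
        missing = np.isnan(col)
        eff[v.variant_id] = np.where(missing, 0.0, 2.0 - col if reversed_ else col)
        col_res = np.empty(n, dtype=object)
        col_res[:] = hit
        col_res[missing] = Resolution.MISSING_AS_WILDTYPE
        res[v.variant_id] = col_res
    return eff.astype(int), res


def compute_prs(
    dosages: DosageMatrix,
    model: PrsModel,
    proxy_map: Optional[ProxyMap] = None,
) -> List[ScoreResult]:
    """Compute the per-sample PRS: sum over variants of weight x dosage."""
    if len(model) == 0:
        raise ValueError("cannot score against an empty model")
    eff, res = resolve_matrix(dosages, model, proxy_map)
    weights = model.weights.to_numpy()
    contributions = eff.to_numpy(dtype=float) * weights[np.newaxis, :]
    scores = contributions.sum(axis=1)
    results = []
    for i, sample in enumerate(eff.index):
        results.append(
            ScoreResult(
                sample_id=sample,
                prs=float(scores[i]),
                per_variant_contributions=dict(
                    zip(model.variant_ids, contributions[i].tolist())
                ),
                resolution_log=dict(zip(model.variant_ids, res.iloc[i])),
            )
        )
    return results


def prs_series(
    dosages: DosageMatrix,
    model: PrsModel,
    proxy_map: Optional[ProxyMap] = None,
) -> pd.Series:
    """Fast path returning only the per-sample PRS values."""
    if len(model) == 0:
        raise ValueError("cannot score against an empty model")
    eff, _ = resolve_matrix(dosages, model, proxy_map)
    scores = eff.to_numpy(dtype=float) @ model.weights.to_numpy()
    return pd.Series(scores, index=eff.index, name="prs")


def score_table(results: List[ScoreResult], precision: int = 4) -> pd.DataFrame:
    """Summary table: one row per sample with PRS and resolution counts."""
    rows = []
    for r in results:
        counts = r.resolution_counts()
        rows.append(
            {
                "sample_id": r.sample_id,
                "prs": round(r.prs, precision),
                "n_direct": counts[Resolution.DIRECT],
                "n_proxy": counts[Resolution.PROXY],
                "n_reversed": counts[Resolution.PROXY_REVERSED],
                "n_wildtype_fallback": counts[Resolution.WILDTYPE_FALLBACK],
                "n_missing_as_wildtype": counts[Resolution.MISSING_AS_WILDTYPE],
            }
        )
    return pd.DataFrame(rows)


def contributions_table(results: List[ScoreResult]) -> pd.DataFrame:
    """Long-format per-variant contribution table."""
    rows = []
    for r in results:
        for vid, contribution in r.per_variant_contributions.items():
            rows.append(
                {
                    "sample_id": r.sample_id,
                    "variant_id": vid,
                    "contribution": contribution,
                    "resolution": r.resolution_log[vid].value,
                }
            )
    return pd.DataFrame(rows)


def score_bounds(model: PrsModel) -> Tuple[float, float]:
    """Attainable PRS range: sum of min(0, 2w) to sum of max(0, 2w)."""
    w = model.weights.to_numpy()
    return float(np.minimum(0.0, 2.0 * w).sum()), float(np.maximum(0.0, 2.0 * w).sum())
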