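"""NICE risk-category assignment and category-change tabulation.

Risk percentages (e.g. CanRisk/BOADICEA output) are inputs; this module
only bands them and compares the bands between two scoring methods.

Bands (British National Institute for Health and Care Excellence):

* lifetime breast-cancer risk: near-population < 17 %, moderate 17-30 %
  (17 inclusive, 30 exclusive), high >= 30 %;
* 10-year risk: near-population < 3 %, moderate 3-8 % (both inclusive),
  high > 8 %.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Dict, List, Sequence, Tuple, Union

import pandas as pd

from .validate import round_half_up


class Horizon(str, Enum):
    LIFETIME = "lifetime"
    TEN_YEAR = "ten_year"


class Category(str, Enum):
    NEAR_POPULATION = "near_population"
    MODERATE = "moderate"
    HIGH = "high"


CATEGORY_ORDER = [Category.NEAR_POPULATION, Category.MODERATE, Category.HIGH]


def assign_category(risk_percent: float, horizon: Horizon) -> Category:
    """Band a risk percentage for the given horizon.

    Lifetime: < 17 near-population, 17 <= r < 30 moderate, >= 30 high.
    Ten-year: < 3 near-population, 3 <= r <= 8 moderate, > 8 high.
    """
    if risk_percent < 0:
        raise ValueError(f"risk percentage must be non-negative, got {risk_percent}")
    horizon = Horizon(horizon)
    if horizon is Horizon.LIFETIME:
        if risk_percent < 17.0:
            return Category.NEAR_POPULATION
        return Category.MODERATE if risk_percent < 30.0 else Category.HIGH
    if risk_percent < 3.0:
        return Category.NEAR_POPULATION
    return Category.MODERATE if risk_percent <= 8.0 else Category.HIGH


@dataclass(frozen=True)
class RiskRecord:
    subject_id: str
    risk_percent: float
    horizon: Horizon
    scenario_id: str = ""
    category: Category = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        expected = assign_category(self.risk_percent, self.horizon)
        if self.category is None:
            object.__setattr__(self, "category", expected)
        elif self.category is not expected:
            raise ValueError(
                f"{self.subject_id}/{self.scenario_id}: category "
                f"{self.category.value} inconsistent with risk "
                f"{self.risk_percent}% on the {self.horizon.value} horizon"
            )

    @property
    def key(self) -> Tuple[str, str, str]:
        return (self.subject_id, self.scenario_id, self.horizon.value)


@dataclass
class CategoryChangeTable:
    n_pairs: int
    n_changed: int
    pct_changed: float  # exact percentage
    crosstab: pd.DataFrame  # reference categories (rows) x test categories

    @property
    def pct_display(self) -> Tuple[float, int]:
        """(one-decimal, integer) display roundings of the changed fraction."""
        return round_half_up(self.pct_changed, 1), int(round_half_up(self.pct_changed, 0))


def category_change_table(
    ref: Sequence[RiskRecord], test: Sequence[RiskRecord]
) -> CategoryChangeTable:
    """Count category changes between matched reference and test records.

    Records are matched by (subject_id, scenario_id, horizon); keys present
    on one side only are a hard error and are listed in the message.
    """
    ref_by_key: Dict[Tuple[str, str, str], RiskRecord] = {r.key: r for r in ref}
    test_by_key: Dict[Tuple[str, str, str], RiskRecord] = {r.key: r for r in test}
    if len(ref_by_key) != len(ref) or len(test_by_key) != len(test):
        raise ValueError("duplicate (subject, scenario, horizon) keys in input")
    unmatched = set(ref_by_key) ^ set(test_by_key)
    if unmatched:
        listing = ", ".join("/".join(k) for k in sorted(unmatched)[:10])
        raise ValueError(f"unmatched record keys between methods: {listing}")
    labels = [c.value for c in CATEGORY_ORDER]
    crosstab = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    crosstab = crosstab.rename_axis(index="reference", columns="test")
    n_changed = 0
    for key, ref_record in ref_by_key.items():
        test_record = test_by_key[key]
        crosstab.loc[ref_record.category.value, test_record.category.value] += 1
        if ref_record.category is not test_record.category:
            n_changed += 1
    n_pairs = len(ref_by_key)
    return CategoryChangeTable(
        n_pairs=n_pairs,
        n_changed=n_changed,
        pct_changed=n_changed * 100.0 / n_pairs,
        crosstab=crosstab,
    )


RISK_COLUMNS = ["subject_id", "scenario_id", "horizon", "risk_percent", "category"]


def load_risks(path: Union[str, Path], horizon: Horizon | None = None) -> List[RiskRecord]:
    """Load risk records from TSV; the category column is optional on input."""
    df = pd.read_csv(Path(path), sep="\t", dtype=str, keep_default_na=False)
    for col in ("subject_id", "risk_percent"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing risk column {col!r}")
    records = []
    for i, row in df.iterrows():
        row_horizon = Horizon(row["horizon"]) if "horizon" in df.columns else horizon
        if row_horizon is None:
            raise ValueError(f"{path} row {i + 2}: no horizon given")
        records.append(
            RiskRecord(
                subject_id=row["subject_id"],
                scenario_id=row.get("scenario_id", ""),
                horizon=row_horizon,
                risk_percent=float(row["risk_percent"]),
            )
        )
    return records


def save_risks(records: Sequence[RiskRecord], path: Union[str, Path]) -> None:
    rows = [
        {
            "subject_id": r.subject_id,
            "scenario_id": r.scenario_id,
            "horizon": r.horizon.value,
            "risk_percent": r.risk_percent,
            "category": r.category.value,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=RISK_COLUMNS).to_csv(path, sep="\t", index=False)
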