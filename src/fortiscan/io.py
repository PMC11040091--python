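"""CSV readers/writers for branded-food datasets and dataset summaries.

The source database exports UTF-8 CSV; column names vary by export, so a
dialect mapping translates file headers onto the canonical record fields.
Empty cells become absent fields — never zeros — and numeric cells accept
both comma and period decimal separators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from .model import DEFAULT_NUTRIENTS, FORTIFIED, BrandedFoodRecord

#: canonical text columns of a dataset file
TEXT_COLUMNS = (
    "food_id",
    "food_group",
    "food_subgroup",
    "food_name",
    "ingredient_list",
    "legal_name",
    "mandatory_particulars",
)


@dataclass(frozen=True)
class DatasetDialect:
    """Mapping from file headers to canonical fields.

    ``column_map`` maps canonical name -> header in the file (identity by
    default).  ``nutrient_columns`` maps nutrient-value column ids (e.g.
    ``dfe``) to file headers.  ``decimal`` is "." or ",".
    """

    column_map: Mapping[str, str] = field(default_factory=dict)
    nutrient_columns: Mapping[str, str] = field(default_factory=dict)
    decimal: str = "."

    def header(self, canonical: str) -> str:
        return self.column_map.get(canonical, canonical)


DEFAULT_NUTRIENT_COLUMNS = {n: n for n in DEFAULT_NUTRIENTS} | {"dfe": "dfe"}


def _parse_number(cell, decimal: str) -> Optional[float]:
    if cell is None:
        return None
    if isinstance(cell, float):
        return None if math.isnan(cell) else float(cell)
    text = str(cell).strip()
    if not text:
        return None
    if decimal == ",":
        text = text.replace(".", "").replace(",", ".")
    return float(text)


def _clean_text(cell) -> Optional[str]:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return None
    text = str(cell)
    return text if text.strip() else None


def records_from_frame(
    frame: pd.DataFrame, dialect: Optional[DatasetDialect] = None
) -> list[BrandedFoodRecord]:
    dialect = dialect or DatasetDialect()
    nutrient_cols = dict(DEFAULT_NUTRIENT_COLUMNS)
    nutrient_cols.update(dialect.nutrient_columns)
    id_col = dialect.header("food_id")
    if id_col not in frame.columns:
        raise ValueError(f"missing mandatory id column {id_col!r}")
    records = []
    seen: set[str] = set()
    for row_number, row in enumerate(frame.to_dict("records")):
        food_id = _clean_text(row.get(id_col))
        if food_id is None:
            raise ValueError(f"row {row_number}: empty food id")
        if food_id in seen:
            raise ValueError(f"row {row_number}: duplicate food id {food_id!r}")
        seen.add(food_id)
        values = {}
        for nutrient_id, header in nutrient_cols.items():
            if header in frame.columns:
                try:
                    parsed = _parse_number(row.get(header), dialect.decimal)
                except ValueError as exc:
                    raise ValueError(
                        f"row {row_number}, column {header!r}: {exc}"
                    ) from exc
                if parsed is not None:
                    values[nutrient_id] = parsed
        kwargs = {}
        for canonical in TEXT_COLUMNS[1:]:
            header = dialect.header(canonical)
            if header in frame.columns:
                kwargs[canonical] = _clean_text(row.get(header))
        records.append(
            BrandedFoodRecord(
                food_id=food_id, nutrient_values=values, **{
                    k: (v if v is not None else None) for k, v in kwargs.items()
                }
            )
        )
    return records


def read_dataset(
    path: Union[str, Path], dialect: Optional[DatasetDialect] = None
) -> list[BrandedFoodRecord]:
    """One record per row; empty cells become absent fields."""
    frame = pd.read_csv(path, dtype=str, encoding="utf-8", keep_default_na=False)
    frame = frame.replace({"": None})
    return records_from_frame(frame, dialect)


def records_to_frame(records: Iterable[BrandedFoodRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "food_id": r.food_id,
            "food_group": r.food_group,
            "food_subgroup": r.food_subgroup,
            "food_name": r.food_name,
            "ingredient_list": r.ingredient_list,
            "legal_name": r.legal_name,
            "mandatory_particulars": r.mandatory_particulars,
        }
        for nutrient_id in sorted(set(DEFAULT_NUTRIENT_COLUMNS) | set(r.nutrient_values)):
            row[nutrient_id] = r.nutrient_values.get(nutrient_id)
        rows.append(row)
    return pd.DataFrame(rows)


def write_dataset(records: Iterable[BrandedFoodRecord], path: Union[str, Path]) -> None:
    records_to_frame(records).to_csv(path, index=False, encoding="utf-8")


@dataclass(frozen=True)
class DatasetSummary:
    """Coverage, per-nutrient fortified counts, and fortified-by-food-group
    counts with sparse groups merged into "Miscellaneous"."""

    total_foods: int
    coverage: Mapping[str, tuple[int, float]]  # variable -> (n, fraction)
    fortified_per_nutrient: Mapping[str, tuple[int, float]]  # (n, pct of total)
    fortified_any: tuple[int, float]
    fortified_by_group: Mapping[str, Mapping[str, int]]  # nutrient -> group -> n

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"variable": "total_foods", "n": self.total_foods, "value": 100.0}
        ]
        for var, (n, frac) in self.coverage.items():
            rows.append({"variable": f"coverage:{var}", "n": n, "value": 100 * frac})
        for nutrient, (n, pct) in self.fortified_per_nutrient.items():
            rows.append({"variable": f"fortified:{nutrient}", "n": n, "value": pct})
        rows.append(
            {
                "variable": "fortified:any",
                "n": self.fortified_any[0],
                "value": self.fortified_any[1],
            }
        )
        return pd.DataFrame(rows)


MERGE_THRESHOLD = 5  # groups with fewer fortified foods fold into Miscellaneous


def summarize(
    results: pd.DataFrame,
    records: Sequence[BrandedFoodRecord],
    nutrients: Optional[Sequence[str]] = None,
) -> DatasetSummary:
    """Dataset-level summary of a classification run.

    Percentages use the full dataset size as denominator; a food fortified
    with one or more nutrients counts once in the "any" total; food groups
    with fewer than five fortified foods merge into "Miscellaneous".
    """
    total = len(records)
    nutrients = list(nutrients or sorted(results["nutrient"].unique()))
    by_id = {r.food_id: r for r in records}

    coverage = {}
    for var in ("food_group", "ingredient_list", "legal_name", "mandatory_particulars"):
        n = sum(1 for r in records if getattr(r, var) not in (None, ""))
        coverage[var] = (n, n / total if total else 0.0)
    for nutrient in nutrients:
        n = sum(1 for r in records if nutrient in r.nutrient_values)
        coverage[f"{nutrient}_values"] = (n, n / total if total else 0.0)

    fortified = results[results["label"] == FORTIFIED]
    per_nutrient = {}
    for nutrient in nutrients:
        n = int((fortified["nutrient"] == nutrient).sum())
        per_nutrient[nutrient] = (n, 100 * n / total if total else 0.0)
    any_ids = set(fortified["food_id"])
    fortified_any = (len(any_ids), 100 * len(any_ids) / total if total else 0.0)

    by_group: dict[str, dict[str, int]] = {}
    for nutrient in nutrients:
        ids = fortified.loc[fortified["nutrient"] == nutrient, "food_id"]
        groups: dict[str, int] = {}
        for food_id in ids:
            record = by_id.get(food_id)
            group = record.food_group if record and record.food_group else "Unclassified"
            groups[group] = groups.get(group, 0) + 1
        merged: dict[str, int] = {}
        for group, n in sorted(groups.items()):
            key = group if n >= MERGE_THRESHOLD or group == "Miscellaneous" else "Miscellaneous"
            merged[key] = merged.get(key, 0) + n
        by_group[nutrient] = merged

    return DatasetSummary(
        total_foods=total,
        coverage=coverage,
        fortified_per_nutrient=per_nutrient,
        fortified_any=fortified_any,
        fortified_by_group=by_group,
    )
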