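"""Tidy measurement tables (entity × condition × replicate) with CSV round-trip."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

REQUIRED_COLUMNS = ("entity_id", "condition_id", "replicate", "value", "unit")


class TableError(ValueError):
    pass


@dataclass
class MeasurementTable:
    """Long-format measurement records.

    Columns: entity_id, condition_id, replicate (int), value (float), unit (str).
    Invariant: a single unit per entity_id.
    """

    data: pd.DataFrame
    name: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise TableError(f"missing required column(s): {', '.join(missing)}")
        units = self.data.groupby("entity_id")["unit"].nunique()
        bad = units[units > 1]
        if len(bad):
            raise TableError(
                f"conflicting units for entity {bad.index[0]!r}"
            )
        self.data = self.data.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    def condition_ids(self) -> list[str]:
        return sorted(self.data["condition_id"].unique())

    def entity_ids(self) -> list[str]:
        return sorted(self.data["entity_id"].unique())

    def check_conditions(self, declared: set[str]) -> list[str]:
        """Return condition ids not present in *declared*."""
        return sorted(set(self.data["condition_id"]) - set(declared))

    def wide(self, aggregate: str = "mean") -> pd.DataFrame:
        """Pivot to entity × condition, aggregating replicates."""
        return self.data.pivot_table(
            index="entity_id", columns="condition_id", values="value",
            aggfunc=aggregate,
        )


def read_table(path: str | Path, name: str = "", sep: str | None = None) -> MeasurementTable:
    """Read a CSV/TSV measurement table. The header row is required.

    Raises :class:`TableError` naming any missing required column or unit
    conflict.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    df.columns = [c.strip() for c in df.columns]
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TableError(f"missing required column(s): {', '.join(missing)}")
    df["replicate"] = df["replicate"].astype(int)
    df["value"] = df["value"].astype(float)
    return MeasurementTable(df[list(REQUIRED_COLUMNS)], name=name or path.stem)


def write_table(table: MeasurementTable, path: str | Path) -> None:
    """Write to CSV (RFC-4180, UTF-8); round-trips through :func:`read_table`."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    table.data[list(REQUIRED_COLUMNS)].to_csv(path, sep=sep, index=False)


def from_wide(wide: pd.DataFrame, unit: str, name: str = "") -> MeasurementTable:
    """Build a single-replicate table from an entity × condition frame."""
    long = wide.stack().reset_index()
    long.columns = ["entity_id", "condition_id", "value"]
    long["replicate"] = 1
    long["unit"] = unit
    return MeasurementTable(long[list(REQUIRED_COLUMNS)], name=name)
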