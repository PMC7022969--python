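"""Event-record data model and delimited-text I/O.

Herd event histories are exchanged as long-format CSV tables, one row per
animal event. Two files make up a dataset:

* ``events.csv`` — columns ``herd_id, animal_id, event_date, event_type,
  value, parity``. ``value`` (kg) is present exactly for ``MILK_WEIGH``
  events; ``parity`` optionally annotates ``CALVING`` events.
* ``herds.csv`` — columns ``herd_id, zone, breed_group,
  first_followup_year`` with one row per herd.

Identifiers are opaque strings (never coerced to numbers), dates are
ISO-8601, and empty cells are written as empty strings — never 0, which
would be a legal-looking milk weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Closed enumeration of event kinds.
EVENT_TYPES = (
    "BIRTH",
    "CALVING",
    "CONCEPTION",
    "MILK_WEIGH",
    "MASTITIS",
    "LAMENESS",
    "CULL",
)

#: Record-keeping categories used for adoption-level classification.
#: Culling is a productive event because productive life is derived from it.
EVENT_CATEGORY = {
    "BIRTH": "reproductive",
    "CALVING": "reproductive",
    "CONCEPTION": "reproductive",
    "MILK_WEIGH": "productive",
    "CULL": "productive",
    "MASTITIS": "health",
    "LAMENESS": "health",
}

#: Holdridge life-zone labels for the study region (humid and very humid
#: forest in their tropical / low-montane / premontane belts, plus
#: premontane rain forest).
ZONES = (
    "HUMID_FOREST_TROPICAL",
    "HUMID_FOREST_LOW_MONTANE",
    "HUMID_FOREST_PREMONTANE",
    "VERY_HUMID_FOREST_TROPICAL",
    "VERY_HUMID_FOREST_LOW_MONTANE",
    "VERY_HUMID_FOREST_PREMONTANE",
    "RAIN_FOREST_PREMONTANE",
)

BREED_GROUPS = (
    "HOLSTEIN",
    "JERSEY",
    "HOLSTEIN_X_JERSEY",
    "DAIRY_CROSS",
    "DAIRY_X_BOS_INDICUS",
    "OTHER",
)

EVENT_COLUMNS = ["herd_id", "animal_id", "event_date", "event_type", "value", "parity"]
HERD_COLUMNS = ["herd_id", "zone", "breed_group", "first_followup_year"]


class RecordFormatError(ValueError):
    """Raised when an input file violates the event/herd schema."""


@dataclass
class ValidationIssue:
    row: int | None
    rule: str
    message: str


@dataclass
class ValidationReport:
    """Collection of invariant violations found in an event table."""

    issues: list[ValidationIssue] = field(default_factory=list)

    def add(self, row: int | None, rule: str, message: str) -> None:
        self.issues.append(ValidationIssue(row, rule, message))

    @property
    def ok(self) -> bool:
        return not self.issues

    def __len__(self) -> int:
        return len(self.issues)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(i.row, i.rule, i.message) for i in self.issues],
            columns=["row", "rule", "message"],
        )


def _parse_dates(raw: pd.Series, path, column: str) -> pd.Series:
    parsed = pd.to_datetime(raw, format="ISO8601", errors="coerce")
    bad = parsed.isna() & raw.notna() & (raw.astype(str).str.len() > 0)
    if bad.any():
        row = int(bad.idxmax()) + 2  # +1 header, +1 one-based
        raise RecordFormatError(
            f"{path}: unparseable date {raw[bad.idxmax()]!r} in column "
            f"'{column}', line {row}"
        )
    if parsed.isna().any():
        row = int(parsed.isna().idxmax()) + 2
        raise RecordFormatError(f"{path}: missing date in column '{column}', line {row}")
    return parsed


def read_events(path, sep: str = ",") -> pd.DataFrame:
    """Read an event table, validating tokens and types row-by-row.

    Returns a DataFrame with typed columns in the canonical order; row
    order is preserved. Malformed rows raise :class:`RecordFormatError`
    naming the offending line and column.
    """
    df = pd.read_csv(
        path,
        sep=sep,
        dtype={"herd_id": str, "animal_id": str, "event_type": str},
        keep_default_na=True,
    )
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise RecordFormatError(f"{path}: missing columns {missing}")
    bad_type = ~df["event_type"].isin(EVENT_TYPES)
    if bad_type.any():
        idx = int(bad_type.idxmax())
        raise RecordFormatError(
            f"{path}: unknown event_type {df.loc[idx, 'event_type']!r} on line {idx + 2}"
        )
    df = df[EVENT_COLUMNS].copy()
    df["event_date"] = _parse_dates(df["event_date"], path, "event_date")
    try:
        df["value"] = pd.to_numeric(df["value"], errors="raise")
    except (ValueError, TypeError) as exc:
        raise RecordFormatError(f"{path}: non-numeric value column: {exc}") from exc
    df["value"] = df["value"].astype(float)
    try:
        df["parity"] = pd.to_numeric(df["parity"], errors="raise").astype("Int64")
    except (ValueError, TypeError) as exc:
        raise RecordFormatError(f"{path}: non-integer parity column: {exc}") from exc
    return df


def write_events(table: pd.DataFrame, path) -> None:
    """Write an event table as CSV (fixed header, ISO dates, empty cells blank)."""
    out = table[EVENT_COLUMNS].copy()
    out["event_date"] = pd.to_datetime(out["event_date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_herds(path, sep: str = ",") -> pd.DataFrame:
    """Read herd metadata (zone, breed group, first follow-up year)."""
    df = pd.read_csv(path, sep=sep, dtype={"herd_id": str, "zone": str, "breed_group": str})
    missing = [c for c in HERD_COLUMNS if c not in df.columns]
    if missing:
        raise RecordFormatError(f"{path}: missing columns {missing}")
    for col, allowed in (("zone", ZONES), ("breed_group", BREED_GROUPS)):
        bad = ~df[col].isin(allowed)
        if bad.any():
            idx = int(bad.idxmax())
            raise RecordFormatError(
                f"{path}: unknown {col} {df.loc[idx, col]!r} on line {idx + 2}"
            )
    if df["herd_id"].duplicated().any():
        dup = df.loc[df["herd_id"].duplicated(), "herd_id"].iloc[0]
        raise RecordFormatError(f"{path}: duplicate herd_id {dup!r}")
    df["first_followup_year"] = df["first_followup_year"].astype(int)
    return df[HERD_COLUMNS]


def write_herds(table: pd.DataFrame, path) -> None:
    table[HERD_COLUMNS].to_csv(path, index=False)


def validate_events(table: pd.DataFrame, meta: pd.DataFrame | None = None) -> ValidationReport:
    """Check event-table invariants; every finding is a report entry.

    Rules checked (rule tags in parentheses):

    * ``orphan_herd`` — herd_id absent from the metadata table (if given);
    * ``value_presence`` — value present iff event is MILK_WEIGH;
    * ``value_positive`` — milk weights strictly positive;
    * ``birth_first`` — an animal's BIRTH precedes all its other events;
    * ``conception_context`` — CONCEPTION preceded by a CALVING or BIRTH
      of the same animal;
    * ``parity_negative`` — parity, when present, non-negative.
    """
    report = ValidationReport()
    is_milk = table["event_type"] == "MILK_WEIGH"
    has_value = table["value"].notna()

    for idx in table.index[is_milk & ~has_value]:
        report.add(int(idx), "value_presence", "MILK_WEIGH without a value")
    for idx in table.index[~is_milk & has_value]:
        report.add(int(idx), "value_presence",
                   f"{table.loc[idx, 'event_type']} carries a value")
    for idx in table.index[is_milk & has_value & (table["value"] <= 0)]:
        report.add(int(idx), "value_positive",
                   f"non-positive milk weight {table.loc[idx, 'value']}")
    parity = table["parity"]
    for idx in table.index[parity.notna() & (parity.astype("Float64") < 0)]:
        report.add(int(idx), "parity_negative", f"negative parity {parity[idx]}")

    if meta is not None:
        known = set(meta["herd_id"])
        orphan_herds = sorted(set(table["herd_id"]) - known)
        for h in orphan_herds:
            first = int(table.index[table["herd_id"] == h][0])
            report.add(first, "orphan_herd", f"herd_id {h!r} not in herd metadata")

    # per-animal ordering rules
    for (herd, animal), grp in table.groupby(["herd_id", "animal_id"], sort=False):
        births = grp.loc[grp["event_type"] == "BIRTH", "event_date"]
        if not births.empty:
            birth = births.min()
            early = grp[(grp["event_type"] != "BIRTH") & (grp["event_date"] < birth)]
            for idx in early.index:
                report.add(int(idx), "birth_first",
                           f"animal {animal}: event before its BIRTH")
        starts = grp.loc[grp["event_type"].isin(["CALVING", "BIRTH"]), "event_date"]
        first_start = starts.min() if not starts.empty else None
        conc = grp[grp["event_type"] == "CONCEPTION"]
        for idx in conc.index:
            if first_start is None or conc.loc[idx, "event_date"] < first_start:
                report.add(int(idx), "conception_context",
                           f"animal {animal}: CONCEPTION without prior CALVING/BIRTH")
    return report
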