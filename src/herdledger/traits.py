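"""Herd-year performance traits derived from event records.

Six traits, each averaged per herd and calendar year:

* ``AFC`` — age at first calving (months, 30.4375 d/month), over females
  whose first calving falls in the year;
* ``DO``  — days from calving to confirmed conception, over cows that
  conceived in the year (the conception year indexes the record);
* ``DMY`` — mean daily milk yield (kg) over all individual weighings;
* ``PL``  — productive life (years, 365.25 d/year) from first calving to
  culling, over cows culled in the year;
* ``MAST``/``LAM`` — percentage of lactations started in the year with at
  least one clinical mastitis / lameness event (a lactation starts at a
  CALVING; a health event belongs to the lactation whose calving most
  recently precedes it).

Rows outside a herd's follow-up window are omitted. Each row carries the
herd-size class for the year (distinct cows with a calving, conception or
milk weighing) and the five-year calendar period.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DAYS_PER_MONTH = 30.4375
DAYS_PER_YEAR = 365.25

#: Herd-size class edges: class 1 = [5, 20), 2 = [20, 40), 3 = [40, 70),
#: 4 = [70, 100), 5 = 100+. The 40/70/100 interior edges are package
#: defaults for the two classes whose bounds are not published.
HERD_SIZE_EDGES = (20, 40, 70, 100)

CALENDAR_PERIODS = ("<=1990", "1991-1995", "1996-2000", "2001-2005",
                    "2006-2010", ">=2010")


def herd_size_class(n_cows: int) -> int:
    """Map a cow count to herd-size class 1-5."""
    if n_cows < 1:
        raise ValueError("n_cows must be >= 1")
    for cls, edge in enumerate(HERD_SIZE_EDGES, start=1):
        if n_cows < edge:
            return cls
    return 5


def calendar_period(year: int) -> str:
    """Five-year calendar period label; 1990 and earlier pool into the
    first bin, 2011 onward into the last (2010 sits in 2006-2010)."""
    if year <= 1990:
        return "<=1990"
    if year <= 1995:
        return "1991-1995"
    if year <= 2000:
        return "1996-2000"
    if year <= 2005:
        return "2001-2005"
    if year <= 2010:
        return "2006-2010"
    return ">=2010"


def _herd_sizes(events: pd.DataFrame) -> pd.Series:
    """Cows in production per herd-year: distinct animals with a CALVING,
    CONCEPTION or MILK_WEIGH event in the year."""
    prod = events[events["event_type"].isin(["CALVING", "CONCEPTION", "MILK_WEIGH"])]
    return (prod.assign(year=prod["event_date"].dt.year)
            .groupby(["herd_id", "year"])["animal_id"].nunique())


def _attach_lactation(health: pd.DataFrame, calvings: pd.DataFrame) -> pd.DataFrame:
    """Attribute each health event to the same animal's most recent
    preceding calving; events without one are dropped."""
    if health.empty or calvings.empty:
        return pd.DataFrame(columns=["herd_id", "animal_id", "calving_date"])
    h = health.sort_values("event_date")
    c = calvings.sort_values("event_date")
    merged = pd.merge_asof(
        h, c.rename(columns={"event_date": "calving_date"}),
        left_on="event_date", right_on="calving_date",
        by=["herd_id", "animal_id"], direction="backward",
    )
    return merged.dropna(subset=["calving_date"])


def derive_traits(events: pd.DataFrame,
                  followup_map: dict[str, dict[int, int]],
                  levels: dict[str, str] | None = None) -> pd.DataFrame:
    """Compute the herd-year trait table from an event table.

    ``followup_map`` maps each retained herd's calendar years to
    follow-up years (from :func:`herdledger.cohort.select_followup`).
    ``levels`` optionally gates trait domains per herd (a MEDIUM herd
    yields no health traits even if a stray event exists); without it a
    herd yields whatever its events support.

    Returns one row per herd x calendar year x derivable trait with
    columns ``herd_id, calendar_year, followup_year, trait, value,
    n_units, herd_size_class, calendar_period``.
    """
    from .synthetic import LEVEL_TRAITS  # availability pattern

    ev = events.copy()
    ev["event_date"] = pd.to_datetime(ev["event_date"])
    ev["year"] = ev["event_date"].dt.year
    sizes = _herd_sizes(ev)

    pieces: list[pd.DataFrame] = []

    def add(trait: str, grouped: pd.DataFrame) -> None:
        grouped = grouped.rename(columns={"year": "calendar_year"})
        grouped["trait"] = trait
        pieces.append(grouped)

    calvings = ev[ev["event_type"] == "CALVING"]
    births = ev[ev["event_type"] == "BIRTH"]

    # AFC: females with a BIRTH record and a first calving
    if not births.empty and not calvings.empty:
        b = births.groupby(["herd_id", "animal_id"])["event_date"].min()
        fc = calvings.groupby(["herd_id", "animal_id"])["event_date"].min()
        both = pd.concat([b.rename("birth"), fc.rename("first_calving")],
                         axis=1).dropna()
        both = both[both["first_calving"] > both["birth"]]
        if not both.empty:
            both["value"] = ((both["first_calving"] - both["birth"]).dt.days
                             / DAYS_PER_MONTH)
            both["year"] = both["first_calving"].dt.year
            g = (both.groupby([both.index.get_level_values(0), "year"])["value"]
                 .agg(["mean", "size"]).reset_index()
                 .rename(columns={"level_0": "herd_id", "mean": "value",
                                  "size": "n_units"}))
            add("AFC", g)

    # DO: conception paired with the most recent preceding calving
    conceptions = ev[ev["event_type"] == "CONCEPTION"]
    if not conceptions.empty and not calvings.empty:
        merged = pd.merge_asof(
            conceptions.sort_values("event_date"),
            calvings.sort_values("event_date")[
                ["herd_id", "animal_id", "event_date"]
            ].rename(columns={"event_date": "calving_date"}),
            left_on="event_date", right_on="calving_date",
            by=["herd_id", "animal_id"], direction="backward",
        ).dropna(subset=["calving_date"])
        if not merged.empty:
            merged["value"] = (merged["event_date"] - merged["calving_date"]).dt.days
            merged["year"] = merged["event_date"].dt.year
            g = (merged.groupby(["herd_id", "year"])["value"]
                 .agg(["mean", "size"]).reset_index()
                 .rename(columns={"mean": "value", "size": "n_units"}))
            add("DO", g)

    # DMY: mean over all weighings
    milk = ev[ev["event_type"] == "MILK_WEIGH"]
    if not milk.empty:
        g = (milk.groupby(["herd_id", "year"])["value"]
             .agg(["mean", "size"]).reset_index()
             .rename(columns={"mean": "value", "size": "n_units"}))
        add("DMY", g)

    # PL: first calving to culling, indexed by cull year
    culls = ev[ev["event_type"] == "CULL"]
    if not culls.empty and not calvings.empty:
        fc = calvings.groupby(["herd_id", "animal_id"])["event_date"].min()
        cu = culls.groupby(["herd_id", "animal_id"])["event_date"].min()
        both = pd.concat([fc.rename("first_calving"), cu.rename("cull")],
                         axis=1).dropna()
        both = both[both["cull"] > both["first_calving"]]
        if not both.empty:
            both["value"] = ((both["cull"] - both["first_calving"]).dt.days
                             / DAYS_PER_YEAR)
            both["year"] = both["cull"].dt.year
            g = (both.groupby([both.index.get_level_values(0), "year"])["value"]
                 .agg(["mean", "size"]).reset_index()
                 .rename(columns={"level_0": "herd_id", "mean": "value",
                                  "size": "n_units"}))
            add("PL", g)

    # MAST / LAM: share of lactations with >= 1 event
    lact = calvings.assign(year=calvings["event_date"].dt.year)
    denom = lact.groupby(["herd_id", "year"]).size().rename("n_lact")
    for etype, trait in (("MASTITIS", "MAST"), ("LAMENESS", "LAM")):
        hev = ev[ev["event_type"] == etype]
        herds_recording = set(hev["herd_id"])
        if levels is not None:
            herds_recording = {h for h, lvl in levels.items()
                               if trait in LEVEL_TRAITS.get(lvl, ())}
        if not herds_recording or denom.empty:
            continue
        attached = _attach_lactation(
            hev[["herd_id", "animal_id", "event_date"]],
            calvings[["herd_id", "animal_id", "event_date"]],
        )
        frame = denom.reset_index()
        frame = frame[frame["herd_id"].isin(herds_recording)]
        if attached.empty:
            frame["n_hit"] = 0
        else:
            attached["year"] = pd.to_datetime(attached["calving_date"]).dt.year
            hit = (attached.drop_duplicates(
                       ["herd_id", "animal_id", "calving_date"])
                   .groupby(["herd_id", "year"]).size())
            key = pd.MultiIndex.from_frame(frame[["herd_id", "year"]])
            frame["n_hit"] = hit.reindex(key, fill_value=0).to_numpy()
        frame["value"] = 100.0 * frame["n_hit"] / frame["n_lact"]
        frame = frame.rename(columns={"n_lact": "n_units"})
        add(trait, frame[["herd_id", "year", "value", "n_units"]])

    if not pieces:
        return pd.DataFrame(columns=[
            "herd_id", "calendar_year", "followup_year", "trait", "value",
            "n_units", "herd_size_class", "calendar_period"])
    table = pd.concat(pieces, ignore_index=True)

    # restrict to follow-up windows and annotate
    fy = []
    keep = []
    for herd, year in zip(table["herd_id"], table["calendar_year"]):
        m = followup_map.get(herd, {})
        if int(year) in m:
            keep.append(True)
            fy.append(m[int(year)])
        else:
            keep.append(False)
            fy.append(-1)
    table = table[np.array(keep)].copy()
    table["followup_year"] = np.array(fy)[np.array(keep)]

    size_for = sizes.reindex(
        pd.MultiIndex.from_frame(table[["herd_id", "calendar_year"]])
    ).fillna(1).astype(int).to_numpy()
    table["herd_size_class"] = [herd_size_class(max(int(s), 1)) for s in size_for]
    table["calendar_period"] = table["calendar_year"].map(calendar_period)
    cols = ["herd_id", "calendar_year", "followup_year", "trait", "value",
            "n_units", "herd_size_class", "calendar_period"]
    return table[cols].sort_values(
        ["trait", "herd_id", "calendar_year"]).reset_index(drop=True)


@dataclass
class CutoffResult:
    table: pd.DataFrame
    removed: pd.DataFrame  # rows dropped, with a `reason` column


def default_cutoffs(k_sd: float = 4.0) -> dict[str, tuple[float, float]]:
    """Per-trait (min, max) limits at baseline mean +/- k_sd pooled SDs,
    floored at zero; incidence traits additionally capped at 100%."""
    from .synthetic import default_trait_params

    out = {}
    for trait, tp in default_trait_params().items():
        lo = max(tp.mean - k_sd * tp.sd, 0.0)
        hi = tp.mean + k_sd * tp.sd
        if trait in ("MAST", "LAM"):
            hi = min(hi, 100.0)
        out[trait] = (lo, hi)
    return out


def apply_cutoffs(table: pd.DataFrame,
                  limits: dict[str, tuple[float, float]]) -> CutoffResult:
    """Drop herd-year rows outside per-trait [min, max] limits.

    No value is mutated; removed rows are returned with the reason.
    """
    for trait, (lo, hi) in limits.items():
        if not lo < hi:
            raise ValueError(f"cutoff limits for {trait} must satisfy min < max")
    if not limits:
        return CutoffResult(table.copy(), table.iloc[0:0].assign(reason=""))
    lo = table["trait"].map({t: lim[0] for t, lim in limits.items()})
    hi = table["trait"].map({t: lim[1] for t, lim in limits.items()})
    out_of_range = (table["value"] < lo) | (table["value"] > hi)
    out_of_range &= lo.notna()
    removed = table[out_of_range].copy()
    removed["reason"] = np.where(
        removed["value"] < lo[out_of_range], "below minimum", "above maximum")
    return CutoffResult(table[~out_of_range].copy(), removed)
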