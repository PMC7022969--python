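"""Herd selection and adoption-level classification.

A herd's use of the management information system is graded by which
record categories it kept for at least five *consecutive* calendar years:

* LOW    — reproductive records only (births, calvings, conceptions);
* MEDIUM — reproductive and productive (milk weighings, cullings);
* HIGH   — reproductive, productive, and health (mastitis, lameness);
* EXCLUDED — no category reaches a five-year run.

For MEDIUM/HIGH the qualifying runs of the different categories must
overlap in at least five common consecutive years, so the same herd-years
are analyzable across domains. The follow-up window starts at the first
year of the earliest qualifying run (the herd's first implementation) and
is capped at ten follow-up years.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .records import EVENT_CATEGORY

MIN_RUN_YEARS = 5
MAX_FOLLOWUP_YEARS = 10
CATEGORIES = ("reproductive", "productive", "health")


@dataclass
class AdoptionProfile:
    herd_id: str
    years_available: dict = field(default_factory=dict)  # category -> sorted years
    longest_run: dict = field(default_factory=dict)      # category -> int
    level: str = "EXCLUDED"
    followup_window: tuple[int, int] | None = None       # first, last calendar year


def _runs(years: set[int]) -> list[tuple[int, int]]:
    """Maximal consecutive runs (start, end) in a set of years."""
    out = []
    for y in sorted(years):
        if out and y == out[-1][1] + 1:
            out[-1] = (out[-1][0], y)
        else:
            out.append((y, y))
    return out


def _longest(years: set[int]) -> int:
    return max((e - s + 1 for s, e in _runs(years)), default=0)


def _earliest_qualifying(years: set[int], min_run: int) -> tuple[int, int] | None:
    for s, e in _runs(years):
        if e - s + 1 >= min_run:
            return s, e
    return None


def classify_adoption(events: pd.DataFrame, min_records_per_year: int = 1,
                      min_run: int = MIN_RUN_YEARS) -> dict[str, AdoptionProfile]:
    """Classify every herd in an event table by record availability.

    A calendar year counts as covered for a category when it holds at
    least ``min_records_per_year`` events of that category. Returns one
    :class:`AdoptionProfile` per herd; levels are mutually exclusive and,
    together with EXCLUDED, cover all herds.
    """
    if events.empty:
        raise ValueError("event table is empty")
    ev = events[["herd_id", "event_type", "event_date"]].copy()
    ev["category"] = ev["event_type"].map(EVENT_CATEGORY)
    ev["year"] = pd.to_datetime(ev["event_date"]).dt.year
    counts = ev.groupby(["herd_id", "category", "year"]).size()

    profiles: dict[str, AdoptionProfile] = {}
    for herd in ev["herd_id"].unique():
        years: dict[str, set[int]] = {c: set() for c in CATEGORIES}
        if herd in counts.index.get_level_values(0):
            sub = counts.loc[herd]
            for (cat, year), n in sub.items():
                if n >= min_records_per_year:
                    years[cat].add(int(year))
        prof = AdoptionProfile(
            herd_id=herd,
            years_available={c: sorted(years[c]) for c in CATEGORIES},
            longest_run={c: _longest(years[c]) for c in CATEGORIES},
        )
        rp = years["reproductive"] & years["productive"]
        rph = rp & years["health"]
        if (win := _earliest_qualifying(rph, min_run)) is not None:
            prof.level = "HIGH"
        elif (win := _earliest_qualifying(rp, min_run)) is not None:
            prof.level = "MEDIUM"
        elif (win := _earliest_qualifying(years["reproductive"], min_run)) is not None:
            prof.level = "LOW"
        prof.followup_window = win
        profiles[herd] = prof
    return profiles


def select_followup(profiles: dict[str, AdoptionProfile],
                    max_years: int = MAX_FOLLOWUP_YEARS
                    ) -> dict[str, dict[int, int]]:
    """Map each retained herd's calendar years to follow-up years 1..N.

    Follow-up year 1 is the first calendar year of the qualifying run;
    years beyond ``max_years`` are dropped. Excluded herds are absent.
    """
    if max_years < MIN_RUN_YEARS:
        raise ValueError(f"max_years must be >= {MIN_RUN_YEARS}")
    out: dict[str, dict[int, int]] = {}
    for herd, prof in profiles.items():
        if prof.level == "EXCLUDED" or prof.followup_window is None:
            continue
        start, end = prof.followup_window
        end = min(end, start + max_years - 1)
        out[herd] = {y: y - start + 1 for y in range(start, end + 1)}
    return out


def profiles_to_frame(profiles: dict[str, AdoptionProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles.values():
        rows.append({
            "herd_id": p.herd_id,
            "level": p.level,
            "window_start": p.followup_window[0] if p.followup_window else None,
            "window_end": p.followup_window[1] if p.followup_window else None,
            **{f"run_{c}": p.longest_run.get(c, 0) for c in CATEGORIES},
        })
    return pd.DataFrame(rows)
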