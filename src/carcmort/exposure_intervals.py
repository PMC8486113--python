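"""Censored exposure episodes and person-time tabulation.

Movement events are converted, per person, into non-overlapping episodes by
location. Custody episodes end at transfer to another facility type,
release, death, or the window end; community episodes following a *prison*
release (closed or semi-open) end at reincarceration in any facility type,
death, or the window end. Intervals are half-open ``[start, end)`` at day
resolution — the day of a transfer counts toward the destination — and
person-years use a 365.25-day divisor.
"""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd

from .config import CUSTODY_STATES

DAYS_PER_YEAR = 365.25
DEFAULT_WINDOW = (dt.date(2009, 1, 1), dt.date(2018, 12, 31))

PRISON_TYPES = ("closed", "semi_open")


class IntegrityError(ValueError):
    """Event stream violates basic consistency (e.g. events after death)."""


def assemble_person_events(clusters: pd.DataFrame, log: pd.DataFrame,
                           matches: pd.DataFrame | None = None,
                           registry: pd.DataFrame | None = None
                           ) -> pd.DataFrame:
    """Per-person event table from resolved clusters, the movement log and
    (optionally) linked mortality-registry rows.

    A linked registry death becomes a terminal ``death`` event; a death
    already present in the movement log on the same date is kept once.
    Returns columns person_uid, sex, event_type, facility_type, event_date.
    """
    row_map = {}
    for uid, mids, sex in zip(clusters["person_uid"],
                              clusters["member_row_ids"], clusters["sex"]):
        for rid in mids.split(";"):
            row_map[rid] = (uid, sex)
    ev = log[log["row_id"].isin(row_map)].copy()
    assigned = ev["row_id"].map(row_map)
    ev["person_uid"] = assigned.str[0]
    ev["sex"] = assigned.str[1]
    out = ev[["person_uid", "sex", "event_type", "facility_type",
              "event_date"]]

    if matches is not None and registry is not None and len(matches):
        acc = matches[matches["status"] == "accepted"]
        reg = registry.set_index("row_id")
        rows = []
        uid_sex = dict(zip(clusters["person_uid"], clusters["sex"]))
        for duid, drow in zip(acc["person_uid"], acc["death_row_id"]):
            r = reg.loc[drow]
            rows.append((duid, uid_sex.get(duid, r.get("sex", "unknown")),
                         "death", "", r["death_date"]))
        extra = pd.DataFrame(rows, columns=out.columns)
        out = pd.concat([out, extra], ignore_index=True)
        # a movement-log death duplicated by a linked registry death on any
        # date collapses to the registry date (the authoritative record)
        dup = out[out["event_type"] == "death"]
        keep = dup.sort_values("event_date").drop_duplicates(
            "person_uid", keep="first")
        out = pd.concat([out[out["event_type"] != "death"], keep],
                        ignore_index=True)
    return out.sort_values(["person_uid", "event_date"]).reset_index(drop=True)


def drop_conflicting_deaths(events: pd.DataFrame
                            ) -> tuple[pd.DataFrame, int]:
    """Remove death events that are followed by later movement activity for
    the same person (these arise from wrongly merged identities or false
    matches); returns the cleaned events and the number of deaths dropped.
    """
    deaths = events[events["event_type"] == "death"]
    if deaths.empty:
        return events, 0
    last = events.groupby("person_uid")["event_date"].max()
    bad_idx = [i for i, (uid, d) in
               zip(deaths.index, zip(deaths["person_uid"],
                                     deaths["event_date"]))
               if str(last[uid]) > str(d)]
    return events.drop(index=bad_idx), len(bad_idx)


def build_episodes(events: pd.DataFrame,
                   study_window: tuple[dt.date, dt.date] = DEFAULT_WINDOW,
                   post_release_from: tuple[str, ...] = PRISON_TYPES
                   ) -> pd.DataFrame:
    """Convert per-person movement events into censored episodes.

    ``post_release_from`` controls which facility types' releases open a
    community episode (prison types by default; pass all four to rebuild
    the ever-released person-time used in the non-incarcerated
    denominator subtraction).

    Raises :class:`IntegrityError` if a person has events after a death.
    Output columns: person_uid, location, start, end (ISO dates, half-open),
    end_reason, release_date (for post-release episodes).
    """
    wstart, wend = study_window
    wend_excl = wend + dt.timedelta(days=1)
    order = {"arrest": 1, "transfer": 2, "release": 3, "other": 4, "death": 5}
    rows = []

    for uid, grp in events.groupby("person_uid", sort=False):
        evs = sorted(
            ((dt.date.fromisoformat(str(d)[:10]), order.get(t, 4), t, f)
             for d, t, f in zip(grp["event_date"], grp["event_type"],
                                grp["facility_type"])),
            key=lambda e: (e[0], e[1]))
        state: str | None = None  # None = out of follow-up
        seg_start: dt.date | None = None
        release_date: dt.date | None = None
        dead = False

        def close(end, reason):
            nonlocal state, seg_start
            if state is not None and seg_start is not None and end > seg_start:
                s = max(seg_start, wstart)
                e = min(end, wend_excl)
                if e > s:
                    rows.append((uid, state, s.isoformat(), e.isoformat(),
                                 reason,
                                 release_date.isoformat()
                                 if state == "post_release" and release_date
                                 else ""))
            state, seg_start = None, None

        for date, _, etype, fac in evs:
            if dead:
                raise IntegrityError(
                    f"person {uid}: event {etype} on {date} after death")
            if date >= wend_excl:
                continue
            if etype == "other":
                continue
            if etype == "death":
                close(date + dt.timedelta(days=1), "death")
                dead = True
                continue
            if etype == "arrest" or (etype == "transfer" and fac):
                if fac not in CUSTODY_STATES:
                    continue
                if state == "post_release":
                    close(date, "reincarceration")
                elif state in CUSTODY_STATES:
                    close(date, "transfer")
                state, seg_start = fac, date
            elif etype == "release":
                was = state if state in CUSTODY_STATES else fac
                close(date, "release")
                if was in post_release_from:
                    state, seg_start = "post_release", date
                    release_date = date
        if not dead:
            close(wend_excl, "study_end")

    return pd.DataFrame(rows, columns=["person_uid", "location", "start",
                                       "end", "end_reason", "release_date"])


def truncate_overlong(episodes: pd.DataFrame, policy: dict) -> pd.DataFrame:
    """Cap overlong episodes per location to correct for unreported releases.

    ``policy`` maps location -> max duration in days, or ``("quantile", q)``
    to cap at the empirical q-quantile of that location's durations.
    Closed-prison episodes are never truncated.
    """
    ep = episodes.copy()
    start = pd.to_datetime(ep["start"])
    end = pd.to_datetime(ep["end"])
    dur = (end - start).dt.days
    for loc, rule in policy.items():
        if loc == "closed":
            raise ValueError("closed-prison episodes are never truncated")
        mask = ep["location"] == loc
        if not mask.any():
            continue
        if isinstance(rule, tuple) and rule[0] == "quantile":
            cap = int(np.ceil(np.quantile(dur[mask], rule[1])))
        else:
            cap = int(rule)
        over = mask & (dur > cap)
        ep.loc[over, "end"] = (start[over] +
                               pd.Timedelta(days=cap)).dt.date.astype(str)
        ep.loc[over, "end_reason"] = "truncated"
    return ep


def _year_boundaries(s: dt.date, e: dt.date):
    for y in range(s.year + 1, e.year + 1):
        yield dt.date(y, 1, 1)


def tabulate_person_time(episodes: pd.DataFrame,
                         strata: tuple[str, ...] = ("population", "location",
                                                    "sex", "calendar_year"),
                         person_sex: dict | None = None) -> pd.DataFrame:
    """Sum person-years over the requested strata.

    Supported stratum names: population, location, sex, calendar_year,
    release_year, years_since_release. Episodes spanning a calendar-year or
    release-anniversary boundary are split exactly at day resolution, so
    totals are conserved under any stratification.
    """
    valid = {"population", "location", "sex", "calendar_year",
             "release_year", "years_since_release"}
    unknown = set(strata) - valid
    if unknown:
        raise ValueError(f"unknown strata: {sorted(unknown)}")
    acc: dict[tuple, float] = {}
    need_year = "calendar_year" in strata
    need_ysr = "years_since_release" in strata

    for uid, loc, s, e, rel in zip(episodes["person_uid"],
                                   episodes["location"],
                                   episodes["start"], episodes["end"],
                                   episodes["release_date"]):
        s = dt.date.fromisoformat(s)
        e = dt.date.fromisoformat(e)
        rel_d = dt.date.fromisoformat(rel) if rel else None
        cuts = {s, e}
        if need_year:
            cuts.update(_year_boundaries(s, e))
        if need_ysr and rel_d is not None:
            k = 1
            while True:
                ann = rel_d + dt.timedelta(days=round(k * DAYS_PER_YEAR))
                if ann >= e:
                    break
                if ann > s:
                    cuts.add(ann)
                k += 1
        pts = sorted(cuts)
        for a, b in zip(pts[:-1], pts[1:]):
            days = (b - a).days
            if days <= 0:
                continue
            key = []
            for st in strata:
                if st == "population":
                    key.append("post-release" if loc == "post_release"
                               else "incarcerated")
                elif st == "location":
                    key.append(loc)
                elif st == "sex":
                    key.append(person_sex.get(uid, "unknown")
                               if person_sex else "unknown")
                elif st == "calendar_year":
                    key.append(a.year)
                elif st == "release_year":
                    key.append(rel_d.year if rel_d else -1)
                elif st == "years_since_release":
                    # segment starts fall on release anniversaries rounded
                    # to whole days; +1 day absorbs the rounding before
                    # flooring to an integer year index
                    key.append(int(((a - rel_d).days + 1) / DAYS_PER_YEAR)
                               if rel_d else -1)
            acc[tuple(key)] = acc.get(tuple(key), 0.0) + days / DAYS_PER_YEAR

    out = pd.DataFrame([k + (v,) for k, v in sorted(acc.items())],
                       columns=list(strata) + ["person_years"])
    return out
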