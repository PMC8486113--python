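"""Synthetic incarceration-movement and mortality registries with ground truth.

Careers are a continuous-time Markov jump process over the states
{never-incarcerated, closed, semi-open, police, youth, released}; mortality
is a competing exponential clock with intensity

    baseline(age, sex) x state_rate_ratio(state, years-since-release)

so every downstream estimand (standardized IRRs, post-release hazard decay,
cause mixes) is a configured truth. Piecewise-constant intensities are
simulated exactly by restarting the clocks at every age-band edge, release
anniversary, and the youth/adult age threshold.

The generator emits four inputs the analysis needs — a movement log, a
mortality registry (both with corrupted name strings), the wide-binned age
structure of the custodial population, and a projected general-population
age table — plus a truth table binding every registry row to its generating
individual.
"""

from __future__ import annotations

import datetime as dt
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SyntheticConfig, ConfigError, CUSTODY_STATES
from .names import draw_name, perturb_string

DAYS_PER_YEAR = 365.25

# representative ICD-10 underlying-cause pools per broad category
CODE_POOLS = {
    "violence": ["X93", "X95", "X99", "Y00"],
    "suicide": ["X70", "X80", "X68"],
    "communicable": ["A15", "A16", "B20", "J18", "A41"],
    "noncommunicable": ["I21", "I64", "C34", "E14", "K70"],
    "transport": ["V23", "V43", "V89", "V09"],
    "other": ["R99", "Y34", "W19", "X59"],
}
#: share of in-custody male violence deaths certified as "hanging,
#: strangulation and suffocation, undetermined intent" (Y20) — exercises the
#: custody reclassification rule in cause-of-death mapping
Y20_SHARE = 0.10


@dataclass
class CohortData:
    """Everything `generate_cohort` produces for one seed."""

    movement_log: pd.DataFrame
    mortality_registry: pd.DataFrame
    truth: pd.DataFrame
    truth_episodes: pd.DataFrame
    binned_age: pd.DataFrame
    projected_population: pd.DataFrame
    config: SyntheticConfig


class _BandLookup:
    """Piecewise-constant value lookup over age bands."""

    def __init__(self, bands):
        self.bands = sorted(bands)  # (lo, hi, value)
        self.edges = sorted({lo for lo, _, _ in bands}
                            | {hi + 1 for _, hi, _ in bands})

    def value(self, age: float) -> float:
        for lo, hi, v in self.bands:
            if lo <= age <= hi + 0.999999:
                return v
        lo, hi, v = self.bands[-1] if age > self.bands[-1][1] \
            else self.bands[0]
        return v

    def next_edge(self, age: float) -> float:
        for e in self.edges:
            if e > age + 1e-12:
                return e
        return math.inf


class _MortalitySchedule:
    """Piecewise-constant baseline hazard lookup by age and sex."""

    def __init__(self, table):
        self.edges = sorted({lo for lo, _, _, _ in table}
                            | {hi + 1 for _, hi, _, _ in table})
        self.table = sorted(table)

    def rate(self, age: float, sex: str) -> float:
        """events / person-year"""
        for lo, hi, m, f in self.table:
            if lo <= age <= hi + 0.999999:
                return (m if sex == "male" else f) / 1e5
        # outside the table: clamp to nearest band
        lo, hi, m, f = self.table[-1] if age > self.table[-1][1] else self.table[0]
        return (m if sex == "male" else f) / 1e5

    def next_edge(self, age: float) -> float:
        for e in self.edges:
            if e > age + 1e-12:
                return e
        return math.inf


def _rr(state_rate_ratios, state: str, years_since_release: float) -> float:
    if state == "never":
        return 1.0
    if state == "released":
        sched = state_rate_ratios["post_release"]
        idx = min(int(years_since_release), len(sched) - 1)
        return sched[idx]
    return state_rate_ratios[state]


def simulate_career(age0: float, sex: str, config: SyntheticConfig,
                    rng: np.random.Generator,
                    mort: _MortalitySchedule | None = None):
    """Simulate one person's event sequence over the study window.

    Returns ``(events, segments, death)`` where events are
    ``(t_years, event_type, facility)`` tuples, segments are
    ``(state, t_start, t_end, released_from_prison, release_t)`` covering
    [0, end of follow-up), and death is ``None`` or a dict.
    """
    cr = config.career_rates
    if mort is None:
        mort = _MortalitySchedule(config.baseline_mortality)
    arrest_mult = _BandLookup(cr.arrest_age_multipliers) \
        if cr.arrest_age_multipliers else None
    start, end = config.study_window
    window_years = ((end - start).days + 1) / DAYS_PER_YEAR

    t = 0.0
    state = "never"
    release_t: float | None = None
    release_from_prison = False
    events: list[tuple[float, str, str | None]] = []
    segments: list[tuple] = []
    seg_start = 0.0
    death = None

    dest_facs = list(cr.arrest_destination.keys())
    dest_p = np.array([cr.arrest_destination[f] for f in dest_facs])
    dest_p = dest_p / dest_p.sum()

    def close_segment(t_end):
        nonlocal seg_start
        if t_end > seg_start:
            segments.append((state, seg_start, t_end,
                             release_from_prison if state == "released" else False,
                             release_t if state == "released" else None))
        seg_start = t_end

    def arrest_facility(age):
        if age < cr.adult_age:
            return "youth"
        return dest_facs[rng.choice(len(dest_facs), p=dest_p)]

    while t < window_years:
        age = age0 + t
        ysr = (t - release_t) if (state == "released" and release_t is not None) else 0.0
        mrate = mort.rate(age, sex) * _rr(config.state_rate_ratios, state, ysr)

        # candidate transitions out of the current state
        trans: list[tuple[float, tuple]] = []
        arrestable = age >= cr.min_arrest_age
        mult = arrest_mult.value(age) if arrest_mult is not None else 1.0
        if state == "never":
            if cr.arrest_rate * mult > 0 and arrestable:
                trans.append((cr.arrest_rate * mult, ("arrest",)))
        elif state == "released":
            # reincarceration intensity is age-independent: post-release
            # survivorship then has no age selection, so a release cohort's
            # age profile really is the release-flow profile aged forward
            if cr.reincarceration_rate > 0 and arrestable:
                trans.append((cr.reincarceration_rate, ("arrest",)))
        else:
            for to, rate in cr.transfer.get(state, {}).items():
                if rate > 0:
                    trans.append((rate, ("transfer", to)))
            rel = cr.release.get(state, 0.0)
            if rel > 0:
                trans.append((rel, ("release",)))
        total_trans = sum(r for r, _ in trans)

        # next boundary where an intensity changes
        t_bound = window_years - t
        bound_kind = "window"
        e = mort.next_edge(age) - age
        if e < t_bound:
            t_bound, bound_kind = e, "age"
        if state == "released" and release_t is not None:
            e = (math.floor(t - release_t) + 1) - (t - release_t)
            if 1e-12 < e < t_bound:
                t_bound, bound_kind = e, "anniversary"
        if state == "youth" and age < cr.adult_age:
            e = cr.adult_age - age
            if e < t_bound:
                t_bound, bound_kind = e, "adult"
        if state in ("never", "released"):
            if age < cr.min_arrest_age:
                e = cr.min_arrest_age - age
                if e < t_bound:
                    t_bound, bound_kind = e, "age"
            if arrest_mult is not None:
                e = arrest_mult.next_edge(age) - age
                if e < t_bound:
                    t_bound, bound_kind = e, "age"

        t_trans = rng.exponential(1.0 / total_trans) if total_trans > 0 else math.inf
        t_death = rng.exponential(1.0 / mrate) if mrate > 0 else math.inf

        if t_bound <= min(t_trans, t_death):
            t += t_bound
            if bound_kind == "window":
                break
            if bound_kind == "adult":
                # aged out of youth detention: administrative release
                close_segment(t)
                events.append((t, "release", "youth"))
                state = "released"
                release_t = t
                release_from_prison = False
            continue

        if t_death <= t_trans:
            t += t_death
            close_segment(t)
            death = {"t": t, "state": state, "age": age0 + t,
                     "released_from_prison": release_from_prison,
                     "years_since_release": (t - release_t) if state == "released" and release_t is not None else None}
            break

        t += t_trans
        u = rng.random() * total_trans
        acc = 0.0
        action = trans[-1][1]
        for rate, a in trans:
            acc += rate
            if u <= acc:
                action = a
                break
        close_segment(t)
        if action[0] == "arrest":
            fac = arrest_facility(age0 + t)
            events.append((t, "arrest", fac))
            state = fac
        elif action[0] == "transfer":
            events.append((t, "transfer", action[1]))
            state = action[1]
        else:  # release
            events.append((t, "release", state))
            release_from_prison = state in ("closed", "semi_open")
            state = "released"
            release_t = t
    else:
        pass
    close_segment(min(t, window_years))
    return events, segments, death


def _draw_cause(state_key: str, sex: str, in_custody: bool,
                mix: dict, rng: np.random.Generator) -> tuple[str, str]:
    causes = list(mix.keys())
    p = np.array([mix[c] for c in causes])
    broad = causes[rng.choice(len(causes), p=p / p.sum())]
    if broad == "violence" and in_custody and sex == "male" \
            and rng.random() < Y20_SHARE:
        return broad, "Y20"
    pool = CODE_POOLS[broad]
    return broad, pool[rng.integers(len(pool))]


def generate_cohort(config: SyntheticConfig) -> CohortData:
    """Generate movement log, mortality registry, and ground truth.

    Reproducible under a fixed ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    mort = _MortalitySchedule(config.baseline_mortality)
    start, end = config.study_window
    window_years = ((end - start).days + 1) / DAYS_PER_YEAR

    mv_rows, death_rows, truth_rows, ep_rows = [], [], [], []
    mv_n = dth_n = rgi_n = 0
    noise = config.name_noise

    # projected-population accumulator: realized alive person-years of the
    # whole simulated population by sex, calendar year, wide age bin
    pop_bins = {s: [(lo, hi) for lo, hi, _ in config.age_binned_target[s]]
                for s in ("male", "female")}
    pop_acc: dict[tuple, float] = {}
    # custody person-time by sex, calendar year, wide bin: the annual
    # binned age-structure table a prison administration would publish
    cust_acc: dict[tuple, float] = {}

    def record_name(name: str) -> str:
        return perturb_string(name, noise, rng)

    def record_mother(mother: str) -> str:
        if rng.random() < noise.missing_mother_prob:
            return ""
        return perturb_string(mother, noise, rng)

    def to_date(t: float) -> dt.date:
        d = start + dt.timedelta(days=int(round(t * DAYS_PER_YEAR)))
        return min(d, end)

    for i in range(config.n_individuals):
        uid = f"P{i:07d}"
        sex = "male" if rng.random() < config.sex_ratio else "female"
        bins = config.age_binned_target[sex]
        props = np.array([p for _, _, p in bins])
        bi = rng.choice(len(bins), p=props / props.sum())
        lo, hi, _ = bins[bi]
        age0 = lo + rng.random() * (hi + 1 - lo)
        name, mother = draw_name(sex, rng)

        events, segments, death = simulate_career(age0, sex, config, rng, mort)

        # alive person-time into the projected-population table
        t_end_alive = death["t"] if death else window_years
        yr = 0
        while yr * 1.0 < t_end_alive:
            t0, t1 = float(yr), min(yr + 1.0, t_end_alive)
            # calendar years align with follow-up years (window starts Jan 1)
            mid_age = age0 + 0.5 * (t0 + t1)
            for (blo, bhi) in pop_bins[sex]:
                if blo <= mid_age <= bhi + 0.999999:
                    key = (sex, start.year + yr, blo, bhi)
                    pop_acc[key] = pop_acc.get(key, 0.0) + (t1 - t0)
                    break
            yr += 1

        # adult-facility custody only (closed, semi-open, police): the
        # administration's published age table covers prisons, not youth
        # detention, which has no age-structure information
        for st, t0, t1, _, _ in segments:
            if st not in ("closed", "semi_open", "police"):
                continue
            yr = int(t0)
            while yr < t1:
                a, b = max(t0, float(yr)), min(t1, yr + 1.0)
                mid_age = age0 + 0.5 * (a + b)
                for (blo, bhi) in pop_bins[sex]:
                    if blo <= mid_age <= bhi + 0.999999:
                        key = (sex, start.year + yr, blo, bhi)
                        cust_acc[key] = cust_acc.get(key, 0.0) + (b - a)
                        break
                yr += 1

        # internal IDs: possibly a duplicate registration partway through
        row_ids = []
        rgi = None
        rgi2 = None
        dup_cut = None
        if events:
            rgi_n += 1
            rgi = f"R{rgi_n:07d}"
            if rng.random() < config.duplicate_id_prob and len(events) > 1:
                rgi_n += 1
                rgi2 = f"R{rgi_n:07d}"
                dup_cut = int(rng.integers(1, len(events)))

        all_events = list(events)
        # occasional court-appearance rows while in custody ("other" events)
        for st, t0, t1, _, _ in segments:
            if st in CUSTODY_STATES and t1 > t0:
                for _ in range(rng.poisson(0.3 * (t1 - t0))):
                    all_events.append((t0 + rng.random() * (t1 - t0),
                                       "other", st))
        # in-custody death may be recorded in the movement log
        movement_death = False
        if death and death["state"] in CUSTODY_STATES \
                and rng.random() < config.custody_death_in_log_prob:
            movement_death = True
            all_events.append((death["t"], "death", death["state"]))
        all_events.sort(key=lambda e: e[0])

        for k, (t, etype, fac) in enumerate(all_events):
            mv_n += 1
            rid = f"M{mv_n:08d}"
            row_ids.append(rid)
            use_rgi = rgi2 if (dup_cut is not None and k >= dup_cut) else rgi
            mv_rows.append((rid, use_rgi, record_name(name),
                            record_mother(mother), sex, etype,
                            fac if fac in CUSTODY_STATES else "",
                            to_date(t).isoformat()))

        # mortality-registry row
        broad_cause = None
        death_row_id = ""
        if death and rng.random() < config.registry_coverage:
            in_custody = death["state"] in CUSTODY_STATES
            state_key = ("never" if death["state"] == "never"
                         else "post_release" if death["state"] == "released"
                         else death["state"])
            broad_cause, icd = _draw_cause(state_key, sex, in_custody,
                                           config.cause_mix[state_key], rng)
            dth_n += 1
            death_row_id = f"D{dth_n:07d}"
            row_ids.append(death_row_id)
            age_at_death = ("" if rng.random() < config.missing_age_prob
                            else int(death["age"]))
            death_rows.append((death_row_id, record_name(name),
                               record_mother(mother), sex,
                               to_date(death["t"]).isoformat(),
                               age_at_death, icd))

        status = "alive"
        if death:
            st = death["state"]
            status = {"never": "never-incarcerated", "released": "post-release",
                      "closed": "closed", "semi_open": "semi-open",
                      "police": "police", "youth": "youth"}[st]
        truth_rows.append((uid, sex, name, mother, rgi or "", rgi2 or "",
                           ";".join(row_ids), status,
                           round(death["age"], 3) if death else "",
                           to_date(death["t"]).isoformat() if death else "",
                           broad_cause or "", death_row_id, movement_death,
                           round(age0, 3)))

        for st, t0, t1, rel_prison, rel_t in segments:
            ep_rows.append((uid, st, to_date(t0).isoformat(),
                            to_date(t1).isoformat(),
                            round(t1 - t0, 6), rel_prison,
                            to_date(rel_t).isoformat() if rel_t is not None else ""))

    movement_log = pd.DataFrame(
        mv_rows, columns=["row_id", "internal_id", "name", "mother_name",
                          "sex", "event_type", "facility_type", "event_date"])
    mortality_registry = pd.DataFrame(
        death_rows, columns=["row_id", "name", "mother_name", "sex",
                             "death_date", "age_at_death", "icd10_code"])
    truth = pd.DataFrame(
        truth_rows, columns=["person_uid", "sex", "true_name",
                             "true_mother_name", "internal_id",
                             "internal_id2", "registry_row_ids",
                             "true_status_at_death", "true_age_at_death",
                             "death_date", "true_broad_cause",
                             "death_row_id", "death_in_movement_log",
                             "age_at_window_start"])
    truth_episodes = pd.DataFrame(
        ep_rows, columns=["person_uid", "state", "start", "end",
                          "duration_years", "release_from_prison",
                          "release_date"])

    # annual custody age structure in wide bins (realized person-time
    # proportions, as an administration's annual report would state them);
    # falls back to the configured target when a cell has no custody time
    ba_rows = []
    for s in ("male", "female"):
        for yr in range(start.year, end.year + 1):
            tot = sum(cust_acc.get((s, yr, lo, hi), 0.0)
                      for lo, hi, _ in config.age_binned_target[s])
            for lo, hi, p in config.age_binned_target[s]:
                prop = (cust_acc.get((s, yr, lo, hi), 0.0) / tot
                        if tot > 0 else p)
                ba_rows.append((s, yr, lo, hi, prop))
    binned_age = pd.DataFrame(
        ba_rows, columns=["sex", "year", "age_lo", "age_hi", "proportion"])

    pp_rows = [(s, yr, lo, hi, round(py, 6))
               for (s, yr, lo, hi), py in sorted(pop_acc.items())]
    projected_population = pd.DataFrame(
        pp_rows, columns=["sex", "year", "age_lo", "age_hi", "person_years"])

    return CohortData(movement_log, mortality_registry, truth,
                      truth_episodes, binned_age, projected_population,
                      config)


def write_cohort(cohort: CohortData, outdir) -> None:
    """Write the generated tables plus a manifest recording the seed."""
    import pathlib

    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.movement_log.to_csv(out / "movement_log.csv", index=False)
    cohort.mortality_registry.to_csv(out / "mortality_registry.csv", index=False)
    cohort.truth.to_csv(out / "truth.csv", index=False)
    cohort.truth_episodes.to_csv(out / "truth_episodes.csv", index=False)
    cohort.binned_age.to_csv(out / "binned_age.csv", index=False)
    cohort.projected_population.to_csv(out / "projected_population.csv",
                                       index=False)
    cohort.config.to_yaml(out / "config.yaml")
    manifest = {"seed": cohort.config.seed,
                "n_individuals": cohort.config.n_individuals,
                "n_movement_rows": int(len(cohort.movement_log)),
                "n_registry_rows": int(len(cohort.mortality_registry))}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
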