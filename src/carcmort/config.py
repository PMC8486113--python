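"""Configuration for the synthetic-registry generator and the pipeline.

All under-specified analysis parameters (similarity thresholds, truncation
caps, age-bin schemes, smoothing df) surface here with documented defaults so
a run is fully described by one YAML file plus a seed.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, asdict
from typing import Sequence

import yaml

CUSTODY_STATES = ("closed", "semi_open", "police", "youth")
BROAD_CAUSES = ("violence", "suicide", "communicable", "noncommunicable",
                "transport", "other")


class ConfigError(ValueError):
    """Invalid configuration; message names the offending field."""


def _check(cond: bool, field_name: str, msg: str) -> None:
    if not cond:
        raise ConfigError(f"{field_name}: {msg}")


@dataclass
class NameNoise:
    """Corruption model for name strings in both registries.

    ``char_error_prob`` is the per-character probability of a corruption
    event; each event is a substitution / deletion / insertion with the
    given weights. Token-level errors (dropping or swapping whole name
    tokens) and missing mother's names are applied per record.
    """

    char_error_prob: float = 0.0
    sub_weight: float = 0.6
    del_weight: float = 0.2
    ins_weight: float = 0.2
    token_drop_prob: float = 0.0
    token_swap_prob: float = 0.0
    missing_mother_prob: float = 0.0

    def validate(self) -> None:
        for name in ("char_error_prob", "token_drop_prob", "token_swap_prob",
                     "missing_mother_prob"):
            v = getattr(self, name)
            _check(0.0 <= v <= 1.0, f"name_noise.{name}", "must be in [0,1]")
        w = self.sub_weight + self.del_weight + self.ins_weight
        _check(w > 0 and min(self.sub_weight, self.del_weight,
                             self.ins_weight) >= 0,
               "name_noise.*_weight", "weights must be >= 0 and sum > 0")


@dataclass
class CareerRates:
    """Transition intensities of the incarceration career process
    (events per person-year)."""

    arrest_rate: float = 0.05
    #: destination facility probabilities for an adult arrest
    arrest_destination: dict = field(default_factory=lambda: {
        "police": 0.60, "closed": 0.35, "semi_open": 0.05})
    #: facility -> {facility: rate} transfer intensities
    transfer: dict = field(default_factory=lambda: {
        "police": {"closed": 20.0},
        "closed": {"semi_open": 0.5},
        "semi_open": {"closed": 0.5},
        "youth": {},
    })
    #: facility -> release intensity
    release: dict = field(default_factory=lambda: {
        "police": 20.0, "closed": 1.2, "semi_open": 3.5, "youth": 1.1})
    reincarceration_rate: float = 0.25
    adult_age: float = 18.0
    min_arrest_age: float = 12.0
    #: multiplicative age profile of arrest / reincarceration intensity,
    #: shaping the custody age structure (young-adult-heavy, as prison
    #: administrations report) on top of a near-uniform population pyramid
    arrest_age_multipliers: list = field(default_factory=lambda: [
        (4, 13, 0.0), (14, 17, 0.5), (18, 24, 2.2), (25, 29, 3.4),
        (30, 34, 2.8), (35, 45, 1.6), (46, 60, 0.55), (61, 95, 0.07)])

    def validate(self) -> None:
        _check(self.arrest_rate >= 0, "career_rates.arrest_rate", "must be >= 0")
        _check(self.reincarceration_rate >= 0,
               "career_rates.reincarceration_rate", "must be >= 0")
        dest = sum(self.arrest_destination.values())
        _check(abs(dest - 1.0) < 1e-9, "career_rates.arrest_destination",
               "probabilities must sum to 1")
        for fac, rate in self.release.items():
            _check(rate >= 0, f"career_rates.release.{fac}", "must be >= 0")
        for fac, row in self.transfer.items():
            for to, rate in row.items():
                _check(rate >= 0, f"career_rates.transfer.{fac}.{to}",
                       "must be >= 0")
        for lo, hi, m in self.arrest_age_multipliers:
            _check(m >= 0 and lo <= hi,
                   "career_rates.arrest_age_multipliers",
                   "must have lo<=hi and multiplier >= 0")


# All-cause mortality per 100,000 person-years in the never-incarcerated
# state, by age band and sex; loosely shaped like Brazilian male/female
# schedules with the strong young-adult external-cause hump for men.
DEFAULT_BASELINE_MORTALITY: list[tuple[int, int, float, float]] = [
    # (age_low, age_high, male_rate, female_rate)
    (4, 13, 30.0, 20.0),
    (14, 19, 150.0, 45.0),
    (20, 24, 230.0, 55.0),
    (25, 29, 235.0, 60.0),
    (30, 34, 245.0, 75.0),
    (35, 39, 270.0, 100.0),
    (40, 44, 330.0, 150.0),
    (45, 49, 450.0, 230.0),
    (50, 54, 650.0, 350.0),
    (55, 59, 950.0, 520.0),
    (60, 64, 1450.0, 800.0),
    (65, 69, 2300.0, 1300.0),
    (70, 79, 4800.0, 3200.0),
    (80, 95, 13000.0, 10000.0),
]

# Age distribution of the simulated resident population at the window
# start (wide bins, proportions): a gently declining pyramid, near-uniform
# density through adulthood. The 4-13 bin holds children who age into
# arrest-eligible ages during the window, keeping the population's age
# structure quasi-stationary over the decade as a real state population's
# is. The young-adult-heavy *custody* age structure then emerges from the
# age profile of arrest intensity (see CareerRates.arrest_age_multipliers),
# not from the population pyramid.
DEFAULT_AGE_BINNED_TARGET: dict[str, list[tuple[int, int, float]]] = {
    "male": [(4, 13, 0.1649), (14, 17, 0.0660), (18, 24, 0.1117),
             (25, 29, 0.0771), (30, 34, 0.0745), (35, 45, 0.1521),
             (46, 60, 0.1676), (61, 95, 0.1861)],
    "female": [(4, 13, 0.1649), (14, 17, 0.0660), (18, 24, 0.1117),
               (25, 29, 0.0771), (30, 34, 0.0745), (35, 45, 0.1521),
               (46, 60, 0.1676), (61, 95, 0.1861)],
}

# Broad-cause mix of deaths by state at death.
DEFAULT_CAUSE_MIX: dict[str, dict[str, float]] = {
    "never": {"violence": 0.14, "suicide": 0.02, "communicable": 0.08,
              "noncommunicable": 0.56, "transport": 0.15, "other": 0.05},
    "closed": {"violence": 0.32, "suicide": 0.08, "communicable": 0.24,
               "noncommunicable": 0.27, "transport": 0.02, "other": 0.07},
    "semi_open": {"violence": 0.55, "suicide": 0.04, "communicable": 0.12,
                  "noncommunicable": 0.22, "transport": 0.03, "other": 0.04},
    "police": {"violence": 0.45, "suicide": 0.18, "communicable": 0.08,
               "noncommunicable": 0.22, "transport": 0.02, "other": 0.05},
    "youth": {"violence": 0.75, "suicide": 0.06, "communicable": 0.04,
              "noncommunicable": 0.08, "transport": 0.04, "other": 0.03},
    "post_release": {"violence": 0.38, "suicide": 0.04, "communicable": 0.12,
                     "noncommunicable": 0.30, "transport": 0.10,
                     "other": 0.06},
}

DEFAULT_STATE_RATE_RATIOS: dict = {
    "closed": 1.3,
    "semi_open": 2.4,
    "police": 3.1,
    "youth": 8.1,
    # multiplier by integer year since release; last entry extends onward
    "post_release": [3.0],
}


@dataclass
class SyntheticConfig:
    """Full description of a synthetic cohort.

    ``n_individuals`` is the whole simulated resident population sample;
    people who are never arrested form the non-incarcerated comparison
    group and contribute only (possibly) a mortality-registry row.
    """

    n_individuals: int = 10_000
    study_window: tuple[dt.date, dt.date] = (dt.date(2009, 1, 1),
                                             dt.date(2018, 12, 31))
    sex_ratio: float = 0.92  # proportion male
    age_binned_target: dict = field(
        default_factory=lambda: {s: list(b) for s, b in
                                 DEFAULT_AGE_BINNED_TARGET.items()})
    career_rates: CareerRates = field(default_factory=CareerRates)
    baseline_mortality: list = field(
        default_factory=lambda: list(DEFAULT_BASELINE_MORTALITY))
    cause_mix: dict = field(
        default_factory=lambda: {s: dict(m) for s, m in
                                 DEFAULT_CAUSE_MIX.items()})
    state_rate_ratios: dict = field(
        default_factory=lambda: {k: (list(v) if isinstance(v, list) else v)
                                 for k, v in DEFAULT_STATE_RATE_RATIOS.items()})
    name_noise: NameNoise = field(default_factory=NameNoise)
    duplicate_id_prob: float = 0.0
    #: probability an in-custody death is also recorded in the movement log
    custody_death_in_log_prob: float = 0.6
    #: probability a death reaches the mortality registry
    registry_coverage: float = 1.0
    missing_age_prob: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        _check(self.n_individuals >= 0, "n_individuals", "must be >= 0")
        start, end = self.study_window
        _check(start < end, "study_window", "must be a nonempty interval")
        for name in ("sex_ratio", "duplicate_id_prob",
                     "custody_death_in_log_prob", "registry_coverage",
                     "missing_age_prob"):
            v = getattr(self, name)
            _check(0.0 <= v <= 1.0, name, "must be in [0,1]")
        self.career_rates.validate()
        self.name_noise.validate()
        for sex, bins in self.age_binned_target.items():
            tot = sum(p for _, _, p in bins)
            _check(abs(tot - 1.0) < 1e-6, f"age_binned_target.{sex}",
                   "bin proportions must sum to 1")
            for lo, hi, p in bins:
                _check(p >= 0 and lo <= hi, f"age_binned_target.{sex}",
                       "bins must have lo<=hi and proportion >= 0")
        for lo, hi, m, f in self.baseline_mortality:
            _check(m >= 0 and f >= 0, "baseline_mortality", "rates must be >= 0")
        for state, mix in self.cause_mix.items():
            tot = sum(mix.values())
            _check(abs(tot - 1.0) < 1e-9, f"cause_mix.{state}",
                   "cause probabilities must sum to 1 within 1e-9")
            _check(all(v >= 0 for v in mix.values()), f"cause_mix.{state}",
                   "cause probabilities must be >= 0")
        for state, rr in self.state_rate_ratios.items():
            vals = rr if isinstance(rr, (list, tuple)) else [rr]
            _check(all(v >= 0 for v in vals), f"state_rate_ratios.{state}",
                   "rate ratios must be >= 0")
        _check("post_release" in self.state_rate_ratios
               and len(self.state_rate_ratios["post_release"]) > 0,
               "state_rate_ratios.post_release", "must be a nonempty list")

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["study_window"] = [self.study_window[0].isoformat(),
                             self.study_window[1].isoformat()]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        if "study_window" in d:
            s, e = d["study_window"]
            d["study_window"] = (dt.date.fromisoformat(s) if isinstance(s, str) else s,
                                 dt.date.fromisoformat(e) if isinstance(e, str) else e)
        if "career_rates" in d and isinstance(d["career_rates"], dict):
            d["career_rates"] = CareerRates(**d["career_rates"])
        if "name_noise" in d and isinstance(d["name_noise"], dict):
            d["name_noise"] = NameNoise(**d["name_noise"])
        d["age_binned_target"] = {
            s: [tuple(b) for b in bins]
            for s, bins in d.get("age_binned_target",
                                 DEFAULT_AGE_BINNED_TARGET).items()}
        if "baseline_mortality" in d:
            d["baseline_mortality"] = [tuple(r) for r in d["baseline_mortality"]]
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class AnalysisConfig:
    """Parameters of the estimation pipeline (linkage thresholds, truncation
    caps, age-bin scheme, smoothing df)."""

    link_threshold: float = 0.90
    dedup_name_threshold: float = 0.90
    dedup_mother_threshold: float = 0.85
    length_weight_exponent: float = 0.5
    include_uncertain: bool = False
    specificity_floor: float = 0.995
    truncation_caps: dict = field(default_factory=lambda: {
        "police": 30, "semi_open": 730, "youth": 1095})  # days
    standard_bin_width: int = 4
    standard_bin_start: int = 18
    age_fit_bounds: tuple[int, int] = (14, 95)
    hazard_df: float = 4.0
    reduced_cohort_followup_years: float = 5.0

    def validate(self) -> None:
        _check(0 <= self.link_threshold <= 1, "link_threshold",
               "must be in [0,1]")
        for k, v in self.truncation_caps.items():
            _check(v > 0, f"truncation_caps.{k}", "must be positive days")
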