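"""Mortality rates, direct standardization, and rate-ratio inference.

Single rates get exact Poisson (chi-square quantile) confidence intervals.
Directly standardized rates sum age-specific rates with standard-population
weights; their intervals use the gamma approximation for weighted sums of
Poisson counts (Fay & Feuer). Two-sample rate ratios use the exact
conditional-binomial construction — given d1 + d0 events, d1 is binomial
with success probability py1*rho / (py1*rho + py0), and exact binomial
limits are inverted for rho. Standardized rate ratios use the F-distribution
approximation with equivalent-count degrees of freedom D = ASR^2 / Var(ASR).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

PER = 100_000.0


@dataclass
class RateEstimate:
    deaths: int
    person_years: float
    rate_per_100k: float
    ci_low: float
    ci_high: float
    age_bin: object = "all"


@dataclass
class StandardizedRate:
    rate_per_100k: float
    ci_low: float
    ci_high: float
    standard: str
    weights: dict          # age_bin -> weight
    variance: float        # of the rate on the per-person-year scale
    deaths: int


@dataclass
class RateRatio:
    irr: float
    ci_low: float
    ci_high: float
    method: str            # poisson_exact | f_approx
    reference: str = ""
    upper_unbounded: bool = False


def poisson_rate_ci(deaths: int, person_years: float,
                    alpha: float = 0.05) -> tuple[float, float]:
    """Exact Poisson CI for a rate, per 100,000 person-years."""
    if person_years <= 0:
        raise ValueError("person_years must be positive")
    d = deaths
    lo = 0.0 if d == 0 else stats.chi2.ppf(alpha / 2, 2 * d) / 2
    hi = stats.chi2.ppf(1 - alpha / 2, 2 * d + 2) / 2
    return lo / person_years * PER, hi / person_years * PER


def age_specific_rate(deaths: int, person_years: float, age_bin="all",
                      alpha: float = 0.05) -> RateEstimate:
    if person_years <= 0:
        raise ValueError("undefined rate: person_years must be positive")
    rate = deaths / person_years * PER
    lo, hi = poisson_rate_ci(deaths, person_years, alpha)
    return RateEstimate(int(deaths), float(person_years), rate, lo, hi,
                        age_bin)


def standardize(age_rates: list[RateEstimate], weights: dict,
                alpha: float = 0.05,
                standard: str = "incarcerated") -> StandardizedRate:
    """Directly standardized rate: ASR = sum_a w_a r_a.

    Weights must sum to 1 over the provided bins; a bin with nonzero weight
    but no rate estimate is an error. CI by the Fay-Feuer gamma method.
    """
    have = {r.age_bin: r for r in age_rates}
    missing = [b for b, w in weights.items() if w > 0 and b not in have]
    if missing:
        raise ValueError(f"age bins missing rate estimates: {missing}")
    wsum = sum(w for w in weights.values())
    if abs(wsum - 1.0) > 1e-6:
        raise ValueError(f"weights sum to {wsum}, not 1")
    asr = 0.0
    var = 0.0
    wm_max = 0.0
    n_deaths = 0
    for b, w in weights.items():
        if w <= 0:
            continue
        r = have[b]
        asr += w * r.deaths / r.person_years
        var += (w / r.person_years) ** 2 * r.deaths
        wm_max = max(wm_max, w / r.person_years)
        n_deaths += r.deaths
    # Fay-Feuer gamma interval
    if asr <= 0:
        lo = 0.0
    else:
        k = asr ** 2 / var
        lo = stats.gamma.ppf(alpha / 2, k) * var / asr
    asr_u = asr + wm_max
    var_u = var + wm_max ** 2
    k_u = asr_u ** 2 / var_u
    hi = stats.gamma.ppf(1 - alpha / 2, k_u) * var_u / asr_u
    return StandardizedRate(asr * PER, lo * PER, hi * PER, standard,
                            dict(weights), var, n_deaths)


def irr_exact(d1: int, py1: float, d0: int, py0: float,
              alpha: float = 0.05, reference: str = "") -> RateRatio:
    """Exact two-sample Poisson rate ratio with conditional-binomial CI."""
    if py1 <= 0 or py0 <= 0:
        raise ValueError("person-time must be positive in both groups")
    if d1 + d0 == 0:
        raise ValueError("no events in either group; IRR CI undefined")
    irr = (d1 / py1) / (d0 / py0) if d0 > 0 else math.inf
    n = d1 + d0
    # Clopper-Pearson limits for p = py1*rho / (py1*rho + py0)
    p_lo = 0.0 if d1 == 0 else stats.beta.ppf(alpha / 2, d1, n - d1 + 1)
    p_hi = 1.0 if d1 == n else stats.beta.ppf(1 - alpha / 2, d1 + 1, n - d1)
    lo = p_lo / (1 - p_lo) * py0 / py1 if p_lo < 1 else math.inf
    unbounded = p_hi >= 1.0
    hi = math.inf if unbounded else p_hi / (1 - p_hi) * py0 / py1
    return RateRatio(irr, lo, hi, "poisson_exact", reference, unbounded)


def irr_standardized(asr1: StandardizedRate, asr0: StandardizedRate,
                     alpha: float = 0.05, reference: str = "") -> RateRatio:
    """Ratio of directly standardized rates with an F-distribution CI.

    Each ASR is summarized by its equivalent count D = ASR^2 / Var and
    equivalent person-time T = D / ASR; the exact-Poisson-style F limits
    are then applied to (D1, T1) vs (D0, T0):

        lower = (D1 / (D0 + 1)) * (T0 / T1) / F_{1-a/2}(2(D0+1), 2 D1)
        upper = ((D1 + 1) / D0) * (T0 / T1) * F_{1-a/2}(2(D1+1), 2 D0)
    """
    if set(asr1.weights) != set(asr0.weights):
        raise ValueError("standardized rates must share the same standard")
    r1 = asr1.rate_per_100k / PER
    r0 = asr0.rate_per_100k / PER
    if r0 <= 0:
        raise ValueError("reference standardized rate is zero")
    irr = r1 / r0
    d1 = r1 ** 2 / asr1.variance if asr1.variance > 0 else math.inf
    d0 = r0 ** 2 / asr0.variance if asr0.variance > 0 else math.inf
    if not (math.isfinite(d1) and math.isfinite(d0)):
        return RateRatio(irr, irr, irr, "f_approx", reference)
    t1, t0 = d1 / r1, d0 / r0
    if d1 <= 0:
        lo = 0.0
    else:
        f_lo = stats.f.ppf(1 - alpha / 2, 2 * (d0 + 1), 2 * d1)
        lo = d1 / (d0 + 1) * (t0 / t1) / f_lo
    f_hi = stats.f.ppf(1 - alpha / 2, 2 * (d1 + 1), 2 * d0)
    hi = (d1 + 1) / d0 * (t0 / t1) * f_hi
    return RateRatio(irr, lo, hi, "f_approx", reference)


def rates_by_age(deaths_by_bin: pd.DataFrame, py_by_bin: pd.DataFrame,
                 alpha: float = 0.05) -> list[RateEstimate]:
    """Age-specific rates from aligned (age_bin, deaths) and
    (age_bin, person_years) tables; bins with no person-time are skipped."""
    d = dict(zip(deaths_by_bin["age_bin"], deaths_by_bin["deaths"]))
    out = []
    for b, py in zip(py_by_bin["age_bin"], py_by_bin["person_years"]):
        if py > 0:
            out.append(age_specific_rate(int(d.get(b, 0)), float(py), b,
                                         alpha))
    return out


def standardized_irr_for_group(deaths1, py1, deaths0, py0, weights,
                               alpha: float = 0.05,
                               reference: str = "non-incarcerated"):
    """Convenience: build both ASRs on shared weights and form their ratio.

    Weights are restricted to bins with person-time in BOTH groups and
    renormalized, so sparse strata do not error out.
    """
    r1 = {r.age_bin: r for r in rates_by_age(deaths1, py1, alpha)}
    r0 = {r.age_bin: r for r in rates_by_age(deaths0, py0, alpha)}
    usable = {b: w for b, w in weights.items()
              if w > 0 and b in r1 and b in r0}
    tot = sum(usable.values())
    if tot <= 0:
        raise ValueError("no usable age bins shared by both groups")
    usable = {b: w / tot for b, w in usable.items()}
    a1 = standardize(list(r1.values()), usable, alpha)
    a0 = standardize(list(r0.values()), usable, alpha)
    return a1, a0, irr_standardized(a1, a0, alpha, reference)
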