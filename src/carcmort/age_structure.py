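"""Age-structure disaggregation and age-stratified person-time.

The custodial population's age structure is published only in wide bins. A
negative binomial distribution, truncated to the plausible age support and
renormalized, is fitted to the binned proportions by multinomial maximum
likelihood; the fitted single-year masses are then rescaled within each
wide bin so bin totals reproduce the reported proportions exactly. Fine
structure is applied to person-time cells, aged forward one year per year
elapsed (for release cohorts), and corrected for the age-specific death
counts that deplete a cohort over time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "BinnedAgeTable", "TruncNBParams", "FineAgeDistribution", "FitError",
    "fit_truncated_negbin", "adjust_to_bins", "age_forward",
    "subtract_deaths", "non_incarcerated_denominator",
    "allocate_person_time", "to_standard_bins", "standard_weights",
]


class FitError(RuntimeError):
    """Age-distribution fit failed; carries the optimizer trace."""


@dataclass
class BinnedAgeTable:
    """Wide-binned age proportions for one sex and calendar year."""

    sex: str
    calendar_year: int | None
    bins: list  # [(age_low, age_high_inclusive, proportion), ...]

    def validate(self) -> None:
        tot = sum(p for _, _, p in self.bins)
        if abs(tot - 1.0) > 1e-6:
            raise ValueError(f"bin proportions sum to {tot}, not 1")
        prev_hi = None
        for lo, hi, p in self.bins:
            if p < 0 or lo > hi:
                raise ValueError("bins must have lo<=hi and proportion >= 0")
            if prev_hi is not None and lo != prev_hi + 1:
                raise ValueError("bins must be contiguous, non-overlapping")
            prev_hi = hi

    @classmethod
    def from_frame(cls, df: pd.DataFrame, sex: str,
                   year: int | None = None) -> "BinnedAgeTable":
        sub = df[df["sex"] == sex]
        if year is not None and "year" in sub.columns:
            sub = sub[sub["year"] == year]
        sub = sub.drop_duplicates(["age_lo", "age_hi"]).sort_values("age_lo")
        vals = sub["proportion"] if "proportion" in sub.columns \
            else sub["person_years"] / sub["person_years"].sum()
        t = cls(sex, year, [(int(lo), int(hi), float(p)) for lo, hi, p in
                            zip(sub["age_lo"], sub["age_hi"], vals)])
        t.validate()
        return t


@dataclass
class TruncNBParams:
    size: float        # dispersion r
    mean: float        # untruncated mean
    lower_trunc: int
    upper_trunc: int
    loglik: float = np.nan
    boundary: bool = False


@dataclass
class FineAgeDistribution:
    """Single-year age masses on a closed integer support."""

    sex: str
    calendar_year: int | None
    ages: np.ndarray
    masses: np.ndarray

    def validate(self) -> None:
        if abs(self.masses.sum() - 1.0) > 1e-9:
            raise ValueError("fine masses must sum to 1 within 1e-9")
        if (self.masses < -1e-15).any():
            raise ValueError("fine masses must be nonnegative")

    def copy(self) -> "FineAgeDistribution":
        return FineAgeDistribution(self.sex, self.calendar_year,
                                   self.ages.copy(), self.masses.copy())


def _trunc_nb_pmf(ages: np.ndarray, size: float, mean: float) -> np.ndarray:
    p = size / (size + mean)
    pmf = stats.nbinom.pmf(ages, size, p)
    tot = pmf.sum()
    if tot <= 0:
        return np.full_like(pmf, np.nan)
    return pmf / tot


def fit_truncated_negbin(binned: BinnedAgeTable,
                         bounds: tuple[int, int] = (14, 95),
                         tol: float = 1e-8
                         ) -> tuple[TruncNBParams, FineAgeDistribution]:
    """Fit a truncated negative binomial to wide-binned age proportions.

    Maximizes the multinomial likelihood of the bin masses under the
    truncated distribution (size/mean parameterization, renormalized over
    the integer support ``[bounds[0], bounds[1]]``), by Nelder-Mead simplex
    with multistart. Raises :class:`FitError` on non-convergence, and on
    degenerate input (< 3 bins with positive mass).
    """
    binned.validate()
    lo, hi = bounds
    positive = [b for b in binned.bins if b[2] > 0]
    if len(positive) < 3:
        raise FitError(
            f"degenerate binned input: only {len(positive)} bins with "
            "positive mass (need >= 3 to identify size and mean)")
    ages = np.arange(lo, hi + 1)
    bin_idx = []
    for blo, bhi, p in binned.bins:
        sel = (ages >= blo) & (ages <= bhi)
        bin_idx.append((sel, p))

    def nll(theta):
        size, mean = np.exp(theta)
        pmf = _trunc_nb_pmf(ages, size, mean)
        if not np.all(np.isfinite(pmf)):
            return 1e12
        ll = 0.0
        for sel, p in bin_idx:
            if p <= 0:
                continue
            mass = pmf[sel].sum()
            if mass <= 0:
                return 1e12
            ll += p * np.log(mass)
        return -ll

    mids = np.array([(blo + bhi) / 2 for blo, bhi, _ in binned.bins])
    props = np.array([p for _, _, p in binned.bins])
    m0 = float((mids * props).sum())
    best = None
    trace = []
    for r0 in (1.0, 5.0, 20.0, 80.0):
        res = optimize.minimize(nll, np.log([r0, max(m0, lo + 1.0)]),
                                method="Nelder-Mead",
                                options={"xatol": 1e-6, "fatol": tol,
                                         "maxiter": 2000})
        trace.append((r0, res.fun, res.x.tolist(), res.success))
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e12:
        raise FitError(f"truncated NB fit did not converge; trace={trace}")
    size, mean = np.exp(best.x)
    boundary = not (1e-3 < size < 1e4)
    pmf = _trunc_nb_pmf(ages, size, mean)
    params = TruncNBParams(float(size), float(mean), lo, hi,
                           loglik=-float(best.fun), boundary=boundary)
    fine = FineAgeDistribution(binned.sex, binned.calendar_year, ages,
                               pmf / pmf.sum())
    return params, fine


def adjust_to_bins(fine: FineAgeDistribution,
                   binned: BinnedAgeTable) -> FineAgeDistribution:
    """Rescale fine masses by one factor per wide bin so bin totals equal
    the reported proportions exactly; the output sums to 1."""
    binned.validate()
    out = fine.copy()
    covered = np.zeros_like(out.masses, dtype=bool)
    for blo, bhi, p in binned.bins:
        sel = (out.ages >= blo) & (out.ages <= bhi)
        covered |= sel
        mass = out.masses[sel].sum()
        if p == 0:
            out.masses[sel] = 0.0
        elif mass <= 0:
            raise ValueError(
                f"fitted mass is zero in bin [{blo},{bhi}] with reported "
                f"proportion {p}")
        else:
            out.masses[sel] *= p / mass
    out.masses[~covered] = 0.0
    out.masses /= out.masses.sum()
    out.validate()
    return out


def age_forward(dist: FineAgeDistribution, years: int) -> FineAgeDistribution:
    """Shift all mass ``years`` older; mass beyond the upper truncation
    accumulates in the top age. Total mass is conserved."""
    if years < 0:
        raise ValueError("years must be >= 0")
    out = dist.copy()
    if years == 0:
        return out
    m = np.zeros_like(out.masses)
    n = len(m)
    for i, mass in enumerate(out.masses):
        j = min(i + years, n - 1)
        m[j] += mass
    out.masses = m
    return out


def subtract_deaths(py: pd.DataFrame, deaths: pd.DataFrame,
                    cohort_cols: tuple[str, ...] = ("sex", "release_year"),
                    time_col: str = "years_since_release",
                    age_col: str = "age",
                    death_time_fraction: float = 0.5) -> pd.DataFrame:
    """Remove decedents' foregone person-time from an age-stratified table.

    A death at (t0, a0) within an aging cohort removes
    ``1 - death_time_fraction`` person-years from its own cell and one full
    person-year from every later cell (t, a0 + (t - t0)) of the same cohort
    present in the table. Cells are floored at zero with a warning.
    """
    out = py.copy()
    if deaths.empty or deaths["deaths"].sum() == 0:
        return out
    idx_cols = list(cohort_cols) + [time_col, age_col]
    cell = {tuple(k): i for i, k in
            enumerate(out[idx_cols].itertuples(index=False, name=None))}
    vals = out["person_years"].to_numpy(dtype=float).copy()
    max_t = int(out[time_col].max())
    for row in deaths.itertuples(index=False):
        d = getattr(row, "deaths")
        if d <= 0:
            continue
        base = tuple(getattr(row, c) for c in cohort_cols)
        t0, a0 = int(getattr(row, time_col)), int(getattr(row, age_col))
        for t in range(t0, max_t + 1):
            key = base + (t, a0 + (t - t0))
            i = cell.get(key)
            if i is None:
                continue
            vals[i] -= d * ((1.0 - death_time_fraction) if t == t0 else 1.0)
    n_floor = int((vals < 0).sum())
    if n_floor:
        warnings.warn(f"subtract_deaths floored {n_floor} cells at 0 "
                      "(deaths exceeded modeled person-time)")
        vals = np.maximum(vals, 0.0)
    out["person_years"] = vals
    return out


def allocate_person_time(pt: pd.DataFrame,
                         dists: dict,
                         year_col: str = "calendar_year",
                         shift_col: str | None = None,
                         keep: tuple[str, ...] = ()) -> pd.DataFrame:
    """Spread unstratified person-time cells over single-year ages.

    ``dists`` maps (sex, year) -> FineAgeDistribution (year None matches
    any). With ``shift_col`` set (years elapsed since cohort formation) the
    distribution is aged forward by that many years first. Cell totals are
    conserved exactly.
    """
    rows = []
    for r in pt.itertuples(index=False):
        sex = getattr(r, "sex")
        year = int(getattr(r, year_col)) if year_col else None
        dist = dists.get((sex, year)) or dists.get((sex, None))
        if dist is None:
            raise KeyError(f"no age distribution for ({sex}, {year})")
        shift = int(getattr(r, shift_col)) if shift_col else 0
        if shift:
            dist = age_forward(dist, shift)
        py = getattr(r, "person_years")
        base = tuple(getattr(r, c) for c in keep)
        for a, m in zip(dist.ages, dist.masses):
            if m > 0:
                rows.append(base + (sex, year, shift, int(a), py * m))
    cols = list(keep) + ["sex", year_col or "calendar_year",
                         shift_col or "shift", "age", "person_years"]
    out = pd.DataFrame(rows, columns=cols)
    if shift_col is None:
        out = out.drop(columns=["shift"])
    return out


def to_standard_bins(age_df: pd.DataFrame, width: int = 4, start: int = 18,
                     top: int = 95, age_col: str = "age",
                     value_col: str = "person_years",
                     group_cols: tuple[str, ...] = ("sex",)) -> pd.DataFrame:
    """Aggregate single-year ages into fixed-width standardization bins
    (default 4-year bins starting at 18; the top bin is open-ended).
    Ages below ``start`` are excluded, mirroring the exclusion of under-18
    records from age-based analyses."""
    df = age_df[age_df[age_col] >= start].copy()
    rel = ((df[age_col] - start) // width).astype(int)
    n_bins = (top - start) // width
    rel = rel.clip(upper=n_bins)
    df["age_bin"] = rel.map(lambda k: start + k * width)
    out = (df.groupby(list(group_cols) + ["age_bin"], as_index=False)
             [value_col].sum())
    return out


def standard_weights(standard_py: pd.DataFrame,
                     group_cols: tuple[str, ...] = ("sex",)) -> pd.DataFrame:
    """Standardization weights (proportions of person-time per age bin)
    from a standard population's binned person-time."""
    out = standard_py.copy()
    tot = out.groupby(list(group_cols))["person_years"].transform("sum")
    out["weight"] = out["person_years"] / tot
    return out[list(group_cols) + ["age_bin", "weight"]]


def non_incarcerated_denominator(projected: pd.DataFrame,
                                 incarcerated: pd.DataFrame,
                                 former_any_release: pd.DataFrame,
                                 on: tuple[str, ...] = ("sex", "age")
                                 ) -> pd.DataFrame:
    """General-population person-time minus custody and ever-released
    person-time, on aligned fine-age tables; negative cells are floored at
    zero with a warning."""
    keys = list(on)

    def agg(df):
        return df.groupby(keys, as_index=False)["person_years"].sum()

    out = agg(projected).rename(columns={"person_years": "py"})
    for name, sub in (("inc", incarcerated), ("fmr", former_any_release)):
        if sub is None or sub.empty:
            continue
        out = out.merge(agg(sub).rename(columns={"person_years": name}),
                        on=keys, how="left")
        out[name] = out[name].fillna(0.0)
        out["py"] = out["py"] - out[name]
    n_neg = int((out["py"] < 0).sum())
    if n_neg:
        warnings.warn(f"non_incarcerated_denominator floored {n_neg} "
                      "negative cells at 0")
        out["py"] = out["py"].clip(lower=0.0)
    return out.rename(columns={"py": "person_years"})[keys + ["person_years"]]
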