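"""ICD-10 underlying-cause mapping to intermediate and broad categories.

The bundled table (``data/cause_map.csv``) maps ICD-10 ranges to the
intermediate categories reported in carceral-mortality work (tuberculosis,
HIV/AIDS, respiratory infections, cardiovascular disease, neoplasms,
transport injuries, interpersonal violence, suicide, drug overdose,
ill-defined, ...) and each intermediate to one broad public-health
category: violence, suicide, communicable, noncommunicable, transport, or
other/unknown. Ranges are matched first-row-first, so specific rows
(tuberculosis) precede their enclosing blocks (all infectious).

Two context rules apply on top of the table:

* deaths of incarcerated men certified as "hanging, strangulation and
  suffocation, undetermined intent" (Y20) are reassigned to interpersonal
  violence (configurable, for sensitivity analysis);
* an absent code, "other ill-defined and unspecified causes" (R99), or
  "unspecified event, undetermined intent" (Y34) is of unknown cause.
"""

from __future__ import annotations

import importlib.resources
import logging
import re
from dataclasses import dataclass
from functools import lru_cache

import pandas as pd

logger = logging.getLogger(__name__)

BROAD_CATEGORIES = ("violence", "suicide", "communicable", "noncommunicable",
                    "transport", "other")

_CODE_RE = re.compile(r"^([A-Z])([0-9]{2})(?:\.?[0-9A-Z]{0,2})$")

UNKNOWN = ("unknown", "other")


class ICD10ParseError(ValueError):
    pass


@dataclass(frozen=True)
class CauseAssignment:
    intermediate: str
    broad: str


def _code_key(code: str) -> tuple[str, int]:
    m = _CODE_RE.match(code.strip().upper())
    if not m:
        raise ICD10ParseError(f"malformed ICD-10 code: {code!r}")
    return m.group(1), int(m.group(2))


def load_cause_map(path=None) -> pd.DataFrame:
    """Load the range -> category table (bundled by default)."""
    if path is None:
        ref = importlib.resources.files("carcmort.data") / "cause_map.csv"
        with importlib.resources.as_file(ref) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    bad = set(df["broad"]) - set(BROAD_CATEGORIES)
    if bad:
        raise ValueError(f"unknown broad categories in cause map: {bad}")
    return df


@lru_cache(maxsize=1)
def _default_map_rows() -> tuple:
    df = load_cause_map()
    return tuple((_code_key(lo), _code_key(hi), im, br) for lo, hi, im, br in
                 zip(df["icd_low"], df["icd_high"], df["intermediate"],
                     df["broad"]))


def map_icd10(code: str | None, in_custody: bool = False,
              sex: str = "unknown", cause_map: pd.DataFrame | None = None,
              custody_hanging_rule: bool = True) -> CauseAssignment:
    """Assign one intermediate and one broad category to a death.

    ``code`` may be None/empty (unknown cause). Malformed codes raise
    :class:`ICD10ParseError`. Codes outside every listed range fall into an
    ``unclassified``/other bucket and are logged.
    """
    if code is None or (isinstance(code, float) and pd.isna(code)) \
            or str(code).strip() == "":
        return CauseAssignment(*UNKNOWN)
    key = _code_key(str(code))
    if key == ("R", 99) or key == ("Y", 34):
        return CauseAssignment(*UNKNOWN)
    if key == ("Y", 20) and custody_hanging_rule and in_custody \
            and sex == "male":
        return CauseAssignment("interpersonal_violence", "violence")
    if cause_map is None:
        rows = _default_map_rows()
    else:
        rows = tuple((_code_key(lo), _code_key(hi), im, br) for lo, hi, im, br
                     in zip(cause_map["icd_low"], cause_map["icd_high"],
                            cause_map["intermediate"], cause_map["broad"]))
    for lo, hi, im, br in rows:
        if lo <= key <= hi:
            return CauseAssignment(im, br)
    logger.info("ICD-10 code %s outside all mapped ranges; using "
                "unclassified/other", code)
    return CauseAssignment("unclassified", "other")


def classify_deaths(registry: pd.DataFrame,
                    in_custody: pd.Series | None = None,
                    cause_map: pd.DataFrame | None = None,
                    custody_hanging_rule: bool = True) -> pd.DataFrame:
    """Vectorized classification of a mortality-registry table.

    ``in_custody`` is a boolean series aligned with ``registry`` (False when
    absent). Adds ``intermediate_cause`` and ``broad_cause`` columns.
    """
    out = registry.copy()
    flags = (in_custody.reindex(out.index).fillna(False)
             if in_custody is not None
             else pd.Series(False, index=out.index))
    inter, broad = [], []
    for code, sex, ic in zip(out["icd10_code"], out["sex"], flags):
        a = map_icd10(code, in_custody=bool(ic), sex=sex,
                      cause_map=cause_map,
                      custody_hanging_rule=custody_hanging_rule)
        inter.append(a.intermediate)
        broad.append(a.broad)
    out["intermediate_cause"] = inter
    out["broad_cause"] = broad
    return out


def tabulate_causes(assignments: pd.DataFrame,
                    strata: tuple[str, ...] = (),
                    cause_col: str = "broad_cause") -> pd.DataFrame:
    """Death counts and within-stratum proportions by cause."""
    cols = list(strata) + [cause_col]
    counts = assignments.groupby(cols, dropna=False).size().rename("deaths")
    out = counts.reset_index()
    if strata:
        tot = out.groupby(list(strata))["deaths"].transform("sum")
    else:
        tot = out["deaths"].sum()
    out["proportion"] = out["deaths"] / tot
    return out
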