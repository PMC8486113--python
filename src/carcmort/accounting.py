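"""Headline accounting: under-reporting ratios, shares, and identities.

Pure arithmetic over a manifest of counts, so the same functions serve a
synthetic pipeline run and a desk check against published tallies.
Division by zero yields None (flagged absent), never an exception.
"""

from __future__ import annotations


def _ratio(num, den):
    if num is None or den in (None, 0):
        return None
    return num / den


def report_accounting(manifest: dict) -> dict:
    """Summary ratios and shares from a run manifest.

    Recognized keys (all optional; absent inputs yield absent outputs):

    * ``registry_total_deaths`` — all mortality-registry rows considered;
    * ``linked_deaths_total``, ``custody_deaths``, ``post_release_deaths``;
    * ``custody_deaths_by_facility`` — mapping facility -> count;
    * ``external_reported_custody_deaths`` — mapping source -> count
      (e.g. the national prison administration's published tally);
    * ``movement_log_death_events``, ``movement_log_deaths_unmatched``;
    * ``custody_person_years`` — mapping facility -> person-years.
    """
    out: dict = {}
    custody = manifest.get("custody_deaths")

    ext = manifest.get("external_reported_custody_deaths") or {}
    out["underreporting_ratios"] = {
        src: _ratio(custody, n) for src, n in ext.items()}

    byfac = manifest.get("custody_deaths_by_facility") or {}
    tot_fac = sum(byfac.values()) if byfac else None
    out["facility_shares_pct"] = {
        fac: (100.0 * n / tot_fac if tot_fac else None)
        for fac, n in byfac.items()}

    reg = manifest.get("registry_total_deaths")
    out["linked_fraction_pct"] = {
        "total": _n100(manifest.get("linked_deaths_total"), reg),
        "in_custody": _n100(custody, reg),
        "post_release": _n100(manifest.get("post_release_deaths"), reg),
    }

    out["unmatched_movement_death_share_pct"] = _n100(
        manifest.get("movement_log_deaths_unmatched"),
        manifest.get("movement_log_death_events"))

    py = manifest.get("custody_person_years") or {}
    out["custody_person_years_total"] = sum(py.values()) if py else None
    out["custody_person_years_components"] = dict(py)
    return out


def _n100(num, den):
    r = _ratio(num, den)
    return None if r is None else 100.0 * r
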