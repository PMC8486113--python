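"""End-to-end orchestration: simulate/load registries, resolve identities,
link deaths, build exposure, estimate rates, hazards and survival.

Every stage writes its table to the output directory; a run manifest
records row counts at each filter step, the death-partition tallies, and
the configuration hash, so the run's accounting identities can be checked
from the manifest alone.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
import logging
import pathlib

import numpy as np
import pandas as pd

from . import __version__
from .accounting import report_accounting
from .age_structure import (BinnedAgeTable, allocate_person_time,
                            adjust_to_bins, fit_truncated_negbin,
                            non_incarcerated_denominator, standard_weights,
                            subtract_deaths, to_standard_bins)
from .cause_of_death import classify_deaths
from .config import AnalysisConfig, SyntheticConfig, CUSTODY_STATES
from .exposure_intervals import (assemble_person_events, build_episodes,
                                 drop_conflicting_deaths,
                                 tabulate_person_time, truncate_overlong)
from .hazard_survival import (ReducedCohortSpec, build_reduced_cohort,
                              km_estimate, log_rank, smooth_hazard)
from .identity_resolution import (deduplicate_movements, evaluate_linkage,
                                  filter_posthumous_activity, link_deaths)
from .rates import irr_exact, standardized_irr_for_group
from .synthetic_registry import generate_cohort, write_cohort

logger = logging.getLogger(__name__)

VIOLENT_SET = ("violence", "suicide")


def _age_bins_frame(df, bin_start, bin_width, top=95):
    """Deaths with a known adult age -> counts per standardization bin."""
    ages = pd.to_numeric(df["age_at_death"], errors="coerce")
    known = df[ages.notna()].copy()
    known["age"] = ages[ages.notna()].astype(int)
    known = known[known["age"] >= bin_start]
    n_bins = (top - bin_start) // bin_width
    rel = ((known["age"] - bin_start) // bin_width).clip(upper=n_bins)
    known["age_bin"] = bin_start + rel * bin_width
    return known


def run_pipeline(syn_config: SyntheticConfig | None = None,
                 analysis: AnalysisConfig | None = None,
                 out_dir=None, seed: int | None = None,
                 tables: dict | None = None) -> dict:
    """Run the full analysis and return a results dict.

    Either ``syn_config`` (generate registries) or ``tables`` (user-supplied
    DataFrames: movement_log, mortality_registry, binned_age,
    projected_population, optionally truth) must be given. Writes CSVs and
    ``manifest.json`` to ``out_dir`` when set.
    """
    analysis = analysis or AnalysisConfig()
    analysis.validate()
    truth = None
    if tables is None:
        if syn_config is None:
            raise ValueError("need syn_config or tables")
        if seed is not None:
            syn_config.seed = seed
        cohort = generate_cohort(syn_config)
        log, registry = cohort.movement_log, cohort.mortality_registry
        binned_age, projected = cohort.binned_age, cohort.projected_population
        truth = cohort.truth
        window = syn_config.study_window
    else:
        log = tables["movement_log"]
        registry = tables["mortality_registry"]
        binned_age = tables["binned_age"]
        projected = tables["projected_population"]
        truth = tables.get("truth")
        window = tables.get("study_window",
                            (dt.date(2009, 1, 1), dt.date(2018, 12, 31)))
        cohort = None

    manifest: dict = {
        "software_version": __version__,
        "seed": getattr(syn_config, "seed", None) if syn_config else seed,
        "config_hash": hashlib.sha256(
            json.dumps(syn_config.to_dict() if syn_config else {},
                       sort_keys=True).encode()).hexdigest()[:16],
        "counts": {"movement_rows": int(len(log)),
                   "registry_rows": int(len(registry))},
    }
    counts = manifest["counts"]

    # --- identity resolution & linkage ----------------------------------
    clusters = deduplicate_movements(
        log, name_threshold=analysis.dedup_name_threshold,
        mother_threshold=analysis.dedup_mother_threshold,
        length_exponent=analysis.length_weight_exponent)
    counts["person_clusters"] = int(len(clusters))
    matches = link_deaths(clusters, registry,
                          threshold=analysis.link_threshold,
                          include_uncertain=analysis.include_uncertain,
                          length_exponent=analysis.length_weight_exponent)
    counts["match_candidates"] = int(len(matches))
    n_acc_raw = int((matches["status"] == "accepted").sum())
    matches = filter_posthumous_activity(matches, clusters, registry)
    counts["matches_rejected_posthumous_activity"] = (
        n_acc_raw - int((matches["status"] == "accepted").sum()))
    counts["matches_accepted"] = int((matches["status"] == "accepted").sum())
    counts["matches_uncertain"] = int((matches["status"] == "uncertain").sum())
    linkage_report = {"threshold": analysis.link_threshold,
                      "include_uncertain": analysis.include_uncertain,
                      "accepted": counts["matches_accepted"],
                      "uncertain": counts["matches_uncertain"]}
    if truth is not None:
        vm = evaluate_linkage(matches, clusters, truth,
                              analysis.link_threshold)
        linkage_report.update(sensitivity=vm.sensitivity,
                              specificity=vm.specificity, ppv=vm.ppv,
                              undefined=vm.undefined)

    # --- exposure episodes ----------------------------------------------
    events = assemble_person_events(clusters, log, matches, registry)
    events, n_conflict = drop_conflicting_deaths(events)
    counts["conflicting_death_events_dropped"] = n_conflict
    episodes = build_episodes(events, window)
    episodes = truncate_overlong(episodes, analysis.truncation_caps)
    counts["episodes"] = int(len(episodes))
    sex_map = dict(zip(clusters["person_uid"], clusters["sex"]))

    pt_cust = tabulate_person_time(
        episodes[episodes["location"].isin(CUSTODY_STATES)],
        ("sex", "location", "calendar_year"), sex_map)
    pt_post = tabulate_person_time(
        episodes[episodes["location"] == "post_release"],
        ("sex", "release_year", "years_since_release"), sex_map)
    manifest["custody_person_years"] = {
        loc: float(v) for loc, v in
        pt_cust.groupby("location")["person_years"].sum().items()}
    manifest["post_release_person_years"] = float(
        pt_post["person_years"].sum())

    # ever-released community time (releases from any facility type), for
    # the non-incarcerated denominator subtraction
    episodes_any = build_episodes(events, window,
                                  post_release_from=CUSTODY_STATES)
    episodes_any = truncate_overlong(episodes_any, analysis.truncation_caps)
    pt_post_any = tabulate_person_time(
        episodes_any[episodes_any["location"] == "post_release"],
        ("sex", "release_year", "years_since_release"), sex_map)

    # --- death partition -------------------------------------------------
    acc = matches[matches["status"] == "accepted"]
    person_of_death = dict(zip(acc["death_row_id"], acc["person_uid"]))
    death_eps = episodes[episodes["end_reason"] == "death"]
    loc_at_death = dict(zip(death_eps["person_uid"], death_eps["location"]))
    rel_info = {uid: (rd, ys) for uid, rd, ys in zip(
        death_eps["person_uid"], death_eps["release_date"],
        death_eps["start"])}

    registry = registry.copy()
    registry["person_uid"] = registry["row_id"].map(person_of_death)
    registry["location_at_death"] = registry["person_uid"].map(loc_at_death)
    linked = registry["person_uid"].notna()
    in_custody = registry["location_at_death"].isin(CUSTODY_STATES)
    classified = classify_deaths(registry, in_custody=in_custody)

    counts["linked_deaths_total"] = int(linked.sum())
    counts["custody_deaths"] = int((linked & in_custody).sum())
    counts["post_release_deaths"] = int(
        (registry["location_at_death"] == "post_release").sum())
    counts["other_community_deaths_linked"] = (
        counts["linked_deaths_total"] - counts["custody_deaths"]
        - counts["post_release_deaths"])
    counts["unlinked_registry_deaths"] = int((~linked).sum())
    counts["custody_deaths_by_facility"] = {
        f: int((registry["location_at_death"] == f).sum())
        for f in CUSTODY_STATES}

    # movement-log deaths with no registry match: all-cause hazard only
    mv_death_rows = log[log["event_type"] == "death"]
    death_cluster_uids = set()
    row_to_cluster = {}
    for cuid, mids in zip(clusters["person_uid"], clusters["member_row_ids"]):
        for rid in mids.split(";"):
            row_to_cluster[rid] = cuid
    for rid in mv_death_rows["row_id"]:
        death_cluster_uids.add(row_to_cluster.get(rid))
    linked_uids = set(acc["person_uid"])
    counts["movement_log_death_events"] = int(len(mv_death_rows))
    counts["movement_log_deaths_unmatched"] = int(
        len(death_cluster_uids - linked_uids - {None}))

    manifest["external_reported_custody_deaths"] = {
        "movement_log": counts["movement_log_death_events"]}

    # --- age structure ---------------------------------------------------
    dists = {}
    fit_params = {}
    for sex in ("male", "female"):
        # pooled per-sex fit as fallback for sparse years
        sub = binned_age[binned_age["sex"] == sex]
        pooled = (sub.groupby(["age_lo", "age_hi"], as_index=False)
                  ["proportion"].mean())
        pooled["proportion"] /= pooled["proportion"].sum()
        pooled["sex"] = sex
        bt0 = BinnedAgeTable.from_frame(pooled, sex)
        params, fine0 = fit_truncated_negbin(bt0, analysis.age_fit_bounds)
        fine0 = adjust_to_bins(fine0, bt0)
        fit_params[sex] = params
        dists[(sex, None)] = fine0
        # annual fits where the published table supports them
        for y in range(window[0].year, window[1].year + 1):
            try:
                bt = BinnedAgeTable.from_frame(binned_age, sex, y)
                _, fine = fit_truncated_negbin(bt, analysis.age_fit_bounds)
                dists[(sex, y)] = adjust_to_bins(fine, bt)
            except Exception:
                dists[(sex, y)] = fine0
    manifest["age_fit"] = {s: {"size": p.size, "mean": p.mean,
                               "boundary": p.boundary}
                           for s, p in fit_params.items()}

    cust_age = allocate_person_time(pt_cust, dists, "calendar_year",
                                    keep=("location",))
    post_age = allocate_person_time(pt_post, dists, "release_year",
                                    shift_col="years_since_release")
    post_any_age = allocate_person_time(pt_post_any, dists, "release_year",
                                        shift_col="years_since_release")

    # modeled release-cohort sizes (persons), for the death-depletion
    # adjustment: ages are depleted in person units, then each cell's
    # observed person-time is re-spread over the adjusted age profile
    pr_only = episodes[episodes["location"] == "post_release"].copy()
    pr_only["release_year"] = pr_only["release_date"].str[:4].astype(int)
    pr_only["sex"] = pr_only["person_uid"].map(sex_map)
    cohort_n = (pr_only.groupby(["sex", "release_year"])["person_uid"]
                .nunique().rename("n").reset_index())
    post_persons = pt_post.merge(cohort_n, on=["sex", "release_year"],
                                 how="left")
    post_persons["person_years"] = post_persons["n"].fillna(0.0)
    post_model = allocate_person_time(
        post_persons.drop(columns=["n"]), dists, "release_year",
        shift_col="years_since_release")

    # death-depletion adjustment of the post-release age structure
    pr_deaths = classified[classified["location_at_death"] == "post_release"]
    ages = pd.to_numeric(pr_deaths["age_at_death"], errors="coerce")
    pr_d = pr_deaths[ages.notna()].copy()
    pr_d["age"] = ages[ages.notna()].astype(int)
    rel = pr_d["person_uid"].map(rel_info)
    pr_d["release_year"] = rel.map(
        lambda t: int(t[0][:4]) if isinstance(t, tuple) and t[0] else -1)
    pr_d["death_date_d"] = pd.to_datetime(pr_d["death_date"])
    rel_date = rel.map(lambda t: t[0] if isinstance(t, tuple) else "")
    ysr = ((pr_d["death_date_d"] - pd.to_datetime(rel_date.replace("", None)))
           .dt.days / 365.25)
    pr_d["years_since_release"] = ysr.fillna(0).astype(int)
    death_tab = (pr_d.groupby(["sex", "release_year",
                               "years_since_release", "age"])
                 .size().rename("deaths").reset_index())
    import warnings as _warnings
    with _warnings.catch_warnings(record=True) as caught:
        _warnings.simplefilter("always")
        adj_model = subtract_deaths(post_model, death_tab)
    manifest["depletion_floor_warnings"] = [str(w.message) for w in caught]
    # re-spread each cell's observed person-time over the depleted profile
    key = ["sex", "release_year", "years_since_release"]
    post_adj = adj_model.copy()
    obs = pt_post.set_index(key)["person_years"]
    tot1 = post_adj.groupby(key)["person_years"].transform("sum")
    cell_obs = post_adj.set_index(key).index.map(obs).to_numpy(dtype=float)
    scale = np.where(tot1 > 0, np.nan_to_num(cell_obs) /
                     np.where(tot1 > 0, tot1, 1.0), 0.0)
    post_adj["person_years"] = post_adj["person_years"] * scale

    # non-incarcerated denominator: projection fine ages minus custody and
    # ever-released person-time
    proj_fine = []
    for sexv in ("male", "female"):
        for y in range(window[0].year, window[1].year + 1):
            sub = projected[(projected["sex"] == sexv)
                            & (projected["year"] == y)
                            & (projected["age_lo"]
                               >= analysis.age_fit_bounds[0])]
            if sub.empty:
                continue
            bt = BinnedAgeTable.from_frame(sub, sexv, y)
            try:
                _, fine = fit_truncated_negbin(bt, analysis.age_fit_bounds)
                fine = adjust_to_bins(fine, bt)
            except Exception:
                fine = dists[(sexv, None)]
            tot = sub["person_years"].sum()
            for a, m in zip(fine.ages, fine.masses):
                if m > 0:
                    proj_fine.append((sexv, int(a), tot * m))
    proj_fine = pd.DataFrame(proj_fine, columns=["sex", "age",
                                                 "person_years"])
    noninc_age = non_incarcerated_denominator(proj_fine, cust_age,
                                              post_any_age)

    # --- rates -----------------------------------------------------------
    bs, bw = analysis.standard_bin_start, analysis.standard_bin_width
    cust_bins = to_standard_bins(cust_age, bw, bs,
                                 group_cols=("sex", "location"))
    post_bins = to_standard_bins(post_adj, bw, bs, group_cols=("sex",))
    noninc_bins = to_standard_bins(noninc_age, bw, bs, group_cols=("sex",))
    std_py = to_standard_bins(cust_age, bw, bs, group_cols=("sex",))
    weights = standard_weights(std_py)

    d_known = _age_bins_frame(classified, bs, bw)
    counts["deaths_missing_age"] = int(
        pd.to_numeric(classified["age_at_death"], errors="coerce").isna()
        .sum())

    def deaths_for(mask, sexv):
        sub = d_known[mask & (d_known["sex"] == sexv)]
        return (sub.groupby("age_bin").size().rename("deaths")
                .reset_index())

    results_rates = []
    irr_summaries = {}
    for sexv in ("male", "female"):
        w = weights[weights["sex"] == sexv]
        wmap = dict(zip(w["age_bin"], w["weight"]))
        ref_py = noninc_bins[noninc_bins["sex"] == sexv][
            ["age_bin", "person_years"]]
        ref_d = deaths_for(d_known["person_uid"].isna(), sexv)
        groups = {}
        if sexv == "male":
            for fac in ("closed", "semi_open", "police"):
                groups[fac] = (
                    deaths_for(d_known["location_at_death"] == fac, sexv),
                    cust_bins[(cust_bins["sex"] == sexv)
                              & (cust_bins["location"] == fac)]
                    [["age_bin", "person_years"]])
        else:
            cust_all = (cust_bins[cust_bins["sex"] == sexv]
                        .groupby("age_bin", as_index=False)
                        ["person_years"].sum())
            groups["incarcerated"] = (
                deaths_for(d_known["location_at_death"]
                           .isin(CUSTODY_STATES), sexv), cust_all)
        groups["post_release"] = (
            deaths_for(d_known["location_at_death"] == "post_release", sexv),
            post_bins[post_bins["sex"] == sexv]
            [["age_bin", "person_years"]])
        for gname, (gd, gpy) in groups.items():
            if gd["deaths"].sum() == 0 or gpy["person_years"].sum() <= 0:
                continue
            try:
                a1, a0, rr = standardized_irr_for_group(
                    gd, gpy, ref_d, ref_py, wmap)
            except ValueError as e:
                logger.warning("skipping %s/%s: %s", sexv, gname, e)
                continue
            results_rates.append({
                "sex": sexv, "group": gname,
                "deaths": int(gd["deaths"].sum()),
                "person_years": float(gpy["person_years"].sum()),
                "asr_per_100k": a1.rate_per_100k,
                "asr_ci_low": a1.ci_low, "asr_ci_high": a1.ci_high,
                "ref_asr_per_100k": a0.rate_per_100k,
                "irr": rr.irr, "irr_ci_low": rr.ci_low,
                "irr_ci_high": rr.ci_high, "method": rr.method})
            irr_summaries[f"{sexv}_{gname}"] = (rr.irr, rr.ci_low,
                                               rr.ci_high)

    # youth detention: crude rates without age structure, vs boys 14-19
    yd = int((registry["location_at_death"] == "youth").sum())
    y_py = manifest["custody_person_years"].get("youth", 0.0)
    boys = noninc_age[(noninc_age["sex"] == "male")
                      & (noninc_age["age"].between(14, 19))]
    ages_all = pd.to_numeric(classified["age_at_death"], errors="coerce")
    boys_d = int(((classified["person_uid"].isna())
                  & (classified["sex"] == "male")
                  & ages_all.between(14, 19)).sum())
    if yd > 0 and y_py > 0 and boys_d > 0 and len(boys):
        rr = irr_exact(yd, y_py, boys_d, boys["person_years"].sum(),
                       reference="non-incarcerated boys 14-19")
        results_rates.append({
            "sex": "male", "group": "youth_crude", "deaths": yd,
            "person_years": y_py,
            "asr_per_100k": yd / y_py * 1e5,
            "asr_ci_low": np.nan, "asr_ci_high": np.nan,
            "ref_asr_per_100k": boys_d / boys["person_years"].sum() * 1e5,
            "irr": rr.irr, "irr_ci_low": rr.ci_low,
            "irr_ci_high": rr.ci_high, "method": rr.method})
        irr_summaries["male_youth_crude"] = (rr.irr, rr.ci_low, rr.ci_high)

    rates_df = pd.DataFrame(results_rates)

    # --- post-release hazard curves --------------------------------------
    cause_of_person = dict(zip(classified["person_uid"],
                               classified["broad_cause"]))
    pr_eps = episodes[(episodes["location"] == "post_release")]
    pr_eps = pr_eps[pr_eps["person_uid"].map(sex_map).eq("male")]
    dur = ((pd.to_datetime(pr_eps["end"]) - pd.to_datetime(pr_eps["start"]))
           .dt.days / 365.25).to_numpy()
    died = (pr_eps["end_reason"] == "death").to_numpy()
    cause = pr_eps["person_uid"].map(cause_of_person).fillna("").to_numpy()
    ok = dur > 0
    hazard_curves = {}
    for cs, evmask in (("all", died),
                       ("violence_suicide", died & np.isin(cause,
                                                           VIOLENT_SET)),
                       ("other", died & ~np.isin(cause, VIOLENT_SET))):
        try:
            hazard_curves[cs] = smooth_hazard(dur[ok], evmask[ok], cs,
                                              df=analysis.hazard_df)
        except ValueError as e:
            logger.warning("hazard %s skipped: %s", cs, e)

    # --- reduced cohort survival -----------------------------------------
    rc = build_reduced_cohort(
        episodes, window[1],
        ReducedCohortSpec(analysis.reduced_cohort_followup_years,
                          analysis.reduced_cohort_followup_years),
        person_cause=cause_of_person, person_sex=sex_map, sex="male")
    counts["reduced_cohort"] = int(len(rc))
    survival = {}
    if len(rc) and rc["incarceration_stratum"].nunique() >= 2:
        viol_event = rc["event"] & rc["broad_cause"].isin(VIOLENT_SET)
        if viol_event.sum() > 0:
            try:
                lr = log_rank(rc["incarceration_stratum"],
                              rc["duration_years"], viol_event)
                survival["logrank_violent"] = {
                    "statistic": lr.statistic, "df": lr.df,
                    "p_value": lr.p_value}
            except ValueError:
                pass
        km_tabs = []
        for s, grp in rc.groupby("incarceration_stratum"):
            ev = grp["event"] & grp["broad_cause"].isin(VIOLENT_SET)
            km = km_estimate(grp["duration_years"], ev)
            km_tabs.append(pd.DataFrame({
                "stratum": s, "time": km.times, "survival": km.survival,
                "at_risk": km.at_risk}))
        survival["km"] = pd.concat(km_tabs, ignore_index=True) \
            if km_tabs else pd.DataFrame()

    manifest.update(
        registry_total_deaths=counts["registry_rows"],
        linked_deaths_total=counts["linked_deaths_total"],
        custody_deaths=counts["custody_deaths"],
        post_release_deaths=counts["post_release_deaths"],
        custody_deaths_by_facility=counts["custody_deaths_by_facility"],
        movement_log_death_events=counts["movement_log_death_events"],
        movement_log_deaths_unmatched=counts["movement_log_deaths_unmatched"],
    )
    accounting = report_accounting(manifest)

    results = {"manifest": manifest, "linkage": linkage_report,
               "clusters": clusters, "matches": matches,
               "episodes": episodes, "classified_deaths": classified,
               "person_time_custody": pt_cust,
               "person_time_post_release": pt_post,
               "age_py_custody": cust_age, "age_py_post_release": post_adj,
               "age_py_non_incarcerated": noninc_age,
               "rates": rates_df, "irr": irr_summaries,
               "hazard": hazard_curves, "survival": survival,
               "accounting": accounting, "truth": truth}
    if cohort is not None:
        results["cohort"] = cohort

    if out_dir is not None:
        _write_outputs(results, pathlib.Path(out_dir), cohort)
    return results


def _write_outputs(results, out: pathlib.Path, cohort) -> None:
    out.mkdir(parents=True, exist_ok=True)
    if cohort is not None:
        write_cohort(cohort, out / "synthetic")
    results["clusters"].to_csv(out / "clusters.csv", index=False)
    results["matches"].to_csv(out / "matches.csv", index=False)
    results["episodes"].to_csv(out / "episodes.csv", index=False)
    results["classified_deaths"].to_csv(out / "deaths_classified.csv",
                                        index=False)
    results["person_time_custody"].to_csv(out / "person_time.csv",
                                          index=False)
    results["age_py_custody"].to_csv(out / "age_stratified_py.csv",
                                     index=False)
    if len(results["rates"]):
        results["rates"].to_csv(out / "rates.csv", index=False)
    hz = []
    for cs, hc in results["hazard"].items():
        hz.append(pd.DataFrame({"cause_set": cs, "time": hc.time_grid,
                                "hazard": hc.hazard,
                                "band_low": hc.band_low,
                                "band_high": hc.band_high}))
    if hz:
        pd.concat(hz, ignore_index=True).to_csv(out / "hazard_curves.csv",
                                                index=False)
    km = results["survival"].get("km")
    if km is not None and len(km):
        km.to_csv(out / "km_curves.csv", index=False)
    if "logrank_violent" in results["survival"]:
        (out / "logrank.json").write_text(
            json.dumps(results["survival"]["logrank_violent"], indent=2))
    (out / "linkage_report.json").write_text(
        json.dumps(results["linkage"], indent=2))
    (out / "manifest.json").write_text(
        json.dumps(results["manifest"], indent=2, default=float))
    (out / "accounting.json").write_text(
        json.dumps(results["accounting"], indent=2, default=float))
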