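"""Within-registry deduplication and cross-registry fuzzy linkage.

Two decision trees resolve unique individuals in the movement log:

* same internal ID, multiple name spellings — merged when names are highly
  similar (or moderately similar with agreeing mother's names);
* same or similar name, different internal IDs — merged only when mother's
  names also agree; a missing mother's name routes the pair to the
  uncertain branch (no merge).

Linkage then matches each mortality-registry row to at most one resolved
person by a combined name + mother's-name similarity, with a validated
acceptance threshold. All similarities use Levenshtein distance normalized
by the longer string and down-weighted by relative length difference.
"""

from __future__ import annotations

import itertools
import unicodedata
from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd

__all__ = [
    "name_similarity", "deduplicate_movements", "link_deaths",
    "evaluate_linkage", "select_threshold", "ValidationMetrics",
]


def normalize_name(s: str) -> str:
    """ASCII-fold, uppercase, collapse whitespace."""
    if not isinstance(s, str):
        return ""
    s = unicodedata.normalize("NFKD", s)
    s = "".join(c for c in s if not unicodedata.combining(c))
    return " ".join(s.upper().split())


def name_similarity(a: str, b: str, length_exponent: float = 0.5) -> float:
    """Levenshtein similarity in [0,1], weighted by length difference.

    ``(1 - d(a,b)/max(|a|,|b|)) * (min(|a|,|b|)/max(|a|,|b|))**length_exponent``;
    0.0 when either string is empty, 1.0 for identical non-empty strings.
    Symmetric by construction.
    """
    if not a or not b:
        return 0.0
    if a == b:
        return 1.0
    la, lb = len(a), len(b)
    mx, mn = max(la, lb), min(la, lb)
    d = edlib.align(a, b, task="distance")["editDistance"]
    base = 1.0 - d / mx
    return base * (mn / mx) ** length_exponent


def _sim_floored(a: str, b: str, length_exponent: float, floor: float) -> float:
    """`name_similarity`, short-circuited to 0.0 once the result provably
    falls below ``floor`` (length-ratio bound, then banded edit distance)."""
    if not a or not b:
        return 0.0
    if a == b:
        return 1.0
    la, lb = len(a), len(b)
    mx, mn = (la, lb) if la >= lb else (lb, la)
    lw = (mn / mx) ** length_exponent
    if lw < floor:  # similarity <= length weight
        return 0.0
    kmax = int(mx * (1.0 - floor / lw)) + 1
    d = edlib.align(a, b, task="distance", k=kmax)["editDistance"]
    if d < 0:
        return 0.0
    s = (1.0 - d / mx) * lw
    return s if s >= floor else 0.0


# -- blocking ---------------------------------------------------------------

_VOWELS = set("AEIOU")


def _token_key(tok: str) -> str:
    """Crude phonetic key: first letter + consonant skeleton, H dropped."""
    if not tok:
        return ""
    head = tok[0]
    rest = "".join(c for c in tok[1:] if c not in _VOWELS and c != "H")
    return (head + rest)[:5]


def _blocking_keys(name: str) -> set[str]:
    return {_token_key(t) for t in name.split() if len(t) > 2}


def _candidate_pairs(names_a: list[str], names_b: list[str] | None = None):
    """Index pairs sharing at least one token blocking key.

    With ``names_b`` None, pairs within one list; otherwise cross pairs
    (i in a, j in b).
    """
    index: dict[str, list[int]] = {}
    for i, nm in enumerate(names_a):
        for k in _blocking_keys(nm):
            index.setdefault(k, []).append(i)
    pairs = set()
    if names_b is None:
        for members in index.values():
            if len(members) > 1:
                for i, j in itertools.combinations(members, 2):
                    pairs.add((i, j))
        return pairs
    for j, nm in enumerate(names_b):
        seen = set()
        for k in _blocking_keys(nm):
            for i in index.get(k, ()):
                if i not in seen:
                    seen.add(i)
                    pairs.add((i, j))
    return pairs


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def _mode(values) -> str:
    from collections import Counter

    vals = [v for v in values if v]
    if not vals:
        return ""
    best = max(Counter(vals).items(), key=lambda kv: (kv[1], kv[0]))
    return best[0]


def deduplicate_movements(log: pd.DataFrame,
                          name_threshold: float = 0.90,
                          mother_threshold: float = 0.85,
                          length_exponent: float = 0.5,
                          use_blocking: bool = True) -> pd.DataFrame:
    """Resolve unique individuals in the movement log.

    Returns one row per person cluster with columns ``person_uid``,
    ``member_row_ids`` (semicolon-joined), ``canonical_name``,
    ``canonical_mother_name``, ``sex``, ``last_event_date``. Clusters
    partition the input rows.
    """
    if len(log) == 0:
        raise ValueError("movement log is empty")
    log = log.reset_index(drop=True)
    names = [normalize_name(n) for n in log["name"]]
    mothers = [normalize_name(m) for m in log["mother_name"].fillna("")]

    uf = _UnionFind(len(log))

    # tree A: same internal ID, possibly different name spellings
    for _, idx in log.groupby("internal_id").indices.items():
        idx = list(idx)
        if len(idx) < 2:
            continue
        # compare each row against the first occurrence of each distinct name
        reps: list[int] = []
        for i in idx:
            merged = False
            for r in reps:
                ns = _sim_floored(names[i], names[r], length_exponent, 0.6)
                if ns >= name_threshold:
                    uf.union(r, i)
                    merged = True
                    break
                ms = (_sim_floored(mothers[i], mothers[r], length_exponent,
                                   mother_threshold)
                      if mothers[i] and mothers[r] else 0.0)
                if ns >= 0.6 and ms >= mother_threshold:
                    uf.union(r, i)
                    merged = True
                    break
            if not merged:
                reps.append(i)

    # tree B: similar names under different internal IDs; requires the
    # mother's name to agree, else the pair stays unmerged (uncertain branch)
    members_of: dict[int, list[int]] = {}
    for i in range(len(log)):
        members_of.setdefault(uf.find(i), []).append(i)
    rgis = list(log["internal_id"])
    root_list = sorted(members_of)
    root_name, root_mother, root_rgi = {}, {}, {}
    for r in root_list:
        mem = members_of[r]
        root_name[r] = _mode([names[i] for i in mem])
        root_mother[r] = _mode([mothers[i] for i in mem])
        root_rgi[r] = {rgis[i] for i in mem}
    rl_names = [root_name[r] for r in root_list]
    if use_blocking:
        pairs = _candidate_pairs(rl_names)
    else:
        pairs = set(itertools.combinations(range(len(root_list)), 2))
    for i, j in pairs:
        ri, rj = root_list[i], root_list[j]
        if root_rgi[ri] & root_rgi[rj]:
            continue  # handled by tree A
        ns = _sim_floored(rl_names[i], rl_names[j], length_exponent,
                          name_threshold)
        if ns < name_threshold:
            continue
        mi, mj = root_mother[ri], root_mother[rj]
        if not mi or not mj:
            continue  # uncertain branch: never merge without mother's name
        if _sim_floored(mi, mj, length_exponent,
                        mother_threshold) >= mother_threshold:
            uf.union(ri, rj)

    clusters = {}
    for i in range(len(log)):
        clusters.setdefault(uf.find(i), []).append(i)
    rows = []
    row_ids = list(log["row_id"])
    dates = list(log["event_date"])
    sexes = list(log["sex"]) if "sex" in log.columns else None
    for k, (_, mem) in enumerate(sorted(clusters.items())):
        rows.append({
            "person_uid": f"C{k + 1:07d}",
            "member_row_ids": ";".join(row_ids[i] for i in mem),
            "canonical_name": _mode([names[i] for i in mem]),
            "canonical_mother_name": _mode([mothers[i] for i in mem]),
            "sex": _mode([sexes[i] for i in mem]) if sexes else "unknown",
            "last_event_date": max(dates[i] for i in mem),
        })
    return pd.DataFrame(rows)


def link_deaths(clusters: pd.DataFrame, registry: pd.DataFrame,
                threshold: float = 0.90,
                include_uncertain: bool = False,
                length_exponent: float = 0.5,
                use_blocking: bool = True) -> pd.DataFrame:
    """Match mortality-registry rows to resolved persons.

    At most one person per death row (best combined score). The combined
    score is the mean of name and mother similarity when both sides carry a
    mother's name, else the name similarity alone. A best match whose
    mother's name is missing on either side and whose perfect name score is
    shared by several persons is *uncertain*: accepted only when
    ``include_uncertain`` is set. Ties at the best score prefer the person
    whose last movement precedes the death date; remaining ties are
    uncertain.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0,1]")
    cols = ["death_row_id", "person_uid", "name_score", "mother_score",
            "combined_score", "status"]
    if len(registry) == 0:
        return pd.DataFrame(columns=cols)

    cl_names = [normalize_name(n) for n in clusters["canonical_name"]]
    cl_mothers = [normalize_name(m) for m in
                  clusters["canonical_mother_name"].fillna("")]
    cl_last = pd.to_datetime(clusters["last_event_date"]).tolist()
    de_names = [normalize_name(n) for n in registry["name"]]
    de_mothers = [normalize_name(m) for m in registry["mother_name"].fillna("")]

    if use_blocking:
        pairs = _candidate_pairs(cl_names, de_names)
    else:
        pairs = {(i, j) for i in range(len(clusters))
                 for j in range(len(registry))}
    # candidate pairs below this name similarity are never reportable
    # matches at any plausible threshold and are dropped unscored
    candidate_floor = 0.4
    by_death: dict[int, list[tuple]] = {}
    for i, j in pairs:
        ns = _sim_floored(cl_names[i], de_names[j], length_exponent,
                          candidate_floor)
        if ns <= 0.0:
            continue
        if cl_mothers[i] and de_mothers[j]:
            ms = name_similarity(cl_mothers[i], de_mothers[j], length_exponent)
            combined = 0.5 * (ns + ms)
        else:
            ms = np.nan
            combined = ns
        by_death.setdefault(j, []).append((combined, ns, ms, i))

    death_dates = pd.to_datetime(registry["death_date"]).tolist()
    out = []
    for j, cands in by_death.items():
        cands.sort(key=lambda c: -c[0])
        best = cands[0][0]
        top = [c for c in cands if c[0] >= best - 1e-12]
        chosen = top[0]
        tied = len(top) > 1
        if tied:
            before = [c for c in top
                      if cl_last[c[3]] <= death_dates[j]]
            if len(before) == 1:
                chosen = before[0]
                tied = False
            elif before:
                top = before
                chosen = top[0]
        combined, ns, ms, i = chosen
        mother_missing = not (cl_mothers[i] and de_mothers[j])
        n_perfect_names = sum(1 for c in cands if c[1] >= 1.0 - 1e-12)
        uncertain = (combined >= threshold and
                     ((mother_missing and n_perfect_names > 1) or tied))
        # the name itself must clear the threshold; the mother's name can
        # confirm or veto (through the combined mean) but never substitute
        # for a dissimilar name
        if combined < threshold or ns < threshold:
            status = "rejected"
        elif uncertain:
            status = "uncertain" if not include_uncertain else "accepted"
        else:
            status = "accepted"
        out.append({"death_row_id": registry["row_id"].iloc[j],
                    "person_uid": clusters["person_uid"].iloc[i],
                    "name_score": ns, "mother_score": ms,
                    "combined_score": combined, "status": status})
    return pd.DataFrame(out, columns=cols)


def filter_posthumous_activity(matches: pd.DataFrame,
                               clusters: pd.DataFrame,
                               registry: pd.DataFrame) -> pd.DataFrame:
    """Post-linkage filter: reject accepted matches whose person has
    movement activity dated after the matched death (a false match —
    living people do not generate arrests)."""
    if matches.empty:
        return matches
    last = dict(zip(clusters["person_uid"], clusters["last_event_date"]))
    dd = dict(zip(registry["row_id"], registry["death_date"]))
    out = matches.copy()
    bad = [st == "accepted" and str(last.get(p, "")) > str(dd.get(d, ""))
           for st, p, d in zip(out["status"], out["person_uid"],
                               out["death_row_id"])]
    out.loc[bad, "status"] = "rejected"
    return out


@dataclass
class ValidationMetrics:
    """Confusion-matrix summary of linkage quality over candidate pairs."""

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    threshold: float
    n_labeled_pairs: int
    undefined: list = field(default_factory=list)


def truth_pair_labels(candidates: pd.DataFrame, clusters: pd.DataFrame,
                      truth: pd.DataFrame) -> pd.Series:
    """Boolean label per candidate row: does the death row truly belong to
    the person cluster? Derived from the truth table's row-level provenance."""
    row_to_person: dict[str, str] = {}
    death_to_person: dict[str, str] = {}
    for uid, rids, drow in zip(truth["person_uid"],
                               truth["registry_row_ids"],
                               truth["death_row_id"]):
        for rid in str(rids).split(";"):
            if rid.startswith("M"):
                row_to_person[rid] = uid
        if drow:
            death_to_person[drow] = uid
    cluster_persons = {}
    for cuid, mids in zip(clusters["person_uid"], clusters["member_row_ids"]):
        persons = {row_to_person.get(r) for r in mids.split(";")}
        cluster_persons[cuid] = persons - {None}
    return pd.Series(
        [death_to_person.get(d) in cluster_persons.get(p, set())
         for d, p in zip(candidates["death_row_id"],
                         candidates["person_uid"])],
        index=candidates.index)


def evaluate_linkage(candidates: pd.DataFrame, clusters: pd.DataFrame,
                     truth: pd.DataFrame,
                     threshold: float = float("nan")) -> ValidationMetrics:
    """Sensitivity / specificity / PPV of the linkage against ground truth.

    Sensitivity is over all *true* person-death pairs (cohort deaths present
    in the registry); specificity is over scored candidate non-pairs.
    Undefined metrics (zero denominators) are reported in ``undefined``.
    """
    # truth denominator: registry deaths generated by a person with >=1
    # movement row
    has_movement = truth["registry_row_ids"].str.contains("M")
    true_matches = truth[(truth["death_row_id"] != "") & has_movement]
    n_true = len(true_matches)

    if len(candidates):
        labels = truth_pair_labels(candidates, clusters, truth)
        accepted = candidates["status"] == "accepted"
        tp = int((labels & accepted).sum())
        fp = int((~labels & accepted).sum())
        tn = int((~labels & ~accepted).sum())
        n_nonpairs = fp + tn
        n_accepted = tp + fp
    else:
        tp = fp = tn = n_nonpairs = n_accepted = 0

    undefined = []
    if n_true == 0:
        sens = None
        undefined.append("sensitivity")
    else:
        sens = tp / n_true
    spec = tn / n_nonpairs if n_nonpairs else None
    if spec is None:
        undefined.append("specificity")
    ppv = tp / n_accepted if n_accepted else None
    if ppv is None:
        undefined.append("ppv")
    return ValidationMetrics(sens, spec, ppv, threshold,
                             int(len(candidates)), undefined)


def select_threshold(scores, labels, objective: str = "spec_first",
                     specificity_floor: float = 0.995):
    """Choose an acceptance threshold from scored labeled pairs.

    ``spec_first`` (default) maximizes sensitivity subject to
    specificity >= floor, mirroring a specificity-first linkage objective;
    ``youden`` maximizes sensitivity + specificity - 1. Returns
    ``(threshold, info)`` where info records the achieved operating point
    and a ``degenerate`` flag when all scores are identical.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if len(scores) == 0:
        raise ValueError("no labeled pairs")
    uniq = np.unique(scores)
    if len(uniq) == 1:
        return float(uniq[0]), {"degenerate": True, "sensitivity": None,
                                "specificity": None}
    pos, neg = labels.sum(), (~labels).sum()
    cand = np.concatenate([uniq, [uniq[-1] + 1e-9]])
    best, best_key = None, None
    for t in cand:
        acc = scores >= t
        sens = (acc & labels).sum() / pos if pos else 0.0
        spec = (~acc & ~labels).sum() / neg if neg else 1.0
        if objective == "youden":
            key = (sens + spec - 1.0,)
            ok = True
        else:
            ok = spec >= specificity_floor
            key = (sens, spec)
        if ok and (best_key is None or key > best_key):
            best_key, best = key, (t, sens, spec)
    if best is None:  # floor unattainable: fall back to max specificity
        t = float(cand[-1])
        best = (t, 0.0, 1.0)
    t, sens, spec = best
    # center inside the separating gap when one exists
    below = uniq[uniq < t]
    if len(below) and t <= uniq[-1]:
        t = 0.5 * (below[-1] + uniq[uniq >= t][0])
    return float(t), {"degenerate": False, "sensitivity": float(sens),
                      "specificity": float(spec)}
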