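"""Similarity, deduplication decision trees, linkage, and threshold
selection, checked against hand arithmetic and the truth table."""


import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from carcmort import SyntheticConfig, generate_cohort
from carcmort.identity_resolution import (
    ValidationMetrics, deduplicate_movements, evaluate_linkage, link_deaths,
    name_similarity, select_threshold, truth_pair_labels)

NAME_ALPHA = st.text(alphabet="ABCDEFGH ", min_size=0, max_size=12)


class TestNameSimilarity:
    def test_identity(self):
        assert name_similarity("MARIA DA SILVA", "MARIA DA SILVA") == 1.0

    def test_empty_string_convention(self):
        assert name_similarity("", "MARIA") == 0.0
        assert name_similarity("", "") == 0.0

    def test_hand_dp_value_equal_lengths(self):
        # edit distance 1, max length 3, equal lengths => weight 1
        assert name_similarity("ABC", "ABD") == pytest.approx(2 / 3)

    def test_length_weight_exponent(self):
        # "AB" vs "ABCD": d=2, base 0.5, weight (2/4)^0.5
        assert name_similarity("AB", "ABCD", 0.5) == \
            pytest.approx(0.5 * np.sqrt(0.5))
        assert name_similarity("AB", "ABCD", 0.0) == pytest.approx(0.5)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(a=NAME_ALPHA, b=NAME_ALPHA)
    def test_symmetric_and_bounded(self, a, b):
        s = name_similarity(a, b)
        assert s == name_similarity(b, a)
        assert 0.0 <= s <= 1.0


def _mklog(rows):
    return pd.DataFrame(rows, columns=["row_id", "internal_id", "name",
                                       "mother_name", "sex", "event_type",
                                       "facility_type", "event_date"])


class TestDeduplicate:
    def test_same_id_identical_names_merge(self):
        log = _mklog([
            ("M1", "R1", "JOSE SILVA", "ANA SILVA", "male", "arrest",
             "closed", "2010-01-01"),
            ("M2", "R1", "JOSE SILVA", "ANA SILVA", "male", "release",
             "closed", "2010-06-01")])
        cl = deduplicate_movements(log)
        assert len(cl) == 1
        assert set(cl.iloc[0]["member_row_ids"].split(";")) == {"M1", "M2"}

    def test_distinct_people_stay_separate(self):
        log = _mklog([
            ("M1", "R1", "JOSE SILVA", "ANA SILVA", "male", "arrest",
             "closed", "2010-01-01"),
            ("M2", "R2", "CARLOS SOUZA", "RITA GOMES", "male", "arrest",
             "police", "2010-06-01")])
        cl = deduplicate_movements(log)
        assert len(cl) == 2

    def test_same_name_different_id_requires_mother_agreement(self):
        base = ("JOSE PEREIRA LIMA", "male", "arrest", "closed", "2010-01-01")
        log = _mklog([
            ("M1", "R1", base[0], "ANA SILVA") + base[1:],
            ("M2", "R2", base[0], "ANA SILVA") + base[1:],
            ("M3", "R3", base[0], "RITA GOMES") + base[1:],
            ("M4", "R4", base[0], "") + base[1:],  # missing -> uncertain
        ])
        cl = deduplicate_movements(log)
        merged = {frozenset(c.split(";")) for c in cl["member_row_ids"]}
        assert frozenset({"M1", "M2"}) in merged
        assert len(cl) == 3  # M3 and M4 remain singletons

    def test_cluster_count_recovers_truth_with_duplicate_ids(self):
        cfg = SyntheticConfig(n_individuals=1500, seed=31,
                              duplicate_id_prob=0.10)
        c = generate_cohort(cfg)
        cl = deduplicate_movements(c.movement_log)
        n_true = c.truth["registry_row_ids"].str.contains("M").sum()
        assert len(cl) == n_true

    def test_clusters_partition_the_log(self, noisy_cohort):
        cl = deduplicate_movements(noisy_cohort.movement_log)
        all_ids = [r for m in cl["member_row_ids"] for r in m.split(";")]
        assert len(all_ids) == len(set(all_ids)) == \
            len(noisy_cohort.movement_log)

    def test_blocking_matches_brute_force(self):
        cfg = SyntheticConfig(n_individuals=250, seed=32)
        cfg.name_noise.char_error_prob = 0.02
        c = generate_cohort(cfg)
        blocked = deduplicate_movements(c.movement_log, use_blocking=True)
        brute = deduplicate_movements(c.movement_log, use_blocking=False)
        key = lambda df: sorted(frozenset(m.split(";"))
                                for m in df["member_row_ids"])
        assert key(blocked) == key(brute)


class TestLinkDeaths:
    def test_exact_match_accepted_with_score_one(self):
        cl = pd.DataFrame([{"person_uid": "C1",
                            "canonical_name": "JOSE SILVA",
                            "canonical_mother_name": "ANA SILVA",
                            "sex": "male", "last_event_date": "2010-01-01"}])
        reg = pd.DataFrame([{"row_id": "D1", "name": "JOSE SILVA",
                             "mother_name": "ANA SILVA", "sex": "male",
                             "death_date": "2011-01-01"}])
        m = link_deaths(cl, reg)
        assert len(m) == 1
        assert m.iloc[0]["status"] == "accepted"
        assert m.iloc[0]["combined_score"] == 1.0

    def test_below_threshold_rejected(self):
        cl = pd.DataFrame([{"person_uid": "C1",
                            "canonical_name": "JOSE SILVA",
                            "canonical_mother_name": "ANA SILVA",
                            "sex": "male", "last_event_date": "2010-01-01"}])
        reg = pd.DataFrame([{"row_id": "D1", "name": "JOSE MARTINS GOMES",
                             "mother_name": "RITA LIMA", "sex": "male",
                             "death_date": "2011-01-01"}])
        m = link_deaths(cl, reg, threshold=0.9)
        assert (m["status"] == "rejected").all()

    def test_empty_registry_gives_empty_output(self):
        cl = pd.DataFrame([{"person_uid": "C1", "canonical_name": "A B",
                            "canonical_mother_name": "", "sex": "male",
                            "last_event_date": "2010-01-01"}])
        m = link_deaths(cl, cl.iloc[0:0].rename(columns={}))
        assert len(m) == 0

    def test_missing_mother_with_multiple_perfect_names_is_uncertain(self):
        cl = pd.DataFrame([
            {"person_uid": "C1", "canonical_name": "JOSE SILVA",
             "canonical_mother_name": "ANA GOMES", "sex": "male",
             "last_event_date": "2010-01-01"},
            {"person_uid": "C2", "canonical_name": "JOSE SILVA",
             "canonical_mother_name": "RITA LIMA", "sex": "male",
             "last_event_date": "2010-02-01"}])
        reg = pd.DataFrame([{"row_id": "D1", "name": "JOSE SILVA",
                             "mother_name": "", "sex": "male",
                             "death_date": "2011-01-01"}])
        m = link_deaths(cl, reg, include_uncertain=False)
        assert (m["status"] == "uncertain").all()
        m2 = link_deaths(cl, reg, include_uncertain=True)
        assert (m2["status"] == "accepted").all()

    def test_threshold_monotonicity_against_truth(self, noisy_cohort):
        c = noisy_cohort
        cl = deduplicate_movements(c.movement_log)
        sens, spec, prev_accept = [], [], None
        for thr in [0.70, 0.80, 0.90, 0.95, 1.0]:
            m = link_deaths(cl, c.mortality_registry, threshold=thr)
            acc = set(m.loc[m["status"] == "accepted", "death_row_id"])
            if prev_accept is not None:
                assert acc <= prev_accept  # raising threshold shrinks set
            prev_accept = acc
            vm = evaluate_linkage(m, cl, c.truth, thr)
            sens.append(vm.sensitivity)
            spec.append(vm.specificity)
        assert all(a >= b - 1e-12 for a, b in zip(sens, sens[1:]))
        assert all(a <= b + 1e-12 for a, b in zip(spec, spec[1:]))


class TestEvaluateLinkage:
    def _truth_world(self):
        """8 true pairs accepted, 2 true rejected, 1 false accepted,
        89 false rejected -> sens 0.8, spec 89/90, ppv 8/9."""
        truth_rows, clusters, cands = [], [], []
        for i in range(10):
            truth_rows.append({"person_uid": f"P{i}",
                               "registry_row_ids": f"M{i};D{i}",
                               "death_row_id": f"D{i}"})
            clusters.append({"person_uid": f"C{i}",
                             "member_row_ids": f"M{i}"})
            cands.append({"death_row_id": f"D{i}", "person_uid": f"C{i}",
                          "name_score": 1.0, "mother_score": 1.0,
                          "combined_score": 1.0,
                          "status": "accepted" if i < 8 else "rejected"})
        # false pairs: D_i vs wrong clusters
        k = 0
        for i in range(10):
            for j in range(10):
                if i == j or k >= 90:
                    continue
                k += 1
                cands.append({"death_row_id": f"D{i}",
                              "person_uid": f"C{j}",
                              "name_score": 0.5, "mother_score": 0.5,
                              "combined_score": 0.5,
                              "status": "accepted" if k == 1 else "rejected"})
        return (pd.DataFrame(cands), pd.DataFrame(clusters),
                pd.DataFrame(truth_rows))

    def test_confusion_matrix_arithmetic(self):
        cands, clusters, truth = self._truth_world()
        vm = evaluate_linkage(cands, clusters, truth)
        assert vm.sensitivity == pytest.approx(0.8)
        assert vm.specificity == pytest.approx(89 / 90)
        assert vm.ppv == pytest.approx(8 / 9)

    def test_all_rejected_signals_undefined_ppv(self):
        cands, clusters, truth = self._truth_world()
        cands["status"] = "rejected"
        vm = evaluate_linkage(cands, clusters, truth)
        assert vm.sensitivity == 0.0
        assert vm.ppv is None and "ppv" in vm.undefined

    def test_no_true_matches_signals_undefined_sensitivity(self):
        truth = pd.DataFrame([{"person_uid": "P0",
                               "registry_row_ids": "M0",
                               "death_row_id": ""}])
        clusters = pd.DataFrame([{"person_uid": "C0",
                                  "member_row_ids": "M0"}])
        vm = evaluate_linkage(pd.DataFrame(columns=[
            "death_row_id", "person_uid", "status"]), clusters, truth)
        assert vm.sensitivity is None
        assert "sensitivity" in vm.undefined


def test_zero_noise_end_to_end_recovery(clean_cohort, clean_linkage):
    clusters, matches = clean_linkage
    vm = evaluate_linkage(matches, clusters, clean_cohort.truth)
    assert vm.sensitivity == 1.0
    assert vm.specificity == 1.0
    assert vm.ppv == 1.0


class TestSelectThreshold:
    def test_separated_scores_return_midpoint(self):
        scores = [0.2, 0.3, 0.8, 0.9]
        labels = [False, False, True, True]
        t, info = select_threshold(scores, labels)
        assert t == pytest.approx(0.55)
        assert info["sensitivity"] == 1.0 and info["specificity"] == 1.0

    def test_identical_scores_flag_degenerate(self):
        t, info = select_threshold([0.5, 0.5, 0.5], [True, False, True])
        assert t == 0.5
        assert info["degenerate"]

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            select_threshold([], [])

    def test_matches_exhaustive_sweep_on_beta_mixture(self, rng):
        pos = rng.beta(8, 2, 400)
        neg = rng.beta(2, 8, 2000)
        scores = np.concatenate([pos, neg])
        labels = np.concatenate([np.ones(400, bool), np.zeros(2000, bool)])
        floor = 0.98
        t, info = select_threshold(scores, labels, specificity_floor=floor)
        # brute-force sweep over all observed scores
        best = None
        for cand in np.unique(scores):
            acc = scores >= cand
            sens = (acc & labels).sum() / labels.sum()
            spec = (~acc & ~labels).sum() / (~labels).sum()
            if spec >= floor and (best is None or sens > best[0]):
                best = (sens, cand)
        acc = scores >= t
        sens_t = (acc & labels).sum() / labels.sum()
        assert sens_t == pytest.approx(best[0])
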