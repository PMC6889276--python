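import itertools

import numpy as np
import pytest

from respkit import (
    Assessment,
    Cohort,
    CriterionConfig,
    DataIntegrityError,
    TargetLesionMeasurement,
    classify_choi,
    classify_recist,
    cohens_kappa,
    mean_attenuation,
    response_at,
    select_target_lesions,
    sum_of_diameters,
    transition_table,
    transition_table_from_marginals,
)

from conftest import make_patient

CFG = CriterionConfig()


def _assessment(lesions, day=0, pid="P"):
    return Assessment(
        patient_id=pid,
        day=day,
        measurements=[
            TargetLesionMeasurement(f"L{i}", organ, day, diam, None)
            for i, (organ, diam) in enumerate(lesions, 1)
        ],
    )


class TestTargetSelection:
    def test_per_organ_cap(self):
        base = _assessment([("liver", 30), ("liver", 20), ("liver", 10), ("node", 15)])
        chosen = select_target_lesions(base)
        diams = {m.lesion_id: m.diameter for m in base.measurements}
        assert [diams[c] for c in chosen] == [30, 20, 15]

    def test_single_lesion(self):
        base = _assessment([("liver", 12)])
        assert select_target_lesions(base) == ["L1"]

    def test_no_measurable_disease(self):
        base = _assessment([("liver", 0)])
        with pytest.raises(DataIntegrityError, match="no measurable"):
            select_target_lesions(base)

    def _oracle_best_total(self, lesions, max_total=5, max_per_organ=2):
        """Exhaustive search over cap-respecting subsets, maximising total diameter."""
        best = 0.0
        items = [x for x in lesions if x[1] > 0]
        for k in range(1, min(max_total, len(items)) + 1):
            for sub in itertools.combinations(items, k):
                per = {}
                for organ, _ in sub:
                    per[organ] = per.get(organ, 0) + 1
                if all(v <= max_per_organ for v in per.values()):
                    best = max(best, sum(d for _, d in sub))
        return best

    @pytest.mark.parametrize("seed", range(20))
    def test_greedy_matches_bruteforce_on_random_lesion_sets(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 8))
        lesions = [
            (str(rng.choice(["liver", "node", "lung", "peri"])), float(rng.integers(1, 60)))
            for _ in range(n)
        ]
        base = _assessment(lesions)
        chosen = select_target_lesions(base)
        diams = {m.lesion_id: m.diameter for m in base.measurements}
        assert sum(diams[c] for c in chosen) == self._oracle_best_total(lesions)


class TestSums:
    def test_sum_and_mean(self):
        a = Assessment(
            patient_id="P", day=0,
            measurements=[
                TargetLesionMeasurement("L1", "liver", 0, 30, 120),
                TargetLesionMeasurement("L2", "liver", 0, 20, 80),
                TargetLesionMeasurement("L3", "node", 0, 15, None),
            ],
        )
        ids = ["L1", "L2", "L3"]
        assert sum_of_diameters(a, ids) == 65
        assert mean_attenuation(a, ids) == 100  # mean over available HU only

    def test_missing_target_row_is_error(self):
        a = _assessment([("liver", 30)])
        with pytest.raises(DataIntegrityError, match="L9"):
            sum_of_diameters(a, ["L9"])

    def test_all_missing_hu(self):
        a = _assessment([("liver", 30)])
        assert mean_attenuation(a, ["L1"]) is None


# Independent rule-table oracles: direct threshold evaluation from raw numbers.

def _recist_oracle(s, baseline, nadir):
    if s - nadir >= 5 and nadir > 0 and 100 * (s - nadir) / nadir >= 20:
        return "PD"
    if s == 0:
        return "CR"
    if 100 * (s - baseline) / baseline <= -30:
        return "PR"
    return "SD"


def _choi_oracle(s, baseline, hu_pct):
    if s == 0:
        return "CR"
    size_pct = 100 * (s - baseline) / baseline
    if size_pct <= -10 or (hu_pct is not None and hu_pct <= -15):
        return "PR"
    if size_pct >= 10 and not (hu_pct is not None and hu_pct <= -15):
        return "PD"
    return "SD"


class TestRuleGrid:
    """Exhaustive sweep of sign/magnitude combinations around every threshold."""

    SIZE_PCTS = [-100, -35, -30.0, -29.9, -10.1, -10.0, -9.9, -0.1, 0,
                 9.9, 10.0, 10.1, 19.9, 20.0, 20.1, 35]
    BASELINES = [18, 25, 50, 120]   # vary absolute mm at fixed percent
    HU_PCTS = [None, -30, -15.1, -15.0, -14.9, -5, 0, 10]

    @pytest.mark.parametrize("baseline", BASELINES)
    def test_recist_single_followup_grid(self, baseline):
        for pct in self.SIZE_PCTS:
            s = round(baseline * (1 + pct / 100), 6)
            p = make_patient("P", [(0, baseline, 100.0), (180, s, 100.0)])
            got = classify_recist(p, CFG).responses[0].label
            assert got == _recist_oracle(s, baseline, baseline), (baseline, pct)

    @pytest.mark.parametrize("baseline", BASELINES)
    def test_choi_single_followup_grid(self, baseline):
        for pct, hu_pct in itertools.product(self.SIZE_PCTS, self.HU_PCTS):
            s = round(baseline * (1 + pct / 100), 6)
            hu = None if hu_pct is None else 100.0 * (1 + hu_pct / 100)
            p = make_patient("P", [(0, baseline, 100.0), (180, s, hu)])
            got = classify_choi(p, CFG).responses[0].label
            assert got == _choi_oracle(s, baseline, hu_pct), (baseline, pct, hu_pct)

    def test_recist_nadir_grid_with_prior_shrinkage(self):
        # nadir established below baseline, then regrowth around the PD boundary
        baseline = 50.0
        nadir = 40.0
        for pct in self.SIZE_PCTS:
            s = round(nadir * (1 + pct / 100), 6)
            p = make_patient("P", [(0, baseline, 100.0), (90, nadir, 100.0), (180, s, 100.0)])
            series = classify_recist(p, CFG)
            assert len(series.responses) == 2
            assert series.responses[1].label == _recist_oracle(s, baseline, nadir), pct


class TestClassifyRecist:
    def test_pr_at_minus_35(self):
        p = make_patient("P", [(0, 100, None), (100, 65, None)])
        assert classify_recist(p).responses[0].label == "PR"

    def test_pd_needs_both_percent_and_absolute(self):
        # +20% but only +4 mm vs nadir: still SD
        p = make_patient("P", [(0, 20, None), (100, 24, None)])
        assert classify_recist(p).responses[0].label == "SD"
        p = make_patient("P", [(0, 100, None), (100, 121, None)])
        assert classify_recist(p).responses[0].label == "PD"

    def test_new_lesion_forces_pd_even_when_shrinking(self):
        p = make_patient("P", [(0, 100, None), (100, 50, None)], new_lesion_days=(100,))
        r = classify_recist(p).responses[0]
        assert r.label == "PD" and r.trigger == "new_lesion"

    def test_series_terminates_at_first_pd(self):
        p = make_patient("P", [(0, 50, None), (100, 65, None), (200, 40, None)])
        series = classify_recist(p)
        assert [r.label for r in series.responses] == ["PD"]

    def test_cr_when_sum_zero(self):
        p = make_patient("P", [(0, 12, None), (100, 0, None)])
        assert classify_recist(p).responses[0].label == "CR"


class TestClassifyChoi:
    def test_hu_drop_is_pr(self):
        p = make_patient("P", [(0, 100, 100.0), (100, 95, 80.0)])
        r = classify_choi(p).responses[0]
        assert r.label == "PR" and r.trigger == "hu_drop"

    def test_growth_with_hypoattenuation_is_still_pr(self):
        # grows +12% yet hypo-attenuates 30%: the PD clause is excluded
        p = make_patient("P", [(0, 100, 100.0), (100, 112, 70.0)])
        assert classify_choi(p).responses[0].label == "PR"

    def test_growth_without_hu_response_is_pd(self):
        p = make_patient("P", [(0, 100, 100.0), (100, 112, 95.0)])
        assert classify_choi(p).responses[0].label == "PD"

    def test_missing_followup_hu_disables_attenuation_clause(self):
        p = make_patient("P", [(0, 100, 100.0), (100, 112, None)])
        r = classify_choi(p).responses[0]
        assert r.label == "PD" and "hu_unavailable" in r.trigger

    def test_missing_baseline_hu_flags_size_only(self):
        p = make_patient("P", [(0, 100, None), (100, 80, 70.0)])
        series = classify_choi(p)
        assert any("size_only" in f for f in series.flags)
        assert series.responses[0].label == "PR"  # -20% size

    def test_nadir_reference_policy(self):
        cfg = CriterionConfig(reference_policy_choi_pd="nadir")
        # baseline 100 -> nadir 80 -> 92: +15% vs nadir (PD), -8% vs baseline (SD)
        p = make_patient("P", [(0, 100, 100.0), (90, 80, 100.0), (180, 92, 100.0)])
        assert classify_choi(p, cfg).responses[1].label == "PD"
        assert classify_choi(p, CFG).responses[1].label == "SD"
        # the size-PR clause (vs baseline) outranks nadir-referenced PD
        p2 = make_patient("P", [(0, 100, 100.0), (90, 80, 100.0), (180, 90, 100.0)])
        assert classify_choi(p2, cfg).responses[1].label == "PR"  # -10% vs baseline


class TestProperties:
    def test_recist_pr_implies_choi_pr_on_random_series(self):
        rng = np.random.default_rng(42)
        checked = 0
        for _ in range(2000):
            baseline = float(rng.uniform(10, 120))
            hu0 = float(rng.uniform(60, 160))
            days = (90, 180, 300)
            sums = baseline * np.exp(rng.normal(0, 0.35, len(days)))
            hus = hu0 * (1 + rng.normal(0, 0.15, len(days)))
            p = make_patient("P", [(0, baseline, hu0)] + list(zip(days, sums, hus)))
            rec = {r.day: r.label for r in classify_recist(p, CFG).responses}
            cho = {r.day: r.label for r in classify_choi(p, CFG).responses}
            for day, label in rec.items():
                if label == "PR" and day in cho:
                    assert cho[day] == "PR", (baseline, sums)
                    checked += 1
        assert checked > 50  # the property was actually exercised

    def test_monotone_severity_larger_sum_never_leaves_pd(self):
        rng = np.random.default_rng(7)
        for _ in range(500):
            baseline = float(rng.uniform(10, 100))
            s1 = float(baseline * rng.uniform(0.5, 1.6))
            p = make_patient("P", [(0, baseline, None), (100, s1, None)])
            if classify_recist(p, CFG).responses[0].label != "PD":
                continue
            bigger = s1 * float(rng.uniform(1.0, 2.0))
            p2 = make_patient("P", [(0, baseline, None), (100, bigger, None)])
            assert classify_recist(p2, CFG).responses[0].label == "PD"

    def test_no_labels_after_first_pd_under_either_criterion(self):
        p = make_patient(
            "P", [(0, 50, 100.0), (90, 62, 100.0), (180, 40, 60.0), (270, 30, 50.0)]
        )
        for series in (classify_recist(p, CFG), classify_choi(p, CFG)):
            labels = [r.label for r in series.responses]
            if "PD" in labels:
                assert labels.index("PD") == len(labels) - 1


class TestResponseAt:
    def _series(self, triples):
        p = make_patient("P", [(0, 100, 100.0)] + triples)
        return classify_recist(p, CFG)

    def test_pd_carried_forward(self):
        s = self._series([(100, 130, 100.0)])
        assert response_at(s, 183, 60) == "PD"

    def test_closest_assessment_in_window(self):
        s = self._series([(170, 100, 100.0), (350, 100, 100.0)])
        assert response_at(s, 183, 60) == "SD"

    def test_missing_when_no_assessment_in_window(self):
        s = self._series([(400, 100, 100.0)])
        assert response_at(s, 183, 60) is None


def _cell_patient(pid, r_label, c_label):
    """Single-lesion patient whose 6-month labels are (RECIST, Choi) = (r, c)."""
    recipes = {
        ("PR", "PR"): [(180, 60, 100.0)],                      # -40%
        ("SD", "PR"): [(180, 80, 100.0)],                      # -20%: RECIST SD, Choi PR
        ("SD", "SD"): [(180, 97, 100.0)],                      # -3%
        ("SD", "PD"): [(180, 115, 100.0)],                     # +15%: below RECIST PD
        ("PD", "PR"): [(180, 125, 70.0)],                      # +25% but HU -30%
        ("PD", "SD"): [(90, 80, 100.0), (180, 97, 100.0)],     # regrowth vs nadir only
        ("PD", "PD"): [(180, 130, 100.0)],                     # +30%
    }
    return make_patient(pid, [(0, 100, 100.0)] + recipes[(r_label, c_label)])


class TestTransitionTable:
    PAPER_COUNTS = np.array([[10, 0, 0], [26, 11, 7], [1, 1, 22]])

    def test_engineered_cohort_reproduces_reconstructed_table(self):
        cats = ("PR", "SD", "PD")
        patients = []
        k = 0
        for i, r in enumerate(cats):
            for j, c in enumerate(cats):
                for _ in range(self.PAPER_COUNTS[i, j]):
                    patients.append(_cell_patient(f"P{k:03d}", r, c))
                    k += 1
        table = transition_table(Cohort(patients=patients), 183, 60, CFG)
        assert np.array_equal(table.counts, self.PAPER_COUNTS)
        assert table.n == 78
        assert cohens_kappa(table) == pytest.approx(0.392, abs=5e-4)

    def test_identical_labels_give_diagonal(self):
        patients = [_cell_patient(f"P{i}", lab, lab) for i, lab in
                    enumerate(["PR", "SD", "PD", "PR"])]
        table = transition_table(Cohort(patients=patients), 183, 60, CFG)
        assert table.counts.sum() == np.trace(table.counts) == 4

    def test_empty_cohort(self):
        table = transition_table(Cohort(patients=[]), 183, 60, CFG)
        assert table.n == 0 and table.counts.sum() == 0

    def test_margins_equal_label_counts(self):
        rng = np.random.default_rng(3)
        cats = ("PR", "SD", "PD")
        picks = [(cats[int(a)], cats[int(b)]) for a, b in
                 zip(rng.integers(0, 3, 30), rng.integers(0, 3, 30))]
        # (PD, SD)/(PD, PR) pairs aside, any combination is constructible
        picks = [(r, c) for r, c in picks if (r, c) in
                 {(x, y) for x in cats for y in cats} - {("PR", "SD"), ("PR", "PD")}]
        patients = [_cell_patient(f"P{i}", r, c) for i, (r, c) in enumerate(picks)]
        table = transition_table(Cohort(patients=patients), 183, 60, CFG)
        rows = table.counts.sum(axis=1)
        from collections import Counter

        want = Counter(r for r, _ in picks)
        assert list(rows) == [want.get(c, 0) for c in cats]


class TestReconstruction:
    def test_unique_table_from_printed_marginals(self):
        table = transition_table_from_marginals(
            (12.8, 56.4, 30.7), (47.4, 15.3, 37.1), 78, sd_to_pr=26, sd_to_pd=7
        )
        assert np.array_equal(table.counts, TestTransitionTable.PAPER_COUNTS)

    def test_inconsistent_marginals_rejected(self):
        with pytest.raises(ValueError):
            transition_table_from_marginals((50, 30, 20), (10, 10, 80), 10, 5, 5)


class TestCohensKappa:
    def test_perfect_agreement(self):
        assert cohens_kappa(np.diag([5, 3, 9])) == pytest.approx(1.0)

    def test_matches_statsmodels(self):
        from statsmodels.stats.inter_rater import cohens_kappa as sm_kappa

        table = np.array([[10, 0, 0], [26, 11, 7], [1, 1, 22]])
        assert cohens_kappa(table) == pytest.approx(
            float(sm_kappa(table, return_results=False)), abs=1e-12
        )

    def test_independent_margins_give_near_zero(self):
        rng = np.random.default_rng(0)
        n = 200_000
        a = rng.choice(3, n, p=[0.2, 0.5, 0.3])
        b = rng.choice(3, n, p=[0.4, 0.2, 0.4])
        table = np.zeros((3, 3))
        np.add.at(table, (a, b), 1)
        assert abs(cohens_kappa(table)) < 0.01

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            cohens_kappa(np.zeros((3, 3)))

    def test_degenerate_margins(self):
        # both raters concentrated on one shared category: perfect agreement
        assert cohens_kappa(np.array([[4, 0, 0], [0, 0, 0], [0, 0, 0]])) == 1.0
        # concentrated on different categories: p_e = 0, kappa = 0
        assert cohens_kappa(np.array([[0, 4, 0], [0, 0, 0], [0, 0, 0]])) == 0.0

    def test_invariant_under_simultaneous_permutation(self):
        rng = np.random.default_rng(5)
        table = rng.integers(0, 30, (3, 3)).astype(float)
        perm = np.array([2, 0, 1])
        assert cohens_kappa(table) == pytest.approx(
            cohens_kappa(table[np.ix_(perm, perm)]))
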