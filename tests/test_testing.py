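"""Step 4 testing: composites, longitudinal features, ROC, Cox/logistic trait models."""

import numpy as np
import pandas as pd
import pytest

from painmarkers import (
    SimConfig,
    generate_cohort,
    longitudinal_features,
    risk_oriented_score,
    roc_auc,
    state_tests,
    stratified_run,
    trait_all_years,
    trait_year1,
)
from painmarkers.testing import MarkerPredictor, orient


def brute_force_auc(scores, labels):
    """Independent oracle: fraction of (case, control) pairs won, ties half."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    cases, controls = scores[labels], scores[~labels]
    wins = 0.0
    for c in cases:
        for k in controls:
            wins += 1.0 if c > k else 0.5 if c == k else 0.0
    return wins / (len(cases) * len(controls))


class TestRiskOrientedScore:
    def test_single_increased_marker(self):
        z = pd.DataFrame({"m1": [1.5]})
        assert risk_oriented_score(z, {"m1": "I"}).iloc[0] == 1.5

    def test_cancellation(self):
        z = pd.DataFrame({"m1": [1.0], "m2": [1.0]})
        assert risk_oriented_score(z, {"m1": "I", "m2": "D"}).iloc[0] == 0.0

    def test_hand_summation(self):
        z = pd.DataFrame({"a": [0.5], "b": [-0.2], "c": [1.0]})
        s = risk_oriented_score(z, {"a": "I", "b": "I", "c": "D"})
        assert s.iloc[0] == pytest.approx(-0.7)

    def test_missing_marker_value_drops_sample(self):
        z = pd.DataFrame({"a": [0.5, np.nan], "b": [1.0, 1.0]})
        s = risk_oriented_score(z, {"a": "I", "b": "I"})
        assert s.iloc[0] == 1.5 and np.isnan(s.iloc[1])

    def test_unknown_marker_rejected(self):
        with pytest.raises(ValueError):
            risk_oriented_score(pd.DataFrame({"a": [1.0]}), {"zz": "I"})


class TestLongitudinalFeatures:
    def test_single_visit(self):
        f = longitudinal_features([0], [0.4])
        assert f == {"last_level": 0.4, "max_level": 0.4,
                     "last_slope": 0.0, "max_slope": 0.0}

    def test_slope_hand_computation(self):
        f = longitudinal_features([0, 100], [0.0, 1.0])
        assert f["last_slope"] == pytest.approx(0.01)
        assert f["max_slope"] == pytest.approx(0.01)

    def test_constant_series(self):
        f = longitudinal_features([0, 10, 20], [0.3, 0.3, 0.3])
        assert f["last_level"] == f["max_level"] == 0.3
        assert f["last_slope"] == f["max_slope"] == 0.0

    def test_non_increasing_days_rejected(self):
        with pytest.raises(ValueError):
            longitudinal_features([0, 10, 10], [1, 2, 3])


class TestRocAuc:
    def test_perfect_separation(self):
        auc, p = roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert auc == 1.0 and p < 0.05

    def test_all_ties(self):
        auc, _ = roc_auc([5.0] * 8, [0, 1] * 4)
        assert auc == 0.5

    def test_pair_counting_example(self):
        # cases {3, 2}, controls {1, 2.5}: 3 of 4 pairs won
        auc, _ = roc_auc([3, 2, 1, 2.5], [1, 1, 0, 0])
        assert auc == 0.75

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2, 3], [1, 1, 1])

    def test_matches_brute_force_exhaustively(self, rng):
        """Rank-formula AUC equals pairwise counting on all sizes up to 30."""
        for n in range(2, 31):
            labels = np.zeros(n, bool)
            labels[rng.choice(n, size=rng.integers(1, n), replace=False)] = True
            if labels.all():
                labels[0] = False
            scores = rng.choice([0.0, 0.5, 1.0, 2.0, 3.0], size=n)  # heavy ties
            auc, _ = roc_auc(scores, labels)
            assert auc == pytest.approx(brute_force_auc(scores, labels))

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.normal(size=50)
        labels = rng.integers(0, 2, size=50).astype(bool)
        auc, _ = roc_auc(scores, labels)
        assert auc == pytest.approx(roc_auc_score(labels, scores))


class TestStateTests:
    def test_planted_state_marker_detected(self, rng):
        n = 200
        y = rng.random(n) < 0.4
        scores = pd.Series(rng.normal(1.5 * y, 1.0))
        vas = pd.Series(np.where(y, 7, 2) + rng.integers(0, 2, n))
        res = state_tests(scores, pd.Series(y), vas)
        assert res["auc"] > 0.7 and res["p"] < 0.05
        assert res["t_p"] < 0.05 and res["pearson_r"] > 0

    def test_permuted_labels_centre_at_half(self, rng):
        n = 150
        scores = pd.Series(rng.normal(size=n))
        aucs = []
        for _ in range(30):
            y = pd.Series(rng.permutation([True] * 50 + [False] * 100))
            aucs.append(state_tests(scores, y, pd.Series(np.where(y, 8, 1)))["auc"])
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.05)


def make_followup(subjects, events, last_note=730, index_day=0):
    return pd.DataFrame({
        "subject_id": subjects,
        "index_visit_day": index_day,
        "ed_pain_event_days": events,
        "last_note_day": last_note,
    })


class TestTraitYear1:
    def test_event_after_year_censored(self, rng):
        subs = [f"S{i}" for i in range(40)]
        events = [[100.0] if i < 10 else [400.0] if i < 20 else [] for i in range(40)]
        scores = pd.Series(rng.normal(size=40), index=subs)
        res = trait_year1(scores, make_followup(subs, events))
        # only the day-100 subjects are year-1 cases; day-400 events censor at 365
        assert res["n_cases"] == 10

    def test_cox_recovery_of_planted_hazard(self):
        """Planted log-HR 0.5 per z recovered within +-0.2 at n=300 (3 seeds)."""
        for seed in (1, 2, 3):
            r = np.random.default_rng(seed)
            n = 300
            z = r.normal(size=n)
            rate = 0.0012 * np.exp(0.5 * z)
            first = r.exponential(1 / rate)
            events = [[round(t, 1)] if t <= 730 else [] for t in first]
            subs = [f"S{i}" for i in range(n)]
            res = trait_year1(pd.Series(z, index=subs), make_followup(subs, events))
            assert np.log(res["hazard_ratio"]) == pytest.approx(0.5, abs=0.2)

    def test_null_marker_hr_near_one(self):
        covered = 0
        for seed in range(10):
            r = np.random.default_rng(100 + seed)
            n = 200
            z = r.normal(size=n)
            first = r.exponential(1 / 0.0015, size=n)
            events = [[round(t, 1)] if t <= 730 else [] for t in first]
            subs = [f"S{i}" for i in range(n)]
            res = trait_year1(pd.Series(z, index=subs), make_followup(subs, events))
            covered += abs(np.log(res["hazard_ratio"])) < 2 * 0.12  # ~2 SE at this n
        assert covered >= 9


class TestTraitAllYears:
    def test_logistic_recovery(self):
        """Planted log-OR 0.3 per z recovered within +-0.15 at n=400 (3 seeds)."""
        for seed in (1, 2, 3):
            r = np.random.default_rng(seed)
            n = 400
            z = r.normal(size=n)
            p = 1 / (1 + np.exp(-(-0.3 + 0.3 * z)))
            case = r.random(n) < p
            events = [[200.0] if c else [] for c in case]
            subs = [f"S{i}" for i in range(n)]
            res = trait_all_years(pd.Series(z, index=subs), make_followup(subs, events))
            assert np.log(res["odds_ratio"]) == pytest.approx(0.3, abs=0.15)

    def test_protective_marker_oriented_to_risk(self, rng):
        """A decreased-direction protective marker reports OR > 1 once oriented."""
        n = 300
        raw = rng.normal(size=n)
        p = 1 / (1 + np.exp(-(-0.5 - 0.8 * raw)))  # low values -> risk
        case = rng.random(n) < p
        events = [[150.0] if c else [] for c in case]
        subs = [f"S{i}" for i in range(n)]
        oriented = pd.Series(orient(raw, "D"), index=subs)
        res = trait_all_years(oriented, make_followup(subs, events))
        assert res["odds_ratio"] > 1 and res["p"] < 0.05

    def test_null_marker_or_near_one(self, rng):
        n = 400
        z = pd.Series(rng.normal(size=n), index=[f"S{i}" for i in range(n)])
        case = rng.random(n) < 0.4
        events = [[99.0] if c else [] for c in case]
        res = trait_all_years(z, make_followup(list(z.index), events))
        assert res["odds_ratio"] == pytest.approx(1.0, abs=0.3)

    def test_degenerate_outcome_rejected(self, rng):
        z = pd.Series(rng.normal(size=10), index=[f"S{i}" for i in range(10)])
        with pytest.raises(ValueError):
            trait_all_years(z, make_followup(list(z.index), [[] for _ in range(10)]))


@pytest.fixture(scope="module")
def fitted():
    cohort = generate_cohort(SimConfig(
            n_subjects=60, n_probesets=40, n_algogenes=4, n_suppressors=4,
        effect_size=2.0, p_severe_given_high=0.3, seed=19,
    ))
    planted = cohort.truth[cohort.truth["direction"] != ""]
    z = np.log2(cohort.bundle.intensity).T
    z = (z - z.mean()) / z.std(ddof=1)
    predictors = [
        MarkerPredictor(p, {p: d})
        for p, d in zip(planted["probeset_id"].head(3), planted["direction"].head(3))
    ]
    results = stratified_run(
        predictors, z, cohort.visits, followup=cohort.followup,
    )
    return cohort, z, predictors, results


class TestStratifiedRun:

    def test_all_subjects_row_present(self, fitted):
        _, _, _, results = fitted
        assert ((results["stratum"] == "all") & (results["skip_reason"] == "")).any()

    def test_small_strata_skipped_with_reason(self, fitted):
        _, _, _, results = fitted
        skipped = results[results["skip_reason"] != ""]
        assert len(skipped) > 0
        assert skipped["value"].isna().all()

    def test_year1_cases_subset_of_all_years(self, fitted):
        cohort, _, _, _ = fitted
        fu = cohort.followup
        year1 = {s for s, d in zip(fu["subject_id"], fu["ed_pain_event_days"])
                 if any(e <= 365 for e in d)}
        allyears = {s for s, d in zip(fu["subject_id"], fu["ed_pain_event_days"]) if d}
        assert year1 <= allyears

    def test_orientation_invariance(self, fitted):
        """Negating a marker's z and flipping its direction changes nothing."""
        cohort, z, predictors, results = fitted
        pid = predictors[0].marker_id
        d = predictors[0].directions[pid]
        z_flipped = z.copy()
        z_flipped[pid] = -z_flipped[pid]
        flipped_pred = MarkerPredictor(pid, {pid: "D" if d == "I" else "I"})
        res2 = stratified_run(
            [flipped_pred], z_flipped, cohort.visits, followup=cohort.followup,
        )
        base = results[results["marker"] == pid].reset_index(drop=True)
        pd.testing.assert_frame_equal(base, res2.reset_index(drop=True))

    def test_gender_specific_marker(self):
        """A female-only planted effect is significant in F, not in M."""
        rng = np.random.default_rng(7)
        n_f = n_m = 60
        rows, zvals = [], {}
        for i in range(n_f + n_m):
            g = "F" if i < n_f else "M"
            high = rng.random() < 0.5
            vas = int(rng.integers(6, 11)) if high else int(rng.integers(0, 3))
            sid = f"S{i:03d}"
            rows.append({"subject_id": sid, "visit_id": "V1", "day": 0,
                         "gender": g, "diagnosis": "MDD", "pain_vas": vas,
                         "sf36_21": 3, "sf36_22": 3, "sample_id": f"{sid}_V1"})
            effect = 2.0 if g == "F" else 0.0
            zvals[f"{sid}_V1"] = effect * high + rng.normal()
        visits = pd.DataFrame(rows)
        z = pd.DataFrame({"m1": pd.Series(zvals)})
        res = stratified_run(
            [MarkerPredictor("m1", {"m1": "I"})], z, visits,
            outcomes=["state_high_pain"], modes=["cross_sectional"],
            strata=["gender"],
        )
        by = res.set_index("stratum")
        assert bool(by.at["F", "significant"]) and not bool(by.at["M", "significant"])
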