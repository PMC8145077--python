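"""F1-optimal cutoffs and the group-conditional majority vote."""

import math

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import f1_score

import demrisk as d
from demrisk.ensemble import DIMENSIONS, f1_at_cutoff
from demrisk.prep import FLAG_COLUMNS


def oracle_cutoff(scores, labels):
    """Exhaustive search over unique-score candidates; smallest cutoff on
    F1 ties; +inf when no positives."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    if labels.sum() == 0:
        return math.inf
    best_c, best_f1 = None, -1.0
    for c in np.unique(scores):
        f1 = f1_score(labels, scores >= c, zero_division=0)
        if f1 > best_f1:
            best_c, best_f1 = c, f1
    return float(best_c)


def random_flags(rng, n):
    return pd.DataFrame({c: rng.random(n) < 0.4 for c in FLAG_COLUMNS})


class TestSelectF1Cutoff:
    def test_separable_pair(self):
        c = d.select_f1_cutoff([10, 90], [0, 1])
        assert c == 90
        assert f1_at_cutoff([10, 90], [0, 1], c) == 1.0

    def test_four_point_enumeration(self):
        assert d.select_f1_cutoff([10, 20, 30, 40], [0, 1, 0, 1]) == 20

    def test_no_positives_gives_sentinel(self):
        assert d.select_f1_cutoff([5, 6, 7], [0, 0, 0]) == math.inf

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            d.select_f1_cutoff([1, 2], [1])

    def test_matches_exhaustive_search_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(60):
            n = int(rng.integers(1, 201))
            scores = rng.integers(0, 30, size=n).astype(float)  # many ties
            labels = (rng.random(n) < 0.25).astype(int)
            assert d.select_f1_cutoff(scores, labels) == oracle_cutoff(scores, labels)

    def test_fitted_cutoff_dominates_all_candidates(self):
        rng = np.random.default_rng(19)
        scores = rng.random(100) * 100
        labels = (rng.random(100) < 0.3).astype(int)
        best = d.select_f1_cutoff(scores, labels)
        best_f1 = f1_at_cutoff(scores, labels, best)
        for c in np.unique(scores):
            assert best_f1 >= f1_at_cutoff(scores, labels, c)


class TestFitCutoffTable:
    def test_constant_false_flags_use_full_sample_and_fallback(self):
        scores = np.array([10.0, 20, 30, 40, 50, 60])
        labels = np.array([0, 0, 0, 1, 0, 1])
        flags = pd.DataFrame({c: [False] * 6 for c in FLAG_COLUMNS})
        table = d.fit_cutoff_table(scores, labels, flags)
        full = d.select_f1_cutoff(scores, labels)
        for dim in DIMENSIONS:
            assert table.cell(dim, False) == full
            assert table.cell(dim, True) == table.global_fallback == full
            assert table.provenance[(dim, True)]["fallback"]

    def test_twelve_row_table_equals_per_cell_enumeration(self):
        rng = np.random.default_rng(5)
        scores = rng.integers(0, 100, size=12).astype(float)
        labels = np.array([1, 0, 0, 1, 0, 1, 0, 0, 1, 0, 1, 0])
        flags = random_flags(rng, 12)
        table = d.fit_cutoff_table(scores, labels, flags)
        for dim in DIMENSIONS:
            member = flags[d.ensemble.DIMENSION_FLAGS[dim]].to_numpy()
            for is_member in (True, False):
                mask = member if is_member else ~member
                if mask.sum() == 0 or labels[mask].sum() == 0:
                    expected = table.global_fallback
                else:
                    expected = oracle_cutoff(scores[mask], labels[mask])
                assert table.cell(dim, is_member) == expected

    def test_identical_cell_data_identical_cutoffs(self):
        scores = np.array([10.0, 40, 70, 90])
        labels = np.array([0, 0, 1, 1])
        flags = pd.DataFrame({
            "dep_top_quartile": [True, True, False, False],
            "anx_top_quartile": [True, True, False, False],
            "vision_impaired": [False] * 4,
            "hearing_impaired": [False] * 4,
        })
        table = d.fit_cutoff_table(scores, labels, flags)
        assert table.cell("depression", True) == table.cell("anxiety", True)
        assert table.cell("depression", False) == table.cell("anxiety", False)

    def test_json_roundtrip(self, tmp_path):
        rng = np.random.default_rng(2)
        scores = rng.random(40) * 100
        labels = (rng.random(40) < 0.3).astype(int)
        table = d.fit_cutoff_table(scores, labels, random_flags(rng, 40))
        path = tmp_path / "cutoffs.json"
        table.to_json(path)
        back = d.CutoffTable.from_json(path)
        assert back.cutoffs == table.cutoffs
        assert back.global_fallback == table.global_fallback

    def test_member_only_mode_shares_global_cutoff(self):
        rng = np.random.default_rng(3)
        scores = rng.random(60) * 100
        labels = (rng.random(60) < 0.4).astype(int)
        flags = random_flags(rng, 60)
        table = d.fit_cutoff_table(scores, labels, flags, mode="member_only")
        full = d.select_f1_cutoff(scores, labels)
        for dim in DIMENSIONS:
            assert table.cell(dim, False) == full


class TestClassify:
    def make_table(self, cutoffs_by_dim):
        table = d.CutoffTable(global_fallback=50.0)
        for dim in DIMENSIONS:
            for m in (True, False):
                table.cutoffs[(dim, m)] = cutoffs_by_dim.get((dim, m), 50.0)
        return table

    def test_three_of_four_votes_is_positive(self):
        table = self.make_table({("hearing", False): 90.0})
        res = d.classify(60.0, dict.fromkeys(DIMENSIONS, False), table)
        assert res.weak_votes == (True, True, True, False)
        assert res.final

    def test_two_of_four_votes_is_negative(self):
        table = self.make_table({("vision", False): 90.0, ("hearing", False): 90.0})
        res = d.classify(60.0, dict.fromkeys(DIMENSIONS, False), table)
        assert sum(res.weak_votes) == 2 and not res.final

    def test_tie_at_cutoff_votes_positive(self):
        table = self.make_table({})
        assert d.classify(50.0, dict.fromkeys(DIMENSIONS, False), table).final

    def test_infinite_cutoff_votes_negative(self):
        table = self.make_table(
            {(dim, False): math.inf for dim in DIMENSIONS})
        assert not d.classify(99.0, dict.fromkeys(DIMENSIONS, False), table).final

    def test_membership_selects_the_member_cell(self):
        table = self.make_table({("depression", True): 80.0})
        flags = dict.fromkeys(DIMENSIONS, False)
        assert d.classify(70.0, flags, table).weak_votes[0]
        flags["depression"] = True
        assert not d.classify(70.0, flags, table).weak_votes[0]


class TestPredictCohort:
    def test_empty_input_empty_output(self):
        table = TestClassify().make_table({})
        out = d.predict_cohort(np.array([]), random_flags(np.random.default_rng(0), 0), table)
        assert len(out) == 0

    def test_rowwise_consistency_with_classify(self):
        rng = np.random.default_rng(21)
        scores = rng.random(50) * 100
        labels = (rng.random(50) < 0.3).astype(int)
        flags = random_flags(rng, 50)
        table = d.fit_cutoff_table(scores, labels, flags)
        audit = d.predict_cohort(scores, flags, table)
        for i in range(50):
            res = d.classify(scores[i], flags.iloc[i], table)
            assert audit["final"].iloc[i] == res.final
            assert tuple(audit[f"vote_{dim}"].iloc[i] for dim in DIMENSIONS) == res.weak_votes

    def test_repeated_row_gives_identical_results(self):
        table = TestClassify().make_table({})
        flags = pd.DataFrame({c: [True] * 5 for c in FLAG_COLUMNS})
        out = d.predict_cohort(np.full(5, 61.0), flags, table)
        assert out["final"].nunique() == 1

    def test_misaligned_input_rejected(self):
        table = TestClassify().make_table({})
        with pytest.raises(ValueError):
            d.predict_cohort(np.array([1.0, 2.0]),
                             random_flags(np.random.default_rng(0), 3), table)


class TestEnsembleProperties:
    def test_final_call_monotone_in_score(self):
        rng = np.random.default_rng(31)
        scores = rng.random(80) * 100
        labels = (rng.random(80) < 0.3).astype(int)
        flags = random_flags(rng, 80)
        table = d.fit_cutoff_table(scores, labels, flags)
        for i in range(10):
            f = flags.iloc[[i]]
            grid = np.linspace(0, 100, 201)
            finals = d.predict_cohort(
                grid, pd.concat([f] * len(grid), ignore_index=True), table,
            )["final"].astype(int)
            assert (np.diff(finals) >= 0).all()

    def test_equal_cutoffs_collapse_to_single_threshold(self):
        rng = np.random.default_rng(37)
        scores = rng.random(300) * 100
        truth = (rng.random(300) < 0.2).astype(int)
        flags = random_flags(rng, 300)
        for c in (20.0, 55.0, 90.0):
            table = TestClassify().make_table(
                {(dim, m): c for dim in DIMENSIONS for m in (True, False)})
            ens = d.predict_cohort(scores, flags, table)["final"].astype(int)
            single = (scores >= c).astype(int)
            assert d.confusion(ens, truth) == d.confusion(single, truth)


class TestMajorityVoteClassifier:
    def test_fit_predict_against_function_api(self):
        rng = np.random.default_rng(41)
        n = 120
        X = random_flags(rng, n).assign(risk_score=rng.random(n) * 100)
        y = (rng.random(n) < 0.3).astype(int)
        clf = d.MajorityVoteClassifier().fit(X, y)
        table = d.fit_cutoff_table(X["risk_score"], y, X[FLAG_COLUMNS])
        assert clf.cutoff_table_.cutoffs == table.cutoffs
        np.testing.assert_array_equal(
            clf.predict(X),
            d.predict_cohort(X["risk_score"], X[FLAG_COLUMNS], table)["final"].astype(int),
        )

    def test_sklearn_params_roundtrip(self):
        clf = d.MajorityVoteClassifier(min_votes=2, mode="member_only")
        assert d.MajorityVoteClassifier(**clf.get_params()).min_votes == 2
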