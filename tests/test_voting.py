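"""Vote aggregation: reference-score reproduction, weight laws, oracles."""

from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bfsmr.selectors import ModelPerformance, RankEntry, RankedFeatureList
from bfsmr.voting import (
    DEFAULT_ALIASES,
    REFERENCE_TIERS,
    AliasMap,
    WeightScheme,
    assign_model_weights,
    canonicalize,
    default_rank_weights,
    select_top_k,
    tally_votes,
)

# The five reference top-10 lists fused under w1 = 11 - rank and model-weight
# tiers {ridge, lasso: 1; filter, svm_rfe: 0.5; random_forest: 0.2} yield
# these scores for every canonical feature (voting1, voting2, voting3).
EXPECTED_SCORES = {
    "Age": (3, 30, 25),
    "Sex": (3, 25, 19.4),
    "Tobacco_No": (3, 21, 17),
    "BFType_Maternal": (3, 18, 14),
    "DietEducation": (2, 14, 14),
    "MoDietEducation": (3, 17, 12),
    "PE_Inadequate": (4, 10, 8.4),
    "MoTobacco_Yes": (1, 6, 6),
    "MoNumberCigarettes": (2, 8, 5.5),
    "Birthyear": (2, 10, 5.2),
    "MoSystolicPressure": (2, 14, 4.6),
    "DiastolicPressure": (2, 9, 4.5),
    "MoRDType_LowSalt": (1, 9, 4.5),
    "Sleep_Normal": (1, 9, 4.5),
    "RDType_2000cal": (1, 8, 4),
    "AdeDKnowledge": (1, 7, 3.5),
    "MoDiabetes_No": (1, 3, 3),
    "MoPE_Inadequate": (1, 6, 3),
    "DietCompliesAdvice": (1, 5, 2.5),
    "SystolicPressure": (2, 11, 2.5),
    "MoDiastolicPressure": (2, 10, 2.3),
    "Birthheight": (1, 4, 2),
    "MoRDType_Free": (1, 4, 2),
    "MoBMI": (1, 3, 1.5),
    "MoPEHour": (1, 3, 1.5),
    "Birthweight": (1, 2, 1),
    "DCExecution_No": (1, 1, 1),
    "MoExerciseAdvice": (1, 4, 0.8),
    "MoAlcohol_No": (1, 3, 0.6),
    "MoTobacco_Ex": (1, 1, 0.2),
}


def _mk_list(selector_id, features, k=None):
    k = k or len(features)
    return RankedFeatureList(
        selector_id=selector_id,
        entries=[
            RankEntry(feature=f, rank=r + 1, importance=float(k - r), sign="+")
            for r, f in enumerate(features)
        ],
    )


class TestReferenceFixture:
    def test_union_feature_space_has_thirty_features(self, reference_lists):
        _, F = canonicalize(reference_lists, DEFAULT_ALIASES)
        assert len(F) == 30
        _, F_plain = canonicalize(reference_lists, None)
        assert len(F_plain) == 31  # without the adequate->inadequate merge

    def test_alias_merge_keeps_both_ridge_entries(self, reference_lists):
        canonical, _ = canonicalize(reference_lists, DEFAULT_ALIASES)
        ridge = next(l for l in canonical if l.selector_id == "ridge")
        ranks = [e.rank for e in ridge.entries if e.feature == "PE_Inadequate"]
        assert sorted(ranks) == [7, 9]

    def test_every_score_cell_reproduced(self, reference_tallies):
        for feature, (v1, v2, v3) in EXPECTED_SCORES.items():
            assert reference_tallies["voting1"].score(feature) == v1, feature
            assert reference_tallies["voting2"].score(feature) == v2, feature
            assert reference_tallies["voting3"].score(feature) == v3, feature
        for t in reference_tallies.values():
            assert len(t.feature_space) == 30

    def test_top_ten_by_weighted_votes(self, reference_tallies):
        top = dict(select_top_k(reference_tallies["voting3"], 10))
        assert set(top) == {
            "Age",
            "Sex",
            "Tobacco_No",
            "BFType_Maternal",
            "DietEducation",
            "MoDietEducation",
            "PE_Inadequate",
            "MoTobacco_Yes",
            "MoNumberCigarettes",
            "Birthyear",
        }

    def test_vote_mass_conservation(self, reference_tallies):
        assert reference_tallies["voting1"].total == 50  # M * K
        assert reference_tallies["voting2"].total == 275  # M * K(K+1)/2
        assert reference_tallies["voting3"].total == 176  # K(K+1)/2 * sum(w2)


class TestCanonicalize:
    def test_single_list_identity(self):
        lst = _mk_list("a", ["x", "y", "z"])
        canonical, F = canonicalize([lst])
        assert F == ["x", "y", "z"]
        assert canonical[0].entries == lst.entries

    def test_alias_chain_rejected(self):
        with pytest.raises(ValueError, match="chain"):
            AliasMap({"a": "b", "b": "c"})

    def test_alias_of_absent_feature_is_noop(self):
        lst = _mk_list("a", ["x", "y"])
        _, F = canonicalize([lst], {"ghost": "x"})
        assert F == ["x", "y"]


class TestModelWeights:
    @staticmethod
    def _perf(selector_id, acc, f):
        return ModelPerformance(selector_id=selector_id, accuracy=acc, f_score=f, n_test=100)

    def test_reference_tier_map(self):
        perfs = [self._perf(s, 0.8, 0.8) for s in REFERENCE_TIERS]
        w2 = assign_model_weights(perfs, REFERENCE_TIERS)
        assert w2 == {
            "lasso": 1,
            "ridge": 1,
            "filter_mi": Fraction(1, 2),
            "svm_rfe": Fraction(1, 2),
            "random_forest": Fraction(1, 5),
        }

    def test_auto_identical_performance_single_tier(self):
        perfs = [self._perf(s, 0.85, 0.9) for s in ("a", "b", "c")]
        w2 = assign_model_weights(perfs, "auto")
        assert all(w == 1 for w in w2.values())

    def test_auto_dominant_selector_gets_top_weight(self):
        perfs = [self._perf("good", 0.9, 0.9), self._perf("bad", 0.7, 0.6)]
        w2 = assign_model_weights(perfs, "auto", ladder=(1, 0.5))
        assert w2["good"] == 1 and w2["bad"] == Fraction(1, 2)

    def test_unknown_selector_in_tier_map_rejected(self):
        with pytest.raises(ValueError, match="unknown selector"):
            assign_model_weights([self._perf("a", 0.8, 0.8)], {"a": "t1", "zz": "t2"})


class TestTally:
    def test_single_list_voting1_unit_scores(self):
        tally = tally_votes([_mk_list("a", ["x", "y"])], "voting1")
        assert tally.as_floats() == {"x": 1.0, "y": 1.0}

    def test_two_lists_shared_feature_unit_weights(self):
        lists = [_mk_list("a", ["x", "y", "z"]), _mk_list("b", ["x", "u", "v"])]
        tally = tally_votes(lists, "voting1")
        assert tally.score("x") == 2
        assert all(tally.score(f) == 1 for f in ["y", "z", "u", "v"])

    def test_missing_rank_weight_rejected(self):
        scheme = WeightScheme(w1={1: 2, 2: 1}, w2={"a": 1})
        with pytest.raises(ValueError, match="rank weight"):
            tally_votes([_mk_list("a", ["x", "y", "z"])], "voting2", scheme)

    def test_monotonicity_in_model_weight(self):
        lists = [_mk_list("a", ["x", "y"]), _mk_list("b", ["y", "z"])]
        w1 = default_rank_weights(2)
        lo = tally_votes(lists, "voting3", WeightScheme(w1=w1, w2={"a": 1, "b": 1}))
        hi = tally_votes(lists, "voting3", WeightScheme(w1=w1, w2={"a": 1, "b": 2}))
        assert hi.score("y") > lo.score("y") and hi.score("z") > lo.score("z")
        assert hi.score("x") == lo.score("x")

    def test_permutation_invariance(self, reference_lists, reference_scheme):
        canonical, _ = canonicalize(reference_lists, DEFAULT_ALIASES)
        a = tally_votes(canonical, "voting3", reference_scheme)
        b = tally_votes(list(reversed(canonical)), "voting3", reference_scheme)
        assert a.scores == b.scores


def _brute_force(lists, strategy, w1, w2):
    """Independent double-sum over (list j, rank k) per canonical feature."""
    features = sorted({e.feature for lst in lists for e in lst.entries})
    scores = {}
    for f in features:
        total = Fraction(0)
        for lst in lists:
            for e in lst.entries:
                if e.feature != f:
                    continue
                if strategy == "voting1":
                    total += 1
                elif strategy == "voting2":
                    total += Fraction(w1[e.rank])
                else:
                    total += Fraction(w1[e.rank]) * Fraction(w2[lst.selector_id])
        scores[f] = total
    return scores


@st.composite
def random_lists(draw):
    m = draw(st.integers(1, 4))
    k = draw(st.integers(1, 4))
    pool = [f"g{i}" for i in range(6)]
    lists = []
    for j in range(m):
        feats = draw(
            st.lists(st.sampled_from(pool), min_size=k, max_size=k, unique=True)
        )
        lists.append(_mk_list(f"s{j}", feats))
    w1 = {r: draw(st.integers(1, 9)) + (k - r) * 10 for r in range(1, k + 1)}
    w2 = {f"s{j}": draw(st.sampled_from([1, Fraction(1, 2), Fraction(1, 5), 2])) for j in range(m)}
    return lists, w1, w2


@given(random_lists(), st.sampled_from(["voting1", "voting2", "voting3"]))
@settings(max_examples=150, deadline=None, derandomize=True)
def test_tally_matches_brute_force_double_sum(data, strategy):
    lists, w1, w2 = data
    scheme = WeightScheme(w1=w1, w2=w2)
    tally = tally_votes(lists, strategy, scheme)
    assert tally.scores == _brute_force(lists, strategy, w1, w2)


@given(random_lists())
@settings(max_examples=100, deadline=None, derandomize=True)
def test_strategy_degeneracies_under_unit_weights(data):
    lists, w1, _ = data
    unit_w2 = {lst.selector_id: 1 for lst in lists}
    unit_w1 = {r: 1 for r in w1}
    v3 = tally_votes(lists, "voting3", WeightScheme(w1=w1, w2=unit_w2))
    v2 = tally_votes(lists, "voting2", WeightScheme(w1=w1, w2=unit_w2))
    assert v3.scores == v2.scores
    v2u = tally_votes(lists, "voting2", WeightScheme(w1=unit_w1, w2=unit_w2))
    v1 = tally_votes(lists, "voting1")
    assert v2u.scores == v1.scores


class TestTopK:
    def test_all_equal_scores_sorted_lexicographically(self):
        tally = tally_votes([_mk_list("a", ["c", "b", "a"])], "voting1")
        assert [f for f, _ in select_top_k(tally, 3)] == ["a", "b", "c"]

    def test_k_one_returns_max(self, reference_tallies):
        assert select_top_k(reference_tallies["voting3"], 1) == [("Age", 25.0)]

    def test_k_larger_than_space_warns_and_returns_all(self):
        tally = tally_votes([_mk_list("a", ["x", "y"])], "voting1")
        with pytest.warns(UserWarning, match="exceeds"):
            out = select_top_k(tally, 10)
        assert len(out) == 2

    def test_ties_broken_by_support_before_name(self):
        lists = [_mk_list("s1", ["z", "a"]), _mk_list("s2", ["z", "b"])]
        scheme = WeightScheme(w1={1: 1, 2: 1}, w2={"s1": 1, "s2": 1})
        tally = tally_votes(lists, "voting2", scheme)
        # z scores 2 (support 2); a and b score 1 -> a before b by name
        assert [f for f, _ in select_top_k(tally, 3)] == ["z", "a", "b"]


def test_w1_must_be_positive_and_non_increasing():
    with pytest.raises(ValueError):
        WeightScheme(w1={1: 1, 2: 2}, w2={"a": 1})
    with pytest.raises(ValueError):
        WeightScheme(w1={1: 0}, w2={"a": 1})
    with pytest.raises(ValueError):
        WeightScheme(w1={1: 1}, w2={"a": 0})
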