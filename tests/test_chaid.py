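import numpy as np
import pandas as pd
import pytest

from neolos.chaid import (
    ChaidConfig,
    ChaidTreeClassifier,
    MISSING,
    bonferroni_multiplier,
    grow_tree,
    merge_categories,
)
from neolos.cohort import panel_frame, outcome_vector
from neolos.evaluation import FORCED_ROOT


def count_partitions(c: int, r: int) -> int:
    """Enumeration oracle: number of set partitions of c labelled items
    into exactly r non-empty unlabelled blocks."""

    def rec(items, blocks):
        if not items:
            return 1 if len(blocks) == r else 0
        if len(blocks) > r:
            return 0
        head, rest = items[0], items[1:]
        total = 0
        for i in range(len(blocks)):
            total += rec(rest, [b + [head] if j == i else b for j, b in enumerate(blocks)])
        total += rec(rest, blocks + [[head]])
        return total

    return rec(list(range(c)), [])


class TestBonferroniMultiplier:
    @pytest.mark.parametrize("c,r", [(3, 3), (3, 2), (1, 1), (4, 2), (5, 3), (6, 4)])
    def test_matches_partition_enumeration(self, c, r):
        assert bonferroni_multiplier(c, r) == count_partitions(c, r)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            bonferroni_multiplier(2, 3)


class TestMergeCategories:
    def test_identical_proportions_merge(self):
        values = ["a"] * 40 + ["b"] * 40
        outcome = ([True] * 20 + [False] * 20) * 2
        groups = merge_categories(values, outcome, alpha_merge=0.05)
        assert groups == [("a", "b")]

    def test_appearance_score_levels_stay_separate(self, reference):
        """All pairwise outcome distributions of the published 3-level
        score differ at alpha 0.05, so no merge happens."""
        hs = reference["health_score_24h"]
        values, outcome = [], []
        for name, cases, controls in zip(hs["levels"], hs["cases"], hs["controls"]):
            values += [name] * (cases + controls)
            outcome += [True] * cases + [False] * controls
        groups = merge_categories(values, outcome, alpha_merge=0.05)
        assert sorted(groups) == [("equivocal",), ("healthy",), ("sick",)]

    def test_single_level_unchanged(self):
        assert merge_categories(["x"] * 5, [True, False, True, False, False]) == [("x",)]

    def test_missing_forms_floating_category(self):
        values = ["a"] * 30 + [None] * 30
        outcome = [True] * 15 + [False] * 15 + [True] * 15 + [False] * 15
        groups = merge_categories(values, outcome, alpha_merge=0.05)
        assert groups == [(MISSING, "a")]


class TestTreeGrowth:
    def test_perfect_separation_single_split(self):
        X = pd.DataFrame({"m": [True] * 20 + [False] * 20})
        y = [True] * 20 + [False] * 20
        clf = ChaidTreeClassifier(min_parent=20, min_child=7).fit(X, y)
        root = clf.tree_
        assert root.split_predictor == "m"
        assert root.adjusted_p < 0.05
        assert len(root.children) == 2
        fractions = sorted(c.case_fraction for c in root.children)
        assert fractions == [0.0, 1.0]

    def test_counts_conserved_and_adjustment_dominates_raw(self, cohort_5000):
        panels = panel_frame(cohort_5000)
        y = outcome_vector(cohort_5000)
        clf = grow_tree(panels, y, ChaidConfig(forced_root=FORCED_ROOT))
        stack = [clf.tree_]
        while stack:
            node = stack.pop()
            if node.children:
                assert sum(c.n_cases for c in node.children) == node.n_cases
                assert sum(c.n_controls for c in node.children) == node.n_controls
                assert node.adjusted_p >= node.raw_p - 1e-15
                stack.extend(node.children)

    def test_row_order_invariance(self, cohort_5000):
        sub = cohort_5000[:600]
        panels = panel_frame(sub).reset_index(drop=True)
        y = outcome_vector(sub)
        clf = ChaidTreeClassifier(forced_root=FORCED_ROOT).fit(panels, y)
        rng = np.random.default_rng(5)
        perm = rng.permutation(len(sub))
        clf2 = ChaidTreeClassifier(forced_root=FORCED_ROOT).fit(
            panels.iloc[perm].reset_index(drop=True), y[perm]
        )
        assert clf.tree_.to_dict() == clf2.tree_.to_dict()

    def test_small_node_stops(self):
        X = pd.DataFrame({"m": [True, False] * 5})
        y = [True, False] * 5
        clf = ChaidTreeClassifier(min_parent=20).fit(X, y)
        assert clf.tree_.is_terminal

    def test_forced_root_unknown_marker_rejected(self):
        X = pd.DataFrame({"m": [True, False] * 20})
        y = [True, False] * 20
        with pytest.raises(ValueError, match="unknown markers"):
            ChaidTreeClassifier(forced_root="m OR nope").fit(X, y)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            ChaidConfig(min_parent=5, min_child=7)

    def test_sklearn_params_round_trip(self):
        clf = ChaidTreeClassifier(alpha_split=0.01, forced_root="a OR b")
        params = clf.get_params()
        assert params["alpha_split"] == 0.01
        clone = ChaidTreeClassifier(**params)
        assert clone.get_params() == params


class TestPrediction:
    @pytest.fixture()
    def published_structure(self):
        """Panels realising the published node counts: 23 infants in the
        culture-or-sick node (21 cases), 28 in the CRP/NLR node (12 cases),
        54 lab-negative controls."""
        rows = []
        for culture_or_sick, crp_or_nlr, cases, controls in [
            (True, True, 21, 2),
            (False, True, 12, 16),
            (False, False, 0, 54),
        ]:
            for is_case in [True] * cases + [False] * controls:
                rows.append(
                    {
                        "culture_positive_24h": culture_or_sick,
                        "sick_appearing": culture_or_sick,
                        "crp_or_nlr": crp_or_nlr,
                        "sepsis": is_case,
                    }
                )
        frame = pd.DataFrame(rows)
        return frame.drop(columns="sepsis"), frame["sepsis"].to_numpy()

    def test_routing_reproduces_node_sizes(self, published_structure):
        X, y = published_structure
        clf = ChaidTreeClassifier(forced_root=FORCED_ROOT).fit(X, y)
        nodes, frac = clf.predict_node(X)
        sizes = sorted(np.bincount(nodes)[np.bincount(nodes) > 0].tolist())
        assert sizes == [23, 28, 54]
        # lab-negative leaf holds no cases
        assert frac.min() == 0.0

    def test_root_only_tree_predicts_prevalence(self):
        X = pd.DataFrame({"m": [True, False] * 5})
        y = np.array([True, False] * 5)
        clf = ChaidTreeClassifier(min_parent=20).fit(X, y)
        nodes, frac = clf.predict_node(X)
        assert set(nodes) == {1}
        assert np.allclose(frac, 0.5)

    def test_missing_value_routes_to_majority_child(self):
        X = pd.DataFrame({"m": [True] * 30 + [False] * 10})
        y = np.array([True] * 30 + [False] * 10)
        clf = ChaidTreeClassifier(min_parent=20, min_child=7).fit(X, y)
        nodes, _ = clf.predict_node(pd.DataFrame({"m": [None]}))
        majority = max(clf.tree_.children, key=lambda c: c.n)
        assert nodes[0] == majority.node_id

    def test_predict_proba_shape(self, published_structure):
        X, y = published_structure
        clf = ChaidTreeClassifier(forced_root=FORCED_ROOT).fit(X, y)
        proba = clf.predict_proba(X)
        assert proba.shape == (len(X), 2)
        assert np.allclose(proba.sum(axis=1), 1.0)
        assert clf.predict(X).dtype == bool
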