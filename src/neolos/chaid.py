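"""CHAID decision-tree induction (Chi-square Automatic Interaction
Detection) for nominal predictors and a binary outcome.

At each node, every candidate predictor has its observed categories
iteratively re-merged: the pair of category groups whose outcome
distributions differ least (largest chi-square / Fisher p-value) is
merged while that p exceeds ``alpha_merge``.  The best merged split per
predictor is then judged by a Bonferroni-adjusted p-value: the raw
chi-square p times the Kass multiplier — the number of ways to partition
the ``c`` observed categories into the ``r`` merged groups,

    B(c, r) = sum_{i=0}^{r-1} (-1)^i (r - i)^c / (i! (r - i)!),

i.e. the Stirling number of the second kind.  When ``bonferroni`` is on,
the adjustment additionally multiplies by the number of candidate
predictors examined at the node, so the family-wise probability of any
split under a null outcome stays below ``alpha_split`` (classic CHAID
corrects only within predictor and its false-split rate grows with the
candidate count).

The clinical analysis forces the first split on a composite marker
("positive culture at 24 h OR sick appearance") because that grouping is
a clinical safety choice, not a data-driven one; ``forced_root`` supports
exactly that: a predictor name, or several joined by ``" OR "``.

Missing values form their own floating category (classic CHAID), free to
merge with any group.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator, ClassifierMixin

from .stats import TwoByTwo, chi_square_or_fisher

__all__ = [
    "MISSING",
    "ChaidConfig",
    "ChaidNode",
    "ChaidTreeClassifier",
    "bonferroni_multiplier",
    "merge_categories",
    "grow_tree",
]

#: Category label for a missing predictor value (floating category).
MISSING = "__NA__"


@dataclass
class ChaidConfig:
    """Induction parameters; none are dictated by the clinical analysis
    itself, so all are exposed.  Defaults are sized to be reachable on a
    cohort of about a hundred infants."""

    alpha_merge: float = 0.05
    alpha_split: float = 0.05
    min_parent: int = 20
    min_child: int = 7
    max_depth: int = 3
    bonferroni: bool = True
    forced_root: Optional[str] = None

    def __post_init__(self) -> None:
        for name in ("alpha_merge", "alpha_split"):
            a = getattr(self, name)
            if not 0 < a <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.min_child < 1:
            raise ValueError("min_child must be >= 1")
        if self.min_parent < 2 * self.min_child:
            raise ValueError("min_parent must be >= 2 * min_child")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ChaidConfig":
        with open(path, encoding="utf-8") as fh:
            return cls(**json.load(fh))


def bonferroni_multiplier(c: int, r: int) -> int:
    """Number of distinct partitions of ``c`` nominal categories into
    ``r`` non-empty groups (Kass adjustment; Stirling number S(c, r))."""
    if r > c:
        raise ValueError("merged group count r cannot exceed category count c")
    if r < 1:
        raise ValueError("need at least one group")
    total = 0.0
    for i in range(r):
        total += (-1) ** i * (r - i) ** c / (math.factorial(i) * math.factorial(r - i))
    return int(round(total))


def _pair_p(cases_i: int, controls_i: int, cases_j: int, controls_j: int) -> float:
    """Outcome-association p for a pair of category groups."""
    if cases_i + cases_j == 0 or controls_i + controls_j == 0:
        return 1.0  # identical (degenerate) outcome distributions
    t = TwoByTwo(a=cases_i, b=cases_j, c=controls_i, d=controls_j)
    return chi_square_or_fisher(t).p_value


def _grouped_p(groups: Sequence[Sequence[object]], counts: dict) -> float:
    """Outcome-association p for the full merged grouping (r x 2 table):
    chi-square/Fisher for r = 2, Pearson chi-square otherwise."""
    table = np.array(
        [
            [sum(counts[g][0] for g in grp), sum(counts[g][1] for g in grp)]
            for grp in groups
        ],
        dtype=float,
    )
    if len(groups) == 2:
        t = TwoByTwo(
            a=int(table[0, 0]), b=int(table[1, 0]),
            c=int(table[0, 1]), d=int(table[1, 1]),
        )
        return chi_square_or_fisher(t).p_value
    if table.sum(axis=0).min() == 0:
        return 1.0
    chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
    return float(p)


def _merge_counts(
    counts: dict, alpha_merge: float
) -> list[tuple]:
    """Iterative pairwise merging on per-category (cases, controls) counts.

    Groups are tuples of category labels, kept sorted by string form;
    ties in the merge p break toward the lexicographically first pair.
    """
    groups: list[tuple] = [(label,) for label in sorted(counts, key=str)]
    agg = {g: counts[g[0]] for g in groups}
    while len(groups) > 1:
        best_pair = None
        best_p = -1.0
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                gi, gj = groups[i], groups[j]
                p = _pair_p(agg[gi][0], agg[gi][1], agg[gj][0], agg[gj][1])
                if p > best_p + 1e-12:
                    best_p, best_pair = p, (gi, gj)
        if best_p <= alpha_merge:
            break
        gi, gj = best_pair
        merged = tuple(sorted(gi + gj, key=str))
        agg[merged] = (agg[gi][0] + agg[gj][0], agg[gi][1] + agg[gj][1])
        groups = [g for g in groups if g not in (gi, gj)]
        groups.append(merged)
        groups.sort(key=lambda g: str(g[0]))
        del agg[gi], agg[gj]
    return groups


def merge_categories(
    values: Sequence[object],
    outcome: Sequence[bool],
    alpha_merge: float = 0.05,
) -> list[tuple]:
    """Merge the categories of one nominal predictor against a binary
    outcome.  Returns the merged grouping as tuples of original labels;
    unobserved (empty) categories are simply absent."""
    v = np.asarray(values, dtype=object)
    y = np.asarray(outcome, dtype=bool)
    counts: dict = {}
    for label in pd.unique(v):
        key = MISSING if (label is None or (isinstance(label, float) and np.isnan(label))) else label
        mask = v == label if key != MISSING else pd.isna(v.astype(object))
        c = int(np.sum(y[mask]))
        k = int(np.sum(~y[mask]))
        if c + k > 0:
            counts[key] = (counts.get(key, (0, 0))[0] + c, counts.get(key, (0, 0))[1] + k)
    if not counts:
        raise ValueError("no observed categories")
    if len(counts) == 1:
        return [tuple(counts)]
    return _merge_counts(counts, alpha_merge)


@dataclass
class ChaidNode:
    node_id: int
    depth: int
    n_cases: int
    n_controls: int
    split_predictor: Optional[str] = None
    groups: list[tuple] = field(default_factory=list)
    raw_p: Optional[float] = None
    adjusted_p: Optional[float] = None
    forced: bool = False
    children: list["ChaidNode"] = field(default_factory=list)

    @property
    def is_terminal(self) -> bool:
        return not self.children

    @property
    def n(self) -> int:
        return self.n_cases + self.n_controls

    @property
    def case_fraction(self) -> float:
        return self.n_cases / self.n if self.n else 0.0

    def to_dict(self) -> dict:
        return {
            "node_id": self.node_id,
            "depth": self.depth,
            "n_cases": self.n_cases,
            "n_controls": self.n_controls,
            "split_predictor": self.split_predictor,
            "groups": [[str(x) for x in g] for g in self.groups],
            "raw_p": self.raw_p,
            "adjusted_p": self.adjusted_p,
            "forced": self.forced,
            "children": [c.to_dict() for c in self.children],
        }


def _categorize(value) -> object:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return MISSING
    return value


class ChaidTreeClassifier(BaseEstimator, ClassifierMixin):
    """CHAID recursive partitioning over nominal predictors.

    Parameters mirror :class:`ChaidConfig`.  ``X`` is a DataFrame of
    nominal columns (bool, str or mixed with None/NaN for missing); ``y``
    is a binary outcome.  Fitted attributes: ``tree_`` (the root
    :class:`ChaidNode`), ``nodes_`` (id -> node), ``feature_names_in_``,
    ``classes_``.
    """

    def __init__(
        self,
        alpha_merge: float = 0.05,
        alpha_split: float = 0.05,
        min_parent: int = 20,
        min_child: int = 7,
        max_depth: int = 3,
        bonferroni: bool = True,
        forced_root: Optional[str] = None,
    ):
        self.alpha_merge = alpha_merge
        self.alpha_split = alpha_split
        self.min_parent = min_parent
        self.min_child = min_child
        self.max_depth = max_depth
        self.bonferroni = bonferroni
        self.forced_root = forced_root

    # -- fitting ---------------------------------------------------------

    def fit(self, X: pd.DataFrame, y) -> "ChaidTreeClassifier":
        ChaidConfig(  # validate parameter combination
            alpha_merge=self.alpha_merge, alpha_split=self.alpha_split,
            min_parent=self.min_parent, min_child=self.min_child,
            max_depth=self.max_depth, bonferroni=self.bonferroni,
            forced_root=self.forced_root,
        )
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(X)
        y = np.asarray(y, dtype=bool)
        if len(X) != len(y):
            raise ValueError("X and y must have equal length")
        if len(X) == 0:
            raise ValueError("empty cohort")
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.classes_ = np.array([False, True])
        cols = {
            name: np.array([_categorize(v) for v in X[name]], dtype=object)
            for name in X.columns
        }
        self._forced_name: Optional[str] = None
        if self.forced_root is not None:
            parts = [p.strip() for p in self.forced_root.split(" OR ")]
            unknown = [p for p in parts if p not in cols]
            if unknown:
                raise ValueError(f"forced_root references unknown markers: {unknown}")
            composite = np.full(len(y), False, dtype=object)
            any_missing = np.full(len(y), False)
            for p in parts:
                vals = cols[p]
                is_missing = vals == MISSING
                truth = np.zeros(len(y), dtype=bool)
                truth[~is_missing] = vals[~is_missing].astype(bool)
                composite = np.where(truth, True, composite)
                any_missing |= is_missing
            composite = np.where(~np.asarray(composite, bool) & any_missing, MISSING, composite)
            self._forced_name = self.forced_root
            cols = {self._forced_name: composite, **cols}
        self._columns = cols
        self._next_id = 1
        self.tree_ = self._grow(np.arange(len(y)), y, depth=0)
        self.nodes_: dict[int, ChaidNode] = {}
        stack = [self.tree_]
        while stack:
            node = stack.pop()
            self.nodes_[node.node_id] = node
            stack.extend(node.children)
        self.n_nodes_ = len(self.nodes_)
        return self

    def _new_node(self, y, idx, depth) -> ChaidNode:
        node = ChaidNode(
            node_id=self._next_id,
            depth=depth,
            n_cases=int(np.sum(y[idx])),
            n_controls=int(np.sum(~y[idx])),
        )
        self._next_id += 1
        return node

    def _candidate_predictors(self, depth: int) -> list[str]:
        names = list(self._columns)
        if self._forced_name is not None and depth >= 1:
            # component markers of the forced composite stay available;
            # the composite itself is only used at the root
            names.remove(self._forced_name)
        return names

    def _grow(self, idx: np.ndarray, y: np.ndarray, depth: int) -> ChaidNode:
        node = self._new_node(y, idx, depth)
        if depth >= self.max_depth:
            return node
        if self._forced_name is not None and depth == 0:
            split = self._forced_split(idx, y)
        else:
            if node.n < self.min_parent or node.n_cases == 0 or node.n_controls == 0:
                return node
            split = self._best_split(idx, y, depth)
        if split is None:
            return node
        name, groups, raw_p, adjusted_p, forced = split
        node.split_predictor = name
        node.groups = list(groups)
        node.raw_p = raw_p
        node.adjusted_p = adjusted_p
        node.forced = forced
        values = self._columns[name][idx]
        for grp in groups:
            member = np.isin(values.astype(str), [str(g) for g in grp])
            node.children.append(self._grow(idx[member], y, depth + 1))
        return node

    def _forced_split(self, idx, y):
        name = self._forced_name
        values = self._columns[name][idx]
        counts: dict = {}
        for label in (True, False, MISSING):
            mask = values == label
            if mask.any():
                counts[label] = (int(np.sum(y[idx][mask])), int(np.sum(~y[idx][mask])))
        if True not in counts or False not in counts:
            raise ValueError(
                f"forced root {name!r} does not split the cohort (one side empty)"
            )
        # missing joins the positive (cannot-rule-out) side, conservatively
        groups: list[tuple] = []
        pos = (True, MISSING) if MISSING in counts else (True,)
        groups.append(tuple(sorted(pos, key=str)))
        groups.append((False,))
        agg = {}
        for grp in groups:
            agg[grp] = (
                sum(counts[g][0] for g in grp),
                sum(counts[g][1] for g in grp),
            )
        raw_p = _grouped_p(groups, {g: counts[g] for g in counts})
        return name, groups, raw_p, raw_p, True

    def _best_split(self, idx, y, depth):
        candidates = self._candidate_predictors(depth)
        scored = []
        y_node = y[idx]
        for name in candidates:
            values = self._columns[name][idx]
            counts: dict = {}
            for label in pd.unique(values):
                mask = values == label
                counts[label] = (int(np.sum(y_node[mask])), int(np.sum(~y_node[mask])))
            counts = {k: v for k, v in counts.items() if sum(v) > 0}
            c_observed = len(counts)
            if c_observed < 2:
                continue
            groups = _merge_counts(counts, self.alpha_merge)
            r = len(groups)
            if r < 2:
                continue
            sizes = [sum(sum(counts[g]) for g in grp) for grp in groups]
            if min(sizes) < self.min_child:
                continue
            raw_p = _grouped_p(groups, counts)
            mult = bonferroni_multiplier(c_observed, r)
            if self.bonferroni:
                mult *= len(candidates)
            adjusted = min(1.0, raw_p * mult)
            scored.append((adjusted, r, name, groups, raw_p))
        if not scored:
            return None
        scored.sort(key=lambda t: (t[0], t[1], t[2]))
        adjusted, r, name, groups, raw_p = scored[0]
        if adjusted >= self.alpha_split:
            return None
        return name, groups, raw_p, adjusted, False

    # -- prediction ------------------------------------------------------

    def _route(self, row: dict) -> ChaidNode:
        node = self.tree_
        while not node.is_terminal:
            name = node.split_predictor
            if name == self._forced_name and name not in row:
                parts = [p.strip() for p in name.split(" OR ")]
                vals = [_categorize(row.get(p)) for p in parts]
                if any(v is True for v in vals):
                    value = True
                elif any(v == MISSING for v in vals):
                    value = MISSING
                else:
                    value = False
            else:
                value = _categorize(row.get(name))
            target = None
            for child, grp in zip(node.children, node.groups):
                if str(value) in {str(g) for g in grp}:
                    target = child
                    break
            if target is None:  # unseen / missing category: majority child
                target = max(node.children, key=lambda ch: (ch.n, -ch.node_id))
            node = target
        return node

    def predict_node(self, X: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        """Route panels to terminal nodes: (node ids, training case fractions)."""
        if not hasattr(self, "tree_"):
            raise RuntimeError("classifier is not fitted")
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(X, columns=self.feature_names_in_)
        leaves = [self._route(rec) for rec in X.to_dict(orient="records")]
        return (
            np.array([n.node_id for n in leaves]),
            np.array([n.case_fraction for n in leaves]),
        )

    def predict_proba(self, X) -> np.ndarray:
        _, frac = self.predict_node(X)
        return np.column_stack([1.0 - frac, frac])

    def predict(self, X) -> np.ndarray:
        return self.predict_proba(X)[:, 1] >= 0.5

    # -- serialisation ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "params": self.get_params(),
            "tree": self.tree_.to_dict(),
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def render_text(self) -> str:
        lines: list[str] = []

        def walk(node: ChaidNode, prefix: str, label: str) -> None:
            lines.append(
                f"{prefix}{label}node {node.node_id}: "
                f"{node.n_cases} cases / {node.n_controls} controls"
                + (
                    f" | split on {node.split_predictor}"
                    f" (adj p = {node.adjusted_p:.3g}{', forced' if node.forced else ''})"
                    if node.split_predictor
                    else ""
                )
            )
            for child, grp in zip(node.children, node.groups):
                walk(child, prefix + "  ", f"[{', '.join(map(str, grp))}] -> ")

        walk(self.tree_, "", "")
        return "\n".join(lines)


def grow_tree(panels: pd.DataFrame, outcome, config: Optional[ChaidConfig] = None) -> ChaidTreeClassifier:
    """Functional wrapper: fit a :class:`ChaidTreeClassifier` under ``config``."""
    config = config or ChaidConfig()
    clf = ChaidTreeClassifier(**dataclasses.asdict(config))
    return clf.fit(panels, outcome)
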