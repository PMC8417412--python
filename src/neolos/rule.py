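"""The fixed 24-h antibiotic-discontinuation rule.

A published three-node classifier applied 24 h after the sepsis work-up:

* **node 2** — positive blood culture within 24 h OR sick appearance:
  continue antibiotics;
* **node 3** — otherwise, CRP > 0.75 mg/dl OR NLR > 1.5: continue;
* **node 4** — none of the above: antibiotics may be discontinued.

A missing CRP or NLR counts as elevated (the infant cannot be shown
low-risk), so the rule is conservative under missingness, and flipping
any single marker from negative to positive can never move an infant
from "continue" to "discontinue".

The three nodes double as an ordinal risk score (node 2 > node 3 >
node 4) for ROC analysis; outputs are retrospective classifications,
not treatment recommendations.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import MarkerPanel, PatientRecord, derive_markers
from .stats import DiagnosticMetrics, diagnostic_metrics, ordinal_auc

__all__ = [
    "Decision",
    "RuleNode",
    "RuleDecision",
    "RuleEvaluation",
    "classify",
    "evaluate_rule",
    "FixedDiscontinuationRule",
]


class Decision(str, enum.Enum):
    CONTINUE = "continue"
    DISCONTINUE = "discontinue"


class RuleNode(str, enum.Enum):
    NODE2 = "node2"
    NODE3 = "node3"
    NODE4 = "node4"


_ORDINAL_RISK = {RuleNode.NODE2: 2, RuleNode.NODE3: 1, RuleNode.NODE4: 0}


@dataclass(frozen=True)
class RuleDecision:
    decision: Decision
    node: RuleNode

    @property
    def ordinal_risk(self) -> int:
        return _ORDINAL_RISK[self.node]


def classify(panel: MarkerPanel) -> RuleDecision:
    """Apply the fixed rule to one marker panel."""
    if panel.culture_positive_24h or panel.sick_appearing:
        return RuleDecision(Decision.CONTINUE, RuleNode.NODE2)
    crp = True if panel.crp_high is None else panel.crp_high
    nlr = True if panel.nlr_high is None else panel.nlr_high
    if crp or nlr:
        return RuleDecision(Decision.CONTINUE, RuleNode.NODE3)
    return RuleDecision(Decision.DISCONTINUE, RuleNode.NODE4)


@dataclass(frozen=True)
class RuleEvaluation:
    metrics: DiagnosticMetrics
    node_counts: dict[RuleNode, tuple[int, int]]  # node -> (cases, controls)

    @property
    def ordinal_auc(self) -> float:
        return float(self.metrics.auc)


def evaluate_rule(
    records: Sequence[PatientRecord] | None = None,
    *,
    panels: Sequence[MarkerPanel] | None = None,
    outcome: Sequence[bool] | None = None,
) -> RuleEvaluation:
    """Evaluate the rule on a labelled cohort.

    "Continue" counts as test-positive.  The AUC is the Mann-Whitney
    value over the three ordinal risk nodes, which for these levels can
    never fall below the AUC of the continue/discontinue dichotomy.
    """
    if records is not None:
        panels = [derive_markers(r) for r in records]
        outcome = [r.sepsis for r in records]
    if panels is None or outcome is None:
        raise ValueError("provide records, or panels together with outcome")
    y = np.asarray(outcome, dtype=bool)
    if len(panels) != len(y):
        raise ValueError("panels and outcome must have equal length")
    if y.all() or not y.any():
        raise ValueError("both outcome classes must be present")
    node_counts = {node: [0, 0] for node in RuleNode}
    tp = fp = tn = fn = 0
    for panel, is_case in zip(panels, y):
        d = classify(panel)
        node_counts[d.node][0 if is_case else 1] += 1
        positive = d.decision is Decision.CONTINUE
        if positive and is_case:
            tp += 1
        elif positive:
            fp += 1
        elif is_case:
            fn += 1
        else:
            tn += 1
    metrics = diagnostic_metrics(tp, fp, tn, fn)
    auc = ordinal_auc(
        [tuple(node_counts[n]) for n in (RuleNode.NODE2, RuleNode.NODE3, RuleNode.NODE4)]
    )
    metrics = DiagnosticMetrics(
        sensitivity=metrics.sensitivity,
        specificity=metrics.specificity,
        ppv=metrics.ppv,
        npv=metrics.npv,
        auc=auc,
    )
    return RuleEvaluation(
        metrics=metrics,
        node_counts={n: tuple(v) for n, v in node_counts.items()},
    )


class FixedDiscontinuationRule:
    """Parameterless classifier wrapper around :func:`classify` so the rule
    composes with DataFrame pipelines (columns = marker names)."""

    def predict_node(self, X: pd.DataFrame) -> np.ndarray:
        decisions = self.decide(X)
        return np.array([d.node.value for d in decisions], dtype=object)

    def decide(self, X: pd.DataFrame) -> list[RuleDecision]:
        needed = ["culture_positive_24h", "sick_appearing", "crp_high", "nlr_high"]
        missing_cols = [c for c in needed if c not in X.columns]
        if missing_cols:
            raise ValueError(f"missing marker columns: {missing_cols}")
        out = []
        for rec in X.to_dict(orient="records"):
            panel = MarkerPanel(
                crp_high=_tri(rec["crp_high"]),
                nlr_high=_tri(rec["nlr_high"]),
                crp_or_nlr=None,
                lymphopenia=None,
                abnormal_neutrophils=None,
                abnormal_wbc=None,
                thrombocytopenia=None,
                hyperglycemia=None,
                abnormal_temperature=None,
                tachycardia=None,
                sick_appearing=bool(rec["sick_appearing"]),
                culture_positive_24h=bool(rec["culture_positive_24h"]),
            )
            out.append(classify(panel))
        return out

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """True where antibiotics continue (test-positive)."""
        return np.array(
            [d.decision is Decision.CONTINUE for d in self.decide(X)], dtype=bool
        )


def _tri(value):
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    return bool(value)
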