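"""2x2-table and ROC statistics for diagnostic-accuracy analysis.

Everything downstream — the marker odds-ratio table, the decision-rule
sensitivity/specificity/PPV/NPV, the ordinal tree AUC — reduces to the
operations here.  Conventions:

* Odds ratios use the cross-product (a*d)/(b*c) with a Woolf (logit)
  95% interval, exp(ln OR +/- z*sqrt(1/a+1/b+1/c+1/d)).  With a zero
  cell the Haldane-Anscombe correction adds 0.5 to all four cells
  before both the point estimate and the interval.
* AUC for a binary or ordinal risk score is the Mann-Whitney
  probability that a random case outranks a random control, ties
  counted one half.  For a binary test this equals (se + sp) / 2.
* Percentages are reported to one decimal, rounding half away from
  zero, matching clinical-table convention.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "TwoByTwo",
    "ORResult",
    "DiagnosticMetrics",
    "RocCurve",
    "CutoffResult",
    "AssociationTest",
    "odds_ratio",
    "diagnostic_metrics",
    "ordinal_auc",
    "roc_and_youden",
    "chi_square_or_fisher",
    "hanley_mcneil_se",
    "round_half_up",
]

_Z95 = sps.norm.ppf(0.975)


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round half away from zero (1.25 -> 1.3 at one decimal)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class TwoByTwo:
    """Exposure-by-outcome contingency counts.

    ``a``: exposed cases, ``b``: unexposed cases, ``c``: exposed controls,
    ``d``: unexposed controls.  OR = (a*d)/(b*c).
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")

    @property
    def n_cases(self) -> int:
        return self.a + self.b

    @property
    def n_controls(self) -> int:
        return self.c + self.d

    @classmethod
    def from_arrays(cls, exposed: Sequence[bool], outcome: Sequence[bool]) -> "TwoByTwo":
        e = np.asarray(exposed, dtype=bool)
        y = np.asarray(outcome, dtype=bool)
        if e.shape != y.shape:
            raise ValueError("exposure and outcome must have equal length")
        return cls(
            a=int(np.sum(e & y)),
            b=int(np.sum(~e & y)),
            c=int(np.sum(e & ~y)),
            d=int(np.sum(~e & ~y)),
        )


@dataclass(frozen=True)
class ORResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    corrected: bool = False
    separated: bool = False

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.odds_ratio <= self.ci_high):
            raise ValueError("confidence interval must contain the point estimate")


def odds_ratio(t: TwoByTwo, correction: str = "haldane_if_zero") -> ORResult:
    """Cross-product odds ratio with Woolf 95% CI and Wald two-sided p.

    ``correction='haldane_if_zero'`` (default) adds 0.5 to all four cells
    when any cell is zero; ``'none'`` raises on an undefined OR instead.
    """
    if correction not in ("none", "haldane_if_zero"):
        raise ValueError(f"unknown correction {correction!r}")
    if t.n_cases == 0 or t.n_controls == 0 or (t.a + t.c) == 0 or (t.b + t.d) == 0:
        raise ValueError("both margins of the 2x2 table must be positive")
    cells = (t.a, t.b, t.c, t.d)
    corrected = False
    if 0 in cells:
        if correction == "none":
            raise ValueError(
                "odds ratio undefined with a zero cell and correction='none'"
            )
        cells = tuple(v + 0.5 for v in cells)
        corrected = True
    a, b, c, d = cells
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = math.log(or_)
    z = log_or / se
    p = 2 * sps.norm.sf(abs(z))
    return ORResult(
        odds_ratio=or_,
        ci_low=math.exp(log_or - _Z95 * se),
        ci_high=math.exp(log_or + _Z95 * se),
        p_value=float(p),
        corrected=corrected,
    )


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Sensitivity/specificity/PPV/NPV as percentages; AUC on [0, 1].

    ``ppv``/``npv`` are ``None`` when their denominator is zero (no test
    positives / negatives).  ``auc`` is filled by callers that have a risk
    ordering (binary tests get (se+sp)/2).
    """

    sensitivity: float
    specificity: float
    ppv: Optional[float]
    npv: Optional[float]
    auc: Optional[float] = None

    def rounded(self) -> dict[str, Optional[float]]:
        out: dict[str, Optional[float]] = {}
        for name in ("sensitivity", "specificity", "ppv", "npv"):
            v = getattr(self, name)
            out[name] = None if v is None else round_half_up(v, 1)
        out["auc"] = None if self.auc is None else round_half_up(self.auc, 2)
        return out


def diagnostic_metrics(tp: int, fp: int, tn: int, fn: int) -> DiagnosticMetrics:
    """Diagnostic accuracy of a binary test from its confusion counts.

    AUC is set to the binary Mann-Whitney value (se + sp) / 2.
    """
    for name, v in (("tp", tp), ("fp", fp), ("tn", tn), ("fn", fn)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative, got {v}")
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("both outcome classes must be present")
    se = tp / (tp + fn)
    sp = tn / (tn + fp)
    ppv = 100.0 * tp / (tp + fp) if (tp + fp) > 0 else None
    npv = 100.0 * tn / (tn + fn) if (tn + fn) > 0 else None
    return DiagnosticMetrics(
        sensitivity=100.0 * se,
        specificity=100.0 * sp,
        ppv=ppv,
        npv=npv,
        auc=(se + sp) / 2.0,
    )


def ordinal_auc(group_counts: Sequence[tuple[int, int]]) -> float:
    """Mann-Whitney AUC for an ordinal risk score from per-level counts.

    ``group_counts`` lists ``(cases, controls)`` per risk level ordered
    from highest to lowest risk.  Returns the probability that a random
    case sits at a strictly higher level than a random control, plus half
    the tie probability.
    """
    counts = [(int(c), int(k)) for c, k in group_counts]
    if len(counts) < 2:
        raise ValueError("need at least two risk levels")
    if any(c < 0 or k < 0 for c, k in counts):
        raise ValueError("counts must be non-negative")
    n_cases = sum(c for c, _ in counts)
    n_controls = sum(k for _, k in counts)
    if n_cases == 0 or n_controls == 0:
        raise ValueError("both cases and controls must be present")
    total = 0.0
    controls_below = [0] * len(counts)
    for i in range(len(counts) - 2, -1, -1):
        controls_below[i] = controls_below[i + 1] + counts[i + 1][1]
    for (cases_i, controls_i), below in zip(counts, controls_below):
        total += cases_i * (below + 0.5 * controls_i)
    return total / (n_cases * n_controls)


@dataclass(frozen=True)
class RocCurve:
    """Empirical ROC: points (threshold, sensitivity, 1-specificity), with
    the convention "positive if value > threshold", thresholds at observed
    values (plus -inf for the all-positive corner)."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    one_minus_specificity: np.ndarray

    @property
    def auc(self) -> float:
        return float(np.trapezoid(self.sensitivity, self.one_minus_specificity))


@dataclass(frozen=True)
class CutoffResult:
    threshold: float
    youden: float
    sensitivity: float
    specificity: float


def roc_and_youden(values: Sequence[float], labels: Sequence[bool]) -> tuple[RocCurve, CutoffResult]:
    """ROC curve over observed thresholds and the Youden-optimal cutoff.

    The Youden index se + sp - 1 is maximised; ties break toward the
    lower threshold (favouring sensitivity).  Constant values yield a
    degenerate one-point curve with a warning.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if v.shape != y.shape:
        raise ValueError("values and labels must have equal length")
    n_cases = int(y.sum())
    n_controls = int((~y).sum())
    if n_cases == 0 or n_controls == 0:
        raise ValueError("both classes must be present")
    uniq = np.unique(v)
    if uniq.size == 1:
        warnings.warn("constant predictor: degenerate ROC curve", stacklevel=2)
    # thresholds: each observed value, descending, then -inf (everyone positive)
    thresholds = np.concatenate([uniq[::-1], [-np.inf]])
    se = np.empty_like(thresholds)
    fpr = np.empty_like(thresholds)
    case_vals = v[y]
    control_vals = v[~y]
    for i, t in enumerate(thresholds):
        se[i] = np.sum(case_vals > t) / n_cases
        fpr[i] = np.sum(control_vals > t) / n_controls
    youden = se - fpr
    best = np.max(youden)
    # ties toward the lower threshold: last index among descending thresholds
    idx = np.flatnonzero(youden >= best - 1e-12)[-1]
    curve = RocCurve(thresholds=thresholds, sensitivity=se, one_minus_specificity=fpr)
    cutoff = CutoffResult(
        threshold=float(thresholds[idx]),
        youden=float(youden[idx]),
        sensitivity=float(se[idx]),
        specificity=float(1.0 - fpr[idx]),
    )
    return curve, cutoff


@dataclass(frozen=True)
class AssociationTest:
    statistic: Optional[float]
    p_value: float
    test_used: str  # "chi_square" | "fisher"


def chi_square_or_fisher(t: TwoByTwo) -> AssociationTest:
    """Pearson chi-square (no continuity correction) when every expected
    count is >= 5, otherwise Fisher's exact test (two-sided)."""
    table = np.array([[t.a, t.c], [t.b, t.d]], dtype=float)
    if t.n_cases + t.n_controls == 0 or table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        raise ValueError("both margins must be positive")
    expected = sps.contingency.expected_freq(table)
    if expected.min() >= 5.0:
        chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
        return AssociationTest(statistic=float(chi2), p_value=float(p), test_used="chi_square")
    _, p = sps.fisher_exact(table, alternative="two-sided")
    return AssociationTest(statistic=None, p_value=float(p), test_used="fisher")


def hanley_mcneil_se(auc: float, n_cases: int, n_controls: int) -> float:
    """Hanley-McNeil standard error of an AUC estimate.

    Provided for completeness; printed AUC intervals in the reference
    tables were produced by an unstated method and are not reproduced.
    """
    if not 0.0 <= auc <= 1.0:
        raise ValueError("auc must lie in [0, 1]")
    if n_cases <= 0 or n_controls <= 0:
        raise ValueError("group sizes must be positive")
    q1 = auc / (2 - auc)
    q2 = 2 * auc * auc / (1 + auc)
    var = (
        auc * (1 - auc)
        + (n_cases - 1) * (q1 - auc * auc)
        + (n_controls - 1) * (q2 - auc * auc)
    ) / (n_cases * n_controls)
    return math.sqrt(max(var, 0.0))
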