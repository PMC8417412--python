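"""Univariate logistic screening of candidate sepsis predictors.

Each marker is fit alone against the LOS outcome by maximum-likelihood
logistic regression (statsmodels IRLS/Newton).  For a binary exposure with
all four 2x2 cells positive, the fitted odds ratio equals the
cross-product ratio and the Wald interval equals the Woolf interval — an
identity the test suite asserts.  Perfect or quasi-perfect separation (a
zero cell) is detected up front and reported with the Haldane-corrected
2x2 odds ratio instead of a penalised fit.

Markers with p < 0.2 (strict) are flagged as candidates for decision-tree
induction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import MARKER_NAMES, HealthScore
from .stats import ORResult, TwoByTwo, odds_ratio

__all__ = [
    "ScreenResult",
    "CANDIDATE_ALPHA",
    "univariate_logistic",
    "continuous_logistic",
    "factor_logistic",
    "screen_predictors",
]

#: Candidate threshold for tree induction (strict inequality).
CANDIDATE_ALPHA = 0.2


@dataclass(frozen=True)
class ScreenResult:
    marker: str
    or_result: ORResult
    n_used: int

    @property
    def candidate(self) -> bool:
        return self.or_result.p_value < CANDIDATE_ALPHA


def univariate_logistic(exposure: Sequence[bool], outcome: Sequence[bool]) -> ORResult:
    """Single binary-predictor logistic regression, reported as an OR.

    With any zero cell the MLE does not exist (separation); the result is
    then the Haldane-corrected 2x2 odds ratio, flagged ``separated``.
    """
    e = np.asarray(exposure, dtype=bool)
    y = np.asarray(outcome, dtype=bool)
    if y.all() or not y.any():
        raise ValueError("both outcome classes must be present")
    t = TwoByTwo.from_arrays(e, y)
    if 0 in (t.a, t.b, t.c, t.d):
        corrected = odds_ratio(t, correction="haldane_if_zero")
        return ORResult(
            odds_ratio=corrected.odds_ratio,
            ci_low=corrected.ci_low,
            ci_high=corrected.ci_high,
            p_value=corrected.p_value,
            corrected=True,
            separated=True,
        )
    X = sm.add_constant(e.astype(float))
    fit = sm.Logit(y.astype(float), X).fit(disp=False, maxiter=100)
    if not fit.mle_retvals.get("converged", False):
        raise RuntimeError("logistic regression failed to converge")
    beta = float(fit.params[1])
    se = float(fit.bse[1])
    ci = fit.conf_int()
    return ORResult(
        odds_ratio=float(np.exp(beta)),
        ci_low=float(np.exp(ci[1, 0])),
        ci_high=float(np.exp(ci[1, 1])),
        p_value=float(fit.pvalues[1]),
    )


def continuous_logistic(values: Sequence[float], outcome: Sequence[bool]) -> ORResult:
    """Per-unit odds ratio for a continuous predictor (e.g. CRP in mg/dl,
    NLR per unit ratio).  Not used for tree candidacy."""
    v = np.asarray(values, dtype=float)
    y = np.asarray(outcome, dtype=bool)
    if y.all() or not y.any():
        raise ValueError("both outcome classes must be present")
    X = sm.add_constant(v)
    fit = sm.Logit(y.astype(float), X).fit(disp=False, maxiter=200)
    if not fit.mle_retvals.get("converged", False):
        raise RuntimeError("logistic regression failed to converge")
    ci = fit.conf_int()
    return ORResult(
        odds_ratio=float(np.exp(fit.params[1])),
        ci_low=float(np.exp(ci[1, 0])),
        ci_high=float(np.exp(ci[1, 1])),
        p_value=float(fit.pvalues[1]),
    )


def factor_logistic(
    levels: Sequence[str],
    outcome: Sequence[bool],
    reference: str = "healthy",
) -> dict[str, ORResult]:
    """Multi-level factor (e.g. the 3-level appearance score) against the
    outcome; one OR per non-reference level, reference odds = 1.

    Each level's OR equals the 2x2 cross-product of that level vs the
    reference, so separation per level is handled as in
    :func:`univariate_logistic`.
    """
    lv = np.asarray(levels, dtype=object)
    y = np.asarray(outcome, dtype=bool)
    uniq = sorted(set(lv))
    if reference not in uniq:
        raise ValueError(f"reference level {reference!r} not observed")
    out: dict[str, ORResult] = {}
    ref_mask = lv == reference
    for level in uniq:
        if level == reference:
            continue
        mask = ref_mask | (lv == level)
        out[level] = univariate_logistic(lv[mask] == level, y[mask])
    return out


def screen_predictors(
    panels: pd.DataFrame,
    outcome: Sequence[bool],
    markers: Optional[Sequence[str]] = None,
) -> list[ScreenResult]:
    """Screen every binary marker column of ``panels`` against ``outcome``.

    Records with a missing value for a marker are dropped for that
    marker's regression only.  Results come back sorted by ascending p
    (ties by marker name), which is invariant to patient ordering.
    """
    if len(panels) == 0:
        raise ValueError("empty cohort")
    y = np.asarray(outcome, dtype=bool)
    if len(y) != len(panels):
        raise ValueError("outcome length must match panel rows")
    names = list(markers) if markers is not None else [
        m for m in MARKER_NAMES if m in panels.columns
    ]
    results: list[ScreenResult] = []
    for name in names:
        col = panels[name]
        keep = col.notna().to_numpy()
        if keep.sum() == 0:
            warnings.warn(f"marker {name!r} entirely missing; skipped", stacklevel=2)
            continue
        e = col[keep].astype(bool).to_numpy()
        try:
            res = univariate_logistic(e, y[keep])
        except RuntimeError as exc:
            raise RuntimeError(f"marker {name!r}: {exc}") from exc
        results.append(ScreenResult(marker=name, or_result=res, n_used=int(keep.sum())))
    results.sort(key=lambda r: (r.or_result.p_value, r.marker))
    return results
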