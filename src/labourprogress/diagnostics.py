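"""Diagnostic accuracy of binary classifiers for severe adverse birth outcomes.

Every classifier in this package (alert line, action line, customised
percentile curves) reduces to a 2x2 contingency table against the outcome.
This module computes the standard accuracy statistics — sensitivity,
specificity, positive/negative likelihood ratios, diagnostic odds ratio and
Youden's J — with 95% confidence intervals, and lays classifiers out as
points in ROC space.

CI conventions: Wilson score intervals for proportions, Woolf's log method
for the odds ratio, Simel's log method for likelihood ratios, and a normal
approximation for J with Var(J) = Var(sens) + Var(spec).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "TwoByTwo",
    "Estimate",
    "AccuracyResult",
    "tabulate",
    "accuracy_stats",
    "roc_space_table",
]

_Z = 1.959963984540054  # 97.5th normal percentile


class Estimate(NamedTuple):
    """Point estimate with a 95% confidence interval."""

    value: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class TwoByTwo:
    """Counts cross-classifying a binary test against the outcome.

    ``tp`` counts classifier-positive women with the outcome present.
    ``n_dropped`` records pairs excluded because either flag was
    not evaluable (e.g. too few active-phase exams).
    """

    tp: int
    fp: int
    fn: int
    tn: int
    n_dropped: int = 0

    def __post_init__(self) -> None:
        cells = (self.tp, self.fp, self.fn, self.tn)
        if any(c < 0 or c != int(c) for c in cells):
            raise ValueError(f"cell counts must be non-negative integers, got {cells}")
        if self.total < 1:
            raise ValueError("2x2 table must contain at least one observation")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class AccuracyResult:
    """Accuracy statistics for one binary classifier."""

    counts: TwoByTwo
    sensitivity: Estimate
    specificity: Estimate
    plr: Estimate
    nlr: Estimate
    dor: Estimate
    youden_j: Estimate

    @property
    def roc_point(self) -> tuple[float, float]:
        """(false-positive rate, true-positive rate)."""
        return (1.0 - self.specificity.value, self.sensitivity.value)


def tabulate(
    classifier_flags: Sequence[float],
    outcome_flags: Sequence[float],
) -> TwoByTwo:
    """Cross-tabulate classifier calls against outcomes.

    Flags are 0/1; NaN (or None) in either vector marks a not-evaluable
    pair, which is dropped and counted in ``n_dropped``.
    """
    c = np.asarray(classifier_flags, dtype=float)
    o = np.asarray(outcome_flags, dtype=float)
    if c.shape != o.shape or c.ndim != 1:
        raise ValueError(
            f"flag vectors must be 1-d and equal length, got {c.shape} and {o.shape}"
        )
    keep = ~(np.isnan(c) | np.isnan(o))
    c, o = c[keep].astype(bool), o[keep].astype(bool)
    return TwoByTwo(
        tp=int(np.sum(c & o)),
        fp=int(np.sum(c & ~o)),
        fn=int(np.sum(~c & o)),
        tn=int(np.sum(~c & ~o)),
        n_dropped=int(np.sum(~keep)),
    )


def _wilson(successes: int, n: int) -> Estimate:
    lo, hi = proportion_confint(successes, n, alpha=0.05, method="wilson")
    return Estimate(successes / n, float(lo), float(hi))


def accuracy_stats(counts: TwoByTwo) -> AccuracyResult:
    """All accuracy statistics, with 95% CIs, from a 2x2 table.

    Ratio statistics (LR+, LR-, DOR) apply the Haldane–Anscombe 0.5
    continuity correction to every cell whenever any cell is zero;
    proportions (sensitivity, specificity, J) always use the raw counts.
    """
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    n_pos, n_neg = tp + fn, fp + tn
    if n_pos < 1 or n_neg < 1:
        raise ValueError(
            "undefined statistic: both outcome margins must be non-empty "
            f"(outcome present={n_pos}, absent={n_neg})"
        )

    sens = _wilson(tp, n_pos)
    spec = _wilson(tn, n_neg)

    # corrected cells for ratio statistics only
    if min(tp, fp, fn, tn) == 0:
        a, b, c, d = tp + 0.5, fp + 0.5, fn + 0.5, tn + 0.5
    else:
        a, b, c, d = float(tp), float(fp), float(fn), float(tn)
    m1, m0 = a + c, b + d

    se_c, sp_c = a / m1, d / m0
    plr_val = se_c / (1.0 - sp_c)
    nlr_val = (1.0 - se_c) / sp_c
    # Simel log-method variances
    var_ln_plr = (1.0 / a - 1.0 / m1) + (1.0 / b - 1.0 / m0)
    var_ln_nlr = (1.0 / c - 1.0 / m1) + (1.0 / d - 1.0 / m0)
    plr = _log_ci(plr_val, var_ln_plr)
    nlr = _log_ci(nlr_val, var_ln_nlr)

    dor_val = (a * d) / (b * c)
    var_ln_dor = 1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d  # Woolf
    dor = _log_ci(dor_val, var_ln_dor)

    j_val = sens.value + spec.value - 1.0
    var_j = (
        sens.value * (1.0 - sens.value) / n_pos
        + spec.value * (1.0 - spec.value) / n_neg
    )
    half = _Z * math.sqrt(var_j)
    youden = Estimate(j_val, j_val - half, j_val + half)

    return AccuracyResult(
        counts=counts,
        sensitivity=sens,
        specificity=spec,
        plr=plr,
        nlr=nlr,
        dor=dor,
        youden_j=youden,
    )


def _log_ci(value: float, var_ln: float) -> Estimate:
    half = _Z * math.sqrt(var_ln)
    ln_v = math.log(value)
    return Estimate(value, math.exp(ln_v - half), math.exp(ln_v + half))


def roc_space_table(results: Mapping[str, AccuracyResult]) -> pd.DataFrame:
    """One ROC-space point per classifier: (name, fpr, tpr, J)."""
    if not results:
        raise ValueError("at least one accuracy result is required")
    rows = []
    for name, res in results.items():
        fpr, tpr = res.roc_point
        rows.append(
            {"classifier": name, "fpr": fpr, "tpr": tpr, "youden_j": res.youden_j.value}
        )
    return pd.DataFrame(rows)


def results_frame(results: Mapping[str, AccuracyResult]) -> pd.DataFrame:
    """Flat machine-readable table of all statistics and CIs."""
    rows = []
    for name, r in results.items():
        c = r.counts
        row: dict[str, object] = {
            "classifier": name,
            "tp": c.tp,
            "fp": c.fp,
            "fn": c.fn,
            "tn": c.tn,
            "n_dropped": c.n_dropped,
        }
        for stat in ("sensitivity", "specificity", "plr", "nlr", "dor", "youden_j"):
            est: Estimate = getattr(r, stat)
            row[stat] = est.value
            row[f"{stat}_lo"] = est.ci_low
            row[f"{stat}_hi"] = est.ci_high
        rows.append(row)
    return pd.DataFrame(rows)


def format_result(r: AccuracyResult) -> str:
    """Human-readable one-liner matching the usual reporting style:
    percentages to one decimal, ratios to two."""

    def pct(e: Estimate) -> str:
        return f"{100 * e.value:.1f}% ({100 * e.ci_low:.1f}-{100 * e.ci_high:.1f})"

    def ratio(e: Estimate) -> str:
        return f"{e.value:.2f} ({e.ci_low:.2f}-{e.ci_high:.2f})"

    return (
        f"sens {pct(r.sensitivity)} | spec {pct(r.specificity)} | "
        f"+LR {ratio(r.plr)} | -LR {ratio(r.nlr)} | "
        f"DOR {ratio(r.dor)} | J {pct(r.youden_j)}"
    )
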