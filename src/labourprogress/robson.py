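"""Robson 10-group classification and the 12 modelled analysis subgroups.

The cohort is stratified into mutually exclusive, totally inclusive
obstetric groups by parity, previous caesarean, onset of labour,
gestational age at childbirth and presentation. The eligible population
here (singleton pregnancies in labour) can only occupy groups 1-5, 10 and
the pooled non-cephalic groups 6/7/9; group 8 (multiples) and pre-labour
caesareans are unreachable. Groups 1-5 and 10 are each split by use of
labour augmentation, giving 12 analysis subgroups for curve fitting;
non-cephalic women remain classified but are excluded from fitting.

Classification order: non-cephalic presentation pools first; then preterm
(< 37 completed weeks at childbirth) assigns group 10; then a previous
caesarean assigns group 5; finally parity x onset splits groups 1-4.
Preterm women with a previous caesarean therefore fall in group 10, since
group 5 is defined at term.
"""

from __future__ import annotations

from typing import Optional

import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "POOLED_679",
    "EXCLUDED",
    "MODELLED_GROUPS",
    "ANALYSIS_SUBGROUPS",
    "classify_robson",
    "assign_subgroup",
    "classify_cohort",
    "RobsonClassifier",
]

POOLED_679 = "pooled_679"
EXCLUDED = "excluded"
MODELLED_GROUPS = ("1", "2", "3", "4", "5", "10")
#: the 12 modelled subgroups: group x augmentation (A = augmented, N = not)
ANALYSIS_SUBGROUPS = tuple(f"{g}{s}" for g in MODELLED_GROUPS for s in ("A", "N"))

TERM_WEEKS = 37.0


class ClassificationError(ValueError):
    """A covariate needed for group assignment is missing or invalid."""


def _require(value, field: str):
    if value is None or (isinstance(value, float) and pd.isna(value)):
        raise ClassificationError(f"cannot classify: missing covariate '{field}'")
    return value


def classify_robson(
    parity: int,
    previous_caesarean: bool,
    onset: str,
    gestational_weeks: float,
    presentation: str,
    plurality: int = 1,
) -> str:
    """Assign one woman to her Robson group.

    Returns one of '1'..'5', '10' or 'pooled_679' (non-cephalic
    presentations, pooled for analysis). Raises ClassificationError on a
    missing covariate and on multiple pregnancy, which is outside the
    eligible population rather than silently classifiable.
    """
    parity = _require(parity, "parity")
    previous_caesarean = _require(previous_caesarean, "previous_caesarean")
    onset = _require(onset, "onset")
    gestational_weeks = _require(gestational_weeks, "gestational_weeks")
    presentation = _require(presentation, "presentation")
    if plurality != 1:
        raise ClassificationError(
            "multiple pregnancy is outside the eligible population"
        )
    if onset not in ("spontaneous", "induced"):
        raise ClassificationError(f"unknown onset '{onset}'")
    if presentation not in ("cephalic", "breech", "transverse"):
        raise ClassificationError(f"unknown presentation '{presentation}'")

    if presentation != "cephalic":
        return POOLED_679
    if gestational_weeks < TERM_WEEKS:
        return "10"
    if parity >= 1 and previous_caesarean:
        return "5"
    if parity == 0:
        return "1" if onset == "spontaneous" else "2"
    return "3" if onset == "spontaneous" else "4"


def assign_subgroup(robson_group: str, augmentation: bool) -> str:
    """Map (Robson group, augmentation flag) to an analysis subgroup label.

    Groups 1-5 and 10 yield e.g. '3A' / '10N'; the pooled non-cephalic
    groups return 'excluded' — those women are never curve-modelled but
    stay in the alert/action-line analyses.
    """
    if robson_group == POOLED_679:
        return EXCLUDED
    if robson_group not in MODELLED_GROUPS:
        raise ClassificationError(f"unknown Robson group '{robson_group}'")
    return f"{robson_group}{'A' if augmentation else 'N'}"


def classify_cohort(women: pd.DataFrame) -> pd.DataFrame:
    """Add robson_group and analysis_subgroup columns to a woman-level table."""
    required = {
        "parity",
        "previous_caesarean",
        "onset",
        "gestational_weeks",
        "presentation",
        "augmentation",
    }
    missing = required - set(women.columns)
    if missing:
        raise ClassificationError(f"woman table lacks columns: {sorted(missing)}")
    out = women.copy()
    out["robson_group"] = [
        classify_robson(
            int(r.parity),
            bool(r.previous_caesarean),
            str(r.onset),
            float(r.gestational_weeks),
            str(r.presentation),
        )
        for r in women.itertuples()
    ]
    out["analysis_subgroup"] = [
        assign_subgroup(g, bool(a))
        for g, a in zip(out["robson_group"], out["augmentation"])
    ]
    return out


class RobsonClassifier(BaseEstimator, TransformerMixin):
    """Transformer adding Robson group / analysis subgroup columns."""

    def fit(self, X: pd.DataFrame, y=None):
        self.is_fitted_ = True
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return classify_cohort(X)
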