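"""WHO partograph alert- and action-line geometry and crossing classification.

The alert line rises at 1 cm/h from the first observed active-phase
dilatation (>= 4 cm); the action line runs parallel, four hours to its
right. A woman "crosses" a line when any observed examination falls
strictly below it. Crossing is evaluated only at observed exam points —
the partograph is read at plotting times, and the panel data carry no
information between exams. Observations exactly on a line do not count
as crossing.
"""

from __future__ import annotations

from typing import NamedTuple, Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator

__all__ = [
    "PartographAnchor",
    "CrossingResult",
    "anchor_active_phase",
    "alert_line_value",
    "action_line_value",
    "crossed_alert_line",
    "crossed_action_line",
    "AlertLineClassifier",
    "ActionLineClassifier",
]

ACTIVE_PHASE_THRESHOLD = 4
FULL_DILATATION = 10
ACTION_LINE_LAG_HOURS = 4.0


class PartographAnchor(NamedTuple):
    """Point through which the alert line is drawn (first exam >= 4 cm)."""

    anchor_time: float
    anchor_dilatation: int


class CrossingResult(NamedTuple):
    crossed: bool
    first_crossing_exam_index: Optional[int]


def as_exam_arrays(exams: Sequence) -> tuple[np.ndarray, np.ndarray]:
    """Validate an exam series and return (times, dilatations) arrays.

    Accepts a sequence of (time_hours, dilatation_cm) pairs or any
    2-column array-like. Times must be non-negative and strictly
    increasing; dilatations integer 0..10 and non-decreasing (the
    progressive model admits no regression).
    """
    arr = np.asarray(exams, dtype=float)
    if arr.size == 0:
        raise ValueError("exam series is empty")
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError(f"exam series must be (n, 2) pairs, got shape {arr.shape}")
    t, d = arr[:, 0], arr[:, 1]
    if np.any(t < 0):
        raise ValueError("exam times must be non-negative")
    if np.any(np.diff(t) <= 0):
        raise ValueError("exam times must be strictly increasing")
    if np.any((d < 0) | (d > FULL_DILATATION) | (d != np.round(d))):
        raise ValueError("dilatations must be integers in 0..10")
    if np.any(np.diff(d) < 0):
        raise ValueError("dilatations must be non-decreasing")
    return t, d.astype(int)


def anchor_active_phase(exams: Sequence) -> Optional[PartographAnchor]:
    """First exam at >= 4 cm, or None if labour is never observed there."""
    t, d = as_exam_arrays(exams)
    idx = np.nonzero(d >= ACTIVE_PHASE_THRESHOLD)[0]
    if idx.size == 0:
        return None
    i = int(idx[0])
    return PartographAnchor(float(t[i]), int(d[i]))


def alert_line_value(anchor: PartographAnchor, t: float) -> float:
    """Expected dilatation on the alert line at time ``t`` (1 cm/h, capped at 10)."""
    if t < anchor.anchor_time:
        raise ValueError(f"t={t} precedes anchor time {anchor.anchor_time}")
    return min(
        float(FULL_DILATATION), anchor.anchor_dilatation + (t - anchor.anchor_time)
    )


def action_line_value(anchor: PartographAnchor, t: float) -> float:
    """Action-line dilatation at time ``t``: the alert line shifted 4 h right.

    Before the lag has elapsed the line imposes no deficit, so the value
    floors at the anchor dilatation (which no later exam can undercut).
    """
    if t < anchor.anchor_time:
        raise ValueError(f"t={t} precedes anchor time {anchor.anchor_time}")
    elapsed = t - anchor.anchor_time - ACTION_LINE_LAG_HOURS
    return min(
        float(FULL_DILATATION), anchor.anchor_dilatation + max(0.0, elapsed)
    )


def _crossed(exams: Sequence, line_value) -> Optional[CrossingResult]:
    t, d = as_exam_arrays(exams)
    anchor = anchor_active_phase(exams)
    if anchor is None:
        return None  # not evaluable: active phase never observed
    anchor_idx = int(np.nonzero(d >= ACTIVE_PHASE_THRESHOLD)[0][0])
    for i in range(anchor_idx + 1, len(t)):
        if d[i] < line_value(anchor, t[i]):
            return CrossingResult(True, i)
    return CrossingResult(False, None)


def crossed_alert_line(exams: Sequence) -> Optional[CrossingResult]:
    """Whether any post-anchor exam falls strictly below the alert line.

    Returns None (not evaluable) when no exam reaches the active phase.
    """
    return _crossed(exams, alert_line_value)


def crossed_action_line(exams: Sequence) -> Optional[CrossingResult]:
    """Whether any post-anchor exam falls strictly below the action line."""
    return _crossed(exams, action_line_value)


def n_active_phase_exams(exams: Sequence) -> int:
    """Number of exams between 4 cm and childbirth (dilatation in [4, 10])."""
    _, d = as_exam_arrays(exams)
    return int(np.sum(d >= ACTIVE_PHASE_THRESHOLD))


class _LineClassifier(BaseEstimator):
    """Shared machinery for the alert/action line classifiers.

    ``predict`` maps a list of exam series to 1 (crossed) / 0 (not crossed)
    / NaN (not evaluable: no active-phase anchor, or fewer than
    ``min_active_exams`` exams between 4 cm and childbirth).
    """

    _line = staticmethod(crossed_alert_line)

    def __init__(self, min_active_exams: int = 2):
        self.min_active_exams = min_active_exams

    def fit(self, X=None, y=None):
        """No-op: the line is fixed by convention, not learned."""
        if self.min_active_exams < 1:
            raise ValueError("min_active_exams must be >= 1")
        self.is_fitted_ = True
        return self

    def predict(self, X: Sequence[Sequence]) -> np.ndarray:
        self.fit()
        out = np.full(len(X), np.nan)
        for i, exams in enumerate(X):
            if n_active_phase_exams(exams) < self.min_active_exams:
                continue
            res = type(self)._line(exams)
            if res is not None:
                out[i] = float(res.crossed)
        return out


class AlertLineClassifier(_LineClassifier):
    """Binary classifier: did the woman cross the WHO alert line?"""

    _line = staticmethod(crossed_alert_line)


class ActionLineClassifier(_LineClassifier):
    """Binary classifier: did the woman cross the WHO action line?"""

    _line = staticmethod(crossed_action_line)
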