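"""Progressive multi-state Markov model of cervical dilatation.

Each centimetre of dilatation from 2 to 10 cm is a transient state and
childbirth is the absorbing state; the chain moves one centimetre at a
time, never backwards, so the generator Q is upper-bidiagonal with one
transition intensity lambda_i per transient state. Dilatation is panel
data: it is observed only at irregular examination times, so the
likelihood of an observation pair (s_a, t_a) -> (s_b, t_b) is the
transition probability P_{s_a s_b}(t_b - t_a), and the first-passage time
from 4 cm to d cm is hypoexponential with rates lambda_4 .. lambda_{d-1}.
Percentile labour curves are first-passage-time quantiles of the fitted
chain, one curve per obstetric subgroup and percentile.

Transition probabilities use the closed-form hypoexponential expression
when the rates are well separated, and fall back to the matrix
exponential of the sub-generator when near-ties would make the
closed-form weights numerically unstable (including the exactly-equal,
Erlang, case).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
from scipy.linalg import expm
from scipy.optimize import brentq, minimize
from scipy.special import gammaln
from sklearn.base import BaseEstimator

from .partograph import CrossingResult, anchor_active_phase, as_exam_arrays

__all__ = [
    "BIRTH_STATE",
    "ProgressiveModel",
    "FitResult",
    "PercentileCurve",
    "FitError",
    "DataError",
    "build_generator",
    "transition_matrix",
    "panel_log_likelihood",
    "fit_rates",
    "first_passage_quantile",
    "percentile_curve",
    "crossed_percentile_curve",
    "ProgressiveMarkovModel",
]

#: integer code for the absorbing childbirth state in observation arrays
BIRTH_STATE = 11
FULL_DILATATION = 10
PERCENTILES = (50, 60, 70, 80, 90, 95)

# closed-form hypoexponential weights beyond this magnitude lose enough
# significant digits to matter; switch to the matrix-exponential path
_WEIGHT_LIMIT = 1e6
_LOG_FLOOR = 1e-300


class FitError(RuntimeError):
    """Raised when the panel data cannot support a rate fit."""


class DataError(ValueError):
    """Raised on invalid observation series (e.g. dilatation regression)."""


@dataclass(frozen=True)
class ProgressiveModel:
    """Fitted (or specified) progressive chain.

    ``states`` are the transient dilatation states in ascending order,
    contiguous and ending at 10 cm; ``rates[i]`` is the intensity of
    leaving ``states[i]`` for the next state (the last one feeds the
    absorbing childbirth state).
    """

    states: tuple[int, ...]
    rates: np.ndarray

    def __post_init__(self) -> None:
        states = tuple(int(s) for s in self.states)
        rates = np.asarray(self.rates, dtype=float)
        object.__setattr__(self, "states", states)
        object.__setattr__(self, "rates", rates)
        if len(states) == 0 or len(states) != len(rates):
            raise ValueError("states and rates must be non-empty and equal length")
        if states[-1] != FULL_DILATATION or list(states) != list(
            range(states[0], FULL_DILATATION + 1)
        ):
            raise ValueError("states must be contiguous and end at 10 cm")
        if np.any(~np.isfinite(rates)) or np.any(rates <= 0):
            raise ValueError("all transition intensities must be positive and finite")

    def rate_of(self, state: int) -> float:
        return float(self.rates[state - self.states[0]])

    @property
    def generator(self) -> np.ndarray:
        return build_generator(self.rates)


@dataclass(frozen=True)
class FitResult:
    model: Optional[ProgressiveModel]
    log_likelihood: float
    converged: bool
    n_transitions_used: int


@dataclass(frozen=True)
class PercentileCurve:
    """Time (hours from 4 cm) to reach each dilatation, at one percentile."""

    subgroup: str
    percentile: int
    points: Mapping[int, float] = field(default_factory=dict)

    def time_to(self, dilatation: int) -> float:
        if dilatation == 4:
            return 0.0
        return self.points[int(dilatation)]


def build_generator(rates: Sequence[float]) -> np.ndarray:
    """Upper-bidiagonal generator for a progressive chain plus absorbing state."""
    lam = np.asarray(rates, dtype=float)
    if lam.ndim != 1 or lam.size == 0:
        raise ValueError("rates must be a non-empty 1-d sequence")
    if np.any(~np.isfinite(lam)) or np.any(lam <= 0):
        raise ValueError(f"all rates must be positive and finite, got {lam}")
    k = lam.size
    Q = np.zeros((k + 1, k + 1))
    Q[np.arange(k), np.arange(k)] = -lam
    Q[np.arange(k), np.arange(1, k + 1)] = lam
    return Q


def transition_matrix(Q: np.ndarray, dt: float) -> np.ndarray:
    """P(dt) = exp(Q dt) for a valid generator matrix."""
    if dt < 0:
        raise ValueError(f"time increment must be non-negative, got {dt}")
    return expm(np.asarray(Q, dtype=float) * dt)


def _hypoexp_weights(rates: np.ndarray) -> Optional[np.ndarray]:
    """Partial-fraction weights for the hypoexponential survival function,
    or None when near-equal rates make them unusable."""
    denom = rates[None, :] - rates[:, None]  # [l, m] = lam_m - lam_l
    np.fill_diagonal(denom, 1.0)
    if np.any(denom == 0.0):
        return None
    ratio = rates[None, :] / denom  # [l, m] = lam_m / (lam_m - lam_l)
    np.fill_diagonal(ratio, 1.0)
    w = np.prod(ratio, axis=1)
    if np.max(np.abs(w)) > _WEIGHT_LIMIT:
        return None
    return w


def _hypoexp_cdf(rates: Sequence[float], t: Union[float, np.ndarray]) -> np.ndarray:
    """CDF of a sum of independent exponentials with the given rates.

    Vectorised over ``t``. An empty rate vector is the degenerate
    zero-duration sum (CDF identically 1 for t >= 0).
    """
    lam = np.asarray(rates, dtype=float)
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t < 0):
        raise ValueError("hypoexponential CDF evaluated at negative time")
    if lam.size == 0:
        return np.ones_like(t)
    if lam.size == 1:
        return -np.expm1(-lam[0] * t)
    w = _hypoexp_weights(lam)
    if w is not None:
        out = 1.0 - np.exp(-np.outer(t, lam)) @ w
        return np.clip(out, 0.0, 1.0)
    return _uniformized_cdf(lam, t)


def _uniformized_cdf(lam: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Hypoexponential CDF by uniformization of the progressive sub-chain.

    Stable for tied or near-tied rates (all terms non-negative): with
    uniformization rate q >= max(lam), F(t) = sum_k Pois(k; q t) a_k where
    a_k is the absorption probability after k jumps of the discrete chain
    I + Q/q, accumulated by repeated left-multiplication of the initial
    row vector.
    """
    q = float(np.max(lam)) * 1.0001
    qt_max = q * float(np.max(t))
    K = int(np.ceil(qt_max + 10.0 * np.sqrt(qt_max + 1.0) + 25.0))
    Pu = np.eye(lam.size + 1) + build_generator(lam) / q
    v = np.zeros(lam.size + 1)
    v[0] = 1.0
    absorbed = [v[-1]]
    # absorption probabilities saturate quickly when q ~ all rates; stop
    # there (or at a hard cap) and fold the Poisson tail in analytically
    for _ in range(min(K, 100_000)):
        v = v @ Pu
        absorbed.append(v[-1])
        if v[-1] > 1.0 - 1e-14:
            break
    a = np.asarray(absorbed)
    ks = np.arange(a.size)
    qt = q * t
    with np.errstate(divide="ignore", invalid="ignore"):
        logw = (
            ks[None, :] * np.log(qt[:, None])
            - qt[:, None]
            - gammaln(ks + 1.0)[None, :]
        )
        out = np.exp(logw) @ a
    # Poisson mass beyond the truncation point, weighted by the last
    # (non-decreasing) absorption probability
    from scipy.stats import poisson

    out = np.where(qt > 0.0, out + poisson.sf(a.size - 1, qt) * a[-1], 0.0)
    return np.clip(np.nan_to_num(out, nan=0.0), 0.0, 1.0)


def _pair_prob(
    model: ProgressiveModel, sa: int, sb: int, dt: np.ndarray
) -> np.ndarray:
    """P_{sa,sb}(dt) vectorised over dt, for sb a state or BIRTH_STATE."""
    lo = model.states[0]
    if sa < lo or sa > FULL_DILATATION:
        raise DataError(f"state {sa} outside model support [{lo}, 10]")
    i = sa - lo
    if sb == BIRTH_STATE:
        return _hypoexp_cdf(model.rates[i:], dt)
    j = sb - lo
    if sb < sa:
        raise DataError(f"regression {sa} -> {sb} is impossible in a progressive chain")
    # prob of having reached sb but not sb+1 (or birth, beyond 10 cm)
    reached = _hypoexp_cdf(model.rates[i:j], dt)
    passed = _hypoexp_cdf(model.rates[i : j + 1], dt)
    return np.clip(reached - passed, 0.0, 1.0)


def _series_to_pairs(series_collection) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Flatten a collection of (time, state) series into consecutive-pair arrays.

    Accepts a list of (n, 2) arrays or a mapping id -> array; mapping keys
    label error messages.
    """
    if isinstance(series_collection, Mapping):
        items = list(series_collection.items())
    else:
        items = list(enumerate(series_collection))
    sa_all, sb_all, dt_all = [], [], []
    for key, series in items:
        arr = np.asarray(series, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
            raise DataError(
                f"series {key!r}: need an (n>=2, 2) array of (time, state)"
            )
        t, s = arr[:, 0], arr[:, 1]
        if np.any(np.diff(t) <= 0):
            raise DataError(f"series {key!r}: observation times must strictly increase")
        if np.any(np.diff(s) < 0):
            raise DataError(
                f"series {key!r}: dilatation regression observed (invalid upstream)"
            )
        if np.any(s != np.round(s)):
            raise DataError(f"series {key!r}: states must be integers")
        sa_all.append(s[:-1])
        sb_all.append(s[1:])
        dt_all.append(np.diff(t))
    return (
        np.concatenate(sa_all).astype(int),
        np.concatenate(sb_all).astype(int),
        np.concatenate(dt_all),
    )


def _group_pairs(
    sa: np.ndarray, sb: np.ndarray, dt: np.ndarray
) -> list[tuple[int, int, np.ndarray]]:
    return [
        (a, b, dt[(sa == a) & (sb == b)])
        for a, b in sorted({(int(a), int(b)) for a, b in zip(sa, sb)})
    ]


def _grouped_log_likelihood(
    model: ProgressiveModel, groups: Sequence[tuple[int, int, np.ndarray]]
) -> float:
    lo = model.states[0]
    ll = 0.0
    for a, b, dts in groups:
        if a == b:  # stayed put: exact exponential survival, no inversion
            ll += -model.rates[a - lo] * float(np.sum(dts))
            continue
        p = _pair_prob(model, a, b, dts)
        ll += float(np.sum(np.log(np.maximum(p, _LOG_FLOOR))))
    return ll


def _pairs_log_likelihood(
    model: ProgressiveModel, sa: np.ndarray, sb: np.ndarray, dt: np.ndarray
) -> float:
    return _grouped_log_likelihood(model, _group_pairs(sa, sb, dt))


def panel_log_likelihood(model: ProgressiveModel, series_collection) -> float:
    """Log-likelihood of panel-observed series under the progressive chain.

    Every consecutive observation pair — including the final transition
    into the absorbing birth state, when observed — contributes
    log P_{s_a s_b}(t_b - t_a). Series must be individually monotone.
    """
    sa, sb, dt = _series_to_pairs(series_collection)
    return _pairs_log_likelihood(model, sa, sb, dt)


def _spanning_counts(sa: np.ndarray, sb: np.ndarray) -> dict[int, int]:
    """Number of observed state-change pairs whose interval covers each state."""
    counts: dict[int, int] = {}
    for a, b in zip(sa, sb):
        top = min(int(b), BIRTH_STATE) - 1 if b != a else int(a) - 1
        for s in range(int(a), min(top, FULL_DILATATION) + 1):
            counts[s] = counts.get(s, 0) + 1
    return counts


def _moment_init(
    groups: Sequence[tuple[int, int, np.ndarray]], lo: int, k: int
) -> np.ndarray:
    """Crude per-state rate estimates: spanning transitions over a uniform
    allocation of interval time across spanned states. Starting close to
    the optimum keeps the quasi-Newton iteration short."""
    n_span = np.zeros(k)
    t_at_risk = np.zeros(k)
    for a, b, dts in groups:
        if a == b:
            t_at_risk[a - lo] += float(np.sum(dts))
            continue
        span = range(a - lo, min(b, FULL_DILATATION + 1) - lo)
        share = float(np.sum(dts)) / len(span)
        for i in span:
            n_span[i] += dts.size
            t_at_risk[i] += share
    overall = max(np.sum(n_span) / max(np.sum(t_at_risk), 1e-9), 1e-2)
    with np.errstate(divide="ignore", invalid="ignore"):
        rates = np.where(t_at_risk > 0, n_span / t_at_risk, overall)
    return np.clip(np.nan_to_num(rates, nan=overall), 0.05, 20.0)


def fit_rates(
    series_collection,
    init_rates: Optional[Sequence[float]] = None,
    *,
    min_transitions: int = 5,
    highest_required_state: int = 4,
    gtol: float = 1e-5,
    n_starts: int = 3,
    random_state: int = 0,
) -> FitResult:
    """Maximum-likelihood transition intensities from panel data.

    The model support is the contiguous state range ending at 10 cm whose
    every state is spanned by at least ``min_transitions`` observed
    state-change intervals; sparser low states (below
    ``highest_required_state``) are trimmed, and observation pairs lying
    below or straddling the trimmed boundary are dropped. If a state at or
    above ``highest_required_state`` is undersupported, the fit fails with
    a FitError naming it. Optimisation is quasi-Newton (L-BFGS-B) over log
    rates with ``n_starts`` jittered restarts; non-convergence is flagged
    on the result, not raised.
    """
    sa, sb, dt = _series_to_pairs(series_collection)
    moved = sb > sa
    counts = _spanning_counts(sa[moved], sb[moved])
    lo = FULL_DILATATION
    while lo - 1 >= 2 and counts.get(lo - 1, 0) >= min_transitions:
        lo -= 1
    for s in range(min(lo, highest_required_state), FULL_DILATATION + 1):
        if counts.get(s, 0) < min_transitions:
            raise FitError(
                f"state {s} cm has {counts.get(s, 0)} observed transitions; "
                f"at least {min_transitions} required"
            )
    keep = sa >= lo
    sa, sb, dt = sa[keep], sb[keep], dt[keep]
    n_used = int(np.sum(sb > sa))

    k = FULL_DILATATION - lo + 1
    groups = _group_pairs(sa, sb, dt)
    states = tuple(range(lo, FULL_DILATATION + 1))

    if init_rates is not None:
        base = np.asarray(init_rates, dtype=float)
        if base.size != k or np.any(base <= 0):
            raise ValueError(f"init_rates must be {k} positive values")
    else:
        base = _moment_init(groups, lo, k)

    def nll(theta: np.ndarray) -> float:
        model = ProgressiveModel(states, np.exp(theta))
        return -_grouped_log_likelihood(model, groups)

    # rates bounded to a clinically meaningful range: mean sojourns
    # between one minute and ~1000 hours per centimetre
    bounds = [(np.log(1e-3), np.log(60.0))] * k
    rng = np.random.default_rng(random_state)
    best = None
    for start in range(max(n_starts, 1)):
        theta0 = np.log(base)
        if start > 0:
            theta0 = theta0 + rng.normal(0.0, 0.3, size=k)
        res = minimize(
            nll,
            np.clip(theta0, bounds[0][0], bounds[0][1]),
            method="L-BFGS-B",
            bounds=bounds,
            options={"gtol": gtol, "eps": 1e-6, "maxiter": 500},
        )
        if best is None or res.fun < best.fun:
            best = res
    model = ProgressiveModel(states, np.exp(best.x))
    return FitResult(
        model=model,
        log_likelihood=-float(best.fun),
        converged=bool(best.success),
        n_transitions_used=n_used,
    )


def first_passage_quantile(
    model: ProgressiveModel, to_state: int, p: float, from_state: int = 4
) -> float:
    """p-th quantile (hours) of the first-passage time from_state -> to_state.

    Inverts the hypoexponential CDF of the intervening rates numerically
    (absolute tolerance well below 1e-6 h).
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"quantile level must be in (0, 1), got {p}")
    if not (model.states[0] <= from_state < to_state <= FULL_DILATATION):
        raise ValueError(
            f"need support[0] <= from_state < to_state <= 10, "
            f"got {from_state} -> {to_state}"
        )
    i = from_state - model.states[0]
    j = to_state - model.states[0]
    lam = model.rates[i:j]
    mean = float(np.sum(1.0 / lam))
    hi = mean + 10.0 * float(np.sqrt(np.sum(1.0 / lam**2)))
    while _hypoexp_cdf(lam, hi)[0] < p:
        hi *= 2.0
    return float(
        brentq(lambda t: _hypoexp_cdf(lam, t)[0] - p, 0.0, hi, xtol=1e-9)
    )


def percentile_curve(
    model: ProgressiveModel, subgroup: str, percentile: int
) -> PercentileCurve:
    """Customised labour curve: hours from 4 cm to each dilatation 5..10."""
    if not 0 < percentile < 100:
        raise ValueError(f"percentile must be in (0, 100), got {percentile}")
    if model.states[0] > 4:
        raise FitError(
            f"model support starts at {model.states[0]} cm; curves need 4 cm"
        )
    points = {
        d: first_passage_quantile(model, d, percentile / 100.0)
        for d in range(5, FULL_DILATATION + 1)
    }
    return PercentileCurve(subgroup=subgroup, percentile=percentile, points=points)


def crossed_percentile_curve(
    exams: Sequence, curve: PercentileCurve
) -> Optional[CrossingResult]:
    """Did the woman progress more slowly than the percentile curve?

    The time origin is the first exam at >= 4 cm; when that anchor exam is
    above 4 cm, elapsed times are offset by the curve's own time to the
    anchor dilatation, so the woman is compared with a reference labour
    that reached her anchor at the percentile speed. She crosses when, at
    any later exam showing dilatation d, the offset elapsed time strictly
    exceeds the curve's time from 4 cm to d. Returns None when no exam
    reaches the active phase.
    """
    t, d = as_exam_arrays(exams)
    anchor = anchor_active_phase(exams)
    if anchor is None:
        return None
    offset = curve.time_to(anchor.anchor_dilatation)
    anchor_idx = int(np.nonzero(d >= 4)[0][0])
    for i in range(anchor_idx + 1, len(t)):
        elapsed = t[i] - anchor.anchor_time + offset
        if elapsed > curve.time_to(int(d[i])):
            return CrossingResult(True, i)
    return CrossingResult(False, None)


class ProgressiveMarkovModel(BaseEstimator):
    """Scikit-learn style estimator for the progressive dilatation chain.

    ``fit`` consumes a collection of panel-observed series — each an
    (n, 2) array of (hours, state) with states in 2..10 and 11 for
    childbirth — and exposes the fitted intensities and derived
    first-passage quantiles / percentile curves.
    """

    def __init__(
        self,
        init_rates: Optional[Sequence[float]] = None,
        min_transitions: int = 5,
        highest_required_state: int = 4,
        gtol: float = 1e-5,
        n_starts: int = 3,
        random_state: int = 0,
    ):
        self.init_rates = init_rates
        self.min_transitions = min_transitions
        self.highest_required_state = highest_required_state
        self.gtol = gtol
        self.n_starts = n_starts
        self.random_state = random_state

    def fit(self, X, y=None):
        result = fit_rates(
            X,
            init_rates=self.init_rates,
            min_transitions=self.min_transitions,
            highest_required_state=self.highest_required_state,
            gtol=self.gtol,
            n_starts=self.n_starts,
            random_state=self.random_state,
        )
        self.model_ = result.model
        self.states_ = result.model.states
        self.rates_ = result.model.rates
        self.log_likelihood_ = result.log_likelihood
        self.converged_ = result.converged
        self.n_transitions_used_ = result.n_transitions_used
        return self

    def _check_fitted(self) -> ProgressiveModel:
        if not hasattr(self, "model_"):
            raise FitError("model is not fitted; call fit first")
        return self.model_

    def score(self, X, y=None) -> float:
        """Panel log-likelihood of new series under the fitted chain."""
        return panel_log_likelihood(self._check_fitted(), X)

    def transition_matrix(self, dt: float) -> np.ndarray:
        return transition_matrix(self._check_fitted().generator, dt)

    def first_passage_quantile(
        self, to_state: int, p: float, from_state: int = 4
    ) -> float:
        return first_passage_quantile(self._check_fitted(), to_state, p, from_state)

    def percentile_curve(self, percentile: int, subgroup: str = "") -> PercentileCurve:
        return percentile_curve(self._check_fitted(), subgroup, percentile)
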