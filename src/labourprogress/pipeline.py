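"""End-to-end analysis: classify, fit customised curves, evaluate accuracy.

The flow mirrors the study design: stratify the cohort into Robson groups
and the 12 augmentation-split analysis subgroups; evaluate alert/action
line crossing for every woman with at least two active-phase exams; fit
one progressive Markov model per subgroup on women free of severe adverse
outcomes; derive percentile labour curves (50th-95th); classify every
woman against her own subgroup's curves; and consolidate each classifier
into a 2x2 table against severe adverse outcomes with full accuracy
statistics and a ROC-space layout.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import diagnostics, markov, partograph, robson
from .markov import BIRTH_STATE, PercentileCurve, ProgressiveModel
from .synthetic import EXAM_COLUMNS, WOMAN_COLUMNS

__all__ = [
    "AnalysisConfig",
    "RunReport",
    "run_analysis",
    "plot_outputs",
    "save_report",
    "PercentileCurveClassifier",
]

log = logging.getLogger("labourprogress")

DEFAULT_PERCENTILES = (50, 60, 70, 80, 90, 95)


@dataclass(frozen=True)
class AnalysisConfig:
    percentiles: tuple[int, ...] = DEFAULT_PERCENTILES
    min_exams_active_phase: int = 2
    fit_on_outcome_free_only: bool = True
    min_transitions: int = 5
    n_starts: int = 3
    random_state: int = 0

    def validate(self) -> None:
        if not self.percentiles:
            raise ValueError("at least one percentile is required")
        if any(not 0 < p < 100 for p in self.percentiles):
            raise ValueError("percentiles must lie in (0, 100)")
        if self.min_exams_active_phase < 2:
            raise ValueError("min_exams_active_phase must be >= 2")


@dataclass
class RunReport:
    n_input: int
    counts: dict[str, int]
    fits: pd.DataFrame
    curves: pd.DataFrame
    crossing: pd.DataFrame
    accuracy: dict[str, diagnostics.AccuracyResult]
    accuracy_table: pd.DataFrame
    roc_table: pd.DataFrame
    skipped_subgroups: dict[str, str] = field(default_factory=dict)
    women: Optional[pd.DataFrame] = None  # annotated woman table


def _validate_schema(women: pd.DataFrame, exams: pd.DataFrame) -> None:
    problems = []
    for name, df, cols in (("woman", women, WOMAN_COLUMNS), ("exam", exams, EXAM_COLUMNS)):
        missing = set(cols) - set(df.columns)
        if missing:
            problems.append(f"{name} table missing columns {sorted(missing)}")
    if problems:
        raise ValueError("; ".join(problems))
    orphans = ~exams["id"].isin(set(women["id"]))
    if orphans.any():
        rows = list(exams.index[orphans][:10])
        problems.append(f"exam rows with unknown woman id at lines {rows}")
    if problems:
        raise ValueError("; ".join(problems))


def build_exam_series(exams: pd.DataFrame) -> dict[str, np.ndarray]:
    """Per-woman (time, dilatation) arrays, validated; errors cite rows."""
    series: dict[str, np.ndarray] = {}
    bad: list[str] = []
    for wid, grp in exams.groupby("id", sort=False):
        arr = grp[["time_hours", "dilatation_cm"]].to_numpy(dtype=float)
        try:
            partograph.as_exam_arrays(arr)
        except ValueError as err:
            bad.append(f"{wid} (rows {list(grp.index[:5])}): {err}")
            continue
        series[str(wid)] = arr
    if bad:
        raise ValueError("invalid exam series: " + "; ".join(bad[:10]))
    return series


def _fit_series(
    women: pd.DataFrame,
    series: Mapping[str, np.ndarray],
    subgroup: str,
    outcome_free_only: bool,
) -> list[np.ndarray]:
    """Observation series used to fit one subgroup's model.

    Fitting is anchored in the active phase: exams below 4 cm are observed
    only at admission, leave the sub-4 intensities essentially
    unidentified, and play no role in the curves, so they are dropped.
    Vaginal births append a final transition into the absorbing state at
    the recorded birth time. Caesarean deliveries are right-truncated at
    the decision time, so their series simply end at the last exam.
    """
    rows = women[women["analysis_subgroup"] == subgroup]
    if outcome_free_only:
        rows = rows[rows["severe_adverse_outcome"] == 0]
    out = []
    for r in rows.itertuples():
        arr = series.get(r.id)
        if arr is None:
            continue
        arr = arr[arr[:, 1] >= 4.0]
        obs = list(map(tuple, arr))
        if not r.caesarean and obs and r.birth_time > obs[-1][0]:
            obs.append((float(r.birth_time), float(BIRTH_STATE)))
        if len(obs) >= 2:
            out.append(np.asarray(obs))
    return out


def fit_subgroup_models(
    women: pd.DataFrame,
    series: Mapping[str, np.ndarray],
    config: AnalysisConfig,
) -> tuple[dict[str, markov.FitResult], dict[str, str]]:
    """One progressive-chain fit per modelled analysis subgroup."""
    fits: dict[str, markov.FitResult] = {}
    skipped: dict[str, str] = {}
    for subgroup in robson.ANALYSIS_SUBGROUPS:
        data = _fit_series(women, series, subgroup, config.fit_on_outcome_free_only)
        if not data:
            skipped[subgroup] = "no usable exam series"
            log.warning("subgroup %s: no usable exam series; curves skipped", subgroup)
            continue
        try:
            fits[subgroup] = markov.fit_rates(
                data,
                min_transitions=config.min_transitions,
                n_starts=config.n_starts,
                random_state=config.random_state,
            )
        except markov.FitError as err:
            skipped[subgroup] = str(err)
            log.warning("subgroup %s: %s; curves skipped", subgroup, err)
    return fits, skipped


def _percentile_flags(
    women: pd.DataFrame,
    series: Mapping[str, np.ndarray],
    curves: Mapping[str, Mapping[int, PercentileCurve]],
    percentile: int,
    eligible: np.ndarray,
) -> np.ndarray:
    flags = np.full(len(women), np.nan)
    for i, r in enumerate(women.itertuples()):
        if not eligible[i]:
            continue
        sub_curves = curves.get(r.analysis_subgroup)
        if sub_curves is None or percentile not in sub_curves:
            continue
        res = markov.crossed_percentile_curve(series[r.id], sub_curves[percentile])
        if res is not None:
            flags[i] = float(res.crossed)
    return flags


def run_analysis(
    women: pd.DataFrame,
    exams: pd.DataFrame,
    config: Optional[AnalysisConfig] = None,
) -> RunReport:
    """Full analysis on a cohort; see the module docstring for the flow."""
    config = config or AnalysisConfig()
    config.validate()
    _validate_schema(women, exams)
    women = robson.classify_cohort(women).reset_index(drop=True)
    series = build_exam_series(exams)

    n_input = len(women)
    n_active = np.array(
        [
            partograph.n_active_phase_exams(series[r.id]) if r.id in series else 0
            for r in women.itertuples()
        ]
    )
    eligible = n_active >= config.min_exams_active_phase
    counts = {
        "input": n_input,
        "with_exam_series": int(sum(1 for r in women.itertuples() if r.id in series)),
        "eligible_line_analysis": int(eligible.sum()),
        "excluded_too_few_active_exams": int((~eligible).sum()),
    }
    log.info(
        "cohort: %d women, %d eligible for line analyses",
        n_input,
        counts["eligible_line_analysis"],
    )

    flags: dict[str, np.ndarray] = {}
    series_list = [series.get(r.id, [(0.0, 0)]) for r in women.itertuples()]
    alert = partograph.AlertLineClassifier(config.min_exams_active_phase)
    action = partograph.ActionLineClassifier(config.min_exams_active_phase)
    flags["alert_line"] = alert.fit().predict(series_list)
    flags["action_line"] = action.fit().predict(series_list)

    fit_results, skipped = fit_subgroup_models(women, series, config)
    curves: dict[str, dict[int, PercentileCurve]] = {}
    curve_rows = []
    fit_rows = []
    for subgroup, fr in fit_results.items():
        model = fr.model
        fit_rows.append(
            {
                "subgroup": subgroup,
                **{f"rate_{s}cm": model.rate_of(s) for s in model.states},
                "log_likelihood": fr.log_likelihood,
                "converged": fr.converged,
                "n_transitions_used": fr.n_transitions_used,
            }
        )
        try:
            curves[subgroup] = {
                p: markov.percentile_curve(model, subgroup, p)
                for p in config.percentiles
            }
        except markov.FitError as err:
            skipped[subgroup] = str(err)
            log.warning("subgroup %s: %s", subgroup, err)
            continue
        for p, curve in curves[subgroup].items():
            curve_rows.extend(
                {
                    "subgroup": subgroup,
                    "percentile": p,
                    "dilatation_cm": d,
                    "hours_from_4cm": h,
                }
                for d, h in sorted(curve.points.items())
            )

    for p in config.percentiles:
        flags[f"p{p}_curve"] = _percentile_flags(women, series, curves, p, eligible)

    outcome = women["severe_adverse_outcome"].to_numpy(dtype=float)
    accuracy: dict[str, diagnostics.AccuracyResult] = {}
    for name, f in flags.items():
        counts2x2 = diagnostics.tabulate(f, outcome)
        try:
            accuracy[name] = diagnostics.accuracy_stats(counts2x2)
        except ValueError as err:
            log.warning("classifier %s not evaluable: %s", name, err)

    crossing = pd.DataFrame(
        {
            "id": women["id"],
            **{
                name.replace("_line", "_crossed").replace("_curve", "_crossed"): f
                for name, f in flags.items()
            },
        }
    )
    report = RunReport(
        n_input=n_input,
        counts=counts,
        fits=pd.DataFrame(fit_rows),
        curves=pd.DataFrame(curve_rows),
        crossing=crossing,
        accuracy=accuracy,
        accuracy_table=diagnostics.results_frame(accuracy),
        roc_table=diagnostics.roc_space_table(accuracy),
        skipped_subgroups=skipped,
        women=women,
    )
    return report


def save_report(report: RunReport, out_dir) -> None:
    """Write machine-readable outputs: CSV tables and a JSON run summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.accuracy_table.to_csv(out / "accuracy_table.csv", index=False)
    report.roc_table.to_csv(out / "roc_space.csv", index=False)
    report.curves.to_csv(out / "curves.csv", index=False)
    report.fits.to_csv(out / "models.csv", index=False)
    report.crossing.to_csv(out / "crossing.csv", index=False)
    if report.women is not None:
        report.women.to_csv(out / "women_classified.csv", index=False)
    summary = {
        "n_input": report.n_input,
        "counts": report.counts,
        "skipped_subgroups": report.skipped_subgroups,
        "classifiers": {
            name: {
                "tp": r.counts.tp,
                "fp": r.counts.fp,
                "fn": r.counts.fn,
                "tn": r.counts.tn,
                "n_dropped": r.counts.n_dropped,
                "sensitivity": r.sensitivity.value,
                "specificity": r.specificity.value,
                "dor": r.dor.value,
                "youden_j": r.youden_j.value,
            }
            for name, r in report.accuracy.items()
        },
    }
    with open(out / "run_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)


def plot_outputs(
    report: RunReport,
    women: pd.DataFrame,
    exams: pd.DataFrame,
    out_dir,
    max_spaghetti: int = 2000,
) -> list[Path]:
    """Best-effort plots: spaghetti dilatation-vs-time, 95th-percentile
    curve panel, and the ROC-space scatter with the chance diagonal."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    series = build_exam_series(exams)
    outcome = dict(zip(women["id"], women["severe_adverse_outcome"]))
    fig, ax = plt.subplots(figsize=(8, 5))
    shown = 0
    for wid, arr in series.items():
        if np.sum(arr[:, 1] >= 4) < 2:
            continue
        if shown >= max_spaghetti and not outcome.get(wid):
            continue
        adverse = bool(outcome.get(wid))
        ax.plot(
            arr[:, 0],
            arr[:, 1],
            color="crimson" if adverse else "0.75",
            alpha=0.9 if adverse else 0.25,
            lw=1.2 if adverse else 0.6,
            zorder=2 if adverse else 1,
        )
        shown += 1
    ax.set_xlabel("hours since admission")
    ax.set_ylabel("cervical dilatation (cm)")
    ax.set_title("Labour progress (red: severe adverse outcome)")
    fig.tight_layout()
    p = out / "spaghetti.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)

    if not report.curves.empty:
        fig, ax = plt.subplots(figsize=(7, 5))
        panel_p = int(report.curves["percentile"].max())
        sel = report.curves[report.curves["percentile"] == panel_p]
        for subgroup, grp in sel.groupby("subgroup"):
            if not str(subgroup).endswith("N"):
                continue
            ax.plot(
                [0.0, *grp["hours_from_4cm"]],
                [4, *grp["dilatation_cm"]],
                marker="o",
                ms=3,
                label=str(subgroup),
            )
        ax.set_xlabel("hours from 4 cm")
        ax.set_ylabel("cervical dilatation (cm)")
        ax.set_ylim(4, 10.2)
        ax.set_title(f"{panel_p}th-percentile labour curves (no augmentation)")
        if ax.get_legend_handles_labels()[0]:
            ax.legend(fontsize=8)
        fig.tight_layout()
        p = out / "percentile_curves.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)

    fig, ax = plt.subplots(figsize=(5.5, 5.5))
    ax.plot([0, 1], [0, 1], ls="--", color="0.5", lw=1)
    for r in report.roc_table.itertuples():
        ax.scatter(r.fpr, r.tpr, s=30)
        ax.annotate(r.classifier, (r.fpr, r.tpr), fontsize=7, xytext=(3, 3),
                    textcoords="offset points")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.set_xlabel("false-positive rate (1 - specificity)")
    ax.set_ylabel("true-positive rate (sensitivity)")
    ax.set_title("ROC space")
    fig.tight_layout()
    p = out / "roc_space.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)
    return written


class PercentileCurveClassifier(BaseEstimator):
    """Binary classifier: labour slower than the subgroup's percentile curve.

    ``fit(women, exams)`` fits one progressive chain per analysis subgroup
    (on outcome-free women by default) and builds that percentile's
    curves; ``predict(women, exams)`` returns 1/0/NaN crossing flags
    aligned with the woman table. NaN marks women who are not evaluable:
    excluded subgroup, unfittable curve, or too few active-phase exams.
    """

    def __init__(
        self,
        percentile: int = 50,
        min_exams_active_phase: int = 2,
        fit_on_outcome_free_only: bool = True,
        min_transitions: int = 5,
        n_starts: int = 3,
        random_state: int = 0,
    ):
        self.percentile = percentile
        self.min_exams_active_phase = min_exams_active_phase
        self.fit_on_outcome_free_only = fit_on_outcome_free_only
        self.min_transitions = min_transitions
        self.n_starts = n_starts
        self.random_state = random_state

    def _config(self) -> AnalysisConfig:
        return AnalysisConfig(
            percentiles=(self.percentile,),
            min_exams_active_phase=self.min_exams_active_phase,
            fit_on_outcome_free_only=self.fit_on_outcome_free_only,
            min_transitions=self.min_transitions,
            n_starts=self.n_starts,
            random_state=self.random_state,
        )

    def fit(self, women: pd.DataFrame, exams: pd.DataFrame):
        config = self._config()
        config.validate()
        w = robson.classify_cohort(women)
        series = build_exam_series(exams)
        fits, skipped = fit_subgroup_models(w, series, config)
        self.models_ = {s: fr.model for s, fr in fits.items()}
        self.curves_ = {}
        for s, model in self.models_.items():
            try:
                self.curves_[s] = markov.percentile_curve(model, s, self.percentile)
            except markov.FitError as err:
                skipped[s] = str(err)
        self.skipped_subgroups_ = skipped
        return self

    def predict(self, women: pd.DataFrame, exams: pd.DataFrame) -> np.ndarray:
        if not hasattr(self, "curves_"):
            raise RuntimeError("classifier is not fitted; call fit first")
        w = robson.classify_cohort(women).reset_index(drop=True)
        series = build_exam_series(exams)
        eligible = np.array(
            [
                r.id in series
                and partograph.n_active_phase_exams(series[r.id])
                >= self.min_exams_active_phase
                for r in w.itertuples()
            ]
        )
        curves = {s: {self.percentile: c} for s, c in self.curves_.items()}
        return _percentile_flags(w, series, curves, self.percentile, eligible)
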