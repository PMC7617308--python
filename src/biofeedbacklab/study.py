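"""Cohort-level analysis: QC, baseline normalisation and group statistics.

The analysis flow mirrors the two study designs: per-session metrics are
extracted (beats -> correction -> SDNN/cvSDNN; belt -> filter -> breaths/min),
records failing cardiac or respiratory QC are excluded with logged reasons,
every target metric is baseline-normalised by subtracting the same
participant's baseline value, and the group statistics are computed:
paired t tests within group, independent t tests between groups, a Pearson
correlation between baseline-normalised respiration and cvSDNN, and a 2x2
mixed-design ANOVA (between = group, within = time) computed from sums of
squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as ss

from .cardiac import (
    BeatSeries,
    ExcludedRecordingError,
    correct_ibis,
    detect_ppg_peaks,
    excise_noise,
    find_noisy_spans,
    summarize_hrv,
)
from .cohort import generate_study_cohort
from .records import GROUP_CONTROL, GROUP_TRAINED, ParticipantRecord
from .respiration import respiration_summary

METRICS = ("mean_hr", "cvsdnn", "sdnn", "resp_rate", "adherence")


@dataclass
class StatsResult:
    effect_name: str
    statistic_kind: str  # paired_t | independent_t | pearson_r | F
    statistic_value: float
    df: float | tuple
    p_value: float
    group_means: dict = field(default_factory=dict)
    n: int = 0
    degenerate: bool = False
    note: str = ""


# ---------------------------------------------------------------------- #
# statistics
# ---------------------------------------------------------------------- #


def paired_t(values_a, values_b, effect_name: str = "") -> StatsResult:
    """Two-sided paired t test, df = n - 1.

    A zero-variance difference vector is flagged degenerate instead of
    producing a division by zero.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) != len(b):
        raise ValueError("paired samples must have equal length")
    if len(a) < 3:
        raise ValueError("need at least 3 pairs")
    d = a - b
    means = {"a": float(np.mean(a)), "b": float(np.mean(b))}
    if np.std(d, ddof=1) == 0:
        t = 0.0
        p = 1.0
        return StatsResult(effect_name, "paired_t", t, len(a) - 1, p, means, len(a), degenerate=True,
                           note="zero variance of differences")
    res = ss.ttest_rel(a, b)
    return StatsResult(effect_name, "paired_t", float(res.statistic), len(a) - 1, float(res.pvalue), means, len(a))


def independent_t(values_a, values_b, effect_name: str = "") -> StatsResult:
    """Two-sided independent-samples t test (pooled variance)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least 3 observations per group")
    means = {"a": float(np.mean(a)), "b": float(np.mean(b))}
    if np.std(a, ddof=1) == 0 and np.std(b, ddof=1) == 0:
        return StatsResult(effect_name, "independent_t", 0.0, len(a) + len(b) - 2, 1.0, means,
                           len(a) + len(b), degenerate=True, note="zero variance in both groups")
    res = ss.ttest_ind(a, b)
    return StatsResult(
        effect_name, "independent_t", float(res.statistic), len(a) + len(b) - 2, float(res.pvalue),
        means, len(a) + len(b),
    )


def pearson_r(x, y, effect_name: str = "") -> StatsResult:
    """Pearson correlation with df = n - 2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need at least 4 paired observations")
    res = ss.pearsonr(x, y)
    return StatsResult(effect_name, "pearson_r", float(res.statistic), len(x) - 2, float(res.pvalue), {}, len(x))


def rm_anova_2x2(data: pd.DataFrame, dv: str = "value", within: str = "time",
                 between: str = "group", subject: str = "subject") -> dict[str, StatsResult]:
    """Balanced 2x2 mixed-design ANOVA from sums of squares.

    One between-subject factor (two groups of equal size n) and one
    within-subject factor (two repeated measurements per subject).  Returns
    the between-group main effect (tested against subjects-within-groups),
    the within-subject main effect and the group x time interaction (both
    tested against the subject x time residual); all dfs are (1, 2(n-1)).
    Unbalanced groups are refused: equalise by random exclusion first.
    """
    d = data[[subject, between, within, dv]].dropna()
    groups = sorted(d[between].unique())
    times = sorted(d[within].unique())
    if len(groups) != 2 or len(times) != 2:
        raise ValueError("design must be exactly 2 groups x 2 times")
    counts = d.groupby(between)[subject].nunique()
    if counts.iloc[0] != counts.iloc[1]:
        raise ValueError(f"unbalanced groups ({dict(counts)}): equalise before the ANOVA")
    n = int(counts.iloc[0])
    if d.groupby([subject])[within].count().ne(2).any():
        raise ValueError("every subject needs both repeated measurements")

    gm = d[dv].mean()
    subj_means = d.groupby(subject)[dv].mean()
    group_of = d.groupby(subject)[between].first()
    group_means = d.groupby(between)[dv].mean()
    time_means = d.groupby(within)[dv].mean()
    cell_means = d.groupby([between, within])[dv].mean()

    ss_total = float(((d[dv] - gm) ** 2).sum())
    ss_between_subj = float(2 * ((subj_means - gm) ** 2).sum())
    ss_group = float(2 * n * ((group_means - gm) ** 2).sum())
    ss_subj_within = ss_between_subj - ss_group
    ss_time = float(2 * n * ((time_means - gm) ** 2).sum())
    ss_cells = float(n * ((cell_means - gm) ** 2).sum())
    ss_inter = ss_cells - ss_group - ss_time
    ss_error = ss_total - ss_between_subj - ss_time - ss_inter

    df_denom = 2 * (n - 1)
    ms_subj = ss_subj_within / df_denom if df_denom else np.nan
    ms_err = ss_error / df_denom if df_denom else np.nan

    def f_result(name, ss_effect, ms_denom):
        if ms_denom <= 0:
            f = 0.0 if ss_effect <= 1e-12 else np.inf
        else:
            f = ss_effect / ms_denom
        p = 1.0 if not np.isfinite(f) else float(ss.f.sf(f, 1, df_denom)) if f > 0 else 1.0
        return StatsResult(name, "F", float(f), (1, df_denom), p,
                           {str(k): float(v) for k, v in cell_means.items()}, 2 * n)

    interaction = f_result("interaction", ss_inter, ms_err)
    # signed direction of the interaction contrast (group b at time b vs rest)
    contrast = (
        cell_means.loc[(groups[1], times[1])] - cell_means.loc[(groups[1], times[0])]
        - cell_means.loc[(groups[0], times[1])] + cell_means.loc[(groups[0], times[0])]
    )
    interaction.note = f"contrast={float(contrast):.6g}"
    _ = group_of  # retained for debugging symmetry checks
    return {
        "group": f_result("group", ss_group, ms_subj),
        "time": f_result("time", ss_time, ms_err),
        "interaction": interaction,
    }


# ---------------------------------------------------------------------- #
# per-record metric extraction
# ---------------------------------------------------------------------- #


def compute_session_metrics(record: ParticipantRecord) -> list[dict]:
    """Run the measurement pipelines over every session of a record.

    Rendered sessions go through the full route (peak detection -> noisy-span
    excision -> artifact correction -> HRV summary; filter -> breath
    detection); truth-level sessions already carry a clean BeatSeries and a
    breath count.  Returns one exclusion entry per failed segment.
    """
    exclusions = []
    for session in record.sessions.values():
        if session.ppg is not None:
            beats = detect_ppg_peaks(session.ppg)
            if not beats.qc.excluded:
                spans = find_noisy_spans(session.ppg)
                if spans:
                    import warnings

                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        beats = excise_noise(beats, spans)
            if not beats.qc.excluded and len(beats.ibis) >= 10:
                beats = correct_ibis(beats)
            session.beats = beats
        if session.beats is not None and session.hrv is None:
            try:
                session.hrv = summarize_hrv(session.beats)
            except (ExcludedRecordingError, ValueError) as err:
                exclusions.append(
                    {"participant_id": record.participant_id, "condition": session.condition,
                     "channel": "ppg", "reason": str(err)}
                )
        if session.resp is not None and session.resp_summary is None:
            session.resp_summary = respiration_summary(session.resp)
        if session.resp_summary is not None and not session.resp_summary.usable:
            exclusions.append(
                {"participant_id": record.participant_id, "condition": session.condition,
                 "channel": "respiration", "reason": "no identifiable breath peaks for >60 s"}
            )
    return exclusions


def _metric_value(record: ParticipantRecord, metric: str, condition: str) -> float:
    session = record.sessions.get(condition)
    if session is None:
        raise KeyError(f"no {condition} session for {record.participant_id}")
    if metric in ("mean_hr", "cvsdnn", "sdnn"):
        if session.hrv is None:
            raise ExcludedRecordingError(f"{condition} cardiac metrics unavailable")
        return getattr(session.hrv, metric)
    if metric in ("resp_rate", "adherence"):
        if session.resp_summary is None or not session.resp_summary.usable:
            raise ExcludedRecordingError(f"{condition} respiration unusable")
        return getattr(session.resp_summary, metric)
    raise ValueError(f"unknown metric {metric!r}")


def baseline_normalize(record: ParticipantRecord, metric: str, condition: str) -> float:
    """metric(condition) - metric(baseline) for one participant.

    Raises :class:`ExcludedRecordingError` when either segment failed QC, so
    callers drop the record from that test and log the reason.
    """
    return _metric_value(record, metric, condition) - _metric_value(record, metric, "baseline")


# ---------------------------------------------------------------------- #
# study runner
# ---------------------------------------------------------------------- #


@dataclass
class StudyReport:
    design: str
    metrics: pd.DataFrame
    stats: dict[str, StatsResult]
    exclusions: pd.DataFrame
    accounting: dict = field(default_factory=dict)
    n_input: int = 0


def _collect_pairs(cohort, metric, condition, exclusions, test_name):
    """Baseline-normalised values per record; drops and logs QC failures."""
    values, records = [], []
    for rec in cohort:
        try:
            values.append(baseline_normalize(rec, metric, condition))
            records.append(rec)
        except (ExcludedRecordingError, KeyError) as err:
            exclusions.append(
                {"participant_id": rec.participant_id, "condition": condition,
                 "channel": "analysis", "reason": f"{test_name}: {err}"}
            )
    return np.asarray(values), records


def metrics_table(cohort: list[ParticipantRecord]) -> pd.DataFrame:
    rows = []
    for rec in cohort:
        for cond, session in rec.sessions.items():
            row = {"participant_id": rec.participant_id, "group": rec.group, "condition": cond}
            if session.hrv is not None:
                row.update(
                    mean_hr=session.hrv.mean_hr, mean_ibi=session.hrv.mean_ibi,
                    sdnn=session.hrv.sdnn, cvsdnn=session.hrv.cvsdnn, n_beats=session.hrv.n_beats,
                )
            row["cardiac_excluded"] = session.beats.qc.excluded if session.beats is not None else None
            if session.resp_summary is not None:
                row.update(
                    resp_rate=session.resp_summary.resp_rate, adherence=session.resp_summary.adherence,
                    resp_usable=session.resp_summary.usable,
                )
            rows.append(row)
    return pd.DataFrame(rows)


def run_study(
    cohort: list[ParticipantRecord],
    design: str,
    seed: int = 0,
    out_dir=None,
) -> StudyReport:
    """Execute the full per-study flow on a cohort of participant records.

    QC -> metrics -> baseline normalisation -> group statistics, with an
    exclusion log that accounts for every dropped record and (for the
    two-group design) random exclusion from the larger group to equalise
    group sizes before between-group tests.
    """
    exclusions: list[dict] = []
    for rec in cohort:
        exclusions.extend(compute_session_metrics(rec))
    n_input = len(cohort)

    rng = np.random.default_rng(seed)
    stats: dict[str, StatsResult] = {}
    accounting: dict[str, dict] = {}

    def account(name, n_analyzed, pool=n_input):
        accounting[name] = {"n_input": pool, "n_analyzed": n_analyzed, "n_excluded": pool - n_analyzed}

    if design == "study1":
        for metric, name in (("resp_rate", "resp_baseline_vs_stressor"),
                             ("mean_hr", "hr_stressor_vs_baseline"),
                             ("cvsdnn", "cvsdnn_stressor_vs_baseline")):
            deltas, recs = _collect_pairs(cohort, metric, "stressor", exclusions, name)
            if metric == "resp_rate":
                # baseline - stressor: positive t = slowing under stress
                a = [_metric_value(r, metric, "baseline") for r in recs]
                b = [_metric_value(r, metric, "stressor") for r in recs]
            else:
                a = [_metric_value(r, metric, "stressor") for r in recs]
                b = [_metric_value(r, metric, "baseline") for r in recs]
            stats[name] = paired_t(a, b, name)
            account(name, len(recs))
        both, recs = [], []
        for rec in cohort:
            try:
                both.append((baseline_normalize(rec, "resp_rate", "stressor"),
                             baseline_normalize(rec, "cvsdnn", "stressor")))
                recs.append(rec)
            except (ExcludedRecordingError, KeyError) as err:
                exclusions.append({"participant_id": rec.participant_id, "condition": "stressor",
                                   "channel": "analysis", "reason": f"resp_cvsdnn_correlation: {err}"})
        if len(both) >= 4:
            xs, ys = zip(*both)
            stats["resp_cvsdnn_correlation"] = pearson_r(xs, ys, "resp_cvsdnn_correlation")
            account("resp_cvsdnn_correlation", len(both))
    elif design == "study2":
        # cardiac-complete records, then equalise group sizes at random
        def cardiac_ok(rec):
            try:
                for cond in ("baseline", "intruder", "stressor"):
                    _metric_value(rec, "cvsdnn", cond)
                return True
            except (ExcludedRecordingError, KeyError):
                return False

        usable = [r for r in cohort if cardiac_ok(r)]
        for r in cohort:
            if r not in usable:
                exclusions.append({"participant_id": r.participant_id, "condition": "any",
                                   "channel": "analysis", "reason": "cardiac QC exclusion"})
        by_group = {g: [r for r in usable if r.group == g] for g in (GROUP_CONTROL, GROUP_TRAINED)}
        n_equal = min(len(v) for v in by_group.values())
        for g, recs_g in by_group.items():
            while len(recs_g) > n_equal:
                victim = recs_g.pop(int(rng.integers(len(recs_g))))
                exclusions.append({"participant_id": victim.participant_id, "condition": "any",
                                   "channel": "analysis",
                                   "reason": "randomly excluded to equalise group sizes"})
        control, trained = by_group[GROUP_CONTROL], by_group[GROUP_TRAINED]

        for metric, name in (("mean_hr", "hr_group_difference"),
                             ("cvsdnn", "cvsdnn_group_difference"),
                             ("resp_rate", "resp_group_difference")):
            try:
                d_tr = [baseline_normalize(r, metric, "stressor") for r in trained]
                d_ct = [baseline_normalize(r, metric, "stressor") for r in control]
                stats[name] = independent_t(d_tr, d_ct, name)
                account(name, len(d_tr) + len(d_ct), pool=n_input)
            except (ExcludedRecordingError, ValueError, KeyError) as err:
                exclusions.append({"participant_id": "-", "condition": "stressor",
                                   "channel": "analysis", "reason": f"{name}: {err}"})

        rows = []
        for rec in control + trained:
            for cond in ("intruder", "stressor"):
                rows.append({"subject": rec.participant_id, "group": rec.group, "time": cond,
                             "value": baseline_normalize(rec, "cvsdnn", cond)})
        anova = rm_anova_2x2(pd.DataFrame(rows))
        for key, res in anova.items():
            stats[f"cvsdnn_anova_{key}"] = res
        account("cvsdnn_anova", 2 * n_equal)
    else:
        raise ValueError(f"unknown design {design!r}")

    report = StudyReport(
        design=design,
        metrics=metrics_table(cohort),
        stats=stats,
        exclusions=pd.DataFrame(exclusions, columns=["participant_id", "condition", "channel", "reason"]),
        accounting=accounting,
        n_input=n_input,
    )
    if out_dir is not None:
        from .io import write_study_report

        write_study_report(report, out_dir, seed=seed)
    return report


# ---------------------------------------------------------------------- #
# replicated direction-of-effect checks
# ---------------------------------------------------------------------- #


def replicate_study2_directions(
    n_replicates: int = 100,
    n_per_group: int = 26,
    seed: int = 0,
    profile_overrides: dict | None = None,
) -> dict:
    """Direction-of-effect tally over seeded study-2 cohort replicates.

    For each replicate (ground-truth-level cohorts for speed) counts whether
    (i) the trained group's baseline-normalised respiration is lower than
    controls, (ii) its baseline-normalised cvSDNN is higher, and (iii) the
    group x time interaction contrast for cvSDNN is positive.
    """
    counts = {"resp_lower": 0, "cvsdnn_higher": 0, "interaction_positive": 0}
    root = np.random.SeedSequence(seed)
    for rep_seq in root.spawn(n_replicates):
        rep_seed = int(rep_seq.generate_state(1)[0] % (2**31))
        cohort = generate_study_cohort(
            n_per_group, "study2", seed=rep_seed, render_signals=False, profile_overrides=profile_overrides
        )
        for rec in cohort:
            compute_session_metrics(rec)
        trained = [r for r in cohort if r.group == GROUP_TRAINED]
        control = [r for r in cohort if r.group == GROUP_CONTROL]

        def mean_delta(recs, metric, cond):
            return float(np.mean([baseline_normalize(r, metric, cond) for r in recs]))

        if mean_delta(trained, "resp_rate", "stressor") < mean_delta(control, "resp_rate", "stressor"):
            counts["resp_lower"] += 1
        if mean_delta(trained, "cvsdnn", "stressor") > mean_delta(control, "cvsdnn", "stressor"):
            counts["cvsdnn_higher"] += 1
        contrast = (
            mean_delta(trained, "cvsdnn", "stressor") - mean_delta(trained, "cvsdnn", "intruder")
            - mean_delta(control, "cvsdnn", "stressor") + mean_delta(control, "cvsdnn", "intruder")
        )
        if contrast > 0:
            counts["interaction_positive"] += 1
    counts["n_replicates"] = n_replicates
    return counts
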