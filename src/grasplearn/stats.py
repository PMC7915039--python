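"""Normalization, training outcomes and the statistical battery.

Workflow: each subject's per-trial metric values are normalized by that
subject's pre-training block mean (removing inter-subject scale), the
two training outcomes are computed — the intra-training rate (OLS slope
of the metric across the 30 training trials; negative = improvement)
and the post-training effect (post-block mean minus pre-block mean;
negative = improvement) — and values are de-normalized back to metric
units by the group pre-training mean.  The battery then mirrors the
study's report layout: a one-factor repeated-measures ANOVA over trial
blocks per feedback mode with Tukey-HSD pairwise block comparisons, a
one-way ANOVA on each outcome across feedback modes with Tukey (and
optional Bonferroni family scaling) post hocs, and one-sample t-tests
of each outcome against zero.

The elementary tests are computed from their textbook sum-of-squares
forms so they can be cross-checked against independent reference
implementations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from .synth import METRICS, FeedbackMode

__all__ = [
    "BlockSeries",
    "OutcomeMeasures",
    "RmAnovaResult",
    "OnewayAnovaResult",
    "TtestResult",
    "StatsReport",
    "normalize_subject",
    "denormalize_group",
    "intra_training_rate",
    "post_training_effect",
    "rm_anova",
    "oneway_anova",
    "tukey_posthoc",
    "one_sample_ttest",
    "two_sample_ttest",
    "build_report",
]

BLOCK_ORDER = ("pre", "training", "post")
MODE_ORDER = ("NF", "IF", "IBF")


@dataclass
class BlockSeries:
    """Per-trial values of one metric for one subject and feedback mode."""

    subject_id: str
    feedback_mode: str
    metric: str
    pre: np.ndarray
    training: np.ndarray
    post: np.ndarray
    normalized: bool = False

    def block(self, name: str) -> np.ndarray:
        return getattr(self, name)


@dataclass
class OutcomeMeasures:
    """The two training outcomes for one (subject, mode, metric) cell."""

    intra_training_rate: float   # metric units per trial
    post_training_effect: float  # metric units


def normalize_subject(series: BlockSeries) -> BlockSeries:
    """Divide every value in all three blocks by the pre-block mean.

    The pre block itself is normalized too (its mean becomes exactly 1)
    so all blocks share one scale.
    """
    pre_mean = float(np.mean(series.pre))
    if pre_mean <= 0:
        raise ValueError("pre-block mean must be > 0 for normalization")
    return replace(
        series,
        pre=series.pre / pre_mean,
        training=series.training / pre_mean,
        post=series.post / pre_mean,
        normalized=True)


def denormalize_group(values, group_pre_mean: float):
    """Return normalized values to metric units via the group pre mean."""
    if group_pre_mean <= 0:
        raise ValueError("group pre-training mean must be > 0")
    return np.asarray(values) * group_pre_mean if np.ndim(values) \
        else float(values) * group_pre_mean


def intra_training_rate(training_values: np.ndarray) -> float:
    """OLS slope of the metric on training-trial index 1..n."""
    y = np.asarray(training_values, dtype=float)
    if len(y) < 2:
        raise ValueError("need at least 2 training trials for a slope")
    k = np.arange(1, len(y) + 1, dtype=float)
    kc = k - k.mean()
    return float((kc @ (y - y.mean())) / (kc @ kc))


def post_training_effect(pre: np.ndarray, post: np.ndarray) -> float:
    """mean(post) - mean(pre); negative means improvement."""
    pre, post = np.asarray(pre, dtype=float), np.asarray(post, dtype=float)
    if len(pre) == 0 or len(post) == 0:
        raise ValueError("pre and post blocks must be non-empty")
    return float(post.mean() - pre.mean())


def subject_training_slopes(study, mode, metric: str,
                            normalize: bool = True) -> np.ndarray:
    """Per-subject intra-training rates for one mode/metric of a study.

    Convenience path over :func:`build_report` for power analyses: slopes
    are computed on subject-normalized training trials and returned in
    metric units via the raw group pre-training mean.
    """
    mode = FeedbackMode(mode)
    pre_all: list[float] = []
    per_subject: dict[str, dict[str, np.ndarray]] = {}
    for sess in study.sessions:
        values = {b: [] for b in BLOCK_ORDER}
        for tr in sess.trials:
            values[tr.block.value].append(tr.metrics[metric])
        pre_all.extend(values["pre"])
        if sess.feedback_mode == mode:
            per_subject[sess.subject_id] = {
                b: np.asarray(v, dtype=float) for b, v in values.items()}
    group_pre = float(np.mean(pre_all))
    slopes = []
    for blocks in per_subject.values():
        scale = (group_pre / blocks["pre"].mean()) if normalize else 1.0
        slopes.append(intra_training_rate(blocks["training"]) * scale)
    return np.asarray(slopes)


# ---------------------------------------------------------------------------
# Elementary tests
# ---------------------------------------------------------------------------


@dataclass
class RmAnovaResult:
    F: float
    p: float
    df_effect: int
    df_error: int
    ms_error: float
    pairwise: pd.DataFrame   # columns: level_a, level_b, diff, se, p_tukey
    flag: str | None = None


@dataclass
class OnewayAnovaResult:
    F: float
    p: float
    df_between: int
    df_within: int
    ms_within: float
    flag: str | None = None


@dataclass
class TtestResult:
    t: float
    p: float
    df: int
    flag: str | None = None


def rm_anova(values: np.ndarray,
             level_names: tuple[str, ...] | None = None) -> RmAnovaResult:
    """One-factor within-subject (repeated-measures) ANOVA.

    ``values`` is (n_subjects, n_levels), balanced with no missing
    cells.  Pairwise level differences use the pooled RM error term:
    SE = sqrt(2 * MS_error / n) and Tukey-HSD p from the studentized
    range with (n - 1)(k - 1) error degrees of freedom.
    """
    X = np.asarray(values, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need a (subjects x levels) matrix, both >= 2")
    if not np.all(np.isfinite(X)):
        raise ValueError("missing or non-finite cells are not supported")
    n, k = X.shape
    grand = X.mean()
    ss_total = float(((X - grand) ** 2).sum())
    ss_subject = float(k * ((X.mean(axis=1) - grand) ** 2).sum())
    ss_level = float(n * ((X.mean(axis=0) - grand) ** 2).sum())
    ss_error = max(0.0, ss_total - ss_subject - ss_level)
    df_effect, df_error = k - 1, (k - 1) * (n - 1)
    ms_error = ss_error / df_error

    flag = None
    if ss_level == 0.0:
        F, p = 0.0, 1.0
    elif ms_error == 0.0:
        F, p, flag = np.inf, 0.0, "zero error variance"
    else:
        F = (ss_level / df_effect) / ms_error
        p = float(sps.f.sf(F, df_effect, df_error))

    names = (tuple(level_names) if level_names is not None
             else tuple(f"L{j + 1}" for j in range(k)))
    col_means = X.mean(axis=0)
    rows = []
    se = np.sqrt(2.0 * ms_error / n)
    for i in range(k):
        for j in range(i + 1, k):
            diff = float(col_means[i] - col_means[j])
            if ms_error == 0.0:
                p_pair = 0.0 if diff != 0 else 1.0
            else:
                q = abs(diff) / np.sqrt(ms_error / n)
                p_pair = float(sps.studentized_range.sf(q, k, df_error))
            rows.append({"level_a": names[i], "level_b": names[j],
                         "diff": diff, "se": float(se), "p_tukey": p_pair})
    return RmAnovaResult(F=float(F), p=float(p), df_effect=df_effect,
                         df_error=df_error, ms_error=float(ms_error),
                         pairwise=pd.DataFrame(rows), flag=flag)


def oneway_anova(groups: list[np.ndarray]) -> OnewayAnovaResult:
    """Between/within one-way ANOVA on independent groups."""
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2 or any(len(g) < 2 for g in gs):
        raise ValueError("need >= 2 groups with >= 2 values each")
    all_vals = np.concatenate(gs)
    grand = all_vals.mean()
    ss_between = float(sum(len(g) * (g.mean() - grand) ** 2 for g in gs))
    ss_within = float(sum(((g - g.mean()) ** 2).sum() for g in gs))
    df_b = len(gs) - 1
    df_w = len(all_vals) - len(gs)
    ms_within = ss_within / df_w

    flag = None
    if ss_between == 0.0:
        F, p = 0.0, 1.0
        if ms_within == 0.0:
            flag = "degenerate: zero between- and within-group variance"
    elif ms_within == 0.0:
        F, p, flag = np.inf, 0.0, "zero within-group variance"
    else:
        F = (ss_between / df_b) / ms_within
        p = float(sps.f.sf(F, df_b, df_w))
    return OnewayAnovaResult(F=float(F), p=float(p), df_between=df_b,
                             df_within=df_w, ms_within=float(ms_within),
                             flag=flag)


def tukey_posthoc(groups: list[np.ndarray],
                  bonferroni_families: int = 1,
                  group_names: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Tukey-HSD pairwise p-values, optionally Bonferroni-scaled.

    Uses the Tukey-Kramer form for unequal group sizes.  When several
    metric families are tested, ``bonferroni_families`` multiplies every
    pairwise p (capped at 1).
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("Tukey post hoc needs >= 2 groups")
    if bonferroni_families < 1:
        raise ValueError("bonferroni_families must be >= 1")
    k = len(gs)
    N = sum(len(g) for g in gs)
    df_w = N - k
    ms_within = sum(float(((g - g.mean()) ** 2).sum()) for g in gs) / df_w
    names = (tuple(group_names) if group_names is not None
             else tuple(f"G{j + 1}" for j in range(k)))
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = float(gs[i].mean() - gs[j].mean())
            if ms_within == 0.0:
                p_raw = 0.0 if diff != 0 else 1.0
            else:
                se = np.sqrt(ms_within / 2.0
                             * (1.0 / len(gs[i]) + 1.0 / len(gs[j])))
                q = abs(diff) / se
                p_raw = float(sps.studentized_range.sf(q, k, df_w))
            rows.append({"group_a": names[i], "group_b": names[j],
                         "diff": diff, "p_tukey": p_raw,
                         "p_adjusted": min(1.0,
                                           p_raw * bonferroni_families)})
    return pd.DataFrame(rows)


def one_sample_ttest(values: np.ndarray, mu: float = 0.0) -> TtestResult:
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise ValueError("need n >= 2")
    sd = x.std(ddof=1)
    df = len(x) - 1
    if sd == 0.0:
        t = 0.0 if x.mean() == mu else np.inf * np.sign(x.mean() - mu)
        p = 1.0 if x.mean() == mu else 0.0
        return TtestResult(t=float(t), p=float(p), df=df,
                           flag="zero variance")
    t = (x.mean() - mu) / (sd / np.sqrt(len(x)))
    return TtestResult(t=float(t), p=float(2 * sps.t.sf(abs(t), df)), df=df)


def two_sample_ttest(a: np.ndarray, b: np.ndarray) -> TtestResult:
    """Classic pooled-variance two-sample t-test, two-sided."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need n >= 2 per sample")
    df = len(a) + len(b) - 2
    sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / df
    if sp2 == 0.0:
        equal = a.mean() == b.mean()
        return TtestResult(t=0.0 if equal else np.inf, p=1.0 if equal
                           else 0.0, df=df, flag="zero variance")
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
    return TtestResult(t=float(t), p=float(2 * sps.t.sf(abs(t), df)), df=df)


# ---------------------------------------------------------------------------
# Full report
# ---------------------------------------------------------------------------


@dataclass
class StatsReport:
    """All tables of the outcome analysis.

    ``block_anova`` has one row per (metric, mode) RM-ANOVA over blocks;
    ``block_pairwise`` its pairwise block comparisons (pre - training
    etc., de-normalized units).  ``outcome_anova`` / ``outcome_tukey``
    compare the outcomes across feedback modes and ``one_sample`` tests
    each outcome against zero.  ``outcomes`` holds the per-subject
    outcome values and ``group_pre_mean`` the raw group pre-training
    mean per metric.
    """

    group_pre_mean: dict[str, float]
    outcomes: pd.DataFrame
    block_anova: pd.DataFrame
    block_pairwise: pd.DataFrame
    outcome_anova: pd.DataFrame
    outcome_tukey: pd.DataFrame
    one_sample: pd.DataFrame
    normalized: bool = True


def _series_from_frame(df: pd.DataFrame, subject: str, mode: str,
                       metric: str) -> BlockSeries:
    cell = df[(df["subject"] == subject) & (df["mode"] == mode)]
    blocks = {}
    for b in BLOCK_ORDER:
        sub = cell[cell["block"] == b].sort_values("trial")
        blocks[b] = sub[metric].to_numpy(dtype=float)
    return BlockSeries(subject_id=subject, feedback_mode=mode,
                       metric=metric, **blocks)


def build_report(metrics_df: pd.DataFrame,
                 *,
                 normalize: bool = True,
                 bonferroni_families: int = 1) -> StatsReport:
    """Run normalization, outcomes and the full test battery.

    ``metrics_df`` is the long per-trial table produced by
    :meth:`grasplearn.synth.StudyDataset.to_frame` (or by scoring
    trajectories): columns subject, mode, block, trial and one column
    per metric.  Outcomes are reported in metric units (de-normalized by
    the raw group pre-training mean when ``normalize`` is on).
    """
    required = {"subject", "mode", "block", "trial", *METRICS}
    missing = required - set(metrics_df.columns)
    if missing:
        raise ValueError(f"metrics table missing columns: {sorted(missing)}")
    subjects = sorted(metrics_df["subject"].unique())
    modes = [m for m in MODE_ORDER if m in set(metrics_df["mode"])]

    group_pre = {
        m: float(metrics_df.loc[metrics_df["block"] == "pre", m].mean())
        for m in METRICS}

    outcome_rows = []
    block_means: dict[tuple[str, str], dict[str, list[float]]] = {}
    for metric in METRICS:
        scale = group_pre[metric] if normalize else 1.0
        for mode in modes:
            per_subject_blocks = []
            for subject in subjects:
                series = _series_from_frame(metrics_df, subject, mode,
                                            metric)
                if normalize:
                    series = normalize_subject(series)
                beta = intra_training_rate(series.training) * scale
                delta = post_training_effect(series.pre, series.post) * scale
                outcome_rows.append({
                    "subject": subject, "mode": mode, "metric": metric,
                    "intra_training_rate": beta,
                    "post_training_effect": delta})
                per_subject_blocks.append(
                    [float(np.mean(series.block(b))) * scale
                     for b in BLOCK_ORDER])
            block_means[(metric, mode)] = np.asarray(per_subject_blocks)

    outcomes = pd.DataFrame(outcome_rows)

    anova_rows, pairwise_rows = [], []
    for metric in METRICS:
        for mode in modes:
            res = rm_anova(block_means[(metric, mode)],
                           level_names=BLOCK_ORDER)
            anova_rows.append({"metric": metric, "mode": mode,
                               "F": res.F, "p": res.p,
                               "df_effect": res.df_effect,
                               "df_error": res.df_error})
            pw = res.pairwise.copy()
            pw.insert(0, "mode", mode)
            pw.insert(0, "metric", metric)
            # both orientations, to keep signs unambiguous
            pw["diff_a_minus_b"] = pw.pop("diff")
            pw["diff_b_minus_a"] = -pw["diff_a_minus_b"]
            pairwise_rows.append(pw)

    outcome_anova_rows, tukey_rows, one_sample_rows = [], [], []
    for metric in METRICS:
        for outcome in ("intra_training_rate", "post_training_effect"):
            groups = [
                outcomes.loc[(outcomes["metric"] == metric)
                             & (outcomes["mode"] == mode), outcome]
                .to_numpy() for mode in modes]
            res = oneway_anova(groups)
            outcome_anova_rows.append({
                "metric": metric, "outcome": outcome, "F": res.F,
                "p": res.p, "df_between": res.df_between,
                "df_within": res.df_within, "flag": res.flag})
            tk = tukey_posthoc(groups, bonferroni_families,
                               group_names=tuple(modes))
            tk.insert(0, "outcome", outcome)
            tk.insert(0, "metric", metric)
            tukey_rows.append(tk)
            for mode, g in zip(modes, groups):
                tt = one_sample_ttest(g, 0.0)
                one_sample_rows.append({
                    "metric": metric, "outcome": outcome, "mode": mode,
                    "mean": float(np.mean(g)), "t": tt.t, "p": tt.p,
                    "df": tt.df})

    return StatsReport(
        group_pre_mean=group_pre,
        outcomes=outcomes,
        block_anova=pd.DataFrame(anova_rows),
        block_pairwise=pd.concat(pairwise_rows, ignore_index=True),
        outcome_anova=pd.DataFrame(outcome_anova_rows),
        outcome_tukey=pd.concat(tukey_rows, ignore_index=True),
        one_sample=pd.DataFrame(one_sample_rows),
        normalized=normalize)
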