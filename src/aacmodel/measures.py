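"""Model-free behavioral summaries, entropy-RT coupling, and reliability.

Three model-free task measures are computed per subject-visit, overall and
within each trial type: average chosen runway position, choice variability
(within-subject SD of chosen position), and mean response time.  The
model-based choice-uncertainty statistic is the entropy of the per-trial
policy, -sum p ln p, correlated trial-by-trial with RT (Pearson).  Test-retest
reliability across visits uses the two-way mixed, consistency, single-measure
intraclass correlation ICC(3,1), with the conventional poor (< 0.4),
fair (0.4-0.6) and good (> 0.6) labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .agent import AgentParams, choice_entropy, choice_policy
from .inference import _as_trials
from .task import TRIAL_TYPES, TrialSpec


@dataclass(frozen=True)
class EntropyRtResult:
    """Pearson r between per-trial choice uncertainty and RT.

    ``r`` is NaN when the correlation is undefined; ``reason`` then says why.
    """

    r: float
    reason: str | None = None

    @property
    def missing(self) -> bool:
        return not np.isfinite(self.r)


@dataclass(frozen=True)
class IccResult:
    icc: float
    n_pairs: int

    @property
    def label(self) -> str:
        if self.icc < 0.4:
            return "poor"
        if self.icc <= 0.6:
            return "fair"
        return "good"


def summarize_choices(data) -> pd.DataFrame:
    """Per-condition and overall choice/RT summaries for one subject-visit.

    Returns one row per present trial type plus an "all" row, with columns
    ``mean_position``, ``position_sd`` (ddof=1), ``mean_rt`` and ``n_trials``.
    Absent conditions are omitted with a warning.
    """
    trials = _as_trials(data)
    rows = []
    for cond in TRIAL_TYPES + ("all",):
        sub = trials if cond == "all" else trials[trials["trial_type"] == cond]
        if len(sub) == 0:
            warnings.warn(f"condition {cond} absent; omitted from summary")
            continue
        pos = sub["chosen_position"].to_numpy(dtype=float)
        rt = sub["rt"].to_numpy(dtype=float)
        rows.append(
            {
                "condition": cond,
                "mean_position": pos.mean(),
                "position_sd": pos.std(ddof=1) if len(pos) > 1 else 0.0,
                "mean_rt": float(np.nanmean(rt)),
                "n_trials": len(sub),
            }
        )
    return pd.DataFrame(rows)


def trial_entropies(data, params: AgentParams, form: str = "risk") -> np.ndarray:
    """Choice-uncertainty entropy of the policy on each trial."""
    trials = _as_trials(data)
    ent = {
        t: choice_entropy(choice_policy(params, TrialSpec(t), form=form))
        for t in TRIAL_TYPES
    }
    return np.array([ent[t] for t in trials["trial_type"]])


def entropy_rt_correlation(
    data, params: AgentParams, form: str = "risk"
) -> EntropyRtResult:
    """Per-subject Pearson r between trial-by-trial choice uncertainty and RT."""
    trials = _as_trials(data)
    rt = trials["rt"].to_numpy(dtype=float)
    ok = np.isfinite(rt) & (rt > 0)
    n_dropped = int((~ok).sum())
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} trials with missing/non-positive RT")
    if ok.sum() < 3:
        return EntropyRtResult(np.nan, "fewer than 3 usable trials")
    ent = trial_entropies(trials[ok], params, form=form)
    rt = rt[ok]
    if np.std(ent) <= 1e-12 * max(1.0, np.abs(ent).max()):
        return EntropyRtResult(np.nan, "zero variance in entropy")
    if np.std(rt) <= 1e-12 * max(1.0, np.abs(rt).max()):
        return EntropyRtResult(np.nan, "zero variance in RT")
    r = stats.pearsonr(ent, rt).statistic
    return EntropyRtResult(float(r))


def icc_3_1(visit1, visit2) -> IccResult:
    """ICC(3,1): two-way mixed, consistency, single measures, k = 2 visits.

    Computed from the standard two-way ANOVA decomposition:
    ICC = (MS_subjects - MS_error) / (MS_subjects + (k-1) MS_error).
    Subjects missing either visit are excluded listwise.
    """
    v1 = np.asarray(visit1, dtype=float)
    v2 = np.asarray(visit2, dtype=float)
    if v1.shape != v2.shape or v1.ndim != 1:
        raise ValueError("visit vectors must be 1-d and the same length")
    ok = np.isfinite(v1) & np.isfinite(v2)
    v1, v2 = v1[ok], v2[ok]
    n = len(v1)
    if n < 3:
        raise ValueError("need at least 3 complete subject pairs")
    k = 2
    y = np.column_stack([v1, v2])
    grand = y.mean()
    subj_means = y.mean(axis=1)
    visit_means = y.mean(axis=0)
    ss_subj = k * ((subj_means - grand) ** 2).sum()
    ss_visit = n * ((visit_means - grand) ** 2).sum()
    ss_total = ((y - grand) ** 2).sum()
    ss_err = ss_total - ss_subj - ss_visit
    ms_subj = ss_subj / (n - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    denom = ms_subj + (k - 1) * ms_err
    if denom == 0:
        raise ValueError("degenerate data: zero variance across subjects and error")
    return IccResult(icc=float((ms_subj - ms_err) / denom), n_pairs=n)


def reliability_table(
    values: pd.DataFrame,
    subject_col: str = "subject_id",
    visit_col: str = "visit",
    measure_cols: list[str] | None = None,
) -> pd.DataFrame:
    """ICC(3,1) for each measure column of a long (subject, visit) table."""
    wide_visits = values[visit_col].unique()
    if len(wide_visits) != 2:
        raise ValueError("reliability table needs exactly 2 visits")
    if measure_cols is None:
        measure_cols = [
            c for c in values.columns
            if c not in (subject_col, visit_col)
            and pd.api.types.is_numeric_dtype(values[c])
        ]
    rows = []
    for col in measure_cols:
        wide = values.pivot_table(
            index=subject_col, columns=visit_col, values=col, aggfunc="first"
        )
        res = icc_3_1(wide.iloc[:, 0], wide.iloc[:, 1])
        rows.append(
            {"measure": col, "icc": res.icc, "n_pairs": res.n_pairs,
             "label": res.label}
        )
    return pd.DataFrame(rows)
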