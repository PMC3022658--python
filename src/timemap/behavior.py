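"""Behavioral aggregation and statistics for the self-projection-in-time task.

Participants mentally project themselves to one of three time-points (Past,
Now, Future) and judge events relative to that vantage point.  The analysis
summarizes per-subject reaction times (correct trials only) and error rates
per condition, runs a one-way within-subject (repeated measures) ANOVA over
the Time factor, and correlates questionnaire scores with per-subject mean
reaction times.

The repeated-measures ANOVA is computed by explicit sums-of-squares
decomposition (condition SS, subject SS, residual SS) so the degrees of
freedom are (k-1, (k-1)(n-1)).  No sphericity correction is applied by
default; a Greenhouse-Geisser-corrected p value can be requested.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .scales import CorrelationResult, pearson

__all__ = [
    "CONDITIONS",
    "summarize",
    "rm_anova",
    "RMAnovaResult",
    "correlate_scores_with_rt",
]

CONDITIONS = ("Past", "Now", "Future")


def summarize(trials: pd.DataFrame) -> pd.DataFrame:
    """Per subject x condition: mean RT over correct trials and error rate.

    ``trials`` needs columns ``subject, condition, rt, correct``.  Raises if
    a subject x condition cell has no correct trial (its mean RT would be
    undefined).
    """
    required = {"subject", "condition", "rt", "correct"}
    missing = required - set(trials.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    if (trials["rt"] <= 0).any():
        raise ValueError("non-positive reaction times in trial table")

    rows = []
    for (subj, cond), g in trials.groupby(["subject", "condition"], sort=False):
        correct = g.loc[g["correct"].astype(bool), "rt"]
        if correct.empty:
            raise ValueError(
                f"no correct trials for subject {subj!r}, condition {cond!r}"
            )
        rows.append(
            {
                "subject": subj,
                "condition": cond,
                "mean_rt_correct": float(correct.mean()),
                "error_rate": float(1.0 - g["correct"].astype(bool).mean()),
                "n_trials": int(len(g)),
            }
        )
    return pd.DataFrame(rows)


class RMAnovaResult(NamedTuple):
    F: float
    df1: int
    df2: int
    p: float
    ss_condition: float
    ss_subject: float
    ss_residual: float
    gg_epsilon: float
    p_gg: float
    perfect_separation: bool


def rm_anova(
    summaries: pd.DataFrame,
    measure: str = "mean_rt_correct",
    subject: str = "subject",
    within: str = "condition",
) -> RMAnovaResult:
    """One-way within-subject ANOVA by full sums-of-squares decomposition.

    Every subject must contribute every level of ``within``.  When the
    residual SS is (numerically) zero the design separates perfectly; the
    result is flagged and F is reported as ``inf`` rather than dividing by
    zero.
    """
    from scipy import stats

    wide = summaries.pivot(index=subject, columns=within, values=measure)
    if wide.isna().any().any():
        bad = wide[wide.isna().any(axis=1)].index.tolist()
        raise ValueError(f"missing condition cells for subjects: {bad}")
    x = wide.to_numpy(dtype=float)
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need >= 2 subjects and >= 2 conditions")

    grand = x.mean()
    ss_cond = n * np.sum((x.mean(axis=0) - grand) ** 2)
    ss_subj = k * np.sum((x.mean(axis=1) - grand) ** 2)
    ss_tot = np.sum((x - grand) ** 2)
    ss_res = ss_tot - ss_cond - ss_subj

    df1, df2 = k - 1, (k - 1) * (n - 1)
    scale = max(ss_tot, 1.0)
    if ss_res <= 1e-12 * scale:
        if ss_cond <= 1e-12 * scale:
            # no condition variance at all: F = 0, nothing to separate
            return RMAnovaResult(
                0.0, df1, df2, 1.0, 0.0, ss_subj, 0.0, np.nan, 1.0, False
            )
        return RMAnovaResult(
            np.inf, df1, df2, 0.0, ss_cond, ss_subj, max(ss_res, 0.0),
            np.nan, 0.0, True,
        )

    F = (ss_cond / df1) / (ss_res / df2)
    p = float(stats.f.sf(F, df1, df2))

    # Greenhouse-Geisser epsilon from the double-centred covariance matrix
    cov = np.cov(x, rowvar=False, ddof=1)
    c = cov - cov.mean(axis=0) - cov.mean(axis=1)[:, None] + cov.mean()
    eps = float(np.trace(c) ** 2 / ((k - 1) * np.sum(c * c)))
    eps = min(max(eps, 1.0 / (k - 1)), 1.0)
    p_gg = float(stats.f.sf(F, df1 * eps, df2 * eps))

    return RMAnovaResult(
        float(F), df1, df2, p, float(ss_cond), float(ss_subj), float(ss_res),
        eps, p_gg, False,
    )


def correlate_scores_with_rt(
    summaries: pd.DataFrame,
    scores: pd.DataFrame,
    scales: tuple[str, ...] = ("tpas_score", "pas_score"),
    measure: str = "mean_rt_correct",
) -> dict[str, CorrelationResult]:
    """Correlate scale scores with per-subject mean RT across conditions.

    The RT aggregate is the unweighted mean of the three condition means
    (conditions had equal trial counts by design, so this matches the
    trial-pooled mean in expectation).
    """
    agg = summaries.groupby("subject")[measure].mean()
    merged = scores.set_index("subject").join(agg.rename("_agg"), how="inner")
    if merged["_agg"].isna().any() or len(merged) < len(scores):
        raise ValueError("subjects in scores and summaries do not match")
    return {
        scale: pearson(merged[scale].to_numpy(), merged["_agg"].to_numpy())
        for scale in scales
    }
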