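"""Schizotypy questionnaire scoring and score-level statistics.

Two self-report instruments are supported:

* **tPAS** — temporal Perceptual Aberration Scale: 20 statements rated
  1 ("not at all") to 10 ("very much").  The scale score is the *mean* item
  rating, so it lives on the same 1-10 metric as the items.
* **PAS** — the classical (Chapman) Perceptual Aberration Scale: 35
  true/false items.  The scale score is the number of items endorsed in the
  keyed direction (0-35).  The official key lives in the Chapman instrument;
  by default every item is keyed "true", and a custom key can be supplied.

Also provides the two inferential primitives used throughout the analysis:
Pearson product-moment correlation with a two-tailed t-derived p value, and
the pooled-variance independent-samples t-test (accepting either raw score
vectors or (mean, sd, n) summaries, e.g. when only reported descriptives
are available).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "N_TPAS_ITEMS",
    "N_PAS_ITEMS",
    "tpas_items",
    "TPASResponse",
    "PASResponse",
    "score_tpas",
    "score_pas",
    "pearson",
    "adjust_pvalues",
    "independent_ttest",
    "GroupStats",
    "score_table",
    "read_scores",
    "write_scores",
]

N_TPAS_ITEMS = 20
N_PAS_ITEMS = 35


def tpas_items() -> list[str]:
    """The 20 tPAS statement texts, in item order."""
    text = (
        importlib.resources.files("timemap")
        .joinpath("data/tpas_items.txt")
        .read_text()
    )
    items = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        _num, stmt = line.split("\t", 1)
        items.append(stmt)
    if len(items) != N_TPAS_ITEMS:  # pragma: no cover - packaging guard
        raise RuntimeError("tPAS item file corrupted")
    return items


@dataclass(frozen=True)
class TPASResponse:
    subject: str
    ratings: tuple[int, ...]  # 20 integers in [1, 10]

    def __post_init__(self) -> None:
        _validate_tpas(self.ratings)


@dataclass(frozen=True)
class PASResponse:
    subject: str
    endorsements: tuple[bool, ...]  # 35 booleans

    def __post_init__(self) -> None:
        if len(self.endorsements) != N_PAS_ITEMS:
            raise ValueError(
                f"PAS requires exactly {N_PAS_ITEMS} items, "
                f"got {len(self.endorsements)}"
            )


def _validate_tpas(ratings: Sequence[int]) -> np.ndarray:
    arr = np.asarray(ratings)
    if arr.shape != (N_TPAS_ITEMS,):
        raise ValueError(
            f"tPAS requires exactly {N_TPAS_ITEMS} items, got {arr.shape}"
        )
    bad = [
        i + 1
        for i, v in enumerate(arr)
        if not (np.isfinite(v) and float(v).is_integer() and 1 <= v <= 10)
    ]
    if bad:
        raise ValueError(f"tPAS items out of range [1, 10] or missing: {bad}")
    return arr.astype(float)


def score_tpas(response: TPASResponse | Sequence[int]) -> float:
    """tPAS scale score: arithmetic mean of the 20 item ratings (1-10)."""
    ratings = (
        response.ratings if isinstance(response, TPASResponse) else response
    )
    return float(_validate_tpas(ratings).mean())


def score_pas(
    response: PASResponse | Sequence[bool],
    key: Sequence[bool] | None = None,
) -> int:
    """PAS scale score: count of endorsements in the keyed direction (0-35).

    ``key[i]`` is the keyed (pathological) answer for item ``i``; default all
    ``True``.
    """
    endo = (
        response.endorsements
        if isinstance(response, PASResponse)
        else response
    )
    arr = np.asarray(endo, dtype=bool)
    if arr.shape != (N_PAS_ITEMS,):
        raise ValueError(
            f"PAS requires exactly {N_PAS_ITEMS} items, got {arr.shape}"
        )
    keyed = (
        np.ones(N_PAS_ITEMS, dtype=bool)
        if key is None
        else np.asarray(key, dtype=bool)
    )
    if keyed.shape != (N_PAS_ITEMS,):
        raise ValueError("scoring key must have 35 entries")
    return int(np.sum(arr == keyed))


class CorrelationResult(NamedTuple):
    r: float
    p: float


def pearson(x, y) -> CorrelationResult:
    """Pearson product-moment r with two-tailed p (t-transform, n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    if x.size < 3:
        raise ValueError("Pearson correlation requires n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    res = stats.pearsonr(x, y)
    return CorrelationResult(float(res.statistic), float(res.pvalue))


def adjust_pvalues(pvalues, method: str = "holm") -> np.ndarray:
    """Multiple-testing adjustment: 'bonferroni', 'holm', or 'bh' (FDR).

    The study-default analyses report uncorrected two-tailed p values; this
    is the opt-in correction for users who want family-wise control.
    NaNs pass through untouched.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full_like(p, np.nan)
    mask = ~np.isnan(p)
    q = p[mask]
    m = q.size
    if m == 0:
        return out
    if method == "bonferroni":
        adj = np.minimum(q * m, 1.0)
    elif method == "holm":
        order = np.argsort(q)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * q[idx])
            adj[idx] = min(running, 1.0)
    elif method == "bh":
        order = np.argsort(q)
        adj = np.empty(m)
        running = 1.0
        for rank in range(m - 1, -1, -1):
            idx = order[rank]
            running = min(running, q[idx] * m / (rank + 1))
            adj[idx] = running
    else:
        raise ValueError(f"unknown adjustment method: {method!r}")
    out[mask] = adj
    return out


class GroupStats(NamedTuple):
    """Summary of one group for a summary-statistics t-test."""

    mean: float
    sd: float
    n: int


class TTestResult(NamedTuple):
    t: float
    df: int
    p: float


def _as_stats(group) -> GroupStats:
    if isinstance(group, GroupStats):
        return group
    if isinstance(group, tuple) and len(group) == 3:
        return GroupStats(*group)
    arr = np.asarray(group, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValueError("each group needs n >= 2 observations")
    return GroupStats(float(arr.mean()), float(arr.std(ddof=1)), int(arr.size))


def independent_ttest(group_a, group_b) -> TTestResult:
    """Pooled-variance two-sample t-test.

    Each group is either a raw 1-D vector or a ``(mean, sd, n)`` summary
    (``GroupStats``).  df = n_a + n_b - 2; p is two-tailed.
    """
    a, b = _as_stats(group_a), _as_stats(group_b)
    if a.n < 2 or b.n < 2:
        raise ValueError("each group needs n >= 2")
    if a.sd == 0 and b.sd == 0:
        raise ValueError("zero pooled variance: t undefined")
    t, p = stats.ttest_ind_from_stats(
        a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=True
    )
    return TTestResult(float(t), a.n + b.n - 2, float(p))


# ---------------------------------------------------------------------------
# delimited score tables


def score_table(subjects) -> pd.DataFrame:
    """One row per subject: id, sex, item columns, derived scale scores."""
    rows = []
    for s in subjects:
        row: dict = {"subject": s.subject, "sex": s.sex}
        for i, v in enumerate(s.tpas_ratings, start=1):
            row[f"tpas_{i:02d}"] = int(v)
        for i, v in enumerate(s.pas_endorsements, start=1):
            row[f"pas_{i:02d}"] = int(v)
        row["tpas_score"] = score_tpas(s.tpas_ratings)
        row["pas_score"] = score_pas(s.pas_endorsements)
        rows.append(row)
    return pd.DataFrame(rows)


def write_scores(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_scores(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
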