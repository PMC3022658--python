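"""EP microstate mapping: topographic segmentation, model-order selection,
competitive back-fitting and duration/GFP statistics.

Evoked-potential (EP) *microstates* are time segments during which the scalp
voltage topography stays quasi-stable.  The analysis has two stages:

1. **Segmentation** — a modified spatial k-means clusters the time-point
   topographies of the group-averaged EPs (all conditions concatenated) into
   ``q`` template maps.  The optimal ``q`` is chosen by a cross-validation
   criterion: the residual topographic variance penalized by the number of
   templates,

   ``CV(q) = sigma2 * ((N - 1) / (N - 1 - q))**2``

   with ``N`` electrodes and ``sigma2`` the mean per-sample map power left
   unexplained by the best-fitting template.

2. **Back-fitting** — the group templates are competitively fitted to each
   individual subject's EPs: every sample is assigned to the template with
   the highest spatial correlation, yielding per-map *duration* (assigned
   time points x sampling interval) and *mean GFP* (global field power, the
   spatial standard deviation of the map) per subject and condition.  These
   are the dependent variables for the within-subject ANOVAs and for the
   correlations with questionnaire scores.

Assignment is polarity-sensitive by default: these are stimulus-locked
evoked responses, where component polarity carries meaning (unlike
resting-state microstate analysis).  Set ``polarity_sensitive=False`` for
the classical polarity-invariant variant (squared correlation, eigenvector
template update).

``MicrostateModel`` / ``MicrostateResults`` follow the model/results split:
the model holds the group data and options, ``fit()`` returns a results
object carrying templates, labels, the CV curve and the back-fitting and
statistics methods.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from . import behavior
from .preprocess import Evoked
from .scales import CorrelationResult, pearson

__all__ = [
    "gfp",
    "spatial_corr",
    "normalize_map",
    "MicrostateModel",
    "MicrostateResults",
    "BackfitResult",
    "CVScore",
    "segment",
    "backfit",
    "cross_validation",
    "duration_statistics",
    "correlate_map_stats",
    "identify_time_map",
]

UNASSIGNED = -1


def gfp(x) -> np.ndarray:
    """Global field power: spatial standard deviation at each sample.

    ``sqrt(mean_c (v_c - mean(v))**2)`` — a reference-free amplitude
    measure.  Accepts an Evoked or a channels x samples array (or a single
    map).
    """
    data = x.data if isinstance(x, Evoked) else np.asarray(x, dtype=float)
    if data.ndim == 1:
        data = data[:, None]
    if data.shape[0] < 2:
        raise ValueError("GFP requires >= 2 channels")
    out = data.std(axis=0, ddof=0)
    return out if out.size > 1 else float(out[0])


def normalize_map(v: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-GFP version of a topography."""
    v = np.asarray(v, dtype=float)
    v = v - v.mean()
    g = v.std(ddof=0)
    if g == 0:
        raise ValueError("cannot normalize a flat map")
    return v / g


def spatial_corr(map_a, map_b, polarity_sensitive: bool = True) -> float:
    """Pearson correlation between two topographies across channels.

    With ``polarity_sensitive=False`` the absolute value is returned (for
    polarity-invariant assignment).
    """
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("maps must be 1-D with equal channel counts")
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("spatial correlation undefined for a flat map")
    r = float(a @ b / (na * nb))
    return abs(r) if not polarity_sensitive else r


class CVScore(NamedTuple):
    q: int
    sigma2: float
    cv: float
    n_channels: int


# ---------------------------------------------------------------------------
# internal helpers on centred data


def _center(data: np.ndarray) -> np.ndarray:
    return data - data.mean(axis=0, keepdims=True)


def _corr_matrix(templates: np.ndarray, data_c: np.ndarray) -> np.ndarray:
    """(q, T) spatial correlations; templates (q, N) zero-mean unit-GFP,
    data_c centred channels x samples."""
    norms = np.linalg.norm(data_c, axis=0)
    norms = np.where(norms == 0, 1.0, norms)
    tnorm = np.linalg.norm(templates, axis=1, keepdims=True)
    return (templates @ data_c) / (tnorm * norms[None, :])


def _assign(templates, data_c, polarity_sensitive):
    corr = _corr_matrix(templates, data_c)
    crit = corr if polarity_sensitive else np.abs(corr)
    # ties break to the lowest template index (argmax convention)
    return np.argmax(crit, axis=0), corr


def _update_template(maps: np.ndarray, polarity_sensitive: bool) -> np.ndarray:
    """New template from its assigned maps (channels x n_assigned)."""
    if polarity_sensitive:
        v = maps.sum(axis=1)  # amplitude-weighted mean
        if np.allclose(v, 0):
            v = maps[:, 0]
    else:
        # dominant spatial eigenvector of the map covariance
        _, _, vt = np.linalg.svd(maps.T, full_matrices=False)
        v = vt[0]
        # align polarity with the strongest assigned map
        ref = maps[:, np.argmax(np.linalg.norm(maps, axis=0))]
        if v @ ref < 0:
            v = -v
    return normalize_map(v)


def _kmeans_once(data_c, q, rng, polarity_sensitive, max_iter):
    n_ch, n_t = data_c.shape
    g = np.linalg.norm(data_c, axis=0)
    candidates = np.where(g > 0)[0]
    idx = rng.choice(candidates, size=q, replace=False)
    templates = np.array([normalize_map(data_c[:, i]) for i in idx])
    labels = np.full(n_t, -2)
    for _ in range(max_iter):
        new_labels, _ = _assign(templates, data_c, polarity_sensitive)
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for k in range(q):
            members = np.where(labels == k)[0]
            if members.size == 0:
                # re-seed an empty cluster at the worst-explained sample
                crit = _assign(templates, data_c, polarity_sensitive)[1]
                best = np.max(crit if polarity_sensitive else np.abs(crit), axis=0)
                worst = candidates[np.argmin(best[candidates])]
                templates[k] = normalize_map(data_c[:, worst])
            else:
                templates[k] = _update_template(
                    data_c[:, members], polarity_sensitive
                )
    labels, corr = _assign(templates, data_c, polarity_sensitive)
    return templates, labels, _gev(data_c, corr, labels)


def _gev(data_c, corr, labels) -> float:
    """Global explained variance: GFP^2-weighted squared correlation."""
    g2 = np.sum(data_c**2, axis=0)
    tot = g2.sum()
    if tot == 0:
        return 0.0
    r = corr[labels, np.arange(labels.size)]
    return float(np.sum(g2 * r**2) / tot)


# ---------------------------------------------------------------------------
# model / results


class MicrostateModel:
    """Spatial k-means microstate model of concatenated group-average EPs.

    Parameters
    ----------
    data : channels x samples array
        Group-averaged EPs, all conditions concatenated along time, already
        average-referenced.
    sfreq : float
        Sampling rate in Hz.
    polarity_sensitive : bool
        Assignment criterion (see module docstring).
    """

    def __init__(self, data, sfreq: float, polarity_sensitive: bool = True):
        data = np.asarray(data, dtype=float)
        if data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if sfreq <= 0:
            raise ValueError("sampling rate must be positive")
        self.data = data
        self.sfreq = float(sfreq)
        self.polarity_sensitive = bool(polarity_sensitive)
        self.condition_slices: dict[str, slice] = {}

    @classmethod
    def from_evokeds(
        cls, evokeds: Sequence[Evoked], polarity_sensitive: bool = True
    ) -> "MicrostateModel":
        """Concatenate per-condition group-average Evokeds along time."""
        if not evokeds:
            raise ValueError("need at least one evoked")
        sfreq = evokeds[0].sfreq
        if any(e.sfreq != sfreq for e in evokeds):
            raise ValueError("sampling rates differ across evokeds")
        model = cls(
            np.concatenate([e.data for e in evokeds], axis=1),
            sfreq,
            polarity_sensitive,
        )
        start = 0
        for e in evokeds:
            model.condition_slices[e.condition or str(start)] = slice(
                start, start + e.n_samples
            )
            start += e.n_samples
        return model

    def fit(
        self,
        n_maps: int | None = None,
        q_range: tuple[int, int] = (2, 12),
        n_restarts: int = 10,
        max_iter: int = 200,
        seed: int | np.random.SeedSequence | None = None,
    ) -> "MicrostateResults":
        """Fit templates; select ``n_maps`` by the CV criterion if not given.

        Runs ``n_restarts`` random initializations per candidate ``q`` and
        keeps the solution with the highest global explained variance;
        deterministic under a fixed seed.
        """
        data_c = _center(self.data)
        n_ch, n_t = data_c.shape
        qs = (
            [int(n_maps)]
            if n_maps is not None
            else list(range(q_range[0], min(q_range[1], n_ch - 2) + 1))
        )
        if min(qs) < 1:
            raise ValueError("number of maps must be >= 1")
        if max(qs) > n_t:
            raise ValueError("more maps requested than samples available")
        if max(qs) >= n_ch - 1:
            raise ValueError("CV criterion requires q < n_channels - 1")

        rng = np.random.default_rng(seed)
        fits = {}
        curve = []
        for q in qs:
            best = None
            for _ in range(max(1, int(n_restarts))):
                t, l, gev_ = _kmeans_once(
                    data_c, q, rng, self.polarity_sensitive, max_iter
                )
                if best is None or gev_ > best[2]:
                    best = (t, l, gev_)
            score = cross_validation(best[0], self.data, labels=best[1])
            fits[q] = best
            curve.append(score)
        cv_df = pd.DataFrame(curve)
        q_sel = int(cv_df.loc[cv_df["cv"].idxmin(), "q"])
        templates, labels, gev_val = fits[q_sel]
        return MicrostateResults(
            model=self,
            templates=templates,
            labels=labels,
            gev=gev_val,
            cv_curve=cv_df,
            n_maps=q_sel,
        )


@dataclass
class MicrostateResults:
    """Fitted microstate templates plus segmentation of the group data."""

    model: MicrostateModel
    templates: np.ndarray  # (q, channels), zero-mean unit-GFP rows
    labels: np.ndarray  # (samples,)
    gev: float
    cv_curve: pd.DataFrame
    n_maps: int

    @property
    def sfreq(self) -> float:
        return self.model.sfreq

    def segmentation(self) -> dict[str, np.ndarray]:
        """Per-condition label sequences (if built from_evokeds)."""
        if not self.model.condition_slices:
            return {"all": self.labels}
        return {
            cond: self.labels[sl]
            for cond, sl in self.model.condition_slices.items()
        }

    def backfit(
        self,
        evoked: Evoked,
        window_ms: tuple[float, float] | None = None,
        min_duration_samples: int = 1,
    ) -> "BackfitResult":
        return backfit(
            self.templates,
            evoked,
            window_ms=window_ms,
            min_duration_samples=min_duration_samples,
            polarity_sensitive=self.model.polarity_sensitive,
        )

    def backfit_cohort(
        self,
        evokeds: Sequence[Evoked],
        window_ms: tuple[float, float] | None = None,
        min_duration_samples: int = 1,
    ) -> pd.DataFrame:
        """Back-fit many individual Evokeds -> long fit table
        (subject, condition, template, duration_ms, mean_gfp)."""
        rows = []
        for ev in evokeds:
            res = self.backfit(ev, window_ms, min_duration_samples)
            t = res.table.copy()
            t.insert(0, "condition", ev.condition)
            t.insert(0, "subject", ev.subject)
            rows.append(t)
        return pd.concat(rows, ignore_index=True)

    def plot_cv_curve(self, ax=None):
        from .plotting import plot_cv_curve

        return plot_cv_curve(self, ax=ax)

    def plot_segmentation(self, condition=None, ax=None):
        from .plotting import plot_segmentation

        return plot_segmentation(self, condition=condition, ax=ax)

    def summary(self) -> str:
        lines = [
            "Microstate segmentation",
            "=" * 23,
            f"maps (q):            {self.n_maps}",
            f"channels:            {self.templates.shape[1]}",
            f"samples:             {self.labels.size}",
            f"polarity sensitive:  {self.model.polarity_sensitive}",
            f"global expl. var.:   {self.gev:.4f}",
            "",
            "CV criterion by q:",
            self.cv_curve.to_string(index=False, float_format=lambda v: f"{v:.6g}"),
        ]
        return "\n".join(lines)


class BackfitResult(NamedTuple):
    labels: np.ndarray  # full-length, UNASSIGNED outside the window
    table: pd.DataFrame  # template, duration_ms, mean_gfp, n_samples


# ---------------------------------------------------------------------------
# functional surface


def segment(
    group_evokeds: Sequence[Evoked],
    q: int,
    n_restarts: int = 10,
    seed=None,
    polarity_sensitive: bool = True,
) -> tuple[np.ndarray, np.ndarray, float]:
    """One-call segmentation: returns (templates, labels, explained variance)."""
    model = MicrostateModel.from_evokeds(group_evokeds, polarity_sensitive)
    res = model.fit(n_maps=q, n_restarts=n_restarts, seed=seed)
    return res.templates, res.labels, res.gev


def cross_validation(
    templates: np.ndarray, data: np.ndarray, labels: np.ndarray | None = None
) -> CVScore:
    """Cross-validation criterion for a fitted template set.

    ``sigma2`` is the mean over samples of the map power unexplained by the
    assigned template (unit-norm template vectors), divided by ``N - 1``;
    the criterion inflates it by ``((N - 1)/(N - 1 - q))**2``.
    """
    templates = np.asarray(templates, dtype=float)
    data_c = _center(np.asarray(data, dtype=float))
    n_ch, n_t = data_c.shape
    q = templates.shape[0]
    if q >= n_ch - 1:
        raise ValueError("CV criterion requires q < n_channels - 1")
    if labels is None:
        labels, _ = _assign(templates, data_c, polarity_sensitive=True)
    a = templates / np.linalg.norm(templates, axis=1, keepdims=True)
    proj = np.einsum("ct,tc->t", data_c, a[labels])  # a_label . x_t
    resid = np.maximum(np.sum(data_c**2, axis=0) - proj**2, 0.0)
    sigma2 = float(resid.sum() / (n_t * (n_ch - 1)))
    cv = sigma2 * ((n_ch - 1) / (n_ch - 1 - q)) ** 2
    return CVScore(q=q, sigma2=sigma2, cv=float(cv), n_channels=n_ch)


def _runs(labels: np.ndarray):
    """Yield (start, stop, label) for maximal constant runs."""
    if labels.size == 0:
        return
    change = np.flatnonzero(np.diff(labels)) + 1
    bounds = np.concatenate([[0], change, [labels.size]])
    for a, b in zip(bounds[:-1], bounds[1:]):
        yield int(a), int(b), int(labels[a])


def _smooth_min_duration(labels, corr, min_samples):
    """Reassign runs shorter than min_samples to the stronger neighbor."""
    labels = labels.copy()
    for _ in range(labels.size):  # bounded number of passes
        runs = list(_runs(labels))
        short = [
            (i, r) for i, r in enumerate(runs) if (r[1] - r[0]) < min_samples
        ]
        if not short or len(runs) == 1:
            break
        # handle the shortest run first
        i, (a, b, lab) = min(short, key=lambda t: t[1][1] - t[1][0])
        left = runs[i - 1][2] if i > 0 else None
        right = runs[i + 1][2] if i < len(runs) - 1 else None
        cands = [c for c in (left, right) if c is not None]
        strength = {c: corr[c, a:b].mean() for c in cands}
        labels[a:b] = max(cands, key=lambda c: strength[c])
    return labels


def backfit(
    templates: np.ndarray,
    evoked: Evoked,
    window_ms: tuple[float, float] | None = None,
    min_duration_samples: int = 1,
    polarity_sensitive: bool = True,
) -> BackfitResult:
    """Competitively fit templates to an individual EP.

    Every in-window sample is assigned to the template with the highest
    spatial correlation (polarity-sensitive by default); runs shorter than
    ``min_duration_samples`` are absorbed by the stronger neighboring
    template.  Returns the label sequence and a per-template table with
    duration (ms) and mean GFP over assigned samples (NaN when a template
    receives no sample).
    """
    templates = np.asarray(templates, dtype=float)
    if templates.ndim != 2 or templates.shape[1] != evoked.n_channels:
        raise ValueError("templates and evoked channel counts differ")
    if window_ms is None:
        sl = slice(0, evoked.n_samples)
    else:
        lo = int(np.ceil(window_ms[0] * evoked.sfreq / 1000.0 - 1e-9))
        hi = int(np.floor(window_ms[1] * evoked.sfreq / 1000.0 + 1e-9))
        sl = slice(max(lo, 0), min(hi, evoked.n_samples))
    if sl.stop <= sl.start:
        raise ValueError("empty back-fitting window")

    data_c = _center(evoked.data[:, sl])
    labels_w, corr = _assign(templates, data_c, polarity_sensitive)
    if min_duration_samples > 1:
        crit = corr if polarity_sensitive else np.abs(corr)
        labels_w = _smooth_min_duration(labels_w, crit, min_duration_samples)

    g = gfp(evoked.data[:, sl])
    dt_ms = 1000.0 / evoked.sfreq
    rows = []
    for k in range(templates.shape[0]):
        mask = labels_w == k
        rows.append(
            {
                "template": k,
                "duration_ms": float(mask.sum() * dt_ms),
                "mean_gfp": float(g[mask].mean()) if mask.any() else np.nan,
                "n_samples": int(mask.sum()),
            }
        )
    labels = np.full(evoked.n_samples, UNASSIGNED)
    labels[sl] = labels_w
    return BackfitResult(labels, pd.DataFrame(rows))


def duration_statistics(
    fit_table: pd.DataFrame, measure: str = "duration_ms"
) -> pd.DataFrame:
    """Within-subject ANOVA over conditions per template.

    Returns one row per template with F, df, p.  Templates with missing
    cells for ``measure`` (e.g. GFP of a never-assigned template) are
    evaluated on the complete-case subject subset; if fewer than two
    subjects remain the row carries NaNs.
    """
    out = []
    for tpl, g in fit_table.groupby("template"):
        sub = g.dropna(subset=[measure])
        counts = sub.groupby("subject")["condition"].nunique()
        n_cond = fit_table["condition"].nunique()
        complete = counts[counts == n_cond].index
        sub = sub[sub["subject"].isin(complete)]
        if complete.size < 2:
            out.append(
                {"template": tpl, "F": np.nan, "df1": np.nan, "df2": np.nan,
                 "p": np.nan, "n_subjects": int(complete.size),
                 "perfect_separation": False}
            )
            continue
        res = behavior.rm_anova(sub, measure=measure)
        out.append(
            {"template": tpl, "F": res.F, "df1": res.df1, "df2": res.df2,
             "p": res.p, "n_subjects": int(complete.size),
             "perfect_separation": res.perfect_separation}
        )
    return pd.DataFrame(out)


def identify_time_map(
    fit_table: pd.DataFrame, group_labels: np.ndarray | None = None
) -> int:
    """Template whose duration is most strongly modulated by condition
    (smallest duration-ANOVA p) — the operational definition of the
    condition-sensitive 'time-map'.

    When one segment's duration varies, its temporal neighbor necessarily
    shows the complementary (equally significant) effect; such near-ties
    (p within a factor of 10) are broken toward the template appearing
    *earliest* in the group segmentation ``group_labels`` when given,
    otherwise toward the lowest template index.
    """
    stats_df = duration_statistics(fit_table, "duration_ms")
    valid = stats_df.dropna(subset=["p"])
    if valid.empty:
        raise ValueError("no template with a complete duration table")
    p_min = valid["p"].min()
    tied = valid[valid["p"] <= max(p_min * 10.0, p_min + 1e-300)]["template"]
    if group_labels is None or len(tied) == 1:
        return int(tied.min())
    onsets = {}
    for tpl in tied:
        where = np.flatnonzero(np.asarray(group_labels) == tpl)
        onsets[int(tpl)] = where[0] if where.size else np.inf
    return min(onsets, key=lambda t: (onsets[t], t))


def correlate_map_stats(
    fit_table: pd.DataFrame,
    scores: pd.DataFrame,
    scales: tuple[str, ...] = ("tpas_score", "pas_score"),
    measures: tuple[str, ...] = ("duration_ms", "mean_gfp"),
) -> pd.DataFrame:
    """Pearson r/p of per-subject map statistics against scale scores.

    Each subject contributes the mean of the measure across the three
    conditions (NaN GFP cells are ignored in that mean).
    """
    sc = scores.set_index("subject")
    out = []
    for tpl, g in fit_table.groupby("template"):
        per_subj = g.groupby("subject")[list(measures)].mean()
        joined = per_subj.join(sc[list(scales)], how="inner")
        for measure in measures:
            for scale in scales:
                sub = joined.dropna(subset=[measure, scale])
                try:
                    r, p = pearson(sub[measure].to_numpy(), sub[scale].to_numpy())
                except ValueError:
                    r, p = np.nan, np.nan
                out.append(
                    {"template": tpl, "measure": measure, "scale": scale,
                     "r": r, "p": p, "n": int(len(sub))}
                )
    return pd.DataFrame(out)
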