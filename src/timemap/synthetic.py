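"""Synthetic study generator.

No raw data from the original experiments were ever deposited, so every
input of the analysis chain is simulated with the statistical structure the
analysis assumes: a single latent schizotypy trait per subject that loads on
the tPAS and PAS questionnaire responses, slows reaction times, and
lengthens the planted "time-map" microstate in the evoked potentials.
Default parameters live in ``calibration.yaml`` (see that file for the
measurement models and the summary statistics they were calibrated to).

The EP generator plants a fixed sequence of smooth, mutually orthogonal
template topographies over the 0-800 ms epoch; one segment (onset 350 ms)
has a condition- and trait-dependent duration and is the planted time-map.
Ground-truth segment boundaries are recorded next to every generated
evoked, so recovery can be scored exactly.
"""

from __future__ import annotations

import functools
import importlib.resources
import warnings
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .behavior import CONDITIONS
from .forward import HeadModel, SourceGrid, lead_field
from .montage import Montage, spherical_montage
from .preprocess import Evoked, n_samples_for_window
from .scales import score_pas, score_tpas

__all__ = [
    "calibration",
    "SubjectRecord",
    "CohortSpec",
    "BehaviorSpec",
    "EPGeneratorSpec",
    "generate_cohort",
    "generate_behavior",
    "generate_template_maps",
    "generate_evoked",
    "generate_eeg_cohort",
    "generate_forward",
    "TIMEMAP_ONSET_MS",
]


@functools.cache
def calibration() -> dict:
    """The documented default-parameter file, parsed once."""
    text = (
        importlib.resources.files("timemap").joinpath("calibration.yaml").read_text()
    )
    return yaml.safe_load(text)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


# ---------------------------------------------------------------------------
# cohort


@dataclass(frozen=True)
class SubjectRecord:
    subject: str
    sex: str  # "F" / "M"
    trait: float  # latent schizotypy z-score
    tpas_ratings: tuple[int, ...]
    pas_endorsements: tuple[bool, ...]

    @property
    def tpas_score(self) -> float:
        return score_tpas(self.tpas_ratings)

    @property
    def pas_score(self) -> int:
        return score_pas(self.pas_endorsements)


def _cal(section: str, key: str):
    return calibration()[section][key]


@dataclass(frozen=True)
class CohortSpec:
    """Latent-trait questionnaire cohort (defaults from calibration.yaml)."""

    n_subjects: int = 170
    sex_ratio: float = field(default_factory=lambda: _cal("cohort", "sex_ratio"))
    trait_mean: float = field(default_factory=lambda: _cal("cohort", "trait_mean"))
    trait_sd: float = field(default_factory=lambda: _cal("cohort", "trait_sd"))
    tpas_baseline: float = field(default_factory=lambda: _cal("cohort", "tpas_baseline"))
    tpas_loading: float = field(default_factory=lambda: _cal("cohort", "tpas_loading"))
    tpas_method_sd: float = field(default_factory=lambda: _cal("cohort", "tpas_method_sd"))
    tpas_item_sd: float = field(default_factory=lambda: _cal("cohort", "tpas_item_sd"))
    pas_intercept: float = field(default_factory=lambda: _cal("cohort", "pas_intercept"))
    pas_loading: float = field(default_factory=lambda: _cal("cohort", "pas_loading"))
    pas_method_sd: float = field(default_factory=lambda: _cal("cohort", "pas_method_sd"))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("cohort needs n_subjects >= 2")
        if not 0 <= self.sex_ratio <= 1:
            raise ValueError("sex_ratio must be in [0, 1]")
        for name in ("tpas_loading", "pas_loading", "tpas_baseline", "pas_intercept"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        for name in ("trait_sd", "tpas_method_sd", "tpas_item_sd", "pas_method_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def generate_cohort(spec: CohortSpec) -> list[SubjectRecord]:
    """Draw a cohort of subjects with trait-coupled questionnaire responses."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    z = spec.trait_mean + spec.trait_sd * rng.standard_normal(n)
    n_female = int(round(spec.sex_ratio * n))
    sexes = ["F"] * n_female + ["M"] * (n - n_female)

    u_t = spec.tpas_method_sd * rng.standard_normal(n)
    tpas_raw = (
        spec.tpas_baseline
        + spec.tpas_loading * z[:, None]
        + u_t[:, None]
        + spec.tpas_item_sd * rng.standard_normal((n, 20))
    )
    tpas = np.clip(np.rint(tpas_raw), 1, 10).astype(int)

    u_p = spec.pas_method_sd * rng.standard_normal(n)
    p = _sigmoid(spec.pas_intercept + spec.pas_loading * z + u_p)
    pas = rng.random((n, 35)) < p[:, None]

    return [
        SubjectRecord(
            subject=f"S{i + 1:04d}",
            sex=sexes[i],
            trait=float(z[i]),
            tpas_ratings=tuple(int(v) for v in tpas[i]),
            pas_endorsements=tuple(bool(v) for v in pas[i]),
        )
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# behavior


@dataclass(frozen=True)
class BehaviorSpec:
    """Condition-dependent lognormal reaction times coupled to the trait."""

    condition_rt_means: dict = field(
        default_factory=lambda: dict(_cal("behavior", "condition_rt_means"))
    )
    trait_rt_slope: float = field(default_factory=lambda: _cal("behavior", "trait_rt_slope"))
    rt_sd_between: float = field(default_factory=lambda: _cal("behavior", "rt_sd_between"))
    rt_lognormal_sigma: float = field(
        default_factory=lambda: _cal("behavior", "rt_lognormal_sigma")
    )
    rt_floor_ms: float = field(default_factory=lambda: _cal("behavior", "rt_floor_ms"))
    error_rates: dict = field(default_factory=lambda: dict(_cal("behavior", "error_rates")))
    error_logit_sd: float = field(default_factory=lambda: _cal("behavior", "error_logit_sd"))
    n_trials_per_condition: int = field(
        default_factory=lambda: _cal("behavior", "n_trials_per_condition")
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.condition_rt_means) != set(CONDITIONS):
            raise ValueError(f"condition_rt_means must cover {CONDITIONS}")
        if any(v <= 0 for v in self.condition_rt_means.values()):
            raise ValueError("all RT means must be positive")
        if not all(0 <= self.error_rates.get(c, -1) <= 1 for c in CONDITIONS):
            raise ValueError("error rates must be probabilities for all conditions")
        if self.n_trials_per_condition < 1:
            raise ValueError("need at least one trial per condition")
        for name in ("rt_sd_between", "rt_lognormal_sigma", "error_logit_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _logit(p):
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return np.log(p / (1 - p))


def generate_behavior(subjects, spec: BehaviorSpec) -> pd.DataFrame:
    """Trial table: subject, condition, event_category, direction, rt, correct.

    Per subject x condition, ``n_trials_per_condition`` trials split equally
    among the four stimulus groups (self/nonself x backward/forward).  The
    trial RT is multiplicative-lognormal noise around the subject's
    condition mean (condition mean + between-subject offset + trait slope x
    z, floored at ``rt_floor_ms`` to keep RTs physiological).
    """
    rng = np.random.default_rng(spec.seed)
    n_tr = spec.n_trials_per_condition
    cats = np.array(["self", "self", "nonself", "nonself"])
    dirs = np.array(["backward", "forward", "backward", "forward"])
    group = np.resize(np.arange(4), n_tr)
    sig = spec.rt_lognormal_sigma
    rows = []
    for s in subjects:
        offset = spec.rt_sd_between * rng.standard_normal()
        err_shift = spec.error_logit_sd * rng.standard_normal()
        for cond in CONDITIONS:
            mu = max(
                spec.condition_rt_means[cond] + offset + spec.trait_rt_slope * s.trait,
                spec.rt_floor_ms,
            )
            noise = (
                np.exp(sig * rng.standard_normal(n_tr) - 0.5 * sig**2)
                if sig > 0
                else np.ones(n_tr)
            )
            rt = mu * noise
            p_err = (
                _sigmoid(_logit(spec.error_rates[cond]) + err_shift)
                if spec.error_rates[cond] > 0
                else 0.0
            )
            correct = rng.random(n_tr) >= p_err
            order = rng.permutation(n_tr)
            for t in order:
                rows.append(
                    (s.subject, cond, cats[group[t]], dirs[group[t]],
                     float(rt[t]), bool(correct[t]))
                )
    return pd.DataFrame(
        rows,
        columns=["subject", "condition", "event_category", "direction", "rt", "correct"],
    )


# ---------------------------------------------------------------------------
# template maps


def generate_template_maps(montage: Montage, k: int, seed: int = 0) -> np.ndarray:
    """k smooth, mutually orthogonal, zero-mean, unit-GFP topographies.

    Built from random mixtures of low-order polynomial (spherical-harmonic
    like) functions of the electrode positions, centred and orthonormalized,
    so any pair has spatial correlation exactly 0.
    """
    n_ch = montage.n_channels
    if k > n_ch:
        raise ValueError("cannot build more orthogonal maps than channels")
    if k < 1:
        raise ValueError("k must be >= 1")
    x, y, z = montage.positions.T
    feats = np.column_stack(
        [x, y, z, x * y, y * z, z * x, x**2 - y**2, 2 * z**2 - x**2 - y**2,
         x * y * z, x * (x**2 - 3 * y**2), y * (3 * x**2 - y**2),
         z * (2 * z**2 - 3 * x**2 - 3 * y**2)]
    )
    m = feats.shape[1]
    if k > m:
        raise ValueError(f"smooth basis supports at most {m} maps")
    rng = np.random.default_rng(seed)
    mix = feats @ rng.standard_normal((m, k))
    mix = mix - mix.mean(axis=0, keepdims=True)
    q, _ = np.linalg.qr(mix)
    q = q - q.mean(axis=0, keepdims=True)  # numerically re-centre
    maps = q.T / q.T.std(axis=1, ddof=0)[:, None]
    return maps


# ---------------------------------------------------------------------------
# evoked potentials

TIMEMAP_ONSET_MS = 350.0

# (template, onset_ms, offset_ms); None marks the variable-duration time-map
# segment and the flexible onset of the segment that follows it.
DEFAULT_SEQUENCE = (
    (0, 0.0, 100.0),
    (1, 100.0, 220.0),
    (2, 220.0, 350.0),
    (3, 350.0, None),  # the planted time-map
    (4, None, 620.0),
    (5, 620.0, 800.0),
)


@dataclass(frozen=True)
class EPGeneratorSpec:
    """Planted-microstate evoked-potential generator."""

    n_channels: int = field(default_factory=lambda: _cal("ep", "n_channels"))
    sampling_rate: float = field(default_factory=lambda: _cal("ep", "sampling_rate"))
    epoch_ms: tuple[float, float] = field(
        default_factory=lambda: tuple(_cal("ep", "epoch_ms"))
    )
    template_sequence: tuple = DEFAULT_SEQUENCE
    timemap_duration_means: dict = field(
        default_factory=lambda: dict(_cal("ep", "timemap_duration_means"))
    )
    timemap_duration_resid_sd: dict = field(
        default_factory=lambda: dict(_cal("ep", "timemap_duration_resid_sd"))
    )
    trait_duration_slope: float = field(
        default_factory=lambda: _cal("ep", "trait_duration_slope")
    )
    noise_sd: float = field(default_factory=lambda: _cal("ep", "noise_sd"))
    envelope_floor: float = field(default_factory=lambda: _cal("ep", "envelope_floor"))
    envelope_peak: float = field(default_factory=lambda: _cal("ep", "envelope_peak"))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 2 or self.sampling_rate <= 0:
            raise ValueError("need >= 2 channels and a positive sampling rate")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.epoch_ms[1] <= self.epoch_ms[0]:
            raise ValueError("epoch window must be non-empty")
        if set(self.timemap_duration_means) != set(CONDITIONS):
            raise ValueError(f"timemap_duration_means must cover {CONDITIONS}")
        seq = self.template_sequence
        n_var = sum(1 for s in seq if s[2] is None)
        if n_var != 1:
            raise ValueError("exactly one variable-duration (time-map) segment required")
        var_at = next(i for i, s in enumerate(seq) if s[2] is None)
        if var_at + 1 >= len(seq) or seq[var_at + 1][1] is not None:
            raise ValueError("the segment after the time-map must have onset None")
        # fixed boundaries must be ordered and inside the epoch
        fixed = [s[1] for s in seq if s[1] is not None] + [
            s[2] for s in seq if s[2] is not None
        ]
        lo, hi = self.epoch_ms
        if any(not (lo <= t <= hi) for t in fixed):
            raise ValueError("segment boundaries outside the epoch window")

    @property
    def n_templates(self) -> int:
        return max(s[0] for s in self.template_sequence) + 1

    @property
    def timemap_template(self) -> int:
        return next(s[0] for s in self.template_sequence if s[2] is None)

    @property
    def n_samples(self) -> int:
        return n_samples_for_window(*self.epoch_ms, self.sampling_rate)


def _envelope(n: int, floor: float, peak: float) -> np.ndarray:
    """Smooth positive bump over a segment of n samples."""
    frac = (np.arange(n) + 0.5) / n
    return floor + (peak - floor) * np.sin(np.pi * frac) ** 2


def planted_timemap_duration(
    spec: EPGeneratorSpec, condition: str, trait: float, rng: np.random.Generator
) -> float:
    """Draw one subject x condition time-map duration (ms, pre-rounding)."""
    return (
        spec.timemap_duration_means[condition]
        + spec.trait_duration_slope * trait
        + spec.timemap_duration_resid_sd[condition] * rng.standard_normal()
    )


def generate_evoked(
    subject: SubjectRecord,
    condition: str,
    spec: EPGeneratorSpec,
    templates: np.ndarray,
    rng: np.random.Generator | None = None,
) -> tuple[Evoked, pd.DataFrame]:
    """One synthetic evoked potential plus its ground-truth segment table.

    voltage(t) = envelope(t) * active_template(t) + spatial Gaussian noise,
    re-referenced to the average at every sample.  The time-map segment's
    duration is condition- and trait-dependent, rounded to whole samples
    (clipped to >= 1 sample with a warning).
    """
    if templates.shape[0] < spec.n_templates:
        raise ValueError("template_sequence references more templates than provided")
    if templates.shape[1] != spec.n_channels:
        raise ValueError("template channel count does not match spec")
    if rng is None:
        subj_key = zlib.crc32(subject.subject.encode()) % 2**31
        rng = np.random.default_rng(
            [int(spec.seed), subj_key, CONDITIONS.index(condition)]
        )
    sf = spec.sampling_rate
    dt = 1000.0 / sf
    n = spec.n_samples

    d_ms = planted_timemap_duration(spec, condition, subject.trait, rng)
    d_samp = int(round(d_ms / dt))
    if d_samp < 1:
        warnings.warn("planted time-map duration rounded below one sample; clipped")
        d_samp = 1

    # resolve segment boundaries in samples
    seq = spec.template_sequence
    var_at = next(i for i, s in enumerate(seq) if s[2] is None)
    tm_on = int(round(seq[var_at][1] / dt))
    next_off = int(round(seq[var_at + 1][2] / dt))
    d_samp = min(d_samp, next_off - tm_on - 1)  # leave the next segment >= 1 sample
    bounds = []
    for i, (tpl, on, off) in enumerate(seq):
        if i == var_at:
            a, b = tm_on, tm_on + d_samp
        elif i == var_at + 1:
            a, b = tm_on + d_samp, int(round(off / dt))
        else:
            a, b = int(round(on / dt)), int(round(off / dt))
        bounds.append((tpl, min(a, n), min(b, n)))

    data = np.zeros((spec.n_channels, n))
    for tpl, a, b in bounds:
        if b > a:
            data[:, a:b] = (
                _envelope(b - a, spec.envelope_floor, spec.envelope_peak)[None, :]
                * templates[tpl][:, None]
            )
    if spec.noise_sd > 0:
        data += spec.noise_sd * rng.standard_normal(data.shape)
    data -= data.mean(axis=0, keepdims=True)

    truth = pd.DataFrame(
        [
            {
                "subject": subject.subject,
                "condition": condition,
                "template": tpl,
                "onset_ms": a * dt,
                "offset_ms": b * dt,
                "duration_ms": (b - a) * dt,
                "is_timemap": tpl == spec.timemap_template,
            }
            for tpl, a, b in bounds
        ]
    )
    evoked = Evoked(
        data=data,
        sfreq=sf,
        condition=condition,
        subject=subject.subject,
        reference="average",
        log=("synthetic",),
    )
    return evoked, truth


def generate_eeg_cohort(
    subjects,
    spec: EPGeneratorSpec,
    templates: np.ndarray | None = None,
    montage: Montage | None = None,
) -> tuple[list[Evoked], pd.DataFrame, np.ndarray]:
    """All subject x condition evokeds plus the ground-truth segment table.

    Returns ``(evokeds, truth, templates)``.  Child random streams are
    spawned deterministically from ``spec.seed`` per subject x condition.
    """
    if montage is None:
        montage = spherical_montage(spec.n_channels)
    if templates is None:
        templates = generate_template_maps(montage, spec.n_templates, seed=spec.seed)
    evokeds, truths = [], []
    for i, s in enumerate(subjects):
        for j, cond in enumerate(CONDITIONS):
            rng = np.random.default_rng([int(spec.seed), i, j])
            ev, truth = generate_evoked(s, cond, spec, templates, rng=rng)
            evokeds.append(ev)
            truths.append(truth)
    return evokeds, pd.concat(truths, ignore_index=True), templates


def generate_forward(
    montage: Montage, grid: SourceGrid, head: HeadModel | None = None
) -> np.ndarray:
    """Analytic concentric-spheres lead field for this montage and grid."""
    return lead_field(head or HeadModel(), grid, montage)
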