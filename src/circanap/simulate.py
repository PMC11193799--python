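"""Synthetic cohorts with known circadian ground truth.

Generates everything the analysis consumes — protocol schedules,
epoch-level hypnograms, melatonin series, subject covariates and
quantitative brain maps — from explicit generating models, so that
every downstream estimate can be checked against planted truth.

The REM generating curve for a window with midpoint at circadian time
``t_c`` (hours since DLMOn) and elapsed time ``t_e`` (hours since
baseline wake-up) is

    REM%(t) = a + b * t_e + h * exp(-(t_c - mu)^2 / (2 sigma^2))

clipped to [0, 95]: a baseline, a linear homeostatic accumulation and a
Gaussian circadian surge peaking in the biological night.  Sleep
efficiency follows the same shape on its own scale.  For the two
bracketing nights the circadian distance is wrapped to the nearest 24-h
cycle so that night sleep carries the circadian REM propensity of the
night it falls in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .melatonin import MelatoninSeries, SBCFParams, sbcf
from .protocol import (
    ProtocolConfig,
    ProtocolSchedule,
    Window,
    generate_protocol,
    melatonin_sample_times,
)

logger = logging.getLogger(__name__)

__all__ = [
    "STAGES",
    "SubjectTruth",
    "Hypnogram",
    "QuantMapSet",
    "PlantedCluster",
    "SubjectRecord",
    "CohortBundle",
    "MAP_PARAMS",
    "sample_subject_truth",
    "simulate_hypnogram",
    "simulate_melatonin",
    "simulate_maps",
    "simulate_cohort",
    "tissue_template",
    "default_acrophase",
]

STAGES = np.array(["W", "N1", "N2", "N3", "REM"])
_NONREM_SPLIT = np.array([0.18, 0.60, 0.22])  # N1 : N2 : N3 within NREM sleep

#: Per-map baselines and noise (units of the map): (gm, wm, noise_sd, age_slope)
MAP_PARAMS: dict[str, tuple[float, float, float, float]] = {
    "MTsat": (0.90, 1.80, 0.05, -0.004),   # percent units
    "R1": (0.65, 1.05, 0.03, -0.002),      # 1/s
    "R2star": (16.0, 21.0, 0.80, 0.02),    # 1/s
}


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _truncnorm(rng, mean, sd, lo, hi, size=None):
    """Truncated normal draws by rejection (exact truncation, no clipping)."""
    out = rng.normal(mean, sd, size=size)
    scalar = np.ndim(out) == 0
    out = np.atleast_1d(np.asarray(out, dtype=float))
    for _ in range(200):
        bad = (out < lo) | (out > hi)
        if not bad.any():
            break
        out[bad] = rng.normal(
            np.broadcast_to(mean, out.shape)[bad] if np.ndim(mean) else mean,
            sd, size=int(bad.sum()))
    np.clip(out, lo, hi, out=out)
    return float(out[0]) if scalar else out


def default_acrophase(dlmon_min: float, w_rise: float, nu: float) -> float:
    """Acrophase placing the 25% rising crossing exactly at ``dlmon_min``."""
    return dlmon_min + (2.0 * w_rise / np.pi) * np.arccos(0.25 ** (1.0 / nu))


@dataclass(frozen=True)
class SubjectTruth:
    """Ground-truth generating parameters for one synthetic subject."""

    a_true: float          # REM% baseline at DLMOn
    b_true: float          # REM% per elapsed hour (homeostatic accumulation)
    h_true: float          # REM% circadian amplitude
    mu_true: float         # circadian REM peak, hours since DLMOn
    sigma_true: float      # Gaussian width, hours
    sbcf_true: SBCFParams  # melatonin secretion truth
    dlmon_true: float      # minutes since baseline wake-up
    age: float             # years
    sex: int               # 0 = male, 1 = female
    education: float       # years
    napper: bool
    se_a: float = 50.0     # SE% baseline at DLMOn
    se_b: float = 0.3      # SE% per elapsed hour
    se_h: float = 35.0     # SE% circadian amplitude
    rem_noise_sd: float = 5.0   # nap-level truncated-Gaussian noise, REM%
    se_noise_sd: float = 5.0    # nap-level truncated-Gaussian noise, SE%

    def __post_init__(self) -> None:
        if self.h_true < 0:
            raise ValueError("h_true must be non-negative")
        if self.sigma_true <= 0:
            raise ValueError("sigma_true must be positive")


@dataclass(frozen=True)
class Hypnogram:
    """Scored sleep stages in fixed-length epochs for one window."""

    stages: np.ndarray        # array of stage labels in STAGES
    epoch_length: float       # seconds
    window_ref: str           # nap label or night id

    def __post_init__(self) -> None:
        s = np.asarray(self.stages)
        if not np.isin(s, STAGES).all():
            raise ValueError("unknown stage label in hypnogram")
        object.__setattr__(self, "stages", s)

    @property
    def n_epochs(self) -> int:
        return self.stages.size

    @property
    def duration_min(self) -> float:
        return self.n_epochs * self.epoch_length / 60.0


@dataclass(frozen=True)
class QuantMapSet:
    """One subject's quantitative maps plus tissue probability maps."""

    maps: dict[str, np.ndarray]   # keys MTsat, R1, R2star
    gm_prob: np.ndarray
    wm_prob: np.ndarray
    voxel_size: float             # mm, isotropic

    def __post_init__(self) -> None:
        shape = self.gm_prob.shape
        if self.wm_prob.shape != shape or any(
            m.shape != shape for m in self.maps.values()
        ):
            raise ValueError("all volumes must share one grid")
        for p in (self.gm_prob, self.wm_prob):
            if p.min() < 0 or p.max() > 1:
                raise ValueError("tissue probabilities must lie in [0, 1]")
        if (self.gm_prob + self.wm_prob).max() > 1 + 1e-9:
            raise ValueError("gm_prob + wm_prob must not exceed 1")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.gm_prob.shape


@dataclass(frozen=True)
class PlantedCluster:
    """A voxel block whose values depend linearly on true REM amplitude."""

    map_label: str                 # MTsat | R1 | R2star
    tissue: str                    # gm | wm (bookkeeping only)
    corner: tuple[int, int, int]
    size: tuple[int, int, int]
    beta_scale: float = 1.0        # converts the shared effect_beta to map units

    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(c, c + s) for c, s in zip(self.corner, self.size))

    def voxel_mask(self, shape: tuple[int, ...]) -> np.ndarray:
        mask = np.zeros(shape, dtype=bool)
        mask[self.slices()] = True
        return mask

    def validate(self, shape: tuple[int, ...]) -> None:
        if self.map_label not in MAP_PARAMS:
            raise ValueError(f"unknown map label {self.map_label!r}")
        for c, s, n in zip(self.corner, self.size, shape):
            if c < 0 or s < 1 or c + s > n:
                raise ValueError(
                    f"planted cluster {self.corner}+{self.size} exceeds "
                    f"volume shape {shape}"
                )


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    truth: SubjectTruth
    hypnograms: dict[str, "Hypnogram"]   # keyed by window label
    melatonin: MelatoninSeries
    maps: QuantMapSet


@dataclass(frozen=True)
class CohortBundle:
    config: ProtocolConfig
    schedule: ProtocolSchedule
    subjects: tuple[SubjectRecord, ...]
    effect_beta: float
    cluster_spec: tuple[PlantedCluster, ...]
    seed: int

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def truth_table(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            t = s.truth
            rows.append(dict(
                subject=s.subject_id, a_true=t.a_true, b_true=t.b_true,
                h_true=t.h_true, mu_true=t.mu_true, sigma_true=t.sigma_true,
                dlmon_true=t.dlmon_true, age=t.age, sex=t.sex,
                education=t.education, napper=int(t.napper),
            ))
        return pd.DataFrame(rows).set_index("subject")


# ---------------------------------------------------------------------------
# generating curves

def _circadian_gauss(t_circ_h, mu, sigma, wrap: bool):
    dt = np.asarray(t_circ_h, dtype=float) - mu
    if wrap:
        dt = (dt + 12.0) % 24.0 - 12.0
    return np.exp(-(dt**2) / (2.0 * sigma**2))


def expected_rem_pct(truth: SubjectTruth, window: Window, dlmon_min: float) -> float:
    """Noise-free REM% target for a window (clipped to [0, 95])."""
    t_e = window.midpoint_min / 60.0
    t_c = (window.midpoint_min - dlmon_min) / 60.0
    g = _circadian_gauss(t_c, truth.mu_true, truth.sigma_true,
                         wrap=window.kind == "night")
    val = truth.a_true + truth.b_true * t_e + truth.h_true * float(g)
    return float(np.clip(val, 0.0, 95.0))


def expected_se_pct(truth: SubjectTruth, window: Window, dlmon_min: float) -> float:
    """Noise-free sleep-efficiency target in percent (clipped to [5, 98])."""
    t_e = window.midpoint_min / 60.0
    t_c = (window.midpoint_min - dlmon_min) / 60.0
    g = _circadian_gauss(t_c, truth.mu_true, truth.sigma_true,
                         wrap=window.kind == "night")
    val = truth.se_a + truth.se_b * t_e + truth.se_h * float(g)
    return float(np.clip(val, 5.0, 98.0))


# ---------------------------------------------------------------------------
# simulators

def simulate_hypnogram(
    window: Window,
    truth: SubjectTruth,
    dlmon: float,
    seed,
    epoch_length: float = 30.0,
    schedule: ProtocolSchedule | None = None,
) -> Hypnogram:
    """Draw an epoch-level hypnogram for one nap or night window.

    Nap-level targets for SE and REM% are the generating curves plus
    truncated-Gaussian noise; epochs are then drawn independently from
    the implied stage distribution (W vs sleep by SE; REM vs NREM
    within sleep by REM%; NREM split across N1/N2/N3).  Reproducible
    given the seed.
    """
    if window.kind not in ("nap", "night"):
        raise ValueError(f"cannot simulate sleep in a {window.kind!r} window")
    if schedule is not None and window not in schedule:
        raise ValueError("window is not part of the supplied schedule")
    rng = _as_rng(seed)
    n_epochs = int(round(window.duration_min * 60.0 / epoch_length))

    rem_mean = expected_rem_pct(truth, window, dlmon)
    se_mean = expected_se_pct(truth, window, dlmon)
    rem_t = _truncnorm(rng, rem_mean, truth.rem_noise_sd, 0.0, 95.0)
    se_t = _truncnorm(rng, se_mean, truth.se_noise_sd, 5.0, 98.0)

    p_sleep = se_t / 100.0
    r = rem_t / 100.0
    probs = np.concatenate((
        [1.0 - p_sleep],
        p_sleep * (1.0 - r) * _NONREM_SPLIT,
        [p_sleep * r],
    ))
    probs /= probs.sum()
    idx = rng.choice(5, size=n_epochs, p=probs)
    # index order: W, N1, N2, N3, REM
    order = np.array(["W", "N1", "N2", "N3", "REM"])
    return Hypnogram(order[idx], epoch_length, window.label)


def simulate_melatonin(
    truth: SubjectTruth,
    config: ProtocolConfig,
    noise_sd: float = 0.2,
    seed=0,
) -> MelatoninSeries:
    """Sample the subject's secretion curve on the protocol's scheme.

    ``noise_sd`` is the standard deviation of multiplicative lognormal
    noise on the log scale; zero gives samples exactly on the model
    curve.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = _as_rng(seed)
    t = melatonin_sample_times(config)
    conc = np.asarray(sbcf(t, truth.sbcf_true), dtype=float)
    if noise_sd > 0:
        conc = conc * np.exp(rng.normal(0.0, noise_sd, size=t.size))
    return MelatoninSeries(t, conc)


def tissue_template(shape: tuple[int, int, int] = (16, 16, 16)):
    """Smooth synthetic tissue probability maps: a WM core, a GM shell."""
    grid = np.indices(shape, dtype=float)
    center = (np.asarray(shape, dtype=float) - 1.0) / 2.0
    r = np.sqrt(((grid - center[:, None, None, None]) ** 2).sum(axis=0))
    scale = min(shape) / 16.0
    wm = 0.85 * np.exp(-((r / (5.0 * scale)) ** 2))
    gm = 0.80 * np.exp(-(((r - 6.5 * scale) / (1.8 * scale)) ** 2))
    total = gm + wm
    over = total > 0.98
    gm[over] *= 0.98 / total[over]
    wm[over] *= 0.98 / total[over]
    return gm, wm


def sample_subject_truth(rng, config: ProtocolConfig) -> SubjectTruth:
    """Draw one subject's generating parameters from the cohort model."""
    rng = _as_rng(rng)
    sigma = _truncnorm(rng, 3.0, 0.5, 1.5, 6.0)
    t_min = _truncnorm(rng, -1.0, 0.5, -2.0, 2.0)  # pre-peak trough, h from DLMOn
    mu = t_min + 3.0 * sigma
    h = _truncnorm(rng, 15.0, 5.0, 0.0, 40.0)
    a = _truncnorm(rng, 10.0, 2.0, 2.0, 30.0)
    b = rng.normal(0.2, 0.1)
    dlmon = config.habitual_sleep_time_min - 120.0 + rng.normal(0.0, 30.0)
    w_rise = _truncnorm(rng, 180.0, 20.0, 120.0, 300.0)
    w_fall = _truncnorm(rng, 240.0, 25.0, 150.0, 360.0)
    nu = _truncnorm(rng, 2.0, 0.3, 1.0, 5.0)
    B = _truncnorm(rng, 2.0, 0.5, 0.5, 5.0)
    H = _truncnorm(rng, 10.0, 3.0, 3.0, 25.0)
    phi = default_acrophase(dlmon, w_rise, nu)
    return SubjectTruth(
        a_true=a, b_true=b, h_true=h, mu_true=mu, sigma_true=sigma,
        sbcf_true=SBCFParams(B, H, phi, w_rise, w_fall, nu),
        dlmon_true=dlmon,
        age=_truncnorm(rng, 69.0, 5.0, 59.0, 82.0),
        sex=int(rng.random() < 32.0 / 86.0),
        education=_truncnorm(rng, 14.0, 3.0, 8.0, 22.0),
        napper=bool(rng.random() < 0.65),
    )


def simulate_maps(
    truth: SubjectTruth,
    rng,
    gm_prob: np.ndarray,
    wm_prob: np.ndarray,
    effect_beta: float,
    cluster_spec: tuple[PlantedCluster, ...],
    voxel_size: float = 2.0,
    map_noise: float = 1.0,
    ref_age: float = 69.0,
) -> QuantMapSet:
    """Quantitative maps: tissue baseline + age effect + planted REM effect."""
    rng = _as_rng(rng)
    brain = gm_prob + wm_prob
    maps = {}
    for label, (gm_base, wm_base, noise_sd, age_slope) in MAP_PARAMS.items():
        vol = gm_prob * gm_base + wm_prob * wm_base
        vol = vol + age_slope * (truth.age - ref_age) * brain
        if map_noise > 0:
            vol = vol + rng.normal(0.0, noise_sd * map_noise, size=vol.shape)
        for cl in cluster_spec:
            if cl.map_label == label:
                vol[cl.slices()] += effect_beta * cl.beta_scale * truth.h_true
        maps[label] = vol
    return QuantMapSet(maps, gm_prob, wm_prob, voxel_size)


def simulate_cohort(
    n_subjects: int,
    effect_beta: float = 0.0,
    cluster_spec=(),
    seed: int = 0,
    config: ProtocolConfig | None = None,
    volume_shape: tuple[int, int, int] = (16, 16, 16),
    voxel_size: float = 2.0,
    melatonin_noise_sd: float = 0.2,
    map_noise: float = 1.0,
    drop_naps: int = 0,
) -> CohortBundle:
    """Simulate a full cohort with planted ground truth.

    Each subject gets a schedule-aligned set of hypnograms (all naps
    plus both nights), a melatonin series, covariates and a
    :class:`QuantMapSet` in which ``cluster_spec`` blocks carry a
    ``effect_beta * beta_scale * h_true`` offset.  ``drop_naps``
    randomly deletes that many nap hypnograms across the cohort to
    exercise missing-nap handling.
    """
    cfg = config or ProtocolConfig()
    schedule = generate_protocol(cfg)
    cluster_spec = tuple(cluster_spec)
    for cl in cluster_spec:
        cl.validate(volume_shape)
    gm_prob, wm_prob = tissue_template(volume_shape)
    master = np.random.default_rng(seed)

    subjects = []
    for i in range(n_subjects):
        rng = np.random.default_rng(master.integers(0, 2**31 - 1))
        truth = sample_subject_truth(rng, cfg)
        hyps: dict[str, Hypnogram] = {}
        for w in schedule:
            if w.kind == "wake":
                continue
            hyps[w.label] = simulate_hypnogram(
                w, truth, truth.dlmon_true, rng,
                epoch_length=cfg.epoch_length,
            )
        mel = simulate_melatonin(truth, cfg, melatonin_noise_sd, rng)
        maps = simulate_maps(
            truth, rng, gm_prob, wm_prob, effect_beta, cluster_spec,
            voxel_size=voxel_size, map_noise=map_noise,
        )
        subjects.append(SubjectRecord(f"sub-{i:03d}", truth, hyps, mel, maps))

    if drop_naps > 0:
        nap_labels = [w.label for w in schedule.naps]
        pairs = [(i, lab) for i in range(n_subjects) for lab in nap_labels]
        drop_idx = master.choice(len(pairs), size=min(drop_naps, len(pairs)),
                                 replace=False)
        for k in drop_idx:
            i, lab = pairs[int(k)]
            hyps = dict(subjects[i].hypnograms)
            hyps.pop(lab, None)
            subjects[i] = replace(subjects[i], hypnograms=hyps)
            logger.info("dropped nap %s for %s", lab, subjects[i].subject_id)

    return CohortBundle(cfg, schedule, tuple(subjects), effect_beta,
                        cluster_spec, seed)
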