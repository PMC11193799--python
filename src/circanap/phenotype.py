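"""Nap phenotyping: sleep metrics, circadian alignment and curve fits.

Per nap, sleep efficiency (SE: epochs in N1+N2+N3+REM over the whole
sleep opportunity) and REM% (REM epochs over total sleep time) are
scored from the hypnogram.  Nap values are re-expressed on circadian
time (hours since DLMOn), interpolated with a cubic B-spline onto the
fixed theoretical grid −12, −8, −4, 0, 4, 8, 12, 16, 20, 24 h, and the
profile is fitted with a line-plus-Gaussian model

    f(t) = a + b*t + h * exp(-(t - mu)^2 / (2 sigma^2)),

whose Gaussian height ``h`` is the circadian amplitude and whose slope
``b`` is the homeostatic accumulation.  The curve's pre-peak trough
``t_min = mu - 3 sigma`` (where the Gaussian surge departs baseline) is
constrained to a window of +/- 2 h around DLMOn, anchoring the fit to
the melatonin-defined phase.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import make_interp_spline
from scipy.optimize import least_squares

from .melatonin import PhaseEstimate, extract_dlmo, fit_sbcf
from .protocol import ProtocolSchedule
from .simulate import CohortBundle, Hypnogram, SubjectRecord

logger = logging.getLogger(__name__)

__all__ = [
    "CIRCADIAN_GRID",
    "NIGHT_GRID_POINTS",
    "SLEEP_STAGES",
    "NapMetrics",
    "CircadianSeries",
    "CircadianFit",
    "score_window",
    "align_to_dlmon",
    "interpolate_series",
    "fit_circadian_model",
    "circadian_curve",
    "session_contrasts",
    "baseline_association",
    "phenotype_subject",
    "phenotype_cohort",
]

#: Theoretical circadian grid, hours since DLMOn.
CIRCADIAN_GRID = np.array([-12.0, -8.0, -4.0, 0.0, 4.0, 8.0, 12.0, 16.0, 20.0, 24.0])
#: Grid points falling in the biological night (the two night-time naps).
NIGHT_GRID_POINTS = (4.0, 8.0)
SLEEP_STAGES = ("N1", "N2", "N3", "REM")


@dataclass(frozen=True)
class NapMetrics:
    """Per-window sleep metrics; rem_pct is NaN when no sleep occurred."""

    nap_index: int
    midpoint_min: float     # minutes since baseline wake-up
    se: float               # fraction of opportunity spent asleep, [0, 1]
    rem_pct: float          # REM time as % of total sleep time, or NaN
    tst_min: float          # total sleep time, minutes

    @property
    def rem_defined(self) -> bool:
        return np.isfinite(self.rem_pct)


@dataclass(frozen=True)
class CircadianSeries:
    """A metric interpolated onto the theoretical circadian grid."""

    grid: np.ndarray
    values: np.ndarray
    source: str                    # 'rem_pct' | 'se_pct'
    clamped: np.ndarray            # grid points evaluated at the span edge

    def __post_init__(self) -> None:
        if not np.array_equal(self.grid, CIRCADIAN_GRID):
            raise ValueError("grid must be the fixed 10-point circadian grid")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("interpolated values must be finite")


@dataclass(frozen=True)
class CircadianFit:
    """Line-plus-Gaussian fit of a circadian profile."""

    a: float         # intercept, metric units
    b: float         # accumulation slope, units per hour
    h: float         # circadian amplitude (Gaussian height), units
    mu: float        # peak, hours since DLMOn
    sigma: float     # Gaussian width, hours
    t_min: float     # pre-peak trough mu - 3 sigma, hours since DLMOn
    rss: float
    converged: bool
    source: str = ""


def score_window(hyp: Hypnogram, opportunity_minutes: float) -> NapMetrics:
    """Compute SE and REM% for one scored window.

    A window with zero total sleep time gets ``rem_pct = NaN`` (missing,
    not zero): absence of sleep says nothing about REM propensity.
    """
    covered = hyp.n_epochs * hyp.epoch_length / 60.0
    if abs(covered - opportunity_minutes) > hyp.epoch_length / 60.0:
        raise ValueError(
            f"hypnogram covers {covered:.1f} min but opportunity is "
            f"{opportunity_minutes:.1f} min"
        )
    stages = hyp.stages
    n_sleep = int(np.isin(stages, SLEEP_STAGES).sum())
    n_rem = int((stages == "REM").sum())
    tst = n_sleep * hyp.epoch_length / 60.0
    se = tst / opportunity_minutes
    rem_pct = 100.0 * n_rem / n_sleep if n_sleep > 0 else float("nan")
    idx = int(hyp.window_ref.split("_")[-1]) if hyp.window_ref.startswith("nap_") else -1
    return NapMetrics(idx, float("nan"), se, rem_pct, tst)


def align_to_dlmon(
    metrics: list[NapMetrics],
    phase: PhaseEstimate,
    metric: str = "rem_pct",
) -> list[tuple[float, float]]:
    """Express nap metrics on circadian time (hours since DLMOn).

    Undefined values (NaN) are dropped: a missing nap stays missing.
    """
    if not phase.converged:
        raise ValueError("phase estimate did not converge; cannot align")
    out = []
    for m in metrics:
        value = getattr(m, metric) if metric != "se_pct" else 100.0 * m.se
        t = (m.midpoint_min - phase.dlmon) / 60.0
        if np.isfinite(value):
            out.append((float(t), float(value)))
    return out


def interpolate_series(
    points: list[tuple[float, float]],
    source: str = "rem_pct",
) -> CircadianSeries:
    """Cubic B-spline interpolation onto the theoretical circadian grid.

    The interpolating spline (not-a-knot end conditions) passes through
    every input point exactly.  Grid points outside the observed time
    span are evaluated at the nearest span edge and flagged as clamped.
    """
    if len(points) < 4:
        raise ValueError(f"need >= 4 points to interpolate, got {len(points)}")
    t = np.array([p[0] for p in points], dtype=float)
    y = np.array([p[1] for p in points], dtype=float)
    order = np.argsort(t)
    t, y = t[order], y[order]
    if np.min(np.diff(t)) <= 0:
        raise ValueError("duplicate circadian times in input points")
    spline = make_interp_spline(t, y, k=3)
    eval_t = np.clip(CIRCADIAN_GRID, t[0], t[-1])
    clamped = eval_t != CIRCADIAN_GRID
    if clamped.any():
        logger.debug("clamped grid points: %s", CIRCADIAN_GRID[clamped])
    return CircadianSeries(CIRCADIAN_GRID.copy(), spline(eval_t), source, clamped)


def circadian_curve(t, a, b, h, mu, sigma):
    """Evaluate the line-plus-Gaussian model."""
    t = np.asarray(t, dtype=float)
    return a + b * t + h * np.exp(-((t - mu) ** 2) / (2.0 * sigma**2))


def fit_circadian_model(
    series: CircadianSeries,
    window_halfwidth_h: float = 2.0,
) -> CircadianFit:
    """Constrained least-squares fit of the line-plus-Gaussian model.

    The fit is parameterized over (a, b, h, t_min, sigma) with
    ``mu = t_min + 3 sigma``, so the box bound
    ``t_min in [-window_halfwidth_h, +window_halfwidth_h]`` enforces the
    phase-anchoring constraint exactly: the trough from which the
    circadian surge rises must sit within the window around DLMOn.
    Multi-start over trough and width initializations guards against
    local minima; the lowest-RSS solution is returned.

    The Gaussian width is bounded to [2, 12] h: the floor is half the
    4-h grid spacing, below which a surge is unresolvable and the
    least-squares surface rewards spike solutions of arbitrary height.
    The height is capped at three times the observed data range for the
    same reason.
    """
    y = series.values
    t = series.grid
    w = float(window_halfwidth_h)
    if np.ptp(y) < 1e-12:
        return CircadianFit(float(y.mean()), 0.0, 0.0, 3.0 * 3.0, 3.0,
                            0.0, 0.0, True, series.source)

    def resid(theta):
        a, b, h, t_min, sigma = theta
        mu = t_min + 3.0 * sigma
        return circadian_curve(t, a, b, h, mu, sigma) - y

    # sigma floor = half the 4-h grid spacing: narrower surges cannot be
    # resolved by the sampling and produce runaway spike fits; the height
    # cap likewise ties the Gaussian to the observed data range.
    span = float(np.ptp(y))
    scale = max(abs(y).max(), 1.0)
    lb = np.array([-20.0 * scale, -10.0 * scale, 0.0, -w, 2.0])
    ub = np.array([20.0 * scale, 10.0 * scale, 3.0 * span + 1e-6, w, 12.0])
    b0 = float(np.polyfit(t, y, 1)[0])
    a0 = float(np.clip(np.min(y), lb[0], ub[0]))
    h0 = float(np.clip(span, lb[2], ub[2]))

    best = None
    for t_min0 in (-1.5, 0.0, 1.5):
        for sigma0 in (2.0, 3.0, 5.0):
            theta0 = np.clip(
                np.array([a0, b0, h0, t_min0, sigma0]), lb, ub
            )
            try:
                sol = least_squares(resid, theta0, bounds=(lb, ub), method="trf")
            except Exception:  # pragma: no cover
                continue
            rss = float(np.sum(sol.fun**2))
            if best is None or rss < best[0] - 1e-12:
                best = (rss, sol)
    if best is None:  # pragma: no cover - all starts failed
        return CircadianFit(a0, b0, h0, 0.0 + 9.0, 3.0, 0.0,
                            float("inf"), False, series.source)
    rss, sol = best
    a, b, h, t_min, sigma = sol.x
    return CircadianFit(float(a), float(b), float(h),
                        float(t_min + 3.0 * sigma), float(sigma),
                        float(t_min), rss, bool(sol.success), series.source)


def session_contrasts(
    grid_values: pd.DataFrame | np.ndarray,
    night_points: tuple[float, ...] = NIGHT_GRID_POINTS,
) -> pd.DataFrame:
    """Standardized day-vs-night contrasts per circadian grid point.

    ``grid_values`` holds one row per subject and one column per grid
    point (ordered as :data:`CIRCADIAN_GRID`).  For every non-night
    grid point the paired difference against the subject's mean over
    the night-time naps is summarized as mean difference / SD of
    differences; negative effects mean lower than night.  Subjects with
    a missing night value are excluded (and counted).
    """
    vals = np.asarray(grid_values, dtype=float)
    if vals.ndim != 2 or vals.shape[1] != CIRCADIAN_GRID.size:
        raise ValueError("expected an (n_subjects, 10) array of grid values")
    night_idx = [int(np.where(CIRCADIAN_GRID == p)[0][0]) for p in night_points]
    have_night = np.isfinite(vals[:, night_idx]).all(axis=1)
    n_excluded = int((~have_night).sum())
    if n_excluded:
        logger.info("session_contrasts: excluded %d subjects missing night naps",
                    n_excluded)
    vals = vals[have_night]
    if vals.shape[0] < 2:
        raise ValueError("need >= 2 subjects with both night naps")
    night_mean = vals[:, night_idx].mean(axis=1)
    rows = []
    for j, g in enumerate(CIRCADIAN_GRID):
        if g in night_points:
            continue
        d = vals[:, j] - night_mean
        ok = np.isfinite(d)
        sd = float(np.std(d[ok], ddof=1))
        md = float(np.mean(d[ok]))
        degenerate = sd <= 1e-10 * max(1.0, abs(md))
        eff = 0.0 if degenerate else md / sd
        rows.append(dict(grid_h=float(g), mean_diff=md,
                         sd_diff=sd, effect=eff, n=int(ok.sum())))
    out = pd.DataFrame(rows)
    out.attrs["n_excluded"] = n_excluded
    return out


def baseline_association(
    amplitudes,
    baseline_rem_pct,
    age,
    sex,
    se,
) -> dict:
    """OLS of circadian REM amplitude on baseline-night REM%.

    Covariates: age, sex and baseline-night SE.  Returns the
    baseline-REM coefficient, its t statistic, residual df and p-value.
    """
    import statsmodels.api as sm

    cols = {
        "baseline_rem": np.asarray(baseline_rem_pct, dtype=float),
        "age": np.asarray(age, dtype=float),
        "sex": np.asarray(sex, dtype=float),
        "se": np.asarray(se, dtype=float),
    }
    y = np.asarray(amplitudes, dtype=float)
    X = pd.DataFrame(cols)
    X = sm.add_constant(X)
    ok = np.isfinite(y) & np.isfinite(X.to_numpy()).all(axis=1)
    y, X = y[ok], X[ok]
    if y.size < X.shape[1] + 2:
        raise ValueError("too few complete cases for the regression")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        _, R = np.linalg.qr(X.to_numpy())
        bad = [X.columns[i] for i in range(X.shape[1])
               if abs(R[i, i]) < 1e-8 * abs(R).max()]
        raise ValueError(f"design is rank deficient; collinear columns: {bad}")
    res = sm.OLS(y, X).fit()
    return dict(
        coefficient=float(res.params["baseline_rem"]),
        t=float(res.tvalues["baseline_rem"]),
        df=int(res.df_resid),
        p=float(res.pvalues["baseline_rem"]),
        n=int(y.size),
    )


# ---------------------------------------------------------------------------
# per-subject pipeline

def phenotype_subject(
    record: SubjectRecord,
    schedule: ProtocolSchedule,
    window_halfwidth_h: float = 2.0,
    min_naps: int = 4,
) -> dict | None:
    """Full phenotyping of one subject; None when the subject is unusable.

    Fits the melatonin curve, scores every available nap, interpolates
    REM% and SE onto the circadian grid and fits the circadian model to
    both.  A subject is excluded when the melatonin fit fails or fewer
    than ``min_naps`` naps have defined REM%.
    """
    sfit = fit_sbcf(record.melatonin)
    if not sfit.converged or sfit.params.H <= 0:
        logger.warning("%s: melatonin fit unusable", record.subject_id)
        return None
    phase = extract_dlmo(sfit)

    nap_metrics: list[NapMetrics] = []
    for w in schedule.naps:
        hyp = record.hypnograms.get(w.label)
        if hyp is None:
            continue
        m = score_window(hyp, w.duration_min)
        nap_metrics.append(
            NapMetrics(m.nap_index, w.midpoint_min, m.se, m.rem_pct, m.tst_min)
        )
    defined = [m for m in nap_metrics if m.rem_defined]
    if len(defined) < min_naps:
        logger.warning("%s: only %d naps with defined REM%%",
                       record.subject_id, len(defined))
        return None

    rem_pts = align_to_dlmon(nap_metrics, phase, "rem_pct")
    se_pts = align_to_dlmon(nap_metrics, phase, "se_pct")
    rem_series = interpolate_series(rem_pts, "rem_pct")
    se_series = interpolate_series(se_pts, "se_pct")
    rem_fit = fit_circadian_model(rem_series, window_halfwidth_h)
    se_fit = fit_circadian_model(se_series, window_halfwidth_h)

    base = record.hypnograms.get("baseline_night")
    night_w = next(w for w in schedule.nights if w.label == "baseline_night")
    if base is not None:
        bm = score_window(base, night_w.duration_min)
        baseline_rem, baseline_se = bm.rem_pct, 100.0 * bm.se
    else:  # pragma: no cover - generator always provides the nights
        baseline_rem = baseline_se = float("nan")

    row = dict(
        subject=record.subject_id,
        dlmon=phase.dlmon,
        dlmoff=phase.dlmoff,
        rem_amp=rem_fit.h, rem_slope=rem_fit.b,
        se_amp=se_fit.h, se_slope=se_fit.b,
        mu=rem_fit.mu, sigma=rem_fit.sigma, t_min=rem_fit.t_min,
        mean_rem=float(np.mean([m.rem_pct for m in defined])),
        mean_se=float(np.mean([100.0 * m.se for m in nap_metrics])),
        baseline_rem=baseline_rem, baseline_se=baseline_se,
        age=record.truth.age, sex=record.truth.sex,
        education=record.truth.education,
        rem_converged=rem_fit.converged, se_converged=se_fit.converged,
    )
    row["_rem_grid"] = rem_series.values
    row["_se_grid"] = se_series.values
    return row


def phenotype_cohort(
    bundle: CohortBundle,
    window_halfwidth_h: float = 2.0,
) -> pd.DataFrame:
    """Phenotype every subject in a cohort; excluded subjects are dropped.

    Returns one row per usable subject, indexed by subject id, with the
    circadian grid values stored in the frame's ``attrs`` for contrast
    analyses.
    """
    rows, rem_grids, se_grids = [], [], []
    for rec in bundle.subjects:
        row = phenotype_subject(rec, bundle.schedule, window_halfwidth_h)
        if row is None:
            logger.info("excluding %s from cohort phenotypes", rec.subject_id)
            continue
        rem_grids.append(row.pop("_rem_grid"))
        se_grids.append(row.pop("_se_grid"))
        rows.append(row)
    df = pd.DataFrame(rows).set_index("subject")
    df.attrs["rem_grid"] = np.vstack(rem_grids) if rem_grids else np.empty((0, 10))
    df.attrs["se_grid"] = np.vstack(se_grids) if se_grids else np.empty((0, 10))
    return df
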