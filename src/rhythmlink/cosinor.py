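"""Multi-component cosinor rhythmometry.

The cosinor model fits a time series with a linear combination of cosines at
fixed candidate periods,

    y_i = M + sum_c A_c * cos(2*pi*(t_i - phi_c) / T_c) + e_i,

linearized to an ordinary least-squares problem on per-period cosine/sine
regressors (beta_c = A_c cos(2*pi*phi_c/T_c), gamma_c = A_c sin(2*pi*phi_c/T_c)).
M is the MESOR (rhythm-adjusted mean), A_c the amplitude and phi_c the
acrophase of component c — here expressed in hours from the reference
midnight to the component's peak, in [0, T_c).

Per period the model reports percent rhythm (R^2 of the single-period fit)
and the zero-amplitude F test of that fit; for the full model it reports the
integrated percent rhythm/P value, and the magnitude, orthophase and
bathyphase of the composite curve over the fundamental period (the LCM of the
input periods).  Standard errors for amplitude and acrophase come from
first-order (delta-method) propagation of the coefficient covariance through
the polar transform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .preprocess import impute_series
from .series import HourlySeries

__all__ = [
    "CosinorDesign",
    "CosinorRegressor",
    "RhythmFit",
    "UnderdeterminedDesignError",
    "SingularFitError",
    "build_design",
    "fit_cosinor",
    "component_parameters",
    "rhythm_tests",
    "curve_extrema",
    "window_fits",
    "fits_to_frame",
    "PARAMETER_COLUMNS",
]

HOURS_PER_WEEK = 168
DEFAULT_PERIODS = (8.0, 12.0, 24.0)


class UnderdeterminedDesignError(ValueError):
    """Fewer distinct time points than the design needs."""


class SingularFitError(ValueError):
    """Design matrix is rank deficient (e.g. duplicated period columns)."""


def _fundamental_period(periods: Sequence[float]) -> float:
    """Least common multiple of the periods (exact for rational periods)."""
    fracs = [Fraction(p).limit_denominator(10**6) for p in periods]
    num = 1
    for f in fracs:
        num = num * f.numerator // math.gcd(num, f.numerator)
    den = fracs[0].denominator
    for f in fracs[1:]:
        den = math.gcd(den, f.denominator)
    return float(Fraction(num, den))


def _check_periods(periods: Iterable[float]) -> tuple[float, ...]:
    periods = tuple(float(p) for p in periods)
    if not periods:
        raise ValueError("at least one period required")
    if any(p <= 0 for p in periods):
        raise ValueError("periods must be positive")
    if len(set(periods)) != len(periods):
        raise ValueError("periods must be distinct")
    return tuple(sorted(periods))


@dataclass(frozen=True)
class CosinorDesign:
    """Linearized design: intercept plus cos/sin columns per period."""

    times: np.ndarray
    periods: tuple[float, ...]
    fundamental_period: float
    matrix: np.ndarray
    column_names: tuple[str, ...]


def build_design(times, periods=DEFAULT_PERIODS) -> CosinorDesign:
    """Build the cosinor regression design for the given sampling times.

    Requires at least ``2*len(periods) + 2`` distinct times so the residual
    degrees of freedom are positive.
    """
    periods = _check_periods(periods)
    t = np.asarray(times, dtype=float).ravel()
    n_distinct = np.unique(t).size
    n_cols = 1 + 2 * len(periods)
    if n_distinct < n_cols + 1:
        raise UnderdeterminedDesignError(
            f"need >= {n_cols + 1} distinct times for periods {periods}, got {n_distinct}"
        )
    cols = [np.ones_like(t)]
    names = ["intercept"]
    for period in periods:
        w = 2.0 * np.pi * t / period
        cols.extend([np.cos(w), np.sin(w)])
        names.extend([f"cos-{period:g}", f"sin-{period:g}"])
    return CosinorDesign(
        times=t,
        periods=periods,
        fundamental_period=_fundamental_period(periods),
        matrix=np.column_stack(cols),
        column_names=tuple(names),
    )


def component_parameters(beta, gamma, covariance, period):
    """Polar rhythm parameters and delta-method SEs for one component.

    ``covariance`` is the 3x3 coefficient covariance for (intercept, beta,
    gamma).  Returns (amplitude, acrophase_hours, amp_se, phi_se_hours,
    mesor_se); for a zero-amplitude component the acrophase is conventionally
    0 and its SE is undefined (NaN).
    """
    cov = np.asarray(covariance, dtype=float)
    if cov.shape != (3, 3):
        raise ValueError("covariance must be 3x3 for (intercept, beta, gamma)")
    if not np.allclose(cov, cov.T, atol=1e-10):
        raise ValueError("covariance must be symmetric")
    mesor_se = float(np.sqrt(max(cov[0, 0], 0.0)))
    amp = float(np.hypot(beta, gamma))
    if amp == 0.0:
        return 0.0, 0.0, float("nan"), float("nan"), mesor_se
    phi = (period / (2.0 * np.pi)) * math.atan2(gamma, beta) % period
    g_amp = np.array([0.0, beta / amp, gamma / amp])
    g_phi = (period / (2.0 * np.pi)) * np.array([0.0, -gamma / amp**2, beta / amp**2])
    amp_se = float(np.sqrt(max(g_amp @ cov @ g_amp, 0.0)))
    phi_se = float(np.sqrt(max(g_phi @ cov @ g_phi, 0.0)))
    return amp, float(phi), amp_se, phi_se, mesor_se


def _ols(X: np.ndarray, y: np.ndarray):
    """Least squares with residual diagnostics; raises on rank deficiency."""
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise SingularFitError(f"design rank {rank} < {X.shape[1]} columns")
    resid = y - X @ coef
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    return coef, rss, tss


def _r2_and_ftest(rss: float, tss: float, n: int, k: int):
    """R^2 and zero-amplitude F test with (k, n-k-1) degrees of freedom.

    A constant series (tss == 0) has no rhythm by definition: R^2 = 0, p = 1.
    """
    dfe = n - k - 1
    if tss <= 0 or dfe <= 0:
        return 0.0, 1.0
    r2 = max(0.0, 1.0 - rss / tss)
    if rss <= 0 or r2 >= 1.0:  # numerically perfect fit
        return 1.0, 0.0
    f_stat = (r2 / k) / ((1.0 - r2) / dfe)
    return r2, float(stats.f.sf(f_stat, k, dfe))


def curve_extrema(coef, periods, grid_step_minutes: float = 1.0):
    """Magnitude, orthophase and bathyphase of the composite fitted curve.

    Evaluates the curve on a regular grid over one fundamental period;
    magnitude is half the max-min range, orthophase/bathyphase the times of
    the maximum/minimum (earliest time on ties, by grid order).
    """
    periods = _check_periods(periods)
    fundamental = _fundamental_period(periods)
    t = np.arange(0.0, fundamental, grid_step_minutes / 60.0)
    curve = np.full_like(t, float(coef[0]))
    for i, period in enumerate(periods):
        w = 2.0 * np.pi * t / period
        curve += coef[1 + 2 * i] * np.cos(w) + coef[2 + 2 * i] * np.sin(w)
    magnitude = float((curve.max() - curve.min()) / 2.0)
    orthophase = float(t[np.argmax(curve)])
    bathyphase = float(t[np.argmin(curve)])
    return magnitude, orthophase, bathyphase


class CosinorRegressor(RegressorMixin, BaseEstimator):
    """Least-squares multi-component cosinor model.

    Parameters
    ----------
    periods : sequence of float, default (8, 12, 24)
        Candidate periods in hours (nocturnal, diurnal and circadian cycles
        for the defaults).  Fixed, not estimated.
    grid_step_minutes : float, default 1.0
        Grid resolution for locating the composite curve's extrema.

    Attributes
    ----------
    coef_ : ndarray of shape (2*C + 1,)
        (M, beta_1, gamma_1, ..., beta_C, gamma_C) in period-sorted order.
    mesor_, mesor_se_ : float
    amplitude_, acrophase_, amp_se_, phi_se_ : dict period -> float
        Acrophase in hours from the reference midnight, in [0, T).
    percent_rhythm_, p_value_ : dict period -> float
        R^2 and zero-amplitude F-test p of the single-period refit.
    integrated_percent_rhythm_, integrated_p_ : float
        R^2 and overall F-test p of the full multi-period model.
    magnitude_, orthophase_, bathyphase_ : float
        Extrema summary of the composite curve over the fundamental period.
    covariance_ : ndarray
        Coefficient covariance, residual_variance_ * (X'X)^-1.
    """

    def __init__(self, periods=DEFAULT_PERIODS, grid_step_minutes: float = 1.0):
        self.periods = periods
        self.grid_step_minutes = grid_step_minutes

    def fit(self, X, y):
        t = np.asarray(X, dtype=float)
        if t.ndim == 2:
            if t.shape[1] != 1:
                raise ValueError("X must be 1-dimensional sampling times (hours)")
            t = t[:, 0]
        y = np.asarray(y, dtype=float).ravel()
        if t.shape[0] != y.shape[0]:
            raise ValueError("X and y lengths differ")
        if np.isnan(y).any():
            raise ValueError("series must be imputed before fitting (NaN present)")

        design = build_design(t, self.periods)
        X_mat = design.matrix
        n, p = X_mat.shape
        coef, rss, tss = _ols(X_mat, y)

        self.design_ = design
        self.periods_ = design.periods
        self.fundamental_period_ = design.fundamental_period
        self.n_obs_ = n
        self.coef_ = coef
        dfe = n - p
        self.residual_variance_ = rss / dfe if dfe > 0 else float("nan")
        xtx_inv = np.linalg.inv(X_mat.T @ X_mat)
        self.covariance_ = self.residual_variance_ * xtx_inv

        self.mesor_ = float(coef[0])
        self.amplitude_, self.acrophase_ = {}, {}
        self.amp_se_, self.phi_se_ = {}, {}
        for i, period in enumerate(self.periods_):
            bi, gi = 1 + 2 * i, 2 + 2 * i
            block = self.covariance_[np.ix_([0, bi, gi], [0, bi, gi])]
            amp, phi, amp_se, phi_se, mesor_se = component_parameters(
                coef[bi], coef[gi], block, period
            )
            self.amplitude_[period] = amp
            self.acrophase_[period] = phi
            self.amp_se_[period] = amp_se
            self.phi_se_[period] = phi_se
        self.mesor_se_ = float(np.sqrt(max(self.covariance_[0, 0], 0.0)))

        # single-period refits: percent rhythm is R^2 of "the model using an
        # individual period", not a partition of the full model's SS
        self.percent_rhythm_, self.p_value_ = {}, {}
        for period in self.periods_:
            sub = build_design(t, [period]).matrix
            _, rss_1, tss_1 = _ols(sub, y)
            r2, pval = _r2_and_ftest(rss_1, tss_1, n, 2)
            self.percent_rhythm_[period] = r2
            self.p_value_[period] = pval
        ipr, ip = _r2_and_ftest(rss, tss, n, p - 1)
        self.integrated_percent_rhythm_ = ipr
        self.integrated_p_ = ip

        self.magnitude_, self.orthophase_, self.bathyphase_ = curve_extrema(
            coef, self.periods_, self.grid_step_minutes
        )
        return self

    def predict(self, X):
        t = np.asarray(X, dtype=float)
        if t.ndim == 2:
            t = t[:, 0]
        curve = np.full_like(t, self.coef_[0], dtype=float)
        for i, period in enumerate(self.periods_):
            w = 2.0 * np.pi * t / period
            curve += self.coef_[1 + 2 * i] * np.cos(w) + self.coef_[2 + 2 * i] * np.sin(w)
        return curve


@dataclass
class RhythmFit:
    """All rhythm parameters for one participant x feature x week window."""

    participant_id: str
    feature_name: str
    week: int | None
    n_obs: int
    periods: tuple[float, ...]
    fundamental_period: float
    mesor: float
    mesor_se: float
    amplitude: dict
    acrophase: dict
    amp_se: dict
    phi_se: dict
    percent_rhythm: dict
    p_value: dict
    integrated_percent_rhythm: float
    integrated_p: float
    magnitude: float
    orthophase: float
    bathyphase: float
    residual_variance: float
    model: CosinorRegressor = field(repr=False, default=None)  # type: ignore[assignment]

    def to_row(self) -> dict:
        row = {
            "participant_id": self.participant_id,
            "feature": self.feature_name,
            "week": self.week,
            "n_obs": self.n_obs,
            "MESOR": self.mesor,
            "MESOR_SE": self.mesor_se,
        }
        for period in self.periods:
            tag = f"{period:g}"
            row[f"Amp-{tag}"] = self.amplitude[period]
            row[f"Amp_SE-{tag}"] = self.amp_se[period]
            row[f"PHI-{tag}"] = self.acrophase[period]
            row[f"PHI_SE-{tag}"] = self.phi_se[period]
            row[f"PR-{tag}"] = self.percent_rhythm[period]
            row[f"P-{tag}"] = self.p_value[period]
        row["IPR"] = self.integrated_percent_rhythm
        row["IP"] = self.integrated_p
        row["magnitude"] = self.magnitude
        row["orthophase"] = self.orthophase
        row["bathyphase"] = self.bathyphase
        return row


def PARAMETER_COLUMNS(periods=DEFAULT_PERIODS) -> list[str]:
    """Names of the rhythm-parameter columns for the given periods."""
    cols = ["MESOR", "MESOR_SE"]
    for period in _check_periods(periods):
        tag = f"{period:g}"
        cols += [f"Amp-{tag}", f"Amp_SE-{tag}", f"PHI-{tag}", f"PHI_SE-{tag}",
                 f"PR-{tag}", f"P-{tag}"]
    cols += ["IPR", "IP", "magnitude", "orthophase", "bathyphase"]
    return cols


def fit_cosinor(
    series: HourlySeries,
    periods=DEFAULT_PERIODS,
    week: int | None = None,
    time_reference: float | None = None,
) -> RhythmFit:
    """Fit the cosinor model to one (fully imputed) hourly series.

    ``time_reference`` sets the hour counted as phase zero (defaults to the
    first hour of the series, i.e. the window-start midnight when windows are
    cut on week boundaries).
    """
    if series.missing_mask.any():
        raise ValueError("series contains missing hours; impute before fitting")
    ref = float(series.hours[0]) if time_reference is None else float(time_reference)
    t = series.hours.astype(float) - ref
    model = CosinorRegressor(periods=periods).fit(t, series.values)
    return RhythmFit(
        participant_id=series.participant_id,
        feature_name=series.feature_name,
        week=week,
        n_obs=model.n_obs_,
        periods=model.periods_,
        fundamental_period=model.fundamental_period_,
        mesor=model.mesor_,
        mesor_se=model.mesor_se_,
        amplitude=dict(model.amplitude_),
        acrophase=dict(model.acrophase_),
        amp_se=dict(model.amp_se_),
        phi_se=dict(model.phi_se_),
        percent_rhythm=dict(model.percent_rhythm_),
        p_value=dict(model.p_value_),
        integrated_percent_rhythm=model.integrated_percent_rhythm_,
        integrated_p=model.integrated_p_,
        magnitude=model.magnitude_,
        orthophase=model.orthophase_,
        bathyphase=model.bathyphase_,
        residual_variance=model.residual_variance_,
        model=model,
    )


def rhythm_tests(series: HourlySeries, periods=DEFAULT_PERIODS):
    """Percent rhythm and zero-amplitude significance per period plus the
    integrated (full-model) pair: ({PR_c}, {P_c}, IPR, IP)."""
    fit = fit_cosinor(series, periods)
    return fit.percent_rhythm, fit.p_value, fit.integrated_percent_rhythm, fit.integrated_p


def window_fits(
    streams: Iterable[HourlySeries],
    survey_weeks: Sequence[int] = (1, 6, 15),
    periods=DEFAULT_PERIODS,
    window_radius: int = 1,
    n_weeks: int | None = None,
    max_missing: float = 0.20,
) -> tuple[list[RhythmFit], pd.DataFrame]:
    """Fit each stream in a window of weeks around every survey week.

    For survey week w the window covers weeks max(1, w-radius) to
    min(n_weeks, w+radius) (hours are 1-indexed weeks of 168 h, truncated at
    the study edges).  The missing-data discard rule is applied per window:
    windows with ``max_missing`` or more of their hours missing are logged
    and skipped, the rest are imputed and fitted.
    """
    streams = list(streams)
    fits: list[RhythmFit] = []
    log_rows = []
    for stream in streams:
        total_weeks = n_weeks or int(math.ceil((stream.hours.max() + 1) / HOURS_PER_WEEK))
        for w in survey_weeks:
            lo = max(1, w - window_radius)
            hi = min(total_weeks, w + window_radius)
            start, stop = (lo - 1) * HOURS_PER_WEEK, hi * HOURS_PER_WEEK
            entry = {
                "participant_id": stream.participant_id,
                "feature": stream.feature_name,
                "week": w,
                "window_start_hour": start,
                "window_stop_hour": stop,
            }
            try:
                win = stream.window(start, stop)
            except ValueError:
                log_rows.append({**entry, "fraction_missing": 1.0, "decision": "no-data"})
                continue
            frac = win.fraction_missing
            if frac >= max_missing:
                log_rows.append({**entry, "fraction_missing": frac, "decision": "discarded"})
                continue
            win = impute_series(win)
            try:
                fit = fit_cosinor(win, periods=periods, week=w, time_reference=start)
            except (UnderdeterminedDesignError, SingularFitError) as exc:
                log_rows.append(
                    {**entry, "fraction_missing": frac, "decision": f"fit-error: {exc}"}
                )
                continue
            fits.append(fit)
            log_rows.append({**entry, "fraction_missing": frac, "decision": "fitted"})
    log = pd.DataFrame(
        log_rows,
        columns=["participant_id", "feature", "week", "window_start_hour",
                 "window_stop_hour", "fraction_missing", "decision"],
    )
    return fits, log


def fits_to_frame(fits: Iterable[RhythmFit]) -> pd.DataFrame:
    """One row per fit, one column per rhythm parameter (heat-map layout)."""
    rows = [f.to_row() for f in fits]
    if not rows:
        return pd.DataFrame(columns=["participant_id", "feature", "week", "n_obs"])
    return pd.DataFrame(rows)
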