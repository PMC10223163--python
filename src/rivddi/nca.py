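"""Non-compartmental analysis of concentration-time profiles.

Model-free exposure metrics: linear-trapezoid AUC over a window, peak
concentration and its time, terminal log-linear slope (lambda_z) with the
derived half-life, the between-arm relative-change statistic, and the
two-fold model-qualification check against observed clinical values.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    InvalidInputError,
    InvalidWindowError,
    UndefinedLambdaZError,
)
from .params import ConcentrationProfile

__all__ = [
    "NCAResult",
    "ClinicalReference",
    "TwoFoldResult",
    "auc_trapezoid",
    "cmax_tmax",
    "terminal_lambda_z",
    "relative_change",
    "two_fold_check",
    "nca",
]


@dataclass(frozen=True)
class NCAResult:
    """Non-compartmental metrics of one profile."""

    auc_tau: float        # ng*h/mL, AUC over the dosing interval
    auc_inf: float        # ng*h/mL, AUC extrapolated to infinity (nan if lambda_z undefined)
    cmax: float           # ng/mL
    tmax: float           # h
    lambda_z: float       # 1/h
    t_half: float         # h
    n_points_lambda: int


@dataclass(frozen=True)
class ClinicalReference:
    """Observed clinical value of one metric: mean with its reported range."""

    label: str
    mean: float
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (self.low <= self.mean <= self.high):
            raise InvalidInputError("clinical reference requires low <= mean <= high")


@dataclass(frozen=True)
class TwoFoldResult:
    """Outcome of the two-fold prediction-accuracy check."""

    passed: bool
    ratio: float          # predicted / observed mean
    predicted: float
    reference: ClinicalReference


def auc_trapezoid(profile: ConcentrationProfile, t_start: float, t_end: float) -> float:
    """Linear-trapezoid AUC of ``profile`` over ``[t_start, t_end]`` (ng*h/mL).

    Window edges that fall between grid points are handled by linear
    interpolation.
    """
    t, c = profile.times, profile.conc
    if t_start < t[0] - 1e-12 or t_end > t[-1] + 1e-12 or t_end < t_start:
        raise InvalidWindowError(
            f"window [{t_start}, {t_end}] outside sampled range [{t[0]}, {t[-1]}]"
        )
    inside = (t > t_start) & (t < t_end)
    tt = np.concatenate(([t_start], t[inside], [t_end]))
    cc = np.concatenate(
        ([np.interp(t_start, t, c)], c[inside], [np.interp(t_end, t, c)])
    )
    return float(np.trapezoid(cc, tt))


def cmax_tmax(profile: ConcentrationProfile) -> tuple[float, float]:
    """Grid maximum concentration and its time (first occurrence on ties)."""
    i = int(np.argmax(profile.conc))
    return float(profile.conc[i]), float(profile.times[i])


def terminal_lambda_z(
    profile: ConcentrationProfile, n_points: int | None = None
) -> tuple[float, float]:
    """Terminal elimination rate constant and half-life by log-linear OLS.

    With ``n_points`` given, the regression uses the last ``n_points``
    samples (sparse clinical-style schedules); otherwise the window is the
    last 25 % of the sampled time span (dense simulation grids).  All
    concentrations in the window must be strictly positive.
    """
    t, c = profile.times, profile.conc
    if n_points is None:
        span = t[-1] - t[0]
        mask = t >= t[-1] - 0.25 * span
        tt, cc = t[mask], c[mask]
    else:
        if n_points < 3:
            raise InvalidInputError("lambda_z regression needs at least 3 points")
        tt, cc = t[-n_points:], c[-n_points:]
    if len(tt) < 3:
        raise InvalidInputError("lambda_z regression needs at least 3 points")
    if np.any(cc <= 0):
        raise UndefinedLambdaZError("non-positive concentrations in lambda_z window")
    slope, _ = np.polyfit(tt, np.log(cc), 1)
    lambda_z = -float(slope)
    if lambda_z <= 0:
        raise UndefinedLambdaZError("terminal slope is non-negative")
    return lambda_z, float(np.log(2.0) / lambda_z)


def relative_change(ref_value: float, test_value: float) -> float:
    """Percent decrease of ``test_value`` relative to ``ref_value``.

    ``(1 - test/ref) * 100``: positive when the test arm is lower.
    """
    if ref_value <= 0:
        raise InvalidInputError("reference value must be positive")
    return (1.0 - test_value / ref_value) * 100.0


def two_fold_check(predicted: float, reference: ClinicalReference) -> TwoFoldResult:
    """Pass iff the prediction lies within 0.5-2x the observed mean."""
    if predicted <= 0 or reference.mean <= 0:
        raise InvalidInputError("two-fold check requires positive values")
    ratio = predicted / reference.mean
    return TwoFoldResult(
        passed=0.5 <= ratio <= 2.0, ratio=ratio, predicted=predicted, reference=reference
    )


def nca(
    profile: ConcentrationProfile,
    tau: float | None = None,
    n_points_lambda: int | None = None,
) -> NCAResult:
    """Full non-compartmental workup of one profile.

    ``auc_tau`` covers ``[t0, t0 + tau]`` (the whole grid when ``tau`` is
    None).  ``auc_inf`` adds the tail ``C_last / lambda_z``; it is NaN when
    the terminal slope cannot be estimated.
    """
    t = profile.times
    t_end = t[-1] if tau is None else t[0] + tau
    auc = auc_trapezoid(profile, t[0], t_end)
    cmax, tmax = cmax_tmax(profile)
    try:
        lambda_z, t_half = terminal_lambda_z(profile, n_points_lambda)
        n_used = n_points_lambda if n_points_lambda is not None else int(
            np.sum(t >= t[-1] - 0.25 * (t[-1] - t[0]))
        )
        auc_inf = auc_trapezoid(profile, t[0], t[-1]) + profile.conc[-1] / lambda_z
    except (UndefinedLambdaZError, InvalidInputError):
        lambda_z, t_half, auc_inf, n_used = np.nan, np.nan, np.nan, 0
    return NCAResult(
        auc_tau=auc,
        auc_inf=auc_inf,
        cmax=cmax,
        tmax=tmax,
        lambda_z=lambda_z,
        t_half=t_half,
        n_points_lambda=n_used,
    )
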