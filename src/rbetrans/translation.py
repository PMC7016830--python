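"""Quadratic regression between paired LEM and mMKM dose-volume points.

Per volume level v, patient dose-volume points ``(D_LEM|v, D_MKM|v)`` from
the same plan computed in the two RBE languages are fitted with an
ordinary-least-squares quadratic

    D_MKM|v = a * D_LEM|v^2 + b * D_LEM|v + c

and the fit is inverted, with a 95% confidence band on the mean response,
to translate MKM-language dose constraints into LEM-language values. The
crossing of the *upper* band with the MKM target gives the *lower* (i.e.
conservative, clinically adopted) LEM bound.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .dvh import VolumeSpec

__all__ = [
    "PairedDosePoints",
    "QuadraticFit",
    "TranslatedConstraint",
    "fit_quadratic",
    "fit_quadratic_xy",
    "confidence_band",
    "translate_dvh_point",
    "translate_constraint",
    "translation_table",
]

MIN_POINTS = 4


@dataclass(frozen=True)
class PairedDosePoints:
    """Per-v-level paired dose-volume points, one record per patient."""

    v_level: VolumeSpec
    patient_ids: tuple[str, ...]
    d_lem: np.ndarray
    d_mkm: np.ndarray

    def __post_init__(self) -> None:
        d_lem = np.asarray(self.d_lem, dtype=float)
        d_mkm = np.asarray(self.d_mkm, dtype=float)
        if d_lem.shape != d_mkm.shape or d_lem.ndim != 1:
            raise ValueError("d_lem and d_mkm must be 1-D arrays of equal length")
        if len(self.patient_ids) != d_lem.size:
            raise ValueError("one patient id per pair is required")
        if len(set(self.patient_ids)) != len(self.patient_ids):
            raise ValueError("duplicate patient id within a v-level")
        if np.any(d_lem < 0) or np.any(d_mkm < 0):
            raise ValueError("doses must be non-negative")
        object.__setattr__(self, "d_lem", d_lem)
        object.__setattr__(self, "d_mkm", d_mkm)

    def __len__(self) -> int:
        return self.d_lem.size


@dataclass(frozen=True)
class QuadraticFit:
    """OLS fit of ``y = a x^2 + b x + c`` with coefficient covariance."""

    a: float
    b: float
    c: float
    coef_covariance: np.ndarray  # order (a, b, c)
    residual_variance: float
    n_points: int
    r_squared: float
    domain: tuple[float, float]

    def __post_init__(self) -> None:
        cov = np.asarray(self.coef_covariance, dtype=float)
        if cov.shape != (3, 3):
            raise ValueError("coef_covariance must be 3x3")
        cov = 0.5 * (cov + cov.T)
        if np.any(np.linalg.eigvalsh(cov) < -1e-8 * max(1.0, abs(cov).max())):
            raise ValueError("coef_covariance must be positive semi-definite")
        if self.n_points < MIN_POINTS:
            raise ValueError(f"at least {MIN_POINTS} points are required")
        object.__setattr__(self, "coef_covariance", cov)

    @property
    def coefficients(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c])

    def standard_errors(self) -> np.ndarray:
        return np.sqrt(np.diag(self.coef_covariance))

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        return self.a * x**2 + self.b * x + self.c


def fit_quadratic_xy(
    x: Sequence[float],
    y: Sequence[float],
    cov_type: Literal["classical", "hc3", "cluster"] = "classical",
    cluster_ids: Sequence | None = None,
) -> QuadraticFit:
    """Least-squares quadratic through raw (x, y) dose pairs.

    ``cov_type`` selects the coefficient covariance: ``classical`` is the
    homoscedastic OLS estimate (default, what the published regressions
    report); ``hc3`` is the leverage-corrected heteroscedasticity-robust
    sandwich; ``cluster`` is the cluster-robust sandwich over
    ``cluster_ids`` — appropriate for pooled all-v fits, where the several
    v-level points of one patient share a random offset.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < MIN_POINTS:
        raise ValueError(f"at least {MIN_POINTS} pairs are required for fitting")
    design = np.vstack([x**2, x, np.ones_like(x)]).T
    # scale columns for a well-conditioned solve; rank check on the scaled design
    scale = np.linalg.norm(design, axis=0)
    if np.any(scale == 0) or np.linalg.matrix_rank(design / scale) < 3:
        raise ValueError("degenerate design: dose pairs do not span a quadratic")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    residuals = y - design @ beta
    sse = float(residuals @ residuals)
    dof = x.size - 3
    residual_variance = sse / dof
    xtx_inv = np.linalg.inv(design.T @ design)
    if cov_type == "classical":
        cov = residual_variance * xtx_inv
    elif cov_type == "hc3":
        leverage = np.einsum("ij,jk,ik->i", design, xtx_inv, design)
        meat = design.T @ (design * (residuals**2 / (1.0 - leverage) ** 2)[:, None])
        cov = xtx_inv @ meat @ xtx_inv
    elif cov_type == "cluster":
        if cluster_ids is None:
            raise ValueError("cluster covariance requires cluster_ids")
        ids = np.asarray(cluster_ids)
        if ids.shape != x.shape:
            raise ValueError("cluster_ids must align with the dose pairs")
        meat = np.zeros((3, 3))
        for g in np.unique(ids):
            score = design[ids == g].T @ residuals[ids == g]
            meat += np.outer(score, score)
        n_clusters = np.unique(ids).size
        if n_clusters < 2:
            raise ValueError("cluster covariance requires at least 2 clusters")
        meat *= (n_clusters / (n_clusters - 1)) * ((x.size - 1) / dof)
        cov = xtx_inv @ meat @ xtx_inv
    else:
        raise ValueError(f"unknown cov_type {cov_type!r}")
    sst = float(((y - y.mean()) ** 2).sum())
    if sst > 0:
        r_squared = max(0.0, 1.0 - sse / sst)
    else:
        r_squared = 1.0 if sse < 1e-12 else 0.0
    return QuadraticFit(
        a=float(beta[0]),
        b=float(beta[1]),
        c=float(beta[2]),
        coef_covariance=cov,
        residual_variance=residual_variance,
        n_points=int(x.size),
        r_squared=min(1.0, r_squared),
        domain=(float(x.min()), float(x.max())),
    )


def fit_quadratic(points: PairedDosePoints) -> QuadraticFit:
    """Fit the LEM -> mMKM quadratic for one volume level."""
    return fit_quadratic_xy(points.d_lem, points.d_mkm)


def _mean_response_se(fit: QuadraticFit, x: np.ndarray) -> np.ndarray:
    design = np.vstack([x**2, x, np.ones_like(x)]).T
    var = np.einsum("ij,jk,ik->i", design, fit.coef_covariance, design)
    return np.sqrt(np.maximum(var, 0.0))


def confidence_band(
    fit: QuadraticFit,
    x: float | np.ndarray,
    level: float = 0.95,
) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise confidence band for the mean response at dose(s) ``x``.

    Symmetric band ``poly(x) +/- t * se(x)`` with the Student-t quantile on
    ``n_points - 3`` degrees of freedom and ``se`` from the coefficient
    covariance; widens away from the center of the observed doses.
    """
    if fit.n_points <= 3:
        raise ValueError("confidence band requires more than 3 points")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    x_arr = np.atleast_1d(np.asarray(x, dtype=float))
    pred = fit(x_arr)
    tq = stats.t.ppf(0.5 + level / 2.0, fit.n_points - 3)
    half = tq * _mean_response_se(fit, x_arr)
    lower, upper = pred - half, pred + half
    if np.isscalar(x) or np.ndim(x) == 0:
        return float(lower[0]), float(upper[0])
    return lower, upper


def translate_dvh_point(fit: QuadraticFit, d_lem: float) -> float:
    """Forward-evaluate the fitted map at a LEM dose, floored at 0."""
    return float(max(0.0, fit(float(d_lem))))


@dataclass(frozen=True)
class TranslatedConstraint:
    """A MKM-language dose target mapped back to the LEM language."""

    v_level: VolumeSpec | None
    d_mkm_target: float
    d_lem_point: float
    d_lem_ci: tuple[float, float]

    def __post_init__(self) -> None:
        lo, hi = self.d_lem_ci
        if not (lo <= self.d_lem_point + 1e-9 and self.d_lem_point <= hi + 1e-9):
            raise ValueError("CI must bracket the point estimate")

    @property
    def conservative_d_lem(self) -> float:
        """The clinically adopted value: the lower CI bound."""
        return self.d_lem_ci[0]


def _increasing_root(a: float, b: float, c: float, target: float, domain) -> float:
    """Root of a x^2 + b x + (c - target) = 0 on the increasing branch."""
    lo, hi = domain
    if abs(a) < 1e-14 * max(1.0, abs(b)):
        if b <= 0:
            raise ValueError("target outside model range: map is not increasing")
        return (target - c) / b
    disc = b * b - 4.0 * a * (c - target)
    if disc < 0:
        raise ValueError("target outside model range: no real root")
    sq = np.sqrt(disc)
    roots = [(-b - sq) / (2 * a), (-b + sq) / (2 * a)]
    increasing = [r for r in roots if 2 * a * r + b > 0]
    if not increasing:
        raise ValueError("target outside model range: no increasing-branch root")
    center = 0.5 * (lo + hi)
    return min(increasing, key=lambda r: abs(r - center))


def _band_crossing(
    fit: QuadraticFit,
    target: float,
    which: str,
    level: float,
    x_point: float,
    span: float,
) -> float:
    """Dose at which the chosen band curve crosses ``target``.

    The upper band reaches the target at a smaller dose than the point
    estimate (giving the conservative lower LEM bound); the lower band at a
    larger dose.
    """
    idx = 1 if which == "upper" else 0

    def g(x: float) -> float:
        return confidence_band(fit, x, level)[idx] - target

    at_point = g(x_point)
    if abs(at_point) < 1e-12:
        return x_point
    direction = -1.0 if which == "upper" else 1.0
    step = max(span, 1.0) * 0.05
    x0, x1 = x_point, x_point
    for _ in range(200):
        x1 = x0 + direction * step
        if which == "upper" and x1 < 0:
            x1 = 0.0
        if np.sign(g(x1)) != np.sign(at_point):
            lo, hi = sorted((x0, x1))
            return float(optimize.brentq(g, lo, hi, xtol=1e-10))
        if which == "upper" and x1 == 0.0:
            break
        x0 = x1
        step *= 1.5
    return None


def translate_constraint(
    fit: QuadraticFit,
    d_mkm_target: float,
    level: float = 0.95,
) -> TranslatedConstraint:
    """Invert the fit at a MKM dose target, with a CI on the LEM dose.

    The point estimate is the increasing-branch root of the fitted
    quadratic; the CI bounds are the doses where the upper / lower
    confidence-band curves cross the target. The lower bound (from the
    upper band) is the conservative translated value.
    """
    lo_d, hi_d = fit.domain
    fitted_range = np.sort(fit(np.linspace(lo_d, hi_d, 201)))
    margin = 0.2 * max(fitted_range[-1] - fitted_range[0], 1.0)
    if not (fitted_range[0] - margin <= d_mkm_target <= fitted_range[-1] + margin):
        warnings.warn(
            f"target {d_mkm_target} Gy(RBE) lies outside the fitted "
            f"D_MKM range [{fitted_range[0]:.1f}, {fitted_range[-1]:.1f}] +/- 20%",
            stacklevel=2,
        )
    x_point = _increasing_root(fit.a, fit.b, fit.c, d_mkm_target, fit.domain)
    span = hi_d - lo_d
    se_at_point = float(_mean_response_se(fit, np.array([x_point]))[0])
    tq = stats.t.ppf(0.5 + level / 2.0, fit.n_points - 3)
    if se_at_point * tq < 1e-12:
        ci = (x_point, x_point)  # noiseless fit: degenerate band
    else:
        ci_lo = _band_crossing(fit, d_mkm_target, "upper", level, x_point, span)
        ci_hi = _band_crossing(fit, d_mkm_target, "lower", level, x_point, span)
        if ci_lo is None or ci_hi is None:
            # Fieller-type unbounded interval: the band never descends back to
            # the target (wide bands / few points). Fall back to the
            # delta-method interval around the inverted point.
            slope = abs(2.0 * fit.a * x_point + fit.b)
            half = tq * se_at_point / max(slope, 1e-12)
            warnings.warn(
                "confidence band does not re-cross the target; "
                "reporting a delta-method interval",
                stacklevel=2,
            )
            ci_lo = x_point - half if ci_lo is None else ci_lo
            ci_hi = x_point + half if ci_hi is None else ci_hi
        ci = (min(ci_lo, x_point), max(ci_hi, x_point))
    return TranslatedConstraint(
        v_level=None,
        d_mkm_target=float(d_mkm_target),
        d_lem_point=float(x_point),
        d_lem_ci=ci,
    )


def translation_table(
    fits: dict[VolumeSpec, QuadraticFit],
    targets: dict[VolumeSpec, float],
    level: float = 0.95,
) -> pd.DataFrame:
    """Translate one MKM target per v-level through its per-level fit."""
    rows = []
    for spec, target in targets.items():
        if spec not in fits:
            raise KeyError(f"no fit available for v-level {spec.label()}")
        tc = translate_constraint(fits[spec], target, level=level)
        rows.append(
            {
                "v_level": spec.label(),
                "d_mkm_target": target,
                "d_lem_point": tc.d_lem_point,
                "d_lem_lo": tc.d_lem_ci[0],
                "d_lem_hi": tc.d_lem_ci[1],
                "r_squared": fits[spec].r_squared,
            }
        )
    return pd.DataFrame(rows)
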