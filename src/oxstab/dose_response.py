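"""Dose-response modelling: baseline extrapolation, OxS, threshold inversion.

Injury indices from the ozonation series are fitted with an exponential
``INX = a * exp(b * sumO3)`` by ordinary least squares on the log scale;
the intercept ``a`` is the modelled zero-ozone baseline INX(0).  Oxidative
stability is the injury increase over that baseline expressed as a decimal,

    OxS(n) = -(INX(n) - INX(0)) / 100,    OxS in [-1, 0],

and the critical cumulative dose sumO₃(OxS) is the smallest dose at which a
least-squares polynomial fitted to (sumO₃, OxS) reaches the -0.05 threshold
(a 5 % membrane-injury criterion).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import optimize, stats

from .errors import (DomainError, InsufficientDataError, NoRootError,
                     ValidationError)

log = logging.getLogger(__name__)

OXS_THRESHOLD_DEFAULT = -0.05


@dataclass(frozen=True)
class ExposureSeries:
    """Paired (sumO₃ [ppm], INX [%]) points for one species and zone."""

    species: str
    zone: str
    sum_o3: tuple[float, ...]
    inx: tuple[float, ...]

    def __post_init__(self) -> None:
        x = np.asarray(self.sum_o3, float)
        if len(x) != len(self.inx):
            raise ValidationError("sum_o3 and inx lengths differ")
        if np.any(np.diff(x) <= 0) or np.any(x <= 0):
            raise ValidationError("sum_o3 must be positive and strictly increasing")


@dataclass(frozen=True)
class ExponentialBaselineFit:
    """inx = a * exp(b * sum_o3); a is the modelled INX(0) in percent."""

    a: float
    b: float
    r: float
    p: float

    @property
    def inx0(self) -> float:
        """Baseline injury INX(0), rounded to the reporting precision."""
        return round(self.a, 1)

    def predict(self, sum_o3):
        return self.a * np.exp(self.b * np.asarray(sum_o3, float))


@dataclass(frozen=True)
class DoseResponseFit:
    """Polynomial OxS(sumO₃); coefficients in descending powers."""

    degree: int
    coefficients: tuple[float, ...]
    domain: tuple[float, float]
    r_squared: float
    residuals: tuple[float, ...]
    ci_lower: tuple[float, ...] = field(default=())
    ci_upper: tuple[float, ...] = field(default=())

    def __call__(self, x):
        return np.polyval(self.coefficients, x)


def fit_exponential_baseline(s: ExposureSeries) -> ExponentialBaselineFit:
    """Log-linear OLS fit of the exponential injury-dose relationship.

    ``ln(INX)`` is regressed on sumO₃; the returned ``r`` and ``p`` are the
    correlation and two-sided slope significance of that linear fit.

    Raises
    ------
    DomainError
        If any injury index is not strictly positive.
    InsufficientDataError
        With fewer than three points.
    """
    x = np.asarray(s.sum_o3, float)
    y = np.asarray(s.inx, float)
    if len(x) < 3:
        raise InsufficientDataError(
            f"{s.species} {s.zone}: need >= 3 points, got {len(x)}")
    if np.any(y <= 0):
        raise DomainError(f"{s.species} {s.zone}: INX <= 0, log fit undefined")
    res = stats.linregress(x, np.log(y))
    fit = ExponentialBaselineFit(a=float(np.exp(res.intercept)),
                                 b=float(res.slope),
                                 r=float(res.rvalue), p=float(res.pvalue))
    log.info("%s %s: INX = %.3f * exp(%.3e * sumO3), r=%.3f p=%.3g",
             s.species, s.zone, fit.a, fit.b, fit.r, fit.p)
    return fit


def compute_oxs(inx_n: float, inx_0: float) -> float:
    """Oxidative stability of series n relative to the zero-ozone baseline.

    Positive differences (injury below baseline) are clipped to 0 with a
    warning; the result keeps full precision (round to 2 decimals only for
    reporting).
    """
    for name, v in (("inx_n", inx_n), ("inx_0", inx_0)):
        if not 0.0 <= v <= 100.0:
            raise ValidationError(f"{name}={v} outside [0, 100]")
    oxs = -(inx_n - inx_0) / 100.0
    if oxs > 0:
        log.warning("OxS %.4f > 0 (INX below baseline) clipped to 0", oxs)
        oxs = 0.0
    return oxs


def fit_polynomial_dose_response(sum_o3, oxs, degree: int = 2,
                                 alpha: float = 0.05) -> DoseResponseFit:
    """Least-squares polynomial OxS(sumO₃) with a pointwise confidence band.

    The band is the (1 - alpha) confidence interval of the mean response at
    the observed doses, from the OLS fit on the Vandermonde design.
    """
    x = np.asarray(sum_o3, float)
    y = np.asarray(oxs, float)
    if degree < 1:
        raise ValidationError("degree must be >= 1")
    if len(x) <= degree:
        raise InsufficientDataError(
            f"degree {degree} needs > {degree} points, got {len(x)}")
    design = np.vander(x, degree + 1)  # columns x^degree .. x^0
    model = sm.OLS(y, design).fit()
    pred = model.get_prediction(design).conf_int(alpha=alpha)
    fitted = model.predict(design)
    return DoseResponseFit(
        degree=degree,
        coefficients=tuple(float(c) for c in model.params),
        domain=(0.0, float(x.max())),
        r_squared=float(model.rsquared),
        residuals=tuple(float(r) for r in (y - fitted)),
        ci_lower=tuple(float(v) for v in pred[:, 0]),
        ci_upper=tuple(float(v) for v in pred[:, 1]),
    )


def invert_threshold(fit: DoseResponseFit,
                     threshold: float = OXS_THRESHOLD_DEFAULT,
                     xtol: float = 1e-9) -> tuple[float, bool]:
    """Smallest positive dose at which the fitted curve reaches ``threshold``.

    Scans (0, 2 * max observed dose] for the first sign change of
    ``fit(x) - threshold`` and polishes the bracket with Brent's method to
    ``|fit(x) - threshold| <= xtol``.  Returns ``(dose, extrapolated)``
    where ``extrapolated`` flags a root beyond the observed dose range.

    Raises
    ------
    NoRootError
        If the curve never crosses the threshold in the search interval.
    """
    xmax = 2.0 * fit.domain[1]
    grid = np.linspace(0.0, xmax, 4001)
    g = np.polyval(fit.coefficients, grid) - threshold
    # exact hit on a grid node
    hits = np.flatnonzero(np.abs(g) <= xtol)
    sign_change = np.flatnonzero(np.signbit(g[1:]) != np.signbit(g[:-1]))
    first = None
    if sign_change.size:
        i = sign_change[0]
        first = optimize.brentq(
            lambda x: np.polyval(fit.coefficients, x) - threshold,
            grid[i], grid[i + 1], xtol=xtol)
    if hits.size and (first is None or grid[hits[0]] < first):
        first = float(grid[hits[0]])
    if first is None or first <= 0:
        raise NoRootError(
            f"no crossing of OxS={threshold} within (0, {xmax:.1f}] ppm")
    extrapolated = first > fit.domain[1]
    if extrapolated:
        log.warning("threshold crossing %.1f ppm lies beyond the observed "
                    "dose range (%.1f ppm)", first, fit.domain[1])
    return float(first), extrapolated


def critical_dose(series: ExposureSeries, degree: int = 2,
                  threshold: float = OXS_THRESHOLD_DEFAULT) -> dict:
    """Full per-series chain: baseline fit -> OxS -> polynomial -> inversion.

    Returns a dict with the baseline fit, full-precision OxS values, the
    polynomial fit and the critical dose sumO₃(OxS) in ppm.
    """
    base = fit_exponential_baseline(series)
    oxs = [compute_oxs(v, min(base.a, 100.0)) for v in series.inx]
    poly = fit_polynomial_dose_response(series.sum_o3, oxs, degree=degree)
    dose, extrapolated = invert_threshold(poly, threshold=threshold)
    return {"baseline": base, "oxs": oxs, "poly": poly,
            "sum_o3_oxs": dose, "extrapolated": extrapolated}
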