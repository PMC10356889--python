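"""Inverse dose estimation from a fitted calibration curve.

Given an observed MN count M in N binucleated cells, the point dose solves
y = c + alpha*D + beta*D^2 for D at the observed yield y = M/N.  The 95%
confidence limits merge the two sources of error the assay carries:

* Poisson counting error on M — exact (Garwood) limits from chi-square
  quantiles, or a normal approximation behind a method flag;
* calibration-curve error — a delta-method band y(D) +/- 1.96 * se_y(D)
  around the fitted curve.

The limits come from the curve-crossing construction used in cytogenetic
biodosimetry: the lower dose limit is where the *upper* curve band meets the
*lower* Poisson yield limit, and the upper dose limit is where the lower
band meets the upper yield limit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy.optimize import brentq
from scipy.stats import chi2

from .calibration import LQCurve, predict_yield, yield_se

__all__ = [
    "DoseEstimate",
    "DoseOutOfRangeError",
    "poisson_limits",
    "invert_dose",
    "dose_ci",
    "classify_triage",
    "estimate_doses",
]

TRIAGE_CUTOFF_GY = 1.5
Z95 = 1.959963984540054  # two-sided 95% normal quantile


class DoseOutOfRangeError(RuntimeError):
    """A confidence limit lies beyond the search ceiling D_max."""


@dataclass(frozen=True)
class DoseEstimate:
    """Point dose with merged-error 95% limits and triage class."""

    sample_id: str
    n_bn: int
    n_mn: int
    observed_yield: float
    dose: float
    ci_low: float
    ci_high: float
    triage_class: str
    method_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.ci_low <= self.dose <= self.ci_high):
            raise ValueError(
                f"inconsistent estimate: ci_low={self.ci_low} dose={self.dose} "
                f"ci_high={self.ci_high}"
            )


def poisson_limits(m: int, method: str = "exact") -> tuple[float, float]:
    """95% confidence limits for a Poisson count.

    ``exact`` gives the Garwood interval, lower = chi2(0.025, 2m)/2 (0 when
    m = 0) and upper = chi2(0.975, 2m+2)/2.  ``approx`` gives the normal
    approximation m +/- 1.96*sqrt(m), floored at 0.
    """
    if m < 0:
        raise ValueError("count must be >= 0")
    if method == "exact":
        low = 0.0 if m == 0 else 0.5 * chi2.ppf(0.025, 2 * m)
        high = 0.5 * chi2.ppf(0.975, 2 * m + 2)
    elif method == "approx":
        half = Z95 * math.sqrt(m)
        low, high = max(0.0, m - half), m + half
    else:
        raise ValueError(f"unknown Poisson limit method {method!r}")
    return low, high


def invert_dose(curve: LQCurve, observed_yield: float) -> float:
    """Solve the LQ curve for dose at an observed yield.

    With beta > 0 the positive root of beta*D^2 + alpha*D + (c - y) = 0;
    with beta = 0 the linear solution (y - c)/alpha.  Yields at or below
    background map to dose 0.
    """
    if not math.isfinite(observed_yield):
        raise ValueError("observed yield must be finite")
    y, c, a, b = observed_yield, curve.c, curve.alpha, curve.beta
    if y <= c:
        return 0.0
    if b > 0:
        return (-a + math.sqrt(a * a + 4.0 * b * (y - c))) / (2.0 * b)
    if a > 0:
        return (y - c) / a
    raise ValueError("curve with alpha = beta = 0 is not invertible")


def classify_triage(dose: float, cutoff: float = TRIAGE_CUTOFF_GY) -> str:
    """Binary triage class from the point dose; the cutoff itself is
    classed low (the clinical category is 'at most cutoff')."""
    return f">{cutoff:g}" if dose > cutoff else f"<={cutoff:g}"


def _upper_band(curve: LQCurve, d: float) -> float:
    return predict_yield(curve, d) + Z95 * yield_se(curve, d)


def _lower_band(curve: LQCurve, d: float) -> float:
    return predict_yield(curve, d) - Z95 * yield_se(curve, d)


def dose_ci(
    curve: LQCurve,
    n_mn: int,
    n_bn: int,
    *,
    sample_id: str = "",
    cutoff: float = TRIAGE_CUTOFF_GY,
    d_max: float = 10.0,
    poisson_method: str = "exact",
    xtol: float = 1e-9,
) -> DoseEstimate:
    """Dose estimate with 95% limits merging Poisson and curve errors.

    The point estimate inverts the curve at y = n_mn/n_bn.  The lower limit
    is the smallest dose where the upper curve band reaches the lower
    Poisson yield limit (0 if the band at zero dose already exceeds it); the
    upper limit is the dose where the lower band reaches the upper yield
    limit.  Crossings are located by root bracketing on [0, d_max]; a limit
    beyond ``d_max`` raises :class:`DoseOutOfRangeError`.

    Estimates above the curve's maximum calibrated dose carry an
    ``extrapolated`` flag in ``method_meta`` rather than an error.
    """
    if n_bn <= 0:
        raise ValueError("n_bn must be > 0")
    y_obs = n_mn / n_bn
    dose = invert_dose(curve, y_obs)

    m_low, m_high = poisson_limits(n_mn, poisson_method)
    y_low, y_high = m_low / n_bn, m_high / n_bn

    # lower limit: upper band crosses the lower Poisson yield limit
    if _upper_band(curve, 0.0) >= y_low:
        ci_low = 0.0
    elif _upper_band(curve, d_max) < y_low:
        raise DoseOutOfRangeError(f"lower limit beyond d_max = {d_max} Gy")
    else:
        ci_low = brentq(lambda d: _upper_band(curve, d) - y_low, 0.0, d_max, xtol=xtol)

    # upper limit: lower band crosses the upper Poisson yield limit
    if _lower_band(curve, 0.0) >= y_high:
        ci_high = 0.0
    elif _lower_band(curve, d_max) < y_high:
        raise DoseOutOfRangeError(f"upper limit beyond d_max = {d_max} Gy")
    else:
        ci_high = brentq(lambda d: _lower_band(curve, d) - y_high, 0.0, d_max, xtol=xtol)

    # guard against root-finder noise at the interval ends
    ci_low = min(ci_low, dose)
    ci_high = max(ci_high, dose)

    max_dose = curve.fit_meta.get("max_dose")
    meta = {
        "ci_method": "curve-crossing",
        "poisson_method": poisson_method,
        "d_max": d_max,
        "extrapolated": bool(max_dose is not None and dose > max_dose),
    }
    return DoseEstimate(
        sample_id=sample_id,
        n_bn=n_bn,
        n_mn=n_mn,
        observed_yield=y_obs,
        dose=dose,
        ci_low=ci_low,
        ci_high=ci_high,
        triage_class=classify_triage(dose, cutoff),
        method_meta=meta,
    )


def estimate_doses(curve: LQCurve, samples, **kwargs) -> list[DoseEstimate]:
    """Run :func:`dose_ci` over a sequence of
    :class:`~cbmndose.datasets.SampleObservation`, preserving order."""
    return [
        dose_ci(curve, s.n_mn, s.n_bn, sample_id=s.sample_id, **kwargs)
        for s in samples
    ]
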