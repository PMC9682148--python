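"""LC-MS/MS method-validation statistics.

Implements the standard single-analyte validation quantities:

* **calibration linearity** — ordinary least squares on a serial-dilution
  curve (amount in fmol vs response), with R^2 and a reported linear
  range;
* **LOD / LOQ** — amounts giving signal-to-noise 3 and 10, so
  LOQ/LOD = 10/3 identically;
* **recovery efficiency** RE = IS_before / IS_after x 100 %, comparing
  internal standard spiked before vs after extraction;
* **matrix effect** ME = IS_after / IS_alone x 100 % - 100 %, negative
  values indicating ion suppression by co-extracted matrix.

Replicate intensities are aggregated as ratio-of-means (the mean signal
over n replicates enters each ratio).  Flag thresholds: |ME| > 25 %
(suppressed / enhanced) and RE < 75 % (low recovery); the boundaries
themselves are acceptable (ME = -25 is ok, -25.01 is suppressed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CalibrationCurve",
    "ValidationResult",
    "fit_calibration",
    "lod_loq",
    "recovery_efficiency",
    "matrix_effect",
    "validate_standard",
    "ME_THRESHOLD",
    "RE_THRESHOLD",
]

ME_THRESHOLD = 25.0  # percent, two-sided
RE_THRESHOLD = 75.0  # percent, lower bound


@dataclass(frozen=True)
class CalibrationCurve:
    species: str
    amounts_fmol: tuple[float, ...]
    responses: tuple[float, ...]
    slope: float
    intercept: float
    r_squared: float
    lod_fmol: float | None = None
    loq_fmol: float | None = None
    linear_range_fmol: tuple[float, float] | None = None


def fit_calibration(
    amounts_fmol: Sequence[float],
    responses: Sequence[float],
    species: str = "",
    noise_sd: float | None = None,
    residual_tol: float = 0.15,
) -> CalibrationCurve:
    """OLS calibration line with R^2, LOD/LOQ (when a blank noise SD is
    supplied) and the reported linear range.

    The linear range runs from the lowest point at or above the LOQ to
    the highest point whose relative fit residual is within
    ``residual_tol`` (15 % by default); the top is trimmed iteratively
    (fit, drop a deviating top point, refit) so a saturating high point
    cannot mask its own deviation by dragging the fit.
    """
    x = np.asarray(amounts_fmol, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.size < 3:
        raise ValueError("calibration needs at least 3 points")
    if np.any(x <= 0):
        raise ValueError("calibration amounts must be positive")
    if np.ptp(x) == 0:
        raise ValueError("degenerate calibration: all amounts identical")
    if not np.any(y > 0):
        raise ValueError("degenerate calibration: all responses are zero")
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    n = xs.size
    while n > 3:
        # predict the top point from the fit on the points below it — a
        # saturating point cannot then drag the fit towards itself
        sub = stats.linregress(xs[: n - 1], ys[: n - 1])
        pred = sub.slope * xs[n - 1] + sub.intercept
        if pred != 0 and abs(ys[n - 1] - pred) / abs(pred) > residual_tol:
            n -= 1
        else:
            break
    res = stats.linregress(xs[:n], ys[:n])
    slope, intercept = float(res.slope), float(res.intercept)
    r2 = float(res.rvalue**2)

    lod = loq = None
    if noise_sd is not None:
        lod, loq = lod_loq(noise_sd, slope)

    floor = loq if loq is not None else 0.0
    above = xs[xs >= floor]
    rng = (float(above[0]), float(xs[n - 1])) if above.size else None
    return CalibrationCurve(
        species=species,
        amounts_fmol=tuple(map(float, x)),
        responses=tuple(map(float, y)),
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        lod_fmol=lod,
        loq_fmol=loq,
        linear_range_fmol=rng,
    )


def lod_loq(noise_sd: float, slope: float) -> tuple[float, float]:
    """Amounts at signal-to-noise 3 and 10: LOD = 3 sd / slope,
    LOQ = 10 sd / slope (so LOQ/LOD = 10/3 for any input)."""
    if slope <= 0:
        raise ValueError("calibration slope must be positive")
    if noise_sd < 0:
        raise ValueError("noise SD must be non-negative")
    return 3.0 * noise_sd / slope, 10.0 * noise_sd / slope


def _mean(x) -> float:
    arr = np.asarray(x, dtype=float)
    return float(arr.mean())


def recovery_efficiency(is_before, is_after) -> float:
    """RE (%) = mean(IS spiked before extraction) / mean(IS spiked after)
    x 100.  Scalars or replicate sequences are accepted."""
    after = _mean(is_after)
    if after <= 0:
        raise ValueError("IS_after intensity must be positive")
    return _mean(is_before) / after * 100.0


def matrix_effect(is_after, is_alone) -> float:
    """ME (%) = mean(IS in matrix) / mean(IS in neat solvent) x 100 - 100.
    Negative = ion suppression, positive = enhancement."""
    alone = _mean(is_alone)
    if alone <= 0:
        raise ValueError("IS_alone intensity must be positive")
    return _mean(is_after) / alone * 100.0 - 100.0


@dataclass(frozen=True)
class ValidationResult:
    species: str
    re_percent: float
    me_percent: float
    flags: tuple[str, ...]


def validate_standard(
    species: str, is_before, is_after, is_alone
) -> ValidationResult:
    """RE/ME for one internal standard, with threshold flags.

    Flags: ``suppressed`` (ME < -25), ``enhanced`` (ME > +25),
    ``low_recovery`` (RE < 75); ``ok`` when none apply.  Boundary values
    are acceptable.
    """
    re_ = recovery_efficiency(is_before, is_after)
    me = matrix_effect(is_after, is_alone)
    flags: list[str] = []
    if me < -ME_THRESHOLD:
        flags.append("suppressed")
    elif me > ME_THRESHOLD:
        flags.append("enhanced")
    if re_ < RE_THRESHOLD:
        flags.append("low_recovery")
    if not flags:
        flags.append("ok")
    return ValidationResult(species, re_, me, tuple(flags))
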