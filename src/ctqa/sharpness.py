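"""Edge sharpness from logistic fits to line density profiles.

The transition of HU values across a tissue interface is modelled with a
four-parameter logistic curve

    h(l) = theta_begin + (theta_end - theta_begin) / (1 + exp(-theta1 * (l - theta0)))

and the sharpness of the interface is the magnitude of the curve's slope at
its inflection point, ``|theta1 * (theta_end - theta_begin) / 4|`` in HU/mm.
A scan-level sharpness is the pooled median over a grid of such measurements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit
from scipy.special import expit

from .image import CTImage
from .line_profiles import LineProfile, ProfileLine, extract_profile

__all__ = [
    "LogisticFit",
    "SteepnessMeasurement",
    "ScanSharpness",
    "logistic_model",
    "fit_logistic",
    "steepness_from_fit",
    "measure_scan",
]

# physically motivated parameter bounds (HU range of CT, slope cap in 1/mm)
HU_BOUNDS = (-1100.0, 3100.0)
THETA1_BOUND = 100.0
DEFAULT_MIN_CONTRAST_HU = 50.0


@dataclass
class LogisticFit:
    """Estimated logistic transition parameters for one line profile."""

    theta0: float  # location of the inflection point, mm
    theta1: float  # slope parameter, 1/mm (negative for falling profiles)
    theta_begin: float  # asymptotic HU before the interface
    theta_end: float  # asymptotic HU after the interface
    converged: bool
    residual_norm: float = math.nan  # sum of squared residuals, HU^2

    @property
    def contrast_hu(self) -> float:
        return abs(self.theta_end - self.theta_begin)


@dataclass
class SteepnessMeasurement:
    steepness: float  # HU/mm, >= 0 (nan when excluded for non-convergence)
    fit: LogisticFit
    line: ProfileLine | None = None
    excluded: bool = False
    exclusion_reason: str = ""

    def __post_init__(self) -> None:
        if self.excluded and not self.exclusion_reason:
            raise ValueError("excluded measurements must carry a reason")


@dataclass
class ScanSharpness:
    """Pooled sharpness of one scan: all measurements plus their median."""

    measurements: list[SteepnessMeasurement] = field(default_factory=list)
    median_steepness: float = math.nan
    n_total: int = 0
    n_converged: int = 0
    n_included: int = 0

    @property
    def all_excluded(self) -> bool:
        return self.n_included == 0

    def included_values(self) -> np.ndarray:
        return np.array(
            [m.steepness for m in self.measurements if not m.excluded], dtype=float
        )

    def to_records(self) -> list[dict]:
        """One dict per measurement, suitable for a per-scan CSV report."""
        records = []
        for m in self.measurements:
            ln = m.line
            records.append(
                {
                    "level": ln.level if ln else "",
                    "side": ln.side if ln else "",
                    "location": ln.location if ln else "",
                    "replicate": ln.replicate if ln else -1,
                    "interface_id": ln.interface_id if ln else -1,
                    "theta0": m.fit.theta0,
                    "theta1": m.fit.theta1,
                    "theta_begin": m.fit.theta_begin,
                    "theta_end": m.fit.theta_end,
                    "steepness_hu_per_mm": m.steepness,
                    "converged": m.fit.converged,
                    "excluded": m.excluded,
                    "exclusion_reason": m.exclusion_reason,
                }
            )
        return records


def logistic_model(
    l: np.ndarray | float,
    theta0: float,
    theta1: float,
    theta_begin: float,
    theta_end: float,
) -> np.ndarray | float:
    """Four-parameter logistic transition evaluated at distance(s) ``l`` [mm].

    Uses ``expit`` so the exponential saturates cleanly to the asymptotes
    instead of overflowing.
    """
    return theta_begin + (theta_end - theta_begin) * expit(theta1 * (np.asarray(l, dtype=float) - theta0))


def _logistic_jac(l, theta0, theta1, theta_begin, theta_end):
    z = theta1 * (l - theta0)
    s = expit(z)
    w = s * (1.0 - s)
    amp = theta_end - theta_begin
    return np.column_stack(
        [-amp * w * theta1, amp * w * (l - theta0), 1.0 - s, s]
    )


def _initial_guess(l: np.ndarray, h: np.ndarray) -> tuple[float, float, float, float]:
    begin = float(np.mean(h[:3]))
    end = float(np.mean(h[-3:]))
    mid = 0.5 * (begin + end)
    theta0 = float(l[np.argmin(np.abs(h - mid))])
    span = float(l[-1] - l[0])
    sign = 1.0 if end >= begin else -1.0
    theta1 = sign * 4.0 / span
    return theta0, theta1, begin, end


def fit_logistic(
    profile: LineProfile,
    init: tuple[float, float, float, float] | None = None,
    maxfev: int = 2000,
) -> LogisticFit:
    """Least-squares fit of the logistic transition model to a profile.

    Parameters are bounded to physically sensible ranges (HU asymptotes in
    [-1100, 3100], |theta1| <= 100/mm).  Optimizer failure is reported via
    ``converged=False`` rather than an exception.
    """
    if len(profile) < 5:
        raise ValueError(f"profile has {len(profile)} samples; need at least 5")
    l = profile.distances_mm
    h = profile.values_hu
    span = float(l[-1] - l[0])
    if span <= 0:
        raise ValueError("profile spans zero distance")

    if init is None:
        init = _initial_guess(l, h)
    t0, t1, tb, te = init
    lo = [l[0] - span, -THETA1_BOUND, HU_BOUNDS[0], HU_BOUNDS[0]]
    hi = [l[-1] + span, THETA1_BOUND, HU_BOUNDS[1], HU_BOUNDS[1]]
    p0 = [
        float(np.clip(t0, lo[0], hi[0])),
        float(np.clip(t1, lo[1], hi[1])),
        float(np.clip(tb, lo[2], hi[2])),
        float(np.clip(te, lo[3], hi[3])),
    ]

    def model(x, theta0, theta1, theta_begin, theta_end):
        return logistic_model(x, theta0, theta1, theta_begin, theta_end)

    try:
        popt, _ = curve_fit(
            model,
            l,
            h,
            p0=p0,
            bounds=(lo, hi),
            jac=_logistic_jac,
            maxfev=maxfev,
            method="trf",
        )
    except (RuntimeError, ValueError):
        return LogisticFit(
            theta0=math.nan,
            theta1=math.nan,
            theta_begin=math.nan,
            theta_end=math.nan,
            converged=False,
        )
    if not np.all(np.isfinite(popt)):
        return LogisticFit(*popt, converged=False)  # type: ignore[arg-type]
    residuals = h - logistic_model(l, *popt)
    return LogisticFit(
        theta0=float(popt[0]),
        theta1=float(popt[1]),
        theta_begin=float(popt[2]),
        theta_end=float(popt[3]),
        converged=True,
        residual_norm=float(np.sum(residuals**2)),
    )


def steepness_from_fit(fit: LogisticFit) -> float:
    """Sharpness of a fitted transition: ``|theta1 (theta_end - theta_begin) / 4|``.

    This equals the magnitude of the model's derivative at its inflection
    point.  The absolute value makes rising and falling profiles equivalent.
    """
    if not fit.converged:
        raise ValueError("cannot derive steepness from a non-converged fit")
    return abs(fit.theta1 * (fit.theta_end - fit.theta_begin) / 4.0)


def measure_profile(
    profile: LineProfile,
    min_contrast_hu: float = DEFAULT_MIN_CONTRAST_HU,
) -> SteepnessMeasurement:
    """Fit one profile and apply the convergence / minimum-contrast policy."""
    fit = fit_logistic(profile)
    if not fit.converged:
        return SteepnessMeasurement(
            steepness=math.nan,
            fit=fit,
            line=profile.source_line,
            excluded=True,
            exclusion_reason="fit did not converge",
        )
    steep = steepness_from_fit(fit)
    if fit.contrast_hu < min_contrast_hu:
        return SteepnessMeasurement(
            steepness=steep,
            fit=fit,
            line=profile.source_line,
            excluded=True,
            exclusion_reason=(
                f"contrast {fit.contrast_hu:.1f} HU below minimum {min_contrast_hu:.1f} HU"
            ),
        )
    return SteepnessMeasurement(steepness=steep, fit=fit, line=profile.source_line)


def measure_scan(
    image_stack: CTImage | Sequence[CTImage],
    grid: Sequence[ProfileLine],
    min_contrast_hu: float = DEFAULT_MIN_CONTRAST_HU,
) -> ScanSharpness:
    """Extract, fit and pool every grid line into a per-scan sharpness.

    Each line is resolved to a slice of the stack via its level label
    (apical/mid/basal -> slice 0/1/2; a single image serves all levels).
    Non-converged fits and fits below the minimum HU contrast are excluded
    from the median but retained in the measurement list.
    """
    if isinstance(image_stack, CTImage):
        stack: list[CTImage] = [image_stack]
    else:
        stack = list(image_stack)
    if not stack:
        raise ValueError("empty image stack")
    if not grid:
        raise ValueError("empty measurement grid")

    measurements = []
    for line in grid:
        image = stack[line.slice_index % len(stack)]
        profile = extract_profile(image, line)
        measurements.append(measure_profile(profile, min_contrast_hu=min_contrast_hu))

    included = np.array(
        [m.steepness for m in measurements if not m.excluded], dtype=float
    )
    return ScanSharpness(
        measurements=measurements,
        median_steepness=float(np.median(included)) if included.size else math.nan,
        n_total=len(measurements),
        n_converged=sum(1 for m in measurements if m.fit.converged),
        n_included=int(included.size),
    )
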