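"""Exponential reflectance–bilirubin calibration.

The photometer's 465 nm response to bilirubin in non-hemolyzed samples is
modeled as ``R = a · exp(−b · C)`` with ``a > 0`` (reflectance scale at zero
bilirubin) and ``b > 0`` (decay rate per mg/dL).  The curve is fitted by
nonlinear least squares on the reflectance scale, initialized from an
ordinary regression of ``ln R`` on ``C``, and inverted analytically,
``C = −ln(R / a) / b``, to estimate concentration from a measured
reflectance.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .exceptions import DomainError, FitError
from .optical import Measurement

__all__ = [
    "CalibrationCurve",
    "fit_calibration",
    "predict_reflectance",
    "invert_calibration",
]

_XTOL = 1e-10  # convergence tolerance on parameter updates
_MAX_NFEV = 200


@dataclass(frozen=True)
class CalibrationCurve:
    """Fitted exponential calibration law ``R = a·exp(−b·C)``."""

    a: float
    b: float
    r_squared: float
    n_points: int

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise DomainError("calibration requires a > 0 and b > 0")
        if not 0.0 <= self.r_squared <= 1.0:
            raise DomainError("r_squared must lie in [0, 1]")
        if self.n_points < 3:
            raise DomainError("a calibration needs at least 3 points")

    def to_dict(self) -> dict:
        return {"model": "calibration", **asdict(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationCurve":
        if d.get("model") != "calibration":
            raise DomainError(f"not a calibration model file: model={d.get('model')!r}")
        return cls(a=d["a"], b=d["b"], r_squared=d["r_squared"], n_points=d["n_points"])

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "CalibrationCurve":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _as_arrays(measurements: Sequence[Measurement]) -> tuple[np.ndarray, np.ndarray]:
    conc = np.array([m.bilirubin_nominal for m in measurements], dtype=float)
    refl = np.array([m.r465 for m in measurements], dtype=float)
    return conc, refl


def fit_calibration(measurements: Sequence[Measurement]) -> CalibrationCurve:
    """Fit ``R = a·exp(−b·C)`` to reference (non-hemolyzed) measurements.

    Least squares runs on the reflectance scale; the initial guess comes from
    the closed-form regression of ``ln R`` on ``C``.  ``r_squared`` is the
    coefficient of determination of the fitted curve against the measured
    reflectances.  Exact exponential inputs are recovered to numerical
    precision with ``r_squared = 1``.

    Raises
    ------
    FitError
        Fewer than 3 points, fewer than 2 distinct bilirubin levels, or
        failure of the nonlinear solver (the error carries the log-linear
        initializer in ``initial_params``).
    DomainError
        Any non-positive reflectance.
    """
    measurements = list(measurements)
    if len(measurements) < 3:
        raise FitError(f"need >= 3 calibration points, got {len(measurements)}")
    conc, refl = _as_arrays(measurements)
    if np.any(refl <= 0):
        raise DomainError("calibration reflectances must be > 0")
    if np.unique(conc).size < 2:
        raise FitError("calibration needs >= 2 distinct bilirubin levels")

    # log-linear initializer: ln R = ln a − b C
    slope, intercept = np.polyfit(conc, np.log(refl), 1)
    p0 = (float(np.exp(intercept)), float(-slope))
    try:
        popt, _ = curve_fit(
            lambda c, a, b: a * np.exp(-b * c),
            conc,
            refl,
            p0=p0,
            xtol=_XTOL,
            ftol=_XTOL,
            maxfev=_MAX_NFEV * len(p0),
        )
    except RuntimeError as exc:
        raise FitError(f"calibration fit failed to converge: {exc}", initial_params=p0)
    a, b = float(popt[0]), float(popt[1])
    if a <= 0 or b <= 0:
        raise FitError(
            f"calibration fit produced non-physical parameters a={a:.4g}, b={b:.4g}",
            initial_params=p0,
        )
    fitted = a * np.exp(-b * conc)
    ss_res = float(np.sum((refl - fitted) ** 2))
    ss_tot = float(np.sum((refl - refl.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return CalibrationCurve(a=a, b=b, r_squared=min(max(r2, 0.0), 1.0), n_points=len(measurements))


def predict_reflectance(curve: CalibrationCurve, c_bil: float) -> float:
    """Expected 465 nm reflectance at concentration ``c_bil`` (mg/dL)."""
    if c_bil < 0:
        raise DomainError("bilirubin concentration must be >= 0")
    return curve.a * math.exp(-curve.b * c_bil)


def invert_calibration(curve: CalibrationCurve, r465: float) -> float:
    """Bilirubin concentration (mg/dL) from a 465 nm reflectance.

    Exact inverse of :func:`predict_reflectance`.  A reflectance above the
    curve intercept ``a`` yields a negative concentration, which is returned
    unclamped — clamping would bias downstream error statistics; callers flag
    negative estimates instead (see :func:`bilicomp.compensation.estimate_bilirubin`).
    """
    if r465 <= 0:
        raise DomainError(f"reflectance must be > 0, got {r465}")
    return -math.log(r465 / curve.a) / curve.b
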