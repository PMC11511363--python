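"""Hemoglobin-interference compensation.

Free hemoglobin from hemolysis absorbs at both photometer wavelengths; at
590 nm it is (by assumption) the only absorber, so the reflectance drop there
is a pure hemoglobin signal.  The compensation algorithm:

1. Take the least-hemolyzed group of the panel as the *reference* group.  Its
   per-bilirubin-level mean 465 nm reflectances are the references
   ``R465_ref(level)``; its pooled mean 590 nm reflectance is ``R590_ref``
   (pooling is valid because the 590 nm channel is bilirubin-blind).
2. For every sample, compute reflectance deficits relative to the reference,

       dR590 = R590_ref − R590,   dR465 = R465_ref(level) − R465,

   on per-sample replicate means.
3. Fit the linear law ``dR465 = slope · dR590 + intercept`` by ordinary least
   squares over the per-sample points.
4. For an individual test, predict the hemoglobin-induced 465 nm deficit from
   its own dR590 and add it back:
   ``corrected_r465 = r465 + slope·(R590_ref − r590) + intercept``;
   bilirubin is then read off the exponential calibration curve.

At deployment the bilirubin level of an unknown sample is unknown, so the
per-level 465 nm references are used only to *train* the linear law; the
correction itself needs only the pooled ``R590_ref``, which the fitted model
carries.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .calibration import CalibrationCurve, invert_calibration
from .exceptions import (
    DegenerateFitError,
    DomainError,
    InvalidCorrectionError,
    MissingReferenceError,
)
from .optical import Measurement

__all__ = [
    "ReferenceSet",
    "DeltaPoint",
    "CompensationModel",
    "BilirubinEstimate",
    "compute_references",
    "compute_deltas",
    "fit_compensation",
    "correct_reflectance",
    "estimate_bilirubin",
    "estimate_panel",
]


@dataclass(frozen=True)
class ReferenceSet:
    """Reference reflectances from the least-hemolyzed panel group.

    ``r465_ref_by_level`` maps nominal bilirubin concentration (mg/dL) to the
    mean reference 465 nm reflectance of that level; ``r590_ref`` is the
    single pooled 590 nm reference; ``hb_ref_level`` is the hemoglobin
    concentration (g/dL) of the reference group.
    """

    r465_ref_by_level: Mapping[float, float]
    r590_ref: float
    hb_ref_level: float

    def __post_init__(self) -> None:
        if self.r590_ref <= 0 or any(v <= 0 for v in self.r465_ref_by_level.values()):
            raise DomainError("reference reflectances must be > 0")


@dataclass(frozen=True)
class DeltaPoint:
    """Per-sample mean reflectance deficits relative to the reference group."""

    sample_id: str
    delta_r590: float
    delta_r465: float
    n_tests_averaged: int

    def __post_init__(self) -> None:
        if self.n_tests_averaged < 1:
            raise DomainError("n_tests_averaged must be >= 1")


@dataclass(frozen=True)
class CompensationModel:
    """Fitted linear law ``dR465 = slope·dR590 + intercept``.

    Carries the pooled 590 nm reference reflectance needed to compute dR590
    for an unknown sample at deployment time.
    """

    slope: float
    intercept: float
    r_squared: float
    n_points: int
    r590_ref: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared <= 1.0:
            raise DomainError("r_squared must lie in [0, 1]")
        if self.n_points < 2:
            raise DomainError("compensation fit needs >= 2 points")
        if self.r590_ref <= 0:
            raise DomainError("r590_ref must be > 0")

    def to_dict(self) -> dict:
        return {"model": "compensation", **asdict(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "CompensationModel":
        if d.get("model") != "compensation":
            raise DomainError(f"not a compensation model file: model={d.get('model')!r}")
        return cls(
            slope=d["slope"],
            intercept=d["intercept"],
            r_squared=d["r_squared"],
            n_points=d["n_points"],
            r590_ref=d["r590_ref"],
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "CompensationModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class BilirubinEstimate:
    """A single-test bilirubin estimate with quality flags.

    Flags: ``negative_estimate`` (reflectance above the curve intercept, the
    unclamped estimate is negative), ``invalid_correction`` (the hemoglobin
    correction produced a non-positive reflectance; estimate is NaN).
    """

    sample_id: str
    replicate: int
    bilirubin_nominal: float
    hemoglobin_nominal: float
    r465: float
    r590: float
    estimate_mgdl: float
    compensated: bool
    flags: tuple[str, ...] = ()


def compute_references(measurements: Sequence[Measurement]) -> ReferenceSet:
    """Extract the reference reflectances from a panel.

    The reference group is the subset at the panel's minimum hemoglobin
    level.  Every bilirubin level present in the panel must have at least one
    reference test.
    """
    measurements = list(measurements)
    if not measurements:
        raise DomainError("no measurements")
    hb_ref = min(m.hemoglobin_nominal for m in measurements)
    ref_group = [m for m in measurements if m.hemoglobin_nominal == hb_ref]
    levels = sorted({m.bilirubin_nominal for m in measurements})
    by_level: dict[float, float] = {}
    for level in levels:
        vals = [m.r465 for m in ref_group if m.bilirubin_nominal == level]
        if not vals:
            raise MissingReferenceError(
                f"bilirubin level {level} mg/dL has no test at the reference "
                f"hemoglobin level {hb_ref} g/dL"
            )
        by_level[level] = float(np.mean(vals))
    r590_ref = float(np.mean([m.r590 for m in ref_group]))
    return ReferenceSet(r465_ref_by_level=by_level, r590_ref=r590_ref, hb_ref_level=hb_ref)


def compute_deltas(
    measurements: Sequence[Measurement], refs: ReferenceSet
) -> list[DeltaPoint]:
    """Per-sample mean reflectance deficits relative to the references.

    One point per sample (= one bilirubin × hemolysis combination), computed
    on the mean of that sample's replicates.  Reference-group samples are
    included; their deltas are ~0 (exactly 0 without noise).
    """
    groups: dict[str, list[Measurement]] = {}
    for m in measurements:
        groups.setdefault(m.sample_id, []).append(m)
    out: list[DeltaPoint] = []
    for sample_id, group in groups.items():
        level = group[0].bilirubin_nominal
        if level not in refs.r465_ref_by_level:
            raise MissingReferenceError(
                f"sample {sample_id!r}: no reference for bilirubin level {level} mg/dL"
            )
        out.append(
            DeltaPoint(
                sample_id=sample_id,
                delta_r590=refs.r590_ref - float(np.mean([m.r590 for m in group])),
                delta_r465=refs.r465_ref_by_level[level]
                - float(np.mean([m.r465 for m in group])),
                n_tests_averaged=len(group),
            )
        )
    return out


def fit_compensation(
    deltas: Sequence[DeltaPoint], refs: ReferenceSet
) -> CompensationModel:
    """Ordinary least-squares fit of dR465 on dR590.

    Unweighted, free intercept, closed-form simple-regression estimates
    (slope = Sxy/Sxx).
    """
    deltas = list(deltas)
    if len(deltas) < 2:
        raise DegenerateFitError(f"need >= 2 delta points, got {len(deltas)}")
    x = np.array([d.delta_r590 for d in deltas], dtype=float)
    y = np.array([d.delta_r465 for d in deltas], dtype=float)
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0.0:
        raise DegenerateFitError("all delta_r590 identical; cannot fit the linear law")
    sxy = float(np.sum((x - x.mean()) * (y - y.mean())))
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return CompensationModel(
        slope=slope,
        intercept=intercept,
        r_squared=min(max(r2, 0.0), 1.0),
        n_points=len(deltas),
        r590_ref=refs.r590_ref,
    )


def correct_reflectance(model: CompensationModel, r465: float, r590: float) -> float:
    """Hemoglobin-corrected 465 nm reflectance of an individual test.

    The predicted hemoglobin-induced deficit, ``slope·(r590_ref − r590) +
    intercept``, is added back to the measured 465 nm reflectance.  The result
    may exceed the calibration intercept (handled downstream as a negative,
    flagged estimate).
    """
    if r465 <= 0 or r590 <= 0:
        raise DomainError("reflectances must be > 0")
    corrected = r465 + model.slope * (model.r590_ref - r590) + model.intercept
    if corrected <= 0:
        raise InvalidCorrectionError(
            f"corrected 465 nm reflectance is non-positive ({corrected:.4g}) "
            f"for r465={r465:.4g}, r590={r590:.4g}"
        )
    return corrected


def estimate_bilirubin(
    curve: CalibrationCurve,
    model: CompensationModel | None,
    measurement: Measurement,
    compensate: bool = True,
) -> BilirubinEstimate:
    """Estimate bilirubin for one test, with or without compensation.

    With ``compensate=False`` the calibration curve is inverted on the raw
    465 nm reflectance; with ``compensate=True`` on the hemoglobin-corrected
    one (requires a fitted :class:`CompensationModel`).
    """
    if compensate and model is None:
        raise DomainError("compensated estimation requires a fitted CompensationModel")
    flags: list[str] = []
    if compensate:
        assert model is not None
        try:
            r = correct_reflectance(model, measurement.r465, measurement.r590)
        except InvalidCorrectionError:
            return BilirubinEstimate(
                sample_id=measurement.sample_id,
                replicate=measurement.replicate,
                bilirubin_nominal=measurement.bilirubin_nominal,
                hemoglobin_nominal=measurement.hemoglobin_nominal,
                r465=measurement.r465,
                r590=measurement.r590,
                estimate_mgdl=math.nan,
                compensated=True,
                flags=("invalid_correction",),
            )
    else:
        r = measurement.r465
    est = invert_calibration(curve, r)
    if est < 0:
        flags.append("negative_estimate")
    return BilirubinEstimate(
        sample_id=measurement.sample_id,
        replicate=measurement.replicate,
        bilirubin_nominal=measurement.bilirubin_nominal,
        hemoglobin_nominal=measurement.hemoglobin_nominal,
        r465=measurement.r465,
        r590=measurement.r590,
        estimate_mgdl=est,
        compensated=compensate,
        flags=tuple(flags),
    )


def estimate_panel(
    curve: CalibrationCurve,
    model: CompensationModel | None,
    measurements: Sequence[Measurement],
    compensate: bool = True,
) -> list[BilirubinEstimate]:
    """Estimate bilirubin for every test in a panel."""
    return [estimate_bilirubin(curve, model, m, compensate) for m in measurements]
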