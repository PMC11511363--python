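"""Virtual two-wavelength reflectance photometer.

This module is a stand-in for the bench instrument and the plasma test panel:
a Beer–Lambert-style forward model maps bilirubin (mg/dL) and free hemoglobin
(g/dL) concentrations to blank-normalized reflectance at the measurement
wavelength (465 nm, near the bilirubin absorption peak) and the compensation
wavelength (590 nm, where bilirubin absorption is negligible and hemoglobin
dominates).

Reflectances are dimensionless, normalized to the unloaded strip's blank read
at 590 nm; because the 465 nm channel is brighter than the blank, noise-free
465 nm reflectance sits above 100 (default scale 120 vs 100).

Two interference modes are provided:

``multiplicative``
    Both analytes attenuate exponentially and independently,
    ``R_λ = N_λ · exp(−k_bil,λ·C_bil − k_hb,λ·C_hb)``.  Physically realistic;
    the hemoglobin-induced reflectance drop at 465 nm then depends on the
    bilirubin level, so the linear ΔR465–ΔR590 compensation law is only an
    approximation (as it is on real plasma).

``additive``
    The hemoglobin contribution at 465 nm is an additive offset proportional
    to the hemoglobin-induced drop at 590 nm, making ΔR465 exactly linear in
    ΔR590.  This mode exists for exact-recovery oracle tests of the
    compensation pipeline.

Measurement noise is multiplicative Gaussian per single optical read; the
instrument performs two consecutive reads per test and averages them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .exceptions import DomainError, ParameterizationError

__all__ = [
    "OpticalParams",
    "PanelSpec",
    "Measurement",
    "reflectance",
    "simulate_measurement",
    "simulate_panel",
    "default_params",
    "default_panel_spec",
    "calibration_panel_spec",
    "PANEL_BILIRUBIN_MGDL",
    "PANEL_HEMOGLOBIN_GDL",
    "CALIBRATION_BILIRUBIN_MGDL",
]

#: Bilirubin levels (mg/dL) of the five-level test panel.
PANEL_BILIRUBIN_MGDL: tuple[float, ...] = (4.96, 9.67, 14.47, 19.33, 28.00)
#: Hemolysis levels (free hemoglobin, g/dL) of the test panel.
PANEL_HEMOGLOBIN_GDL: tuple[float, ...] = (0.06, 0.29, 0.50, 0.75, 0.99)
#: Calibration series: the panel levels plus an additional low level.
CALIBRATION_BILIRUBIN_MGDL: tuple[float, ...] = (0.56,) + PANEL_BILIRUBIN_MGDL

_MODES = ("multiplicative", "additive")


@dataclass(frozen=True)
class OpticalParams:
    """Forward-model parameters of the virtual photometer.

    Attributes
    ----------
    n465, n590
        Noise-free blank-normalized reflectance scales at zero analyte
        concentration (dimensionless).  Both channels are normalized to the
        590 nm blank, hence ``n465 > n590`` by default.
    k_bil_465, k_bil_590
        Bilirubin attenuation coefficients, per mg/dL.  ``k_bil_590`` is 0 by
        default: the 590 nm channel is blind to bilirubin.
    k_hb_465, k_hb_590
        Hemoglobin attenuation coefficients, per g/dL.
    noise_rel_sd
        Relative standard deviation of the multiplicative Gaussian noise on a
        single optical read (dimensionless).
    interference_mode
        ``"multiplicative"`` or ``"additive"`` (see module docstring).
    additive_gamma
        Slope of the additive-mode hemoglobin offset at 465 nm
        (dimensionless); unused in multiplicative mode.
    seed
        Default seed for panel simulation.
    """

    n465: float = 120.0
    n590: float = 100.0
    k_bil_465: float = 0.02
    k_bil_590: float = 0.0
    k_hb_465: float = 0.18
    k_hb_590: float = 0.30
    noise_rel_sd: float = 0.01
    interference_mode: str = "multiplicative"
    additive_gamma: float = 0.5
    seed: int = 42

    def __post_init__(self) -> None:
        for name in ("k_bil_465", "k_bil_590", "k_hb_465", "k_hb_590"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.n465 <= 0 or self.n590 <= 0:
            raise DomainError("reflectance scales n465/n590 must be > 0")
        if self.noise_rel_sd < 0:
            raise DomainError("noise_rel_sd must be >= 0")
        if self.interference_mode not in _MODES:
            raise DomainError(
                f"interference_mode must be one of {_MODES}, got "
                f"{self.interference_mode!r}"
            )

    def with_(self, **changes) -> "OpticalParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)


@dataclass(frozen=True)
class PanelSpec:
    """Layout of a simulated test panel.

    Samples are labeled ``BiHj`` with ``i`` indexing the bilirubin level and
    ``j`` the hemolysis level, both 1-based and ascending in concentration;
    each sample is measured ``replicates`` times.
    """

    bilirubin_levels: tuple[float, ...]
    hemoglobin_levels: tuple[float, ...]
    replicates: int = 5

    def __post_init__(self) -> None:
        object.__setattr__(self, "bilirubin_levels", tuple(self.bilirubin_levels))
        object.__setattr__(self, "hemoglobin_levels", tuple(self.hemoglobin_levels))
        if not self.bilirubin_levels or not self.hemoglobin_levels:
            raise DomainError("panel must have at least one level of each analyte")
        for levels, name in (
            (self.bilirubin_levels, "bilirubin_levels"),
            (self.hemoglobin_levels, "hemoglobin_levels"),
        ):
            if any(c < 0 for c in levels):
                raise DomainError(f"{name} must be non-negative")
            if any(b <= a for a, b in zip(levels, levels[1:])):
                raise DomainError(f"{name} must be strictly increasing")
        if self.replicates < 1:
            raise DomainError("replicates must be >= 1")

    @property
    def n_tests(self) -> int:
        return len(self.bilirubin_levels) * len(self.hemoglobin_levels) * self.replicates

    def sample_id(self, i_bil: int, i_hb: int) -> str:
        """Label of the sample at 0-based level indices ``(i_bil, i_hb)``."""
        return f"B{i_bil + 1}H{i_hb + 1}"


@dataclass(frozen=True)
class Measurement:
    """One strip test: a blank-normalized reflectance pair with annotations."""

    sample_id: str
    bilirubin_nominal: float  # mg/dL
    hemoglobin_nominal: float  # g/dL
    replicate: int
    r465: float
    r590: float
    strip_ok: bool = True

    def __post_init__(self) -> None:
        # normalize numpy scalars etc. so CSV writes round-trip via repr()
        for name in ("bilirubin_nominal", "hemoglobin_nominal", "r465", "r590"):
            object.__setattr__(self, name, float(getattr(self, name)))
        object.__setattr__(self, "replicate", int(self.replicate))
        if self.r465 <= 0 or self.r590 <= 0:
            raise DomainError("normalized reflectances must be > 0")
        if self.bilirubin_nominal < 0 or self.hemoglobin_nominal < 0:
            raise DomainError("nominal concentrations must be >= 0")
        if self.replicate < 1:
            raise DomainError("replicate index is 1-based")


def reflectance(
    params: OpticalParams, c_bil: float, c_hb: float, wavelength: int
) -> float:
    """Noise-free normalized reflectance of a sample at one wavelength.

    Parameters
    ----------
    c_bil, c_hb
        Bilirubin (mg/dL) and free-hemoglobin (g/dL) concentrations, >= 0.
    wavelength
        465 (measurement channel) or 590 (compensation channel).

    Returns
    -------
    float
        Positive dimensionless reflectance.  Strictly decreasing in each
        analyte whose attenuation coefficient at this wavelength is positive.
    """
    if c_bil < 0 or c_hb < 0:
        raise DomainError(f"concentrations must be >= 0, got ({c_bil}, {c_hb})")
    if wavelength == 590:
        return params.n590 * math.exp(
            -params.k_bil_590 * c_bil - params.k_hb_590 * c_hb
        )
    if wavelength != 465:
        raise DomainError(f"wavelength must be 465 or 590, got {wavelength}")
    if params.interference_mode == "multiplicative":
        return params.n465 * math.exp(
            -params.k_bil_465 * c_bil - params.k_hb_465 * c_hb
        )
    # additive mode: hemoglobin subtracts the (scaled) reflectance drop it
    # causes on the 590 nm channel, making dR465 exactly linear in dR590
    drop_590 = params.n590 * (1.0 - math.exp(-params.k_hb_590 * c_hb))
    r = params.n465 * math.exp(-params.k_bil_465 * c_bil) - params.additive_gamma * drop_590
    if r <= 0:
        raise ParameterizationError(
            "additive interference mode produced a non-positive 465 nm "
            f"reflectance ({r:.4g}) at c_bil={c_bil}, c_hb={c_hb}; reduce "
            "additive_gamma or the hemoglobin range"
        )
    return r


def simulate_measurement(
    params: OpticalParams,
    c_bil: float,
    c_hb: float,
    rng: np.random.Generator,
    *,
    sample_id: str = "S1",
    replicate: int = 1,
) -> Measurement:
    """Simulate one strip test: two noisy reads per channel, averaged.

    Each single read is ``R · (1 + ε)`` with ``ε ~ N(0, noise_rel_sd)``; the
    reported channel value is the mean of two independent reads, so its
    relative SD is ``noise_rel_sd / sqrt(2)``.  With ``noise_rel_sd = 0`` the
    result equals the deterministic forward model exactly.
    """
    r465 = reflectance(params, c_bil, c_hb, 465)
    r590 = reflectance(params, c_bil, c_hb, 590)
    if params.noise_rel_sd > 0:
        r465 *= 1.0 + rng.normal(0.0, params.noise_rel_sd, size=2).mean()
        r590 *= 1.0 + rng.normal(0.0, params.noise_rel_sd, size=2).mean()
    return Measurement(
        sample_id=sample_id,
        bilirubin_nominal=c_bil,
        hemoglobin_nominal=c_hb,
        replicate=replicate,
        r465=r465,
        r590=r590,
    )


def simulate_panel(
    spec: PanelSpec, params: OpticalParams, seed: int | None = None
) -> list[Measurement]:
    """Simulate a full test panel, deterministically for a given seed.

    Iterates bilirubin levels (outer), hemolysis levels, then replicates
    (inner); sample ids follow the ``BiHj`` convention.  ``seed`` defaults to
    ``params.seed``.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    out: list[Measurement] = []
    for i, c_bil in enumerate(spec.bilirubin_levels):
        for j, c_hb in enumerate(spec.hemoglobin_levels):
            for rep in range(1, spec.replicates + 1):
                out.append(
                    simulate_measurement(
                        params,
                        c_bil,
                        c_hb,
                        rng,
                        sample_id=spec.sample_id(i, j),
                        replicate=rep,
                    )
                )
    return out


def default_params() -> OpticalParams:
    """Documented default forward-model parameters.

    The interference strength is set by the coefficient ratio
    ``k_hb_465 / k_bil_465 = 0.18 / 0.02 = 9``: each g/dL of free hemoglobin
    shifts the apparent (uncompensated) bilirubin reading up by 9 mg/dL, which
    places the uncompensated errors of the default panel in the observed
    few-mg/dL overestimation range.
    """
    return OpticalParams()


def default_panel_spec(replicates: int = 5) -> PanelSpec:
    """The default 5 bilirubin × 5 hemolysis level test panel (125 tests)."""
    return PanelSpec(PANEL_BILIRUBIN_MGDL, PANEL_HEMOGLOBIN_GDL, replicates)


def calibration_panel_spec(replicates: int = 5) -> PanelSpec:
    """Non-hemolyzed calibration series: 6 bilirubin levels at 0.06 g/dL."""
    return PanelSpec(CALIBRATION_BILIRUBIN_MGDL, (PANEL_HEMOGLOBIN_GDL[0],), replicates)
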