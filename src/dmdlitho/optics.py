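"""Optical and dosimetric arithmetic for DMD projection lithography.

Everything here is deliberately closed-form: pixel size and field of view
follow from the objective magnification and the DMD raster, depth of focus
from the classical n*lambda/NA**2 approximation, and delivered energy dose
from an affine LED/DMD power model integrated over the exposure time.

Unit conventions, fixed package-wide: lengths in micrometres (um), areas in
square millimetres (mm^2, dose only), optical power in milliwatts (mW),
time in milliseconds (ms), energy in millijoules (mJ) and dose in mJ/mm^2.
Conversions between these happen inside the operations, never at call sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


class OpticsConfigurationError(ValueError):
    """A light source or objective is missing a parameter an operation needs."""


@dataclass(frozen=True)
class DmdSpec:
    """Digital micromirror device raster dimensions (mirrors = binary pixels)."""

    rows: int
    cols: int

    def __post_init__(self) -> None:
        if self.rows <= 0 or self.cols <= 0:
            raise ValueError("DMD dimensions must be positive")


@dataclass(frozen=True)
class Objective:
    """A microscope objective through which DMD frames are projected.

    Parameters
    ----------
    magnification : float
        Nominal magnification (e.g. 20 for a 20x objective).
    na : float
        Numerical aperture.
    immersion_index : float
        Refractive index of the immersion medium (1.0 air, 1.515 oil).
    measured_pixel_size_um : float, optional
        Empirically measured projected size of one DMD pixel at the sample,
        in um. When absent the pixel size is scaled from a reference
        objective by the magnification ratio.
    """

    name: str
    magnification: float
    na: float
    immersion_index: float = 1.0
    measured_pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        if self.magnification <= 0:
            raise ValueError("magnification must be positive")
        if self.na <= 0:
            raise ValueError("numerical aperture must be positive")
        if self.immersion_index < 1:
            raise ValueError("immersion index must be >= 1")
        if self.measured_pixel_size_um is not None and self.measured_pixel_size_um <= 0:
            raise ValueError("measured pixel size must be positive")

    def pixel_size_um(
        self, reference: "Objective | None" = None
    ) -> float:
        """Projected DMD pixel size at the sample plane.

        Prefers the measured value when present; otherwise scales the
        reference objective's measured pixel size by the magnification
        ratio (a 4x objective projects 5x larger pixels than a 20x one).
        """
        if self.measured_pixel_size_um is not None:
            return self.measured_pixel_size_um
        if reference is None or reference.measured_pixel_size_um is None:
            raise OpticsConfigurationError(
                f"objective {self.name!r} has no measured pixel size and no "
                "reference objective with one was supplied"
            )
        return scale_pixel_size(
            reference.measured_pixel_size_um,
            reference.magnification,
            self.magnification,
        )

    def depth_of_focus_um(self, wavelength_um: float) -> float:
        return depth_of_focus(self.immersion_index, wavelength_um, self.na)


@dataclass(frozen=True)
class LightSource:
    """UV light source with optional DMD ON-pixel-fraction power model.

    ``max_power_mW`` is the optical power at the 100% LED setting, measured
    at the objective surface. The affine slope/intercept describe how the
    delivered power scales with the fraction of DMD mirrors switched ON.
    """

    max_power_mW: float
    wavelength_um: float
    dmd_slope_mW_per_unit_fraction: float | None = None
    dmd_intercept_mW: float | None = None

    def __post_init__(self) -> None:
        if self.max_power_mW < 0:
            raise ValueError("max power must be non-negative")
        if self.wavelength_um <= 0:
            raise ValueError("wavelength must be positive")


@dataclass(frozen=True)
class ExposureSpec:
    """One exposure: delivered power, duration, and illuminated area."""

    power_mW: float
    time_ms: float
    area_mm2: float

    def __post_init__(self) -> None:
        if self.power_mW < 0 or self.time_ms < 0 or self.area_mm2 < 0:
            raise ValueError("exposure parameters must be non-negative")

    @property
    def energy_mJ(self) -> float:
        return exposure_energy(self.power_mW, self.time_ms)

    @property
    def dose_mJ_mm2(self) -> float:
        return energy_dose(self.energy_mJ, self.area_mm2)


def dmd_pixel_size(fov_width_um: float, dmd_cols: int) -> float:
    """Projected pixel size from a measured FOV width and the DMD column count."""
    if fov_width_um <= 0 or dmd_cols <= 0:
        raise ValueError("FOV width and DMD column count must be positive")
    return fov_width_um / dmd_cols


def scale_pixel_size(
    reference_px_um: float, reference_mag: float, target_mag: float
) -> float:
    """Scale a measured pixel size from one objective to another.

    The projected pixel shrinks proportionally with magnification, so the
    target pixel size is ``reference_px_um * reference_mag / target_mag``.
    """
    if reference_px_um <= 0 or reference_mag <= 0 or target_mag <= 0:
        raise ValueError("pixel size and magnifications must be positive")
    return reference_px_um * reference_mag / target_mag


def fov_dimensions(pixel_size_um: float, dmd: DmdSpec) -> tuple[float, float]:
    """(height_um, width_um) of the projected field for a given pixel size."""
    if pixel_size_um <= 0:
        raise ValueError("pixel size must be positive")
    return dmd.rows * pixel_size_um, dmd.cols * pixel_size_um


def depth_of_focus(n: float, wavelength_um: float, na: float) -> float:
    """Axial focus range Delta-z = n * lambda / NA^2 in um.

    The standard scalar approximation: focus depth scales linearly with the
    immersion index and wavelength and falls off with the square of NA.
    """
    if na <= 0:
        raise ValueError("numerical aperture must be positive")
    if wavelength_um <= 0:
        raise ValueError("wavelength must be positive")
    if n < 1:
        raise ValueError("immersion index must be >= 1")
    return n * wavelength_um / na**2


def led_power(fraction: float, source: LightSource) -> float:
    """Optical output at an LED setting, assuming linearity in the setting."""
    if not 0 <= fraction <= 1:
        raise ValueError("LED fraction must lie in [0, 1]")
    return fraction * source.max_power_mW


def dmd_power(on_fraction: float, source: LightSource) -> float:
    """Delivered power as an affine function of the DMD ON-pixel fraction.

    The fitted intercept can be slightly negative; physical power cannot,
    so the result is clamped at zero near the all-OFF end.
    """
    if not 0 <= on_fraction <= 1:
        raise ValueError("ON-pixel fraction must lie in [0, 1]")
    if (
        source.dmd_slope_mW_per_unit_fraction is None
        or source.dmd_intercept_mW is None
    ):
        raise OpticsConfigurationError(
            "light source has no DMD ON-fraction power model (slope/intercept)"
        )
    return max(
        0.0,
        source.dmd_slope_mW_per_unit_fraction * on_fraction + source.dmd_intercept_mW,
    )


def exposure_energy(power_mW: float, time_ms: float) -> float:
    """Energy in mJ delivered by ``power_mW`` applied for ``time_ms``."""
    if power_mW < 0 or time_ms < 0:
        raise ValueError("power and time must be non-negative")
    return power_mW * time_ms / 1000.0


def energy_dose(energy_mJ: float, area_mm2: float) -> float:
    """Areal energy dose in mJ/mm^2. No intermediate rounding anywhere."""
    if area_mm2 <= 0:
        raise ValueError("illuminated area must be positive")
    return energy_mJ / area_mm2


def exposure_time_for_dose(
    target_dose_mJ_mm2: float, power_mW: float, area_mm2: float
) -> float:
    """Exposure time in ms that delivers a target dose at a given power.

    Exact inverse of ``energy_dose(exposure_energy(power, t), area)``.
    """
    if power_mW <= 0:
        raise ValueError("power must be positive")
    if area_mm2 <= 0:
        raise ValueError("illuminated area must be positive")
    if target_dose_mJ_mm2 < 0:
        raise ValueError("target dose must be non-negative")
    return target_dose_mJ_mm2 * area_mm2 * 1000.0 / power_mW


def um2_to_mm2(area_um2: float) -> float:
    return area_um2 / 1e6


def fov_area_mm2(pixel_size_um: float, dmd: DmdSpec) -> float:
    """Illuminated area of the full DMD field in mm^2."""
    h, w = fov_dimensions(pixel_size_um, dmd)
    return um2_to_mm2(h * w)
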