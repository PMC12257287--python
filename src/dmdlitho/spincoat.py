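"""Spin-coat thickness calibration.

Film thickness on a spinning substrate follows, to good approximation,

    h(RPM) = a / sqrt(RPM) + h0

with a material/process constant ``a`` (um * RPM^1/2) and a constant offset
``h0`` (um). The model is linear in (a, h0) after substituting
x = RPM^(-1/2), so fitting is closed-form ordinary least squares — no
iterative optimiser, no tolerance to choose.

The multilayer consistency check compares layer constants c = h * sqrt(RPM)
measured under different spin speeds: if the inverse-square-root law holds,
the constants agree and their symmetric relative difference is small.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class SpinFitError(ValueError):
    """Raised when the calibration points cannot support a fit."""


class UnreachableThicknessError(ValueError):
    """Raised when a target thickness is at or below the curve's offset."""


@dataclass(frozen=True)
class CalibrationPoint:
    """One measured (spin speed, film thickness) pair."""

    rpm: float
    thickness_um: float

    def __post_init__(self) -> None:
        if self.rpm <= 0 or self.thickness_um <= 0:
            raise ValueError("rpm and thickness must be positive")


@dataclass(frozen=True)
class SpinCurve:
    """Fitted h(RPM) = a / sqrt(RPM) + h0 calibration curve.

    ``a`` in um*RPM^1/2, ``h0`` in um, ``r_squared`` the coefficient of
    determination of the fit that produced it (1.0 for an exact curve).
    """

    a: float
    h0: float = 0.0
    r_squared: float = 1.0

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("proportionality constant a must be positive")

    def predict(self, rpm) -> float:
        return predict_thickness(self, rpm)

    def rpm_for(self, target_um: float) -> float:
        return rpm_for_thickness(self, target_um)


@dataclass(frozen=True)
class LayerConstant:
    """c = h * sqrt(RPM): invariant of the spin curve when h0 is negligible."""

    c: float

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError("layer constant must be positive")


def predict_thickness(curve: SpinCurve, rpm) -> float:
    """Film thickness in um at a spin speed, from a fitted curve."""
    rpm = np.asarray(rpm, dtype=float)
    if np.any(rpm <= 0):
        raise ValueError("rpm must be positive")
    out = curve.a / np.sqrt(rpm) + curve.h0
    return float(out) if out.ndim == 0 else out


def rpm_for_thickness(curve: SpinCurve, target_um: float) -> float:
    """Spin speed producing a target thickness; inverse of predict_thickness."""
    if target_um <= curve.h0:
        raise UnreachableThicknessError(
            f"target thickness {target_um} um is not above the curve offset "
            f"h0 = {curve.h0} um; no finite spin speed reaches it"
        )
    return (curve.a / (target_um - curve.h0)) ** 2


def fit_spin_curve(
    points: Iterable[CalibrationPoint | tuple[float, float]],
    with_offset: bool = True,
) -> SpinCurve:
    """Least-squares fit of h = a/sqrt(RPM) + h0 to calibration points.

    Parameters
    ----------
    points : iterable of CalibrationPoint or (rpm, thickness_um)
    with_offset : bool
        Fit the constant offset h0 (default). When False, h0 is forced to
        zero and a single regressor is fitted.

    Returns
    -------
    SpinCurve with the fitted (a, h0) and R^2 = 1 - SS_res/SS_tot,
    SS_tot taken about the sample mean of the thicknesses.
    """
    pts = [
        p if isinstance(p, CalibrationPoint) else CalibrationPoint(*p)
        for p in points
    ]
    n_min = 2 if with_offset else 1
    if len(pts) < n_min:
        raise SpinFitError(
            f"need at least {n_min} calibration points, got {len(pts)}"
        )
    rpm = np.array([p.rpm for p in pts], dtype=float)
    h = np.array([p.thickness_um for p in pts], dtype=float)
    if with_offset and len(np.unique(rpm)) < 2:
        raise SpinFitError("calibration points must span at least two distinct RPMs")

    x = 1.0 / np.sqrt(rpm)
    if with_offset:
        design = np.column_stack([x, np.ones_like(x)])
    else:
        design = x[:, None]
    coef, *_ = np.linalg.lstsq(design, h, rcond=None)
    a = float(coef[0])
    h0 = float(coef[1]) if with_offset else 0.0
    if a <= 0:
        raise SpinFitError(
            "fitted proportionality constant is non-positive; the data do "
            "not follow a decreasing thickness-vs-RPM trend"
        )

    resid = h - (a * x + h0)
    ss_res = float(resid @ resid)
    ss_tot = float(((h - h.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return SpinCurve(a=a, h0=h0, r_squared=r2)


def layer_constant(thickness_um: float, rpm: float) -> LayerConstant:
    """c = h * sqrt(RPM) for one measured layer."""
    if thickness_um <= 0 or rpm <= 0:
        raise ValueError("thickness and rpm must be positive")
    return LayerConstant(c=thickness_um * float(np.sqrt(rpm)))


def multilayer_error(c1: LayerConstant | float, c2: LayerConstant | float) -> float:
    """Symmetric relative difference of two layer constants, in percent.

    100 * |c1 - c2| / mean(c1, c2). Symmetric in its arguments, zero iff
    the constants agree, and invariant under rescaling both by the same
    factor.
    """
    v1 = c1.c if isinstance(c1, LayerConstant) else float(c1)
    v2 = c2.c if isinstance(c2, LayerConstant) else float(c2)
    if v1 <= 0 or v2 <= 0:
        raise ValueError("layer constants must be positive")
    return 100.0 * abs(v1 - v2) / ((v1 + v2) / 2.0)


def split_stacked_depth(total_um: float, n_layers: int) -> float:
    """Per-layer thickness of an n-layer stack of equal layers."""
    if n_layers < 1:
        raise ValueError("layer count must be at least 1")
    return total_um / n_layers


def read_calibration_csv(path) -> list[CalibrationPoint]:
    """Read a two-column calibration table ``rpm,thickness_um`` (header required)."""
    df = pd.read_csv(path)
    missing = {"rpm", "thickness_um"} - set(df.columns)
    if missing:
        raise SpinFitError(
            f"calibration table missing required column(s): {sorted(missing)}"
        )
    return [
        CalibrationPoint(rpm=float(r), thickness_um=float(t))
        for r, t in zip(df["rpm"], df["thickness_um"])
    ]


def synth_calibration_points(
    a: float,
    h0: float,
    rpms: Sequence[float],
    noise_sd_um: float = 0.0,
    seed: int | None = None,
) -> list[CalibrationPoint]:
    """Generate synthetic calibration points from a known curve.

    Emulates a thickness calibration series over the practical spin range
    (the defaults used in tests span 200-3200 RPM): exact model values plus
    additive Gaussian measurement noise of ``noise_sd_um``.
    """
    rng = np.random.default_rng(seed)
    curve = SpinCurve(a=a, h0=h0)
    pts = []
    for rpm in rpms:
        h = predict_thickness(curve, rpm)
        if noise_sd_um > 0:
            h = h + rng.normal(0.0, noise_sd_um)
        pts.append(CalibrationPoint(rpm=float(rpm), thickness_um=float(max(h, 1e-9))))
    return pts
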