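"""Virtual printer and synthetic-fixture generator.

The forward model is deliberately simple and auditable: each exposure
deposits its energy (power x time) uniformly over the illuminated ON
pixels of its field, giving a dose in mJ/mm^2 on a substrate grid; stage
jitter shifts each field by an independent Gaussian offset; optical blur is
a single Gaussian convolution of the accumulated dose map; the resin cures
wherever the dose reaches a material threshold. This captures the dose
arithmetic, tiling geometry and stitching errors of a real DMD print
without any resist chemistry.

The synthetic grid images emulate the stitched-line quality-control print:
dark printed lines on a bright background, with known (returned) line
positions, jitter and rotation, for exercising the qc pipeline against
exact ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import tifffile
from scipy.ndimage import gaussian_filter

from .tiling import TilePlan


@dataclass(frozen=True)
class DoseMap:
    """Accumulated UV dose per substrate cell, mJ/mm^2."""

    grid: np.ndarray
    pixel_pitch_um: float
    origin_um: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=float)
        if np.any(g < 0):
            raise ValueError("dose values must be non-negative")
        object.__setattr__(self, "grid", g)

    def total_energy_mJ(self) -> float:
        """Integrated energy: sum(dose) x cell area."""
        cell_mm2 = (self.pixel_pitch_um / 1000.0) ** 2
        return float(self.grid.sum() * cell_mm2)

    def save_tiff(self, path) -> None:
        tifffile.imwrite(path, self.grid.astype(np.float32))


@dataclass(frozen=True)
class CureMap:
    """Binary cured / washed-away map at a given cure threshold."""

    grid: np.ndarray
    threshold_mJ_mm2: float
    pixel_pitch_um: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "grid", np.asarray(self.grid, dtype=bool))

    @property
    def cured_area_um2(self) -> float:
        return float(self.grid.sum() * self.pixel_pitch_um**2)

    def save_tiff(self, path) -> None:
        tifffile.imwrite(path, self.grid.astype(np.uint8) * 255)


@dataclass(frozen=True)
class SynthGridTruth:
    """Exact geometry of a generated QC grid image.

    Positions are in um in unrotated image coordinates (before the global
    rotation is applied about the image centre): ``vertical_positions_um``
    are x coordinates of vertical lines, ``horizontal_positions_um`` y
    coordinates of horizontal lines, both sorted, jitter included.
    """

    pitch_um: float
    vertical_positions_um: np.ndarray
    horizontal_positions_um: np.ndarray
    jitter_sd_um: float
    angle_deg: float
    line_width_um: float
    pixel_size_um: float

    def true_spacings_um(self, axis: str) -> np.ndarray:
        pos = (
            self.vertical_positions_um
            if axis == "vertical"
            else self.horizontal_positions_um
        )
        return np.diff(pos)


def simulate_print(
    plan: TilePlan,
    power_mW: float,
    substrate_pitch_um: float | None = None,
    psf_sigma_um: float = 0.0,
    jitter_sd_um: float = 0.0,
    seed: int | None = None,
    margin_um: float | None = None,
) -> DoseMap:
    """Accumulate the dose a tile plan deposits on a virtual substrate.

    Each exposure deposits ``time_ms * power_mW / field_area`` uniformly on
    the substrate cells whose centres fall on ON frame pixels, after
    shifting the field by a per-exposure Gaussian stage-jitter offset; the
    summed map is then blurred with a Gaussian PSF of ``psf_sigma_um``
    (zero-padded borders). Deterministic for a fixed seed.

    ``substrate_pitch_um`` defaults to half the projected DMD pixel size
    (Nyquist with respect to the frame raster).
    """
    for name, v in [
        ("power_mW", power_mW),
        ("psf_sigma_um", psf_sigma_um),
        ("jitter_sd_um", jitter_sd_um),
    ]:
        if not math.isfinite(v) or v < 0:
            raise ValueError(f"{name} must be finite and non-negative")
    px = plan.pixel_size_um
    pitch = substrate_pitch_um if substrate_pitch_um is not None else px / 2.0
    if pitch <= 0:
        raise ValueError("substrate pitch must be positive")
    fov_h, fov_w = plan.fov_um
    if margin_um is None:
        margin_um = 4.0 * psf_sigma_um + 6.0 * jitter_sd_um

    rng = np.random.default_rng(seed)
    # jitter offsets drawn up-front, one pair per exposure, so the map is a
    # pure function of (plan, seed) regardless of empty-frame layout
    offsets = (
        rng.normal(0.0, jitter_sd_um, size=(len(plan.exposures), 2))
        if jitter_sd_um > 0
        else np.zeros((len(plan.exposures), 2))
    )

    if not plan.exposures:
        return DoseMap(grid=np.zeros((1, 1)), pixel_pitch_um=pitch)

    xs = np.array([e.stage_x_um for e in plan.exposures])
    ys = np.array([e.stage_y_um for e in plan.exposures])
    x_min = xs.min() - fov_w / 2 - margin_um
    x_max = xs.max() + fov_w / 2 + margin_um
    y_min = ys.min() - fov_h / 2 - margin_um
    y_max = ys.max() + fov_h / 2 + margin_um
    n_cols = max(1, int(math.ceil((x_max - x_min) / pitch)))
    n_rows = max(1, int(math.ceil((y_max - y_min) / pitch)))
    grid = np.zeros((n_rows, n_cols))

    fov_area_mm2 = (fov_h / 1000.0) * (fov_w / 1000.0)
    cx = x_min + (np.arange(n_cols) + 0.5) * pitch
    cy = y_min + (np.arange(n_rows) + 0.5) * pitch
    for e, (jx, jy) in zip(plan.exposures, offsets):
        dose = e.time_ms * power_mW / 1000.0 / fov_area_mm2
        x0 = e.stage_x_um - fov_w / 2 + jx
        y0 = e.stage_y_um - fov_h / 2 + jy
        ci = np.floor((cx - x0) / px).astype(int)
        ri = np.floor((cy - y0) / px).astype(int)
        c_ok = (ci >= 0) & (ci < plan.dmd.cols)
        r_ok = (ri >= 0) & (ri < plan.dmd.rows)
        if not (c_ok.any() and r_ok.any()):
            continue
        on = e.frame[np.ix_(ri[r_ok], ci[c_ok])]
        patch = np.zeros((n_rows, n_cols), dtype=bool)
        patch[np.ix_(r_ok, c_ok)] = on
        grid[patch] += dose

    if psf_sigma_um > 0:
        grid = gaussian_filter(grid, sigma=psf_sigma_um / pitch, mode="constant")
    return DoseMap(grid=grid, pixel_pitch_um=pitch, origin_um=(x_min, y_min))


def default_psf_sigma_um(wavelength_um: float, na: float) -> float:
    """Gaussian approximation of the diffraction-limited spot: 0.21 lambda/NA."""
    if wavelength_um <= 0 or na <= 0:
        raise ValueError("wavelength and NA must be positive")
    return 0.21 * wavelength_um / na


def cure(dose: DoseMap, threshold_mJ_mm2: float) -> CureMap:
    """Threshold a dose map: the resin cures wherever dose >= threshold."""
    if threshold_mJ_mm2 <= 0:
        raise ValueError("cure threshold must be positive")
    return CureMap(
        grid=dose.grid >= threshold_mJ_mm2,
        threshold_mJ_mm2=threshold_mJ_mm2,
        pixel_pitch_um=dose.pixel_pitch_um,
    )


def synth_grid_image(
    pitch_um: float = 50.0,
    n_lines: int = 10,
    line_width_um: float = 5.0,
    jitter_sd_um: float = 0.0,
    angle_deg: float = 0.0,
    noise_sd: float = 0.0,
    pixel_size_um: float = 0.7,
    seed: int | None = None,
    background_gray: float = 220.0,
    line_gray: float = 40.0,
) -> tuple[np.ndarray, SynthGridTruth]:
    """Render a synthetic printed-grid micrograph with exact ground truth.

    ``n_lines`` dark horizontal and vertical lines on a bright background,
    nominally ``pitch_um`` apart, each independently displaced by Gaussian
    jitter of ``jitter_sd_um``, the whole grid rotated by ``angle_deg``
    about the image centre, plus additive Gaussian pixel noise of
    ``noise_sd`` gray levels. Deterministic for a fixed seed.
    """
    if not pitch_um > line_width_um > 0:
        raise ValueError("need pitch_um > line_width_um > 0")
    if n_lines < 2:
        raise ValueError("need at least two lines per axis")
    if pixel_size_um <= 0:
        raise ValueError("pixel size must be positive")
    rng = np.random.default_rng(seed)

    margin = pitch_um
    extent = (n_lines - 1) * pitch_um + 2 * margin
    nominal = margin + np.arange(n_lines) * pitch_um
    xv = np.sort(nominal + rng.normal(0.0, jitter_sd_um, n_lines))
    yh = np.sort(nominal + rng.normal(0.0, jitter_sd_um, n_lines))
    for pos in (xv, yh):
        if pos[0] - line_width_um / 2 < 0 or pos[-1] + line_width_um / 2 > extent:
            raise ValueError("jittered lines exceed the image extent")

    n_px = int(round(extent / pixel_size_um))
    coords = (np.arange(n_px) + 0.5) * pixel_size_um
    X, Y = np.meshgrid(coords, coords)
    c = extent / 2.0
    th = math.radians(angle_deg)
    # rotate sampling coordinates by -angle so the grid appears at +angle
    Xr = c + (X - c) * math.cos(th) + (Y - c) * math.sin(th)
    Yr = c - (X - c) * math.sin(th) + (Y - c) * math.cos(th)

    half_w = line_width_um / 2.0
    dark = np.zeros_like(X, dtype=bool)
    for x0 in xv:
        dark |= np.abs(Xr - x0) <= half_w
    for y0 in yh:
        dark |= np.abs(Yr - y0) <= half_w

    img = np.full(X.shape, background_gray)
    img[dark] = line_gray
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, img.shape)
    img = np.clip(img, 0, 255).astype(np.uint8)

    truth = SynthGridTruth(
        pitch_um=pitch_um,
        vertical_positions_um=xv,
        horizontal_positions_um=yh,
        jitter_sd_um=jitter_sd_um,
        angle_deg=angle_deg,
        line_width_um=line_width_um,
        pixel_size_um=pixel_size_um,
    )
    return img, truth
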