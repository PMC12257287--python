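"""Decompose a physical-units design into ordered DMD exposures.

A design is a binary raster in physical units (ON = expose). Patterns
larger than one projected field of view are printed by stepping the stage
over a grid of abutting tiles and projecting one DMD frame per tile; the
tiles are visited in serpentine (boustrophedon) order to minimise stage
travel.

Coordinate convention, used everywhere in this package: stage and image x
increase rightward, y increases downward (raster row order); the design
origin is its top-left corner; pixel intervals are half-open; DMD frames
are row-major numpy arrays indexed [row, col].
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile
from skimage.feature import match_template

from .optics import DmdSpec, Objective


class AlignmentError(ValueError):
    """Fiducial alignment could not produce a trustworthy offset."""


@dataclass(frozen=True)
class Design:
    """Binary raster mask in physical units.

    ``mask`` is a 2-D boolean array (True = expose); ``pixel_pitch_um`` is
    the physical size of one design pixel; ``origin_um`` the stage
    coordinate (x, y) of the design's top-left corner.
    """

    mask: np.ndarray
    pixel_pitch_um: float
    origin_um: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        m = np.asarray(self.mask)
        if m.ndim != 2 or m.size == 0:
            raise ValueError("design mask must be a non-empty 2-D raster")
        if self.pixel_pitch_um <= 0:
            raise ValueError("pixel pitch must be positive")
        object.__setattr__(self, "mask", m.astype(bool))

    @property
    def extent_um(self) -> tuple[float, float]:
        """(height_um, width_um) of the design."""
        return (
            self.mask.shape[0] * self.pixel_pitch_um,
            self.mask.shape[1] * self.pixel_pitch_um,
        )


@dataclass(frozen=True)
class Exposure:
    """One stage position plus the DMD frame projected there."""

    stage_x_um: float
    stage_y_um: float
    frame: np.ndarray
    time_ms: float

    def __post_init__(self) -> None:
        if self.time_ms < 0:
            raise ValueError("exposure time must be non-negative")
        object.__setattr__(self, "frame", np.asarray(self.frame, dtype=bool))

    @property
    def on_fraction(self) -> float:
        return float(self.frame.mean())


@dataclass
class TilePlan:
    """Ordered exposures covering a design, with projection geometry."""

    exposures: list[Exposure]
    objective_name: str
    dmd: DmdSpec
    pixel_size_um: float
    skipped_empty: int = 0

    def __post_init__(self) -> None:
        for e in self.exposures:
            if e.frame.shape != (self.dmd.rows, self.dmd.cols):
                raise ValueError(
                    f"frame shape {e.frame.shape} does not match DMD "
                    f"{(self.dmd.rows, self.dmd.cols)}"
                )

    @property
    def fov_um(self) -> tuple[float, float]:
        """(height_um, width_um) of one projected field."""
        return (
            self.dmd.rows * self.pixel_size_um,
            self.dmd.cols * self.pixel_size_um,
        )

    def stage_positions(self) -> pd.DataFrame:
        """Stage list as a DataFrame: index, x_um, y_um, time_ms."""
        return pd.DataFrame(
            {
                "index": range(len(self.exposures)),
                "x_um": [e.stage_x_um for e in self.exposures],
                "y_um": [e.stage_y_um for e in self.exposures],
                "time_ms": [e.time_ms for e in self.exposures],
            }
        )


def serpentine_order(n_rows: int, n_cols: int) -> list[tuple[int, int]]:
    """Boustrophedon visit order over an n_rows x n_cols tile grid.

    Row 0 runs left-to-right, row 1 right-to-left, and so on: consecutive
    tiles are always grid neighbours, so total axis-aligned travel is the
    minimum n_rows*n_cols - 1 steps.
    """
    if n_rows < 0 or n_cols < 0:
        raise ValueError("tile counts must be non-negative")
    order: list[tuple[int, int]] = []
    for r in range(n_rows):
        cols = range(n_cols) if r % 2 == 0 else range(n_cols - 1, -1, -1)
        order.extend((r, c) for c in cols)
    return order


def _resample_frame(
    design: Design,
    tile_x0_um: float,
    tile_y0_um: float,
    dmd: DmdSpec,
    pixel_size_um: float,
) -> np.ndarray:
    """Nearest-neighbour sample of the design under one DMD tile.

    A DMD pixel is ON iff its centre falls inside an ON design pixel. The
    DMD is binary, so no anti-aliasing: gray levels would be meaningless.
    """
    ox, oy = design.origin_um
    cx = tile_x0_um + (np.arange(dmd.cols) + 0.5) * pixel_size_um
    cy = tile_y0_um + (np.arange(dmd.rows) + 0.5) * pixel_size_um
    col_idx = np.floor((cx - ox) / design.pixel_pitch_um).astype(int)
    row_idx = np.floor((cy - oy) / design.pixel_pitch_um).astype(int)
    col_ok = (col_idx >= 0) & (col_idx < design.mask.shape[1])
    row_ok = (row_idx >= 0) & (row_idx < design.mask.shape[0])
    frame = np.zeros((dmd.rows, dmd.cols), dtype=bool)
    if col_ok.any() and row_ok.any():
        sub = design.mask[np.ix_(row_idx[row_ok], col_idx[col_ok])]
        frame[np.ix_(row_ok, col_ok)] = sub
    return frame


def plan_tiles(
    design: Design,
    objective: Objective,
    dmd: DmdSpec,
    time_ms: float,
    reference_objective: Objective | None = None,
    overlap_um: float = 0.0,
) -> TilePlan:
    """Tile a design into an ordered serpentine sequence of DMD exposures.

    Tiles abut exactly by default (``overlap_um`` shifts the stage step so
    neighbouring fields overlap; ON pixels in the overlap are simply
    exposed by both frames). The tile count per axis is
    ceil(design_extent / field_extent); frames with no ON pixel are dropped
    from the plan (and counted) to save stage moves.
    """
    if time_ms < 0:
        raise ValueError("exposure time must be non-negative")
    px = objective.pixel_size_um(reference_objective)
    fov_h, fov_w = dmd.rows * px, dmd.cols * px
    if overlap_um < 0 or overlap_um >= min(fov_h, fov_w):
        if overlap_um != 0.0:
            raise ValueError("overlap must be non-negative and smaller than the FOV")
    ext_h, ext_w = design.extent_um
    step_x = fov_w - overlap_um
    step_y = fov_h - overlap_um
    n_tr = max(1, math.ceil((ext_h - overlap_um) / step_y))
    n_tc = max(1, math.ceil((ext_w - overlap_um) / step_x))

    ox, oy = design.origin_um
    exposures: list[Exposure] = []
    skipped = 0
    for tr, tc in serpentine_order(n_tr, n_tc):
        x0 = ox + tc * step_x
        y0 = oy + tr * step_y
        frame = _resample_frame(design, x0, y0, dmd, px)
        if not frame.any():
            skipped += 1
            continue
        exposures.append(
            Exposure(
                stage_x_um=x0 + fov_w / 2,
                stage_y_um=y0 + fov_h / 2,
                frame=frame,
                time_ms=time_ms,
            )
        )
    return TilePlan(
        exposures=exposures,
        objective_name=objective.name,
        dmd=dmd,
        pixel_size_um=px,
        skipped_empty=skipped,
    )


def rasterize_plan(
    plan: TilePlan,
    pixel_pitch_um: float,
    origin_um: tuple[float, float],
    shape: tuple[int, int],
) -> np.ndarray:
    """Paint a plan's ON pixels back onto a design-resolution grid.

    The coverage oracle for tiling: each ON DMD pixel marks the design cell
    its centre falls in. With the design pitch equal to the projected pixel
    size and evenly dividing extents this reproduces the original mask.
    """
    out = np.zeros(shape, dtype=bool)
    ox, oy = origin_um
    fov_h, fov_w = plan.fov_um
    px = plan.pixel_size_um
    for e in plan.exposures:
        x0 = e.stage_x_um - fov_w / 2
        y0 = e.stage_y_um - fov_h / 2
        rr, cc = np.nonzero(e.frame)
        cx = x0 + (cc + 0.5) * px
        cy = y0 + (rr + 0.5) * px
        ci = np.floor((cx - ox) / pixel_pitch_um).astype(int)
        ri = np.floor((cy - oy) / pixel_pitch_um).astype(int)
        ok = (ri >= 0) & (ri < shape[0]) & (ci >= 0) & (ci < shape[1])
        out[ri[ok], ci[ok]] = True
    return out


def plan_exposure_series(
    base_frame: np.ndarray,
    times_ms: list[float],
    spacing_um: float,
    pixel_size_um: float = 1.0,
    objective_name: str = "exposure-series",
) -> TilePlan:
    """Lay out an exposure-time calibration series on one stage row.

    The same frame is projected once per requested duration, stepping the
    stage by ``spacing_um`` between exposures. Inspecting which duration
    first cures cleanly calibrates the exposure time in minutes instead of
    deriving it from resin chemistry.
    """
    times = [float(t) for t in times_ms]
    if any(t < 0 for t in times):
        raise ValueError("exposure times must be non-negative")
    if any(b <= a for a, b in zip(times, times[1:])):
        raise ValueError("exposure times must be strictly increasing")
    frame = np.asarray(base_frame, dtype=bool)
    dmd = DmdSpec(rows=frame.shape[0], cols=frame.shape[1])
    exposures = [
        Exposure(stage_x_um=i * spacing_um, stage_y_um=0.0, frame=frame, time_ms=t)
        for i, t in enumerate(times)
    ]
    return TilePlan(
        exposures=exposures,
        objective_name=objective_name,
        dmd=dmd,
        pixel_size_um=pixel_size_um,
    )


@dataclass(frozen=True)
class AlignmentResult:
    """Translation offset of a fiducial, with the match correlation."""

    dx_um: float
    dy_um: float
    correlation: float

    def __iter__(self):
        return iter((self.dx_um, self.dy_um))


def align_to_fiducial(
    image: np.ndarray,
    template: np.ndarray,
    pixel_size_um: float,
    reference_px: tuple[float, float] | None = None,
    min_correlation: float | None = None,
) -> AlignmentResult:
    """Locate a fiducial template in an image by normalised cross-correlation.

    Returns the (dx_um, dy_um) stage correction that would move the found
    fiducial back to its reference position (default: template centred in
    the image). Raises :class:`AlignmentError` for a flat template or, when
    ``min_correlation`` is given, for a peak correlation below it — a guard
    against aligning to noise.
    """
    img = np.asarray(image, dtype=float)
    tpl = np.asarray(template, dtype=float)
    if tpl.shape[0] >= img.shape[0] or tpl.shape[1] >= img.shape[1]:
        raise AlignmentError("template must be strictly smaller than the image")
    if np.ptp(tpl) == 0:
        raise AlignmentError("flat (zero-variance) template cannot be matched")
    if pixel_size_um <= 0:
        raise ValueError("pixel size must be positive")

    corr = match_template(img, tpl)
    peak = np.unravel_index(np.argmax(corr), corr.shape)
    score = float(corr[peak])
    if min_correlation is not None and score < min_correlation:
        raise AlignmentError(
            f"peak correlation {score:.3f} below threshold {min_correlation:.3f}"
        )
    if reference_px is None:
        reference_px = (
            (img.shape[0] - tpl.shape[0]) / 2.0,
            (img.shape[1] - tpl.shape[1]) / 2.0,
        )
    dy = (peak[0] - reference_px[0]) * pixel_size_um
    dx = (peak[1] - reference_px[1]) * pixel_size_um
    return AlignmentResult(dx_um=dx, dy_um=dy, correlation=score)


def save_plan(plan: TilePlan, json_path, frames_tiff_path) -> None:
    """Serialise a plan: JSON metadata + frames as a multi-page TIFF.

    The TIFF is referenced by file name, resolved relative to the JSON on
    load, so a saved plan directory can be moved or renamed.
    """
    meta = {
        "objective_name": plan.objective_name,
        "dmd": {"rows": plan.dmd.rows, "cols": plan.dmd.cols},
        "pixel_size_um": plan.pixel_size_um,
        "skipped_empty": plan.skipped_empty,
        "frames_tiff": os.path.basename(str(frames_tiff_path)),
        "exposures": [
            {
                "index": i,
                "stage_x_um": e.stage_x_um,
                "stage_y_um": e.stage_y_um,
                "time_ms": e.time_ms,
                "frame_page": i,
            }
            for i, e in enumerate(plan.exposures)
        ],
    }
    with open(json_path, "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
    if plan.exposures:
        stack = np.stack([e.frame.astype(np.uint8) * 255 for e in plan.exposures])
        tifffile.imwrite(frames_tiff_path, stack)


def load_plan(json_path) -> TilePlan:
    """Read back a plan written by :func:`save_plan`."""
    with open(json_path) as fh:
        meta = json.load(fh)
    dmd = DmdSpec(rows=meta["dmd"]["rows"], cols=meta["dmd"]["cols"])
    if meta["exposures"]:
        tiff_path = os.path.join(os.path.dirname(str(json_path)), meta["frames_tiff"])
        stack = tifffile.imread(tiff_path)
        if stack.ndim == 2:
            stack = stack[None]
    exposures = [
        Exposure(
            stage_x_um=rec["stage_x_um"],
            stage_y_um=rec["stage_y_um"],
            frame=stack[rec["frame_page"]] > 0,
            time_ms=rec["time_ms"],
        )
        for rec in meta["exposures"]
    ]
    return TilePlan(
        exposures=exposures,
        objective_name=meta["objective_name"],
        dmd=dmd,
        pixel_size_um=meta["pixel_size_um"],
        skipped_empty=meta.get("skipped_empty", 0),
    )
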