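"""Automated grid detection and quantitative alignment analysis.

Quality control for stitched prints: a micrograph of a regularly spaced
line grid is upscaled, binarised (Otsu) and skeletonised; line segments
are found with the probabilistic Hough transform; segments are classified
as horizontal or vertical by their angle, grouped along the dominant axis
so each physical bar is represented once, and merged by taking the most
distant pair of pooled endpoints. The report carries orientation mean/SD
per axis (as deviation from the assigned axis, so both axes share one
misalignment scale) and grid pitch mean/SD in um — the pitch SD is the
stitching-accuracy figure of merit.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from skimage.filters import threshold_otsu
from skimage.morphology import skeletonize
from skimage.transform import probabilistic_hough_line, resize


class ThresholdingError(ValueError):
    """The image has no contrast to threshold."""


@dataclass(frozen=True)
class LineSegment:
    """A detected segment with endpoints in (x, y) pixel coordinates."""

    p0: tuple[float, float]
    p1: tuple[float, float]

    def __post_init__(self) -> None:
        if self.p0 == self.p1:
            raise ValueError("segment endpoints must be distinct")

    @property
    def angle_deg(self) -> float:
        """Orientation in (-90, 90], 0 = horizontal in image coordinates."""
        return _segment_angle(self.p0, self.p1)

    @property
    def midpoint(self) -> tuple[float, float]:
        return (
            (self.p0[0] + self.p1[0]) / 2.0,
            (self.p0[1] + self.p1[1]) / 2.0,
        )

    @property
    def length(self) -> float:
        return math.hypot(self.p1[0] - self.p0[0], self.p1[1] - self.p0[1])


def _segment_angle(p0, p1) -> float:
    ang = math.degrees(math.atan2(p1[1] - p0[1], p1[0] - p0[0]))
    if ang <= -90.0:
        ang += 180.0
    elif ang > 90.0:
        ang -= 180.0
    return ang


@dataclass(frozen=True)
class MergedLine:
    """One physical bar: the maximally distant endpoint pair of its group."""

    axis: str  # "horizontal" | "vertical"
    span_endpoints: tuple[tuple[float, float], tuple[float, float]]
    position_px: float

    @property
    def angle_deg(self) -> float:
        return _segment_angle(*self.span_endpoints)

    @property
    def axis_deviation_deg(self) -> float:
        """Signed deviation from the assigned axis, in degrees."""
        a = self.angle_deg
        if self.axis == "horizontal":
            return a
        return a - 90.0 if a > 0 else a + 90.0


@dataclass(frozen=True)
class AxisStats:
    """Per-axis orientation and pitch statistics of a detected grid."""

    n_lines: int
    orientation_mean_deg: float | None
    orientation_sd_deg: float | None
    pitch_mean_um: float | None
    pitch_sd_um: float | None


@dataclass(frozen=True)
class GridQCReport:
    """Grid-alignment QC summary in physical units."""

    horizontal: AxisStats
    vertical: AxisStats
    pixel_size_um: float
    upscale_factor: int

    def to_dict(self) -> dict:
        return {
            "pixel_size_um": self.pixel_size_um,
            "upscale_factor": self.upscale_factor,
            "horizontal": vars(self.horizontal),
            "vertical": vars(self.vertical),
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=1, sort_keys=True, **kw)

    def __str__(self) -> str:
        rows = ["axis\tn_lines\torient_mean_deg\torient_sd_deg\tpitch_mean_um\tpitch_sd_um"]
        for name, st in [("horizontal", self.horizontal), ("vertical", self.vertical)]:
            fmt = lambda v: "NA" if v is None else f"{v:.3f}"
            rows.append(
                f"{name}\t{st.n_lines}\t{fmt(st.orientation_mean_deg)}\t"
                f"{fmt(st.orientation_sd_deg)}\t{fmt(st.pitch_mean_um)}\t{fmt(st.pitch_sd_um)}"
            )
        return "\n".join(rows)


def preprocess(image: np.ndarray, upscale_factor: int = 4, dark_lines: bool = True) -> np.ndarray:
    """Upscale (bicubic), Otsu-binarise and skeletonise a grid micrograph.

    Upscaling before skeletonisation gives sub-(original)-pixel line
    positions; ``dark_lines`` selects the polarity (printed lines darker
    than background by default). Returns a boolean skeleton raster.
    """
    img = np.asarray(image, dtype=float)
    if img.size == 0:
        raise ValueError("empty image")
    if upscale_factor < 1:
        raise ValueError("upscale factor must be >= 1")
    if np.ptp(img) == 0:
        raise ThresholdingError("constant image cannot be thresholded")
    if upscale_factor > 1:
        img = resize(
            img,
            (img.shape[0] * upscale_factor, img.shape[1] * upscale_factor),
            order=3,
            preserve_range=True,
            anti_aliasing=False,
        )
    t = threshold_otsu(img)
    binary = img < t if dark_lines else img > t
    return skeletonize(binary)


def detect_segments(
    skeleton: np.ndarray,
    hough_threshold: int = 10,
    min_length_px: int | None = None,
    max_gap_px: int = 5,
    seed: int = 0,
) -> list[LineSegment]:
    """Probabilistic Hough line detection on a skeleton raster.

    ``min_length_px`` defaults to 25% of the shorter image side. Seeded:
    the probabilistic Hough transform samples points randomly, so a fixed
    seed makes detection reproducible.
    """
    skel = np.asarray(skeleton, dtype=bool)
    if min_length_px is None:
        min_length_px = max(1, min(skel.shape) // 4)
    if hough_threshold <= 0 or min_length_px <= 0 or max_gap_px <= 0:
        raise ValueError("Hough parameters must be positive")
    if not skel.any():
        return []
    lines = probabilistic_hough_line(
        skel,
        threshold=hough_threshold,
        line_length=min_length_px,
        line_gap=max_gap_px,
        rng=np.random.default_rng(seed),
    )
    return [
        LineSegment(p0=tuple(map(float, p0)), p1=tuple(map(float, p1)))
        for p0, p1 in lines
        if tuple(p0) != tuple(p1)
    ]


def group_and_merge(
    segments: list[LineSegment],
    angle_tol_deg: float = 45.0,
    group_tol_px: float = 10.0,
) -> tuple[list[MergedLine], list[MergedLine]]:
    """Classify, group and merge segments into one line per physical bar.

    Segments with |angle| <= 45 deg are horizontal, the rest vertical;
    segments whose deviation from the assigned axis exceeds
    ``angle_tol_deg`` are discarded as spurious. Within an axis, segments
    are grouped by single linkage on their midpoint coordinate along the
    dominant axis (y for horizontal bars, x for vertical): a gap larger
    than ``group_tol_px`` starts a new group. Each group's endpoints are
    pooled and the maximally distant pair defines the merged line.
    """
    if angle_tol_deg <= 0 or group_tol_px <= 0:
        raise ValueError("tolerances must be positive")
    horiz: list[LineSegment] = []
    vert: list[LineSegment] = []
    for s in segments:
        a = s.angle_deg
        if abs(a) <= 45.0:
            if abs(a) <= angle_tol_deg:
                horiz.append(s)
        else:
            dev = a - 90.0 if a > 0 else a + 90.0
            if abs(dev) <= angle_tol_deg:
                vert.append(s)

    def merge(axis_segments: list[LineSegment], axis: str) -> list[MergedLine]:
        coord = 1 if axis == "horizontal" else 0  # y for horizontal bars
        ordered = sorted(axis_segments, key=lambda s: s.midpoint[coord])
        merged: list[MergedLine] = []
        group: list[LineSegment] = []

        def flush() -> None:
            if not group:
                return
            pts = [p for s in group for p in (s.p0, s.p1)]
            best = max(
                (
                    (pts[i], pts[j])
                    for i in range(len(pts))
                    for j in range(i + 1, len(pts))
                ),
                key=lambda pq: (pq[0][0] - pq[1][0]) ** 2 + (pq[0][1] - pq[1][1]) ** 2,
            )
            pos = (best[0][coord] + best[1][coord]) / 2.0
            merged.append(
                MergedLine(axis=axis, span_endpoints=best, position_px=pos)
            )

        prev = None
        for s in ordered:
            c = s.midpoint[coord]
            if prev is not None and c - prev > group_tol_px:
                flush()
                group = []
            group.append(s)
            prev = c
        flush()
        return merged

    return merge(horiz, "horizontal"), merge(vert, "vertical")


def _axis_stats(
    lines: list[MergedLine], px_um: float, upscale: int
) -> AxisStats:
    n = len(lines)
    if n == 0:
        return AxisStats(0, None, None, None, None)
    devs = np.array([ln.axis_deviation_deg for ln in lines])
    o_mean = float(devs.mean())
    o_sd = float(devs.std(ddof=1)) if n >= 2 else 0.0
    if n >= 2:
        pos = np.sort([ln.position_px for ln in lines])
        spacings = np.diff(pos) * px_um / upscale
        p_mean = float(spacings.mean())
        p_sd = float(spacings.std(ddof=1)) if len(spacings) >= 2 else 0.0
    else:
        p_mean = p_sd = None
    return AxisStats(n, o_mean, o_sd, p_mean, p_sd)


def grid_statistics(
    horizontal: list[MergedLine],
    vertical: list[MergedLine],
    pixel_size_um: float,
    upscale_factor: int = 1,
) -> GridQCReport:
    """Orientation and pitch statistics of merged grid lines, in um.

    Pitch is the spacing of consecutive sorted line positions converted to
    physical units (detection happened on the upscaled raster, hence the
    division by the upscale factor); axes with fewer than two lines report
    pitch as undefined (None). SDs are sample standard deviations.
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel size must be positive")
    return GridQCReport(
        horizontal=_axis_stats(horizontal, pixel_size_um, upscale_factor),
        vertical=_axis_stats(vertical, pixel_size_um, upscale_factor),
        pixel_size_um=pixel_size_um,
        upscale_factor=upscale_factor,
    )


def analyze_grid(
    image: np.ndarray,
    pixel_size_um: float,
    upscale_factor: int = 4,
    expected_pitch_um: float | None = None,
    dark_lines: bool = True,
    hough_threshold: int = 10,
    min_length_px: int | None = None,
    max_gap_px: int = 5,
    angle_tol_deg: float = 45.0,
    seed: int = 0,
) -> GridQCReport:
    """Full grid-QC pipeline: micrograph in, pitch/orientation report out.

    The grouping tolerance defaults to half the expected pitch when one is
    supplied (in post-upscale pixels), else 10 post-upscale pixels.
    """
    skel = preprocess(image, upscale_factor=upscale_factor, dark_lines=dark_lines)
    segs = detect_segments(
        skel,
        hough_threshold=hough_threshold,
        min_length_px=min_length_px,
        max_gap_px=max_gap_px,
        seed=seed,
    )
    if expected_pitch_um is not None:
        group_tol_px = expected_pitch_um / 2.0 / pixel_size_um * upscale_factor
    else:
        group_tol_px = 10.0
    horiz, vert = group_and_merge(
        segs, angle_tol_deg=angle_tol_deg, group_tol_px=group_tol_px
    )
    return grid_statistics(horiz, vert, pixel_size_um, upscale_factor)
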