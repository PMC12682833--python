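"""Minirhizotron tube geometry: depth registration and observation-area calibration.

A minirhizotron is a transparent tube installed obliquely in the soil; a camera
travels along it and photographs roots at the tube surface at a fixed spacing.
Converting those per-image observations into soil-depth-resolved root profiles
requires two pieces of calibration that this module provides:

* **depth registration** — mapping a distance along the tube to a soil depth.
  Registration is linear between two anchor points (the soil depth of the first
  imaged position and the depth at the far end of the tube).  The nominal slope
  angle of the tube is retained as metadata only; the anchors take precedence.
* **observation area** — the soil surface area observed within a depth interval,
  i.e. (number of image positions in the interval) x image step x image width.
  This is the denominator of planar root length density (pRLD, cm of root per
  cm^2 of image).

Depth intervals are half-open ``[lo, hi)`` throughout so that adjacent bins
partition the profile exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "GeometryError",
    "PositionOutOfRangeError",
    "TubeGeometry",
    "calibrate_image_width_mm",
    "depth_at_position",
    "position_at_depth",
    "pixels_to_cm",
    "observation_area_m2",
]

#: Depth-interval / area pair used to derive the default image width: a 0.25-m
#: depth interval is taken to expose 0.0125 m^2 of observation area.
CAL_INTERVAL_M = 0.25
CAL_AREA_M2 = 0.0125


class GeometryError(ValueError):
    """Invalid tube geometry or geometric query."""


class PositionOutOfRangeError(GeometryError):
    """A tube position or depth lies outside the imaged range."""


def calibrate_image_width_mm(
    tube_length_mm: float,
    image_step_mm: float,
    first_image_position_mm: float,
    first_image_depth_m: float,
    last_image_depth_m: float,
    interval_m: float = CAL_INTERVAL_M,
    area_m2: float = CAL_AREA_M2,
) -> float:
    """Image width (mm) such that, in the continuous limit, a depth interval of
    ``interval_m`` exposes ``area_m2`` of observation area.

    Inverts ``area = (interval / depth_per_image) * step * width``.  Because
    image positions are discrete, any specific interval realises this only to
    within one image's area.
    """
    depth_per_image_m = (
        image_step_mm
        * (last_image_depth_m - first_image_depth_m)
        / (tube_length_mm - first_image_position_mm)
    )
    width_m = area_m2 * depth_per_image_m / (interval_m * image_step_mm / 1000.0)
    return width_m * 1000.0


@dataclass(frozen=True)
class TubeGeometry:
    """Geometry of one inclined minirhizotron tube.

    Parameters
    ----------
    tube_length_mm
        Distance along the tube to the deepest imaged point.
    image_step_mm
        Spacing between successive camera positions along the tube.
    first_image_position_mm
        Tube distance of the shallowest image.
    first_image_depth_m, last_image_depth_m
        Soil depth anchors at ``first_image_position_mm`` and
        ``tube_length_mm``; depth is linear in tube distance between them.
    nominal_angle_deg
        Informational slope of the tube; not used in any computation.
    image_width_mm
        Across-tube field of view.  If ``None``, derived so that a 0.25-m depth
        interval exposes 0.0125 m^2 of observation area (continuous limit).
    px_per_cm
        Pixel calibration for converting detected root length to cm.
    """

    tube_length_mm: float = 5500.0
    image_step_mm: float = 35.0
    first_image_position_mm: float = 0.0
    first_image_depth_m: float = 0.6
    last_image_depth_m: float = 3.0
    nominal_angle_deg: float = 24.0
    image_width_mm: float | None = None
    px_per_cm: float = 100.0

    def __post_init__(self) -> None:
        if not self.first_image_depth_m < self.last_image_depth_m:
            raise GeometryError(
                "first_image_depth_m must be shallower than last_image_depth_m "
                f"(got {self.first_image_depth_m} >= {self.last_image_depth_m})"
            )
        if self.image_step_mm <= 0:
            raise GeometryError(f"image_step_mm must be > 0 (got {self.image_step_mm})")
        if not self.first_image_position_mm < self.tube_length_mm:
            raise GeometryError(
                "first_image_position_mm must precede tube_length_mm "
                f"(got {self.first_image_position_mm} >= {self.tube_length_mm})"
            )
        if self.px_per_cm <= 0:
            raise GeometryError(f"px_per_cm must be > 0 (got {self.px_per_cm})")
        if self.image_width_mm is None:
            object.__setattr__(
                self,
                "image_width_mm",
                calibrate_image_width_mm(
                    self.tube_length_mm,
                    self.image_step_mm,
                    self.first_image_position_mm,
                    self.first_image_depth_m,
                    self.last_image_depth_m,
                ),
            )
        if self.image_width_mm <= 0:
            raise GeometryError(f"image_width_mm must be > 0 (got {self.image_width_mm})")

    # -- derived quantities -------------------------------------------------

    @property
    def depth_span_m(self) -> float:
        return self.last_image_depth_m - self.first_image_depth_m

    @property
    def depth_per_image_m(self) -> float:
        """Soil-depth increment between successive images."""
        return (
            self.image_step_mm
            * self.depth_span_m
            / (self.tube_length_mm - self.first_image_position_mm)
        )

    @property
    def n_images(self) -> int:
        span = self.tube_length_mm - self.first_image_position_mm
        return int(np.floor(span / self.image_step_mm + 1e-9)) + 1

    def image_positions_mm(self) -> np.ndarray:
        """Tube distances of all camera positions, shallow to deep."""
        return self.first_image_position_mm + self.image_step_mm * np.arange(self.n_images)

    def image_depths_m(self) -> np.ndarray:
        """Soil depths of all camera positions, strictly increasing."""
        return depth_at_position(self.image_positions_mm(), self)

    @property
    def per_image_area_m2(self) -> float:
        return self.image_step_mm * self.image_width_mm * 1e-6

    @property
    def per_image_area_cm2(self) -> float:
        return self.per_image_area_m2 * 1e4


def depth_at_position(position_mm, geom: TubeGeometry):
    """Soil depth (m) at a tube distance, by linear interpolation between the
    geometry's two depth anchors.  Accepts scalars or arrays.

    Raises
    ------
    PositionOutOfRangeError
        If any position lies outside
        ``[first_image_position_mm, tube_length_mm]``.
    """
    pos = np.asarray(position_mm, dtype=float)
    lo, hi = geom.first_image_position_mm, geom.tube_length_mm
    bad = (pos < lo - 1e-9) | (pos > hi + 1e-9)
    if np.any(bad):
        offending = np.atleast_1d(pos)[np.atleast_1d(bad)]
        raise PositionOutOfRangeError(
            f"position(s) {offending.tolist()} mm outside imaged tube range [{lo}, {hi}] mm"
        )
    frac = (pos - lo) / (hi - lo)
    depth = geom.first_image_depth_m + frac * geom.depth_span_m
    return float(depth) if np.isscalar(position_mm) else depth


def position_at_depth(depth_m, geom: TubeGeometry):
    """Inverse of :func:`depth_at_position` (m -> mm along tube)."""
    dep = np.asarray(depth_m, dtype=float)
    lo, hi = geom.first_image_depth_m, geom.last_image_depth_m
    bad = (dep < lo - 1e-9) | (dep > hi + 1e-9)
    if np.any(bad):
        offending = np.atleast_1d(dep)[np.atleast_1d(bad)]
        raise PositionOutOfRangeError(
            f"depth(s) {offending.tolist()} m outside imaged depth range [{lo}, {hi}] m"
        )
    frac = (dep - lo) / geom.depth_span_m
    pos = geom.first_image_position_mm + frac * (geom.tube_length_mm - geom.first_image_position_mm)
    return float(pos) if np.isscalar(depth_m) else pos


def pixels_to_cm(length_px, geom: TubeGeometry):
    """Convert detected root length from pixels to cm via ``px_per_cm``."""
    px = np.asarray(length_px, dtype=float)
    if np.any(px < 0):
        raise GeometryError("negative pixel count")
    out = px / geom.px_per_cm
    return float(out) if np.isscalar(length_px) else out


def observation_area_m2(depth_lo: float, depth_hi: float, geom: TubeGeometry) -> float:
    """Soil observation area (m^2) for the half-open depth interval
    ``[depth_lo, depth_hi)``: image count in the interval x step x width.

    Both endpoints must lie within the imaged depth range.  An interval that
    contains no image position has zero area.
    """
    if not depth_lo < depth_hi:
        raise GeometryError(f"inverted depth interval [{depth_lo}, {depth_hi})")
    lo_ok = geom.first_image_depth_m - 1e-9
    hi_ok = geom.last_image_depth_m + 1e-9
    if depth_lo < lo_ok or depth_hi > hi_ok:
        raise PositionOutOfRangeError(
            f"interval [{depth_lo}, {depth_hi}) m outside imaged depth range "
            f"[{geom.first_image_depth_m}, {geom.last_image_depth_m}] m"
        )
    depths = geom.image_depths_m()
    n = int(np.count_nonzero((depths >= depth_lo) & (depths < depth_hi)))
    return n * geom.per_image_area_m2


def _count_images_in(depth_lo: float, depth_hi: float, geom: TubeGeometry) -> int:
    """Image count in ``[depth_lo, depth_hi)`` without range checks (internal,
    used for binning where outer bin edges may overhang the imaged range)."""
    depths = geom.image_depths_m()
    return int(np.count_nonzero((depths >= depth_lo) & (depths < depth_hi)))


def with_px_per_cm(geom: TubeGeometry, px_per_cm: float) -> TubeGeometry:
    return replace(geom, px_per_cm=px_per_cm)
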