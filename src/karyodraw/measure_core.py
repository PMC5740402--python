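"""Geometry of traced chromosomes.

A chromosome is measured by tracing a polyline path along its axis on a
metaphase photograph.  Everything downstream (arm lengths, centromere
index, landmark positions) is expressed in *arc length* along that path.
Fragmented chromosomes are handled by concatenating the arc-length spaces
of their fragments; the spatial gap between fragments contributes zero
length, since the bridging distance is an artifact of chromosome spreading,
not chromatin.

Coordinates are continuous pixel units, origin at the top-left of the
image, y increasing downward (standard raster convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "MeasurementError",
    "Polyline",
    "ScaleCalibration",
    "Landmark",
    "Segment",
    "RelativeLandmark",
    "ChromosomeMeasurement",
    "Metaphase",
    "polyline_length",
    "calibrate",
    "join_fragments",
    "place_centromere",
    "landmark_relative",
]


class MeasurementError(ValueError):
    """Raised for geometrically invalid measurements."""


@dataclass(frozen=True)
class Polyline:
    """An ordered open polygonal chain of image points (pixels)."""

    vertices: tuple[tuple[float, float], ...]

    def __init__(self, vertices: Sequence[Sequence[float]]):
        pts = tuple((float(x), float(y)) for x, y in vertices)
        if len(pts) < 1:
            raise MeasurementError("polyline needs at least one vertex")
        for x, y in pts:
            if not (math.isfinite(x) and math.isfinite(y)):
                raise MeasurementError(f"non-finite vertex ({x}, {y})")
        object.__setattr__(self, "vertices", pts)

    def __len__(self) -> int:
        return len(self.vertices)

    @property
    def length(self) -> float:
        return polyline_length(self)

    def reversed(self) -> "Polyline":
        return Polyline(self.vertices[::-1])

    def point_at(self, arc: float) -> tuple[float, float]:
        """Point at a given arc length from the start (clamped to ends)."""
        v = np.asarray(self.vertices, dtype=float)
        if len(v) == 1:
            return tuple(v[0])
        seg = np.linalg.norm(np.diff(v, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        arc = min(max(arc, 0.0), cum[-1])
        i = int(np.searchsorted(cum, arc, side="right")) - 1
        i = min(i, len(seg) - 1)
        t = 0.0 if seg[i] == 0 else (arc - cum[i]) / seg[i]
        p = v[i] + t * (v[i + 1] - v[i])
        return (float(p[0]), float(p[1]))


def polyline_length(p: Polyline) -> float:
    """Arc length: the sum of Euclidean segment lengths, in pixels."""
    v = np.asarray(p.vertices, dtype=float)
    if len(v) < 2:
        return 0.0
    return float(np.linalg.norm(np.diff(v, axis=0), axis=1).sum())


@dataclass(frozen=True)
class ScaleCalibration:
    """Pixel→micrometre calibration from a traced scale bar."""

    bar_pixels: float
    bar_physical: float  # µm

    def __post_init__(self):
        if not (self.bar_pixels > 0 and self.bar_physical > 0):
            raise MeasurementError("scale bar pixel and physical lengths must be > 0")

    @property
    def pixels_per_micron(self) -> float:
        return self.bar_pixels / self.bar_physical

    def to_um(self, px: float) -> float:
        return px / self.pixels_per_micron


def calibrate(bar: Polyline, known_um: float) -> ScaleCalibration:
    """Build a calibration from a traced scale bar of known physical length."""
    px = polyline_length(bar)
    if px <= 0:
        raise MeasurementError("scale bar trace has zero length")
    if not known_um > 0:
        raise MeasurementError("scale bar physical length must be > 0")
    return ScaleCalibration(bar_pixels=px, bar_physical=float(known_um))


@dataclass(frozen=True)
class Landmark:
    """A point signal, band or satellite at an arc interval on the path.

    ``arc_start == arc_end`` for point signals; bands and satellites span a
    positive interval.  Arcs are pixels along the concatenated path from the
    path start.
    """

    name: str
    kind: str  # signal_point | band | satellite
    color: str
    arc_start: float
    arc_end: float

    KINDS = ("signal_point", "band", "satellite")

    def __post_init__(self):
        if self.kind not in self.KINDS:
            raise MeasurementError(f"unknown landmark kind {self.kind!r}")
        if not (0 <= self.arc_start <= self.arc_end):
            raise MeasurementError(
                f"landmark {self.name!r}: need 0 <= arc_start <= arc_end"
            )
        if self.kind == "signal_point" and self.arc_start != self.arc_end:
            raise MeasurementError(f"point signal {self.name!r} must have zero width")


@dataclass(frozen=True)
class Segment:
    """A colored arc interval painting part of the chromosome body (GISH)."""

    color: str
    arc_start: float
    arc_end: float

    def __post_init__(self):
        if not (0 <= self.arc_start < self.arc_end):
            raise MeasurementError("segment needs 0 <= arc_start < arc_end")


@dataclass(frozen=True)
class RelativeLandmark:
    """A landmark re-expressed as fractions of total chromosome length.

    Fractions are measured from the short-arm telomere after orientation
    normalization.  ``size`` is the landmark extent in the measurement unit
    (µm when calibrated, else px).
    """

    name: str
    kind: str
    color: str
    arm: str  # p | q | spanning
    frac_start: float
    frac_end: float
    size: float
    unit: str


@dataclass
class ChromosomeMeasurement:
    """One traced chromosome: fragments, centromere, landmarks, segments."""

    name: str
    fragments: list[Polyline]
    centromere_arc: Optional[float] = None
    landmarks: list[Landmark] = field(default_factory=list)
    segments: list[Segment] = field(default_factory=list)
    color: Optional[str] = None

    def __post_init__(self):
        if not self.fragments:
            raise MeasurementError(f"chromosome {self.name!r} has no fragments")

    @property
    def total_length(self) -> float:
        return sum(polyline_length(f) for f in self.fragments)

    @property
    def short_arm(self) -> Optional[float]:
        return self.centromere_arc

    @property
    def long_arm(self) -> Optional[float]:
        if self.centromere_arc is None:
            return None
        return self.total_length - self.centromere_arc


@dataclass
class Metaphase:
    """All measurements from one metaphase plate, plus calibration."""

    id: str
    measurements: list[ChromosomeMeasurement]
    calibration: Optional[ScaleCalibration] = None
    image_ref: Optional[str] = None

    def __post_init__(self):
        names = [m.name for m in self.measurements]
        if len(names) != len(set(names)):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise MeasurementError(f"duplicate measurement names in metaphase: {dup}")

    @property
    def unit(self) -> str:
        return "um" if self.calibration is not None else "px"


def join_fragments(fragments: Sequence[Polyline]) -> tuple[Polyline, float]:
    """Concatenate fragment arc-length spaces into one virtual path.

    Returns the joined polyline (vertices concatenated in order; the jump
    between consecutive fragments is *not* counted as length) and the total
    arc length.  A local arc position ``a`` on fragment ``i`` maps to global
    arc ``sum(length of fragments < i) + a``.
    """
    frags = list(fragments)
    if not frags:
        raise MeasurementError("cannot join an empty fragment list")
    total = sum(polyline_length(f) for f in frags)
    verts: list[tuple[float, float]] = []
    for f in frags:
        verts.extend(f.vertices)
    return Polyline(verts), total


def _reverse_measurement(m: ChromosomeMeasurement) -> ChromosomeMeasurement:
    """Reverse the path direction; all arcs map through arc' = L − arc."""
    L = m.total_length
    frags = [f.reversed() for f in reversed(m.fragments)]
    lms = [
        replace(lm, arc_start=L - lm.arc_end, arc_end=L - lm.arc_start)
        for lm in m.landmarks
    ]
    segs = [
        replace(s, arc_start=L - s.arc_end, arc_end=L - s.arc_start)
        for s in m.segments
    ]
    cen = None if m.centromere_arc is None else L - m.centromere_arc
    return ChromosomeMeasurement(
        name=m.name,
        fragments=frags,
        centromere_arc=cen,
        landmarks=lms,
        segments=segs,
        color=m.color,
    )


def place_centromere(m: ChromosomeMeasurement, arc: float) -> ChromosomeMeasurement:
    """Set the centromere and normalize orientation so the short arm is first.

    If the marked arc lies past the midpoint the whole path (centromere,
    landmarks, segments) is reflected through arc' = L − arc, so that
    afterwards Ls = centromere_arc ≤ L/2 ≤ Ll.  An exact metacentric
    (arc = L/2) is left unflipped.  Idempotent: re-placing the resulting
    centromere arc is a no-op.
    """
    L = m.total_length
    if not (0 < arc < L):
        raise MeasurementError(
            f"centromere arc {arc} outside the open interval (0, {L})"
        )
    out = ChromosomeMeasurement(
        name=m.name,
        fragments=list(m.fragments),
        centromere_arc=float(arc),
        landmarks=list(m.landmarks),
        segments=list(m.segments),
        color=m.color,
    )
    if arc > L / 2:
        out = _reverse_measurement(out)
    return out


def landmark_relative(
    m: ChromosomeMeasurement,
    lm: Landmark,
    calibration: Optional[ScaleCalibration] = None,
) -> RelativeLandmark:
    """Express a landmark as length fractions and assign it to an arm.

    The measurement must already be oriented (short arm first).  Arm rule:
    a landmark entirely on one side of the centromere gets that arm ("p"
    before, "q" after); one straddling it is "spanning".  A zero-width point
    exactly at the centromere is assigned to "p" (deterministic tie-break);
    intervals touching the centromere at one end go to the arm holding the
    rest of the interval.
    """
    L = m.total_length
    if not (0 <= lm.arc_start and lm.arc_end <= L):
        raise MeasurementError(
            f"landmark {lm.name!r} interval [{lm.arc_start}, {lm.arc_end}] "
            f"outside path [0, {L}]"
        )
    cen = m.centromere_arc
    if cen is None:
        arm = "p"  # no centromere: whole body treated as one arm
    elif lm.arc_start == lm.arc_end:
        arm = "p" if lm.arc_start <= cen else "q"
    elif lm.arc_end <= cen:
        arm = "p"
    elif lm.arc_start >= cen:
        arm = "q"
    else:
        arm = "spanning"
    size_px = lm.arc_end - lm.arc_start
    if calibration is not None:
        size, unit = calibration.to_um(size_px), "um"
    else:
        size, unit = size_px, "px"
    return RelativeLandmark(
        name=lm.name,
        kind=lm.kind,
        color=lm.color,
        arm=arm,
        frac_start=lm.arc_start / L,
        frac_end=lm.arc_end / L,
        size=size,
        unit=unit,
    )
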