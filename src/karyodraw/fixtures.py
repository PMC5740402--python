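"""Synthetic metaphase generator with known ground truth.

A generated metaphase mimics what a cytogeneticist would trace by hand on
a photograph: each chromosome is a smooth polyline of a prescribed arc
length placed at a random, non-overlapping pose, with a centromere mark,
optional point/band landmarks, and a traced scale bar for calibration.
Because the generator knows the exact lengths, centromere indices and
landmark fractions it drew, the full measurement pipeline can be checked
against that ground truth — exactly at zero noise, statistically when
homologs and metaphases are jittered.

Species presets reproduce the chromosome counts and landmark topology of
well-studied validation karyotypes (hemp, a wild rose, two Allium species
and a Festuca × Lolium recombinant hybrid); their numeric lengths are
plausible synthetic values, not published measurements.

All randomness flows from a single integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .measure_core import (
    ChromosomeMeasurement,
    Landmark,
    MeasurementError,
    Metaphase,
    Polyline,
    ScaleCalibration,
    Segment,
    place_centromere,
)

__all__ = [
    "GroundTruth",
    "ChromosomeTruth",
    "make_random_metaphase",
    "make_species_fixture",
    "rasterize_metaphase",
    "SPECIES_PRESETS",
]

PIXELS_PER_MICRON = 12.0  # emulated image magnification
SCALE_BAR_UM = 10.0


@dataclass
class ChromosomeTruth:
    """Exact generated parameters for one chromosome (µm, normalized)."""

    name: str
    L: float
    Ls: float
    Ll: float
    CI: float
    landmark_fracs: dict[str, tuple[float, float]] = field(default_factory=dict)


@dataclass
class GroundTruth:
    """Per-chromosome exact values plus the nominal per-group parameters."""

    chromosomes: dict[str, ChromosomeTruth]
    nominal_L: dict[str, float]   # homolog-group name -> nominal length (µm)
    nominal_CI: dict[str, float]  # homolog-group name -> nominal CI (%)
    noise_sd: float
    seed: int


def _smooth_polyline(
    rng: np.random.Generator,
    length_px: float,
    origin: tuple[float, float],
    n_segments: int = 24,
    wiggle: float = 0.12,
) -> Polyline:
    """A gently curving path of *exactly* the requested arc length.

    A unit-step random walk with small heading increments is scaled
    uniformly (scaling scales arc length linearly, so the final length is
    exact to float precision) and centered by bounding box on ``origin`` —
    its spatial extent never exceeds its arc length, which keeps grid-placed
    chromosomes from touching.
    """
    heading = rng.uniform(0, 2 * math.pi)
    pts = [(0.0, 0.0)]
    x = y = 0.0
    for _ in range(n_segments):
        heading += rng.normal(0.0, wiggle)
        x += math.cos(heading)
        y += math.sin(heading)
        pts.append((x, y))
    raw = Polyline(pts)
    s = length_px / raw.length
    scaled = [(px * s, py * s) for px, py in pts]
    xs = [p[0] for p in scaled]
    ys = [p[1] for p in scaled]
    cx, cy = (min(xs) + max(xs)) / 2, (min(ys) + max(ys)) / 2
    ox, oy = origin
    return Polyline([(ox + px - cx, oy + py - cy) for px, py in scaled])


def _grid_origin(rng: np.random.Generator, index: int, cols: int, cell: float) -> tuple[float, float]:
    r, c = divmod(index, cols)
    jitter = cell * 0.08
    return (
        cell * (c + 0.5) + rng.uniform(-jitter, jitter),
        cell * (r + 0.5) + rng.uniform(-jitter, jitter),
    )


def make_random_metaphase(
    n_chromosomes: int,
    length_range_um: tuple[float, float] = (4.0, 14.0),
    ci_range: tuple[float, float] = (25.0, 50.0),
    ploidy: int = 2,
    noise_sd: float = 0.0,
    seed: int = 0,
    with_landmarks: bool = True,
    metaphase_id: Optional[str] = None,
    random_orientation: bool = True,
    split_fragments: bool = False,
    base_seed: Optional[int] = None,
) -> tuple[Metaphase, GroundTruth]:
    """Generate a random metaphase of ``n_chromosomes`` homolog groups.

    Each group has a nominal length (uniform in ``length_range_um``, µm) and
    nominal centromere index (uniform in ``ci_range``, percent); every one
    of its ``ploidy`` copies jitters both multiplicatively by
    ``1 + N(0, noise_sd)`` (CI clipped to (5, 50)).  Copies of group ``g``
    are named ``"g"`` at ploidy 1 and ``"ga"``, ``"gb"``, … otherwise.
    Landmark fractions are shared within a group and never jittered.

    ``base_seed`` fixes the *nominal* karyotype (group lengths, CIs and
    landmark layout) independently of ``seed``, so several metaphases of
    the same nominal complement can be drawn with different noise — the
    emulation of re-measuring one individual across metaphase plates.

    Returns the metaphase plus the exact ground truth actually drawn.
    """
    if n_chromosomes < 1:
        raise MeasurementError("need at least one chromosome group")
    lo, hi = length_range_um
    if not (0 < lo <= hi):
        raise MeasurementError(f"invalid length range {length_range_um}")
    clo, chi = ci_range
    if not (0 < clo <= chi <= 50):
        raise MeasurementError(f"invalid CI range {ci_range} (percent, <= 50)")
    if ploidy < 1:
        raise MeasurementError("ploidy must be >= 1")
    rng = np.random.default_rng(seed)
    rng_nom = np.random.default_rng(seed if base_seed is None else base_seed)

    ppm = PIXELS_PER_MICRON
    # nominal group parameters, sorted longest first
    base_L = np.sort(rng_nom.uniform(lo, hi, size=n_chromosomes))[::-1]
    base_CI = rng_nom.uniform(clo, chi, size=n_chromosomes)

    group_landmarks: list[list[tuple[str, str, str, float, float]]] = []
    for g in range(n_chromosomes):
        lms = []
        if with_landmarks:
            if rng_nom.random() < 0.6:
                frac = float(rng_nom.uniform(0.05, 0.95))
                lms.append((f"sig{g + 1}", "signal_point", "#d62728", frac, frac))
            if rng_nom.random() < 0.4:
                a = float(rng_nom.uniform(0.05, 0.75))
                b = a + float(rng_nom.uniform(0.05, 0.2))
                lms.append((f"band{g + 1}", "band", "#2ca02c", a, min(b, 0.98)))
        group_landmarks.append(lms)

    n_total = n_chromosomes * ploidy
    cols = math.ceil(math.sqrt(n_total))
    cell = hi * ppm * 1.3 + 40.0

    measurements: list[ChromosomeMeasurement] = []
    truth: dict[str, ChromosomeTruth] = {}
    for g in range(n_chromosomes):
        for c in range(ploidy):
            name = (str(g + 1) if ploidy == 1
                    else f"{g + 1}{chr(ord('a') + c)}")
            L_um = float(base_L[g] * (1.0 + (rng.normal(0, noise_sd) if noise_sd else 0.0)))
            CI = float(np.clip(base_CI[g] * (1.0 + (rng.normal(0, noise_sd) if noise_sd else 0.0)), 5.0, 50.0))
            L_px = L_um * ppm
            origin = _grid_origin(rng, g * ploidy + c, cols, cell)
            path = _smooth_polyline(rng, L_px, origin)
            cen_frac = CI / 100.0

            flipped = bool(random_orientation and rng.random() < 0.5)
            if cen_frac >= 0.5:
                flipped = False  # exact metacentric: normalizer would not flip back
            lm_fracs: dict[str, tuple[float, float]] = {}
            landmarks = []
            for lname, kind, color, fa, fb in group_landmarks[g]:
                lm_fracs[lname] = (fa, fb)
                if flipped:
                    a_px, b_px = (1 - fb) * L_px, (1 - fa) * L_px
                else:
                    a_px, b_px = fa * L_px, fb * L_px
                landmarks.append(Landmark(lname, kind, color, a_px, b_px))
            cen_arc = ((1 - cen_frac) if flipped else cen_frac) * L_px

            if split_fragments and len(path) >= 6:
                half = len(path.vertices) // 2
                off = cell * 0.15
                frags = [
                    Polyline(path.vertices[: half + 1]),
                    Polyline([(x + off, y + off) for x, y in path.vertices[half:]]),
                ]
                # splitting duplicates one vertex; rebuild at exact length
                scale = L_px / sum(f.length for f in frags)
                frags = [Polyline([(x * scale, y * scale) for x, y in f.vertices])
                         for f in frags]
            else:
                frags = [path]

            m = ChromosomeMeasurement(
                name=name, fragments=frags, landmarks=landmarks)
            m = place_centromere(m, cen_arc)
            measurements.append(m)
            truth[name] = ChromosomeTruth(
                name=name, L=L_um, Ls=L_um * cen_frac,
                Ll=L_um * (1 - cen_frac), CI=CI, landmark_fracs=lm_fracs,
            )

    mp = Metaphase(
        id=metaphase_id or f"synthetic-{seed}",
        measurements=measurements,
        calibration=ScaleCalibration(
            bar_pixels=SCALE_BAR_UM * ppm, bar_physical=SCALE_BAR_UM),
    )
    gt = GroundTruth(
        chromosomes=truth,
        nominal_L={str(g + 1): float(base_L[g]) for g in range(n_chromosomes)},
        nominal_CI={str(g + 1): float(base_CI[g]) for g in range(n_chromosomes)},
        noise_sd=noise_sd,
        seed=seed,
    )
    return mp, gt


# ---------------------------------------------------------------------------
# species presets

LOLIUM_COLOR = "#2ca02c"   # probe (Dig, green pseudocolor)
FESTUCA_COLOR = "#3b5bd6"  # block DNA, DAPI counterstain (blue)

SPECIES_PRESETS = (
    "cannabis_sativa",
    "rosa_wichurana",
    "allium_cepa",
    "allium_fistulosum",
    "festulolium_f2",
)


def _paired_lengths(n_pairs: int, longest: float, shortest: float) -> list[float]:
    return list(np.linspace(longest, shortest, n_pairs))


def _preset_metaphase(
    taxon: str,
    pair_lengths: list[float],
    pair_cis: list[float],
    seed: int,
) -> Metaphase:
    rng = np.random.default_rng(seed)
    ppm = PIXELS_PER_MICRON
    n_pairs = len(pair_lengths)
    cols = math.ceil(math.sqrt(2 * n_pairs))
    cell = max(pair_lengths) * ppm * 1.3 + 40.0
    measurements = []
    for g in range(n_pairs):
        for c in range(2):
            name = f"{g + 1}{'ab'[c]}"
            L_px = pair_lengths[g] * ppm
            origin = _grid_origin(rng, 2 * g + c, cols, cell)
            path = _smooth_polyline(rng, L_px, origin)
            m = ChromosomeMeasurement(name=name, fragments=[path])
            m = place_centromere(m, pair_cis[g] / 100.0 * L_px)
            measurements.append(m)
    return Metaphase(
        id=f"{taxon}-demo",
        measurements=measurements,
        calibration=ScaleCalibration(SCALE_BAR_UM * ppm, SCALE_BAR_UM),
    )


def make_species_fixture(preset: str, seed: int = 0) -> Metaphase:
    """A demonstration metaphase for one of the validation karyotypes.

    Chromosome counts and landmark topology follow the published
    complements; the numeric lengths are synthetic.

    * ``cannabis_sativa`` — 2n = 2x = 20; the sex-chromosome pair is
      flagged black and a NOR-bearing pair green.
    * ``rosa_wichurana`` — 2n = 2x = 14; red satellites on the two
      shortest chromosomes (13 and 14 in length order).
    * ``allium_cepa`` — 2n = 2x = 16, unmarked.
    * ``allium_fistulosum`` — 2n = 2x = 16 with 5S rDNA point signals and
      HAT58 repeat bands.
    * ``festulolium_f2`` — 2n = 34 recombinant hybrid; two-color genome
      painting with recombination breakpoints on several chromosomes.
    """
    if preset not in SPECIES_PRESETS:
        raise MeasurementError(
            f"unknown species preset {preset!r}; choose from {SPECIES_PRESETS}")
    rng = np.random.default_rng(seed + 101)

    if preset == "cannabis_sativa":
        lengths = _paired_lengths(10, 6.4, 3.2)
        cis = [float(x) for x in rng.uniform(32, 48, 10)]
        mp = _preset_metaphase(preset, lengths, cis, seed)
        # pair 10 (shortest): heteromorphic sex pair, flagged black
        # pair 6: NOR-bearing, flagged green
        for m in mp.measurements:
            if m.name in ("10a", "10b"):
                m.color = "#000000"
            if m.name in ("6a", "6b"):
                m.color = "#2ca02c"
        return mp

    if preset == "rosa_wichurana":
        lengths = _paired_lengths(7, 5.8, 2.9)
        cis = [float(x) for x in rng.uniform(34, 48, 7)]
        mp = _preset_metaphase(preset, lengths, cis, seed)
        for m in mp.measurements:
            if m.name in ("7a", "7b"):  # shortest pair -> chromosomes 13 & 14
                L = m.total_length
                m.landmarks.append(
                    Landmark("SAT", "satellite", "#d62728", 0.82 * L, 0.97 * L))
        return mp

    if preset == "allium_cepa":
        lengths = _paired_lengths(8, 15.5, 9.0)
        cis = [float(x) for x in rng.uniform(36, 49, 8)]
        return _preset_metaphase(preset, lengths, cis, seed)

    if preset == "allium_fistulosum":
        lengths = _paired_lengths(8, 15.0, 8.6)
        cis = [float(x) for x in rng.uniform(36, 49, 8)]
        mp = _preset_metaphase(preset, lengths, cis, seed)
        for m in mp.measurements:
            L = m.total_length
            if m.name in ("6a", "6b"):  # 5S rDNA locus
                m.landmarks.append(
                    Landmark("5S rDNA", "signal_point", "#d62728",
                             0.18 * L, 0.18 * L))
            if m.name in ("1a", "1b", "4a", "4b"):  # subtelomeric HAT58 repeat
                m.landmarks.append(
                    Landmark("HAT58", "band", "#2ca02c", 0.88 * L, 0.97 * L))
        return mp

    # festulolium_f2: 2n = 34, whole-genome two-color painting
    n = 34
    rng2 = np.random.default_rng(seed + 202)
    lengths = list(np.linspace(11.5, 5.0, n))
    cis = [float(x) for x in rng2.uniform(30, 48, n)]
    ppm = PIXELS_PER_MICRON
    cols = math.ceil(math.sqrt(n))
    cell = max(lengths) * ppm * 1.3 + 40.0
    # chromosomes 5, 12, 22 and 29 (length order) carry recombination points
    recombinant = {5: 1, 12: 2, 22: 1, 29: 1}  # index -> number of breakpoints
    measurements = []
    for i in range(n):
        name = str(i + 1)
        L_px = lengths[i] * ppm
        origin = _grid_origin(rng2, i, cols, cell)
        path = _smooth_polyline(rng2, L_px, origin)
        base = LOLIUM_COLOR if i % 2 == 0 else FESTUCA_COLOR
        other = FESTUCA_COLOR if base == LOLIUM_COLOR else LOLIUM_COLOR
        nb = recombinant.get(i + 1, 0)
        if nb == 0:
            segments = [Segment(base, 0.0, L_px)]
        else:
            cuts = sorted(float(x) for x in rng2.uniform(0.2, 0.8, nb))
            bounds = [0.0] + [c * L_px for c in cuts] + [L_px]
            segments = [
                Segment(base if j % 2 == 0 else other, bounds[j], bounds[j + 1])
                for j in range(len(bounds) - 1)
            ]
        m = ChromosomeMeasurement(name=name, fragments=[path], segments=segments)
        m = place_centromere(m, cis[i] / 100.0 * L_px)
        measurements.append(m)
    return Metaphase(
        id="festulolium_f2-demo",
        measurements=measurements,
        calibration=ScaleCalibration(SCALE_BAR_UM * ppm, SCALE_BAR_UM),
    )


# ---------------------------------------------------------------------------
# demo rasterizer

STROKE_COLOR = (205, 205, 215)
BAR_COLOR = (255, 230, 40)


def rasterize_metaphase(mp: Metaphase, stroke: int = 5, margin: int = 30):
    """Draw the traced paths as thick strokes on a dark background (PIL image).

    Purely illustrative: the package never measures pixels from this image.
    The scale bar, when calibrated, is drawn in a distinct color at the
    bottom left.
    """
    from PIL import Image, ImageDraw

    xs, ys = [], []
    for m in mp.measurements:
        for f in m.fragments:
            for x, y in f.vertices:
                xs.append(x)
                ys.append(y)
    x0, y0 = min(xs) - margin, min(ys) - margin
    w = int(math.ceil(max(xs) - x0 + margin))
    h = int(math.ceil(max(ys) - y0 + margin + 30))
    img = Image.new("RGB", (w, h), (18, 18, 30))
    draw = ImageDraw.Draw(img)
    for m in mp.measurements:
        for f in m.fragments:
            pts = [(x - x0, y - y0) for x, y in f.vertices]
            if len(pts) == 1:
                x, y = pts[0]
                draw.ellipse([x - stroke, y - stroke, x + stroke, y + stroke],
                             fill=STROKE_COLOR)
            else:
                draw.line(pts, fill=STROKE_COLOR, width=stroke, joint="curve")
    if mp.calibration is not None:
        bar = mp.calibration.bar_pixels
        draw.line([(10, h - 12), (10 + bar, h - 12)], fill=BAR_COLOR, width=4)
    return img
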