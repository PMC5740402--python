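"""Per-chromosome and per-karyotype statistics.

Conventions used throughout:

* centromere index CI = 100 · Ls / L (short-arm length as a percentage of
  total chromosome length), so CI ≤ 50 after orientation normalization;
* arm ratio r = Ll / Ls (long over short, ≥ 1), undefined for telocentrics
  (Ls = 0);
* relative length RL = 100 · L_i / Σ_j L_j over the whole measured
  complement of the metaphase, so ΣRL = 100 (users comparing against
  haploid-set conventions can multiply by the ploidy);
* chromosomes are numbered by decreasing length, starting with the largest.

Standard deviations are sample SDs (n − 1 denominator); a group of one is
reported with SD 0 and flagged via ``n``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .measure_core import (
    ChromosomeMeasurement,
    MeasurementError,
    Metaphase,
    RelativeLandmark,
    landmark_relative,
    place_centromere,
)

__all__ = [
    "KaryotypeRecord",
    "Karyotype",
    "AveragedRecord",
    "AveragedKaryotype",
    "centromere_index",
    "arm_ratio",
    "build_karyotype",
    "reduce_karyotype",
    "average_karyotypes",
]


def centromere_index(Ls: float, L: float) -> float:
    """Centromere index: short arm length × 100 / total chromosome length."""
    if L <= 0:
        raise MeasurementError("chromosome length must be > 0")
    if not (0 <= Ls <= L):
        raise MeasurementError("short arm must lie within [0, L]")
    return 100.0 * Ls / L


def arm_ratio(Ls: float, Ll: float) -> Optional[float]:
    """Arm ratio Ll/Ls; None (undefined) for a telocentric with Ls = 0."""
    if Ls < 0 or Ll < 0:
        raise MeasurementError("arm lengths must be non-negative")
    if Ls == 0:
        return None
    return Ll / Ls


@dataclass
class FracSegment:
    """A colored body interval in length fractions (GISH painting)."""

    color: str
    frac_start: float
    frac_end: float


@dataclass
class KaryotypeRecord:
    """Derived statistics for one measured chromosome."""

    name: str
    L: float
    Ls: Optional[float]
    Ll: Optional[float]
    CI: Optional[float]
    r: Optional[float]
    RL: float
    unit: str
    landmarks: list[RelativeLandmark] = field(default_factory=list)
    segments: list[FracSegment] = field(default_factory=list)
    color: Optional[str] = None

    @property
    def holocentric(self) -> bool:
        return self.Ls is None


@dataclass
class Karyotype:
    """An ordered chromosome complement from one metaphase."""

    records: list[KaryotypeRecord]
    source: str
    unit: str

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class AveragedRecord:
    """Mean ± SD statistics for one homolog group or named chromosome."""

    name: str
    n: int
    mean_L: float
    sd_L: float
    mean_Ls: Optional[float]
    sd_Ls: Optional[float]
    mean_Ll: Optional[float]
    sd_Ll: Optional[float]
    mean_CI: Optional[float]
    sd_CI: Optional[float]
    unit: str
    landmarks: list[RelativeLandmark] = field(default_factory=list)
    segments: list[FracSegment] = field(default_factory=list)
    color: Optional[str] = None


@dataclass
class AveragedKaryotype:
    """Averaged complement, either across homologs or across metaphases."""

    records: list[AveragedRecord]
    source: str
    unit: str

    def __len__(self) -> int:
        return len(self.records)


def _record_sort_key(r: KaryotypeRecord):
    # descending L, ties by descending CI (None sorts last), then name
    ci = r.CI if r.CI is not None else -1.0
    return (-r.L, -ci, r.name)


def build_karyotype(
    mp: Metaphase, keep_names: bool = False, force_px: bool = False
) -> Karyotype:
    """Compute ordered per-chromosome statistics for one metaphase.

    Lengths are calibrated to µm when the metaphase carries a scale
    calibration (unless ``force_px``).  Records are sorted by decreasing
    length and renamed 1..N in that order; ``keep_names`` preserves the
    measurement names instead.
    """
    if not mp.measurements:
        raise MeasurementError(f"metaphase {mp.id!r} has no measurements")
    cal = None if force_px else mp.calibration
    unit = "um" if cal is not None else "px"
    scale = 1.0 / cal.pixels_per_micron if cal is not None else 1.0
    total = sum(m.total_length for m in mp.measurements) * scale

    records = []
    for m in mp.measurements:
        if m.centromere_arc is not None:
            # normalize orientation (short arm first) regardless of how the
            # path was traced
            m = place_centromere(m, m.centromere_arc)
        L_px = m.total_length
        L = L_px * scale
        if m.centromere_arc is not None:
            Ls = m.centromere_arc * scale
            Ll = L - Ls
            CI = centromere_index(Ls, L)
            r = arm_ratio(Ls, Ll)
        else:
            Ls = Ll = CI = r = None
        lms = [landmark_relative(m, lm, cal) for lm in m.landmarks]
        segs = [
            FracSegment(s.color, s.arc_start / L_px, s.arc_end / L_px)
            for s in m.segments
        ]
        records.append(
            KaryotypeRecord(
                name=m.name, L=L, Ls=Ls, Ll=Ll, CI=CI, r=r,
                RL=100.0 * L / total, unit=unit,
                landmarks=lms, segments=segs, color=m.color,
            )
        )
    records.sort(key=_record_sort_key)
    if not keep_names:
        for i, rec in enumerate(records, start=1):
            rec.name = str(i)
    return Karyotype(records=records, source=mp.id, unit=unit)


def _mean_sd(values: Sequence[Optional[float]]) -> tuple[Optional[float], Optional[float]]:
    vals = [v for v in values if v is not None]
    if not vals:
        return None, None
    mean = float(np.mean(vals))
    sd = 0.0 if len(vals) == 1 else float(np.std(vals, ddof=1))
    return mean, sd


def _merge_group(name: str, recs: list[KaryotypeRecord], unit: str) -> AveragedRecord:
    mean_L, sd_L = _mean_sd([r.L for r in recs])
    mean_Ls, sd_Ls = _mean_sd([r.Ls for r in recs])
    mean_Ll, sd_Ll = _mean_sd([r.Ll for r in recs])
    mean_CI, sd_CI = _mean_sd([r.CI for r in recs])
    # landmarks/segments: representative copy from the longest member
    rep = max(recs, key=lambda r: (len(r.landmarks) + len(r.segments), r.L))
    return AveragedRecord(
        name=name, n=len(recs),
        mean_L=mean_L, sd_L=sd_L,
        mean_Ls=mean_Ls, sd_Ls=sd_Ls,
        mean_Ll=mean_Ll, sd_Ll=sd_Ll,
        mean_CI=mean_CI, sd_CI=sd_CI,
        unit=unit,
        landmarks=list(rep.landmarks), segments=list(rep.segments),
        color=rep.color,
    )


def reduce_karyotype(k: Karyotype, ploidy: int) -> AveragedKaryotype:
    """Merge homologs by length order to obtain a monoploid karyotype.

    Records are sorted by decreasing length and consecutive groups of
    ``ploidy`` are merged; groups are numbered 1..N/ploidy.  Homolog
    grouping is purely positional (by length rank), so wildly unequal
    homologs can be misgrouped — the caller is responsible for a sensible
    complement.
    """
    if ploidy < 1:
        raise MeasurementError("ploidy must be a positive integer")
    n = len(k.records)
    rem = n % ploidy
    if rem != 0:
        raise MeasurementError(
            f"{n} chromosomes are not divisible by ploidy {ploidy} "
            f"(remainder {rem})"
        )
    recs = sorted(k.records, key=_record_sort_key)
    out = []
    for g in range(n // ploidy):
        group = recs[g * ploidy:(g + 1) * ploidy]
        out.append(_merge_group(str(g + 1), group, k.unit))
    return AveragedKaryotype(records=out, source=k.source, unit=k.unit)


def average_karyotypes(ks: Sequence[Karyotype]) -> AveragedKaryotype:
    """Average chromosomes with the same names across several karyotypes.

    Matching is strictly by record name.  A name present in only a subset
    of the inputs is kept (with its own ``n``); if no name is shared by at
    least two karyotypes and more than one karyotype is supplied, the
    matching is considered failed.
    """
    ks = list(ks)
    if not ks:
        raise MeasurementError("need at least one karyotype to average")
    units = {k.unit for k in ks}
    if len(units) > 1:
        raise MeasurementError(f"cannot average mixed units: {sorted(units)}")
    unit = units.pop()

    by_name: dict[str, list[KaryotypeRecord]] = {}
    order: list[str] = []
    for k in ks:
        for r in k.records:
            if r.name not in by_name:
                by_name[r.name] = []
                order.append(r.name)
            by_name[r.name].append(r)

    if len(ks) > 1 and all(len(v) == 1 for v in by_name.values()):
        raise MeasurementError("no chromosome names shared between karyotypes")

    partial = [n for n in order if len(by_name[n]) < len(ks)]
    if partial:
        warnings.warn(
            f"chromosomes {partial} are present in only some karyotypes; "
            "their averages use fewer samples",
            stacklevel=2,
        )

    out = [_merge_group(name, by_name[name], unit) for name in order]
    out.sort(key=lambda r: (-r.mean_L, r.name))
    source = "+".join(k.source for k in ks)
    return AveragedKaryotype(records=out, source=source, unit=unit)
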