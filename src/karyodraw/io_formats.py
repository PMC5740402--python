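"""Readers and writers: measurement JSON, two-sheet xlsx, CSV mirror, storage.

The on-disk measurement format is a small versioned JSON schema (documented
in ``MEASUREMENT_SCHEMA_DOC``); validation errors carry JSON-pointer paths
to the offending fields.  Karyotype tables are exchanged as xlsx workbooks
with exactly two sheets — ``Chromosomes`` (per-chromosome statistics) and
``Metadata`` (landmark/segment positions and sizes) — which round-trip
losslessly, plus a CSV mirror (one file per sheet) for tool chains that do
not read xlsx.  A storage file is an append-only JSON container of named
karyotypes for later averaging.
"""

from __future__ import annotations

import json
import math
import os
from typing import Any, Optional, Sequence, Union

import openpyxl

from .karyostats import (
    AveragedKaryotype,
    AveragedRecord,
    FracSegment,
    Karyotype,
    KaryotypeRecord,
)
from .measure_core import (
    ChromosomeMeasurement,
    Landmark,
    Metaphase,
    Polyline,
    RelativeLandmark,
    ScaleCalibration,
    Segment,
)

__all__ = [
    "FormatError",
    "SCHEMA_VERSION",
    "read_metaphase",
    "write_metaphase",
    "metaphase_to_dict",
    "metaphase_from_dict",
    "write_karyotype_xlsx",
    "read_karyotype_xlsx",
    "write_karyotype_csv",
    "storage_add",
    "storage_list",
    "storage_get",
]

SCHEMA_VERSION = "1.0"

MEASUREMENT_SCHEMA_DOC = {
    "schema_version": "string, required, currently '1.0'",
    "id": "string, required — metaphase identifier",
    "image_ref": "string or null — provenance pointer to the source image",
    "calibration": "null or {bar_pixels: number>0, bar_physical_um: number>0}",
    "measurements": [
        {
            "name": "string, unique within the metaphase",
            "fragments": "list of polylines; each polyline is a list of [x, y]",
            "centromere_arc": "number in (0, total length) or null (holocentric)",
            "color": "string or null — idiogram body color override",
            "landmarks": [
                {
                    "name": "string",
                    "kind": "signal_point | band | satellite",
                    "color": "string",
                    "arc_start": "number ≥ 0 (px along the joined path)",
                    "arc_end": "number ≥ arc_start",
                }
            ],
            "segments": [
                {"color": "string", "arc_start": "number", "arc_end": "number"}
            ],
        }
    ],
}


class FormatError(ValueError):
    """A file does not match the expected schema/layout.

    ``paths`` holds JSON-pointer strings to the offending locations.
    """

    def __init__(self, message: str, paths: Optional[list[str]] = None):
        self.paths = paths or []
        if self.paths:
            message = f"{message}: {', '.join(self.paths)}"
        super().__init__(message)


# ---------------------------------------------------------------------------
# measurement JSON

class _Validator:
    def __init__(self):
        self.errors: list[str] = []

    def fail(self, ptr: str, why: str):
        self.errors.append(f"{ptr} ({why})")

    def require(self, obj: dict, key: str, typ, ptr: str, allow_none=False):
        if key not in obj:
            self.fail(f"{ptr}/{key}", "missing")
            return None
        v = obj[key]
        if v is None:
            if not allow_none:
                self.fail(f"{ptr}/{key}", "null not allowed")
            return None
        if typ is float:
            if not isinstance(v, (int, float)) or isinstance(v, bool) \
                    or not math.isfinite(v):
                self.fail(f"{ptr}/{key}", "expected finite number")
                return None
            return float(v)
        if not isinstance(v, typ):
            self.fail(f"{ptr}/{key}", f"expected {typ.__name__}")
            return None
        return v


def _validate_metaphase_dict(doc: Any) -> list[str]:
    v = _Validator()
    if not isinstance(doc, dict):
        return ["/ (expected object)"]
    ver = v.require(doc, "schema_version", str, "")
    if ver is not None and ver != SCHEMA_VERSION:
        v.fail("/schema_version", f"unsupported version {ver!r}")
    v.require(doc, "id", str, "")
    if "image_ref" in doc and doc["image_ref"] is not None \
            and not isinstance(doc["image_ref"], str):
        v.fail("/image_ref", "expected string or null")
    cal = doc.get("calibration")
    if cal is not None:
        if not isinstance(cal, dict):
            v.fail("/calibration", "expected object or null")
        else:
            bp = v.require(cal, "bar_pixels", float, "/calibration")
            bu = v.require(cal, "bar_physical_um", float, "/calibration")
            if bp is not None and bp <= 0:
                v.fail("/calibration/bar_pixels", "must be > 0")
            if bu is not None and bu <= 0:
                v.fail("/calibration/bar_physical_um", "must be > 0")
    ms = v.require(doc, "measurements", list, "")
    if ms is not None:
        if not ms:
            v.fail("/measurements", "must not be empty")
        for i, m in enumerate(ms):
            ptr = f"/measurements/{i}"
            if not isinstance(m, dict):
                v.fail(ptr, "expected object")
                continue
            v.require(m, "name", str, ptr)
            frags = v.require(m, "fragments", list, ptr)
            total = 0.0
            if frags is not None:
                if not frags:
                    v.fail(f"{ptr}/fragments", "needs at least one fragment")
                for j, fr in enumerate(frags):
                    fptr = f"{ptr}/fragments/{j}"
                    if not isinstance(fr, list) or len(fr) < 2:
                        v.fail(fptr, "fragment needs >= 2 vertices")
                        continue
                    ok = True
                    for kk, pt in enumerate(fr):
                        if (not isinstance(pt, list) or len(pt) != 2
                                or not all(isinstance(c, (int, float))
                                           and not isinstance(c, bool)
                                           and math.isfinite(c) for c in pt)):
                            v.fail(f"{fptr}/{kk}", "expected [x, y] finite numbers")
                            ok = False
                    if ok:
                        total += Polyline(fr).length
            cen = m.get("centromere_arc")
            if cen is not None:
                if not isinstance(cen, (int, float)) or isinstance(cen, bool):
                    v.fail(f"{ptr}/centromere_arc", "expected number or null")
                elif total > 0 and not (0 < cen < total):
                    v.fail(f"{ptr}/centromere_arc",
                           f"must lie in (0, {total:.6g})")
            for j, lm in enumerate(m.get("landmarks", []) or []):
                lptr = f"{ptr}/landmarks/{j}"
                if not isinstance(lm, dict):
                    v.fail(lptr, "expected object")
                    continue
                v.require(lm, "name", str, lptr)
                kind = v.require(lm, "kind", str, lptr)
                if kind is not None and kind not in Landmark.KINDS:
                    v.fail(f"{lptr}/kind", f"unknown kind {kind!r}")
                v.require(lm, "color", str, lptr)
                a = v.require(lm, "arc_start", float, lptr)
                b = v.require(lm, "arc_end", float, lptr)
                if a is not None and b is not None:
                    if not (0 <= a <= b):
                        v.fail(lptr, "need 0 <= arc_start <= arc_end")
                    elif total > 0 and b > total * (1 + 1e-9):
                        v.fail(f"{lptr}/arc_end", "beyond path length")
            for j, sg in enumerate(m.get("segments", []) or []):
                sptr = f"{ptr}/segments/{j}"
                if not isinstance(sg, dict):
                    v.fail(sptr, "expected object")
                    continue
                v.require(sg, "color", str, sptr)
                a = v.require(sg, "arc_start", float, sptr)
                b = v.require(sg, "arc_end", float, sptr)
                if a is not None and b is not None and not (0 <= a < b):
                    v.fail(sptr, "need 0 <= arc_start < arc_end")
    return v.errors


def metaphase_to_dict(mp: Metaphase) -> dict:
    cal = None
    if mp.calibration is not None:
        cal = {
            "bar_pixels": mp.calibration.bar_pixels,
            "bar_physical_um": mp.calibration.bar_physical,
        }
    return {
        "schema_version": SCHEMA_VERSION,
        "id": mp.id,
        "image_ref": mp.image_ref,
        "calibration": cal,
        "measurements": [
            {
                "name": m.name,
                "fragments": [[[x, y] for x, y in f.vertices] for f in m.fragments],
                "centromere_arc": m.centromere_arc,
                "color": m.color,
                "landmarks": [
                    {
                        "name": lm.name, "kind": lm.kind, "color": lm.color,
                        "arc_start": lm.arc_start, "arc_end": lm.arc_end,
                    }
                    for lm in m.landmarks
                ],
                "segments": [
                    {"color": s.color, "arc_start": s.arc_start, "arc_end": s.arc_end}
                    for s in m.segments
                ],
            }
            for m in mp.measurements
        ],
    }


def metaphase_from_dict(doc: dict) -> Metaphase:
    errors = _validate_metaphase_dict(doc)
    if errors:
        raise FormatError("invalid measurement file", errors)
    cal = None
    if doc.get("calibration") is not None:
        cal = ScaleCalibration(
            bar_pixels=float(doc["calibration"]["bar_pixels"]),
            bar_physical=float(doc["calibration"]["bar_physical_um"]),
        )
    measurements = []
    for m in doc["measurements"]:
        measurements.append(ChromosomeMeasurement(
            name=m["name"],
            fragments=[Polyline(f) for f in m["fragments"]],
            centromere_arc=(None if m.get("centromere_arc") is None
                            else float(m["centromere_arc"])),
            landmarks=[
                Landmark(lm["name"], lm["kind"], lm["color"],
                         float(lm["arc_start"]), float(lm["arc_end"]))
                for lm in m.get("landmarks", []) or []
            ],
            segments=[
                Segment(s["color"], float(s["arc_start"]), float(s["arc_end"]))
                for s in m.get("segments", []) or []
            ],
            color=m.get("color"),
        ))
    return Metaphase(
        id=doc["id"], measurements=measurements, calibration=cal,
        image_ref=doc.get("image_ref"),
    )


def _canonical_json(doc: dict) -> str:
    return json.dumps(doc, indent=2, sort_keys=True, ensure_ascii=False) + "\n"


def write_metaphase(mp: Metaphase, path: Union[str, os.PathLike]) -> None:
    """Write a metaphase as canonical (sorted-key, indented) JSON."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_canonical_json(metaphase_to_dict(mp)))


def read_metaphase(path: Union[str, os.PathLike]) -> Metaphase:
    """Read and validate a measurement JSON file."""
    with open(path, "r", encoding="utf-8") as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as e:
            raise FormatError(f"not valid JSON: {e}") from e
    return metaphase_from_dict(doc)


# ---------------------------------------------------------------------------
# xlsx / CSV karyotype tables

CHROMOSOME_COLUMNS = [
    "Chromosome", "Unit", "Length", "Short arm", "Long arm",
    "Centromere index", "Arm ratio", "Relative length (%)",
]
AVERAGED_EXTRA_COLUMNS = ["n", "SD Length", "SD Short arm", "SD Long arm", "SD CI"]
METADATA_COLUMNS = [
    "Chromosome", "Landmark", "Type", "Color", "Arm",
    "Position (frac)", "Start", "End", "Size",
]

AnyKaryotype = Union[Karyotype, AveragedKaryotype]


def _rl_values(records) -> list[float]:
    tot = sum(getattr(r, "mean_L", None) or getattr(r, "L", 0.0) for r in records)
    return [100.0 * (getattr(r, "mean_L", None) or getattr(r, "L", 0.0)) / tot
            for r in records]


def _chromosome_rows(k: AnyKaryotype) -> tuple[list[str], list[list]]:
    averaged = isinstance(k, AveragedKaryotype)
    header = CHROMOSOME_COLUMNS + (AVERAGED_EXTRA_COLUMNS if averaged else [])
    # averaged records carry no stored RL; derive it from the mean lengths
    rls = _rl_values(k.records) if averaged else [r.RL for r in k.records]
    rows = []
    for rec, rl in zip(k.records, rls):
        if averaged:
            ar = (None if not rec.mean_Ls
                  else (rec.mean_Ll / rec.mean_Ls if rec.mean_Ls > 0 else None))
            rows.append([
                rec.name, rec.unit, rec.mean_L, rec.mean_Ls, rec.mean_Ll,
                rec.mean_CI, ar, rl,
                rec.n, rec.sd_L, rec.sd_Ls, rec.sd_Ll, rec.sd_CI,
            ])
        else:
            rows.append([
                rec.name, rec.unit, rec.L, rec.Ls, rec.Ll,
                rec.CI, rec.r, rl,
            ])
    return header, rows


def _metadata_rows(k: AnyKaryotype) -> list[list]:
    rows = []
    for rec in k.records:
        L = getattr(rec, "mean_L", None) or getattr(rec, "L", 0.0)
        if rec.color is not None:
            rows.append([rec.name, "body", "chromosome_color", rec.color,
                         None, None, None, None, None])
        for lm in rec.landmarks:
            mid = (lm.frac_start + lm.frac_end) / 2.0
            rows.append([rec.name, lm.name, lm.kind, lm.color, lm.arm,
                         mid, lm.frac_start, lm.frac_end, lm.size])
        for sg in rec.segments:
            mid = (sg.frac_start + sg.frac_end) / 2.0
            rows.append([rec.name, "", "segment", sg.color, None,
                         mid, sg.frac_start, sg.frac_end,
                         (sg.frac_end - sg.frac_start) * L])
    return rows


def write_karyotype_xlsx(k: AnyKaryotype, path: Union[str, os.PathLike]) -> None:
    """Write the two-sheet workbook: ``Chromosomes`` and ``Metadata``."""
    wb = openpyxl.Workbook()
    ws = wb.active
    ws.title = "Chromosomes"
    header, rows = _chromosome_rows(k)
    ws.append(header)
    for row in rows:
        ws.append(row)
    meta = wb.create_sheet("Metadata")
    meta.append(METADATA_COLUMNS)
    for row in _metadata_rows(k):
        meta.append(row)
    wb.save(path)


def _cellf(v) -> Optional[float]:
    return None if v is None else float(v)


def read_karyotype_xlsx(path: Union[str, os.PathLike]) -> AnyKaryotype:
    """Read a two-sheet karyotype workbook back into memory (exact inverse)."""
    wb = openpyxl.load_workbook(path, read_only=True, data_only=True)
    expected_sheets = ["Chromosomes", "Metadata"]
    if wb.sheetnames != expected_sheets:
        raise FormatError(
            f"expected sheets {expected_sheets}, found {wb.sheetnames}")
    ws = wb["Chromosomes"]
    rows = [list(r) for r in ws.iter_rows(values_only=True)]
    if not rows:
        raise FormatError("Chromosomes sheet is empty")
    header = [c for c in rows[0] if c is not None]
    averaged = header == CHROMOSOME_COLUMNS + AVERAGED_EXTRA_COLUMNS
    if not averaged and header != CHROMOSOME_COLUMNS:
        for i, (got, want) in enumerate(zip(header, CHROMOSOME_COLUMNS)):
            if got != want:
                raise FormatError(
                    f"Chromosomes column {i + 1}: expected {want!r}, found {got!r}")
        raise FormatError(
            f"Chromosomes header has {len(header)} columns, "
            f"expected {len(CHROMOSOME_COLUMNS)} or "
            f"{len(CHROMOSOME_COLUMNS) + len(AVERAGED_EXTRA_COLUMNS)}")

    meta = wb["Metadata"]
    mrows = [list(r) for r in meta.iter_rows(values_only=True)]
    if not mrows or [c for c in mrows[0] if c is not None] != METADATA_COLUMNS:
        found = mrows[0] if mrows else []
        raise FormatError(f"Metadata header mismatch: found {found}")

    colors: dict[str, str] = {}
    landmarks: dict[str, list[RelativeLandmark]] = {}
    segments: dict[str, list[FracSegment]] = {}
    meta_units: dict[str, str] = {}
    for row in mrows[1:]:
        if row[0] is None:
            continue
        name = str(row[0])
        typ = row[2]
        if typ == "chromosome_color":
            colors[name] = row[3]
        elif typ == "segment":
            segments.setdefault(name, []).append(
                FracSegment(row[3], float(row[6]), float(row[7])))
        else:
            landmarks.setdefault(name, []).append(RelativeLandmark(
                name=str(row[1]), kind=str(typ), color=str(row[3]),
                arm=str(row[4]), frac_start=float(row[6]),
                frac_end=float(row[7]), size=float(row[8]),
                unit=meta_units.get(name, "px"),
            ))

    records: list = []
    unit = "px"
    for row in rows[1:]:
        if row[0] is None:
            continue
        name = str(row[0])
        unit = str(row[1])
        lms = [
            RelativeLandmark(lm.name, lm.kind, lm.color, lm.arm,
                             lm.frac_start, lm.frac_end, lm.size, unit)
            for lm in landmarks.get(name, [])
        ]
        if averaged:
            records.append(AveragedRecord(
                name=name, n=int(row[8]),
                mean_L=float(row[2]), sd_L=_cellf(row[9]),
                mean_Ls=_cellf(row[3]), sd_Ls=_cellf(row[10]),
                mean_Ll=_cellf(row[4]), sd_Ll=_cellf(row[11]),
                mean_CI=_cellf(row[5]), sd_CI=_cellf(row[12]),
                unit=unit, landmarks=lms,
                segments=segments.get(name, []), color=colors.get(name),
            ))
        else:
            records.append(KaryotypeRecord(
                name=name, L=float(row[2]), Ls=_cellf(row[3]),
                Ll=_cellf(row[4]), CI=_cellf(row[5]), r=_cellf(row[6]),
                RL=float(row[7]), unit=unit, landmarks=lms,
                segments=segments.get(name, []), color=colors.get(name),
            ))
    wb.close()
    src = os.path.splitext(os.path.basename(str(path)))[0]
    if averaged:
        return AveragedKaryotype(records=records, source=src, unit=unit)
    return Karyotype(records=records, source=src, unit=unit)


def write_karyotype_csv(k: AnyKaryotype, basepath: Union[str, os.PathLike]) -> tuple[str, str]:
    """CSV mirror of the workbook: ``<base>_chromosomes.csv`` + ``<base>_metadata.csv``."""
    import csv

    base = str(basepath)
    if base.lower().endswith(".csv"):
        base = base[:-4]
    header, rows = _chromosome_rows(k)
    p1, p2 = f"{base}_chromosomes.csv", f"{base}_metadata.csv"
    with open(p1, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        w.writerows(rows)
    with open(p2, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(METADATA_COLUMNS)
        w.writerows(_metadata_rows(k))
    return p1, p2


# ---------------------------------------------------------------------------
# storage: append-only container of named karyotypes

def _karyotype_to_entry(name: str, k: AnyKaryotype) -> dict:
    averaged = isinstance(k, AveragedKaryotype)
    recs = []
    for r in k.records:
        d: dict[str, Any] = {
            "name": r.name, "unit": r.unit, "color": r.color,
            "landmarks": [
                {"name": lm.name, "kind": lm.kind, "color": lm.color,
                 "arm": lm.arm, "frac_start": lm.frac_start,
                 "frac_end": lm.frac_end, "size": lm.size, "unit": lm.unit}
                for lm in r.landmarks
            ],
            "segments": [
                {"color": s.color, "frac_start": s.frac_start,
                 "frac_end": s.frac_end}
                for s in r.segments
            ],
        }
        if averaged:
            d.update(n=r.n, mean_L=r.mean_L, sd_L=r.sd_L,
                     mean_Ls=r.mean_Ls, sd_Ls=r.sd_Ls,
                     mean_Ll=r.mean_Ll, sd_Ll=r.sd_Ll,
                     mean_CI=r.mean_CI, sd_CI=r.sd_CI)
        else:
            d.update(L=r.L, Ls=r.Ls, Ll=r.Ll, CI=r.CI, r=r.r, RL=r.RL)
        recs.append(d)
    return {
        "name": name,
        "kind": "averaged" if averaged else "karyotype",
        "source": k.source,
        "unit": k.unit,
        "records": recs,
    }


def _entry_to_karyotype(e: dict) -> AnyKaryotype:
    def lms(r):
        return [RelativeLandmark(**lm) for lm in r.get("landmarks", [])]

    def segs(r):
        return [FracSegment(**s) for s in r.get("segments", [])]

    if e["kind"] == "averaged":
        records = [
            AveragedRecord(
                name=r["name"], n=r["n"],
                mean_L=r["mean_L"], sd_L=r["sd_L"],
                mean_Ls=r["mean_Ls"], sd_Ls=r["sd_Ls"],
                mean_Ll=r["mean_Ll"], sd_Ll=r["sd_Ll"],
                mean_CI=r["mean_CI"], sd_CI=r["sd_CI"],
                unit=r["unit"], landmarks=lms(r), segments=segs(r),
                color=r.get("color"),
            )
            for r in e["records"]
        ]
        return AveragedKaryotype(records=records, source=e["source"], unit=e["unit"])
    records = [
        KaryotypeRecord(
            name=r["name"], L=r["L"], Ls=r["Ls"], Ll=r["Ll"], CI=r["CI"],
            r=r["r"], RL=r["RL"], unit=r["unit"], landmarks=lms(r),
            segments=segs(r), color=r.get("color"),
        )
        for r in e["records"]
    ]
    return Karyotype(records=records, source=e["source"], unit=e["unit"])


def _load_storage(path) -> dict:
    if not os.path.exists(path):
        return {"schema_version": SCHEMA_VERSION, "entries": []}
    with open(path, "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    if not isinstance(doc, dict) or "entries" not in doc:
        raise FormatError(f"{path} is not a karyotype storage file")
    return doc


def storage_add(path: Union[str, os.PathLike], name: str, k: AnyKaryotype) -> None:
    """Append a named karyotype to the storage file (names must be unique)."""
    doc = _load_storage(path)
    if any(e["name"] == name for e in doc["entries"]):
        raise FormatError(f"storage already contains an entry named {name!r}")
    doc["entries"].append(_karyotype_to_entry(name, k))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_canonical_json(doc))


def storage_list(path: Union[str, os.PathLike]) -> list[str]:
    """Entry names in insertion order."""
    return [e["name"] for e in _load_storage(path)["entries"]]


def storage_get(path: Union[str, os.PathLike], name: str) -> AnyKaryotype:
    """Fetch one stored karyotype by name."""
    for e in _load_storage(path)["entries"]:
        if e["name"] == name:
            return _entry_to_karyotype(e)
    raise FormatError(f"no storage entry named {name!r}")
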