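"""Resolution-independent idiogram layout and SVG/PNG rendering.

The layout step turns a (possibly averaged) karyotype into an
``IdiogramScene``: a list of chromosome glyphs plus drawing primitives in
an abstract unit space (the SVG viewBox).  The render step serializes the
same primitives either to SVG 1.1 (hand-emitted XML, byte-deterministic)
or to PNG through matplotlib at a chosen DPI, so both outputs share one
geometry.

Conventions: chromosomes are drawn as vertical bodies, short arm up, left
to right in record order; with ``alignment="centromere"`` every centromeric
constriction sits on one shared horizontal line.  Glyph height is strictly
proportional to chromosome length with a single shared scale factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

from .karyostats import AveragedKaryotype, Karyotype
from .measure_core import MeasurementError

__all__ = ["IdiogramStyle", "IdiogramScene", "ChromosomeGlyph", "layout_idiogram", "render"]


# fixed ordered palette so repeated renders are reproducible
DEFAULT_PALETTE = (
    "#1f77b4", "#ff7f0e", "#2ca02c", "#d62728", "#9467bd",
    "#8c564b", "#e377c2", "#7f7f7f", "#bcbd22", "#17becf",
)


@dataclass(frozen=True)
class IdiogramStyle:
    """Appearance knobs for an idiogram (all sizes in drawing units)."""

    chromosome_width: float = 14.0
    spacing: float = 26.0
    alignment: str = "centromere"  # centromere | top
    max_body_height: float = 200.0
    body_color: str = "#d4d4d4"
    centromere_color: str = "#4d4d4d"
    show_legend: bool = True
    show_error_bars: bool = True
    scale_bar: Optional[float] = None  # physical length (unit of the karyotype)
    margin: float = 24.0
    font_size: float = 10.0

    def __post_init__(self):
        if self.chromosome_width <= 0 or self.spacing <= 0:
            raise MeasurementError("chromosome_width and spacing must be > 0")
        if self.alignment not in ("centromere", "top"):
            raise MeasurementError(f"unknown alignment {self.alignment!r}")


# ---------------------------------------------------------------------------
# drawing primitives (shared by the SVG and PNG back ends)

@dataclass(frozen=True)
class Rect:
    x: float; y: float; w: float; h: float
    fill: str
    stroke: Optional[str] = None


@dataclass(frozen=True)
class Circle:
    cx: float; cy: float; r: float
    fill: str


@dataclass(frozen=True)
class Line:
    x1: float; y1: float; x2: float; y2: float
    stroke: str
    width: float = 1.0


@dataclass(frozen=True)
class Polygon:
    points: tuple[tuple[float, float], ...]
    fill: str


@dataclass(frozen=True)
class Text:
    x: float; y: float
    s: str
    size: float
    anchor: str = "middle"  # start | middle | end


Primitive = Union[Rect, Circle, Line, Polygon, Text]


@dataclass
class ChromosomeGlyph:
    """One chromosome body with its landmarks and labels."""

    name: str
    x: float            # left edge
    width: float
    top_y: float
    height: float
    cen_y: Optional[float]  # y of the centromeric constriction, if any
    primitives: list[Primitive] = field(default_factory=list)


@dataclass
class IdiogramScene:
    """Laid-out idiogram: glyphs, decorations, canvas extents, legend."""

    glyphs: list[ChromosomeGlyph]
    decorations: list[Primitive]
    width: float
    height: float
    legend: list[tuple[str, str]]


def _record_geometry(rec) -> tuple[float, Optional[float], Optional[float], str]:
    """(L, Ls_drawn, color) for plain and averaged records.

    For averaged records the drawn arm split comes from mean_L · mean_CI/100
    so the constriction matches the averaged centromere index.
    """
    if hasattr(rec, "mean_L"):
        L = rec.mean_L
        Ls = None if rec.mean_CI is None else L * rec.mean_CI / 100.0
    else:
        L = rec.L
        Ls = rec.Ls
    return L, Ls, getattr(rec, "color", None)


def layout_idiogram(
    k: Union[Karyotype, AveragedKaryotype],
    style: IdiogramStyle = IdiogramStyle(),
) -> IdiogramScene:
    """Place chromosome glyphs for a karyotype in record order."""
    records = k.records
    if not records:
        raise MeasurementError("cannot lay out an empty karyotype")
    averaged = isinstance(k, AveragedKaryotype)

    geoms = [_record_geometry(r) for r in records]
    max_L = max(g[0] for g in geoms)
    if max_L <= 0:
        raise MeasurementError("all chromosome lengths are zero")
    scale = style.max_body_height / max_L  # drawing units per length unit

    # shared centromere line: deepest short arm defines it
    short_arms = [(ls if ls is not None else l / 2) * scale for l, ls, _ in geoms]
    label_band = 2.2 * style.font_size
    if style.alignment == "centromere":
        cen_line = style.margin + max(short_arms)
    else:
        cen_line = None

    w = style.chromosome_width
    glyphs: list[ChromosomeGlyph] = []
    legend: dict[str, str] = {}
    notch = w * 0.28  # half-depth of the centromeric constriction

    for i, (rec, (L, Ls, color)) in enumerate(zip(records, geoms)):
        h = L * scale
        x = style.margin + i * (w + style.spacing)
        ls_h = None if Ls is None else Ls * scale
        if style.alignment == "centromere":
            top_y = cen_line - (ls_h if ls_h is not None else h / 2)
        else:
            top_y = style.margin
        cen_y = None if ls_h is None else top_y + ls_h
        bottom = top_y + h

        prims: list[Primitive] = []
        body = color or style.body_color
        if cen_y is None:
            prims.append(Rect(x, top_y, w, h, fill=body, stroke="#303030"))
        else:
            prims.append(Rect(x, top_y, w, cen_y - top_y, fill=body, stroke="#303030"))
            prims.append(Rect(x, cen_y, w, bottom - cen_y, fill=body, stroke="#303030"))

        # GISH painting: colored sub-intervals of the body
        for seg in getattr(rec, "segments", []):
            y0 = top_y + seg.frac_start * h
            y1 = top_y + seg.frac_end * h
            prims.append(Rect(x, y0, w, y1 - y0, fill=seg.color))
            legend.setdefault(f"segment:{seg.color}", seg.color)

        # centromeric constriction as a symmetric bowtie overlay
        if cen_y is not None:
            prims.append(Polygon(
                points=(
                    (x, cen_y - notch), (x + w / 2, cen_y), (x, cen_y + notch),
                ),
                fill=style.centromere_color,
            ))
            prims.append(Polygon(
                points=(
                    (x + w, cen_y - notch), (x + w / 2, cen_y), (x + w, cen_y + notch),
                ),
                fill=style.centromere_color,
            ))

        for lm in getattr(rec, "landmarks", []):
            legend.setdefault(lm.name, lm.color)
            if lm.kind == "signal_point":
                cy = top_y + lm.frac_start * h
                prims.append(Circle(x + w + 5.0, cy, 3.2, fill=lm.color))
            else:
                y0 = top_y + lm.frac_start * h
                y1 = top_y + lm.frac_end * h
                prims.append(Rect(x, y0, w, y1 - y0, fill=lm.color))
                if lm.kind == "satellite":
                    # thin gap marking the secondary constriction
                    gy = y1 if lm.frac_start < 0.5 else y0
                    prims.append(Line(x, gy, x + w, gy, stroke="#ffffff", width=1.4))

        if averaged and style.show_error_bars:
            sd_L = rec.sd_L or 0.0
            if sd_L > 0:
                xb = x + w / 2
                d = sd_L * scale
                prims.append(Line(xb, bottom - d, xb, bottom + d, stroke="#202020"))
                prims.append(Line(xb - 3, bottom - d, xb + 3, bottom - d, stroke="#202020"))
                prims.append(Line(xb - 3, bottom + d, xb + 3, bottom + d, stroke="#202020"))
            sd_Ls = rec.sd_Ls or 0.0
            if sd_Ls > 0 and cen_y is not None:
                xb = x - 4.0
                d = sd_Ls * scale
                prims.append(Line(xb, cen_y - d, xb, cen_y + d, stroke="#a01010"))
                prims.append(Line(xb - 3, cen_y - d, xb + 3, cen_y - d, stroke="#a01010"))
                prims.append(Line(xb - 3, cen_y + d, xb + 3, cen_y + d, stroke="#a01010"))

        prims.append(Text(x + w / 2, bottom + 1.6 * style.font_size,
                          rec.name, style.font_size))
        glyphs.append(ChromosomeGlyph(
            name=rec.name, x=x, width=w, top_y=top_y, height=h, cen_y=cen_y,
            primitives=prims,
        ))

    body_right = style.margin + len(records) * (w + style.spacing)
    max_bottom = max(g.top_y + g.height for g in glyphs)

    decorations: list[Primitive] = []
    legend_entries = [(n, c) for n, c in legend.items()]
    legend_w = 0.0
    if style.show_legend and legend_entries:
        lx = body_right + 10.0
        ly = style.margin
        for j, (name, color) in enumerate(legend_entries):
            yj = ly + j * 1.8 * style.font_size
            decorations.append(Rect(lx, yj, 10, 10, fill=color, stroke="#303030"))
            decorations.append(Text(lx + 14, yj + 9, name, style.font_size, anchor="start"))
        legend_w = 10 + 14 + max(len(n) for n, _ in legend_entries) * 0.62 * style.font_size

    if style.scale_bar is not None and style.scale_bar > 0:
        sb_h = style.scale_bar * scale
        sx = body_right + legend_w + 18.0
        sy = style.margin
        decorations.append(Line(sx, sy, sx, sy + sb_h, stroke="#202020", width=2.0))
        decorations.append(Line(sx - 3, sy, sx + 3, sy, stroke="#202020"))
        decorations.append(Line(sx - 3, sy + sb_h, sx + 3, sy + sb_h, stroke="#202020"))
        unit = "µm" if k.unit == "um" else "px"
        decorations.append(Text(sx + 6, sy + sb_h / 2 + 3,
                                f"{style.scale_bar:g} {unit}", style.font_size,
                                anchor="start"))
        legend_w += 18.0 + 6 + 6 * 0.62 * style.font_size

    width = body_right + legend_w + style.margin
    height = max_bottom + label_band + style.margin
    return IdiogramScene(
        glyphs=glyphs, decorations=decorations,
        width=width, height=height,
        legend=legend_entries if style.show_legend else [],
    )


# ---------------------------------------------------------------------------
# SVG back end

def _f(v: float) -> str:
    return f"{v:.3f}".rstrip("0").rstrip(".")


def _esc(s: str) -> str:
    return (s.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")
            .replace('"', "&quot;"))


def _svg_primitive(p: Primitive) -> str:
    if isinstance(p, Rect):
        stroke = f' stroke="{p.stroke}" stroke-width="0.8"' if p.stroke else ""
        return (f'<rect x="{_f(p.x)}" y="{_f(p.y)}" width="{_f(p.w)}" '
                f'height="{_f(p.h)}" fill="{p.fill}"{stroke}/>')
    if isinstance(p, Circle):
        return f'<circle cx="{_f(p.cx)}" cy="{_f(p.cy)}" r="{_f(p.r)}" fill="{p.fill}"/>'
    if isinstance(p, Line):
        return (f'<line x1="{_f(p.x1)}" y1="{_f(p.y1)}" x2="{_f(p.x2)}" '
                f'y2="{_f(p.y2)}" stroke="{p.stroke}" stroke-width="{_f(p.width)}"/>')
    if isinstance(p, Polygon):
        pts = " ".join(f"{_f(x)},{_f(y)}" for x, y in p.points)
        return f'<polygon points="{pts}" fill="{p.fill}"/>'
    if isinstance(p, Text):
        return (f'<text x="{_f(p.x)}" y="{_f(p.y)}" font-size="{_f(p.size)}" '
                f'font-family="Helvetica, Arial, sans-serif" '
                f'text-anchor="{p.anchor}">{_esc(p.s)}</text>')
    raise TypeError(f"unknown primitive {p!r}")


def scene_to_svg(scene: IdiogramScene) -> str:
    """Serialize a scene to SVG 1.1 with one <g> per chromosome glyph."""
    out = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{_f(scene.width)}" height="{_f(scene.height)}" '
        f'viewBox="0 0 {_f(scene.width)} {_f(scene.height)}">',
    ]
    for g in scene.glyphs:
        out.append(f'<g id="chromosome-{_esc(g.name)}" class="chromosome">')
        out.extend("  " + _svg_primitive(p) for p in g.primitives)
        out.append("</g>")
    if scene.decorations:
        out.append('<g id="decorations">')
        out.extend("  " + _svg_primitive(p) for p in scene.decorations)
        out.append("</g>")
    out.append("</svg>")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# PNG back end (matplotlib renders the same primitives)

def _png_render(scene: IdiogramScene, path: str, dpi: int) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib import patches

    fig_w = scene.width / 72.0
    fig_h = scene.height / 72.0
    fig, ax = plt.subplots(figsize=(fig_w, fig_h))
    ax.set_xlim(0, scene.width)
    ax.set_ylim(scene.height, 0)  # y down, as in the SVG
    ax.set_aspect("equal")
    ax.axis("off")
    fig.subplots_adjust(left=0, right=1, top=1, bottom=0)

    prims: list[Primitive] = []
    for g in scene.glyphs:
        prims.extend(g.primitives)
    prims.extend(scene.decorations)
    for p in prims:
        if isinstance(p, Rect):
            ax.add_patch(patches.Rectangle(
                (p.x, p.y), p.w, p.h, facecolor=p.fill,
                edgecolor=p.stroke or "none", linewidth=0.8))
        elif isinstance(p, Circle):
            ax.add_patch(patches.Circle((p.cx, p.cy), p.r, facecolor=p.fill))
        elif isinstance(p, Line):
            ax.plot([p.x1, p.x2], [p.y1, p.y2], color=p.stroke, linewidth=p.width)
        elif isinstance(p, Polygon):
            ax.add_patch(patches.Polygon(list(p.points), facecolor=p.fill))
        elif isinstance(p, Text):
            ha = {"start": "left", "middle": "center", "end": "right"}[p.anchor]
            ax.text(p.x, p.y, p.s, fontsize=p.size, ha=ha, va="baseline")
    fig.savefig(path, dpi=dpi)
    plt.close(fig)


def render(scene: IdiogramScene, format: str, path: str, dpi: int = 300) -> None:
    """Write a scene to ``path`` as ``svg`` or ``png``.

    SVG output is deterministic: identical scenes yield byte-identical
    files.  PNG is rasterized at ``dpi``.
    """
    if format == "svg":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(scene_to_svg(scene))
    elif format == "png":
        _png_render(scene, path, dpi)
    else:
        raise MeasurementError(f"unknown render format {format!r}")
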