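"""SVG rendering of logo layouts.

Glyphs are filled outlines extracted from matplotlib's bundled DejaVu
fonts and emitted as SVG paths, so the output does not depend on fonts
installed on the viewing system.  Rendering is a pure function of
(layout, style): element order is stable, floats are formatted to fixed
precision and no timestamps are embedded, so two runs with identical
inputs produce byte-identical documents.

Single-character glyphs are scaled non-uniformly to fill their boxes
exactly (the classic logo look).  Multi-character string glyphs
("C→T", "H3K4ME1") are first scaled uniformly to the box width and then
stretched vertically, with the stretch capped at 8x the uniform scale;
past the cap the glyph is vertically centered in its box, since extreme
stretching makes strings unreadable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from functools import lru_cache
from typing import Mapping

from matplotlib.font_manager import FontProperties
from matplotlib.path import Path as MplPath
from matplotlib.textpath import TextPath
from matplotlib.ticker import MaxNLocator

from .errors import ValidationError
from .layout import LogoLayout

__all__ = ["StyleOptions", "render", "render_to_file", "default_color"]

# classic nucleotide colors; everything else cycles through a categorical map
_BASE_COLORS = {"A": "#109648", "C": "#255c99", "G": "#f7b32b", "T": "#d62839"}
_CYCLE = [
    "#1f77b4", "#ff7f0e", "#2ca02c", "#d62728", "#9467bd", "#8c564b",
    "#e377c2", "#7f7f7f", "#bcbd22", "#17becf", "#aec7e8", "#ffbb78",
    "#98df8a", "#ff9896", "#c5b0d5", "#c49c94", "#f7b6d2", "#c7c7c7",
    "#dbdb8d", "#9edae5",
]

MAX_STRETCH = 8.0


@dataclass
class StyleOptions:
    """Rendering options; unknown keys are rejected to catch typos."""

    width_per_position: float = 60.0
    plot_height: float = 240.0
    margin: float = 46.0
    colors: Mapping[str, str] = field(default_factory=dict)
    below_axis_alpha: float | None = None
    axis_color: str = "#333333"
    font_family: str = "DejaVu Sans"
    font_weight: str = "bold"
    label_size: float = 11.0
    y_label: str | None = None

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, object]) -> "StyleOptions":
        known = {f.name for f in fields(cls)}
        kwargs = {}
        for key, val in dict(mapping).items():
            if key not in known:
                raise ValidationError(f"unknown style key {key!r}")
            if key in ("width_per_position", "plot_height", "margin", "label_size",
                       "below_axis_alpha"):
                val = float(val)
            kwargs[key] = val
        return cls(**kwargs)


def default_color(symbol: str, order: list[str], overrides: Mapping[str, str]) -> str:
    """Color for a symbol: explicit override, nucleotide classic, else cycle."""
    if symbol in overrides:
        return overrides[symbol]
    if symbol in _BASE_COLORS:
        return _BASE_COLORS[symbol]
    others = [s for s in order if s not in _BASE_COLORS and s not in overrides]
    return _CYCLE[others.index(symbol) % len(_CYCLE)]


def _f(x: float) -> str:
    s = f"{x:.3f}".rstrip("0").rstrip(".")
    return "0" if s in ("-0", "") else s


@lru_cache(maxsize=512)
def _glyph_geometry(text: str, family: str, weight: str):
    """Vertices/codes of the text outline at size 100, plus its tight bbox."""
    prop = FontProperties(family=family, weight=weight)
    tp = TextPath((0, 0), text, size=100, prop=prop)
    ext = tp.get_extents()
    return tuple(map(tuple, tp.vertices)), tuple(tp.codes), (ext.x0, ext.y0, ext.width, ext.height)


def _path_d(vertices, codes, transform) -> str:
    """Convert matplotlib path codes to an SVG path string under ``transform``."""
    parts: list[str] = []
    i = 0
    n = len(codes)
    while i < n:
        code = codes[i]
        if code == MplPath.MOVETO:
            x, y = transform(*vertices[i])
            parts.append(f"M{_f(x)} {_f(y)}")
            i += 1
        elif code == MplPath.LINETO:
            x, y = transform(*vertices[i])
            parts.append(f"L{_f(x)} {_f(y)}")
            i += 1
        elif code == MplPath.CURVE3:
            (cx, cy), (x, y) = (transform(*vertices[i]), transform(*vertices[i + 1]))
            parts.append(f"Q{_f(cx)} {_f(cy)} {_f(x)} {_f(y)}")
            i += 2
        elif code == MplPath.CURVE4:
            pts = [transform(*vertices[i + k]) for k in range(3)]
            parts.append("C" + " ".join(f"{_f(px)} {_f(py)}" for px, py in pts))
            i += 3
        elif code == MplPath.CLOSEPOLY:
            parts.append("Z")
            i += 1
        else:  # pragma: no cover - matplotlib emits no other codes
            i += 1
    return "".join(parts)


def render(lay: LogoLayout, style: StyleOptions | None = None) -> str:
    """Render a layout to an SVG document string."""
    style = style or StyleOptions()
    L = len(lay.positions)
    ymin, ymax = lay.y_range
    span = ymax - ymin
    if span <= 0:
        span, ymin, ymax = 1.0, 0.0, 1.0
    sx = style.width_per_position
    sy = style.plot_height / span
    m = style.margin
    width = m + L * sx + m / 2
    height = m / 2 + style.plot_height + m

    def to_px(x: float, y: float) -> tuple[float, float]:
        return (m + (x + 0.5) * sx, m / 2 + (ymax - y) * sy)

    out: list[str] = []
    out.append('<?xml version="1.0" encoding="UTF-8"?>')
    out.append(
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{_f(width)}" '
        f'height="{_f(height)}" viewBox="0 0 {_f(width)} {_f(height)}">'
    )
    out.append(f'<rect width="{_f(width)}" height="{_f(height)}" fill="#ffffff"/>')

    order = []
    for b in lay.boxes:
        if b.symbol not in order:
            order.append(b.symbol)

    # glyph boxes
    for b in lay.boxes:
        x0, ytop = to_px(b.x0, b.y1)
        x1, ybot = to_px(b.x1, b.y0)
        bw, bh = x1 - x0, ybot - ytop
        if bw <= 0 or bh <= 0:
            continue
        verts, codes, (gx0, gy0, gw, gh) = _glyph_geometry(
            b.glyph_text, style.font_family, style.font_weight
        )
        if gw <= 0 or gh <= 0:
            continue
        if len(b.glyph_text) > 1:
            s_uni = bw / gw
            s_vert = bh / gh
            if s_vert > MAX_STRETCH * s_uni:
                s_vert = MAX_STRETCH * s_uni
            scale_x, scale_y = s_uni, s_vert
            draw_h = gh * scale_y
            off_y = ytop + (bh - draw_h) / 2.0
        else:
            scale_x, scale_y = bw / gw, bh / gh
            off_y = ytop

        def gt(vx, vy, _sx=scale_x, _sy=scale_y, _ox=x0 - gx0 * scale_x,
               _oy=off_y, _gy0=gy0, _gh=gh):
            # font y is up; svg y is down: flip within the glyph box
            return (_ox + vx * _sx, _oy + (_gy0 + _gh - vy) * _sy)

        d = _path_d(verts, codes, gt)
        color = default_color(b.symbol, order, style.colors)
        alpha = ""
        if b.side == "below" and style.below_axis_alpha is not None:
            alpha = f' fill-opacity="{_f(style.below_axis_alpha)}"'
        out.append(f'<path d="{d}" fill="{color}"{alpha}/>')

    # axes
    ax0, ay = to_px(-0.5, 0.0)
    ax1, _ = to_px(L - 0.5, 0.0)
    out.append(
        f'<line x1="{_f(ax0)}" y1="{_f(ay)}" x2="{_f(ax1)}" y2="{_f(ay)}" '
        f'stroke="{style.axis_color}" stroke-width="1.5"/>'
    )
    font = f'font-family="{style.font_family}" font-size="{_f(style.label_size)}"'
    # x tick labels under the plot
    base_y = m / 2 + style.plot_height + style.label_size + 4
    for k, lab in enumerate(lay.positions):
        cx, _ = to_px(k, 0.0)
        out.append(
            f'<text x="{_f(cx)}" y="{_f(base_y)}" text-anchor="middle" {font} '
            f'fill="{style.axis_color}">{_escape(str(lab))}</text>'
        )
    # y ticks
    ticks = [t for t in MaxNLocator(nbins=5).tick_values(ymin, ymax) if ymin <= t <= ymax]
    x_axis_px = m
    out.append(
        f'<line x1="{_f(x_axis_px)}" y1="{_f(to_px(0, ymax)[1])}" '
        f'x2="{_f(x_axis_px)}" y2="{_f(to_px(0, ymin)[1])}" '
        f'stroke="{style.axis_color}" stroke-width="1"/>'
    )
    for t in ticks:
        _, ty = to_px(0.0, t)
        out.append(
            f'<line x1="{_f(x_axis_px - 4)}" y1="{_f(ty)}" x2="{_f(x_axis_px)}" '
            f'y2="{_f(ty)}" stroke="{style.axis_color}" stroke-width="1"/>'
        )
        out.append(
            f'<text x="{_f(x_axis_px - 7)}" y="{_f(ty + style.label_size / 3)}" '
            f'text-anchor="end" {font} fill="{style.axis_color}">{_f(t)}</text>'
        )
    y_label = style.y_label
    if y_label is None:
        y_label = "bits" if lay.mode == "standard" else "Enrichment score (log2)"
    mid_y = m / 2 + style.plot_height / 2
    out.append(
        f'<text x="{_f(12.0)}" y="{_f(mid_y)}" text-anchor="middle" {font} '
        f'fill="{style.axis_color}" transform="rotate(-90 {_f(12.0)} {_f(mid_y)})">'
        f"{_escape(y_label)}</text>"
    )
    out.append("</svg>")
    return "\n".join(out) + "\n"


def _escape(text: str) -> str:
    return text.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")


def render_to_file(lay: LogoLayout, path, style: StyleOptions | None = None) -> None:
    svg = render(lay, style)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(svg)
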