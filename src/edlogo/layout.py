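"""Deterministic glyph layout for stacked logos.

Each position occupies one unit slot on the x axis (slot k spans
[k - 0.5, k + 0.5), centered on integer k), shrunk by a gap fraction on
each side.  Within a position, every symbol with a nonzero score becomes
a box of height |r_i|: positive scores tile upward from the axis,
negative scores tile downward, and reading the whole stack bottom-to-top
gives the symbols in increasing score order, so the largest glyphs sit
furthest from the axis.  Ties are broken by alphabet order with the
lower-index symbol nearer the axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .matrices import ScoreMatrix

__all__ = ["GlyphBox", "LogoLayout", "layout"]

#: scores within this of zero are not drawn
ZERO_TOL = 1e-12


@dataclass(frozen=True)
class GlyphBox:
    """One placed glyph: its x/y extent, axis side and stacking rank."""

    position: object
    symbol: str
    glyph_text: str
    x0: float
    x1: float
    y0: float
    y1: float
    side: str  # "above" | "below"
    rank: int  # bottom-to-top index within the whole stack

    @property
    def height(self) -> float:
        return self.y1 - self.y0


@dataclass
class LogoLayout:
    """Resolved glyph boxes plus the axis metadata needed to render them."""

    boxes: list[GlyphBox]
    positions: list[object]
    mode: str
    centering: str

    def at(self, position: object) -> list[GlyphBox]:
        return [b for b in self.boxes if b.position == position]

    @property
    def y_range(self) -> tuple[float, float]:
        if not self.boxes:
            return (0.0, 1.0)
        return (
            min(0.0, min(b.y0 for b in self.boxes)),
            max(0.0, max(b.y1 for b in self.boxes)),
        )


def layout(scores: ScoreMatrix, gap: float = 0.05) -> LogoLayout:
    """Resolve a score matrix into glyph boxes.

    ``gap`` is the fraction of the unit position width trimmed from each
    side of every slot.  The output is deterministic: stacking order is
    (score, alphabet index) with the tie rule above, and symbols whose
    score is zero to within 1e-12 are dropped.
    """
    if not 0 <= gap < 0.5:
        raise ValidationError("gap must be in [0, 0.5)")
    boxes: list[GlyphBox] = []
    for k, (lab, alph) in enumerate(zip(scores.positions, scores.alphabets)):
        v = scores.values[k]
        if not np.all(np.isfinite(v)):
            raise ValidationError(f"non-finite score at position {lab!r}")
        x0, x1 = k - 0.5 + gap, k + 0.5 - gap
        neg = [(float(v[i]), i) for i in range(v.size) if v[i] < -ZERO_TOL]
        pos = [(float(v[i]), i) for i in range(v.size) if v[i] > ZERO_TOL]
        # bottom-to-top = increasing score; ties put the lower alphabet
        # index nearer the axis (top of the below-stack, bottom of the above-stack)
        neg.sort(key=lambda t: (t[0], -t[1]))
        pos.sort(key=lambda t: (t[0], t[1]))
        rank = 0
        y = -sum(abs(r) for r, _ in neg)
        for r, i in neg:
            sym = alph.symbols[i]
            boxes.append(
                GlyphBox(lab, sym, alph.label(sym), x0, x1, y, y + abs(r), "below", rank)
            )
            y += abs(r)
            rank += 1
        y = 0.0
        for r, i in pos:
            sym = alph.symbols[i]
            boxes.append(
                GlyphBox(lab, sym, alph.label(sym), x0, x1, y, y + r, "above", rank)
            )
            y += r
            rank += 1
    return LogoLayout(boxes, list(scores.positions), scores.mode, scores.centering)


def write_layout_table(lay: LogoLayout, stream) -> None:
    """Serialize a layout as a TSV of glyph boxes."""
    stream.write(f"# mode = {lay.mode}\n# centering = {lay.centering}\n")
    stream.write("position\tsymbol\tx0\tx1\ty0\ty1\tside\trank\n")
    for b in lay.boxes:
        stream.write(
            f"{b.position}\t{b.symbol}\t{b.x0:.9g}\t{b.x1:.9g}\t"
            f"{b.y0:.9g}\t{b.y1:.9g}\t{b.side}\t{b.rank}\n"
        )
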