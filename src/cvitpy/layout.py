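"""Unit-to-pixel geometry: backbone placement, the affine coordinate
transform, ruler ticks, and greedy label collision handling.

Backbones are drawn as parallel vertical bars, top-aligned, left to
right in input order, all sharing one pixels-per-unit scale so that the
drawn lengths of chromosomes keep their true proportions -- the point of
a whole-genome view.  The scale is auto-fitted so the longest backbone
fills the drawable height unless the config pins ``pixels_per_unit``.

Coordinates are backbone units (bp, cM, ...); the transform is purely
affine: ``y = y_top + (pos - backbone.start) * scale``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .config import RenderConfig
from .gff_io import Backbone

__all__ = [
    "LayoutError",
    "BackboneGeom",
    "LayoutFrame",
    "TickSet",
    "LabelCandidate",
    "PlacedLabel",
    "compute_frame",
    "to_pixel",
    "ruler_ticks",
    "place_labels",
]

#: horizontal room reserved for the ruler gutter when the ruler is on
RULER_GUTTER = 56


class LayoutError(Exception):
    pass


@dataclass
class BackboneGeom:
    seqid: str
    start: float
    end: float
    x_center: int
    y_top: int
    drawn_length: float
    label: str = ""


@dataclass
class LayoutFrame:
    image_width: int
    image_height: int
    margin: int
    top_pad: int
    bottom_pad: int
    scale: float  # pixels per backbone unit, shared by all backbones
    order: list[str]
    geoms: dict[str, BackboneGeom]
    ruler_x: int = 0  # gutter right edge; 0 when no ruler

    def geom(self, seqid: str) -> BackboneGeom:
        try:
            return self.geoms[seqid]
        except KeyError:
            raise LayoutError(f"unknown backbone {seqid!r}") from None


@dataclass
class TickSet:
    """Ruler ticks as offsets from the backbone start, in backbone units."""

    positions: list[float]
    labels: list[str]
    is_major: list[bool]
    step: float


@dataclass
class LabelCandidate:
    text: str
    anchor: tuple[float, float]   # px
    side: str                     # left|right|above|below
    width: int
    height: int
    group: str = ""               # labels collide only within (group, side)


@dataclass
class PlacedLabel:
    text: str
    x1: int
    y1: int
    x2: int
    y2: int
    side: str


def compute_frame(backbones: list[Backbone], config: RenderConfig) -> LayoutFrame:
    """Place backbones and pick the shared unit->pixel scale.

    With ``pixels_per_unit`` left at 0 the scale is chosen so the
    longest backbone exactly fills the drawable height; a fixed scale
    that overflows the image is fatal and the error reports the minimal
    image height that would fit.
    """
    if not backbones:
        raise LayoutError("no backbones to lay out")
    g = config.general
    title_pad = g.font_size + 10 if g.title else 0
    label_pad = g.font_size + 8  # backbone labels above the bars
    top_pad = g.margin + title_pad + label_pad
    bottom_pad = g.margin
    drawable = g.image_height - top_pad - bottom_pad
    if drawable <= 0:
        raise LayoutError(f"image_height {g.image_height} leaves no drawable area")
    max_span = max(b.span for b in backbones)
    if max_span <= 0:
        raise LayoutError("all backbones have zero span")
    if g.pixels_per_unit > 0:
        scale = g.pixels_per_unit
        if max_span * scale > drawable:
            needed = math.ceil(max_span * scale + top_pad + bottom_pad)
            raise LayoutError(
                f"fixed scale {scale} px/unit overflows the image: "
                f"need image_height >= {needed}"
            )
    else:
        scale = drawable / max_span

    gutter = RULER_GUTTER if g.ruler else 0
    needed_width = 2 * g.margin + gutter + len(backbones) * g.chrom_spacing
    image_width = max(g.image_width, needed_width)
    ruler_x = g.margin + gutter if g.ruler else 0

    geoms: dict[str, BackboneGeom] = {}
    order: list[str] = []
    for i, bb in enumerate(backbones):
        x_center = g.margin + gutter + g.chrom_spacing // 2 + i * g.chrom_spacing
        geoms[bb.seqid] = BackboneGeom(
            seqid=bb.seqid,
            start=bb.start,
            end=bb.end,
            x_center=x_center,
            y_top=top_pad,
            drawn_length=bb.span * scale,
            label=bb.label,
        )
        order.append(bb.seqid)
    return LayoutFrame(
        image_width=image_width,
        image_height=g.image_height,
        margin=g.margin,
        top_pad=top_pad,
        bottom_pad=bottom_pad,
        scale=scale,
        order=order,
        geoms=geoms,
        ruler_x=ruler_x,
    )


def to_pixel(frame: LayoutFrame, seqid: str, pos: float) -> tuple[float, float]:
    """Map a backbone-unit coordinate to (x, y) pixels.

    Strictly increasing and linear in ``pos``; the backbone start maps
    to its y_top and the end to y_top + drawn length.  Positions outside
    the backbone span are an error -- validate first.
    """
    geom = frame.geom(seqid)
    if not (geom.start <= pos <= geom.end):
        raise LayoutError(
            f"position {pos} outside backbone {seqid} [{geom.start}, {geom.end}]"
        )
    return (float(geom.x_center), geom.y_top + (pos - geom.start) * frame.scale)


def _nice_step(span: float) -> float:
    """Largest {1,2,5}x10^k step giving 4-10 major ticks over ``span``."""
    best = None
    k_hi = math.ceil(math.log10(span)) + 1
    for k in range(k_hi, k_hi - 8, -1):
        for m in (5, 2, 1):
            step = m * 10.0 ** k
            n = math.floor(span / step + 1e-9) + 1
            if 4 <= n <= 10:
                if best is None or step > best:
                    best = step
    if best is None:  # pathological span; fall back to quarters
        best = span / 4
    return best


def _fmt_tick(v: float) -> str:
    if abs(v - round(v)) < 1e-9:
        return str(int(round(v)))
    return f"{v:g}"


def ruler_ticks(frame: LayoutFrame, config: RenderConfig) -> TickSet:
    """Tick marks over the longest backbone using the 1-2-5 decade rule.

    Positions are offsets from the backbone start (0 at the top), with
    minor ticks at fifths of the major step; labels are bare numbers --
    unit names are the caller's semantics.
    """
    span = max(g.end - g.start for g in frame.geoms.values())
    step = _nice_step(span)
    minor = step / 5.0
    positions: list[float] = []
    labels: list[str] = []
    major_flags: list[bool] = []
    n_minor = math.floor(span / minor + 1e-9)
    for i in range(n_minor + 1):
        pos = i * minor
        if pos > span + 1e-9:
            break
        is_major = i % 5 == 0
        positions.append(min(pos, span))
        labels.append(_fmt_tick(pos) if is_major else "")
        major_flags.append(is_major)
    return TickSet(positions=positions, labels=labels, is_major=major_flags, step=step)


def place_labels(
    candidates: list[LabelCandidate], frame: LayoutFrame, gap: int = 2
) -> tuple[list[PlacedLabel], list[str]]:
    """Greedy downward sweep resolving label collisions.

    Labels start at their preferred side of the anchor; when two boxes
    in the same (group, side) overlap vertically, the later one (by
    anchor y, then input order) is nudged down by the minimal amount.
    Boxes are clamped inside the image; a label that still cannot fit is
    dropped and reported.
    """
    placed: list[PlacedLabel] = []
    dropped: list[str] = []
    indexed = sorted(enumerate(candidates), key=lambda t: (t[1].anchor[1], t[0]))
    last_bottom: dict[tuple[str, str], float] = {}
    for _, cand in indexed:
        ax, ay = cand.anchor
        w, h = cand.width, cand.height
        if cand.side == "right":
            x1 = ax + gap
            y1 = ay - h / 2
        elif cand.side == "left":
            x1 = ax - gap - w
            y1 = ay - h / 2
        elif cand.side == "above":
            x1 = ax - w / 2
            y1 = ay - gap - h
        else:  # below
            x1 = ax - w / 2
            y1 = ay + gap
        x1 = min(max(x1, 0), frame.image_width - w)
        key = (cand.group, cand.side)
        floor_y = last_bottom.get(key)
        if floor_y is not None and y1 < floor_y + gap:
            y1 = floor_y + gap
        y1 = max(y1, 0.0)
        if y1 + h > frame.image_height:
            y1 = frame.image_height - h  # clamp inward from the bottom edge
            if y1 < 0 or (floor_y is not None and y1 < floor_y + gap):
                dropped.append(cand.text)
                continue
        placed.append(
            PlacedLabel(
                text=cand.text,
                x1=int(round(x1)),
                y1=int(round(y1)),
                x2=int(round(x1 + w)),
                y2=int(round(y1 + h)),
                side=cand.side,
            )
        )
        last_bottom[key] = y1 + h
    return placed, dropped
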