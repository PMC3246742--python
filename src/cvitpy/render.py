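"""Raster rendering of backbones, glyphs, histograms and the legend.

Everything is drawn on an RGBA canvas (a thin wrapper over a Pillow
image) with anti-aliasing off by default so repeated runs are
byte-identical.  Draw order is fixed: backbones, then border bands,
centromere overlays, range bars, histogram bars, position dots, marker
ticks, and finally text labels -- later layers paint over earlier ones,
which is what lets a centromere sit on top of its chromosome bar.

Every rendered feature yields one :class:`DrawnFeature` carrying its
pixel bounding box; these feed the coordinate file and HTML image maps.
Features routed to the histogram glyph are the one exception: they are
aggregated into fixed-width bins and each non-empty bin yields one
DrawnFeature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from PIL import Image, ImageDraw, ImageFont

from .config import RGBA, GlyphStyle, RenderConfig, StyleResolver
from .gff_io import Backbone, FeatureCollection, GenomeFeature
from .layout import (
    LabelCandidate,
    LayoutFrame,
    compute_frame,
    place_labels,
    ruler_ticks,
    to_pixel,
)

__all__ = [
    "Canvas",
    "DrawnFeature",
    "HistogramSeries",
    "RenderResult",
    "draw_backbone",
    "draw_centromere",
    "draw_position",
    "draw_range",
    "draw_border",
    "draw_marker",
    "bin_histogram",
    "draw_histogram",
    "build_legend",
    "render",
]

BACKBONE_COLOR: RGBA = (205, 205, 215, 255)
BACKBONE_OUTLINE: RGBA = (120, 120, 130, 255)
TEXT_COLOR: RGBA = (30, 30, 30, 255)
RULER_COLOR: RGBA = (90, 90, 90, 255)
STACK_GAP = 2  # px between stacked glyph columns


class Canvas:
    """Deterministic RGBA drawing surface.

    Wraps ``PIL.Image``; the blend/fill/text primitives here are the
    full drawing contract of the glyph functions, and the outputs module
    serializes the underlying image.
    """

    def __init__(self, width: int, height: int, background: RGBA = (255, 255, 255, 255), antialias: bool = False):
        self.width = int(width)
        self.height = int(height)
        self.antialias = antialias
        self.image = Image.new("RGBA", (self.width, self.height), background)
        self.draw = ImageDraw.Draw(self.image)
        self._fonts: dict[tuple[str, int], ImageFont.ImageFont] = {}

    def font(self, path: str = "", size: int = 10):
        key = (path, size)
        if key not in self._fonts:
            if path:
                try:
                    self._fonts[key] = ImageFont.truetype(path, size)
                except OSError:
                    self._fonts[key] = ImageFont.load_default(size)
            else:
                self._fonts[key] = ImageFont.load_default(size)
        return self._fonts[key]

    def text_size(self, text: str, path: str = "", size: int = 10) -> tuple[int, int]:
        box = self.draw.textbbox((0, 0), text, font=self.font(path, size))
        return (int(math.ceil(box[2] - box[0])), int(math.ceil(box[3] - box[1])))

    def fill_rect(self, box: tuple[int, int, int, int], color: RGBA, rounded: int = 0) -> None:
        """Fill the inclusive pixel box; alpha < 255 blends over what is there."""
        x1, y1, x2, y2 = box
        if x1 > x2 or y1 > y2:
            return
        if color[3] >= 255:
            if rounded > 0:
                self.draw.rounded_rectangle((x1, y1, x2, y2), radius=rounded, fill=color)
            else:
                self.draw.rectangle((x1, y1, x2, y2), fill=color)
            return
        cx1, cy1 = max(x1, 0), max(y1, 0)
        cx2, cy2 = min(x2, self.width - 1), min(y2, self.height - 1)
        if cx1 > cx2 or cy1 > cy2:
            return
        overlay = Image.new("RGBA", (cx2 - cx1 + 1, cy2 - cy1 + 1), color)
        region = self.image.crop((cx1, cy1, cx2 + 1, cy2 + 1))
        self.image.paste(Image.alpha_composite(region, overlay), (cx1, cy1))

    def fill_circle(self, cx: float, cy: float, diameter: int, color: RGBA, outline_only: bool = False) -> None:
        r = diameter / 2.0
        box = (cx - r, cy - r, cx + r - 1, cy + r - 1)
        if self.antialias:
            self._aa_ellipse(box, color, outline_only)
        elif outline_only:
            self.draw.ellipse(box, outline=color)
        else:
            self.draw.ellipse(box, fill=color)

    def _aa_ellipse(self, box, color, outline_only: bool) -> None:
        # 4x supersampling for publication output; off by default
        ss = 4
        x1, y1, x2, y2 = box
        w = int(math.ceil(x2 - x1 + 1)) * ss
        h = int(math.ceil(y2 - y1 + 1)) * ss
        if w <= 0 or h <= 0:
            return
        layer = Image.new("RGBA", (w, h), (0, 0, 0, 0))
        d = ImageDraw.Draw(layer)
        if outline_only:
            d.ellipse((0, 0, w - 1, h - 1), outline=color, width=ss)
        else:
            d.ellipse((0, 0, w - 1, h - 1), fill=color)
        layer = layer.resize((w // ss, h // ss), Image.LANCZOS)
        self.image.alpha_composite(layer, (int(x1), int(y1)))

    def line(self, x1: float, y1: float, x2: float, y2: float, color: RGBA, width: int = 1) -> None:
        self.draw.line((x1, y1, x2, y2), fill=color, width=width)

    def text(self, xy: tuple[float, float], text: str, color: RGBA = TEXT_COLOR, path: str = "", size: int = 10) -> None:
        self.draw.text(xy, text, fill=color, font=self.font(path, size))

    def tobytes(self) -> bytes:
        return self.image.tobytes()


@dataclass
class DrawnFeature:
    """A rendered feature's name and pixel bounding box (inclusive)."""

    name: str
    glyph_kind: str
    box: tuple[int, int, int, int]
    locator: str = ""


@dataclass
class HistogramSeries:
    """Per-bin feature counts for one backbone.

    Bins are half-open ``[start + k*bin, start + (k+1)*bin)`` with the
    last bin truncated at the backbone end; each feature is counted
    once, in the bin holding its midpoint, so the counts sum to the
    number of contributing features.
    """

    seqid: str
    bin_size: float
    counts: list[int]
    max_bar_length: int = 60

    @property
    def total(self) -> int:
        return sum(self.counts)


@dataclass
class RenderResult:
    canvas: Canvas
    legend: Canvas
    drawn: list[DrawnFeature]
    dropped_labels: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# geometry helpers


def _ybox(frame: LayoutFrame, feature: GenomeFeature) -> tuple[int, int]:
    _, ys = to_pixel(frame, feature.seqid, feature.start)
    _, ye = to_pixel(frame, feature.seqid, feature.end)
    return int(round(ys)), int(round(ye))


def _clamp_box(box: tuple[int, int, int, int], canvas: Canvas) -> tuple[int, int, int, int]:
    x1, y1, x2, y2 = box
    return (
        max(0, min(x1, canvas.width - 1)),
        max(0, min(y1, canvas.height - 1)),
        max(0, min(x2, canvas.width - 1)),
        max(0, min(y2, canvas.height - 1)),
    )


def _feature_name(feature: GenomeFeature, index: int) -> str:
    if feature.name:
        return feature.name
    s = int(feature.start) if float(feature.start).is_integer() else feature.start
    e = int(feature.end) if float(feature.end).is_integer() else feature.end
    return f"{feature.seqid}:{s}-{e}:{index}"


def _lateral_box(
    geom_x: int, bar_width: int, offset: int, glyph_width: int, column: int
) -> tuple[int, int]:
    """x-extent of a glyph stacked ``column`` steps outward from the bar.

    ``offset`` is signed distance from the bar edge; its sign picks the
    side (negative = left).
    """
    half = bar_width // 2
    side = -1 if offset < 0 else 1
    base = abs(offset) + column * (glyph_width + STACK_GAP)
    if side < 0:
        x2 = geom_x - half - base
        return (x2 - glyph_width + 1, x2)
    x1 = geom_x + half + base
    return (x1, x1 + glyph_width - 1)


class _ColumnStack:
    """Greedy interval-graph coloring for outward glyph stacking.

    Feed intervals in ascending y1 order; each gets the first column
    whose previous occupant ends above it.
    """

    def __init__(self) -> None:
        self._last_end: list[int] = []

    def assign(self, y1: int, y2: int) -> int:
        for i, last in enumerate(self._last_end):
            if y1 > last:
                self._last_end[i] = y2
                return i
        self._last_end.append(y2)
        return len(self._last_end) - 1


# ---------------------------------------------------------------------------
# glyph drawing


def draw_backbone(canvas: Canvas, frame: LayoutFrame, backbone: Backbone, config: RenderConfig) -> DrawnFeature:
    """Rounded chromosome bar with its label centered above."""
    g = config.general
    geom = frame.geom(backbone.seqid)
    half = g.chrom_width // 2
    y1 = geom.y_top
    y2 = int(round(geom.y_top + geom.drawn_length))
    box = (geom.x_center - half, y1, geom.x_center - half + g.chrom_width - 1, y2)
    radius = min(g.chrom_width // 2, max(1, (y2 - y1) // 2))
    canvas.fill_rect(box, BACKBONE_COLOR, rounded=radius)
    tw, th = canvas.text_size(backbone.label, g.font, g.font_size)
    canvas.text((geom.x_center - tw / 2, y1 - th - 4), backbone.label, path=g.font, size=g.font_size)
    return DrawnFeature(name=backbone.label, glyph_kind="backbone", box=_clamp_box(box, canvas), locator=backbone.seqid)


def draw_centromere(
    canvas: Canvas, frame: LayoutFrame, feature: GenomeFeature, style: GlyphStyle, config: RenderConfig, index: int = 0
) -> DrawnFeature:
    """Rectangle over the bar, overhanging each edge by ``style.overhang``."""
    geom = frame.geom(feature.seqid)
    half = config.general.chrom_width // 2
    y1, y2 = _ybox(frame, feature)
    box = (
        geom.x_center - half - style.overhang,
        y1,
        geom.x_center - half + config.general.chrom_width - 1 + style.overhang,
        y2,
    )
    canvas.fill_rect(box, style.effective_color())
    return DrawnFeature(_feature_name(feature, index), "centromere", _clamp_box(box, canvas), feature.locator())


def draw_position(
    canvas: Canvas, frame: LayoutFrame, feature: GenomeFeature, style: GlyphStyle, config: RenderConfig,
    column: int = 0, index: int = 0,
) -> DrawnFeature:
    """Point glyph (rect, circle or doublecircle) beside the bar at the
    feature midpoint; ``column`` stacks co-located points outward."""
    geom = frame.geom(feature.seqid)
    _, ym = to_pixel(frame, feature.seqid, feature.midpoint)
    ym = int(round(ym))
    d = style.width
    x1, x2 = _lateral_box(geom.x_center, config.general.chrom_width, style.offset, d, column)
    y1 = ym - d // 2
    box = (x1, y1, x1 + d - 1, y1 + d - 1)
    color = style.effective_color()
    if style.shape == "rect":
        canvas.fill_rect(box, color)
    else:
        cx = (x1 + x2 + 1) / 2.0
        canvas.fill_circle(cx, ym, d, color)
        if style.shape == "doublecircle":
            canvas.fill_circle(cx, ym, d + 4, color, outline_only=True)
            box = (x1 - 2, y1 - 2, x1 + d + 1, y1 + d + 1)
    return DrawnFeature(_feature_name(feature, index), "position", _clamp_box(box, canvas), feature.locator())


def draw_range(
    canvas: Canvas, frame: LayoutFrame, feature: GenomeFeature, style: GlyphStyle, config: RenderConfig,
    column: int = 0, index: int = 0,
) -> DrawnFeature:
    """Bar parallel to the backbone spanning the feature's y-extent;
    overlapping ranges on one side go to further columns outward."""
    geom = frame.geom(feature.seqid)
    y1, y2 = _ybox(frame, feature)
    x1, x2 = _lateral_box(geom.x_center, config.general.chrom_width, style.offset, style.width, column)
    box = (x1, y1, x2, y2)
    canvas.fill_rect(box, style.effective_color())
    return DrawnFeature(_feature_name(feature, index), "range", _clamp_box(box, canvas), feature.locator())


def draw_border(
    canvas: Canvas, frame: LayoutFrame, feature: GenomeFeature, style: GlyphStyle, config: RenderConfig, index: int = 0
) -> DrawnFeature:
    """Translucent band across the bar's own width (no overhang)."""
    geom = frame.geom(feature.seqid)
    half = config.general.chrom_width // 2
    y1, y2 = _ybox(frame, feature)
    box = (geom.x_center - half, y1, geom.x_center - half + config.general.chrom_width - 1, y2)
    canvas.fill_rect(box, style.effective_color())
    return DrawnFeature(_feature_name(feature, index), "border", _clamp_box(box, canvas), feature.locator())


def draw_marker(
    canvas: Canvas, frame: LayoutFrame, feature: GenomeFeature, style: GlyphStyle, config: RenderConfig, index: int = 0
) -> DrawnFeature:
    """Short horizontal tick sticking out from the bar edge."""
    geom = frame.geom(feature.seqid)
    _, ym = to_pixel(frame, feature.seqid, feature.midpoint)
    ym = int(round(ym))
    x1, x2 = _lateral_box(geom.x_center, config.general.chrom_width, style.offset, style.tick_length, 0)
    box = (x1, ym, x2, ym)
    canvas.fill_rect(box, style.effective_color())
    return DrawnFeature(_feature_name(feature, index), "marker", _clamp_box(box, canvas), feature.locator())


# ---------------------------------------------------------------------------
# histograms


def bin_histogram(
    features: list[GenomeFeature], backbone: Backbone, bin_size: float, max_bar_length: int = 60
) -> HistogramSeries:
    """Count features per fixed-width bin along one backbone.

    Each feature is counted exactly once, in the half-open bin holding
    its midpoint; the last bin is truncated at the backbone end.
    """
    if bin_size <= 0:
        raise ValueError("bin size must be > 0")
    span = backbone.span
    n_bins = max(1, math.ceil(span / bin_size - 1e-9))
    counts = [0] * n_bins
    for feat in features:
        idx = int((feat.midpoint - backbone.start) // bin_size)
        idx = min(max(idx, 0), n_bins - 1)
        counts[idx] += 1
    return HistogramSeries(seqid=backbone.seqid, bin_size=bin_size, counts=counts, max_bar_length=max_bar_length)


def draw_histogram(
    canvas: Canvas, frame: LayoutFrame, series: HistogramSeries, style: GlyphStyle, config: RenderConfig,
    global_max: int | None = None,
) -> list[DrawnFeature]:
    """One horizontal bar per non-empty bin, length proportional to the
    count over ``global_max`` (shared across all series so densities are
    comparable between chromosomes)."""
    geom = frame.geom(series.seqid)
    peak = global_max if global_max is not None else max(series.counts, default=0)
    drawn: list[DrawnFeature] = []
    if peak <= 0:
        return drawn
    half = config.general.chrom_width // 2
    side = -1 if style.offset < 0 else 1
    base_x = geom.x_center + side * (half + abs(style.offset))
    color = style.effective_color()
    for k, count in enumerate(series.counts):
        if count == 0:
            continue
        lo = geom.start + k * series.bin_size
        hi = min(geom.start + (k + 1) * series.bin_size, geom.end)
        _, y1 = to_pixel(frame, series.seqid, lo)
        _, y2 = to_pixel(frame, series.seqid, hi)
        length = max(1, int(round(count / peak * series.max_bar_length)))
        if side < 0:
            box = (base_x - length + 1, int(round(y1)), base_x, int(round(y2)))
        else:
            box = (base_x, int(round(y1)), base_x + length - 1, int(round(y2)))
        canvas.fill_rect(box, color)
        drawn.append(
            DrawnFeature(
                name=f"{series.seqid}:hist:{k}",
                glyph_kind="histogram",
                box=_clamp_box(box, canvas),
                locator=f"{series.seqid} bin {k} (n={count})",
            )
        )
    return drawn


# ---------------------------------------------------------------------------
# legend


def build_legend(entries: list[tuple[str, str, GlyphStyle]], config: RenderConfig) -> Canvas:
    """Swatch + label rows, one per distinct (glyph kind, class) drawn,
    in first-appearance order, preceded by a backbone row."""
    g = config.general
    row_h = max(18, g.font_size + 8)
    probe = Canvas(10, 10)
    rows: list[tuple[str, RGBA]] = [("backbone", BACKBONE_COLOR)]
    seen: set[tuple[str, str]] = set()
    for kind, cls, style in entries:
        key = (kind, cls)
        if key in seen:
            continue
        seen.add(key)
        label = f"{kind}: {cls}" if cls else kind
        rows.append((label, style.effective_color()))
    width = max(probe.text_size(lbl, g.font, g.font_size)[0] for lbl, _ in rows) + 56
    height = row_h * len(rows) + 16
    legend = Canvas(width, height, g.background, antialias=g.antialias)
    y = 8
    for label, color in rows:
        legend.fill_rect((10, y + 3, 10 + 20, y + row_h - 6), color)
        legend.text((38, y + 2), label, path=g.font, size=g.font_size)
        y += row_h
    return legend


# ---------------------------------------------------------------------------
# full-image rendering


def _draw_title_and_ruler(canvas: Canvas, frame: LayoutFrame, config: RenderConfig) -> None:
    g = config.general
    if g.title:
        tw, _ = canvas.text_size(g.title, g.font, g.font_size + 2)
        canvas.text(((frame.image_width - tw) / 2, g.margin // 2), g.title, path=g.font, size=g.font_size + 2)
    if not g.ruler:
        return
    ticks = ruler_ticks(frame, config)
    x = frame.ruler_x - 6
    longest = max(frame.geoms.values(), key=lambda gm: gm.end - gm.start)
    y0 = longest.y_top
    canvas.line(x, y0, x, y0 + longest.drawn_length, RULER_COLOR)
    for pos, label, major in zip(ticks.positions, ticks.labels, ticks.is_major):
        y = y0 + pos * frame.scale
        tick_len = 5 if major else 2
        canvas.line(x - tick_len, y, x, y, RULER_COLOR)
        if major and label:
            tw, th = canvas.text_size(label, g.font, max(7, g.font_size - 2))
            canvas.text((x - tick_len - tw - 2, y - th / 2), label, RULER_COLOR, g.font, max(7, g.font_size - 2))


def render(collection: FeatureCollection, config: RenderConfig) -> RenderResult:
    """Render a validated collection to genome + legend canvases.

    Styles are resolved in GFF input order (palette determinism), glyphs
    are drawn in the fixed layer order, and each rendered feature (or
    non-empty histogram bin) contributes exactly one DrawnFeature, in
    draw order.
    """
    g = config.general
    resolver = StyleResolver(config)
    styled: list[tuple[GenomeFeature, GlyphStyle, int]] = [
        (feat, resolver.resolve(feat), i) for i, feat in enumerate(collection.features)
    ]
    frame = compute_frame(collection.backbones, config)
    canvas = Canvas(frame.image_width, frame.image_height, g.background, antialias=g.antialias)
    _draw_title_and_ruler(canvas, frame, config)

    drawn: list[DrawnFeature] = []
    legend_entries: list[tuple[str, str, GlyphStyle]] = []
    for bb in collection.backbones:
        drawn.append(draw_backbone(canvas, frame, bb, config))

    by_kind: dict[str, list[tuple[GenomeFeature, GlyphStyle, int]]] = {}
    for feat, style, i in styled:
        by_kind.setdefault(style.kind, []).append((feat, style, i))
        legend_entries.append((style.kind, feat.feature_class or "", style))

    label_candidates: list[LabelCandidate] = []

    def queue_label(feat: GenomeFeature, style: GlyphStyle, box: tuple[int, int, int, int]) -> None:
        if style.label == "none" or not feat.name:
            return
        x1, y1, x2, y2 = box
        anchors = {
            "left": (x1, (y1 + y2) / 2),
            "right": (x2, (y1 + y2) / 2),
            "above": ((x1 + x2) / 2, y1),
            "below": ((x1 + x2) / 2, y2),
        }
        w, h = canvas.text_size(feat.name, g.font, g.font_size)
        label_candidates.append(
            LabelCandidate(feat.name, anchors[style.label], style.label, w, h, group=feat.seqid)
        )

    for feat, style, i in by_kind.get("border", ()):
        d = draw_border(canvas, frame, feat, style, config, index=i)
        drawn.append(d)
        queue_label(feat, style, d.box)
    for feat, style, i in by_kind.get("centromere", ()):
        d = draw_centromere(canvas, frame, feat, style, config, index=i)
        drawn.append(d)
        queue_label(feat, style, d.box)

    # ranges: greedy outward stacking per (backbone, side)
    range_feats = by_kind.get("range", [])
    stacks: dict[tuple[str, int], _ColumnStack] = {}
    for feat, style, i in sorted(range_feats, key=lambda t: (_ybox(frame, t[0])[0], t[2])):
        y1, y2 = _ybox(frame, feat)
        side = -1 if style.offset < 0 else 1
        col = stacks.setdefault((feat.seqid, side), _ColumnStack()).assign(y1, y2)
        d = draw_range(canvas, frame, feat, style, config, column=col, index=i)
        drawn.append(d)
        queue_label(feat, style, d.box)

    # histograms: one series per backbone, normalized to the global peak
    hist_feats = by_kind.get("histogram", [])
    if hist_feats:
        bmap = collection.backbone_map()
        per_seqid: dict[str, list[tuple[GenomeFeature, GlyphStyle, int]]] = {}
        for feat, style, i in hist_feats:
            per_seqid.setdefault(feat.seqid, []).append((feat, style, i))
        series_list: list[tuple[HistogramSeries, GlyphStyle]] = []
        for seqid in frame.order:
            if seqid not in per_seqid:
                continue
            group = per_seqid[seqid]
            style = group[0][1]
            series = bin_histogram([f for f, _, _ in group], bmap[seqid], style.bin_size, style.max_bar_length)
            series_list.append((series, style))
        global_max = max((max(s.counts, default=0) for s, _ in series_list), default=0)
        for series, style in series_list:
            drawn.extend(draw_histogram(canvas, frame, series, style, config, global_max=global_max))

    # positions: outward stacking of co-located points
    pos_feats = by_kind.get("position", [])
    pos_stacks: dict[tuple[str, int], _ColumnStack] = {}
    for feat, style, i in sorted(
        pos_feats, key=lambda t: (int(round(to_pixel(frame, t[0].seqid, t[0].midpoint)[1])), t[2])
    ):
        _, ym = to_pixel(frame, feat.seqid, feat.midpoint)
        ym = int(round(ym))
        h = style.width
        side = -1 if style.offset < 0 else 1
        col = pos_stacks.setdefault((feat.seqid, side), _ColumnStack()).assign(ym - h // 2, ym - h // 2 + h - 1)
        d = draw_position(canvas, frame, feat, style, config, column=col, index=i)
        drawn.append(d)
        queue_label(feat, style, d.box)

    for feat, style, i in by_kind.get("marker", ()):
        d = draw_marker(canvas, frame, feat, style, config, index=i)
        drawn.append(d)
        queue_label(feat, style, d.box)

    placed, dropped = place_labels(label_candidates, frame, gap=g.label_gap)
    for lab in placed:
        canvas.text((lab.x1, lab.y1), lab.text, path=g.font, size=g.font_size)

    legend = build_legend(legend_entries, config)
    return RenderResult(canvas=canvas, legend=legend, drawn=drawn, dropped_labels=dropped)
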