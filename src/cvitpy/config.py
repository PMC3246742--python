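"""Layered rendering configuration and per-feature style resolution.

An INI file (``[section]``, ``key = value``, ``#`` comments) controls
nearly every aspect of the output image: canvas geometry, fonts, the
ruler, and one section per glyph kind (centromere, position, range,
border, marker, histogram) plus ordered ``[override:...]`` sections that
restyle features matched on (source, ftype, class).  Precedence is
CLI ``--set section.key=value`` > file > built-in defaults, and the
resolved :class:`GlyphStyle` for a feature is always fully concrete.

Colors accept the CSS name list and ``#RRGGBB``/``#RRGGBBAA`` hex (both
via Pillow); a feature-level ``color`` GFF attribute beats everything.
Classes without an explicit color draw from a fixed ordered palette of
ten high-contrast colors, assigned by first appearance, cycling when
there are more classes than palette entries.
"""

from __future__ import annotations

import configparser
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from PIL import ImageColor

from .gff_io import GenomeFeature

__all__ = [
    "RGBA",
    "GLYPH_KINDS",
    "PALETTE",
    "ConfigError",
    "GeneralConfig",
    "OverrideRule",
    "RenderConfig",
    "GlyphStyle",
    "StyleResolver",
    "parse_color",
    "load_config",
    "resolve_style",
    "glyph_kind_for",
]

RGBA = tuple[int, int, int, int]

GLYPH_KINDS = ("centromere", "position", "range", "border", "marker", "histogram")

LABEL_PLACEMENTS = ("none", "left", "right", "above", "below")

POSITION_SHAPES = ("rect", "circle", "doublecircle")

#: fixed ordered palette for class coloring (assignment by first appearance)
PALETTE: tuple[RGBA, ...] = tuple(
    ImageColor.getrgb(c) + (255,)
    for c in (
        "#1f77b4",  # blue
        "#ff7f0e",  # orange
        "#2ca02c",  # green
        "#d62728",  # red
        "#9467bd",  # purple
        "#8c564b",  # brown
        "#e377c2",  # pink
        "#7f7f7f",  # grey
        "#bcbd22",  # olive
        "#17becf",  # cyan
    )
)


class ConfigError(Exception):
    """Unusable configuration: bad syntax or an invalid value (named)."""


def parse_color(value: str) -> RGBA:
    """CSS color name or ``#RRGGBB(AA)`` hex to an RGBA tuple."""
    try:
        rgb = ImageColor.getrgb(value.strip())
    except ValueError as exc:
        raise ConfigError(f"unrecognized color {value!r}") from exc
    if len(rgb) == 3:
        return rgb + (255,)
    return rgb  # type: ignore[return-value]


@dataclass
class GeneralConfig:
    """Image-wide options (pixels unless stated otherwise)."""

    image_width: int = 900
    image_height: int = 700
    margin: int = 40
    chrom_spacing: int = 80
    chrom_width: int = 16
    background: RGBA = (255, 255, 255, 255)
    title: str = ""
    font: str = ""          # TrueType path; empty = built-in face
    font_size: int = 10
    ruler: bool = True
    #: fixed pixels-per-unit scale; 0 = auto-fit longest backbone
    pixels_per_unit: float = 0.0
    backbone_types: tuple[str, ...] = ("chromosome",)
    #: span (backbone units) at or below which a feature is point-like
    position_span_threshold: float = 1.0
    label_gap: int = 2
    antialias: bool = False


@dataclass
class GlyphStyle:
    """Concrete drawing options for one glyph kind, post-resolution."""

    kind: str
    color: RGBA
    shape: str = "rect"          # position glyphs only
    width: int = 8               # bar/rect width or point diameter, px
    offset: int = 10             # signed; negative = left of backbone
    label: str = "none"          # none|left|right|above|below
    font: str = ""
    font_size: int = 10
    transparency: float = 1.0    # 0-1 alpha multiplier on the fill
    overhang: int = 4            # centromere: px beyond each bar edge
    tick_length: int = 8         # marker glyph
    bin_size: float = 400_000.0  # histogram: bin width in backbone units
    max_bar_length: int = 60     # histogram: px for the fullest bin

    def effective_color(self) -> RGBA:
        r, g, b, a = self.color
        return (r, g, b, max(0, min(255, round(a * self.transparency))))


#: per-kind built-in defaults, overlaid by file/CLI layers
_GLYPH_DEFAULTS: dict[str, dict[str, object]] = {
    "centromere": dict(color=(0, 0, 0, 255), width=0, offset=0, overhang=4),
    "position": dict(color=None, shape="circle", width=6, offset=12),
    "range": dict(color=None, width=8, offset=-14),
    "border": dict(color=(120, 120, 120, 255), transparency=0.5, offset=0),
    "marker": dict(color=(60, 60, 60, 255), offset=2, tick_length=8),
    "histogram": dict(color=(0, 128, 0, 255), offset=6, bin_size=400_000.0, max_bar_length=60),
}

_STYLE_KEYS = {
    "color": parse_color,
    "shape": str,
    "width": int,
    "offset": int,
    "label": str,
    "font": str,
    "font_size": int,
    "transparency": float,
    "overhang": int,
    "tick_length": int,
    "bin_size": float,
    "max_bar_length": int,
}

_GENERAL_KEYS = {
    "image_width": int,
    "image_height": int,
    "margin": int,
    "chrom_spacing": int,
    "chrom_width": int,
    "background": parse_color,
    "title": str,
    "font": str,
    "font_size": int,
    "ruler": None,  # bool, handled specially
    "pixels_per_unit": float,
    "backbone_types": None,  # comma list
    "position_span_threshold": float,
    "label_gap": int,
    "antialias": None,
}

_BOOL_KEYS = {"ruler", "antialias"}
_TRUE = {"1", "on", "true", "yes"}
_FALSE = {"0", "off", "false", "no"}


@dataclass
class OverrideRule:
    """First matching rule (file order) restyles a feature.

    All stated matchers must hold; an unset matcher matches anything.
    """

    name: str
    source: str | None = None
    ftype: str | None = None
    feature_class: str | None = None
    glyph: str | None = None              # reassign the glyph kind
    options: dict[str, object] = field(default_factory=dict)

    def matches(self, feature: GenomeFeature) -> bool:
        if self.source is not None and feature.source != self.source:
            return False
        if self.ftype is not None and feature.ftype.lower() != self.ftype.lower():
            return False
        if self.feature_class is not None and (feature.feature_class or "") != self.feature_class:
            return False
        return True


@dataclass
class RenderConfig:
    general: GeneralConfig = field(default_factory=GeneralConfig)
    glyph_defaults: dict[str, dict[str, object]] = field(
        default_factory=lambda: {k: dict(v) for k, v in _GLYPH_DEFAULTS.items()}
    )
    overrides: list[OverrideRule] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def validate(self) -> None:
        g = self.general
        if g.pixels_per_unit < 0:
            raise ConfigError("pixels_per_unit must be >= 0 (0 = auto)")
        if g.image_width <= 0 or g.image_height <= 0:
            raise ConfigError("image_width and image_height must be positive")
        for kind, opts in self.glyph_defaults.items():
            if kind not in GLYPH_KINDS:
                raise ConfigError(f"unknown glyph kind {kind!r}")
            t = opts.get("transparency")
            if t is not None and not (0.0 <= float(t) <= 1.0):
                raise ConfigError(f"{kind}.transparency must be in [0, 1]")
            bs = opts.get("bin_size")
            if bs is not None and float(bs) <= 0:
                raise ConfigError(f"{kind}.bin_size must be > 0")
        for rule in self.overrides:
            if rule.glyph is not None and rule.glyph not in GLYPH_KINDS:
                raise ConfigError(f"override {rule.name!r} references unknown glyph kind {rule.glyph!r}")


def _coerce(section: str, key: str, raw: str, warnings: list[str]):
    if section == "general":
        if key not in _GENERAL_KEYS:
            warnings.append(f"unknown key general.{key} ignored")
            return _SKIP
        if key in _BOOL_KEYS:
            low = raw.strip().lower()
            if low in _TRUE:
                return True
            if low in _FALSE:
                return False
            raise ConfigError(f"general.{key}: expected on/off, got {raw!r}")
        if key == "backbone_types":
            return tuple(t.strip() for t in raw.split(",") if t.strip())
        conv = _GENERAL_KEYS[key]
    else:
        if key not in _STYLE_KEYS:
            warnings.append(f"unknown key {section}.{key} ignored")
            return _SKIP
        conv = _STYLE_KEYS[key]
    try:
        value = conv(raw.strip()) if conv is not str else raw.strip()
    except ConfigError:
        raise
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{section}.{key}: invalid value {raw!r}") from exc
    if key == "label" and value not in LABEL_PLACEMENTS:
        raise ConfigError(f"{section}.label must be one of {LABEL_PLACEMENTS}")
    if key == "shape" and value not in POSITION_SHAPES:
        raise ConfigError(f"{section}.shape must be one of {POSITION_SHAPES}")
    return value


_SKIP = object()


def _apply(config: RenderConfig, section: str, key: str, raw: str) -> None:
    value = _coerce(section, key, raw, config.warnings)
    if value is _SKIP:
        return
    if section == "general":
        setattr(config.general, key, value)
    else:
        config.glyph_defaults[section][key] = value


def load_config(path: str | None = None, cli_overrides: Sequence[str] = ()) -> RenderConfig:
    """Build a RenderConfig from defaults, an optional INI file, and CLI
    ``section.key=value`` overrides, in that precedence order (CLI wins).

    Unknown keys are collected as warnings; syntax errors and
    type-invalid values (negative scale, transparency outside [0, 1],
    a bad color) are fatal and name the offending key or line.
    """
    config = RenderConfig()
    if path is not None:
        parser = configparser.ConfigParser(inline_comment_prefixes=("#",), interpolation=None)
        parser.optionxform = str  # keep key case
        try:
            with open(path, "r", encoding="utf-8") as fh:
                parser.read_file(fh, source=path)
        except OSError as exc:
            raise ConfigError(f"cannot read config file {path}: {exc}") from exc
        except configparser.Error as exc:
            raise ConfigError(f"unparsable config file: {exc}") from exc
        for section in parser.sections():
            if section.lower().startswith("override"):
                _load_override(config, section, dict(parser.items(section)))
            elif section == "general" or section in GLYPH_KINDS:
                for key, raw in parser.items(section):
                    _apply(config, section, key, raw)
            else:
                config.warnings.append(f"unknown section [{section}] ignored")
    for item in cli_overrides:
        if "=" not in item or "." not in item.split("=", 1)[0]:
            raise ConfigError(f"override must look like section.key=value, got {item!r}")
        dotted, _, raw = item.partition("=")
        section, _, key = dotted.partition(".")
        if section != "general" and section not in GLYPH_KINDS:
            raise ConfigError(f"unknown section {section!r} in override {item!r}")
        _apply(config, section, key, raw)
    config.validate()
    return config


def _load_override(config: RenderConfig, section: str, items: dict[str, str]) -> None:
    rule = OverrideRule(name=section)
    for key, raw in items.items():
        if key == "source":
            rule.source = raw.strip()
        elif key in ("ftype", "type"):
            rule.ftype = raw.strip()
        elif key == "class":
            rule.feature_class = raw.strip()
        elif key == "glyph":
            rule.glyph = raw.strip()
        else:
            value = _coerce("override", key, raw, config.warnings) if key in _STYLE_KEYS else _SKIP
            if value is _SKIP:
                config.warnings.append(f"unknown key {section}.{key} ignored")
            else:
                rule.options[key] = value
    config.overrides.append(rule)


# ---------------------------------------------------------------------------
# glyph dispatch & style resolution


def glyph_kind_for(feature: GenomeFeature, config: RenderConfig) -> str:
    """Which glyph draws this feature.

    Override rules carrying a ``glyph`` key win (first match); otherwise
    ftype ``centromere`` gets the centromere overlay, spans at or below
    the point threshold get position dots, and everything else is a
    range bar.
    """
    for rule in config.overrides:
        if rule.glyph is not None and rule.matches(feature):
            return rule.glyph
    if feature.ftype.lower() == "centromere":
        return "centromere"
    if feature.span <= config.general.position_span_threshold:
        return "position"
    return "range"


class StyleResolver:
    """Resolves concrete styles, remembering class->palette assignments.

    Palette colors are handed out in first-appearance order of classes,
    cycling modulo the palette length, so identical inputs always get
    identical colors.
    """

    def __init__(self, config: RenderConfig):
        self.config = config
        self.class_colors: dict[str, RGBA] = {}

    def color_for_class(self, cls: str) -> RGBA:
        if cls not in self.class_colors:
            self.class_colors[cls] = PALETTE[len(self.class_colors) % len(PALETTE)]
        return self.class_colors[cls]

    def resolve(self, feature: GenomeFeature) -> GlyphStyle:
        kind = glyph_kind_for(feature, self.config)
        g = self.config.general
        opts: dict[str, object] = dict(self.config.glyph_defaults[kind])
        for rule in self.config.overrides:  # first match wins
            if rule.matches(feature):
                opts.update(rule.options)
                break
        # color precedence: feature attribute > override rule > kind default > class palette
        attr_color = feature.attr("color")
        if attr_color is not None:
            color = parse_color(attr_color)
        elif opts.get("color") is not None:
            color = opts["color"]  # type: ignore[assignment]
        else:
            color = self.color_for_class(feature.feature_class or "")
        style = GlyphStyle(kind=kind, color=color, font=g.font, font_size=g.font_size)
        for k, v in opts.items():
            if k != "color" and v is not None:
                style = replace(style, **{k: v})
        return style


def resolve_style(feature: GenomeFeature, config: RenderConfig) -> GlyphStyle:
    """One-shot resolution sharing a resolver cached on the config."""
    resolver = getattr(config, "_resolver", None)
    if resolver is None:
        resolver = StyleResolver(config)
        config._resolver = resolver  # type: ignore[attr-defined]
    return resolver.resolve(feature)
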