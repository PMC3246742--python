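"""Serialization of the three output files plus the optional image map.

Every successful run writes exactly three files -- the genome PNG, the
legend PNG, and a tab-separated coordinate file mapping each drawn
feature's name to its pixel bounding box.  The coordinate file uses the
same raster convention as the PNG (origin top-left, y down) and is what
web front ends consume to build clickable HTML image maps.

Coordinate file dialect (this implementation's own)::

    #name	x1	y1	x2	y2
    Gm09	42	60	57	640
    ...
"""

from __future__ import annotations

import html
import os
from pathlib import Path

from .render import Canvas, DrawnFeature

__all__ = [
    "OutputError",
    "COORDS_HEADER",
    "write_outputs",
    "read_coords",
    "write_imagemap",
]

COORDS_HEADER = "#name\tx1\ty1\tx2\ty2"


class OutputError(Exception):
    pass


def write_outputs(
    genome: Canvas, legend: Canvas, drawn: list[DrawnFeature], out_prefix: str | os.PathLike
) -> tuple[Path, Path, Path]:
    """Write ``<prefix>.png``, ``<prefix>.legend.png`` and
    ``<prefix>.coords.tsv`` (one row per DrawnFeature, in draw order).

    Returns the three paths; an unwritable location is fatal and names
    the failing path.
    """
    prefix = Path(out_prefix)
    png_path = prefix.with_name(prefix.name + ".png")
    legend_path = prefix.with_name(prefix.name + ".legend.png")
    coords_path = prefix.with_name(prefix.name + ".coords.tsv")
    try:
        prefix.parent.mkdir(parents=True, exist_ok=True)
        genome.image.save(png_path, format="PNG")
        legend.image.save(legend_path, format="PNG")
        lines = [COORDS_HEADER]
        for d in drawn:
            x1, y1, x2, y2 = d.box
            lines.append(f"{d.name}\t{x1}\t{y1}\t{x2}\t{y2}")
        coords_path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    except OSError as exc:
        raise OutputError(f"cannot write output under {prefix}: {exc}") from exc
    return (png_path, legend_path, coords_path)


def read_coords(path: str | os.PathLike) -> list[DrawnFeature]:
    """Parse a coordinate file back into (name, box) records.

    Inverse of the coordinate-file half of :func:`write_outputs`; glyph
    kinds are not stored in the file and come back empty.
    """
    out: list[DrawnFeature] = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line or line.startswith("#"):
            continue
        name, x1, y1, x2, y2 = line.split("\t")
        out.append(DrawnFeature(name=name, glyph_kind="", box=(int(x1), int(y1), int(x2), int(y2))))
    return out


def write_imagemap(drawn: list[DrawnFeature], url_template: str, map_name: str = "cvit") -> str:
    """HTML client-side image map: one ``<area>`` per drawn feature.

    ``url_template`` must contain a ``{name}`` placeholder; names are
    HTML-escaped in both the href and the title.
    """
    if "{name}" not in url_template:
        raise OutputError("url template must contain a {name} placeholder")
    areas = []
    for d in drawn:
        name = html.escape(d.name, quote=True)
        href = html.escape(url_template.format(name=d.name), quote=True)
        x1, y1, x2, y2 = d.box
        areas.append(
            f'  <area shape="rect" coords="{x1},{y1},{x2},{y2}" href="{href}" title="{name}" alt="{name}">'
        )
    body = "\n".join(areas)
    inner = f"\n{body}\n" if areas else "\n"
    return f'<map name="{html.escape(map_name, quote=True)}">{inner}</map>\n'
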