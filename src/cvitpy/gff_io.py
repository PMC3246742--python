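"""GFF3 reading, validation, partitioning and writing.

Every downstream stage consumes the typed records produced here.  The
dialect is standard 9-column GFF3 (tab-delimited, ``.`` for missing
values, ``key=value;`` attribute pairs with percent-encoding of
``;=%&,``) with one deliberate extension: start/end coordinates are kept
as floats so that genetic-map (centimorgan) and cytogenetic
(centiMcClintock) unit systems, which are not integral, pass through
unchanged.  Records are flat -- Parent/ID hierarchies are not resolved,
and an embedded ``##FASTA`` section is skipped.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, TextIO
from urllib.parse import quote, unquote

__all__ = [
    "GenomeFeature",
    "Backbone",
    "FeatureCollection",
    "ValidationReport",
    "GFFError",
    "GFFParseError",
    "parse_gff",
    "partition",
    "validate",
    "write_gff",
]

#: strand values accepted by the GFF3 spec
STRANDS = frozenset({"+", "-", ".", "?"})

#: characters that must be percent-encoded inside attribute values
_ATTR_UNSAFE = ";=%&,\t\n\r"


class GFFError(Exception):
    """Structural problem with GFF data (e.g. no backbone records)."""


class GFFParseError(GFFError):
    """A malformed GFF line; carries the 1-based line number."""

    def __init__(self, line_no: int, message: str):
        self.line_no = line_no
        super().__init__(f"line {line_no}: {message}")


@dataclass
class GenomeFeature:
    """One GFF3 record, backbone or feature alike.

    Coordinates are 1-based inclusive in whatever linear unit the file
    uses (bp, cM, cMC, ...); they are stored as floats and ``start <=
    end`` always holds for parsed records.
    """

    seqid: str
    source: str
    ftype: str
    start: float
    end: float
    score: float | None
    strand: str
    attributes: dict[str, str] = field(default_factory=dict)
    #: provenance only -- excluded from equality so round trips compare clean
    line_no: int | None = field(default=None, compare=False)

    def attr(self, key: str, default: str | None = None) -> str | None:
        """Case-insensitive attribute lookup (``Name``/``name`` both hit)."""
        lk = key.lower()
        for k, v in self.attributes.items():
            if k.lower() == lk:
                return v
        return default

    @property
    def name(self) -> str | None:
        return self.attr("Name")

    @property
    def feature_class(self) -> str | None:
        return self.attr("class")

    @property
    def span(self) -> float:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    def locator(self) -> str:
        """Human-readable handle used in validation and error messages."""
        where = f"line {self.line_no}" if self.line_no is not None else "record"
        return f"{where} ({self.seqid}:{_fmt_num(self.start)}-{_fmt_num(self.end)})"


@dataclass
class Backbone:
    """A drawable chromosome / linkage group / pseudomolecule.

    "Chromosome" is just the default name for the backbone features are
    hung on; any linear stretch with a unit span qualifies.
    """

    seqid: str
    start: float
    end: float
    label: str = ""
    source_record: GenomeFeature | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.label:
            self.label = self.seqid

    @property
    def span(self) -> float:
        return self.end - self.start


@dataclass
class FeatureCollection:
    """Backbones plus features grouped by (glyph kind, class).

    The groups form a partition: every non-backbone record lands in
    exactly one group, so ``len(backbones) + sum(group sizes)`` equals
    the number of parsed records.
    """

    backbones: list[Backbone]
    features: list[GenomeFeature]
    #: (glyph kind, class label) -> features, in first-appearance order
    groups: dict[tuple[str, str], list[GenomeFeature]]

    def backbone_map(self) -> dict[str, Backbone]:
        return {b.seqid: b for b in self.backbones}


@dataclass
class ValidationReport:
    errors: list[tuple[str, str]] = field(default_factory=list)
    warnings: list[tuple[str, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


# ---------------------------------------------------------------------------
# parsing


def _parse_attributes(col9: str, line_no: int) -> dict[str, str]:
    attrs: dict[str, str] = {}
    if col9 in (".", ""):
        return attrs
    for chunk in col9.split(";"):
        if not chunk.strip():
            continue
        if "=" not in chunk:
            raise GFFParseError(line_no, f"attribute without '=': {chunk!r}")
        key, _, value = chunk.partition("=")
        key = unquote(key.strip())
        if not key:
            raise GFFParseError(line_no, f"empty attribute key in {chunk!r}")
        if key in attrs:
            raise GFFParseError(line_no, f"duplicate attribute key {key!r}")
        attrs[key] = unquote(value)
    return attrs


def _parse_number(token: str, line_no: int, what: str) -> float:
    try:
        return float(token)
    except ValueError:
        raise GFFParseError(line_no, f"non-numeric {what}: {token!r}") from None


def parse_gff(stream: str | TextIO | Iterable[str]) -> list[GenomeFeature]:
    """Parse GFF3 text into records, preserving input order.

    ``#`` comment lines and ``##`` directives are skipped; everything
    after a ``##FASTA`` directive is ignored.  Malformed lines raise
    :class:`GFFParseError` naming the line number.  Empty input yields
    an empty list.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    records: list[GenomeFeature] = []
    for line_no, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line.strip():
            continue
        if line.startswith("#"):
            if line.strip().upper() == "##FASTA":
                break
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise GFFParseError(line_no, f"expected 9 tab-separated columns, got {len(cols)}")
        seqid, source, ftype, c_start, c_end, c_score, strand, _phase, col9 = cols
        if not seqid or seqid == ".":
            raise GFFParseError(line_no, "empty seqid")
        start = _parse_number(c_start, line_no, "start")
        end = _parse_number(c_end, line_no, "end")
        if start > end:
            raise GFFParseError(line_no, f"start {c_start} > end {c_end}")
        score = None if c_score == "." else _parse_number(c_score, line_no, "score")
        if strand not in STRANDS:
            raise GFFParseError(line_no, f"bad strand {strand!r}")
        records.append(
            GenomeFeature(
                seqid=seqid,
                source=unquote(source),
                ftype=unquote(ftype),
                start=start,
                end=end,
                score=score,
                strand=strand,
                attributes=_parse_attributes(col9, line_no),
                line_no=line_no,
            )
        )
    return records


# ---------------------------------------------------------------------------
# writing


def _fmt_num(x: float) -> str:
    """Integral floats print as integers so bp files stay conventional."""
    if float(x).is_integer():
        return str(int(x))
    return repr(float(x))


def _encode_attr(value: str) -> str:
    return quote(value, safe="".join(c for c in map(chr, range(33, 127)) if c not in _ATTR_UNSAFE) + " ")


def write_gff(records: Iterable[GenomeFeature]) -> str:
    """Serialize records as GFF3 text; inverse of :func:`parse_gff`.

    ``parse_gff(write_gff(x)) == x`` field-for-field, attribute values
    percent-encoded where GFF3 requires.
    """
    out = ["##gff-version 3"]
    for rec in records:
        if rec.attributes:
            col9 = ";".join(f"{_encode_attr(k)}={_encode_attr(v)}" for k, v in rec.attributes.items())
        else:
            col9 = "."
        out.append(
            "\t".join(
                [
                    rec.seqid,
                    _encode_attr(rec.source) if rec.source else ".",
                    _encode_attr(rec.ftype) if rec.ftype else ".",
                    _fmt_num(rec.start),
                    _fmt_num(rec.end),
                    "." if rec.score is None else _fmt_num(rec.score),
                    rec.strand,
                    ".",
                    col9,
                ]
            )
        )
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# partitioning & validation


def partition(records: list[GenomeFeature], config) -> FeatureCollection:
    """Split parsed records into backbones and glyph/class groups.

    Records whose type is one of the configured backbone types (default
    just ``chromosome``) become :class:`Backbone` objects in input
    order; everything else is grouped by the glyph kind and class the
    config resolves for it.  A file with no backbone record is a fatal
    error: there is nothing to draw features on.
    """
    from .config import glyph_kind_for  # late import to avoid a cycle

    backbone_types = {t.lower() for t in config.general.backbone_types}
    backbones: list[Backbone] = []
    seen: set[str] = set()
    features: list[GenomeFeature] = []
    groups: dict[tuple[str, str], list[GenomeFeature]] = {}
    for rec in records:
        if rec.ftype.lower() in backbone_types:
            if rec.seqid in seen:
                raise GFFError(f"duplicate backbone seqid {rec.seqid!r}")
            seen.add(rec.seqid)
            backbones.append(
                Backbone(
                    seqid=rec.seqid,
                    start=rec.start,
                    end=rec.end,
                    label=rec.name or rec.seqid,
                    source_record=rec,
                )
            )
        else:
            features.append(rec)
            key = (glyph_kind_for(rec, config), rec.feature_class or "")
            groups.setdefault(key, []).append(rec)
    if not backbones:
        raise GFFError("no chromosome records: input must contain at least one backbone")
    return FeatureCollection(backbones=backbones, features=features, groups=groups)


def validate(collection: FeatureCollection, label_kinds: Mapping[str, bool] | None = None) -> ValidationReport:
    """Check that every feature hangs on a known backbone and fits inside it.

    Never raises: every violation is reported, not just the first.
    ``label_kinds`` optionally maps glyph kind -> whether labels were
    requested, to warn about features lacking a Name.
    """
    report = ValidationReport()
    bmap = collection.backbone_map()
    wants_label = label_kinds or {}
    for (kind, _cls), feats in collection.groups.items():
        labelled = wants_label.get(kind, False)
        for feat in feats:
            bb = bmap.get(feat.seqid)
            if bb is None:
                report.errors.append((feat.locator(), f"unknown seqid {feat.seqid!r}: no such backbone"))
                continue
            if feat.start < bb.start or feat.end > bb.end:
                report.errors.append(
                    (
                        feat.locator(),
                        f"feature [{_fmt_num(feat.start)}, {_fmt_num(feat.end)}] outside backbone "
                        f"{bb.seqid} [{_fmt_num(bb.start)}, {_fmt_num(bb.end)}]",
                    )
                )
            if labelled and feat.name is None:
                report.warnings.append((feat.locator(), "label requested but record has no Name"))
    return report
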