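"""BLAST add-on converters: tabular hits to displayable GFF, and
sliding-window collapsing of adjacent HSPs.

``blast_to_gff`` lifts protein/transcript-space BLAST results onto
genome coordinates by joining the subject (peptide) id against a GFF
file of peptide gene locations; alternatively a two-column query-id to
peptide-id map can drive the join directly.  ``cluster_hsps`` merges
runs of HSPs from the same query on the same backbone whenever the gap
between consecutive intervals (next start minus previous end) is within
the window -- single-linkage chaining on the start-sorted list, which is
the order-independent reading of "adjacent within a sliding window" and
gives idempotent, window-monotone output.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable, TextIO

from .gff_io import GenomeFeature

__all__ = [
    "BlastHit",
    "ConverterError",
    "parse_blast_tabular",
    "parse_idmap",
    "blast_to_gff",
    "cluster_hsps",
]


class ConverterError(Exception):
    pass


@dataclass
class BlastHit:
    """One row of 12-column NCBI BLAST tabular output (``-outfmt 6``).

    Subject coordinates arrive inverted for minus-strand nucleotide
    hits; they are normalised to ``subject_start <= subject_end`` with
    the orientation kept in :attr:`subject_strand`.
    """

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    evalue: float
    bit_score: float
    subject_strand: str = "+"


def parse_blast_tabular(stream: str | TextIO | Iterable[str]) -> list[BlastHit]:
    """Parse BLAST ``-outfmt 6`` rows; ``#`` comment lines are skipped."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    hits: list[BlastHit] = []
    for line_no, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 12:
            raise ConverterError(f"line {line_no}: expected 12 tab-separated columns, got {len(cols)}")
        try:
            s_start, s_end = int(cols[8]), int(cols[9])
            strand = "+"
            if s_start > s_end:
                s_start, s_end = s_end, s_start
                strand = "-"
            hits.append(
                BlastHit(
                    query_id=cols[0],
                    subject_id=cols[1],
                    percent_identity=float(cols[2]),
                    alignment_length=int(cols[3]),
                    mismatches=int(cols[4]),
                    gap_opens=int(cols[5]),
                    query_start=int(cols[6]),
                    query_end=int(cols[7]),
                    subject_start=s_start,
                    subject_end=s_end,
                    evalue=float(cols[10]),
                    bit_score=float(cols[11]),
                    subject_strand=strand,
                )
            )
        except ValueError as exc:
            raise ConverterError(f"line {line_no}: bad numeric field: {exc}") from exc
    return hits


def parse_idmap(stream: str | TextIO | Iterable[str]) -> list[tuple[str, str]]:
    """Two-column whitespace/tab-delimited query-id -> peptide-id pairs."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    pairs: list[tuple[str, str]] = []
    for line_no, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split()
        if len(cols) != 2 or not cols[0] or not cols[1]:
            raise ConverterError(f"line {line_no}: expected two non-empty columns")
        pairs.append((cols[0], cols[1]))
    return pairs


def _peptide_index(peptides: Iterable[GenomeFeature]) -> dict[str, list[GenomeFeature]]:
    index: dict[str, list[GenomeFeature]] = {}
    for pep in peptides:
        key = pep.name or pep.attr("ID")
        if key:
            index.setdefault(key, []).append(pep)
    return index


def blast_to_gff(
    peptides: list[GenomeFeature],
    hits: list[BlastHit] | None = None,
    idmap: list[tuple[str, str]] | None = None,
    source: str = "blast",
) -> tuple[list[GenomeFeature], int]:
    """Lift BLAST hits (or id pairs) onto genome coordinates.

    Each hit whose subject id matches a located peptide (by ``Name`` or
    ``ID``) becomes one feature at the peptide's seqid/start/end with
    ``Name`` and ``class`` set to the query id; for BLAST input the
    e-value rides in the score column so significance can drive display
    color.  Returns (features, skipped count of unmatched subjects);
    zero matches overall is an error pointing at id-format mismatch.
    """
    if (hits is None) == (idmap is None):
        raise ConverterError("provide exactly one of BLAST hits or an id map")
    index = _peptide_index(peptides)
    out: list[GenomeFeature] = []
    skipped = 0
    pairs: list[tuple[str, str, float | None, str]] = []
    if hits is not None:
        for h in hits:
            pairs.append((h.query_id, h.subject_id, h.evalue, h.subject_strand))
    else:
        for q, p in idmap:  # type: ignore[union-attr]
            pairs.append((q, p, None, "."))
    for query, subject, evalue, strand in pairs:
        located = index.get(subject)
        if not located:
            skipped += 1
            continue
        for pep in located:
            out.append(
                GenomeFeature(
                    seqid=pep.seqid,
                    source=source,
                    ftype="match",
                    start=pep.start,
                    end=pep.end,
                    score=evalue,
                    strand=strand if strand != "." else pep.strand,
                    attributes={"Name": query, "class": query},
                )
            )
    if not out:
        raise ConverterError(
            "zero matches: no BLAST subject id matched a located peptide "
            "(check that subject ids and peptide Name/ID attributes use the same format)"
        )
    return out, skipped


def cluster_hsps(features: list[GenomeFeature], window: float) -> list[GenomeFeature]:
    """Collapse adjacent HSPs within a gap window.

    Within each (seqid, Name) group, features are sorted by start and a
    run is chained while ``next.start - prev.end <= window``; each run
    becomes one feature from the run's min start to max end.  The merged
    feature keeps the group's Name/class, carries ``hsp_count`` (the sum
    of members' counts, so re-clustering is a no-op), and its score is
    the members' best (minimum) e-value when scores are present.
    Different queries or backbones never merge.
    """
    if window < 0:
        raise ConverterError("window must be >= 0")
    groups: dict[tuple[str, str], list[GenomeFeature]] = {}
    for feat in features:
        groups.setdefault((feat.seqid, feat.name or ""), []).append(feat)
    out: list[GenomeFeature] = []
    for (seqid, name), members in sorted(groups.items()):
        members = sorted(members, key=lambda f: (f.start, f.end))
        run: list[GenomeFeature] = [members[0]]
        for feat in members[1:]:
            if feat.start - max(m.end for m in run) <= window:
                run.append(feat)
            else:
                out.append(_merge_run(run, seqid, name))
                run = [feat]
        out.append(_merge_run(run, seqid, name))
    return out


def _merge_run(run: list[GenomeFeature], seqid: str, name: str) -> GenomeFeature:
    first = run[0]
    scores = [f.score for f in run if f.score is not None]
    count = sum(int(f.attr("hsp_count") or 1) for f in run)
    strands = {f.strand for f in run}
    attrs = {k: v for k, v in first.attributes.items() if k.lower() != "hsp_count"}
    if name and not any(k.lower() == "name" for k in attrs):
        attrs["Name"] = name
    attrs["hsp_count"] = str(count)
    return GenomeFeature(
        seqid=seqid,
        source=first.source,
        ftype=first.ftype,
        start=min(f.start for f in run),
        end=max(f.end for f in run),
        score=min(scores) if scores else None,  # e-value 0.0 is best
        strand=strands.pop() if len(strands) == 1 else ".",
        attributes=attrs,
    )
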