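"""Seeded synthetic genome generator with built-in ground truth.

Emulates the data shapes the viewer exists for -- chromosomes with
centromeres, gene sets whose density dips around the pericentromere,
synteny blocks colored by partner chromosome, and chained BLAST HSPs --
without simulating any sequence content: coordinates and counts only.
Every quantity a downstream assertion needs (per-chromosome feature
counts, gene midpoints for arbitrary re-binning, the expected
post-clustering interval for each HSP chain) is recorded in a
:class:`Truth` object at generation time, so tests never have to trust
the code paths they are checking.

The defaults sketch a maize-sized genome (10 chromosomes of 150-300
megabase units) scaled to a few hundred genes per chromosome so whole
suites run in seconds; the same generator scales to thousands of
features by raising the counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .gff_io import GenomeFeature, write_gff

__all__ = ["GenomeSpec", "ChainTruth", "Truth", "FixtureData", "generate"]


@dataclass
class GenomeSpec:
    n_chromosomes: int = 10
    span_range: tuple[float, float] = (150e6, 300e6)
    centromere_frac_range: tuple[float, float] = (0.35, 0.65)
    #: centromere length as a fraction of the chromosome span
    centromere_len_frac: float = 0.05
    genes_per_chromosome: int = 300
    density: str = "pericentromere_depleted"  # or "uniform"
    n_synteny_blocks: int = 30
    n_queries: int = 5
    hits_per_query: tuple[int, int] = (2, 6)
    #: gap between consecutive HSPs in a chain, backbone units
    gap_range: tuple[float, float] = (1_000, 50_000)
    hsp_len_range: tuple[float, float] = (200, 2_000)
    #: fraction of BLAST rows pointing at a peptide with no known location
    unmatched_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chromosomes <= 0:
            raise ValueError("need at least one chromosome")
        if self.density not in ("uniform", "pericentromere_depleted"):
            raise ValueError(f"unknown density profile {self.density!r}")


@dataclass
class ChainTruth:
    """Expected merge result for one HSP chain at any window.

    Clustering at window >= max_gap collapses the chain to exactly
    [start, end]; window < min_gap leaves all n_hsps intervals apart.
    """

    seqid: str
    query: str
    start: float
    end: float
    n_hsps: int
    max_gap: float
    min_gap: float


@dataclass
class Truth:
    seed: int
    chrom_spans: dict[str, tuple[float, float]]
    per_chrom_counts: dict[str, dict[str, int]]
    gene_midpoints: dict[str, list[float]]
    chains: list[ChainTruth]
    blast_matched: int
    blast_skipped: int

    def gene_bin_counts(self, seqid: str, bin_size: float) -> list[int]:
        """Expected histogram counts from the recorded gene midpoints."""
        start, end = self.chrom_spans[seqid]
        n_bins = max(1, int(np.ceil((end - start) / bin_size - 1e-9)))
        counts = [0] * n_bins
        for mid in self.gene_midpoints[seqid]:
            idx = min(int((mid - start) // bin_size), n_bins - 1)
            counts[idx] += 1
        return counts

    def to_tsv(self) -> str:
        lines = [f"#seed\t{self.seed}"]
        for seqid, (s, e) in self.chrom_spans.items():
            c = self.per_chrom_counts[seqid]
            lines.append(
                f"chrom\t{seqid}\t{s:g}\t{e:g}\t{c.get('gene', 0)}\t{c.get('synteny', 0)}\t{c.get('centromere', 0)}"
            )
        for ch in self.chains:
            lines.append(
                f"chain\t{ch.seqid}\t{ch.query}\t{ch.start:g}\t{ch.end:g}\t{ch.n_hsps}\t{ch.max_gap:g}\t{ch.min_gap:g}"
            )
        lines.append(f"blast\t{self.blast_matched}\t{self.blast_skipped}")
        return "\n".join(lines) + "\n"


@dataclass
class FixtureData:
    backbone_gff: str
    feature_gff: str
    blast_tabular: str
    idmap: str
    truth: Truth
    #: chained HSPs as GFF features, ready for cluster_hsps
    hsp_gff: str = ""
    backbone_records: list[GenomeFeature] = field(default_factory=list)
    feature_records: list[GenomeFeature] = field(default_factory=list)
    hsp_records: list[GenomeFeature] = field(default_factory=list)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "backbones": outdir / "backbones.gff3",
            "features": outdir / "features.gff3",
            "hsps": outdir / "hsps.gff3",
            "blast": outdir / "hits.blast.tsv",
            "idmap": outdir / "idmap.tsv",
            "truth": outdir / "truth.tsv",
        }
        paths["backbones"].write_text(self.backbone_gff, encoding="utf-8")
        paths["features"].write_text(self.feature_gff, encoding="utf-8")
        paths["hsps"].write_text(self.hsp_gff, encoding="utf-8")
        paths["blast"].write_text(self.blast_tabular, encoding="utf-8")
        paths["idmap"].write_text(self.idmap, encoding="utf-8")
        paths["truth"].write_text(self.truth.to_tsv(), encoding="utf-8")
        return paths


def _sample_gene_midpoint(rng: np.random.Generator, span: float, cen_mid: float, density: str) -> float:
    """Rejection-sample a midpoint; the depleted profile thins a window
    of +/-15% of the span around the centromere to a fifth."""
    while True:
        mid = float(rng.uniform(0.02 * span, 0.98 * span))
        if density == "uniform":
            return mid
        if abs(mid - cen_mid) > 0.15 * span or rng.random() < 0.2:
            return mid


def generate(spec: GenomeSpec) -> FixtureData:
    """Build the full fixture set for one genome spec.

    Deterministic for a given seed; the generated GFF always validates
    cleanly (every feature inside its chromosome).
    """
    rng = np.random.default_rng(spec.seed)
    backbone_records: list[GenomeFeature] = []
    feature_records: list[GenomeFeature] = []
    chrom_spans: dict[str, tuple[float, float]] = {}
    per_chrom: dict[str, dict[str, int]] = {}
    gene_midpoints: dict[str, list[float]] = {}
    cen_mid_by_chrom: dict[str, float] = {}
    seqids: list[str] = []

    for i in range(spec.n_chromosomes):
        seqid = f"chr{i + 1:02d}"
        seqids.append(seqid)
        span = float(np.floor(rng.uniform(*spec.span_range)))
        backbone_records.append(
            GenomeFeature(seqid, "fixture", "chromosome", 1.0, span, None, ".", {"Name": seqid})
        )
        chrom_spans[seqid] = (1.0, span)
        per_chrom[seqid] = {"gene": 0, "synteny": 0, "centromere": 0}
        gene_midpoints[seqid] = []

        cen_frac = float(rng.uniform(*spec.centromere_frac_range))
        cen_len = spec.centromere_len_frac * span
        cen_start = max(1.0, np.floor(cen_frac * span - cen_len / 2))
        cen_end = min(span, np.floor(cen_start + cen_len))
        cen_mid_by_chrom[seqid] = (cen_start + cen_end) / 2
        feature_records.append(
            GenomeFeature(
                seqid, "fixture", "centromere", cen_start, cen_end, None, ".",
                {"Name": f"{seqid}_cen", "class": "centromere"},
            )
        )
        per_chrom[seqid]["centromere"] += 1

    gene_no = 0
    for seqid in seqids:
        start, span = chrom_spans[seqid][0], chrom_spans[seqid][1]
        for _ in range(spec.genes_per_chromosome):
            mid = _sample_gene_midpoint(rng, span, cen_mid_by_chrom[seqid], spec.density)
            length = float(np.floor(rng.uniform(1_000, 5_000)))
            g_start = max(start, np.floor(mid - length / 2))
            g_end = min(span, np.floor(g_start + length))
            gene_no += 1
            name = f"g{gene_no:05d}"
            feature_records.append(
                GenomeFeature(
                    seqid, "fixture", "gene", g_start, g_end, None,
                    "+" if rng.random() < 0.5 else "-",
                    {"Name": name, "class": "gene"},
                )
            )
            gene_midpoints[seqid].append((g_start + g_end) / 2)
            per_chrom[seqid]["gene"] += 1

    for b in range(spec.n_synteny_blocks):
        seqid = seqids[int(rng.integers(len(seqids)))]
        partner = seqids[int(rng.integers(len(seqids)))]
        span = chrom_spans[seqid][1]
        length = float(np.floor(rng.uniform(0.02, 0.08) * span))
        s = float(np.floor(rng.uniform(1, span - length)))
        feature_records.append(
            GenomeFeature(
                seqid, "fixture", "synteny", s, np.floor(s + length), None, ".",
                {"Name": f"blk{b + 1:03d}", "class": partner},
            )
        )
        per_chrom[seqid]["synteny"] += 1

    # BLAST HSP chains with known extents and gaps
    hsp_records: list[GenomeFeature] = []
    chains: list[ChainTruth] = []
    blast_rows: list[str] = []
    idmap_rows: list[str] = []
    matched = 0
    skipped = 0
    gene_records = [f for f in feature_records if f.ftype == "gene"]
    for q in range(spec.n_queries):
        query = f"q{q + 1:03d}"
        seqid = seqids[int(rng.integers(len(seqids)))]
        span = chrom_spans[seqid][1]
        n_hsps = int(rng.integers(spec.hits_per_query[0], spec.hits_per_query[1] + 1))
        pos = float(np.floor(rng.uniform(0.05, 0.6) * span))
        gaps: list[float] = []
        chain_start = pos
        qpos = 1
        for h in range(n_hsps):
            length = float(np.floor(rng.uniform(*spec.hsp_len_range)))
            end = min(span, np.floor(pos + length))
            hsp_records.append(
                GenomeFeature(
                    seqid, "blast", "match_part", pos, end,
                    float(10.0 ** -rng.uniform(5, 50)), "+",
                    {"Name": query, "class": query},
                )
            )
            chain_end = end
            if h < n_hsps - 1:
                gap = float(np.floor(rng.uniform(*spec.gap_range)))
                gaps.append(gap)
                pos = end + gap
            qpos += int(length)
        chains.append(
            ChainTruth(
                seqid=seqid,
                query=query,
                start=chain_start,
                end=chain_end,
                n_hsps=n_hsps,
                max_gap=max(gaps) if gaps else 0.0,
                min_gap=min(gaps) if gaps else 0.0,
            )
        )
        # BLAST tabular + id map against located genes (the peptide file)
        target = gene_records[int(rng.integers(len(gene_records)))] if gene_records else None
        if target is None or rng.random() < spec.unmatched_fraction:
            subject = f"missing_pep{q:03d}"
            skipped += 1
        else:
            subject = target.name or "g00001"
            matched += 1
        alen = int(rng.integers(80, 400))
        blast_rows.append(
            "\t".join(
                [
                    query, subject, f"{rng.uniform(70, 100):.2f}", str(alen),
                    str(int(rng.integers(0, 30))), str(int(rng.integers(0, 5))),
                    "1", str(alen), "1", str(alen),
                    f"{10.0 ** -rng.uniform(5, 50):.2e}", f"{rng.uniform(50, 500):.1f}",
                ]
            )
        )
        idmap_rows.append(f"{query}\t{subject}")

    truth = Truth(
        seed=spec.seed,
        chrom_spans=chrom_spans,
        per_chrom_counts=per_chrom,
        gene_midpoints=gene_midpoints,
        chains=chains,
        blast_matched=matched,
        blast_skipped=skipped,
    )
    return FixtureData(
        backbone_gff=write_gff(backbone_records),
        feature_gff=write_gff(feature_records),
        blast_tabular="\n".join(blast_rows) + ("\n" if blast_rows else ""),
        idmap="\n".join(idmap_rows) + ("\n" if idmap_rows else ""),
        truth=truth,
        hsp_gff=write_gff(hsp_records),
        backbone_records=backbone_records,
        feature_records=feature_records,
        hsp_records=hsp_records,
    )
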