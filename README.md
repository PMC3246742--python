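# cvitpy — whole-genome-at-a-time visualization from GFF3

`cvitpy` draws all the chromosomes of a genome side by side in a single
raster image, with annotated features rendered as glyphs on and beside
each chromosome bar. It is aimed at the genome-scale questions a
per-region browser cannot answer at a glance: where are the gene-rich
and gene-poor regions, where do internal duplication (synteny) blocks
fall, how do BLAST hits distribute over a whole assembly, where are the
centromeres. Typical users are genome-project and comparative-genomics
groups who need publication images and clickable overview pages.

Input is plain GFF3. One or more records of type `chromosome` (or any
configured backbone type — `linkage_group`, `pseudomolecule`, ...)
define the *backbones*; every other record is a feature tied to a
backbone by its `seqid` column, named with the `Name` attribute and
color-grouped with the `class` attribute. Coordinates can be in **any
linear unit** — base pairs, centimorgans, centiMcClintocks, microns —
because every drawing operation reduces to one shared affine map:

    y(pos) = y_top + (pos − start) · s

with a single pixels-per-unit scale *s* chosen so the longest backbone
fills the drawable height (or pinned in config). Shared scale means
drawn lengths stay proportional to unit spans across chromosomes.

Six glyph kinds cover the standard displays: `centromere` (black
rectangle over the bar), `position` (point marks), `range` (bars beside
the backbone, e.g. synteny blocks), `border`, `marker`, and `histogram`
— fixed-width bin counts (e.g. genes per 400 kbp) drawn as bars whose
lengths are normalized to the global maximum so densities compare across
chromosomes. Every run writes exactly three files: the genome PNG, a
legend PNG, and a TSV of feature names with pixel bounding boxes for
building interactive image maps. Converters are included for turning
12-column tabular BLAST output into displayable GFF (`blast2gff`) and
for collapsing adjacent HSPs of one query within a gap window
(`clusterhsp`).

## Worked example

Generate a small synthetic genome (3 chromosomes, centromeres, genes,
synteny blocks) and render it:

```python
from cvitpy import GenomeSpec, generate

fx = generate(GenomeSpec(n_chromosomes=3, genes_per_chromosome=40,
                         n_synteny_blocks=6, seed=1))
open("bb.gff3", "w").write(fx.backbone_gff)
open("ft.gff3", "w").write(fx.feature_gff)
```

```bash
$ cvit draw -o demo bb.gff3 ft.gff3
[INFO] done: 132 drawn features
```

132 drawn features = 3 chromosome bars + 3 centromeres + 120 genes + 6
synteny blocks. Three files appear — `demo.png`, `demo.legend.png`,
`demo.coords.tsv` — and the coordinate file starts:

```
#name	x1	y1	x2	y2
chr01	128	58	143	660
chr02	208	58	223	514
chr03	288	58	303	580
chr01_cen	124	425	147	455
```

Each row is one drawn feature's pixel bounding box (origin top-left, y
down, identical to the PNG): `chr01` spans 602 px of height while
`chr02` spans 456 px — the same ratio as their unit spans, because the
scale is shared — and the centromere rectangle `chr01_cen` is 4 px wider
on each side than the bar it overlays. Add `--imagemap --url-template
'search?f={name}'` for a ready-made HTML `<map>` fragment.

A gene-density view needs only a config that routes genes to the
histogram glyph:

```ini
[override:density]
ftype = gene
glyph = histogram

[histogram]
bin_size = 400000
```

```bash
cvit draw -c density.ini -o density bb.gff3 ft.gff3
```

BLAST workflow, composable through files or pipes:

```bash
cvit blast2gff -b hits.tsv -p peptides.gff3 -o lifted.gff3
cvit clusterhsp -w 50000 lifted.gff3 -o merged.gff3
cvit draw -o genome bb.gff3 merged.gff3
```

Exit codes are stable: 0 success, 1 I/O problems, 2 data validation
(out-of-bounds features, no chromosome records, zero BLAST matches).

## Documentation

`docs/methods.md` describes the geometry model, glyph dispatch and
styling precedence, the histogram and clustering definitions, what the
synthetic-data generator does and does not emulate, and known
limitations.
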