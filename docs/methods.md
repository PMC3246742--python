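# Methods

## What the package computes

`cvitpy` renders an arbitrary set of linear "backbones" — chromosomes,
linkage groups, pseudomolecules, BACs or contigs — side by side with the
features annotated on them, from plain GFF3. The design goal is the
whole-genome-at-a-time view: all backbones in one raster image at one
shared scale, so genome-wide patterns (gene density, duplication blocks,
centromere positions, BLAST hit clustering) are visible at a glance.
Close-up, interactive inspection of single regions is deliberately left
to genome browsers.

The unit system is not assumed: coordinates are stored as floats, so
base pairs, centimorgans, centiMcClintocks or microns all work, and a
backbone's unit span is whatever its GFF record says. All geometry
reduces to one affine map per backbone,

    y(pos) = y_top + (pos − start) · s,   x(pos) = x_center,

with a single pixels-per-unit scale `s` shared by every backbone. By
default `s` is chosen so the longest backbone exactly fills the drawable
height (image height minus margins and label/title pads); setting
`general.pixels_per_unit` pins it instead, and an overflowing pinned
scale is a hard error that reports the minimal image height that would
fit. Backbones are vertical, top-aligned, and ordered left to right by
input order. Top alignment and a shared (rather than per-backbone) scale
were open choices; both were picked because they keep drawn lengths
proportional to unit spans, which is the property the whole-genome view
exists to show.

## Input contract and validation

GFF3 records are flat: column 1 ties a feature to its backbone, columns
4–5 are 1-based inclusive coordinates, and column 9 carries `Name`
(display label), `class` (color grouping) and optionally `color`
(explicit override). `Name`/`name` and `class`/`Class` are matched
case-insensitively because real files mix the cases. Records whose type
is a configured backbone type (default `chromosome`; `linkage_group`
etc. can be added) become backbones; everything else must land on a
known backbone and lie inside its span. Validation reports *every*
violation rather than stopping at the first, and a file with no backbone
record is fatal — there is nothing to draw on. Duplicate backbone seqids
are treated as an error rather than last-wins; the format gives no
guidance here and an error is the safer reading. `##FASTA` sections are
skipped, Parent/ID hierarchies are not resolved, and unknown attributes
round-trip untouched.

## Glyphs and styling

Six glyph kinds cover the figures this kind of tool produces:

| kind       | geometry                                              | default |
|------------|-------------------------------------------------------|---------|
| centromere | rectangle over the bar, 4 px overhang per side        | black   |
| position   | point (rect/circle/doublecircle), 6 px, at midpoint   | palette |
| range      | bar beside the backbone spanning the feature          | palette |
| border     | translucent band across the bar width                 | grey, α 0.5 |
| marker     | 8 px tick off the bar edge                            | dark grey |
| histogram  | per-bin horizontal bars (see below)                   | green   |

Dispatch: ftype `centromere` → centromere; span ≤ 1 unit → position
(unit-agnostic, so it behaves for both bp and cM data); everything else
→ range. `[override:*]` config sections matched on (source, ftype,
class) can reassign the glyph and restyle it; the first matching rule in
file order wins. A feature-level `color` attribute beats everything;
otherwise classes draw from a fixed, ordered 10-color palette assigned
by first appearance in the input, cycling past ten classes — that makes
color assignment a pure function of the input file, hence reproducible.
Transparency is a 0–1 multiplier on the fill alpha.

Configuration is layered INI: built-in defaults, then the file, then
repeatable CLI `--set section.key=value` overrides; unknown keys warn
instead of failing so configs survive version skew. Colors accept the
CSS name list and `#RRGGBB(AA)` hex. Fonts: the default face is the
renderer's built-in scalable font; any TrueType path can be configured,
with a warn-and-fallback when unreadable. The option vocabulary is this
package's own and is not claimed file-compatible with other tools'
configs.

## Histograms

Density display bins features into fixed-width bins, half-open
`[start + k·b, start + (k+1)·b)` with the last bin truncated at the
backbone end (`⌈span/b⌉` bins). A feature is counted once, in the bin
containing its midpoint — not once per overlapped bin — so bin counts
always sum to the feature count, a conservation law the tests check
against a brute-force counter. The default bin size is 400,000 units,
the gene-density configuration the tool's canonical use case calls for;
it is a plain config key (`histogram.bin_size`) and should be changed
for non-bp unit systems. Bar lengths are normalized to the global
maximum bin count across all chromosomes in the image, not
per-chromosome, so bars are comparable between chromosomes; that is the
point of the display and was an open choice, made once and documented
here.

## Layout details

Ruler ticks use the standard 1-2-5 decade rule: the largest step of the
form {1,2,5}·10^k giving between 4 and 10 major ticks over the longest
backbone, with minor ticks at fifths. Tick positions are offsets from
the backbone start (0 at the top), which keeps the ruler meaningful for
backbones that do not start at 1. The ruler is optional
(`general.ruler = off`).

Overlapping glyphs stack outward in columns: greedy interval-graph
coloring on the start-sorted boxes, per backbone and side, with a 2 px
gap. Labels are resolved by a single greedy downward sweep — the later
label (by anchor y, then input order) is nudged down minimally, clamped
inside the image, and dropped with a warning when it cannot fit. No
leader lines; at whole-genome densities the sweep is adequate and it is
deterministic.

Draw order is fixed: backbones → borders → centromeres → ranges →
histograms → positions → markers → labels. Later layers paint over
earlier ones, which is what puts centromere rectangles on top of the
chromosome bars.

## Outputs and determinism

Each run writes exactly three files — genome PNG, legend PNG, and a TSV
coordinate file (`#name  x1  y1  x2  y2`, top-left origin, y down, same
convention as the PNG) with one row per drawn feature in draw order.
Features without a `Name` get synthesized ids `seqid:start-end:k` so the
coordinate file is total. The legend contains one swatch row per
distinct (glyph kind, class) actually drawn, in first-appearance order.
An HTML image map (one `<area>` per row) is an optional fourth output
behind `--imagemap`. Anti-aliasing is off by default so two runs on the
same inputs are byte-identical; a config flag re-enables it for
publication output at the cost of that guarantee.

## Converters

`blast2gff` lifts protein/transcript-space BLAST results onto genome
coordinates by joining the 12-column tabular subject id against a GFF of
peptide locations (`Name` or `ID`), or by a two-column query→peptide id
map; each match emits one feature at the peptide's location with
`Name`/`class` set to the query id and the e-value in the score column
(e-value, not bit score, because significance is what display coloring
keys on; 0.0 sorts as best). Inverted subject coordinates are normalized
with strand `-`. Unmatched subjects are skipped and counted; zero
matches overall is an error, since it almost always means an id-format
mismatch.

`clusterhsp` collapses adjacent HSPs of one query: within each (seqid,
Name) group, sorted by start, a run is chained while the gap (next start
minus the running max end) is ≤ the window, and each run merges into one
feature with `hsp_count` and the members' best e-value. "Adjacent within
a sliding window" was formalized as this gap-threshold single linkage
because it is the order-independent reading; the window measures the
*gap*, not start-to-start distance. `hsp_count` sums members' existing
counts so re-clustering is a no-op — the operation is idempotent,
monotone in the window, and equivalent to a transitive-closure merger
(tested against one on random instances).

## Synthetic data

The fixture generator emulates the shapes of real inputs: chromosomes
(default 10, spans 150–300 Mu, a maize-sized genome), one centromere
each (5% of the span, placed at 35–65% of the length), genes (default
300 per chromosome, with a pericentromere-depleted profile that thins a
±15%-of-span window around the centromere to a fifth — so density plots
are non-trivial), synteny blocks classed by partner chromosome, and
per-query HSP chains with recorded gaps. The gene count is scaled down
from real genomes so suites run in seconds; the generator takes the same
shape to thousands of features (the scale checks render 5,000). All
randomness flows from one recorded seed through a single generator; no
global RNG state.

Ground truth is recorded *at generation time*: per-chromosome counts,
gene midpoints (from which expected bin counts for any bin size follow
by direct counting), and each HSP chain's extent with its min/max gap
(clustering at window ≥ max gap must give exactly the chain interval).
Tests assert against these records, not against the code paths under
test. What the generator does **not** emulate: sequence content, real
length distributions, overlapping gene models, assembly gaps, or any
correlation structure between feature classes — so green tests show the
geometry, grouping and counting machinery is right, not that any
biological conclusion would survive contact with a real genome.

## Known limitations

- Raster output only; no SVG/PDF, no curved inter-chromosome arcs, no
  interactive zoom.
- No horizontal layout mode and no per-backbone zooming.
- Flat GFF3 only: Parent/ID hierarchies and ontology-term validation are
  out of scope.
- Label collision handling is one downward sweep; pathological label
  densities drop labels (with warnings) rather than leader-lining them.
- The coordinate-file dialect and config vocabulary are this package's
  own; no compatibility with other implementations' files is claimed.
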