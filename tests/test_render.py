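"""Glyph drawing, histogram binning, legend and full-image rendering."""

import random

import pytest

from cvitpy import (
    Canvas,
    bin_histogram,
    build_legend,
    compute_frame,
    load_config,
    parse_gff,
    partition,
    render,
    write_gff,
)
from cvitpy.config import GlyphStyle, StyleResolver
from cvitpy.gff_io import Backbone, GenomeFeature
from cvitpy.render import (
    draw_backbone,
    draw_border,
    draw_centromere,
    draw_histogram,
    draw_marker,
    draw_position,
    draw_range,
)

RED = (255, 0, 0, 255)
WHITE = (255, 255, 255, 255)


def feat(seqid="c1", start=100.0, end=200.0, ftype="gene", **attrs):
    return GenomeFeature(seqid, "test", ftype, float(start), float(end), None, ".", dict(attrs))


def frame_for(backbones, config):
    return compute_frame(backbones, config)


@pytest.fixture
def one_bb_config():
    # span 1000 at 0.5 px/unit for hand-checkable geometry
    return load_config(cli_overrides=["general.pixels_per_unit=0.5", "general.image_height=700"])


@pytest.fixture
def scene(one_bb_config):
    backbone = Backbone("c1", 1.0, 1001.0)
    frame = frame_for([backbone], one_bb_config)
    canvas = Canvas(frame.image_width, frame.image_height)
    return backbone, frame, canvas, one_bb_config


class TestCanvas:
    def test_fill_rect_paints_exactly_the_box(self):
        canvas = Canvas(20, 30, WHITE)
        canvas.fill_rect((3, 4, 7, 9), RED)
        px = canvas.image.load()
        painted = {(x, y) for x in range(20) for y in range(30) if px[x, y] == RED}
        assert painted == {(x, y) for x in range(3, 8) for y in range(4, 10)}

    def test_alpha_blend_mixes_with_background(self):
        canvas = Canvas(4, 4, WHITE)
        canvas.fill_rect((0, 0, 3, 3), (0, 0, 0, 128))
        r, g, b, a = canvas.image.load()[1, 1]
        assert a == 255
        assert 120 < r < 135  # ~50% grey over white


class TestGlyphGeometry:
    def test_backbone_bar_height_and_width(self, scene):
        backbone, frame, canvas, config = scene
        d = draw_backbone(canvas, frame, backbone, config)
        x1, y1, x2, y2 = d.box
        assert (y2 - y1) == pytest.approx(1000 * 0.5, abs=1)
        assert (x2 - x1 + 1) == config.general.chrom_width

    def test_centromere_overhang_and_extent(self, scene):
        backbone, frame, canvas, config = scene
        style = GlyphStyle(kind="centromere", color=(0, 0, 0, 255), overhang=4)
        d = draw_centromere(canvas, frame, feat(start=401, end=601, ftype="centromere"), style, config)
        x1, y1, x2, y2 = d.box
        assert (y2 - y1) == pytest.approx(200 * 0.5, abs=1)
        assert (x2 - x1 + 1) == config.general.chrom_width + 2 * 4
        geom = frame.geoms["c1"]
        assert (x1 + x2) / 2 == pytest.approx(geom.x_center, abs=1)

    def test_centromere_default_style_is_black(self, default_config):
        resolver = StyleResolver(default_config)
        style = resolver.resolve(feat(ftype="centromere", start=400, end=600))
        assert style.color == (0, 0, 0, 255)

    def test_range_bar_proportional_and_on_configured_side(self, scene):
        backbone, frame, canvas, config = scene
        style = GlyphStyle(kind="range", color=RED, width=8, offset=-14)
        d = draw_range(canvas, frame, feat(start=1, end=501), style, config)
        x1, y1, x2, y2 = d.box
        geom = frame.geoms["c1"]
        assert (y2 - y1) == pytest.approx(geom.drawn_length / 2, abs=1)
        assert x2 < geom.x_center  # negative offset: strictly left
        # exact pixel-set fidelity for the rect glyph
        px = canvas.image.load()
        painted = {
            (x, y)
            for x in range(canvas.width)
            for y in range(canvas.height)
            if px[x, y] == RED
        }
        assert painted == {(x, y) for x in range(x1, x2 + 1) for y in range(y1, y2 + 1)}

    def test_overlapping_ranges_stack_disjoint_share(self, one_bb_config):
        text = write_gff(
            [feat(ftype="chromosome", start=1, end=1001, seqid="c1")]
            + [feat(start=100, end=400, **{"class": "s"}), feat(start=200, end=500, **{"class": "s"}),
               feat(start=600, end=900, **{"class": "s"})]
        )
        coll = partition(parse_gff(text), one_bb_config)
        result = render(coll, one_bb_config)
        boxes = [d.box for d in result.drawn if d.glyph_kind == "range"]
        assert len(boxes) == 3
        b1, b2, b3 = sorted(boxes, key=lambda b: b[1])
        assert b1[0] != b2[0]  # overlapping pair in different columns
        assert b3[0] == b1[0]  # disjoint third reuses the first column

    def test_stacked_ranges_never_overlap_within_column(self, one_bb_config):
        rng = random.Random(5)
        feats = []
        for i in range(60):
            s = rng.uniform(1, 900)
            feats.append(feat(start=s, end=min(1001.0, s + rng.uniform(20, 150)), **{"class": "s"}))
        text = write_gff([feat(ftype="chromosome", start=1, end=1001)] + feats)
        coll = partition(parse_gff(text), one_bb_config)
        result = render(coll, one_bb_config)
        boxes = [d.box for d in result.drawn if d.glyph_kind == "range"]
        by_column = {}
        for x1, y1, x2, y2 in boxes:
            by_column.setdefault(x1, []).append((y1, y2))
        for spans in by_column.values():
            spans.sort()
            for (a1, a2), (b1, b2) in zip(spans, spans[1:]):
                assert a2 < b1, "two bars share a column and overlap in y"

    def test_border_band_matches_bar_width(self, scene):
        backbone, frame, canvas, config = scene
        style = GlyphStyle(kind="border", color=(100, 100, 100, 255), transparency=0.5)
        d = draw_border(canvas, frame, feat(start=101, end=201), style, config)
        x1, _, x2, _ = d.box
        assert (x2 - x1 + 1) == config.general.chrom_width

    def test_zero_length_border_is_one_pixel_line(self, scene):
        backbone, frame, canvas, config = scene
        style = GlyphStyle(kind="border", color=(100, 100, 100, 255))
        d = draw_border(canvas, frame, feat(start=501, end=501), style, config)
        assert d.box[1] == d.box[3]

    def test_position_circle_diameter(self, scene):
        backbone, frame, canvas, config = scene
        style = GlyphStyle(kind="position", color=RED, shape="circle", width=6, offset=12)
        d = draw_position(canvas, frame, feat(start=500, end=500), style, config)
        x1, y1, x2, y2 = d.box
        assert (x2 - x1 + 1) == 6
        assert (y2 - y1 + 1) == 6

    def test_colocated_positions_displace_outward(self, one_bb_config):
        text = write_gff(
            [feat(ftype="chromosome", start=1, end=1001)]
            + [feat(start=500, end=500, **{"class": "m"}), feat(start=500, end=500, **{"class": "m"})]
        )
        coll = partition(parse_gff(text), one_bb_config)
        result = render(coll, one_bb_config)
        boxes = [d.box for d in result.drawn if d.glyph_kind == "position"]
        assert len(boxes) == 2
        assert boxes[0][0] != boxes[1][0]
        width = boxes[0][2] - boxes[0][0] + 1
        assert abs(boxes[1][0] - boxes[0][0]) == width + 2  # one glyph width + gap

    def test_marker_tick_right_of_bar(self, scene):
        backbone, frame, canvas, config = scene
        style = GlyphStyle(kind="marker", color=RED, offset=2, tick_length=8)
        d = draw_marker(canvas, frame, feat(start=500, end=500), style, config)
        geom = frame.geoms["c1"]
        assert d.box[0] > geom.x_center + config.general.chrom_width // 2 - 1
        assert d.box[2] - d.box[0] + 1 == 8


class TestHistogram:
    def test_midpoint_binning_hand_checked(self):
        bbone = Backbone("c1", 1.0, 1_000_000.0)
        feats = [feat(start=m, end=m) for m in (100, 250, 399_999, 400_001)]
        series = bin_histogram(feats, bbone, 400_000)
        assert series.counts == [3, 1, 0]
        assert len(series.counts) == 3  # ceil(1e6 / 4e5)

    def test_no_features_all_zero(self):
        series = bin_histogram([], Backbone("c1", 1.0, 1000.0), 100)
        assert series.counts == [0] * 10

    def test_counts_conserved_vs_brute_force(self):
        """200 random fixtures: sum == N and per-bin counts match an
        independent per-interval counter."""
        rng = random.Random(2024)
        for _ in range(200):
            span = rng.uniform(1000, 5e6)
            start = rng.choice([0.0, 1.0])
            bbone = Backbone("c1", start, start + span)
            bin_size = rng.choice([span / rng.uniform(2, 50), 400_000.0])
            n = rng.randint(0, 60)
            feats = []
            for _ in range(n):
                s = rng.uniform(start, start + span - 1)
                feats.append(feat(start=s, end=min(start + span, s + rng.uniform(0, 1000))))
            series = bin_histogram(feats, bbone, bin_size)
            assert sum(series.counts) == n
            # brute force: count midpoints per half-open interval
            edges = [start + k * bin_size for k in range(len(series.counts))]
            brute = []
            for k, lo in enumerate(edges):
                hi = lo + bin_size if k < len(edges) - 1 else start + span + 1e-9
                brute.append(
                    sum(1 for f in feats if lo <= f.midpoint < hi or (k == len(edges) - 1 and f.midpoint >= hi))
                )
            assert series.counts == brute

    def test_bar_lengths_linear_normalization(self, scene):
        backbone, frame, canvas, config = scene
        from cvitpy.render import HistogramSeries

        series = HistogramSeries("c1", 400.0, [3, 1, 0], max_bar_length=60)
        style = GlyphStyle(kind="histogram", color=(0, 128, 0, 255), offset=6, max_bar_length=60)
        drawn = draw_histogram(canvas, frame, series, style, config, global_max=3)
        lengths = [d.box[2] - d.box[0] + 1 for d in drawn]
        assert lengths == [60, 20]  # zero-count bin draws nothing
        assert len(drawn) == 2

    def test_equal_counts_full_length(self, scene):
        backbone, frame, canvas, config = scene
        from cvitpy.render import HistogramSeries

        series = HistogramSeries("c1", 500.0, [4, 4], max_bar_length=40)
        style = GlyphStyle(kind="histogram", color=(0, 128, 0, 255), offset=6, max_bar_length=40)
        drawn = draw_histogram(canvas, frame, series, style, config, global_max=4)
        assert [d.box[2] - d.box[0] + 1 for d in drawn] == [40, 40]

    def test_default_histogram_color_is_green(self, default_config):
        assert default_config.glyph_defaults["histogram"]["color"] == (0, 128, 0, 255)


class TestLegend:
    def test_one_row_per_distinct_kind_class(self, default_config):
        style = GlyphStyle(kind="range", color=RED)
        entries = [("range", "synteny_Gm15", style)] * 1000 + [("centromere", "centromere", style)]
        legend = build_legend(entries, default_config)
        # backbone row + 2 distinct entries
        assert legend.height == 3 * 18 + 16

    def test_backbones_only_legend(self, default_config):
        legend = build_legend([], default_config)
        assert legend.height == 1 * 18 + 16


class TestRender:
    def test_drawn_feature_counting(self, one_bb_config):
        config = load_config(cli_overrides=["general.pixels_per_unit=0.5"])
        recs = [feat(ftype="chromosome", seqid=s, start=1, end=1001) for s in ("a", "b")]
        recs += [feat(ftype="centromere", seqid=s, start=450, end=550) for s in ("a", "b")]
        rng = random.Random(1)
        for i in range(100):
            s = rng.uniform(1, 900)
            recs.append(feat(seqid=rng.choice(["a", "b"]), start=s, end=s + 50, **{"class": "blk"}))
        coll = partition(recs, config)
        result = render(coll, config)
        assert len(result.drawn) == 104  # 2 backbones + 2 centromeres + 100 ranges

    def test_empty_feature_set_backbones_only(self, default_config):
        coll = partition([feat(ftype="chromosome", start=1, end=1000)], default_config)
        result = render(coll, default_config)
        assert [d.glyph_kind for d in result.drawn] == ["backbone"]

    def test_byte_determinism(self, small_collection, default_config):
        a = render(small_collection, load_config())
        b = render(small_collection, load_config())
        assert a.canvas.tobytes() == b.canvas.tobytes()
        assert a.legend.tobytes() == b.legend.tobytes()
        assert [(d.name, d.box) for d in a.drawn] == [(d.name, d.box) for d in b.drawn]

    def test_all_boxes_inside_image(self, small_collection, default_config):
        result = render(small_collection, default_config)
        for d in result.drawn:
            x1, y1, x2, y2 = d.box
            assert 0 <= x1 <= x2 < result.canvas.width
            assert 0 <= y1 <= y2 < result.canvas.height

    def test_unnamed_features_get_synthesized_ids(self, default_config):
        recs = [
            feat(ftype="chromosome", start=1, end=1000),
            GenomeFeature("c1", "t", "gene", 100.0, 300.0, None, ".", {}),
        ]
        result = render(partition(recs, default_config), default_config)
        names = [d.name for d in result.drawn if d.glyph_kind != "backbone"]
        assert names == ["c1:100-300:0"]
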