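"""Gene-model parsing, exon feature decomposition and the interval index."""

import numpy as np
import pytest

from snvaa import fixtures
from snvaa.gene_model import (
    FeatureClass,
    TranscriptModel,
    build_exon_features,
    build_feature_index,
    gene_symbol_for,
    parse_kgxref,
    parse_known_gene,
    parse_known_gene_counted,
)


def test_parse_known_gene_direct_field_mapping(tmp_path):
    path = tmp_path / "kg.txt"
    path.write_text("uc001aaa.3\tchr1\t+\t100\t400\t150\t350\t2\t100,250,\t200,400,\n")
    (model,) = parse_known_gene(str(path))
    assert model.ucsc_id == "uc001aaa.3"
    assert model.chromosome == "chr1"
    assert model.strand == "+"
    assert (model.tx_start, model.tx_end) == (100, 400)
    assert (model.cds_start, model.cds_end) == (150, 350)
    assert model.exons == [(100, 200), (250, 400)]


def test_parse_known_gene_skips_malformed_rows(tmp_path):
    path = tmp_path / "kg.txt"
    path.write_text(
        "uc1.1\tchr1\t+\t100\t400\t150\t350\t3\t100,250,\t200,400,\n"  # count mismatch
        "uc2.1\tchr1\t+\t100\t400\t150\t350\t2\t100,250,\t200,400,\n"
        "uc3.1\tchr1\t+\tnotanumber\t400\t150\t350\t2\t100,250,\t200,400,\n"
    )
    models, n_skipped = parse_known_gene_counted(str(path))
    assert [m.ucsc_id for m in models] == ["uc2.1"]
    assert n_skipped == 2


def test_parse_known_gene_missing_file():
    with pytest.raises(OSError):
        parse_known_gene("/nonexistent/kg.txt")


def test_known_gene_roundtrip_on_fixture(mini_bundle, mini_bundle_dir):
    """Parsing the fixture gene-model file and re-serializing it is lossless."""
    models = parse_known_gene(mini_bundle_dir["known_gene"])
    assert len(models) == len(mini_bundle.transcripts)
    lines = []
    for t in models:
        starts = ",".join(str(s) for s, _ in t.exons) + ","
        ends = ",".join(str(e) for _, e in t.exons) + ","
        lines.append("\t".join([
            t.ucsc_id, t.chromosome, t.strand,
            str(t.tx_start), str(t.tx_end), str(t.cds_start), str(t.cds_end),
            str(len(t.exons)), starts, ends, "", t.ucsc_id,
        ]) + "\n")
    with open(mini_bundle_dir["known_gene"], "rt", encoding="utf-8") as fh:
        assert "".join(lines) == fh.read()


def test_parse_kgxref_and_dedup(tmp_path):
    path = tmp_path / "kgXref.txt"
    path.write_text(
        "uc001aaa.3\tNR_046018\t\t\tDDX11L1\t\t\t\n"
        "uc002bbb.1\tx\t\t\tA\t\t\t\n"
        "uc002bbb.1\tx\t\t\tB\t\t\t\n"
    )
    mapping = parse_kgxref(str(path))
    assert mapping["uc001aaa.3"] == "DDX11L1"
    assert mapping["uc002bbb.1"] == "A"  # first symbol wins
    assert gene_symbol_for(mapping, "uc_missing.1") == "uc_missing.1"


def test_kgxref_fixture_truth_table(mini_bundle, mini_bundle_dir):
    mapping = parse_kgxref(mini_bundle_dir["kgxref"])
    for tx, symbol in mini_bundle.xref.items():
        assert mapping[tx] == symbol


def _spans(features, cls):
    return [(f.start, f.end) for f in features if f.feature_class is cls]


def test_build_exon_features_plus_strand(demo_transcript):
    feats = build_exon_features(demo_transcript, upstream_window=0, downstream_window=0)
    assert _spans(feats, FeatureClass.UTR5) == [(100, 150)]
    assert _spans(feats, FeatureClass.CDS) == [(150, 200), (250, 350)]
    assert _spans(feats, FeatureClass.INTRON) == [(200, 250)]
    assert _spans(feats, FeatureClass.UTR3) == [(350, 400)]
    second_cds = [f for f in feats if f.feature_class is FeatureClass.CDS][1]
    assert second_cds.cds_offset_before == 50


def test_build_exon_features_minus_strand(demo_transcript_minus):
    feats = build_exon_features(demo_transcript_minus, upstream_window=0, downstream_window=0)
    assert _spans(feats, FeatureClass.UTR3) == [(100, 150)]
    assert _spans(feats, FeatureClass.UTR5) == [(350, 400)]
    left_cds = [f for f in feats if f.feature_class is FeatureClass.CDS][0]
    assert (left_cds.start, left_cds.end) == (150, 200)
    assert left_cds.cds_offset_before == 100


def test_flanking_windows_follow_strand(demo_transcript, demo_transcript_minus):
    plus = build_exon_features(demo_transcript, 1000, 500)
    minus = build_exon_features(demo_transcript_minus, 1000, 500)
    assert _spans(plus, FeatureClass.UPSTREAM) == [(-900, 100)]
    assert _spans(plus, FeatureClass.DOWNSTREAM) == [(400, 900)]
    assert _spans(minus, FeatureClass.UPSTREAM) == [(400, 1400)]
    assert _spans(minus, FeatureClass.DOWNSTREAM) == [(-400, 100)]


def test_noncoding_transcript_labels():
    t = TranscriptModel(
        ucsc_id="nc.1", chromosome="chr1", strand="+",
        tx_start=100, tx_end=400, cds_start=100, cds_end=100,
        exons=[(100, 200), (250, 400)],
    )
    feats = build_exon_features(t, 0, 0)
    classes = {f.feature_class for f in feats}
    assert classes == {FeatureClass.NONCODING_EXON, FeatureClass.INTRON}
    assert _spans(feats, FeatureClass.NONCODING_EXON) == [(100, 200), (250, 400)]


def test_invalid_transcript_is_fatal():
    with pytest.raises(ValueError, match="bad.1"):
        TranscriptModel(
            ucsc_id="bad.1", chromosome="chr1", strand="+",
            tx_start=100, tx_end=400, cds_start=90, cds_end=350,
            exons=[(100, 400)],
        )


def test_feature_tiling_covers_padded_span_once(mini_bundle):
    """Per transcript, features tile the padded span exactly, no overlap."""
    up, down = 1000, 1000
    for t in mini_bundle.transcripts:
        feats = sorted(build_exon_features(t, up, down), key=lambda f: f.start)
        assert sum(f.end - f.start for f in feats) == (t.tx_end - t.tx_start) + up + down
        for a, b in zip(feats, feats[1:]):
            assert a.end == b.start  # contiguous, hence non-overlapping
        assert feats[0].start == t.tx_start - (up if t.strand == "+" else down)
        assert feats[-1].end == t.tx_end + (down if t.strand == "+" else up)


def test_cds_offsets_increase_along_transcript(mini_bundle):
    for t in mini_bundle.transcripts:
        if not t.is_coding:
            continue
        cds = [f for f in build_exon_features(t, 0, 0) if f.feature_class is FeatureClass.CDS]
        assert sum(f.end - f.start for f in cds) == t.cds_length
        in_tx_order = cds if t.strand == "+" else cds[::-1]
        offsets = [f.cds_offset_before for f in in_tx_order]
        assert offsets[0] == 0
        assert offsets == sorted(offsets)
        lengths = [f.end - f.start for f in in_tx_order]
        assert all(b == a + n for a, n, b in zip(offsets, lengths, offsets[1:]))


def test_strand_mirror_symmetry():
    """Mirroring a transcript mirrors its feature classes and intervals."""
    mirrored = fixtures.mirror_bundle(
        fixtures.generate_bundle(seed=5, n_transcripts=6, n_variants=1, indel_fraction=0.0)
    )
    original = fixtures.generate_bundle(seed=5, n_transcripts=6, n_variants=1, indel_fraction=0.0)
    for t, tm in zip(original.transcripts, mirrored.transcripts):
        L = len(original.genome[t.chromosome])
        feats = build_exon_features(t, 0, 0)
        feats_m = build_exon_features(tm, 0, 0)
        reflected = sorted((L - f.end, L - f.start, f.feature_class) for f in feats)
        assert reflected == sorted((f.start, f.end, f.feature_class) for f in feats_m)


def test_index_matches_linear_scan(mini_bundle):
    """10,000 random point queries agree with a brute-force feature scan."""
    features = [
        f
        for t in mini_bundle.transcripts
        for f in build_exon_features(t, 1000, 1000)
    ]
    idx = build_feature_index(features)
    assert idx.visit_count == len(features)  # single-pass build
    rng = np.random.default_rng(0)
    chroms = sorted({f.chromosome for f in features})
    max_pos = max(f.end for f in features) + 100
    for _ in range(10_000):
        chrom = chroms[rng.integers(len(chroms))]
        p = int(rng.integers(0, max_pos))
        expected = sorted(
            (f for f in features if f.chromosome == chrom and f.contains(p)),
            key=lambda f: (f.start, f.end, f.transcript),
        )
        assert idx.query(chrom, p) == expected


def test_empty_index_returns_empty():
    idx = build_feature_index([])
    assert idx.query("chr1", 123) == []
    assert len(idx) == 0
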