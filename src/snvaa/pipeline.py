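"""The five-step annotation pipeline.

Step 1 builds the per-exon feature annotation from the gene models;
step 2 sorts it into the feature-start file and writes the gene mapping;
step 3 classifies variants by region against the feature index; step 4
predicts amino-acid changes for coding hits; step 5 prioritizes the
per-transcript hits of each variant into the final annotated file.

Each step reads only the configured inputs and the previous steps'
intermediate files, so running the steps individually and running
:func:`run_pipeline` end-to-end produce byte-identical outputs.
"""

from __future__ import annotations

import csv
import logging
import os

from . import coding_effect as ce
from . import gene_model as gm
from . import region_mapper as rm
from .prioritizer import PriorityTable, ScoredHit, prioritize_hits
from .variant_io import NA, PipelineConfig, parse_vcf, write_annotated

logger = logging.getLogger(__name__)

STEP1_FILE = "step1_exon_annotation.tsv"
STEP2_FEATURES_FILE = "step2_feature_starts.tsv"
STEP2_GENES_FILE = "step2_gene_mapping.tsv"
STEP3_FILE = "step3_region_hits.tsv"
STEP4_FILE = "step4_aa_predictions.tsv"

_FEATURE_HEADER = ["transcript", "chrom", "strand", "class", "start", "end",
                   "exon_rank", "cds_offset_before"]
_STEP3_HEADER = ["variant_key", "transcript", "gene_symbol", "strand",
                 "hit_class", "cds_offset", "junction_distance"]
_STEP4_HEADER = ["variant_key", "transcript", "aa_position", "aa_change",
                 "effect_class", "ref_chain", "alt_chain"]


def _out_dir(config: PipelineConfig) -> str:
    d = os.path.dirname(os.path.abspath(config.output_path)) or "."
    os.makedirs(d, exist_ok=True)
    return d


def _write_tsv(path: str, header: list[str], rows: list[list]) -> None:
    with open(path, "wt", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(header)
        writer.writerows(rows)


def _feature_row(f: gm.ExonFeature) -> list:
    return [f.transcript, f.chromosome, f.strand, str(f.feature_class),
            f.start, f.end, f.exon_rank, f.cds_offset_before]


def _read_features(path: str) -> list[gm.ExonFeature]:
    feats = []
    with open(path, "rt", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        next(reader)  # header
        for row in reader:
            feats.append(
                gm.ExonFeature(
                    transcript=row[0], chromosome=row[1], strand=row[2],
                    feature_class=gm.FeatureClass(row[3]),
                    start=int(row[4]), end=int(row[5]),
                    exon_rank=int(row[6]), cds_offset_before=int(row[7]),
                )
            )
    return feats


def step1_exon_annotation(config: PipelineConfig) -> str:
    """Build labelled exon features for every transcript (step 1)."""
    out = os.path.join(_out_dir(config), STEP1_FILE)
    models = gm.parse_known_gene(config.gene_annotation)
    rows = []
    for t in models:
        for f in gm.build_exon_features(t, config.upstream_window, config.downstream_window):
            rows.append(_feature_row(f))
    _write_tsv(out, _FEATURE_HEADER, rows)
    logger.info("step 1: %d features from %d transcripts -> %s", len(rows), len(models), out)
    return out


def step2_feature_index(config: PipelineConfig) -> tuple[str, str]:
    """Sort features into the feature-start file; write the gene mapping (step 2)."""
    d = _out_dir(config)
    feats = _read_features(os.path.join(d, STEP1_FILE))
    feats.sort(key=lambda f: (f.chromosome, f.start, f.end, f.transcript, f.feature_class.value))
    features_out = os.path.join(d, STEP2_FEATURES_FILE)
    _write_tsv(features_out, _FEATURE_HEADER, [_feature_row(f) for f in feats])

    xref = gm.parse_kgxref(config.conversion_file)
    genes_out = os.path.join(d, STEP2_GENES_FILE)
    _write_tsv(genes_out, ["ucsc_id", "gene_symbol"],
               [[k, v] for k, v in sorted(xref.items())])
    logger.info("step 2: %d features, %d gene symbols", len(feats), len(xref))
    return features_out, genes_out


def _read_gene_mapping(path: str) -> dict[str, str]:
    mapping = {}
    with open(path, "rt", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        next(reader)
        for row in reader:
            mapping[row[0]] = row[1]
    return mapping


def step3_classify_regions(config: PipelineConfig) -> str:
    """Classify every variant by genomic region across transcripts (step 3)."""
    d = _out_dir(config)
    feats = _read_features(os.path.join(d, STEP2_FEATURES_FILE))
    xref = _read_gene_mapping(os.path.join(d, STEP2_GENES_FILE))
    idx = gm.build_feature_index(feats)
    rows = []
    for v in parse_vcf(config.vcf_file):
        for hit in rm.classify_variant(v.chromosome, v.position, idx, xref,
                                       config.intron_boundary):
            rows.append([v.key, hit.transcript, hit.gene_symbol, hit.strand,
                         str(hit.hit_class), hit.cds_offset, hit.junction_distance])
    out = os.path.join(d, STEP3_FILE)
    _write_tsv(out, _STEP3_HEADER, rows)
    logger.info("step 3: %d hits -> %s", len(rows), out)
    return out


def step4_predict_aa_changes(config: PipelineConfig) -> str:
    """Predict amino-acid changes for coding SNP hits (step 4)."""
    d = _out_dir(config)
    seqs = ce.parse_sequence_file(config.sequence_file)
    rows = []
    with open(os.path.join(d, STEP3_FILE), "rt", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        next(reader)
        for row in reader:
            key, transcript, _symbol, _strand, hit_class, cds_offset, _jd = row
            if hit_class != str(rm.HitClass.CDSHIT):
                continue
            _chrom, _pos, ref, alt = key.rsplit(":", 3)
            if len(ref) != 1 or len(alt) != 1:
                continue  # indels: region class only, no codon prediction
            seq = seqs.get(transcript)
            if seq is None:
                logger.warning("%s: no CDS sequence for %s, effect UNKNOWN", key, transcript)
                effect = ce.CodingEffect(int(cds_offset) // 3 + 1, "NNN", "NNN", "X", "X",
                                         ce.EffectClass.UNKNOWN)
            else:
                effect = ce.predict_aa_change(int(cds_offset), ref, alt, seq)
            if effect.effect_class is ce.EffectClass.UNKNOWN:
                ref_chain = alt_chain = NA
            else:
                ref_chain, alt_chain = ce.build_aa_chains(seq, effect)
            rows.append([key, transcript, effect.aa_position, effect.display,
                         str(effect.effect_class), ref_chain, alt_chain])
    out = os.path.join(d, STEP4_FILE)
    _write_tsv(out, _STEP4_HEADER, rows)
    logger.info("step 4: %d coding predictions -> %s", len(rows), out)
    return out


def _parse_display(display: str, aa_position: int) -> ce.CodingEffect | None:
    """Rebuild a CodingEffect from a step-4 'K(AAA) -> E(GAA)' display string."""
    if display == NA or "->" not in display:
        return None
    left, right = (part.strip() for part in display.split("->", 1))
    ref_aa, ref_codon = left[0], left[2:5]
    alt_aa, alt_codon = right[0], right[2:5]
    if ref_aa == alt_aa:
        cls = ce.EffectClass.SYN
    elif alt_aa == "*":
        cls = ce.EffectClass.NSN
    elif ref_aa == "*":
        cls = ce.EffectClass.STL
    else:
        cls = ce.EffectClass.NSM
    return ce.CodingEffect(aa_position, ref_codon, alt_codon, ref_aa, alt_aa, cls)


def step5_prioritize(config: PipelineConfig, table: PriorityTable | None = None) -> str:
    """Collapse per-transcript hits to one row per variant (step 5)."""
    d = _out_dir(config)
    hits_by_key: dict[str, list[rm.RegionHit]] = {}
    with open(os.path.join(d, STEP3_FILE), "rt", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        next(reader)
        for row in reader:
            key = row[0]
            chrom, pos, _ref, _alt = key.rsplit(":", 3)
            hits_by_key.setdefault(key, []).append(
                rm.RegionHit(
                    chromosome=chrom, position=int(pos), transcript=row[1],
                    gene_symbol=row[2], strand=row[3],
                    hit_class=rm.HitClass(row[4]),
                    cds_offset=int(row[5]), junction_distance=int(row[6]),
                )
            )

    effects: dict[tuple[str, str], tuple[ce.CodingEffect | None, str, str]] = {}
    with open(os.path.join(d, STEP4_FILE), "rt", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        next(reader)
        for row in reader:
            key, transcript, aa_position, display, effect_class, ref_chain, alt_chain = row
            effect = _parse_display(display, int(aa_position))
            if effect is None and effect_class == str(ce.EffectClass.UNKNOWN):
                effect = ce.CodingEffect(int(aa_position), "NNN", "NNN", "X", "X",
                                         ce.EffectClass.UNKNOWN)
            effects[(key, transcript)] = (effect, ref_chain, alt_chain)

    records = []
    for v in parse_vcf(config.vcf_file):
        scored = []
        for hit in hits_by_key.get(v.key, [rm.intergenic_hit(v.chromosome, v.position)]):
            effect, ref_chain, alt_chain = effects.get((v.key, hit.transcript), (None, NA, NA))
            if hit.hit_class is not rm.HitClass.CDSHIT:
                effect, ref_chain, alt_chain = None, NA, NA
            scored.append(ScoredHit(hit=hit, effect=effect,
                                    ref_chain=ref_chain, alt_chain=alt_chain))
        records.append(prioritize_hits(v, scored, table))
    write_annotated(records, config.output_path)
    logger.info("step 5: %d annotated variants -> %s", len(records), config.output_path)
    return config.output_path


def run_pipeline(config: PipelineConfig, table: PriorityTable | None = None) -> str:
    """Run steps 1-5 in order; returns the final annotated file path."""
    step1_exon_annotation(config)
    step2_feature_index(config)
    step3_classify_regions(config)
    step4_predict_aa_changes(config)
    return step5_prioritize(config, table)
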