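"""Variant-to-region assignment across overlapping transcripts.

Maps each variant (by its 0-based anchor position) onto every transcript
feature containing it and reports one RegionHit per feature: CDSHIT with
a coding-base offset, UTRs, intron (upgraded to INTRON_SPLICE within the
configured boundary of an exon edge), flanking windows, non-coding exons,
or a single INTERGENIC hit when nothing overlaps. Overlap resolution is
deferred to the prioritizer; this module reports all hits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

from .gene_model import ExonFeature, FeatureClass, FeatureIndex, TranscriptModel

logger = logging.getLogger(__name__)

DEFAULT_INTRON_BOUNDARY = 6


class HitClass(str, Enum):
    CDSHIT = "CDSHIT"
    UTR5 = "UTR5"
    UTR3 = "UTR3"
    INTRON = "INTRON"
    INTRON_SPLICE = "INTRON_SPLICE"
    UPSTREAM = "UPSTREAM"
    DOWNSTREAM = "DOWNSTREAM"
    NONCODING_EXON = "NONCODING_EXON"
    INTERGENIC = "INTERGENIC"

    def __str__(self) -> str:  # noqa: D105
        return self.value


@dataclass(frozen=True)
class RegionHit:
    """One variant-by-transcript region assignment.

    ``cds_offset`` is the 0-based coding-base index in transcript
    orientation (-1 unless CDSHIT); ``junction_distance`` is the 1-based
    distance to the nearest exon edge (-1 unless intronic).
    """

    chromosome: str
    position: int            # 1-based VCF position of the variant
    transcript: str
    gene_symbol: str
    strand: str
    hit_class: HitClass
    cds_offset: int = -1
    junction_distance: int = -1


_FEATURE_TO_HIT = {
    FeatureClass.CDS: HitClass.CDSHIT,
    FeatureClass.UTR5: HitClass.UTR5,
    FeatureClass.UTR3: HitClass.UTR3,
    FeatureClass.INTRON: HitClass.INTRON,
    FeatureClass.UPSTREAM: HitClass.UPSTREAM,
    FeatureClass.DOWNSTREAM: HitClass.DOWNSTREAM,
    FeatureClass.NONCODING_EXON: HitClass.NONCODING_EXON,
}


def intergenic_hit(chromosome: str, position: int) -> RegionHit:
    return RegionHit(
        chromosome=chromosome,
        position=position,
        transcript="NA",
        gene_symbol="NA",
        strand="NA",
        hit_class=HitClass.INTERGENIC,
    )


def classify_variant(
    chromosome: str,
    position: int,
    idx: FeatureIndex,
    xref: dict[str, str] | None = None,
    intron_boundary: int = DEFAULT_INTRON_BOUNDARY,
) -> list[RegionHit]:
    """Classify one variant (1-based ``position``) against the feature index.

    Returns one RegionHit per overlapping transcript feature. Intronic hits
    whose 1-based distance to either flanking exon edge is within
    ``intron_boundary`` become INTRON_SPLICE. A variant overlapping no
    feature — including one on a chromosome absent from the index — yields
    a single INTERGENIC hit.
    """
    xref = xref or {}
    p = position - 1
    if chromosome not in idx.chromosomes:
        logger.warning("chromosome %s absent from feature index", chromosome)
        return [intergenic_hit(chromosome, position)]
    features = idx.query(chromosome, p)
    if not features:
        return [intergenic_hit(chromosome, position)]
    hits = []
    for f in features:
        hits.append(hit_from_feature(f, p, position, xref, intron_boundary))
    return hits


def hit_from_feature(
    f: ExonFeature,
    p: int,
    position: int,
    xref: dict[str, str],
    intron_boundary: int,
) -> RegionHit:
    """Turn one containing feature into a RegionHit for position ``p`` (0-based)."""
    hit_class = _FEATURE_TO_HIT[f.feature_class]
    cds_offset = -1
    junction_distance = -1
    if hit_class is HitClass.CDSHIT:
        if f.strand == "+":
            cds_offset = f.cds_offset_before + (p - f.start)
        else:
            cds_offset = f.cds_offset_before + (f.end - 1 - p)
    elif hit_class is HitClass.INTRON:
        # Base adjacent to an exon has distance 1.
        junction_distance = min(p - f.start + 1, f.end - p)
        if 1 <= junction_distance <= intron_boundary:
            hit_class = HitClass.INTRON_SPLICE
    return RegionHit(
        chromosome=f.chromosome,
        position=position,
        transcript=f.transcript,
        gene_symbol=xref.get(f.transcript) or f.transcript,
        strand=f.strand,
        hit_class=hit_class,
        cds_offset=cds_offset,
        junction_distance=junction_distance,
    )


def genomic_to_cds_offset(t: TranscriptModel, p: int) -> int:
    """Coding-base index (transcript orientation) of genomic position ``p``.

    Plus strand: bases before the containing CDS piece plus the offset into
    it; minus strand: mirror-counted from the genomic-right end. Raises if
    ``p`` is not inside the CDS of ``t``.
    """
    pieces = t.cds_pieces()
    total = sum(e - s for s, e in pieces)
    before = 0
    for s, e in pieces:
        if s <= p < e:
            if t.strand == "+":
                return before + (p - s)
            after_piece = total - before - (e - s)
            return after_piece + (e - 1 - p)
        before += e - s
    raise ValueError(f"position {p} not in CDS of {t.ucsc_id}")
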