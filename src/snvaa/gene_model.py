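"""Gene-model ingestion and per-exon feature annotation.

Parses UCSC knownGene-style transcript tables and kgXref symbol
cross-references, decomposes each transcript into labelled genomic
features (UTR5/CDS/UTR3/intron plus flanking upstream/downstream
windows), and builds a point-queryable interval index over them.

All coordinates are 0-based half-open (the native knownGene convention);
conversion from 1-based VCF positions happens at the VCF boundary only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable

from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

DEFAULT_UPSTREAM_WINDOW = 1000
DEFAULT_DOWNSTREAM_WINDOW = 1000


class FeatureClass(str, Enum):
    """Genomic feature classes a transcript decomposes into."""

    UPSTREAM = "UPSTREAM"
    UTR5 = "UTR5"
    CDS = "CDS"
    INTRON = "INTRON"
    UTR3 = "UTR3"
    DOWNSTREAM = "DOWNSTREAM"
    NONCODING_EXON = "NONCODING_EXON"

    def __str__(self) -> str:  # noqa: D105
        return self.value


@dataclass
class TranscriptModel:
    """One gene-model row: transcript bounds, CDS bounds and exon list.

    ``cds_start == cds_end`` encodes a non-coding transcript.
    """

    ucsc_id: str
    chromosome: str
    strand: str
    tx_start: int
    tx_end: int
    cds_start: int
    cds_end: int
    exons: list[tuple[int, int]]
    gene_symbol: str = ""

    def __post_init__(self) -> None:
        self.validate()

    @property
    def is_coding(self) -> bool:
        return self.cds_start < self.cds_end

    @property
    def cds_length(self) -> int:
        """Total spliced CDS length in bp."""
        return sum(
            min(e, self.cds_end) - max(s, self.cds_start)
            for s, e in self.exons
            if s < self.cds_end and e > self.cds_start
        )

    def cds_pieces(self) -> list[tuple[int, int]]:
        """Genomic CDS intervals (exons clipped to the CDS span), ascending."""
        return [
            (max(s, self.cds_start), min(e, self.cds_end))
            for s, e in self.exons
            if s < self.cds_end and e > self.cds_start
        ]

    def validate(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.ucsc_id}: strand must be '+' or '-', got {self.strand!r}")
        if not (0 <= self.tx_start <= self.cds_start <= self.cds_end <= self.tx_end):
            raise ValueError(
                f"{self.ucsc_id}: coordinate ordering violated "
                f"(tx [{self.tx_start},{self.tx_end}), cds [{self.cds_start},{self.cds_end}))"
            )
        prev_end = None
        for s, e in self.exons:
            if not (self.tx_start <= s < e <= self.tx_end):
                raise ValueError(f"{self.ucsc_id}: exon [{s},{e}) outside tx bounds")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"{self.ucsc_id}: exons overlap or are unsorted at [{s},{e})")
            prev_end = e


@dataclass(frozen=True)
class ExonFeature:
    """One labelled genomic interval tied to a transcript.

    ``exon_rank`` counts exons in transcript (strand) orientation and is -1
    for UPSTREAM/DOWNSTREAM/INTRON. ``cds_offset_before`` is the number of
    coding bases of the transcript strictly 5' (transcript orientation) of
    this feature; -1 for non-CDS features.
    """

    transcript: str
    chromosome: str
    strand: str
    feature_class: FeatureClass
    start: int
    end: int
    exon_rank: int = -1
    cds_offset_before: int = -1

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"{self.transcript}: empty feature {self.feature_class} [{self.start},{self.end})"
            )

    def contains(self, p: int) -> bool:
        return self.start <= p < self.end


def parse_known_gene(path: str) -> list[TranscriptModel]:
    """Parse a knownGene-style TSV into transcript models.

    Expects >=10 columns per row: name, chrom, strand, txStart, txEnd,
    cdsStart, cdsEnd, exonCount, exonStarts, exonEnds (the two exon lists
    comma-terminated). Trailing columns are ignored. Malformed rows are
    skipped with a warning; the skip count is attached to the returned
    list as the attribute ``n_skipped`` via :func:`parse_known_gene_counted`.
    """
    models, _ = parse_known_gene_counted(path)
    return models


def parse_known_gene_counted(path: str) -> tuple[list[TranscriptModel], int]:
    """As :func:`parse_known_gene` but also return the skipped-row count."""
    models: list[TranscriptModel] = []
    n_skipped = 0
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 10:
                logger.warning("%s:%d: fewer than 10 columns, skipped", path, lineno)
                n_skipped += 1
                continue
            try:
                name = fields[0].strip()
                chrom = normalize_chrom(fields[1].strip())
                strand = fields[2].strip()
                tx_start, tx_end = int(fields[3]), int(fields[4])
                cds_start, cds_end = int(fields[5]), int(fields[6])
                exon_count = int(fields[7])
                starts = [int(x) for x in fields[8].rstrip(",").split(",") if x]
                ends = [int(x) for x in fields[9].rstrip(",").split(",") if x]
                if len(starts) != exon_count or len(ends) != exon_count:
                    raise ValueError(
                        f"exonCount={exon_count} but {len(starts)} starts / {len(ends)} ends"
                    )
                model = TranscriptModel(
                    ucsc_id=name,
                    chromosome=chrom,
                    strand=strand,
                    tx_start=tx_start,
                    tx_end=tx_end,
                    cds_start=cds_start,
                    cds_end=cds_end,
                    exons=list(zip(starts, ends)),
                )
            except (ValueError, IndexError) as exc:
                logger.warning("%s:%d: malformed gene-model row (%s), skipped", path, lineno, exc)
                n_skipped += 1
                continue
            models.append(model)
    return models, n_skipped


def parse_kgxref(path: str, symbol_column: int = 4) -> dict[str, str]:
    """Parse a kgXref-style TSV mapping UCSC transcript ids to gene symbols.

    ``symbol_column`` is the 0-based index of the gene-symbol column
    (default 4, i.e. the fifth column as in UCSC kgXref). Duplicate ids
    keep the first symbol and log a warning.
    """
    mapping: dict[str, str] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) <= symbol_column:
                logger.warning("%s:%d: too few columns, skipped", path, lineno)
                continue
            ucsc_id = fields[0].strip()
            symbol = fields[symbol_column].strip()
            if ucsc_id in mapping:
                logger.warning("%s:%d: duplicate id %s, keeping first symbol", path, lineno, ucsc_id)
                continue
            mapping[ucsc_id] = symbol
    return mapping


def gene_symbol_for(xref: dict[str, str], ucsc_id: str) -> str:
    """Symbol lookup; an unmapped id renders as itself (never empty)."""
    return xref.get(ucsc_id) or ucsc_id


def normalize_chrom(chrom: str) -> str:
    """Unify '1' and 'chr1' to 'chr1' so VCFs and gene models interoperate."""
    return chrom if chrom.startswith("chr") else f"chr{chrom}"


def build_exon_features(
    t: TranscriptModel,
    upstream_window: int = DEFAULT_UPSTREAM_WINDOW,
    downstream_window: int = DEFAULT_DOWNSTREAM_WINDOW,
) -> list[ExonFeature]:
    """Decompose a transcript into labelled, non-overlapping genomic features.

    Each exon is split at cds_start/cds_end into UTR and CDS pieces; exonic
    segments 5' of the CDS in transcript orientation are UTR5 and 3' are UTR3
    (so on the minus strand the genomic-left UTR is UTR3). Gaps between exons
    are INTRON. The upstream window precedes tx_start on the plus strand and
    follows tx_end on the minus strand (downstream swapped). The features tile
    [tx_start - left_window, tx_end + right_window) exactly.

    Non-coding transcripts (cds_start == cds_end) label all exons
    NONCODING_EXON.
    """
    if upstream_window < 0 or downstream_window < 0:
        raise ValueError("windows must be >= 0")
    t.validate()

    plus = t.strand == "+"
    feats: list[ExonFeature] = []

    def add(cls: FeatureClass, start: int, end: int, rank: int = -1, cob: int = -1) -> None:
        if start < end:
            feats.append(
                ExonFeature(
                    transcript=t.ucsc_id,
                    chromosome=t.chromosome,
                    strand=t.strand,
                    feature_class=cls,
                    start=start,
                    end=end,
                    exon_rank=rank,
                    cds_offset_before=cob,
                )
            )

    # Flanking windows: upstream precedes the transcript in its own orientation.
    left_win = upstream_window if plus else downstream_window
    right_win = downstream_window if plus else upstream_window
    add(FeatureClass.UPSTREAM if plus else FeatureClass.DOWNSTREAM, t.tx_start - left_win, t.tx_start)
    add(FeatureClass.DOWNSTREAM if plus else FeatureClass.UPSTREAM, t.tx_end, t.tx_end + right_win)

    n_exons = len(t.exons)
    # Coding bases genomically left of each exon's CDS piece, for offset bookkeeping.
    cds_before_left = 0
    prev_end: int | None = None
    for i, (es, ee) in enumerate(t.exons):
        rank = i if plus else n_exons - 1 - i
        if prev_end is not None and prev_end < es:
            add(FeatureClass.INTRON, prev_end, es)
        prev_end = ee
        if not t.is_coding:
            add(FeatureClass.NONCODING_EXON, es, ee, rank=rank)
            continue
        left_utr_cls = FeatureClass.UTR5 if plus else FeatureClass.UTR3
        right_utr_cls = FeatureClass.UTR3 if plus else FeatureClass.UTR5
        add(left_utr_cls, es, min(ee, t.cds_start), rank=rank)
        cs, ce = max(es, t.cds_start), min(ee, t.cds_end)
        if cs < ce:
            # cds_offset_before counts coding bases 5' of this piece in
            # transcript orientation: on minus strand that is everything
            # genomically to the right.
            cob = cds_before_left if plus else t.cds_length - cds_before_left - (ce - cs)
            add(FeatureClass.CDS, cs, ce, rank=rank, cob=cob)
            cds_before_left += ce - cs
        add(right_utr_cls, max(es, t.cds_end), ee, rank=rank)

    feats.sort(key=lambda f: f.start)
    return feats


class FeatureIndex:
    """Per-chromosome interval index over exon features.

    A point query at genomic position ``p`` returns exactly the features
    whose half-open interval contains ``p``. Construction is single-pass
    over the input features (``visit_count`` records how many were touched).
    """

    def __init__(self, features: Iterable[ExonFeature] = ()) -> None:
        self._trees: dict[str, IntervalTree] = {}
        self.visit_count = 0
        for f in features:
            self._trees.setdefault(f.chromosome, IntervalTree()).addi(f.start, f.end, f)
            self.visit_count += 1

    @property
    def chromosomes(self) -> set[str]:
        return set(self._trees)

    def query(self, chromosome: str, p: int) -> list[ExonFeature]:
        """All features whose [start, end) contains genomic position ``p``."""
        tree = self._trees.get(chromosome)
        if tree is None:
            return []
        return sorted((iv.data for iv in tree[p]), key=lambda f: (f.start, f.end, f.transcript))

    def __len__(self) -> int:
        return sum(len(t) for t in self._trees.values())


def build_feature_index(features: Iterable[ExonFeature]) -> FeatureIndex:
    """Build the point-queryable index (single pass over ``features``)."""
    return FeatureIndex(features)
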