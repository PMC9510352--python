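"""VCF ingestion, run configuration, and the annotated-output writer.

The final output is a TSV with one row per input variant (multi-allelic
rows expanded to one row per alternate allele) and 20 named annotation
columns — 21 when the VCF carries genotype data, in which case the first
column is the sample ID. Non-applicable fields hold the literal "NA".
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from cyvcf2 import VCF

logger = logging.getLogger(__name__)

from .gene_model import (
    DEFAULT_DOWNSTREAM_WINDOW,
    DEFAULT_UPSTREAM_WINDOW,
    normalize_chrom,
)
from .region_mapper import DEFAULT_INTRON_BOUNDARY

NA = "NA"

#: Final-output column names, in order (a "Sample ID" column precedes these
#: when the VCF carries genotype data).
ANNOTATION_COLUMNS = [
    "Chromosome",
    "Variant Position",
    "Gene Symbol",
    "UCSC ID",
    "Strand",
    "AA Position of Mutation (for CDSHIT)",
    "Variant Type",
    "Amino Acid Ref (Codon) -> AA SNP (Codon)",
    "Variant Class",
    "Ref AA chain",
    "Alt AA chain",
    "Hit Type",
    "Known dbSNP",
    "Ref nt",
    "Alt nt",
    "Quality",
    "Depth",
    "Allele Freq",
    "Read Categories",
    "Info",
]


@dataclass
class VariantRecord:
    """One variant as parsed from a VCF row (one alt allele)."""

    chromosome: str
    position: int            # 1-based
    dbsnp_id: str = "."
    ref_allele: str = ""
    alt_allele: str = ""
    quality: str = "."
    depth: int | None = None
    allele_freq: float | None = None
    read_categories: str | None = None
    info: str = "."
    sample_id: str | None = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if not self.ref_allele or not self.alt_allele:
            raise ValueError("ref and alt alleles must be non-empty")
        self.ref_allele = self.ref_allele.upper()
        self.alt_allele = self.alt_allele.upper()

    @property
    def is_snp(self) -> bool:
        return len(self.ref_allele) == 1 and len(self.alt_allele) == 1

    @property
    def variant_type(self) -> str:
        return "SNP" if self.is_snp else "indel"

    @property
    def key(self) -> str:
        return f"{self.chromosome}:{self.position}:{self.ref_allele}:{self.alt_allele}"


@dataclass
class PipelineConfig:
    """Run configuration (the key=value config file, with defaults applied)."""

    vcf_file: str
    gene_annotation: str
    conversion_file: str
    sequence_file: str
    intron_boundary: int = DEFAULT_INTRON_BOUNDARY
    upstream_window: int = DEFAULT_UPSTREAM_WINDOW
    downstream_window: int = DEFAULT_DOWNSTREAM_WINDOW
    output_path: str = ""

    def __post_init__(self) -> None:
        if self.intron_boundary < 0:
            raise ValueError("intronBoundary must be >= 0")
        if not self.output_path:
            self.output_path = self.vcf_file + ".annotated.tsv"


@dataclass
class AnnotatedRecord:
    """One 20/21-column output row; NA for non-applicable fields."""

    chromosome: str
    variant_position: int
    gene_symbol: str = NA
    ucsc_id: str = NA
    strand: str = NA
    aa_position: str = NA
    variant_type: str = NA
    aa_change: str = NA
    variant_class: str = NA
    ref_aa_chain: str = NA
    alt_aa_chain: str = NA
    hit_type: str = NA
    dbsnp_id: str = "."
    ref_nt: str = NA
    alt_nt: str = NA
    quality: str = "."
    depth: str = NA
    allele_freq: str = NA
    read_categories: str = NA
    info: str = "."
    sample_id: str | None = None

    def to_fields(self) -> list[str]:
        fields = [
            self.chromosome,
            str(self.variant_position),
            self.gene_symbol,
            self.ucsc_id,
            self.strand,
            self.aa_position,
            self.variant_type,
            self.aa_change,
            self.variant_class,
            self.ref_aa_chain,
            self.alt_aa_chain,
            self.hit_type,
            self.dbsnp_id,
            self.ref_nt,
            self.alt_nt,
            self.quality,
            self.depth,
            self.allele_freq,
            self.read_categories,
            self.info,
        ]
        fields = [f if f not in ("", None) else NA for f in fields]
        if self.sample_id is not None:
            return [self.sample_id] + fields
        return fields


def _format_qual(qual: float | None) -> str:
    if qual is None:
        return "."
    if float(qual).is_integer():
        return str(int(qual))
    return f"{qual:g}"


def _per_alt(value, alt_index: int):
    """INFO values for multi-allelic sites come as sequences; pick this alt's."""
    if value is None:
        return None
    if isinstance(value, (tuple, list)):
        return value[alt_index] if alt_index < len(value) else None
    return value


def parse_vcf(path: str) -> Iterator[VariantRecord]:
    """Stream VariantRecords from a VCF (plain or gzip), one per alt allele.

    Depth and allele frequency come from INFO DP and AF (falling back to
    AF1); read categories from DP4. Rows with symbolic alternate alleles
    (<DEL>, breakends, '*') are skipped with a warning. When the VCF has
    genotype columns the first sample's name is attached to every record.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"VCF file not found: {path}")
    vcf = VCF(path)
    sample_id = vcf.samples[0] if vcf.samples else None
    for v in vcf:
        raw_info = str(v).rstrip("\n").split("\t")[7]
        dp4 = v.INFO.get("DP4")
        read_categories = (
            ",".join(str(int(x)) for x in dp4) if isinstance(dp4, (tuple, list)) else None
        )
        depth = v.INFO.get("DP")
        for i, alt in enumerate(v.ALT):
            if alt.startswith("<") or alt == "*" or "[" in alt or "]" in alt:
                logger.warning("%s:%d: symbolic alt %s skipped", v.CHROM, v.POS, alt)
                continue
            af = _per_alt(v.INFO.get("AF"), i)
            if af is None:
                af = _per_alt(v.INFO.get("AF1"), i)
            try:
                yield VariantRecord(
                    chromosome=normalize_chrom(v.CHROM),
                    position=v.POS,
                    dbsnp_id=v.ID or ".",
                    ref_allele=v.REF,
                    alt_allele=alt,
                    quality=_format_qual(v.QUAL),
                    depth=int(depth) if depth is not None else None,
                    allele_freq=float(af) if af is not None else None,
                    read_categories=read_categories,
                    info=raw_info,
                    sample_id=sample_id,
                )
            except ValueError as exc:
                logger.warning("%s:%d: malformed record (%s), skipped", v.CHROM, v.POS, exc)


# Config-file keys -> PipelineConfig fields. Path-valued keys resolve
# relative to the config file's directory.
_REQUIRED_KEYS = {
    "vcfFile": "vcf_file",
    "geneAnnotation": "gene_annotation",
    "conversionFile": "conversion_file",
    "sequenceFile": "sequence_file",
}
_OPTIONAL_INT_KEYS = {
    "intronBoundary": "intron_boundary",
    "upstreamWindow": "upstream_window",
    "downstreamWindow": "downstream_window",
}


def parse_config(path: str) -> PipelineConfig:
    """Parse a key=value config file ('#' starts a comment; unknown keys warn)."""
    if not os.path.exists(path):
        raise FileNotFoundError(f"config file not found: {path}")
    base = os.path.dirname(os.path.abspath(path))
    raw: dict[str, str] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                logger.warning("%s:%d: not a key=value line, ignored", path, lineno)
                continue
            key, value = (part.strip() for part in line.split("=", 1))
            raw[key] = value

    missing = [k for k in _REQUIRED_KEYS if not raw.get(k)]
    if missing:
        raise ValueError(f"config {path} missing required keys: {', '.join(missing)}")

    kwargs: dict[str, object] = {}
    for key, value in raw.items():
        if key in _REQUIRED_KEYS:
            kwargs[_REQUIRED_KEYS[key]] = os.path.join(base, value)
        elif key in _OPTIONAL_INT_KEYS:
            kwargs[_OPTIONAL_INT_KEYS[key]] = int(value)
        elif key == "outputFile":
            kwargs["output_path"] = os.path.join(base, value)
        else:
            logger.warning("%s: unknown config key %r ignored", path, key)
    return PipelineConfig(**kwargs)  # type: ignore[arg-type]


def write_annotated(records: Iterable[AnnotatedRecord], path: str) -> str:
    """Write the final annotated TSV (constant column count, NA for nulls)."""
    records = list(records)
    with_sample = {r.sample_id is not None for r in records}
    if len(with_sample) > 1:
        raise ValueError("records mix presence and absence of sample_id")
    has_sample = with_sample.pop() if with_sample else False
    header = (["Sample ID"] if has_sample else []) + ANNOTATION_COLUMNS
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("\t".join(header) + "\n")
        for r in records:
            fields = r.to_fields()
            assert len(fields) == len(header)
            fh.write("\t".join(fields) + "\n")
    return path
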