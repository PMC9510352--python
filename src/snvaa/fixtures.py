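"""Synthetic genomes, gene models and variant sets with known truth.

Generates internally consistent bundles — a random genome, transcript
models on both strands with 1-8 exons, isoform pairs sharing a CDS,
strand-resolved CDS sequences, and a VCF whose per-variant truth table is
filled by an independent brute-force annotator — and writes them out in
the four input dialects the pipeline consumes (knownGene TSV, kgXref TSV,
sequence TSV, VCF) plus a truth TSV and a FASTA of the genome.

The brute-force annotator deliberately shares no interval-index or
codon-arithmetic code with the pipeline modules: it classifies by linear
scans over transcript coordinates and derives coding consequences by
translating the entire reference and alternate CDS (via Biopython) and
diffing the protein strings.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq

from .gene_model import TranscriptModel
from .variant_io import VariantRecord

logger = logging.getLogger(__name__)

BASES = np.array(list("ACGT"))
STOP_CODONS = ("TAA", "TAG", "TGA")
DEFAULT_CHROM_LENGTH = 100_000
DEFAULT_UPSTREAM = 1000
DEFAULT_DOWNSTREAM = 1000
DEFAULT_INTRON_BOUNDARY = 6

#: Region classes a bundle can plant variants in, with default weights.
DEFAULT_REGION_MIX: dict[str, float] = {
    "CDSHIT": 0.40,
    "UTR5": 0.08,
    "UTR3": 0.08,
    "INTRON": 0.10,
    "INTRON_SPLICE": 0.08,
    "UPSTREAM": 0.06,
    "DOWNSTREAM": 0.06,
    "NONCODING_EXON": 0.07,
    "INTERGENIC": 0.07,
}

# Most-damaging-first priority tiers, re-declared here so the oracle's
# exhaustive sort stays independent of the prioritizer module.
_ORACLE_PRIORITY: dict[tuple[str, str | None] | str, int] = {
    ("CDSHIT", "NSN"): 0, ("CDSHIT", "STL"): 0,
    ("CDSHIT", "NSM"): 1,
    ("CDSHIT", "SYN"): 2,
    ("CDSHIT", "UNKNOWN"): 3, ("CDSHIT", None): 3,
    "UTR5": 4, "UTR3": 5, "INTRON_SPLICE": 6, "NONCODING_EXON": 7,
    "INTRON": 8, "UPSTREAM": 9, "DOWNSTREAM": 10, "INTERGENIC": 11,
}


@dataclass(frozen=True)
class TruthEntry:
    """Oracle-derived expected annotation for one variant."""

    hit_class: str
    effect_class: str | None
    aa_position: int | None
    ref_aa: str | None
    alt_aa: str | None
    transcript: str
    gene_symbol: str


@dataclass
class SyntheticBundle:
    """A self-consistent synthetic study: genome, models, variants, truth."""

    genome: dict[str, str]
    transcripts: list[TranscriptModel]
    xref: dict[str, str]
    sequences: list[tuple[str, str, str]]   # (ucsc_id, sign, spliced CDS)
    variants: list[VariantRecord]
    truth: dict[str, TruthEntry]
    upstream_window: int = DEFAULT_UPSTREAM
    downstream_window: int = DEFAULT_DOWNSTREAM
    intron_boundary: int = DEFAULT_INTRON_BOUNDARY


# ---------------------------------------------------------------------------
# genome / transcript construction


def _random_genome(rng: np.random.Generator, n_chroms: int, length: int) -> dict[str, list[str]]:
    return {
        f"chr{i + 1}": list(rng.choice(BASES, size=length))
        for i in range(n_chroms)
    }


def _exonic_to_genomic(exons: list[tuple[int, int]], k: int) -> int:
    """Genomic coordinate of the k-th exonic base counted from the genomic left."""
    for s, e in exons:
        if k < e - s:
            return s + k
        k -= e - s
    raise IndexError("exonic index out of range")


def _coding_positions(t: TranscriptModel) -> list[int]:
    """Genomic positions of the CDS bases in transcript (coding) orientation."""
    pos: list[int] = []
    for s, e in t.cds_pieces():
        pos.extend(range(s, e))
    return pos if t.strand == "+" else pos[::-1]


def _random_coding_sequence(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + random internal sense codons + one stop codon."""
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = "".join(rng.choice(BASES, size=3))
        if c not in STOP_CODONS:
            codons.append(c)
    codons.append(str(rng.choice(STOP_CODONS)))
    return "".join(codons)


def _plant_transcript(
    rng: np.random.Generator,
    genome: dict[str, list[str]],
    chrom: str,
    cursor: int,
    tx_id: str,
    noncoding: bool,
) -> TranscriptModel | None:
    """Lay one transcript down starting near ``cursor``; returns None if it
    would run past the chromosome end."""
    n_exons = int(rng.integers(1, 9))
    exon_lens = rng.integers(80, 301, size=n_exons)
    intron_lens = rng.integers(30, 501, size=max(0, n_exons - 1))
    tx_start = cursor
    exons: list[tuple[int, int]] = []
    p = tx_start
    for i in range(n_exons):
        exons.append((p, p + int(exon_lens[i])))
        p += int(exon_lens[i])
        if i < n_exons - 1:
            p += int(intron_lens[i])
    tx_end = exons[-1][1]
    if tx_end + DEFAULT_DOWNSTREAM + 10 > len(genome[chrom]):
        return None
    strand = "+" if rng.random() < 0.5 else "-"

    if noncoding:
        return TranscriptModel(
            ucsc_id=tx_id, chromosome=chrom, strand=strand,
            tx_start=tx_start, tx_end=tx_end,
            cds_start=tx_start, cds_end=tx_start, exons=exons,
        )

    total_exonic = int(sum(exon_lens))
    # Transcript-orientation UTR lengths; CDS length divisible by 3, >= 8 codons.
    max_cds = total_exonic - 30
    n_codons = int(rng.integers(8, max(9, max_cds // 3)))
    cds_len = 3 * n_codons
    slack = total_exonic - cds_len
    utr5 = int(rng.integers(10, slack - 9))
    utr3 = slack - utr5
    left_off, right_off = (utr5, utr3) if strand == "+" else (utr3, utr5)
    cds_start = _exonic_to_genomic(exons, left_off)
    cds_end = _exonic_to_genomic(exons, total_exonic - right_off - 1) + 1
    t = TranscriptModel(
        ucsc_id=tx_id, chromosome=chrom, strand=strand,
        tx_start=tx_start, tx_end=tx_end,
        cds_start=cds_start, cds_end=cds_end, exons=exons,
    )
    # Write a clean coding sequence (ATG ... stop, no internal stop) into the
    # genome along the transcript's CDS positions.
    coding = _random_coding_sequence(rng, n_codons)
    if strand == "-":
        coding_on_genome = str(Seq(coding).reverse_complement())
    else:
        coding_on_genome = coding
    seq = genome[chrom]
    for base, gpos in zip(coding_on_genome, (g for s, e in t.cds_pieces() for g in range(s, e))):
        seq[gpos] = base
    return t


def _make_isoform(
    rng: np.random.Generator,
    primary: TranscriptModel,
    tx_id: str,
    chrom_len: int,
    left_limit: int,
) -> TranscriptModel | None:
    """An isoform sharing the primary's CDS exactly, with extended outer UTRs."""
    if not primary.is_coding:
        return None
    ext5 = int(rng.integers(5, 51))
    ext3 = int(rng.integers(5, 51))
    new_start = primary.tx_start - ext5
    new_end = primary.tx_end + ext3
    if new_start <= left_limit or new_end + DEFAULT_DOWNSTREAM + 10 > chrom_len:
        return None
    exons = list(primary.exons)
    exons[0] = (new_start, exons[0][1])
    exons[-1] = (exons[-1][0], new_end)
    return TranscriptModel(
        ucsc_id=tx_id, chromosome=primary.chromosome, strand=primary.strand,
        tx_start=new_start, tx_end=new_end,
        cds_start=primary.cds_start, cds_end=primary.cds_end, exons=exons,
    )


def _spliced_cds(genome: dict[str, str], t: TranscriptModel) -> str:
    """Strand-resolved spliced CDS read directly off the genome."""
    seq = "".join(genome[t.chromosome][s:e] for s, e in t.cds_pieces())
    return str(Seq(seq).reverse_complement()) if t.strand == "-" else seq


# ---------------------------------------------------------------------------
# the brute-force oracle


def _classify_in_transcript(
    t: TranscriptModel,
    p: int,
    upstream: int,
    downstream: int,
    boundary: int,
) -> str | None:
    """Region class of 0-based position ``p`` for one transcript, or None."""
    plus = t.strand == "+"
    left_pad = upstream if plus else downstream
    right_pad = downstream if plus else upstream
    if t.tx_start - left_pad <= p < t.tx_start:
        return "UPSTREAM" if plus else "DOWNSTREAM"
    if t.tx_end <= p < t.tx_end + right_pad:
        return "DOWNSTREAM" if plus else "UPSTREAM"
    if not (t.tx_start <= p < t.tx_end):
        return None
    for i, (s, e) in enumerate(t.exons):
        if s <= p < e:
            if not t.is_coding:
                return "NONCODING_EXON"
            if p < t.cds_start:
                return "UTR5" if plus else "UTR3"
            if p >= t.cds_end:
                return "UTR3" if plus else "UTR5"
            return "CDSHIT"
        if i + 1 < len(t.exons) and e <= p < t.exons[i + 1][0]:
            dist = min(p - e + 1, t.exons[i + 1][0] - p)
            return "INTRON_SPLICE" if 1 <= dist <= boundary else "INTRON"
    return None


def _oracle_effect(
    genome: dict[str, str],
    t: TranscriptModel,
    p: int,
    ref: str,
    alt: str,
) -> tuple[str, int, str, str]:
    """(effect_class, aa_position, ref_aa, alt_aa) by whole-protein diff."""
    coding = _coding_positions(t)
    idx = coding.index(p)
    ref_cds = _spliced_cds(genome, t)
    chrom_seq = genome[t.chromosome]
    alt_chrom = chrom_seq[:p] + alt + chrom_seq[p + 1 :]
    alt_cds = _spliced_cds({**genome, t.chromosome: alt_chrom}, t)
    ref_prot = str(Seq(ref_cds).translate())
    alt_prot = str(Seq(alt_cds).translate())
    i = idx // 3
    ref_aa, alt_aa = ref_prot[i], alt_prot[i]
    if ref_aa == alt_aa:
        cls = "SYN"
    elif alt_aa == "*":
        cls = "NSN"
    elif ref_aa == "*":
        cls = "STL"
    else:
        cls = "NSM"
    return cls, i + 1, ref_aa, alt_aa


def brute_force_annotate(
    v: VariantRecord,
    bundle: SyntheticBundle,
) -> TruthEntry:
    """Expected annotation of one variant by exhaustive linear scans.

    Classifies against every transcript by direct coordinate comparison,
    derives coding consequences by translating the whole reference and
    alternate CDS, and prioritizes by exhaustive sort. Asymptotically
    naive by design; shares no index or codon arithmetic with the
    pipeline.
    """
    p = v.position - 1
    hits: list[tuple[int, str, str, str | None, int | None, str | None, str | None]] = []
    for t in bundle.transcripts:
        if t.chromosome != v.chromosome:
            continue
        cls = _classify_in_transcript(
            t, p, bundle.upstream_window, bundle.downstream_window, bundle.intron_boundary
        )
        if cls is None:
            continue
        effect = aa_pos = ref_aa = alt_aa = None
        if cls == "CDSHIT" and v.is_snp:
            effect, aa_pos, ref_aa, alt_aa = _oracle_effect(
                bundle.genome, t, p, v.ref_allele, v.alt_allele
            )
        key = (cls, effect) if cls == "CDSHIT" else cls
        hits.append((_ORACLE_PRIORITY[key], t.ucsc_id, cls, effect, aa_pos, ref_aa, alt_aa))
    if not hits:
        return TruthEntry("INTERGENIC", None, None, None, None, "NA", "NA")
    hits.sort(key=lambda h: (h[0], h[1]))
    _, tx, cls, effect, aa_pos, ref_aa, alt_aa = hits[0]
    return TruthEntry(
        hit_class=cls, effect_class=effect, aa_position=aa_pos,
        ref_aa=ref_aa, alt_aa=alt_aa, transcript=tx,
        gene_symbol=bundle.xref.get(tx, tx),
    )


# ---------------------------------------------------------------------------
# variant planting


def _candidate_pools(
    transcripts: list[TranscriptModel],
    genome: dict[str, str],
    upstream: int,
    downstream: int,
    boundary: int,
) -> dict[str, list[tuple[str, int]]]:
    """Candidate (chrom, 0-based position) pools per region class."""
    pools: dict[str, list[tuple[str, int]]] = {k: [] for k in DEFAULT_REGION_MIX}
    covered: dict[str, np.ndarray] = {
        c: np.zeros(len(s), dtype=bool) for c, s in genome.items()
    }
    for t in transcripts:
        plus = t.strand == "+"
        left_pad = upstream if plus else downstream
        right_pad = downstream if plus else upstream
        lo = max(0, t.tx_start - left_pad)
        hi = min(len(genome[t.chromosome]), t.tx_end + right_pad)
        covered[t.chromosome][lo:hi] = True
        for p in range(lo, hi):
            cls = _classify_in_transcript(t, p, upstream, downstream, boundary)
            if cls is not None:
                pools[cls].append((t.chromosome, p))
    for chrom, mask in covered.items():
        for p in np.flatnonzero(~mask):
            pools["INTERGENIC"].append((chrom, int(p)))
    return pools


def _draw_variant(
    rng: np.random.Generator,
    target: str,
    pools: dict[str, list[tuple[str, int]]],
    bundle: SyntheticBundle,
    is_indel: bool,
    max_attempts: int = 50,
) -> VariantRecord:
    """Rejection-sample a variant whose prioritized oracle class == target."""
    pool = pools[target]
    v = None
    for _ in range(max_attempts):
        chrom, p = pool[int(rng.integers(len(pool)))]
        seq = bundle.genome[chrom]
        ref = seq[p]
        if is_indel:
            if rng.random() < 0.5 and p + 3 < len(seq):   # deletion
                dlen = int(rng.integers(1, 4))
                ref_allele, alt_allele = seq[p : p + 1 + dlen], ref
            else:                                          # insertion
                ins = "".join(rng.choice(BASES, size=int(rng.integers(1, 4))))
                ref_allele, alt_allele = ref, ref + ins
        else:
            ref_allele = ref
            alt_allele = str(rng.choice([b for b in "ACGT" if b != ref]))
        v = VariantRecord(
            chromosome=chrom, position=p + 1,
            ref_allele=ref_allele, alt_allele=alt_allele,
        )
        if brute_force_annotate(v, bundle).hit_class == target:
            return v
    logger.warning("could not plant a %s variant in %d attempts; keeping last draw",
                   target, max_attempts)
    return v


# ---------------------------------------------------------------------------
# bundle generation


def generate_bundle(
    seed: int,
    n_transcripts: int = 20,
    n_variants: int = 80,
    region_mix: dict[str, float] | None = None,
    chrom_length: int = DEFAULT_CHROM_LENGTH,
    indel_fraction: float = 0.05,
    noncoding_fraction: float = 0.12,
    isoform_fraction: float = 0.35,
    upstream_window: int = DEFAULT_UPSTREAM,
    downstream_window: int = DEFAULT_DOWNSTREAM,
    intron_boundary: int = DEFAULT_INTRON_BOUNDARY,
    _attempt: int = 0,
) -> SyntheticBundle:
    """Generate a deterministic synthetic bundle for a given seed.

    Transcripts are laid out on as many chromosomes as they need, on both
    strands, with isoform pairs sharing an identical CDS to exercise
    prioritization; variants are planted per ``region_mix`` so that each
    one's prioritized oracle class equals its target class. The truth table
    is filled by :func:`brute_force_annotate`, never by the pipeline.
    """
    if n_transcripts < 1:
        raise ValueError("n_transcripts must be >= 1")
    mix = dict(region_mix) if region_mix else dict(DEFAULT_REGION_MIX)
    if any(w < 0 for w in mix.values()) or sum(mix.values()) <= 0:
        raise ValueError("region_mix weights must be >= 0 and sum > 0")
    unknown = set(mix) - set(DEFAULT_REGION_MIX)
    if unknown:
        raise ValueError(f"unknown region classes in mix: {sorted(unknown)}")

    rng = np.random.default_rng(seed + _attempt * 1_000_003)
    genome_lists = _random_genome(rng, 2, chrom_length)
    chrom_names = list(genome_lists)

    transcripts: list[TranscriptModel] = []
    xref: dict[str, str] = {}
    chrom_i = 0
    cursor = upstream_window + 100
    gene_no = 0
    while len(transcripts) < n_transcripts:
        chrom = chrom_names[chrom_i]
        tx_id = f"uc{gene_no + 1:06d}.1"
        noncoding = rng.random() < noncoding_fraction
        t = _plant_transcript(rng, genome_lists, chrom, cursor, tx_id, noncoding)
        if t is None:
            chrom_i += 1
            if chrom_i >= len(chrom_names):
                name = f"chr{len(chrom_names) + 1}"
                genome_lists[name] = list(rng.choice(BASES, size=chrom_length))
                chrom_names.append(name)
            cursor = upstream_window + 100
            continue
        gene_no += 1
        transcripts.append(t)
        xref[t.ucsc_id] = f"GENE{gene_no}"
        locus_end = t.tx_end
        if len(transcripts) < n_transcripts and rng.random() < isoform_fraction:
            iso = _make_isoform(rng, t, f"uc{gene_no:06d}.2", len(genome_lists[chrom]),
                                left_limit=cursor - 60)
            if iso is not None:
                transcripts.append(iso)
                xref[iso.ucsc_id] = xref[t.ucsc_id]
                locus_end = max(locus_end, iso.tx_end)
        cursor = locus_end + int(rng.integers(300, 3001))

    genome = {c: "".join(s) for c, s in genome_lists.items()}

    # Invariant check: every coding CDS starts ATG, ends with a stop, mod 3.
    sequences: list[tuple[str, str, str]] = []
    for t in transcripts:
        if not t.is_coding:
            continue
        cds = _spliced_cds(genome, t)
        assert len(cds) % 3 == 0 and cds.startswith("ATG") and cds[-3:] in STOP_CODONS, t.ucsc_id
        sequences.append((t.ucsc_id, t.strand, cds))

    bundle = SyntheticBundle(
        genome=genome, transcripts=transcripts, xref=xref,
        sequences=sequences, variants=[], truth={},
        upstream_window=upstream_window, downstream_window=downstream_window,
        intron_boundary=intron_boundary,
    )

    pools = _candidate_pools(transcripts, genome, upstream_window,
                             downstream_window, intron_boundary)
    requested = [k for k, w in mix.items() if w > 0]
    infeasible = [k for k in requested if not pools[k]]
    if infeasible:
        logger.warning("region mix infeasible (%s empty), regenerating", infeasible)
        if _attempt >= 9:
            raise RuntimeError(f"could not satisfy region mix after 10 attempts: {infeasible}")
        return generate_bundle(
            seed, n_transcripts, n_variants, region_mix, chrom_length,
            indel_fraction, noncoding_fraction, isoform_fraction,
            upstream_window, downstream_window, intron_boundary,
            _attempt=_attempt + 1,
        )

    weights = np.array([mix[k] for k in requested], dtype=float)
    weights /= weights.sum()
    targets = [requested[i] for i in rng.choice(len(requested), size=n_variants, p=weights)]
    variants: list[VariantRecord] = []
    seen_keys: set[str] = set()
    for i, target in enumerate(targets):
        is_indel = rng.random() < indel_fraction
        for _ in range(20):  # avoid duplicate variant keys
            v = _draw_variant(rng, target, pools, bundle, is_indel)
            if v.key not in seen_keys:
                break
        seen_keys.add(v.key)
        variants.append(v)

    variants.sort(key=lambda v: (v.chromosome, v.position, v.ref_allele, v.alt_allele))
    for i, v in enumerate(variants):
        v.dbsnp_id = f"rs{i + 1}"
        v.quality = str(int(rng.integers(20, 100)))
        v.depth = int(rng.integers(10, 200))
        v.allele_freq = round(float(rng.uniform(0.05, 0.95)), 3)
        fwd_ref = int(rng.integers(0, v.depth + 1))
        v.read_categories = ",".join(
            str(x) for x in (fwd_ref, v.depth - fwd_ref,
                             int(rng.integers(0, 50)), int(rng.integers(0, 50)))
        )
        v.sample_id = "SAMPLE1"
    bundle.variants = variants
    bundle.truth = {v.key: brute_force_annotate(v, bundle) for v in variants}
    return bundle


# ---------------------------------------------------------------------------
# mirroring (for strand-symmetry checks)


def mirror_bundle(bundle: SyntheticBundle) -> SyntheticBundle:
    """Reflect every coordinate, flip strands and reverse-complement the genome.

    A variant at 0-based p maps to L-1-p with complemented alleles; the
    mirrored bundle's truth is recomputed with the oracle. Only defined for
    substitution-only bundles (indel anchors do not mirror cleanly).
    """
    genome = {c: str(Seq(s).reverse_complement()) for c, s in bundle.genome.items()}
    lengths = {c: len(s) for c, s in bundle.genome.items()}

    def refl(chrom: str, s: int, e: int) -> tuple[int, int]:
        L = lengths[chrom]
        return L - e, L - s

    transcripts = []
    for t in bundle.transcripts:
        exons = [refl(t.chromosome, s, e) for s, e in reversed(t.exons)]
        cs, ce = refl(t.chromosome, t.cds_start, t.cds_end)
        ts, te = refl(t.chromosome, t.tx_start, t.tx_end)
        if not t.is_coding:
            cs = ce = ts
        transcripts.append(
            TranscriptModel(
                ucsc_id=t.ucsc_id, chromosome=t.chromosome,
                strand="-" if t.strand == "+" else "+",
                tx_start=ts, tx_end=te, cds_start=cs, cds_end=ce, exons=exons,
            )
        )
    sequences = [
        (tx, "-" if sign == "+" else "+", seq) for tx, sign, seq in bundle.sequences
    ]
    variants = []
    for v in bundle.variants:
        if not v.is_snp:
            raise ValueError("mirror_bundle supports substitution-only bundles")
        L = lengths[v.chromosome]
        variants.append(
            VariantRecord(
                chromosome=v.chromosome, position=L - (v.position - 1),
                dbsnp_id=v.dbsnp_id,
                ref_allele=str(Seq(v.ref_allele).complement()),
                alt_allele=str(Seq(v.alt_allele).complement()),
                quality=v.quality, depth=v.depth, allele_freq=v.allele_freq,
                read_categories=v.read_categories, info=v.info, sample_id=v.sample_id,
            )
        )
    mirrored = SyntheticBundle(
        genome=genome, transcripts=transcripts, xref=dict(bundle.xref),
        sequences=sequences, variants=variants, truth={},
        upstream_window=bundle.upstream_window,
        downstream_window=bundle.downstream_window,
        intron_boundary=bundle.intron_boundary,
    )
    mirrored.truth = {v.key: brute_force_annotate(v, mirrored) for v in variants}
    return mirrored


# ---------------------------------------------------------------------------
# writers


def write_bundle(bundle: SyntheticBundle, out_dir: str, with_genotypes: bool = True) -> dict[str, str]:
    """Write all pipeline input dialects plus truth and genome FASTA.

    Returns a dict of logical name -> path (known_gene, kgxref, sequence,
    vcf, truth, fasta, config).
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "known_gene": os.path.join(out_dir, "knownGene.txt"),
        "kgxref": os.path.join(out_dir, "kgXref.txt"),
        "sequence": os.path.join(out_dir, "cds_sequences.txt"),
        "vcf": os.path.join(out_dir, "variants.vcf"),
        "truth": os.path.join(out_dir, "truth.tsv"),
        "fasta": os.path.join(out_dir, "genome.fa"),
        "config": os.path.join(out_dir, "config.txt"),
    }

    with open(paths["known_gene"], "wt", encoding="utf-8") as fh:
        for t in bundle.transcripts:
            starts = ",".join(str(s) for s, _ in t.exons) + ","
            ends = ",".join(str(e) for _, e in t.exons) + ","
            fh.write("\t".join([
                t.ucsc_id, t.chromosome, t.strand,
                str(t.tx_start), str(t.tx_end), str(t.cds_start), str(t.cds_end),
                str(len(t.exons)), starts, ends, "", t.ucsc_id,
            ]) + "\n")

    with open(paths["kgxref"], "wt", encoding="utf-8") as fh:
        for tx, symbol in bundle.xref.items():
            fh.write("\t".join([tx, tx, "", "", symbol, "", "", ""]) + "\n")

    with open(paths["sequence"], "wt", encoding="utf-8") as fh:
        for tx, sign, seq in bundle.sequences:
            fh.write(f"{tx}\t{sign}\t{seq}\n")

    write_vcf(bundle.variants, paths["vcf"], bundle.genome, with_genotypes)

    with open(paths["truth"], "wt", encoding="utf-8") as fh:
        fh.write("variant_key\thit_class\teffect_class\taa_position\tref_aa\talt_aa"
                 "\ttranscript\tgene_symbol\n")
        for v in bundle.variants:
            e = bundle.truth[v.key]
            fh.write("\t".join([
                v.key, e.hit_class, e.effect_class or "NA",
                str(e.aa_position) if e.aa_position else "NA",
                e.ref_aa or "NA", e.alt_aa or "NA", e.transcript, e.gene_symbol,
            ]) + "\n")

    with open(paths["fasta"], "wt", encoding="utf-8") as fh:
        for chrom, seq in bundle.genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")

    with open(paths["config"], "wt", encoding="utf-8") as fh:
        fh.write(
            f"vcfFile = variants.vcf\n"
            f"geneAnnotation = knownGene.txt\n"
            f"conversionFile = kgXref.txt\n"
            f"sequenceFile = cds_sequences.txt\n"
            f"intronBoundary = {bundle.intron_boundary}\n"
            f"upstreamWindow = {bundle.upstream_window}\n"
            f"downstreamWindow = {bundle.downstream_window}\n"
            f"outputFile = annotated.tsv\n"
        )
    return paths


def write_vcf(
    variants: list[VariantRecord],
    path: str,
    genome: dict[str, str] | None = None,
    with_genotypes: bool = True,
) -> str:
    """Write variants as a plain VCF v4.2 file."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if genome:
            for chrom, seq in genome.items():
                fh.write(f"##contig=<ID={chrom},length={len(seq)}>\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Raw read depth">\n')
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">\n')
        fh.write('##INFO=<ID=DP4,Number=4,Type=Integer,Description='
                 '"Ref-forward, ref-reverse, alt-forward and alt-reverse read counts">\n')
        if with_genotypes:
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
        if with_genotypes:
            sample = next((v.sample_id for v in variants if v.sample_id), "SAMPLE1")
            cols += ["FORMAT", sample]
        fh.write("\t".join(cols) + "\n")
        for v in variants:
            info_parts = []
            if v.depth is not None:
                info_parts.append(f"DP={v.depth}")
            if v.allele_freq is not None:
                info_parts.append(f"AF={v.allele_freq:g}")
            if v.read_categories:
                info_parts.append(f"DP4={v.read_categories}")
            row = [v.chromosome, str(v.position), v.dbsnp_id, v.ref_allele,
                   v.alt_allele, str(v.quality), "PASS", ";".join(info_parts) or "."]
            if with_genotypes:
                row += ["GT", "0/1"]
            fh.write("\t".join(row) + "\n")
    return path
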