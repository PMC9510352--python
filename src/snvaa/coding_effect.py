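"""Amino-acid change prediction for coding-sequence variants.

Given a strand-resolved spliced CDS per transcript, a coding-base offset
and a substitution, this module extracts the affected codon, applies the
(strand-complemented, for minus-strand transcripts) alternate base,
translates both codons with the standard genetic code, and classifies the
consequence as SYN (synonymous), NSM (nonsynonymous/missense), NSN
(nonsense/stop-gain) or STL (stop-loss). Any N in the affected codon, a
reference-allele mismatch, or an offset beyond the last full codon of an
incomplete CDS yields UNKNOWN.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

logger = logging.getLogger(__name__)

# Standard genetic code (translation table 1). Authored here because
# strand-aware codon substitution is the core of this package; tests
# cross-check every codon against an independent published table.
CODON_TABLE: dict[str, str] = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class EffectClass(str, Enum):
    SYN = "SYN"        # synonymous
    NSM = "NSM"        # nonsynonymous (missense)
    NSN = "NSN"        # nonsense (stop-gain)
    STL = "STL"        # stop-loss
    UNKNOWN = "UNKNOWN"

    def __str__(self) -> str:  # noqa: D105
        return self.value


@dataclass
class TranscriptSequence:
    """Spliced CDS of one transcript in coding orientation.

    ``cds_sequence`` is already reverse-complemented for minus-strand
    transcripts; ``strand_sign`` records the genomic strand. A length not
    divisible by 3 flags the transcript ``incomplete_cds`` (annotatable up
    to the last full codon).
    """

    transcript: str
    strand_sign: str
    cds_sequence: str

    def __post_init__(self) -> None:
        self.cds_sequence = self.cds_sequence.upper()
        if not self.cds_sequence:
            raise ValueError(f"{self.transcript}: empty CDS sequence")
        if set(self.cds_sequence) - set("ACGTN"):
            raise ValueError(f"{self.transcript}: CDS alphabet must be ACGTN")
        if self.strand_sign not in ("+", "-"):
            raise ValueError(f"{self.transcript}: strand sign must be '+' or '-'")

    @property
    def incomplete_cds(self) -> bool:
        return len(self.cds_sequence) % 3 != 0


@dataclass(frozen=True)
class CodingEffect:
    """Codon-level consequence of a single-base CDS substitution."""

    aa_position: int         # 1-based codon index
    ref_codon: str
    alt_codon: str
    ref_aa: str
    alt_aa: str
    effect_class: EffectClass

    @property
    def display(self) -> str:
        """Render as ``refAA(refCodon) -> altAA(altCodon)``."""
        if self.effect_class is EffectClass.UNKNOWN:
            return "NA"
        return f"{self.ref_aa}({self.ref_codon}) -> {self.alt_aa}({self.alt_codon})"


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate_codon(codon: str) -> str:
    """Translate one codon under the standard genetic code.

    Stops render as '*'; any codon containing N renders as 'X'.
    """
    if len(codon) != 3:
        raise ValueError(f"codon must have length 3, got {codon!r}")
    codon = codon.upper()
    if "N" in codon:
        return "X"
    try:
        return CODON_TABLE[codon]
    except KeyError:
        raise ValueError(f"unrecognized codon {codon!r}") from None


def translate_cds(seq: str, to_first_stop: bool = True) -> str:
    """Translate a CDS codon-by-codon, by default stopping before the first stop."""
    aas = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        aa = translate_codon(seq[i : i + 3])
        if aa == "*" and to_first_stop:
            break
        aas.append(aa)
    return "".join(aas)


def parse_sequence_file(path: str) -> dict[str, TranscriptSequence]:
    """Parse the strand-resolved CDS file (TSV: ucsc_id, sign, sequence).

    Sequences are upper-cased; duplicates keep the first entry and warn;
    empty sequences are skipped with a warning.
    """
    seqs: dict[str, TranscriptSequence] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                logger.warning("%s:%d: fewer than 3 columns, skipped", path, lineno)
                continue
            tx, sign, seq = fields[0].strip(), fields[1].strip(), fields[2].strip()
            if not seq:
                logger.warning("%s:%d: empty sequence for %s, skipped", path, lineno, tx)
                continue
            if tx in seqs:
                logger.warning("%s:%d: duplicate transcript %s, keeping first", path, lineno, tx)
                continue
            record = TranscriptSequence(transcript=tx, strand_sign=sign, cds_sequence=seq)
            if record.incomplete_cds:
                logger.warning("%s: CDS length %d not divisible by 3 (incomplete_cds)",
                               tx, len(record.cds_sequence))
            seqs[tx] = record
    return seqs


def predict_aa_change(
    cds_offset: int,
    ref_allele: str,
    alt_allele: str,
    seq: TranscriptSequence,
) -> CodingEffect:
    """Predict the amino-acid change of a single-base CDS substitution.

    ``cds_offset`` is the 0-based coding-base index in transcript
    orientation; ``ref_allele``/``alt_allele`` are the genomic (plus-strand)
    alleles from the VCF and are complemented for minus-strand transcripts
    before substitution. A mismatch between the strand-resolved reference
    base and the CDS sequence yields UNKNOWN with a warning rather than a
    silent override.
    """
    if len(ref_allele) != 1 or len(alt_allele) != 1:
        raise ValueError("predict_aa_change handles single-base substitutions only")
    codon_index = cds_offset // 3
    within = cds_offset % 3
    aa_position = codon_index + 1
    if cds_offset < 0 or cds_offset >= len(seq.cds_sequence):
        raise ValueError(f"{seq.transcript}: cds_offset {cds_offset} outside CDS")
    ref_codon = seq.cds_sequence[codon_index * 3 : codon_index * 3 + 3]
    if len(ref_codon) < 3:
        # Beyond the last full codon of an incomplete CDS.
        return CodingEffect(aa_position, ref_codon, ref_codon, "X", "X", EffectClass.UNKNOWN)

    minus = seq.strand_sign == "-"
    ref_tx = complement(ref_allele.upper()) if minus else ref_allele.upper()
    alt_tx = complement(alt_allele.upper()) if minus else alt_allele.upper()

    if seq.cds_sequence[cds_offset] != ref_tx:
        logger.warning(
            "%s: reference mismatch at cds_offset %d (CDS has %s, VCF implies %s)",
            seq.transcript, cds_offset, seq.cds_sequence[cds_offset], ref_tx,
        )
        return CodingEffect(aa_position, ref_codon, ref_codon, "X", "X", EffectClass.UNKNOWN)

    alt_codon = ref_codon[:within] + alt_tx + ref_codon[within + 1 :]
    ref_aa = translate_codon(ref_codon)
    alt_aa = translate_codon(alt_codon)
    if ref_aa == "X" or alt_aa == "X":
        cls = EffectClass.UNKNOWN
    elif ref_aa == alt_aa:
        cls = EffectClass.SYN
    elif alt_aa == "*":
        cls = EffectClass.NSN
    elif ref_aa == "*":
        cls = EffectClass.STL
    else:
        cls = EffectClass.NSM
    return CodingEffect(aa_position, ref_codon, alt_codon, ref_aa, alt_aa, cls)


def build_aa_chains(seq: TranscriptSequence, effect: CodingEffect) -> tuple[str, str]:
    """Full reference and alternate protein chains for a coding effect.

    Both chains are translated up to (not including) the first stop codon;
    a stop-gain therefore truncates the alternate chain at the new stop.
    """
    if effect.effect_class is EffectClass.UNKNOWN:
        raise ValueError("cannot build chains for an UNKNOWN effect")
    cds = seq.cds_sequence
    off = (effect.aa_position - 1) * 3
    alt_cds = cds[:off] + effect.alt_codon + cds[off + 3 :]
    return translate_cds(cds), translate_cds(alt_cds)
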