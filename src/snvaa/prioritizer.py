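"""Mutation-effect prioritization and downstream summaries.

Collapses the per-transcript region hits of one variant to the single
highest-priority annotation under a total order (stop-gain/stop-loss >
missense > synonymous within coding; coding > UTR > splice-proximal
intron > other non-coding), and computes cohort summaries: region
distribution, coding-effect class counts, and the hydropathy-conversion
table over missense variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .coding_effect import CodingEffect, EffectClass
from .region_mapper import HitClass, RegionHit
from .variant_io import NA, AnnotatedRecord, VariantRecord

# Kyte-Doolittle hydropathy index, standard published values.
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

#: Default priority order, most damaging first. Keys are either a HitClass
#: (non-coding tiers) or a (HitClass.CDSHIT, EffectClass) pair; pairs
#: sharing a tier are listed together.
DEFAULT_PRIORITY_ORDER: list[tuple] = [
    ((HitClass.CDSHIT, EffectClass.NSN), (HitClass.CDSHIT, EffectClass.STL)),
    ((HitClass.CDSHIT, EffectClass.NSM),),
    ((HitClass.CDSHIT, EffectClass.SYN),),
    ((HitClass.CDSHIT, EffectClass.UNKNOWN),),
    (HitClass.UTR5,),
    (HitClass.UTR3,),
    (HitClass.INTRON_SPLICE,),
    (HitClass.NONCODING_EXON,),
    (HitClass.INTRON,),
    (HitClass.UPSTREAM,),
    (HitClass.DOWNSTREAM,),
    (HitClass.INTERGENIC,),
]


@dataclass
class PriorityTable:
    """Total order over producible (hit_class, effect_class) keys."""

    ranks: dict = field(default_factory=dict)

    @classmethod
    def default(cls) -> "PriorityTable":
        return cls.from_order(DEFAULT_PRIORITY_ORDER)

    @classmethod
    def from_order(cls, order: list[tuple]) -> "PriorityTable":
        """Build from a list of tiers; keys in one tier share a rank."""
        ranks: dict = {}
        for rank, tier in enumerate(order):
            for key in tier:
                ranks[key] = rank
        return cls(ranks=ranks)

    def rank(self, hit_class: HitClass, effect_class: EffectClass | None = None) -> int:
        if hit_class is HitClass.CDSHIT:
            key = (hit_class, effect_class or EffectClass.UNKNOWN)
        else:
            key = hit_class
        try:
            return self.ranks[key]
        except KeyError:
            raise ValueError(f"priority table has no rank for {key!r}") from None


@dataclass(frozen=True)
class ScoredHit:
    """A region hit with its (optional) coding effect and protein chains."""

    hit: RegionHit
    effect: CodingEffect | None = None
    ref_chain: str = NA
    alt_chain: str = NA


def prioritize_hits(
    variant: VariantRecord,
    hits: list[ScoredHit],
    table: PriorityTable | None = None,
) -> AnnotatedRecord:
    """Select the highest-priority hit of one variant and render its row.

    Pure and permutation-invariant: minimal rank wins, ties broken by
    lexicographically smallest transcript id.
    """
    if not hits:
        raise ValueError(f"{variant.key}: no hits to prioritize")
    table = table or PriorityTable.default()
    best = min(
        hits,
        key=lambda sh: (
            table.rank(sh.hit.hit_class, sh.effect.effect_class if sh.effect else None),
            sh.hit.transcript,
            sh.hit.hit_class.value,
        ),
    )
    return render_record(variant, best)


def render_record(variant: VariantRecord, sh: ScoredHit) -> AnnotatedRecord:
    """Render one selected hit as the final annotated row."""
    hit, effect = sh.hit, sh.effect
    known = effect is not None and effect.effect_class is not EffectClass.UNKNOWN
    return AnnotatedRecord(
        chromosome=variant.chromosome,
        variant_position=variant.position,
        gene_symbol=hit.gene_symbol,
        ucsc_id=hit.transcript,
        strand=hit.strand,
        aa_position=str(effect.aa_position) if known else NA,
        variant_type=variant.variant_type,
        aa_change=effect.display if known else NA,
        variant_class=str(effect.effect_class) if effect is not None else NA,
        ref_aa_chain=sh.ref_chain if known else NA,
        alt_aa_chain=sh.alt_chain if known else NA,
        hit_type=str(hit.hit_class),
        dbsnp_id=variant.dbsnp_id,
        ref_nt=variant.ref_allele,
        alt_nt=variant.alt_allele,
        quality=str(variant.quality),
        depth=str(variant.depth) if variant.depth is not None else NA,
        allele_freq=f"{variant.allele_freq:g}" if variant.allele_freq is not None else NA,
        read_categories=variant.read_categories or NA,
        info=variant.info,
        sample_id=variant.sample_id,
    )


def hydropathy_class(aa: str) -> str:
    """'hydrophobic' iff the Kyte-Doolittle index is positive, else 'hydrophilic'."""
    try:
        return "hydrophobic" if KYTE_DOOLITTLE[aa] > 0 else "hydrophilic"
    except KeyError:
        raise ValueError(f"not a standard amino acid: {aa!r}") from None


def _aa_from_change(change: str) -> tuple[str, str] | None:
    """Extract (ref_aa, alt_aa) from a 'K(AAA) -> E(GAA)' display string."""
    if "->" not in change:
        return None
    left, right = (part.strip() for part in change.split("->", 1))
    if not left or not right:
        return None
    return left[0], right[0]


def summarize(
    records: list[AnnotatedRecord],
    group_labels: list[str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Cohort summary tables over final annotated records.

    Returns three DataFrames: ``regions`` (counts and percentages by Hit
    Type), ``variant_classes`` (effect-class counts within CDSHIT) and
    ``hydropathy`` (ref-class x alt-class conversion counts over missense
    records), each stratified by ``group_labels`` when given. Percentages
    sum to 100 per stratum up to rounding.
    """
    if group_labels is not None and len(group_labels) != len(records):
        raise ValueError("group_labels length must match records")
    df = pd.DataFrame(
        {
            "hit_type": [r.hit_type for r in records],
            "variant_class": [r.variant_class for r in records],
            "aa_change": [r.aa_change for r in records],
            "group": group_labels if group_labels is not None else ["all"] * len(records),
        }
    )

    if df.empty:
        empty = pd.DataFrame()
        return {"regions": empty, "variant_classes": empty, "hydropathy": empty}

    regions = (
        df.groupby(["group", "hit_type"]).size().rename("count").reset_index()
    )
    totals = regions.groupby("group")["count"].transform("sum")
    regions["percent"] = 100.0 * regions["count"] / totals

    cds = df[df["hit_type"] == str(HitClass.CDSHIT)]
    variant_classes = (
        cds.groupby(["group", "variant_class"]).size().rename("count").reset_index()
    )

    nsm = df[df["variant_class"] == str(EffectClass.NSM)].copy()
    rows = []
    for _, row in nsm.iterrows():
        pair = _aa_from_change(row["aa_change"])
        if pair is None:
            continue
        ref_aa, alt_aa = pair
        if ref_aa not in KYTE_DOOLITTLE or alt_aa not in KYTE_DOOLITTLE:
            continue
        rows.append(
            {
                "group": row["group"],
                "ref_class": hydropathy_class(ref_aa),
                "alt_class": hydropathy_class(alt_aa),
            }
        )
    if rows:
        hydropathy = (
            pd.DataFrame(rows)
            .groupby(["group", "ref_class", "alt_class"])
            .size()
            .rename("count")
            .reset_index()
        )
    else:
        hydropathy = pd.DataFrame(columns=["group", "ref_class", "alt_class", "count"])

    return {"regions": regions, "variant_classes": variant_classes, "hydropathy": hydropathy}
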