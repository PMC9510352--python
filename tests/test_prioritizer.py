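"""Hit prioritization, hydropathy classes, and cohort summaries."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from snvaa.coding_effect import CodingEffect, EffectClass
from snvaa.prioritizer import (
    KYTE_DOOLITTLE,
    PriorityTable,
    ScoredHit,
    hydropathy_class,
    prioritize_hits,
    summarize,
)
from snvaa.region_mapper import HitClass, RegionHit
from snvaa.variant_io import AnnotatedRecord, VariantRecord


def _variant():
    return VariantRecord(chromosome="chr1", position=100, ref_allele="A", alt_allele="G")


def _hit(tx: str, cls: HitClass) -> RegionHit:
    return RegionHit(chromosome="chr1", position=100, transcript=tx,
                     gene_symbol=tx, strand="+", hit_class=cls,
                     cds_offset=0 if cls is HitClass.CDSHIT else -1)


def _effect(cls: EffectClass) -> CodingEffect:
    aa = {"SYN": ("K", "K"), "NSM": ("K", "E"), "NSN": ("K", "*"),
          "STL": ("*", "Q"), "UNKNOWN": ("X", "X")}[cls.value]
    return CodingEffect(1, "AAA", "GAA", aa[0], aa[1], cls)


def _scored(tx: str, cls: HitClass, effect: EffectClass | None = None) -> ScoredHit:
    return ScoredHit(hit=_hit(tx, cls), effect=_effect(effect) if effect else None)


def test_missense_outranks_synonymous():
    rec = prioritize_hits(_variant(), [
        _scored("txA", HitClass.CDSHIT, EffectClass.SYN),
        _scored("txB", HitClass.CDSHIT, EffectClass.NSM),
    ])
    assert rec.ucsc_id == "txB"
    assert rec.variant_class == "NSM"


def test_utr5_outranks_intron():
    rec = prioritize_hits(_variant(), [
        _scored("txA", HitClass.INTRON),
        _scored("txB", HitClass.UTR5),
    ])
    assert rec.ucsc_id == "txB"
    assert rec.hit_type == "UTR5"


def test_ties_break_on_smallest_transcript_id():
    rec = prioritize_hits(_variant(), [
        _scored("txZ", HitClass.UTR3),
        _scored("txA", HitClass.UTR3),
    ])
    assert rec.ucsc_id == "txA"


def test_default_table_ranks_coding_over_all_noncoding():
    table = PriorityTable.default()
    coding_worst = max(
        table.rank(HitClass.CDSHIT, e)
        for e in (EffectClass.NSN, EffectClass.STL, EffectClass.NSM,
                  EffectClass.SYN, EffectClass.UNKNOWN)
    )
    for cls in HitClass:
        if cls is HitClass.CDSHIT:
            continue
        assert table.rank(cls) > coding_worst


def test_rank_table_is_total_over_producible_pairs():
    table = PriorityTable.default()
    for effect in list(EffectClass) + [None]:
        assert isinstance(table.rank(HitClass.CDSHIT, effect), int)
    for cls in HitClass:
        if cls is not HitClass.CDSHIT:
            assert isinstance(table.rank(cls), int)
    with pytest.raises(ValueError):
        PriorityTable(ranks={}).rank(HitClass.CDSHIT, EffectClass.SYN)


_HIT_POOL = [
    ("tx%02d" % i, cls, eff)
    for i, (cls, eff) in enumerate(
        [(HitClass.CDSHIT, e) for e in (EffectClass.SYN, EffectClass.NSM,
                                        EffectClass.NSN, EffectClass.UNKNOWN)]
        + [(c, None) for c in (HitClass.UTR5, HitClass.UTR3, HitClass.INTRON,
                               HitClass.INTRON_SPLICE, HitClass.UPSTREAM,
                               HitClass.DOWNSTREAM, HitClass.NONCODING_EXON)]
    )
]


@given(st.permutations(_HIT_POOL), st.integers(min_value=1, max_value=len(_HIT_POOL)))
def test_prioritization_is_permutation_invariant(perm, k):
    hits = [_scored(tx, cls, eff) for tx, cls, eff in perm[:k]]
    baseline = prioritize_hits(_variant(), sorted(hits, key=lambda s: s.hit.transcript))
    shuffled = prioritize_hits(_variant(), hits)
    assert shuffled.to_fields() == baseline.to_fields()


def test_prioritize_selection_matches_full_sort_oracle():
    """Selected hit equals argmin-by-(rank, id) from an independent full sort."""
    import numpy as np

    table = PriorityTable.default()
    rng = np.random.default_rng(21)
    pool_classes = [c for c in HitClass if c is not HitClass.INTERGENIC]
    for _ in range(1000):
        n = int(rng.integers(1, 6))
        hits = []
        for i in rng.choice(len(pool_classes), size=n, replace=True):
            cls = pool_classes[int(i)]
            eff = None
            if cls is HitClass.CDSHIT:
                eff = list(EffectClass)[int(rng.integers(5))]
            hits.append(_scored(f"tx{int(rng.integers(100)):03d}", cls, eff))
        rec = prioritize_hits(_variant(), hits, table)
        ranked = sorted(
            hits,
            key=lambda s: (table.rank(s.hit.hit_class,
                                      s.effect.effect_class if s.effect else None),
                           s.hit.transcript),
        )
        assert rec.ucsc_id == ranked[0].hit.transcript


def test_hydropathy_classes():
    assert hydropathy_class("I") == "hydrophobic"
    assert hydropathy_class("R") == "hydrophilic"
    with pytest.raises(ValueError):
        hydropathy_class("*")
    # sign rule partitions the 20 amino acids 7 / 13
    hydrophobic = {aa for aa in KYTE_DOOLITTLE if hydropathy_class(aa) == "hydrophobic"}
    assert hydrophobic == set("ACFILMV")
    assert len(KYTE_DOOLITTLE) - len(hydrophobic) == 13


def _record(hit_type, variant_class="NA", aa_change="NA"):
    return AnnotatedRecord(chromosome="chr1", variant_position=1,
                           hit_type=hit_type, variant_class=variant_class,
                           aa_change=aa_change)


def test_summarize_region_percentages():
    records = [_record("CDSHIT", "SYN")] * 6 + [_record("INTRON")] * 4
    tables = summarize(records)
    regions = tables["regions"].set_index("hit_type")
    assert regions.loc["CDSHIT", "percent"] == pytest.approx(60.0)
    assert regions.loc["INTRON", "percent"] == pytest.approx(40.0)
    assert tables["regions"]["count"].sum() == 10
    assert tables["hydropathy"].empty  # no NSM records, no error


def test_summarize_hydropathy_conversion():
    records = [
        _record("CDSHIT", "NSM", "I(ATT) -> R(AGA)"),   # hydrophobic -> hydrophilic
        _record("CDSHIT", "NSM", "K(AAA) -> E(GAA)"),   # hydrophilic -> hydrophilic
        _record("CDSHIT", "SYN", "K(AAA) -> K(AAG)"),   # not NSM, excluded
    ]
    hydro = summarize(records)["hydropathy"].set_index(["ref_class", "alt_class"])
    assert hydro.loc[("hydrophobic", "hydrophilic"), "count"].item() == 1
    assert hydro.loc[("hydrophilic", "hydrophilic"), "count"].item() == 1
    assert hydro["count"].sum() == 2


def test_summarize_stratified_counts_conserved():
    records = [_record("CDSHIT", "NSM", "K(AAA) -> E(GAA)"), _record("UTR5"),
               _record("INTRON"), _record("CDSHIT", "SYN")]
    labels = ["pathogenic", "pathogenic", "benign", "benign"]
    tables = summarize(records, labels)
    per_group = tables["regions"].groupby("group")["count"].sum()
    assert per_group["pathogenic"] == 2 and per_group["benign"] == 2
    pct = tables["regions"].groupby("group")["percent"].sum()
    assert pct["pathogenic"] == pytest.approx(100.0)
    assert pct["benign"] == pytest.approx(100.0)


def test_summarize_empty_input():
    tables = summarize([])
    assert all(t.empty for t in tables.values())
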