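"""Filter cascade: support, rarity and parental-absence rules plus their
monotonicity and order-independence properties."""
import dataclasses
import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from triodnm.filters import (
    FilterConfig,
    extract_dnms,
    is_de_novo,
    is_rare,
    passes_site_support,
)
from triodnm.types import (
    AnnotationRecord,
    Genotype,
    SampleCall,
    TrioCall,
    VariantSite,
)

CFG = FilterConfig()
SITE = VariantSite("chr1", 1000, "A", "G")


def call(genotype, depth, alt):
    return SampleCall(
        genotype=genotype, depth=depth, alt_reads=alt, ref_reads=depth - alt
    )


def trio(proband, father, mother, **kw):
    return TrioCall(site=SITE, proband=proband, father=father, mother=mother, **kw)


HET, REF = Genotype.HET, Genotype.HOM_REF


@pytest.mark.parametrize(
    "depth,alt,expected",
    [
        (10, 4, True),   # exact boundary of all three support rules
        (30, 5, False),  # 5/30 = 16.7% < 20%
        (9, 9, False),   # depth below 10 even at VAF 1.0
        (0, 0, False),   # uncovered site is a clean False, not an error
        (20, 4, True),   # VAF exactly 20%
        (20, 3, False),  # too few alt reads
    ],
)
def test_site_support(depth, alt, expected):
    assert passes_site_support(call(HET, depth, alt), CFG) is expected


def ann(afs=None, inhouse=0.0):
    return AnnotationRecord(
        site=SITE, gene="G", panel_afs=afs or {}, inhouse_carrier_fraction=inhouse
    )


def test_rarity_rule():
    assert is_rare(ann({"1000g": 0.004, "evs": 0.004}), CFG)
    assert not is_rare(ann({"1000g": 0.005}), CFG)  # >= 0.5% is filtered out
    assert is_rare(ann(), CFG)  # absent from all panels = frequency 0
    assert is_rare(None, CFG)
    assert not is_rare(ann(inhouse=0.01), CFG)


def test_de_novo_basic_patterns():
    good = call(HET, 30, 15)
    clean = call(REF, 30, 0)
    assert is_de_novo(trio(good, clean, clean), CFG)
    # a het parent means inherited, whatever the read support
    assert not is_de_novo(trio(good, call(HET, 30, 15), clean), CFG)
    # one stray parental read in a deep parent is tolerated by default
    assert is_de_novo(trio(good, clean, call(REF, 40, 1)), CFG)
    # ... but not under the strict-zero preset
    strict = FilterConfig.strict_parental_zero()
    assert not is_de_novo(trio(good, clean, call(REF, 40, 1)), strict)
    # missing parental genotype is uninformative
    assert not is_de_novo(trio(good, clean, call(Genotype.MISSING, 0, 0)), CFG)
    # shallow parent cannot exclude inheritance
    assert not is_de_novo(trio(good, clean, call(REF, 6, 0)), CFG)


def test_parental_absence_matches_truth_table():
    """Brute force over parental read counts against the written rule."""
    good = call(HET, 30, 15)
    clean = call(REF, 40, 0)
    for depth in range(0, 45, 4):
        for alt in range(0, min(depth, 6) + 1):
            parent = call(REF, depth, alt)
            expected = (
                depth >= CFG.require_parent_depth
                and alt <= CFG.max_parent_alt_reads
                and depth > 0
                and alt / depth <= CFG.max_parent_vaf
            )
            assert is_de_novo(trio(good, clean, parent), CFG) is expected, (depth, alt)


def _random_trios(n=200, seed=3):
    import numpy as np

    r = np.random.default_rng(seed)
    trios, annotations = [], {}
    for i in range(n):
        site = VariantSite("chr1", 10 + i, "A", "G")
        depth = int(r.integers(0, 60))
        alt = int(r.integers(0, depth + 1)) if depth else 0
        gt = HET if alt else REF
        proband = call(gt, depth, alt)
        parents = []
        for _ in range(2):
            pd = int(r.integers(0, 60))
            pa = int(r.integers(0, 4)) if pd >= 3 else 0
            parents.append(call(HET if r.random() < 0.15 else REF, pd, min(pa, pd)))
        t = TrioCall(site=site, proband=proband, father=parents[0], mother=parents[1])
        trios.append(t)
        af = float(r.choice([0.0, 0.001, 0.004, 0.01, 0.2]))
        annotations[site.key] = AnnotationRecord(
            site=site, gene=f"G{i}", panel_afs={"1000g": af} if af else {}
        )
    return trios, annotations


def _keys(records):
    return {(r.trio_id, r.site.key) for r in records}


RELAXATIONS = [
    ("min_depth", 5),
    ("min_alt_reads", 2),
    ("min_vaf", 0.1),
    ("max_panel_af", 0.05),
    ("max_inhouse_fraction", 0.05),
    ("max_parent_alt_reads", 3),
    ("max_parent_vaf", 0.10),
    ("require_parent_depth", 5),
]


@pytest.mark.parametrize("field,relaxed", RELAXATIONS)
def test_relaxing_any_threshold_grows_the_dnm_set(field, relaxed):
    trios, annotations = _random_trios()
    base = _keys(extract_dnms(trios, annotations, CFG))
    loose = _keys(
        extract_dnms(trios, annotations, dataclasses.replace(CFG, **{field: relaxed}))
    )
    assert base <= loose


def test_filter_order_independence():
    """Applying support/rarity/de-novo in any order keeps the same set."""
    trios, annotations = _random_trios(seed=8)
    filters = {
        "support": lambda t: t.proband.genotype.carries_alt
        and passes_site_support(t.proband, CFG),
        "rare": lambda t: is_rare(annotations.get(t.site.key), CFG),
        "denovo": lambda t: is_de_novo(t, CFG),
    }
    reference = _keys(extract_dnms(trios, annotations, CFG))
    for order in itertools.permutations(filters.values()):
        kept = trios
        for f in order:
            kept = [t for t in kept if f(t)]
        assert {(t.trio_id, t.site.key) for t in kept} == reference


def test_mosaic_flag_and_rarity_exclusion():
    clean = call(REF, 30, 0)
    low_vaf = trio(call(HET, 40, 8), clean, clean)  # VAF 0.20: retained, flagged
    common = TrioCall(
        site=VariantSite("chr1", 2000, "C", "T"),
        proband=call(HET, 40, 20),
        father=clean,
        mother=clean,
    )
    annotations = {
        common.site.key: AnnotationRecord(
            site=common.site, gene="CMN", panel_afs={"evs": 0.01}
        )
    }
    records = extract_dnms([low_vaf, common], annotations, CFG)
    assert len(records) == 1
    assert records[0].site == SITE
    assert records[0].mosaic_flag  # VAF 0.20 < 0.25
    assert records[0].unannotated  # no annotation supplied for that site
    high_vaf = trio(call(HET, 40, 12), clean, clean)  # VAF 0.30
    assert not extract_dnms([high_vaf], {}, CFG)[0].mosaic_flag


def test_records_sorted_and_counted():
    clean = call(REF, 30, 0)
    sites = [VariantSite("chr2", 5, "A", "T"), VariantSite("chr1", 9, "A", "T")]
    trios = [
        TrioCall(site=s, proband=call(HET, 30, 15), father=clean, mother=clean)
        for s in sites
    ]
    recs = extract_dnms(trios, {}, CFG)
    assert [r.site.chrom for r in recs] == ["chr1", "chr2"]


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    depth=st.integers(0, 200),
    alt=st.integers(0, 200),
    min_vaf=st.floats(0.0, 1.0),
)
def test_support_rule_is_threshold_arithmetic(depth, alt, min_vaf):
    alt = min(alt, depth)
    cfg = FilterConfig(min_vaf=min_vaf)
    got = passes_site_support(call(HET if alt else REF, depth, alt), cfg)
    want = depth >= 10 and alt >= 4 and (depth > 0 and alt / depth >= min_vaf)
    assert got == want
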