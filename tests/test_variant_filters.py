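"""Variant filter cascade: printed-rule boundaries and an independent
predicate oracle."""

import numpy as np
import pytest

from sitpipe.io_formats import AnnotatedVariant, SiteMetrics
from sitpipe.variant_filters import (
    apply_site_filters,
    evaluate,
    passes_af,
    passes_consequence,
    passes_deleteriousness,
    passes_genotype_quality,
    retained_variants,
)

GOOD_SITE = SiteMetrics(qd=20, fs=1, mq=60, haplotype_score=2, mq_rank_sum=0, read_pos_rank_sum=0)


def make_variant(**kwargs) -> AnnotatedVariant:
    base = dict(
        individual_id="S1",
        chrom="1",
        pos=100,
        ref="A",
        alt="G",
        gene="GENE1",
        consequence="missense",
        zygosity="het",
        dp=30,
        gq=99,
        ad_ref=15,
        ad_alt=15,
        cadd=30.0,
        af=1e-4,
        site=GOOD_SITE,
    )
    base.update(kwargs)
    return AnnotatedVariant(**base)


@pytest.mark.parametrize(
    "kwargs, failed",
    [
        # SNV site thresholds; absent metrics never fail
        (dict(site=SiteMetrics(qd=1.9)), ("QD",)),
        (dict(site=SiteMetrics(fs=61)), ("FS",)),
        (dict(site=SiteMetrics(mq=39.9)), ("MQ",)),
        (dict(site=SiteMetrics(haplotype_score=13.1)), ("HAPSCORE",)),
        (dict(site=SiteMetrics(mq_rank_sum=-12.6)), ("MQRS",)),
        (dict(site=SiteMetrics(read_pos_rank_sum=-8.1)), ("RPRS",)),
        (dict(site=SiteMetrics(mq=41)), ()),  # strict-inequality boundary
        (dict(site=SiteMetrics()), ()),
        # indel-specific thresholds
        (dict(ref="AT", alt="A", site=SiteMetrics(fs=250)), ("FS",)),
        (dict(ref="AT", alt="A", site=SiteMetrics(fs=100)), ()),
        (dict(ref="AT", alt="A", site=SiteMetrics(mq=10)), ()),  # no indel MQ rule
    ],
)
def test_site_filters(kwargs, failed):
    assert apply_site_filters(make_variant(**kwargs)).failed_rules == failed


@pytest.mark.parametrize(
    "kwargs, retained",
    [
        (dict(consequence="splicing", splice_distance=2), True),
        (dict(consequence="splicing", splice_distance=3), False),
        (dict(consequence="splicing", splice_distance=None), True),
        (dict(consequence="synonymous"), False),
        (dict(consequence="unknown"), False),
        (dict(consequence="stop_gain"), True),
        (dict(consequence="inframe_indel", ref="A", alt="AGGG"), True),
        (dict(consequence="other_exonic"), True),
    ],
)
def test_consequence(kwargs, retained):
    assert passes_consequence(make_variant(**kwargs)).retained is retained


@pytest.mark.parametrize(
    "kwargs, retained",
    [
        # AlphaMissense-pathogenic rescue below the CADD threshold
        (dict(cadd=1.0, am_class="pathogenic"), True),
        # benign class does not override a qualifying CADD score
        (dict(cadd=26.0, am_class="benign"), True),
        (dict(cadd=19.0, am_class="benign"), False),
        (dict(cadd=19.9, am_class=None), False),
        (dict(cadd=20.0, am_class=None), True),
        (dict(consequence="stop_gain", cadd=50.0, am_class=None), True),
        # rescue is missense-only
        (dict(consequence="stop_gain", cadd=10.0, am_class="pathogenic"), False),
        (dict(cadd=None, am_class=None), False),
        # carried-over legacy rows bypass the deleteriousness rule only
        (dict(cadd=16.0, am_class=None, legacy_retained=True,
              consequence="inframe_indel", ref="A", alt="AGGG"), True),
    ],
)
def test_deleteriousness(kwargs, retained):
    assert passes_deleteriousness(make_variant(**kwargs)).retained is retained


@pytest.mark.parametrize(
    "kwargs, failed",
    [
        (dict(dp=6, ad_ref=3, ad_alt=3), ("DP",)),
        (dict(dp=7, ad_ref=3, ad_alt=4), ()),
        (dict(ref="AT", alt="A", dp=9, ad_ref=4, ad_alt=5), ("DP",)),
        (dict(ref="AT", alt="A", dp=10, ad_ref=5, ad_alt=5), ()),
        (dict(gq=19), ("GQ",)),
        # allelic balance exactly 1:3 is retained ("more extreme than" is strict)
        (dict(dp=32, ad_ref=24, ad_alt=8), ()),
        (dict(dp=32, ad_ref=8, ad_alt=24), ()),
        (dict(dp=29, ad_ref=24, ad_alt=5), ("AB",)),
        (dict(zygosity="hom", dp=29, ad_ref=24, ad_alt=5), ()),  # AB is het-only
        (dict(dp=30, ad_ref=0, ad_alt=0), ("AB_UNDEFINED",)),
    ],
)
def test_genotype_quality(kwargs, failed):
    assert passes_genotype_quality(make_variant(**kwargs)).failed_rules == failed


@pytest.mark.parametrize(
    "af, model, retained",
    [
        (0.0032, "recessive", True),
        (0.0051, "recessive", False),
        (0.0032, "dominant", False),
        (0.00005, "dominant", True),
        (0.000051, "dominant", False),
        (None, "recessive", True),  # novel variants retained
        (None, "dominant", True),
    ],
)
def test_af(af, model, retained):
    assert passes_af(make_variant(af=af), model).retained is retained


def test_dominant_af_rule_nested_in_recessive():
    rng = np.random.default_rng(7)
    for _ in range(200):
        v = make_variant(af=float(10 ** rng.uniform(-6, -1)))
        if passes_af(v, "dominant").retained:
            assert passes_af(v, "recessive").retained


def _random_variant(rng) -> AnnotatedVariant:
    csq = str(rng.choice(["missense", "stop_gain", "frameshift", "inframe_indel",
                          "splicing", "synonymous", "unknown", "other_exonic"]))
    is_indel = bool(rng.random() < 0.3)
    dp = int(rng.integers(0, 60))
    ad_alt = int(rng.integers(0, dp + 1))
    zyg = str(rng.choice(["het", "hom"]))

    def maybe(value):
        return None if rng.random() < 0.2 else value

    site = SiteMetrics(
        qd=maybe(float(rng.uniform(0, 40))),
        fs=maybe(float(rng.uniform(0, 300))),
        mq=maybe(float(rng.uniform(0, 70))),
        haplotype_score=maybe(float(rng.uniform(0, 20))),
        mq_rank_sum=maybe(float(rng.uniform(-20, 5))),
        read_pos_rank_sum=maybe(float(rng.uniform(-25, 5))),
    )
    return make_variant(
        ref="AT" if is_indel else "A",
        alt="A" if is_indel else "G",
        consequence=csq,
        splice_distance=maybe(int(rng.integers(0, 6))) if csq == "splicing" else None,
        zygosity=zyg,
        dp=dp,
        gq=int(rng.integers(0, 100)),
        ad_ref=dp - ad_alt,
        ad_alt=ad_alt,
        cadd=maybe(float(rng.uniform(0, 50))),
        am_class=maybe(str(rng.choice(["pathogenic", "benign", "ambiguous"]))),
        af=maybe(float(10 ** rng.uniform(-6, -1))),
        site=site,
        legacy_retained=bool(rng.random() < 0.05),
    )


def _oracle_retained(v: AnnotatedVariant, model: str) -> bool:
    """Independent plain re-statement of the five published rules."""
    is_snv = len(v.ref) == 1 and len(v.alt) == 1
    m = v.site
    if is_snv:
        if m.qd is not None and m.qd < 2:
            return False
        if m.fs is not None and m.fs > 60:
            return False
        if m.mq is not None and m.mq < 40:
            return False
        if m.haplotype_score is not None and m.haplotype_score > 13:
            return False
        if m.mq_rank_sum is not None and m.mq_rank_sum < -12.5:
            return False
        if m.read_pos_rank_sum is not None and m.read_pos_rank_sum < -8:
            return False
    else:
        if m.qd is not None and m.qd < 2:
            return False
        if m.fs is not None and m.fs > 200:
            return False
        if m.read_pos_rank_sum is not None and m.read_pos_rank_sum < -20:
            return False
    if v.consequence in {"synonymous", "unknown"}:
        return False
    if v.consequence == "splicing" and v.splice_distance is not None and v.splice_distance > 2:
        return False
    if not v.legacy_retained:
        has_cadd = v.cadd is not None and v.cadd >= 20
        rescued = v.consequence == "missense" and v.am_class == "pathogenic"
        if not (has_cadd or rescued):
            return False
    if v.dp < (7 if is_snv else 10):
        return False
    if v.gq < 20:
        return False
    if v.zygosity == "het":
        tot = v.ad_ref + v.ad_alt
        if tot == 0:
            return False
        if not 0.25 <= v.ad_alt / tot <= 0.75:
            return False
    cutoff = 0.005 if model == "recessive" else 0.00005
    return (v.af or 0.0) <= cutoff


@pytest.mark.parametrize("model", ["recessive", "dominant"])
def test_oracle_equivalence_random_variants(model):
    """Cascade membership equals brute-force evaluation of the five
    predicates on 1000 random variants."""
    rng = np.random.default_rng(42)
    variants = [_random_variant(rng) for _ in range(1000)]
    got = {id(v) for v in retained_variants(variants, model)}
    expected = {id(v) for v in variants if _oracle_retained(v, model)}
    assert got == expected


def test_failed_rules_consistency():
    rng = np.random.default_rng(3)
    for _ in range(200):
        v = _random_variant(rng)
        d = evaluate(v, "recessive")
        assert d.retained == (not d.failed_rules)


def test_empty_input():
    assert retained_variants([], "recessive") == []


def test_unknown_model_rejected():
    with pytest.raises(ValueError):
        retained_variants([make_variant()], "additive")
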