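"""Variant-level retention cascade.

Five rules applied in a fixed order to each called variant:

1. site hard filters (caller quality metrics, type-specific thresholds),
2. consequence class (exonic/splicing-within-2bp only),
3. deleteriousness (CADD phred >= 20, with an AlphaMissense-pathogenic
   rescue for missense SNVs below that score),
4. genotype quality (depth, genotype quality, allelic balance),
5. model-specific population allele-frequency cutoff
   (recessive <= 0.005, dominant <= 0.00005).

Boundary semantics follow the published rules exactly as printed:
"DP below 7" fails DP=6 and passes DP=7; allelic balance "more extreme
than 3:1 or 1:3" is a strict inequality so exactly 1:3 is retained;
CADD ">= 20" retains 20.0. An absent allele frequency means the variant
is novel and is retained under both models. Calls flagged
``legacy_retained`` bypass only the deleteriousness rule: their evidence
was scored by an earlier pipeline version.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .io_formats import AnnotatedVariant

__all__ = [
    "FilterDecision",
    "AF_CUTOFFS",
    "apply_site_filters",
    "passes_consequence",
    "passes_deleteriousness",
    "passes_genotype_quality",
    "passes_af",
    "retained_variants",
]

AF_CUTOFFS = {"recessive": 0.005, "dominant": 0.00005}

# Site hard-filter thresholds, (metric, fail-predicate) per variant type.
_SNV_SITE_RULES = (
    ("QD", lambda m: m.qd is not None and m.qd < 2),
    ("FS", lambda m: m.fs is not None and m.fs > 60),
    ("MQ", lambda m: m.mq is not None and m.mq < 40),
    ("HAPSCORE", lambda m: m.haplotype_score is not None and m.haplotype_score > 13),
    ("MQRS", lambda m: m.mq_rank_sum is not None and m.mq_rank_sum < -12.5),
    ("RPRS", lambda m: m.read_pos_rank_sum is not None and m.read_pos_rank_sum < -8),
)
_INDEL_SITE_RULES = (
    ("QD", lambda m: m.qd is not None and m.qd < 2),
    ("FS", lambda m: m.fs is not None and m.fs > 200),
    ("RPRS", lambda m: m.read_pos_rank_sum is not None and m.read_pos_rank_sum < -20),
)

_RETAINED_CONSEQUENCES = {"missense", "stop_gain", "frameshift", "inframe_indel", "other_exonic"}


@dataclass(frozen=True)
class FilterDecision:
    retained: bool
    failed_rules: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.retained != (len(self.failed_rules) == 0):
            raise ValueError("retained must be equivalent to an empty failed_rules")


def _decision(failed: Sequence[str]) -> FilterDecision:
    return FilterDecision(retained=not failed, failed_rules=tuple(failed))


def apply_site_filters(v: AnnotatedVariant) -> FilterDecision:
    """Caller hard filters; absent metrics never fail."""
    rules = _SNV_SITE_RULES if v.variant_type == "SNV" else _INDEL_SITE_RULES
    return _decision([name for name, fails in rules if fails(v.site)])


def passes_consequence(v: AnnotatedVariant) -> FilterDecision:
    """Exonic and near-boundary splicing classes only.

    Splicing variants lacking an annotated distance are treated as within
    the 2 bp boundary (the annotator already classed them as splicing).
    """
    if v.consequence in _RETAINED_CONSEQUENCES:
        return _decision([])
    if v.consequence == "splicing":
        if v.splice_distance is None or v.splice_distance <= 2:
            return _decision([])
        return _decision(["SPLICE_DISTANCE"])
    return _decision(["CONSEQUENCE"])


def passes_deleteriousness(v: AnnotatedVariant) -> FilterDecision:
    """CADD >= 20, or an AlphaMissense-pathogenic rescue for missense.

    The benign exclusion acts only on the CADD<20 rescue path: a missense
    variant at CADD >= 20 is retained even with a benign class.
    """
    if v.legacy_retained:
        return _decision([])
    if v.cadd is not None and v.cadd >= 20:
        return _decision([])
    if v.consequence == "missense" and v.am_class == "pathogenic":
        return _decision([])
    return _decision(["DELETERIOUSNESS"])


def passes_genotype_quality(v: AnnotatedVariant) -> FilterDecision:
    failed: list[str] = []
    dp_min = 7 if v.variant_type == "SNV" else 10
    if v.dp < dp_min:
        failed.append("DP")
    if v.gq < 20:
        failed.append("GQ")
    if v.zygosity == "het":
        total = v.ad_ref + v.ad_alt
        if total == 0:
            failed.append("AB_UNDEFINED")
        else:
            f = v.ad_alt / total
            if not 0.25 <= f <= 0.75:
                failed.append("AB")
    return _decision(failed)


def passes_af(v: AnnotatedVariant, model: str) -> FilterDecision:
    """Population allele-frequency rule; absent AF is treated as novel."""
    cutoff = AF_CUTOFFS[model]
    af = 0.0 if v.af is None else v.af
    return _decision([] if af <= cutoff else ["AF"])


def evaluate(v: AnnotatedVariant, model: str) -> FilterDecision:
    """All five rules in fixed order; order affects only the reported
    failed_rules, never membership."""
    failed: list[str] = []
    failed += apply_site_filters(v).failed_rules
    failed += passes_consequence(v).failed_rules
    failed += passes_deleteriousness(v).failed_rules
    failed += passes_genotype_quality(v).failed_rules
    failed += passes_af(v, model).failed_rules
    return _decision(failed)


def retained_variants(variants: Iterable[AnnotatedVariant], model: str) -> list[AnnotatedVariant]:
    if model not in AF_CUTOFFS:
        raise ValueError(f"model must be one of {sorted(AF_CUTOFFS)}, got {model!r}")
    return [v for v in variants if evaluate(v, model).retained]
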