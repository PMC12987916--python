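"""A published situs inversus totalis cohort, encoded as input.

The study's per-individual table of most likely causal variants (38 SIT
cases, two recruitment stages, 19 of them carrying retained qualifying
variants) is public, printed data; the raw genomes are not. This module
re-encodes that table — individual, stage, PCD status, sex/age, zygosity,
gene, chromosome, population allele frequency, CADD phred score,
AlphaMissense class, and the footnoted flags — as typed inputs, together
with the confirmed/unconfirmed candidate-gene annotations it references,
so the prioritization pipeline can be exercised end-to-end against the
printed group counts.

Genomic positions are synthetic placeholders (annotation, not coordinates,
drives every downstream rule); genotype-quality fields are nominal passing
values since the table lists only variants that passed those filters.
Variants footnoted as carried over from the earlier stage-I pipeline
(inframe indels at CADD 16/17) are marked ``legacy_retained``.
"""

from __future__ import annotations

from .io_formats import AnnotatedVariant, CandidateGene, Individual, SiteMetrics

__all__ = ["reference_individuals", "reference_variants", "reference_candidates"]

_NOMINAL_SITE = SiteMetrics(qd=20.0, fs=1.0, mq=60.0, haplotype_score=1.0,
                            mq_rank_sum=0.0, read_pos_rank_sum=0.0)

# individual_id, stage, pcd, sex, age
_CASES = [
    # genetically solved
    ("SIT003", "I", False, "M", 50), ("SIT009", "I", True, "M", 46),
    ("SIT011", "I", True, "F", 23), ("SIT016", "I", True, "F", 32),
    ("SIT017", "I", False, "F", 40), ("SIT018", "I", True, "M", 48),
    ("SIT019", "I", False, "M", 18), ("SIT022", "I", True, "F", 31),
    ("SIT023", "I", False, "M", 21), ("SIT026", "I", True, "M", 39),
    ("SIT043", "II", False, "F", 54), ("SIT044", "II", True, "M", 66),
    ("SIT051", "II", False, "F", 44), ("SIT055", "II", True, "F", 20),
    ("SIT056", "II", False, "F", 52), ("SIT059", "II", False, "M", 35),
    ("SIT060", "II", False, "F", 40), ("SIT061", "II", False, "M", 74),
    ("SIT066", "II", False, "M", 51),
    # genetically unsolved
    ("SIT004", "I", False, "F", 26), ("SIT005", "I", False, "M", 23),
    ("SIT007", "I", False, "M", 27), ("SIT010", "I", False, "F", 35),
    ("SIT013", "I", False, "F", 36), ("SIT045", "II", False, "F", 47),
    ("SIT047", "II", False, "M", 22), ("SIT049", "II", False, "F", 44),
    ("SIT052", "II", False, "F", 19), ("SIT054", "II", False, "M", 32),
    ("SIT058", "II", False, "M", 74), ("SIT062", "II", False, "F", 66),
    ("SIT063", "II", False, "F", 60), ("SIT064", "II", False, "F", 73),
    ("SIT067", "II", False, "F", 54), ("SIT068", "II", False, "F", 39),
    ("SIT078", "II", False, "M", 34), ("SIT080", "II", False, "F", 47),
    ("SIT085", "II", False, "F", 58),
]

# individual, gene, chrom, consequence, variant type, zygosity, af, cadd,
# am_class, legacy
_VARIANT_ROWS = [
    ("SIT003", "PKD1L1", "7", "splicing", "indel", "hom", 0.0005, 23.0, None, False),
    ("SIT009", "DNAAF11", "8", "splicing", "SNV", "hom", None, 33.0, None, False),
    ("SIT011", "DNAH11", "7", "stop_gain", "SNV", "hom", None, 32.0, None, False),
    ("SIT016", "DNAAF1", "16", "splicing", "SNV", "het", 0.00001, 24.0, None, False),
    ("SIT016", "DNAAF1", "16", "missense", "SNV", "het", 0.00003, 23.0, "pathogenic", False),
    ("SIT017", "DNAH5", "5", "stop_gain", "SNV", "het", None, 42.0, None, False),
    ("SIT017", "DNAH5", "5", "frameshift", "indel", "het", None, 36.0, None, False),
    ("SIT018", "CCDC114", "19", "inframe_indel", "indel", "hom", 0.0002, 16.0, None, True),
    ("SIT019", "CFAP52", "17", "missense", "SNV", "het", 0.0004, 1.0, "pathogenic", False),
    ("SIT019", "CFAP52", "17", "stop_gain", "SNV", "het", None, 45.0, None, False),
    ("SIT022", "DNAH5", "5", "stop_gain", "SNV", "het", 0.000007, 50.0, None, False),
    ("SIT022", "DNAH5", "5", "frameshift", "indel", "het", 0.0001, 25.0, None, False),
    ("SIT023", "CCDC151", "19", "inframe_indel", "indel", "hom", 0.00004, 17.0, None, True),
    ("SIT026", "DNAH5", "5", "splicing", "SNV", "het", 0.00002, 34.0, None, False),
    ("SIT026", "DNAH5", "5", "missense", "SNV", "het", 0.00005, 26.0, "pathogenic", False),
    ("SIT043", "DNAH11", "7", "missense", "SNV", "het", None, 27.0, "pathogenic", False),
    ("SIT043", "DNAH11", "7", "missense", "SNV", "het", 0.0002, 26.0, "benign", False),
    ("SIT044", "DNAH9", "17", "missense", "SNV", "het", None, 24.0, "benign", False),
    ("SIT044", "DNAH9", "17", "stop_gain", "SNV", "het", 0.0002, 35.0, None, False),
    ("SIT051", "DNAAF4", "15", "stop_gain", "SNV", "hom", None, 35.0, None, False),
    ("SIT055", "DNAH11", "7", "splicing", "SNV", "hom", None, 33.0, None, False),
    ("SIT056", "DNAH5", "5", "stop_gain", "SNV", "het", 0.000007, 50.0, None, False),
    ("SIT056", "DNAH5", "5", "stop_gain", "SNV", "het", 0.0002, 41.0, None, False),
    ("SIT059", "FOXJ1", "17", "missense", "SNV", "het", 0.00002, 21.0, "benign", False),
    ("SIT060", "DNAH9", "17", "frameshift", "indel", "het", 0.0005, 25.0, None, False),
    ("SIT060", "DNAH9", "17", "missense", "SNV", "het", 0.000007, 25.0, "pathogenic", False),
    ("SIT061", "DNAH8", "6", "missense", "SNV", "het", 0.0003, 22.0, "benign", False),
    ("SIT061", "DNAH8", "6", "missense", "SNV", "het", 0.002, 26.0, "benign", False),
    ("SIT066", "PKD1L1", "7", "splicing", "indel", "hom", 0.0005, 23.0, None, False),
    # unsolved cases with notable (unconfirmed-candidate) findings
    ("SIT058", "PCSK5", "9", "missense", "SNV", "het", 0.000020, 29.4, "ambiguous", False),
    ("SIT058", "PCSK5", "9", "missense", "SNV", "het", 0.000026, 26.7, "benign", False),
    ("SIT062", "MEGF8", "19", "missense", "SNV", "het", 0.0032, 32.0, "benign", False),
    ("SIT062", "MEGF8", "19", "missense", "SNV", "het", 0.0025, 20.9, "benign", False),
    ("SIT063", "NOTCH1", "9", "missense", "SNV", "het", 0.000066, 22.7, None, False),
    # the flagged control: compound-het DNAH6 missense pair
    ("SIT084", "DNAH6", "2", "missense", "SNV", "het", 0.0001, 24.0, "benign", False),
    ("SIT084", "DNAH6", "2", "missense", "SNV", "het", None, 27.0, "benign", False),
]

_CONFIRMED_RECESSIVE = [
    "PKD1L1", "DNAAF11", "DNAH11", "DNAAF1", "DNAH5", "CCDC114",
    "CFAP52", "CCDC151", "DNAH9", "DNAAF4", "DNAH8",
]
_CONFIRMED_DOMINANT = ["FOXJ1"]
_UNCONFIRMED = ["PCSK5", "MEGF8", "NOTCH1", "DNAH6"]
_PCD_LINKED = {
    "DNAH5", "DNAH8", "DNAH9", "DNAH11", "DNAAF1", "DNAAF4",
    "DNAAF11", "CCDC114", "CCDC151", "DNAH6",
}


def reference_individuals() -> list[Individual]:
    """The 38 SIT cases (as printed) plus 38 controls including SIT084."""
    inds = [
        Individual(iid, "case", stage, sex, float(age), pcd=pcd)
        for iid, stage, pcd, sex, age in _CASES
    ]
    inds.append(Individual("SIT084", "control", "II", "M", 45.0))
    for k in range(37):
        stage = "I" if k < 15 else "II"
        sex = "F" if k % 2 else "M"
        inds.append(Individual(f"CON{k + 1:03d}", "control", stage, sex, 40.0 + k % 20))
    return inds


def reference_variants() -> dict[str, list[AnnotatedVariant]]:
    """Per-individual retained-variant calls from the printed table."""
    out: dict[str, list[AnnotatedVariant]] = {}
    for i, row in enumerate(_VARIANT_ROWS):
        iid, gene, chrom, csq, vtype, zygosity, af, cadd, am, legacy = row
        if vtype == "SNV":
            ref, alt = "C", "T"
        else:
            ref, alt = ("CAT", "C") if csq != "inframe_indel" else ("C", "CAGG")
        if zygosity == "hom":
            ad_ref, ad_alt = 0, 30
        else:
            ad_ref, ad_alt = 15, 15
        out.setdefault(iid, []).append(
            AnnotatedVariant(
                individual_id=iid,
                chrom=chrom,
                pos=1000 + 10 * i,
                ref=ref,
                alt=alt,
                gene=gene,
                consequence=csq,
                zygosity=zygosity,
                dp=30,
                gq=99,
                ad_ref=ad_ref,
                ad_alt=ad_alt,
                splice_distance=2 if csq == "splicing" else None,
                cadd=cadd,
                am_class=am,
                af=af,
                site=_NOMINAL_SITE,
                legacy_retained=legacy,
            )
        )
    return out


def reference_candidates() -> list[CandidateGene]:
    """Candidate-gene annotations referenced by the printed table: confirmed
    recessive/dominant causes plus the genes explicitly left unconfirmed."""
    out = [
        CandidateGene(g, source="published cohort table", confirmed_mode="recessive",
                      pcd_linked=g in _PCD_LINKED)
        for g in _CONFIRMED_RECESSIVE
    ]
    out += [
        CandidateGene(g, source="published cohort table", confirmed_mode="dominant",
                      pcd_linked=g in _PCD_LINKED)
        for g in _CONFIRMED_DOMINANT
    ]
    out += [
        CandidateGene(g, source="published cohort table", confirmed_mode="unconfirmed",
                      pcd_linked=g in _PCD_LINKED)
        for g in _UNCONFIRMED
    ]
    return out
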