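"""Domain types and external representations.

The package reads and writes a small, explicit dialect of standard text
formats: annotated VCF 4.2 for per-individual variant calls, TSV for the
cohort/phenotype/candidate-gene tables and the biallelic genotype matrix,
and JSON for reports.

Annotation is consumed, never computed, so the VCF INFO keys are a fixed
clean dialect rather than any particular annotator's field names:

========== ==============================================================
INFO key   meaning
========== ==============================================================
GENE       gene symbol
CSQ_CLASS  consequence class (missense, stop_gain, frameshift,
           inframe_indel, splicing, synonymous, unknown, other_exonic)
SPLICE_DIST distance in bp to the nearest exon/intron boundary
CADD       CADD phred deleteriousness score
AM_CLASS   AlphaMissense class (pathogenic, benign, ambiguous)
GNOMAD_AF  gnomAD population allele frequency
QD, FS, MQ, HAPSCORE, MQRS, RPRS   site-level caller metrics
LEGACY     flag: retained by the earlier stage-I pipeline
PHASED_CIS flag: variant observed in phase (cis) with another variant in
           the same gene for the carrier
========== ==============================================================

Numeric INFO values are stored as VCF Strings so that a write/read cycle
reproduces every typed field exactly. Multiallelic records are rejected:
ALT alleles must be pre-split.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
import pysam

__all__ = [
    "SiteMetrics",
    "AnnotatedVariant",
    "Individual",
    "CandidateGene",
    "PhenotypeRecord",
    "CONSEQUENCES",
    "read_annotated_vcf",
    "write_annotated_vcf",
    "read_candidate_list",
    "write_candidate_list",
    "read_individuals",
    "write_individuals",
    "read_phenotypes",
    "write_phenotypes",
    "read_genotype_tsv",
    "write_genotype_tsv",
    "write_report",
]

CONSEQUENCES = frozenset(
    {
        "missense",
        "stop_gain",
        "frameshift",
        "inframe_indel",
        "splicing",
        "synonymous",
        "unknown",
        "other_exonic",
    }
)

X_CHROMS = {"X", "chrX"}
Y_CHROMS = {"Y", "chrY"}


@dataclass(frozen=True)
class SiteMetrics:
    """GATK-style site quality metrics; any may be absent (None)."""

    qd: Optional[float] = None
    fs: Optional[float] = None
    mq: Optional[float] = None
    haplotype_score: Optional[float] = None
    mq_rank_sum: Optional[float] = None
    read_pos_rank_sum: Optional[float] = None

    def __post_init__(self) -> None:
        if self.fs is not None and self.fs < 0:
            raise ValueError("FS must be non-negative")
        if self.mq is not None and self.mq < 0:
            raise ValueError("MQ must be non-negative")


@dataclass(frozen=True)
class AnnotatedVariant:
    """One called variant in one individual, with every field the filter
    cascade and the inheritance models read.

    ``am_class`` and ``af`` use None for absent; an absent allele
    frequency means the variant is unobserved in the reference population
    (treated as novel downstream). ``legacy_retained`` marks calls carried
    over from an earlier pipeline stage whose deleteriousness evidence was
    assessed under different scoring. ``phased_cis`` records externally
    supplied phase: the variant was seen on the same haplotype as another
    variant of the same gene in this carrier.
    """

    individual_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    consequence: str
    zygosity: str  # het | hom | hemi
    dp: int
    gq: int
    ad_ref: int
    ad_alt: int
    splice_distance: Optional[int] = None
    cadd: Optional[float] = None
    am_class: Optional[str] = None  # pathogenic | benign | ambiguous
    af: Optional[float] = None
    site: SiteMetrics = field(default_factory=SiteMetrics)
    legacy_retained: bool = False
    phased_cis: bool = False

    @property
    def variant_type(self) -> str:
        return "SNV" if len(self.ref) == 1 and len(self.alt) == 1 else "indel"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.dp < 0:
            raise ValueError("dp must be non-negative")
        if self.ad_ref + self.ad_alt > self.dp:
            raise ValueError("ad_ref + ad_alt may not exceed dp")
        if self.af is not None and not 0.0 <= self.af <= 1.0:
            raise ValueError(f"af out of [0,1]: {self.af}")
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")
        if self.zygosity not in {"het", "hom", "hemi"}:
            raise ValueError(f"unknown zygosity {self.zygosity!r}")
        if self.zygosity == "hemi" and self.chrom not in X_CHROMS | Y_CHROMS:
            raise ValueError("hemizygous call on an autosome")


@dataclass(frozen=True)
class Individual:
    individual_id: str
    cohort: str  # case | control
    stage: str  # I | II
    sex: str  # M | F
    age: float
    pcd: bool = False
    handedness: str = "right"  # right | left | ambidextrous

    def __post_init__(self) -> None:
        if self.cohort not in {"case", "control"}:
            raise ValueError(f"cohort must be case/control, got {self.cohort!r}")
        if self.stage not in {"I", "II"}:
            raise ValueError(f"stage must be I/II, got {self.stage!r}")
        if self.sex not in {"M", "F"}:
            raise ValueError(f"sex must be M/F, got {self.sex!r}")
        if self.age <= 0:
            raise ValueError("age must be positive")
        if self.handedness not in {"right", "left", "ambidextrous"}:
            raise ValueError(f"bad handedness {self.handedness!r}")


@dataclass(frozen=True)
class CandidateGene:
    """A candidate-list entry: the unit against which a qualifying gene is
    confirmed (or not) as a plausible cause."""

    gene: str
    source: str = ""
    confirmed_mode: str = "unconfirmed"  # recessive | dominant | x_linked | unconfirmed
    pcd_linked: bool = False

    def __post_init__(self) -> None:
        if self.confirmed_mode not in {"recessive", "dominant", "x_linked", "unconfirmed"}:
            raise ValueError(f"bad confirmed_mode {self.confirmed_mode!r}")


@dataclass(frozen=True)
class PhenotypeRecord:
    """Per-individual brain-asymmetry phenotypes.

    Laterality indexes are signed (positive = rightward dominance).
    Torque metrics are the petalia/bending measures; sinus volumes in mm^3.
    Any numeric field may be absent (None) for incomplete records.
    """

    individual_id: str
    li_word: Optional[float] = None
    li_praxis: Optional[float] = None
    li_spatial: Optional[float] = None
    li_face: Optional[float] = None
    n_atypical: Optional[int] = None
    frontal_petalia: Optional[float] = None
    frontal_bending: Optional[float] = None
    occipital_petalia: Optional[float] = None
    occipital_bending: Optional[float] = None
    sinus_left: Optional[float] = None
    sinus_right: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n_atypical is not None and self.n_atypical not in range(5):
            raise ValueError("n_atypical must lie in 0..4")
        for v in (self.sinus_left, self.sinus_right):
            if v is not None and v < 0:
                raise ValueError("sinus volumes must be non-negative")


# ---------------------------------------------------------------------------
# VCF I/O

_INFO_FLOAT_KEYS = ("CADD", "GNOMAD_AF", "QD", "FS", "MQ", "HAPSCORE", "MQRS", "RPRS")


def _vcf_header(sample_ids: Sequence[str], contigs: Sequence[str]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for contig in contigs:
        header.contigs.add(contig)
    header.add_meta("INFO", items=[("ID", "GENE"), ("Number", "1"), ("Type", "String"),
                                   ("Description", "Gene symbol")])
    header.add_meta("INFO", items=[("ID", "CSQ_CLASS"), ("Number", "1"), ("Type", "String"),
                                   ("Description", "Consequence class")])
    header.add_meta("INFO", items=[("ID", "SPLICE_DIST"), ("Number", "1"), ("Type", "Integer"),
                                   ("Description", "Distance to exon/intron boundary (bp)")])
    header.add_meta("INFO", items=[("ID", "AM_CLASS"), ("Number", "1"), ("Type", "String"),
                                   ("Description", "AlphaMissense class")])
    for key in _INFO_FLOAT_KEYS:
        header.add_meta("INFO", items=[("ID", key), ("Number", "1"), ("Type", "String"),
                                       ("Description", f"{key} (numeric, stored as string)")])
    header.add_meta("INFO", items=[("ID", "LEGACY"), ("Number", "0"), ("Type", "Flag"),
                                   ("Description", "Retained by stage-I legacy pipeline")])
    header.add_meta("INFO", items=[("ID", "PHASED_CIS"), ("Number", "0"), ("Type", "Flag"),
                                   ("Description", "In phase (cis) with another variant in the gene")])
    header.add_meta("FORMAT", items=[("ID", "GT"), ("Number", "1"), ("Type", "String"),
                                     ("Description", "Genotype")])
    header.add_meta("FORMAT", items=[("ID", "DP"), ("Number", "1"), ("Type", "Integer"),
                                     ("Description", "Read depth")])
    header.add_meta("FORMAT", items=[("ID", "GQ"), ("Number", "1"), ("Type", "Integer"),
                                     ("Description", "Genotype quality")])
    header.add_meta("FORMAT", items=[("ID", "AD"), ("Number", "R"), ("Type", "Integer"),
                                     ("Description", "Allele read depths")])
    for sid in sample_ids:
        header.add_sample(sid)
    return header


def _sort_key(chrom: str) -> tuple:
    c = chrom.removeprefix("chr")
    return (0, int(c)) if c.isdigit() else (1, c)


def write_annotated_vcf(
    variants: Iterable[AnnotatedVariant],
    sample_ids: Sequence[str],
    path: str | Path,
) -> None:
    """Write per-individual variants to a plain-text VCF.

    Variants with identical (chrom, pos, ref, alt) are merged into one
    record; site-level annotation is taken from the first carrier and must
    be consistent across carriers. Non-carrier samples are written as
    homozygous reference with nominal DP/GQ.
    """
    by_site: dict[tuple, list[AnnotatedVariant]] = {}
    for v in variants:
        by_site.setdefault((v.chrom, v.pos, v.ref, v.alt), []).append(v)

    contigs = sorted({k[0] for k in by_site}, key=_sort_key)
    header = _vcf_header(sample_ids, contigs)
    path = Path(path)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for key in sorted(by_site, key=lambda k: (_sort_key(k[0]), k[1], k[2], k[3])):
            chrom, pos, ref, alt = key
            carriers = by_site[key]
            proto = carriers[0]
            rec = out.new_record(contig=chrom, start=pos - 1, stop=pos - 1 + len(ref),
                                 alleles=(ref, alt))
            rec.info["GENE"] = proto.gene
            rec.info["CSQ_CLASS"] = proto.consequence
            if proto.splice_distance is not None:
                rec.info["SPLICE_DIST"] = proto.splice_distance
            if proto.am_class is not None:
                rec.info["AM_CLASS"] = proto.am_class
            for attr, keyname in (("cadd", "CADD"), ("af", "GNOMAD_AF")):
                val = getattr(proto, attr)
                if val is not None:
                    rec.info[keyname] = repr(val)
            for attr, keyname in (("qd", "QD"), ("fs", "FS"), ("mq", "MQ"),
                                  ("haplotype_score", "HAPSCORE"),
                                  ("mq_rank_sum", "MQRS"),
                                  ("read_pos_rank_sum", "RPRS")):
                val = getattr(proto.site, attr)
                if val is not None:
                    rec.info[keyname] = repr(val)
            if proto.legacy_retained:
                rec.info["LEGACY"] = True
            if proto.phased_cis:
                rec.info["PHASED_CIS"] = True

            carrier_map = {v.individual_id: v for v in carriers}
            haploid = any(v.zygosity == "hemi" for v in carriers)
            for sid in sample_ids:
                sample = rec.samples[sid]
                v = carrier_map.get(sid)
                if v is None:
                    sample["GT"] = (0,) if haploid else (0, 0)
                    sample["DP"] = 30
                    sample["GQ"] = 99
                    sample["AD"] = (30, 0)
                else:
                    if v.zygosity == "hemi":
                        sample["GT"] = (1,)
                    elif v.zygosity == "hom":
                        sample["GT"] = (1, 1)
                    else:
                        sample["GT"] = (0, 1)
                    sample["DP"] = v.dp
                    sample["GQ"] = v.gq
                    sample["AD"] = (v.ad_ref, v.ad_alt)
            out.write(rec)


def _info_float(rec: pysam.VariantRecord, key: str) -> Optional[float]:
    if key not in rec.info:
        return None
    raw = rec.info[key]
    if isinstance(raw, tuple):
        raw = raw[0]
    return float(raw)


def read_annotated_vcf(
    path: str | Path,
    cohort_map: Mapping[str, str],
) -> list[AnnotatedVariant]:
    """Read an annotated VCF into one :class:`AnnotatedVariant` per
    (record, sample) pair where the sample carries at least one alternate
    allele.

    ``cohort_map`` maps every expected sample id to its cohort; a sample
    present in the VCF but absent from the map is an error. Multiallelic
    ALT fields are rejected (records must be pre-split). Absent annotation
    keys map to None, never to an error.
    """
    path = Path(path)
    out: list[AnnotatedVariant] = []
    with pysam.VariantFile(str(path)) as vcf:
        unknown = [s for s in vcf.header.samples if s not in cohort_map]
        if unknown:
            raise ValueError(f"unknown sample ids in VCF: {sorted(unknown)}")
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                raise ValueError(
                    f"multiallelic or ALT-less record at {rec.chrom}:{rec.pos}; "
                    "records must be pre-split to a single ALT allele"
                )
            alt = rec.alts[0]
            if "," in alt:
                raise ValueError(f"comma in ALT at {rec.chrom}:{rec.pos}")
            site = SiteMetrics(
                qd=_info_float(rec, "QD"),
                fs=_info_float(rec, "FS"),
                mq=_info_float(rec, "MQ"),
                haplotype_score=_info_float(rec, "HAPSCORE"),
                mq_rank_sum=_info_float(rec, "MQRS"),
                read_pos_rank_sum=_info_float(rec, "RPRS"),
            )
            gene = rec.info.get("GENE", "")
            csq = rec.info.get("CSQ_CLASS", "unknown")
            splice_dist = rec.info.get("SPLICE_DIST")
            am = rec.info.get("AM_CLASS")
            cadd = _info_float(rec, "CADD")
            af = _info_float(rec, "GNOMAD_AF")
            legacy = bool(rec.info.get("LEGACY", False))
            cis = bool(rec.info.get("PHASED_CIS", False))
            for sid in rec.samples:
                sample = rec.samples[sid]
                gt = sample.get("GT")
                if gt is None:
                    continue
                alleles = [a for a in gt if a is not None]
                n_alt = sum(1 for a in alleles if a == 1)
                if n_alt == 0:
                    continue
                if len(alleles) == 1:
                    zygosity = "hemi"
                elif n_alt == 2:
                    zygosity = "hom"
                else:
                    zygosity = "het"
                ad = sample.get("AD") or (0, 0)
                out.append(
                    AnnotatedVariant(
                        individual_id=sid,
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        gene=gene,
                        consequence=csq,
                        zygosity=zygosity,
                        dp=int(sample.get("DP") or 0),
                        gq=int(sample.get("GQ") or 0),
                        ad_ref=int(ad[0] or 0),
                        ad_alt=int(ad[1] or 0) if len(ad) > 1 else 0,
                        splice_distance=int(splice_dist) if splice_dist is not None else None,
                        cadd=cadd,
                        am_class=am,
                        af=af,
                        site=site,
                        legacy_retained=legacy,
                        phased_cis=cis,
                    )
                )
    return out


# ---------------------------------------------------------------------------
# TSV tables


def read_candidate_list(path: str | Path) -> list[CandidateGene]:
    """Read the candidate-gene TSV (gene, source, confirmed_mode, pcd_linked),
    deduplicating identical rows; duplicate symbols with conflicting modes
    raise."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene", "source", "confirmed_mode", "pcd_linked"}
    if not required.issubset(df.columns):
        raise ValueError(f"candidate list must have columns {sorted(required)}")
    if df.empty:
        warnings.warn("candidate list is empty", stacklevel=2)
        return []
    conflicts = [
        g for g, sub in df.groupby("gene")
        if sub["confirmed_mode"].nunique() > 1
    ]
    if conflicts:
        raise ValueError(f"conflicting confirmed_mode for genes: {sorted(conflicts)}")
    seen: dict[str, CandidateGene] = {}
    for row in df.itertuples(index=False):
        if row.gene in seen:
            continue
        seen[row.gene] = CandidateGene(
            gene=row.gene,
            source=row.source if isinstance(row.source, str) else "",
            confirmed_mode=row.confirmed_mode,
            pcd_linked=str(row.pcd_linked).lower() in {"true", "1", "yes"},
        )
    return list(seen.values())


def write_candidate_list(candidates: Sequence[CandidateGene], path: str | Path) -> None:
    pd.DataFrame(
        {
            "gene": [c.gene for c in candidates],
            "source": [c.source for c in candidates],
            "confirmed_mode": [c.confirmed_mode for c in candidates],
            "pcd_linked": [c.pcd_linked for c in candidates],
        }
    ).to_csv(path, sep="\t", index=False)


_IND_COLS = ["individual_id", "cohort", "stage", "sex", "age", "pcd", "handedness"]


def read_individuals(path: str | Path) -> list[Individual]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns) != _IND_COLS:
        raise ValueError(f"individual table must have columns {_IND_COLS}")
    inds = [
        Individual(
            individual_id=r.individual_id,
            cohort=r.cohort,
            stage=r.stage,
            sex=r.sex,
            age=float(r.age),
            pcd=str(r.pcd).lower() in {"true", "1", "yes"},
            handedness=r.handedness,
        )
        for r in df.itertuples(index=False)
    ]
    ids = [i.individual_id for i in inds]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate individual ids")
    return inds


def write_individuals(individuals: Sequence[Individual], path: str | Path) -> None:
    pd.DataFrame(
        [[i.individual_id, i.cohort, i.stage, i.sex, repr(i.age), i.pcd, i.handedness]
         for i in individuals],
        columns=_IND_COLS,
    ).to_csv(path, sep="\t", index=False)


_PHENO_NUMERIC = [
    "li_word", "li_praxis", "li_spatial", "li_face",
    "frontal_petalia", "frontal_bending", "occipital_petalia", "occipital_bending",
    "sinus_left", "sinus_right",
]


def read_phenotypes(path: str | Path, individuals: Sequence[Individual]) -> list[PhenotypeRecord]:
    """Read the phenotype TSV and validate ids against the cohort table.

    Missing numeric cells propagate as None; a non-numeric cell raises an
    error naming the offending row.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    known = {i.individual_id for i in individuals}
    records: list[PhenotypeRecord] = []
    for idx, row in df.iterrows():
        iid = row["individual_id"]
        if iid not in known:
            raise ValueError(f"phenotype row {idx}: unknown individual {iid!r}")
        values: dict[str, object] = {"individual_id": iid}
        for col in _PHENO_NUMERIC:
            raw = row.get(col)
            if raw is None or (isinstance(raw, float) and math.isnan(raw)) or raw == "":
                values[col] = None
                continue
            try:
                values[col] = float(raw)
            except ValueError:
                raise ValueError(f"phenotype row {idx} ({iid}): non-numeric {col}={raw!r}")
        raw_n = row.get("n_atypical")
        if raw_n is None or (isinstance(raw_n, float) and math.isnan(raw_n)) or raw_n == "":
            values["n_atypical"] = None
        else:
            values["n_atypical"] = int(float(raw_n))
        records.append(PhenotypeRecord(**values))  # type: ignore[arg-type]
    return records


def write_phenotypes(records: Sequence[PhenotypeRecord], path: str | Path) -> None:
    cols = ["individual_id"] + _PHENO_NUMERIC + ["n_atypical"]
    rows = []
    for r in records:
        row = [r.individual_id]
        for col in _PHENO_NUMERIC:
            v = getattr(r, col)
            row.append("" if v is None else repr(v))
        row.append("" if r.n_atypical is None else str(r.n_atypical))
        rows.append(row)
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Genotype matrix (samples x variants, {0,1,2,NA})


def write_genotype_tsv(calls: pd.DataFrame, path: str | Path) -> None:
    """Write a samples x variants dosage matrix; missing dosages as NA."""
    out = calls.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", na_rep="NA", float_format="%.0f")


def read_genotype_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="sample_id", na_values=["NA"])
    bad = ~(df.isin([0, 1, 2]) | df.isna())
    if bad.to_numpy().any():
        raise ValueError("genotype dosages must be 0, 1, 2 or NA")
    return df.astype(float)


# ---------------------------------------------------------------------------
# Reports


def write_report(calls, summary: Mapping, out_dir: str | Path, stats: Mapping | None = None) -> None:
    """Write the per-individual calls TSV and a JSON summary.

    Output is byte-stable for fixed inputs: calls are sorted by individual
    id and JSON keys are sorted.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for c in sorted(calls, key=lambda c: c.individual_id):
        rows.append(
            [
                c.individual_id,
                c.status,
                c.assigned_gene or "",
                c.model or "",
                ";".join(c.notable_genes),
                c.tie_flag,
            ]
        )
    pd.DataFrame(
        rows,
        columns=["individual_id", "status", "assigned_gene", "model", "notable_genes", "tie_flag"],
    ).to_csv(out_dir / "calls.tsv", sep="\t", index=False)

    payload = {"summary": dict(summary)}
    if stats is not None:
        payload["statistics"] = stats
    with open(out_dir / "report.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
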